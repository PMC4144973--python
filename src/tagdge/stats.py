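"""Two-library differential expression by the Audic-Claverie count test.

For a gene observed x times among n1 clean tags in one library and y times
among n2 in the other, the test conditions on x and asks how surprising y
is under equal underlying abundance. The conditional point mass is

    p(y | x) = (n2/n1)^y * (x+y)! / (x! * y! * (1 + n2/n1)^(x+y+1)),

which is exactly the negative binomial NB(r = x+1, p = n1/(n1+n2)) over y.
Both tails are therefore regularized incomplete beta functions, evaluated
directly (never as one-minus-the-other) so the statistic stays accurate for
counts up to 1e6 and totals up to 1e8. The two-sided p-value is the doubled
smaller tail, capped at 1.

Calling follows the study's rules: genes under a 10-TPM floor in both
libraries are excluded, zero counts are replaced by a default of one before
the TPM-scale log2 ratio, and a gene is called up/down when the adjusted
p-value passes the FDR ceiling, the raw p-value passes its own ceiling, and
|log2 ratio| >= 1 (a second, twofold tier is flagged at |log2 ratio| >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def tpm(count: int, clean_total: int) -> float:
    """Tags per million clean tags: count / clean_total * 1e6."""
    if clean_total < 1:
        raise ValueError("clean_total must be >= 1")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / clean_total * 1e6


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value; accepts scalars or arrays."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("library totals must be >= 1")
    q1 = n1 / (n1 + n2)
    q2 = n2 / (n1 + n2)
    lower = special.betainc(x + 1.0, y + 1.0, q1)  # P(Y <= y)
    # P(Y >= y); for y = 0 the upper tail is the whole distribution
    upper = np.where(y > 0, special.betainc(np.maximum(y, 1.0), x + 1.0, q2), 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def adjust(p_values, method: str = "bh"):
    """Multiple-testing adjustment: 'bonferroni' (min(1, m*p)) or 'bh' step-up."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(ADJUST_METHODS)}")
    return multipletests(p, method=ADJUST_METHODS[method])[1]


@dataclass(frozen=True)
class DegThresholds:
    """The study's DEG thresholds.

    min_tpm: genes below this TPM in both libraries are excluded.
    log2_tier1 / log2_tier2: |log2 ratio| floors for calling / the
        twofold tier.
    fdr_max: ceiling on the adjusted p-value.
    p_max: ceiling on the raw p-value (applied conjointly with fdr_max).
    zero_default: count substituted for zero before the ratio.
    """

    min_tpm: float = 10.0
    log2_tier1: float = 1.0
    log2_tier2: float = 2.0
    fdr_max: float = 0.001
    p_max: float = 1e-4
    zero_default: int = 1

    def __post_init__(self):
        if min(self.min_tpm, self.log2_tier1, self.log2_tier2, self.fdr_max, self.p_max) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.zero_default <= 0:
            raise ValueError("zero_default must be positive")
        if self.log2_tier2 < self.log2_tier1:
            raise ValueError("log2_tier2 must be >= log2_tier1")


@dataclass(frozen=True)
class DegRecord:
    """Per-gene test outcome for one control-vs-treatment library pair."""

    gene_id: str
    x: int  # count in the control (exposure) library
    y: int  # count in the treatment (exclusion) library
    n1: int
    n2: int
    log2_ratio: float  # treatment over control, TPM scale, zero-default applied
    p_value: float
    q_value: float
    call: str  # up / down / unchanged
    tier: str  # none / tier1 / tier2


def call_degs(
    control,
    treatment,
    thresholds: DegThresholds | None = None,
    method: str = "bh",
) -> list[DegRecord]:
    """Call DEGs (treatment relative to control) for a shared gene universe.

    ``control`` and ``treatment`` are GeneCountTable-like objects exposing
    ``counts`` (gene -> int), ``tpm`` (gene -> float) and
    ``clean_tag_total``. Records are emitted only for genes surviving the
    TPM floor; the adjustment is computed over that surviving set.
    """
    if thresholds is None:
        thresholds = DegThresholds()
    n1 = control.clean_tag_total
    n2 = treatment.clean_tag_total
    if n1 <= 0 or n2 <= 0:
        raise ValueError("clean-tag totals must be positive")
    if set(control.counts) != set(treatment.counts):
        raise ValueError("control and treatment tables cover different gene sets")

    genes = [
        g
        for g in control.counts
        if control.tpm[g] >= thresholds.min_tpm or treatment.tpm[g] >= thresholds.min_tpm
    ]
    if not genes:
        return []
    x = np.array([control.counts[g] for g in genes], dtype=np.int64)
    y = np.array([treatment.counts[g] for g in genes], dtype=np.int64)

    xz = np.maximum(x, thresholds.zero_default * (x == 0))
    yz = np.maximum(y, thresholds.zero_default * (y == 0))
    log2_ratio = np.log2((yz / n2) / (xz / n1))

    p = np.atleast_1d(ac_pvalue(x, y, n1, n2))
    q = adjust(p, method=method)

    records = []
    for i, g in enumerate(genes):
        significant = q[i] <= thresholds.fdr_max and p[i] <= thresholds.p_max
        lr = float(log2_ratio[i])
        if significant and abs(lr) >= thresholds.log2_tier1:
            call = "up" if lr > 0 else "down"
            tier = "tier2" if abs(lr) >= thresholds.log2_tier2 else "tier1"
        else:
            call, tier = "unchanged", "none"
        records.append(
            DegRecord(
                gene_id=g,
                x=int(x[i]),
                y=int(y[i]),
                n1=n1,
                n2=n2,
                log2_ratio=lr,
                p_value=float(p[i]),
                q_value=float(q[i]),
                call=call,
                tier=tier,
            )
        )
    return records
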