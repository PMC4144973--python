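"""Relative qPCR quantification (2^-ddCt) and digital-vs-qPCR concordance.

ddCt = (Ct_target,treatment - Ct_reference,treatment)
     - (Ct_target,control  - Ct_reference,control);
fold change = 2^-ddCt, treatment relative to control. Fold changes are
compared against digital (tag-count) fold changes in the signed-integer
convention common in expression tables: +f means f-fold up, -f means f-fold
down (signed_fold(0.125) = -8). A target that fails to amplify is carried
as the ``ND`` sentinel and, under the default policy, treated as strong
down-regulation when scoring sign concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class _NotDetected:
    """Sentinel for a transcript undetectable by qPCR."""

    def __repr__(self):
        return "ND"


ND = _NotDetected()


@dataclass(frozen=True)
class CtMeasurement:
    """Threshold cycles for target and reference genes in both conditions.

    A missing (not-detected) Ct is represented by None.
    """

    gene_id: str
    ct_target_treatment: float | None
    ct_reference_treatment: float | None
    ct_target_control: float | None
    ct_reference_control: float | None
    replicate_id: int = 0

    def __post_init__(self):
        for name in (
            "ct_target_treatment",
            "ct_reference_treatment",
            "ct_target_control",
            "ct_reference_control",
        ):
            value = getattr(self, name)
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, or None (not detected)")


def ddct_fold_change(m: CtMeasurement):
    """2^-ddCt fold change (treatment over control), or ND if any Ct is missing."""
    cts = (
        m.ct_target_treatment,
        m.ct_reference_treatment,
        m.ct_target_control,
        m.ct_reference_control,
    )
    if any(ct is None for ct in cts):
        return ND
    ddct = (m.ct_target_treatment - m.ct_reference_treatment) - (
        m.ct_target_control - m.ct_reference_control
    )
    return 2.0 ** (-ddct)


def average_replicates(measurements: list[CtMeasurement]) -> CtMeasurement:
    """Average replicate Ct values on the Ct scale before computing ddCt.

    A field that is not detected in any replicate propagates as None.
    """
    if not measurements:
        raise ValueError("no measurements to average")
    gene_ids = {m.gene_id for m in measurements}
    if len(gene_ids) != 1:
        raise ValueError(f"replicates mix gene_ids: {sorted(gene_ids)}")

    def mean_or_none(values):
        if any(v is None for v in values):
            return None
        return sum(values) / len(values)

    return CtMeasurement(
        gene_id=measurements[0].gene_id,
        ct_target_treatment=mean_or_none([m.ct_target_treatment for m in measurements]),
        ct_reference_treatment=mean_or_none([m.ct_reference_treatment for m in measurements]),
        ct_target_control=mean_or_none([m.ct_target_control for m in measurements]),
        ct_reference_control=mean_or_none([m.ct_reference_control for m in measurements]),
    )


def signed_fold(fold_change: float) -> float:
    """Signed-integer fold convention: fc if fc >= 1 else -1/fc."""
    if fold_change is ND:
        return ND
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    return fold_change if fold_change >= 1.0 else -1.0 / fold_change


def _sign(value) -> int:
    value = float(value)
    return (value > 0) - (value < 0)


def concordance(
    digital_fc: dict[str, float],
    qpcr_fc: dict[str, float],
    nd_as_down: bool = True,
) -> dict[str, float]:
    """Sign agreement between digital and qPCR signed fold changes.

    Genes are compared when numeric in both platforms; an ND qPCR value is
    treated as strong down-regulation (sign -1) when ``nd_as_down`` is on,
    and excluded otherwise. Returns n_compared, n_sign_agree, and
    agreement_fraction.
    """
    shared = sorted(set(digital_fc) & set(qpcr_fc))
    if not shared:
        raise ValueError("no overlapping genes between digital and qPCR fold changes")
    n_compared = 0
    n_agree = 0
    for gene in shared:
        d, q = digital_fc[gene], qpcr_fc[gene]
        if d is ND:
            continue
        if q is ND:
            if not nd_as_down:
                continue
            q_sign = -1
        else:
            q_sign = _sign(q)
        n_compared += 1
        if _sign(d) == q_sign:
            n_agree += 1
    return {
        "n_compared": n_compared,
        "n_sign_agree": n_agree,
        "agreement_fraction": n_agree / n_compared if n_compared else float("nan"),
    }
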