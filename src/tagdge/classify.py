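"""Nine-way cross-cultivar response classification, clustering, bin tables.

Each gene carries one of nine mutually exclusive labels built from its
(up/down/unchanged) calls in the two cultivars' exclusion-vs-exposure
contrasts: concordant (Xup-Yup, Xdown-Ydown), single-cultivar (Xup, Xdown,
Yup, Ydown), discordant (Xup-Ydown, Xdown-Yup), or unchanged. Per-cultivar
totals reconstruct from the category counts by simple bookkeeping, e.g.
total up-regulated in X = Xup + Xup-Yup + Xup-Ydown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tagdge.stats import DegRecord

logger = logging.getLogger(__name__)

REGULATED_LABELS = (
    "Xup-Yup",
    "Xdown-Ydown",
    "Xup",
    "Xdown",
    "Yup",
    "Ydown",
    "Xup-Ydown",
    "Xdown-Yup",
)
RESPONSE_LABELS = REGULATED_LABELS + ("unchanged",)

_PAIR_TO_LABEL = {
    ("up", "up"): "Xup-Yup",
    ("down", "down"): "Xdown-Ydown",
    ("up", "unchanged"): "Xup",
    ("down", "unchanged"): "Xdown",
    ("unchanged", "up"): "Yup",
    ("unchanged", "down"): "Ydown",
    ("up", "down"): "Xup-Ydown",
    ("down", "up"): "Xdown-Yup",
    ("unchanged", "unchanged"): "unchanged",
}


def _call_at_tier(record: DegRecord | None, tier: str) -> str:
    if record is None or record.call == "unchanged":
        return "unchanged"
    if tier == "tier2" and record.tier != "tier2":
        return "unchanged"
    return record.call


def classify_response(
    deg_x: dict[str, DegRecord],
    deg_y: dict[str, DegRecord],
    tier: str = "tier1",
) -> dict[str, str]:
    """Label every gene in the union of both cultivars' record sets.

    A gene missing from one cultivar (e.g. filtered by the TPM floor there)
    is treated as unchanged in that cultivar, so the labels partition the
    whole universe. ``tier='tier2'`` restricts calls to the twofold tier.
    """
    if tier not in ("tier1", "tier2"):
        raise ValueError("tier must be 'tier1' or 'tier2'")
    universe = set(deg_x) | set(deg_y)
    return {
        g: _PAIR_TO_LABEL[(_call_at_tier(deg_x.get(g), tier), _call_at_tier(deg_y.get(g), tier))]
        for g in universe
    }


def venn_counts(categories: dict[str, str]) -> dict[str, int]:
    """Gene counts per response label (all nine labels always present)."""
    counts = dict.fromkeys(RESPONSE_LABELS, 0)
    for label in categories.values():
        counts[label] += 1
    return counts


def cultivar_totals(counts: dict[str, int]) -> dict[str, float]:
    """Per-cultivar regulation totals and percentages from category counts.

    The bookkeeping identities of the two-circle-per-cultivar diagram:
    a cultivar's up-regulated total is the sum of every category in which
    it is up, regardless of the other cultivar's state.
    """
    c = {label: counts.get(label, 0) for label in REGULATED_LABELS}
    x_up = c["Xup"] + c["Xup-Yup"] + c["Xup-Ydown"]
    x_down = c["Xdown"] + c["Xdown-Ydown"] + c["Xdown-Yup"]
    y_up = c["Yup"] + c["Xup-Yup"] + c["Xdown-Yup"]
    y_down = c["Ydown"] + c["Xdown-Ydown"] + c["Xup-Ydown"]
    totals = {
        "x_up": x_up,
        "x_down": x_down,
        "x_total": x_up + x_down,
        "y_up": y_up,
        "y_down": y_down,
        "y_total": y_up + y_down,
    }
    for cultivar in ("x", "y"):
        total = totals[f"{cultivar}_total"]
        for direction in ("up", "down"):
            totals[f"{cultivar}_{direction}_percent"] = (
                100.0 * totals[f"{cultivar}_{direction}"] / total if total else float("nan")
            )
    return totals


@dataclass(frozen=True)
class LinkageStep:
    """One agglomerative merge: the pair of cluster ids and its height.

    Cluster ids follow the usual convention: 0..n-1 are the input rows and
    the cluster created by step k gets id n+k.
    """

    merged_pair: tuple[int, int]
    height: float
    size: int


def cluster_ratios(ratio_matrix) -> list[LinkageStep]:
    """Average-linkage (UPGMA) hierarchical clustering under Euclidean distance.

    Implemented with the Lance-Williams update; among equally distant pairs
    the lexicographically smallest (i, j) cluster-id pair merges first, so
    the merge sequence is fully deterministic. Heights are non-decreasing
    (average linkage is reducible).
    """
    X = np.asarray(ratio_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratio matrix contains non-finite values")

    n = X.shape[0]
    # full distance matrix padded for the n-1 merged clusters
    m = 2 * n - 1
    D = np.full((m, m), np.inf)
    diff = X[:, None, :] - X[None, :, :]
    D[:n, :n] = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, np.inf)

    active = np.zeros(m, dtype=bool)
    active[:n] = True
    sizes = np.zeros(m, dtype=np.int64)
    sizes[:n] = 1

    steps: list[LinkageStep] = []
    for k in range(n - 1):
        idx = np.flatnonzero(active)
        sub = D[np.ix_(idx, idx)]
        # lexicographically smallest (i, j) among minima: scan upper triangle
        # in row-major order via argmin on the masked matrix
        iu = np.triu_indices(len(idx), k=1)
        dists = sub[iu]
        best = np.argmin(dists)  # argmin returns the first (lowest-pair) minimum
        height = float(dists[best])
        i, j = int(idx[iu[0][best]]), int(idx[iu[1][best]])

        new = n + k
        ni, nj = sizes[i], sizes[j]
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        D[new, others] = (ni * D[i, others] + nj * D[j, others]) / (ni + nj)
        D[others, new] = D[new, others]
        active[i] = active[j] = False
        active[new] = True
        sizes[new] = ni + nj
        steps.append(LinkageStep(merged_pair=(i, j), height=height, size=int(ni + nj)))
    return steps


@dataclass(frozen=True)
class BinAnnotation:
    """A functional bin: hierarchical dotted code, name, and member genes."""

    bin_id: str
    bin_name: str
    gene_ids: frozenset[str]


def bin_summary(
    categories: dict[str, str],
    bins: list[BinAnnotation],
) -> pd.DataFrame:
    """Cross-tabulate response categories against functional bins.

    One row per bin, one column per regulated label plus a recomputed Total;
    a gene in several bins is counted once in each. Genes referenced by a
    bin but absent from the classification are skipped with a warning.
    """
    seen = set()
    rows = []
    for b in bins:
        if b.bin_id in seen:
            raise ValueError(f"duplicate bin_id {b.bin_id!r}")
        seen.add(b.bin_id)
        row = dict.fromkeys(REGULATED_LABELS, 0)
        for gene in sorted(b.gene_ids):
            if gene not in categories:
                logger.warning("bin %s references unknown gene %s; skipped", b.bin_id, gene)
                continue
            label = categories[gene]
            if label != "unchanged":
                row[label] += 1
        row["Total"] = sum(row[label] for label in REGULATED_LABELS)
        rows.append({"bin_id": b.bin_id, "bin_name": b.bin_name, **row})
    return pd.DataFrame(rows, columns=["bin_id", "bin_name", *REGULATED_LABELS, "Total"])
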