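"""Tag cleaning, copy-number profiling, and sequencing-saturation curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from tagdge.simulate import ANCHOR, TAG_LENGTH, TagLibrary, _BASE_SET

# closed integer copy-number intervals; the last bin is open-ended (>100)
COPY_NUMBER_BINS: tuple[tuple[int, float], ...] = (
    (1, 1),
    (2, 5),
    (6, 10),
    (11, 20),
    (21, 50),
    (51, 100),
    (101, float("inf")),
)

BIN_LABELS = ("1", "2-5", "6-10", "11-20", "21-50", "51-100", ">100")


@dataclass(frozen=True)
class CopyNumberProfile:
    """Distinct-tag counts per copy-number bin; bins partition the tags."""

    bin_counts: dict[str, int]

    @property
    def n_distinct(self) -> int:
        return sum(self.bin_counts.values())


@dataclass(frozen=True)
class SaturationCurve:
    """Distinct genes (or tags) detected at increasing subsampled depths."""

    depths: tuple[int, ...]
    detected: tuple[int, ...]
    mode: str


def clean_tags(raw_tags: Iterable[tuple[str, int]], sample_id: str = "sample") -> TagLibrary:
    """Filter raw (tag, count) pairs down to clean tags.

    Removes tags with ambiguous/non-ACGT characters, tags not exactly 21 nt,
    and tags lacking the CATG anchor; duplicate rows for the same tag are
    aggregated. Empty input yields an empty library.
    """
    counts: dict[str, int] = {}
    for tag, count in raw_tags:
        count = int(count)
        if count <= 0:
            raise ValueError(f"non-positive count {count} for tag {tag!r}")
        if len(tag) != TAG_LENGTH:
            continue
        if not tag.startswith(ANCHOR):
            continue
        if not _BASE_SET.issuperset(tag):
            continue
        counts[tag] = counts.get(tag, 0) + count
    return TagLibrary(sample_id=sample_id, tag_counts=counts)


def copy_number_profile(lib: TagLibrary) -> CopyNumberProfile:
    """Bin each distinct tag by its copy number (count)."""
    bins = dict.fromkeys(BIN_LABELS, 0)
    for count in lib.tag_counts.values():
        for (lo, hi), label in zip(COPY_NUMBER_BINS, BIN_LABELS):
            if lo <= count <= hi:
                bins[label] += 1
                break
    return CopyNumberProfile(bin_counts=bins)


def saturation_curve(
    lib: TagLibrary,
    mapping_index=None,
    step: int = 100_000,
    mode: str = "genes",
    seed: int = 0,
) -> SaturationCurve:
    """Detected distinct genes (or tags) as a function of sequencing depth.

    Subsamples tags without replacement via a random permutation of the
    expanded tag multiset, evaluating detection at depths step, 2*step, ...
    and finally the full library depth. In ``genes`` mode a tag contributes
    the gene it resolves to through ``mapping_index`` (exact first, then
    unambiguous 1-mismatch); unresolved tags contribute nothing.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if mode not in ("genes", "tags"):
        raise ValueError("mode must be 'genes' or 'tags'")
    if mode == "genes" and mapping_index is None:
        raise ValueError("mode='genes' requires a mapping index")

    distinct = list(lib.tag_counts)
    counts = np.array([lib.tag_counts[t] for t in distinct], dtype=np.int64)
    total = int(counts.sum())

    if mode == "genes":
        from tagdge.mapping import resolve_tag

        # unit id per distinct tag: resolved gene (shared by synonymous tags)
        # or -1 for tags that do not resolve to a single gene
        gene_ids: dict[str, int] = {}
        unit = np.empty(len(distinct), dtype=np.int64)
        for i, tag in enumerate(distinct):
            gene, _ = resolve_tag(tag, mapping_index)
            unit[i] = gene_ids.setdefault(gene, len(gene_ids)) if gene is not None else -1
    else:
        unit = np.arange(len(distinct), dtype=np.int64)

    rng = np.random.default_rng(seed)
    expanded = np.repeat(unit, counts)
    rng.shuffle(expanded)

    depths = list(range(step, total + 1, step))
    if not depths or depths[-1] != total:
        depths.append(total)

    # first-occurrence position of each unit in the shuffled stream
    valid = expanded >= 0
    positions = np.flatnonzero(valid)
    units = expanded[valid]
    _, first_idx = np.unique(units, return_index=True)
    first_pos = np.sort(positions[first_idx])

    detected = tuple(int(np.searchsorted(first_pos, d, side="left")) for d in depths)
    return SaturationCurve(depths=tuple(depths), detected=detected, mode=mode)
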