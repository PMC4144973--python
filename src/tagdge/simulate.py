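"""Synthetic transcriptomes and DGE tag libraries with known truth.

The simulator emulates the tag-library chemistry: each transcript
contributes the 21-nt tag anchored at its 3'-most NlaIII site (CATG) with
at least 17 nt downstream (the MmeI cut releases CATG + 17 nt). Libraries
are multinomial samples over genes' canonical tags, with an optional
single-substitution error process confined to the 17-nt suffix so every
erroneous tag sits at Hamming distance 1 from its source.

Expression truth is a two-cultivar (X, Y) by two-condition
(exposure/exclusion) layout: baseline per-gene tag fractions are drawn
log-normal (long-tailed, mimicking realistic copy-number spectra) and a
configurable fraction of genes per cultivar receives a 2^(+-effect) fold
change in the exclusion condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAG_LENGTH = 21
ANCHOR = "CATG"
SUFFIX_LENGTH = TAG_LENGTH - len(ANCHOR)  # 17
_BASES = "ACGT"
_BASE_SET = frozenset(_BASES)

CULTIVARS = ("X", "Y")
CONDITIONS = ("exposure", "exclusion")


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside A/C/G/T."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One synthetic transcript (3' portion relevant to tag extraction)."""

    gene_id: str
    sequence: str
    has_poly_a: bool = True


@dataclass(frozen=True)
class TagLibrary:
    """One sample's multiset of 21-nt tags.

    ``clean_tag_total`` always equals the sum of ``tag_counts`` values; it
    is the TPM denominator downstream.
    """

    sample_id: str
    tag_counts: dict[str, int]
    clean_tag_total: int = field(default=-1)

    def __post_init__(self):
        total = sum(self.tag_counts.values())
        if self.clean_tag_total == -1:
            object.__setattr__(self, "clean_tag_total", total)
        elif self.clean_tag_total != total:
            raise ValueError(
                f"clean_tag_total={self.clean_tag_total} does not match "
                f"sum of tag counts ({total})"
            )

    @property
    def n_distinct(self) -> int:
        return len(self.tag_counts)


class ExpressionTruth:
    """Ground-truth expression for a 2 cultivars x 2 conditions design.

    Stores the baseline (exposure) tag fraction per gene and the true log2
    fold change (exclusion over exposure) per cultivar; per-library expected
    fractions are renormalized to sum to one.
    """

    def __init__(self, table: pd.DataFrame, effect_log2fc: float):
        required = {"baseline", "log2fc_X", "log2fc_Y", "is_de_X", "is_de_Y"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        self.table = table
        self.effect_log2fc = float(effect_log2fc)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def log2fc(self, cultivar: str) -> pd.Series:
        return self.table[f"log2fc_{cultivar}"]

    def is_de(self, cultivar: str) -> pd.Series:
        return self.table[f"is_de_{cultivar}"]

    def mean_expression(self, cultivar: str = "X", condition: str = "exposure") -> pd.Series:
        """Expected per-gene tag fraction for one library (sums to 1)."""
        if cultivar not in CULTIVARS:
            raise ValueError(f"unknown cultivar {cultivar!r}; expected one of {CULTIVARS}")
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        w = self.table["baseline"].to_numpy(dtype=float)
        if condition == "exclusion":
            w = w * np.exp2(self.table[f"log2fc_{cultivar}"].to_numpy(dtype=float))
        w = w / w.sum()
        return pd.Series(w, index=self.table.index, name=f"{cultivar}_{condition}")

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _validate_sequence(sequence: str) -> None:
    if not _BASE_SET.issuperset(sequence):
        bad = sorted(set(sequence) - _BASE_SET)
        raise InvalidSequenceError(f"sequence contains non-A/C/G/T characters: {bad}")


def digest_transcript(sequence: str) -> str:
    """Extract the canonical 21-nt tag from a transcript sequence.

    Returns CATG plus the 17 nt immediately 3' of the 3'-most CATG that has
    at least 17 nt downstream, mirroring the NlaIII digest followed by the
    MmeI cut 17 bp downstream of the recognition site. Returns the empty
    string when no qualifying site exists.
    """
    _validate_sequence(sequence)
    if len(sequence) < TAG_LENGTH:
        return ""
    # rightmost CATG whose start is <= len-21 so a full 21-nt tag fits
    i = sequence.rfind(ANCHOR, 0, len(sequence) - SUFFIX_LENGTH)
    if i < 0:
        return ""
    return sequence[i : i + TAG_LENGTH]


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (200, 2000),
    seed: int = 0,
    poly_a_fraction: float = 0.9,
) -> list[TranscriptRecord]:
    """Generate random transcripts, each guaranteed one qualifying CATG site.

    Sequences are uniform random over A/C/G/T; if no CATG with >=17 nt
    downstream arises by chance, one is planted 21 nt from the 3' end so
    every gene yields a canonical tag. Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 25:
        raise ValueError("length_range lower bound must be >= 25 (CATG + 17 nt + margin)")
    if hi < lo:
        raise ValueError("length_range upper bound below lower bound")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    records = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        if not digest_transcript(seq):
            pos = length - TAG_LENGTH
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR) :]
        records.append(
            TranscriptRecord(
                gene_id=f"gene_{i:0{width}d}",
                sequence=seq,
                has_poly_a=bool(rng.random() < poly_a_fraction),
            )
        )
    return records


def simulate_expression(
    transcriptome: list[TranscriptRecord],
    de_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    sigma: float = 1.5,
    min_fraction: float = 0.0,
    seed: int = 0,
) -> ExpressionTruth:
    """Assign baseline expression and per-cultivar differential effects.

    Baseline fractions are log-normal with shape ``sigma`` (default 1.5, a
    long-tailed copy-number spectrum). Independently per cultivar, a
    ``de_fraction`` of genes has its exclusion-condition mean multiplied by
    2^(+-effect_log2fc) with random sign. ``min_fraction`` floors the
    normalized baseline fraction (useful to guarantee a minimum expected
    count at a given depth).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be non-negative")
    n = len(transcriptome)
    if n == 0:
        raise ValueError("transcriptome is empty")
    rng = np.random.default_rng(seed)
    baseline = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    baseline /= baseline.sum()
    if min_fraction > 0:
        baseline = np.maximum(baseline, min_fraction)
        baseline /= baseline.sum()

    n_de = int(round(de_fraction * n))
    data = {"baseline": baseline}
    for cultivar in CULTIVARS:
        fc = np.zeros(n)
        if n_de > 0 and effect_log2fc > 0:
            idx = rng.choice(n, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            fc[idx] = signs * effect_log2fc
        data[f"log2fc_{cultivar}"] = fc
        data[f"is_de_{cultivar}"] = np.abs(fc) >= effect_log2fc if effect_log2fc > 0 else np.zeros(n, bool)
    table = pd.DataFrame(data, index=pd.Index([t.gene_id for t in transcriptome], name="gene_id"))
    return ExpressionTruth(table, effect_log2fc)


def _mutate_suffix(tag: str, slot: int) -> str:
    """Apply the ``slot``-th of the 51 single substitutions to the suffix."""
    pos, alt = divmod(slot, 3)
    pos += len(ANCHOR)
    original = tag[pos]
    replacement = [b for b in _BASES if b != original][alt]
    return tag[:pos] + replacement + tag[pos + 1 :]


def simulate_tag_library(
    transcriptome: list[TranscriptRecord],
    truth: ExpressionTruth,
    depth: int = 1_000_000,
    error_rate: float = 0.01,
    seed: int = 0,
    cultivar: str = "X",
    condition: str = "exposure",
    sample_id: str | None = None,
) -> TagLibrary:
    """Sample one tag library of ``depth`` clean tags.

    Tags are drawn multinomially over genes' canonical tags proportional to
    the library's expected fractions; each tag independently receives one
    uniform substitution in its 17-nt suffix with probability ``error_rate``
    (the CATG anchor is structural and never mutated). Genes lacking a
    qualifying CATG site are excluded from sampling with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    fractions = truth.mean_expression(cultivar, condition)

    tags, weights = [], []
    for t in transcriptome:
        tag = digest_transcript(t.sequence)
        if not tag:
            logger.warning("gene %s has no qualifying CATG site; excluded from sampling", t.gene_id)
            continue
        tags.append(tag)
        weights.append(fractions[t.gene_id])
    if not tags:
        raise ValueError("no transcript yields a qualifying tag")
    p = np.asarray(weights, dtype=float)
    p /= p.sum()

    rng = np.random.default_rng(seed)
    gene_counts = rng.multinomial(depth, p)

    counts: dict[str, int] = {}
    n_variants = SUFFIX_LENGTH * 3
    for tag, count in zip(tags, gene_counts):
        if count == 0:
            continue
        n_err = rng.binomial(count, error_rate) if error_rate > 0 else 0
        if count - n_err > 0:
            counts[tag] = counts.get(tag, 0) + int(count - n_err)
        if n_err > 0:
            variant_counts = rng.multinomial(n_err, np.full(n_variants, 1.0 / n_variants))
            for slot in np.flatnonzero(variant_counts):
                variant = _mutate_suffix(tag, int(slot))
                counts[variant] = counts.get(variant, 0) + int(variant_counts[slot])
    if sample_id is None:
        sample_id = f"{cultivar}_{condition}"
    return TagLibrary(sample_id=sample_id, tag_counts=counts)
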