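"""Tag-to-gene mapping with perfect or single-mismatch homology.

Each gene is indexed by its canonical tag (the 3'-most CATG + 17 nt).
A library tag is resolved in tiered priority: exact hash hit first, then the
set of genes whose canonical tag lies at Hamming distance 1 (mismatches in
the structural CATG anchor are not considered). A tag whose best tier hits
more than one gene is conservatively discarded into ``ambiguous_count``;
a tag hitting nothing goes to ``unmapped_count``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from tagdge.simulate import (
    ANCHOR,
    SUFFIX_LENGTH,
    TagLibrary,
    TranscriptRecord,
    _mutate_suffix,
    digest_transcript,
)
from tagdge.stats import tpm as _tpm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagIndex:
    """Forward (gene -> canonical tag) and reverse (tag -> genes) lookup."""

    canonical_tag_by_gene: dict[str, str]
    genes_by_tag: dict[str, frozenset[str]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.canonical_tag_by_gene)


@dataclass(frozen=True)
class GeneCountTable:
    """Per-gene raw counts and TPM for one library after mapping.

    Invariant: sum(counts) + unmapped_count + ambiguous_count equals
    clean_tag_total, and tpm[g] = counts[g] / clean_tag_total * 1e6.
    """

    sample_id: str
    counts: dict[str, int]
    clean_tag_total: int
    unmapped_count: int = 0
    ambiguous_count: int = 0
    tpm: dict[str, float] = field(default=None)

    def __post_init__(self):
        if self.tpm is None:
            object.__setattr__(
                self,
                "tpm",
                {g: _tpm(c, self.clean_tag_total) for g, c in self.counts.items()},
            )
        mapped = sum(self.counts.values())
        if mapped + self.unmapped_count + self.ambiguous_count != self.clean_tag_total:
            raise ValueError(
                "count conservation violated: "
                f"{mapped} mapped + {self.unmapped_count} unmapped + "
                f"{self.ambiguous_count} ambiguous != {self.clean_tag_total} total"
            )


def build_tag_index(transcriptome: list[TranscriptRecord]) -> TagIndex:
    """Index one canonical tag per gene; genes without a site are skipped."""
    if not transcriptome:
        raise ValueError("transcriptome is empty")
    forward: dict[str, str] = {}
    reverse: dict[str, set[str]] = {}
    for record in transcriptome:
        if record.gene_id in forward:
            raise ValueError(f"duplicate gene_id {record.gene_id!r}")
        tag = digest_transcript(record.sequence)
        if not tag:
            logger.warning("gene %s has no qualifying CATG site; not indexed", record.gene_id)
            continue
        forward[record.gene_id] = tag
        reverse.setdefault(tag, set()).add(record.gene_id)
    return TagIndex(
        canonical_tag_by_gene=forward,
        genes_by_tag={t: frozenset(g) for t, g in reverse.items()},
    )


def resolve_tag(
    tag: str, index: TagIndex, allow_mismatch: bool = True
) -> tuple[str | None, str]:
    """Resolve one tag to a gene.

    Returns (gene_id, "exact"|"mismatch") for an unambiguous hit,
    (None, "ambiguous") when the best tier hits several genes, and
    (None, "unmapped") when nothing is hit.
    """
    exact = index.genes_by_tag.get(tag)
    if exact:
        if len(exact) == 1:
            return next(iter(exact)), "exact"
        return None, "ambiguous"
    if allow_mismatch and len(tag) == len(ANCHOR) + SUFFIX_LENGTH and tag.startswith(ANCHOR):
        hits: set[str] = set()
        for slot in range(SUFFIX_LENGTH * 3):
            genes = index.genes_by_tag.get(_mutate_suffix(tag, slot))
            if genes:
                hits.update(genes)
        if len(hits) == 1:
            return next(iter(hits)), "mismatch"
        if hits:
            return None, "ambiguous"
    return None, "unmapped"


def map_tags(lib: TagLibrary, index: TagIndex, allow_mismatch: bool = True) -> GeneCountTable:
    """Map a clean tag library onto the gene index, producing counts and TPM."""
    counts = dict.fromkeys(index.canonical_tag_by_gene, 0)
    unmapped = 0
    ambiguous = 0
    for tag, count in lib.tag_counts.items():
        gene, status = resolve_tag(tag, index, allow_mismatch=allow_mismatch)
        if gene is not None:
            counts[gene] += count
        elif status == "ambiguous":
            ambiguous += count
        else:
            unmapped += count
    return GeneCountTable(
        sample_id=lib.sample_id,
        counts=counts,
        clean_tag_total=lib.clean_tag_total,
        unmapped_count=unmapped,
        ambiguous_count=ambiguous,
    )


def merge_replicate_counts(tables: list[GeneCountTable]) -> GeneCountTable:
    """Element-wise sum of replicate count tables; TPM recomputed from totals."""
    if not tables:
        raise ValueError("no tables to merge")
    universe = set(tables[0].counts)
    for t in tables[1:]:
        if set(t.counts) != universe:
            raise ValueError("replicate tables have mismatched gene sets")
    counts = {g: sum(t.counts[g] for t in tables) for g in tables[0].counts}
    return GeneCountTable(
        sample_id="+".join(t.sample_id for t in tables),
        counts=counts,
        clean_tag_total=sum(t.clean_tag_total for t in tables),
        unmapped_count=sum(t.unmapped_count for t in tables),
        ambiguous_count=sum(t.ambiguous_count for t in tables),
    )
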