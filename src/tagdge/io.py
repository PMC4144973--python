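"""File formats: FASTA transcriptomes; TSV tag, count, DEG, and Ct tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.classify import REGULATED_LABELS, BinAnnotation, LinkageStep
from tagdge.mapping import GeneCountTable
from tagdge.qpcr import ND
from tagdge.simulate import TagLibrary, TranscriptRecord
from tagdge.stats import DegRecord


def write_transcriptome_fasta(transcriptome: list[TranscriptRecord], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description=f"poly_a={t.has_poly_a}")
        for t in transcriptome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcriptome_fasta(path) -> list[TranscriptRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        has_poly_a = "poly_a=True" in rec.description
        out.append(TranscriptRecord(gene_id=rec.id, sequence=str(rec.seq).upper(), has_poly_a=has_poly_a))
    return out


def write_tag_library(lib: TagLibrary, path) -> None:
    df = pd.DataFrame(sorted(lib.tag_counts.items()), columns=["tag", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_tag_library(path, sample_id: str | None = None) -> TagLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    if sample_id is None:
        sample_id = Path(path).stem
    return TagLibrary(sample_id=sample_id, tag_counts=dict(zip(df["tag"], df["count"])))


def read_raw_tags(path) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return list(zip(df["tag"], df["count"]))


def write_count_table(table: GeneCountTable, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": sorted(table.counts),
            "count": [table.counts[g] for g in sorted(table.counts)],
            "tpm": [table.tpm[g] for g in sorted(table.counts)],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_deg_table(records: list[DegRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "count1": r.x,
            "count2": r.y,
            "tpm1": r.x / r.n1 * 1e6,
            "tpm2": r.y / r.n2 * 1e6,
            "log2_ratio": r.log2_ratio,
            "p": r.p_value,
            "q": r.q_value,
            "call": r.call,
            "tier": r.tier,
        }
        for r in sorted(records, key=lambda r: r.gene_id)
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "count1", "count2", "tpm1", "tpm2", "log2_ratio", "p", "q", "call", "tier"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_linkage_steps(steps: list[LinkageStep], path) -> None:
    pd.DataFrame(
        [
            {"step": i, "cluster_a": s.merged_pair[0], "cluster_b": s.merged_pair[1],
             "height": s.height, "size": s.size}
            for i, s in enumerate(steps)
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bin_annotations(path) -> list[BinAnnotation]:
    """Bin table TSV with columns bin_id, bin_name, gene_id (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bins = []
    for (bin_id, bin_name), group in df.groupby(["bin_id", "bin_name"], sort=True):
        bins.append(BinAnnotation(bin_id=bin_id, bin_name=bin_name, gene_ids=frozenset(group["gene_id"])))
    return bins


def _parse_fold(value):
    return ND if str(value).strip() == "ND" else float(value)


def load_validation_foldchanges() -> pd.DataFrame:
    """Packaged digital-vs-qPCR signed fold changes for 16 pathway genes.

    Published comparison table from the two-cultivar sunlight-exclusion
    experiment; 'ND' marks transcripts undetectable by qPCR.
    """
    with resources.files("tagdge.data").joinpath("validation_foldchanges.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("digital_x", "digital_y", "qpcr_x", "qpcr_y"):
        df[col] = df[col].map(_parse_fold)
    return df.set_index("gene_id")


def read_ct_table(path) -> pd.DataFrame:
    """Ct TSV: gene_id, replicate_id, ct_target_treatment, ct_reference_treatment,
    ct_target_control, ct_reference_control; empty/ND cells mean not detected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in df.columns:
        if col.startswith("ct_"):
            df[col] = df[col].map(
                lambda v: None if pd.isna(v) or str(v).strip() in ("", "ND") else float(v)
            )
    return df
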