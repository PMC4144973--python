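"""End-to-end pipeline: simulate -> clean -> map -> DEG -> classify -> report.

A single PipelineConfig (loadable from YAML) drives a fully reproducible
run over the 2 cultivars x 2 conditions design; every output is a
tab-delimited table plus a JSON manifest recording versions, seeds, and
every threshold actually applied.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import tagdge.io as tio
from tagdge.classify import classify_response, cluster_ratios, cultivar_totals, venn_counts
from tagdge.mapping import build_tag_index, map_tags
from tagdge.simulate import (
    CONDITIONS,
    CULTIVARS,
    generate_transcriptome,
    simulate_expression,
    simulate_tag_library,
)
from tagdge.stats import DegThresholds, call_degs
from tagdge.tagproc import clean_tags, copy_number_profile, saturation_curve


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic-study run."""

    seed: int = 0
    n_genes: int = 2000
    length_range: tuple[int, int] = (200, 2000)
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    sigma: float = 1.5
    min_fraction: float = 0.0
    depth: int = 1_000_000
    error_rate: float = 0.01
    adjust_method: str = "bh"
    allow_mismatch: bool = True
    saturation_step: int = 100_000
    thresholds: DegThresholds = field(default_factory=DegThresholds)
    outdir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = DegThresholds(**raw["thresholds"])
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(self.length_range)
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result bundle under config.outdir.

    Returns the in-memory bundle: transcriptome, truth, libraries, count
    tables, DEG records per cultivar, categories/venn/totals at both tiers,
    linkage steps over the twofold genes, and the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 2 + 4 + 4)

    transcriptome = generate_transcriptome(
        config.n_genes, config.length_range, seed=seeds[0]
    )
    truth = simulate_expression(
        transcriptome,
        de_fraction=config.de_fraction,
        effect_log2fc=config.effect_log2fc,
        sigma=config.sigma,
        min_fraction=config.min_fraction,
        seed=seeds[1],
    )
    tio.write_transcriptome_fasta(transcriptome, outdir / "transcriptome.fasta")
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", float_format="%.8g")

    index = build_tag_index(transcriptome)
    libraries = {}
    tables = {}
    samples = [(c, cond) for c in CULTIVARS for cond in CONDITIONS]
    for k, (cultivar, condition) in enumerate(samples):
        raw = simulate_tag_library(
            transcriptome,
            truth,
            depth=config.depth,
            error_rate=config.error_rate,
            seed=seeds[2 + k],
            cultivar=cultivar,
            condition=condition,
        )
        lib = clean_tags(raw.tag_counts.items(), sample_id=raw.sample_id)
        libraries[(cultivar, condition)] = lib
        tio.write_tag_library(lib, outdir / f"tags_{lib.sample_id}.tsv")

        profile = copy_number_profile(lib)
        with open(outdir / f"copy_number_{lib.sample_id}.tsv", "w") as fh:
            fh.write("bin\tdistinct_tags\n")
            for label, n in profile.bin_counts.items():
                fh.write(f"{label}\t{n}\n")

        curve = saturation_curve(
            lib, mapping_index=index, step=config.saturation_step, mode="genes",
            seed=seeds[6 + k],
        )
        with open(outdir / f"saturation_{lib.sample_id}.tsv", "w") as fh:
            fh.write("depth\tdetected_genes\n")
            for d, n in zip(curve.depths, curve.detected):
                fh.write(f"{d}\t{n}\n")

        table = map_tags(lib, index, allow_mismatch=config.allow_mismatch)
        tables[(cultivar, condition)] = table
        tio.write_count_table(table, outdir / f"counts_{lib.sample_id}.tsv")

    degs = {}
    for cultivar in CULTIVARS:
        records = call_degs(
            tables[(cultivar, "exposure")],
            tables[(cultivar, "exclusion")],
            thresholds=config.thresholds,
            method=config.adjust_method,
        )
        degs[cultivar] = {r.gene_id: r for r in records}
        tio.write_deg_table(records, outdir / f"deg_{cultivar}.tsv")

    bundle = {
        "transcriptome": transcriptome,
        "truth": truth,
        "index": index,
        "libraries": libraries,
        "tables": tables,
        "degs": degs,
    }

    for tier in ("tier1", "tier2"):
        categories = classify_response(degs["X"], degs["Y"], tier=tier)
        counts = venn_counts(categories)
        totals = cultivar_totals(counts)
        bundle[f"categories_{tier}"] = categories
        bundle[f"venn_{tier}"] = counts
        bundle[f"totals_{tier}"] = totals
        with open(outdir / f"venn_{tier}.tsv", "w") as fh:
            fh.write("label\tgenes\n")
            for label, n in counts.items():
                fh.write(f"{label}\t{n}\n")
        with open(outdir / f"cultivar_totals_{tier}.tsv", "w") as fh:
            fh.write("quantity\tvalue\n")
            for key, value in totals.items():
                fh.write(f"{key}\t{value:.6g}\n")

    # cluster the log2-ratio profiles of the twofold-regulated genes
    tier2_genes = sorted(
        g for g, label in bundle["categories_tier2"].items() if label != "unchanged"
    )
    if len(tier2_genes) >= 2:
        matrix = np.array(
            [
                [
                    degs["X"][g].log2_ratio if g in degs["X"] else 0.0,
                    degs["Y"][g].log2_ratio if g in degs["Y"] else 0.0,
                ]
                for g in tier2_genes
            ]
        )
        steps = cluster_ratios(matrix)
        bundle["linkage"] = steps
        tio.write_linkage_steps(steps, outdir / "linkage_tier2.tsv")

    manifest = {
        "package": "tagdge",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_tier2_regulated": len(tier2_genes),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
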