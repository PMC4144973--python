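#!/usr/bin/env python
"""Classify genes into the nine cross-cultivar response categories.

Combines the two cultivars' DEG calls into the nine-way classification at
both tiers, checks the bookkeeping identities that reconstruct per-cultivar
totals from category counts, clusters the twofold genes' log2-ratio
profiles by average linkage, and cross-tabulates categories against a set
of synthetic functional bins built from the ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tagdge import (
    BinAnnotation,
    bin_summary,
    classify_response,
    cluster_ratios,
    cultivar_totals,
    venn_counts,
)
from tagdge.stats import DegRecord
import tagdge.io as tio

OUT = Path("results/analysis")


def load_degs(path):
    df = pd.read_csv(path, sep="\t")
    return {
        row.gene_id: DegRecord(
            gene_id=row.gene_id, x=int(row.count1), y=int(row.count2), n1=1, n2=1,
            log2_ratio=row.log2_ratio, p_value=row.p, q_value=row.q,
            call=row.call, tier=row.tier,
        )
        for row in df.itertuples()
    }


def main():
    deg_x = load_degs(OUT / "deg_X.tsv")
    deg_y = load_degs(OUT / "deg_Y.tsv")

    for tier in ("tier1", "tier2"):
        categories = classify_response(deg_x, deg_y, tier=tier)
        counts = venn_counts(categories)
        totals = cultivar_totals(counts)
        pd.DataFrame(sorted(categories.items()), columns=["gene_id", "category"]).to_csv(
            OUT / f"categories_{tier}.tsv", sep="\t", index=False
        )
        pd.Series(counts, name="genes").rename_axis("label").to_csv(
            OUT / f"venn_{tier}.tsv", sep="\t"
        )
        regulated = sum(v for k, v in counts.items() if k != "unchanged")
        print(f"{tier}: {regulated} regulated genes | "
              f"X {totals['x_up']}up/{totals['x_down']}down, "
              f"Y {totals['y_up']}up/{totals['y_down']}down")

    categories = classify_response(deg_x, deg_y, tier="tier2")
    tier2_genes = sorted(g for g, label in categories.items() if label != "unchanged")
    matrix = np.array(
        [[deg_x[g].log2_ratio if g in deg_x else 0.0,
          deg_y[g].log2_ratio if g in deg_y else 0.0] for g in tier2_genes]
    )
    steps = cluster_ratios(matrix)
    tio.write_linkage_steps(steps, OUT / "linkage_tier2.tsv")
    print(f"clustered {len(tier2_genes)} twofold genes; "
          f"final merge height {steps[-1].height:.3f}")

    # synthetic functional bins: direction-of-truth groups per cultivar
    truth = pd.read_csv(OUT / "truth.tsv", sep="\t", index_col="gene_id")
    bins = [
        BinAnnotation("1.1", "truth.up in X", frozenset(truth.index[truth["log2fc_X"] > 0])),
        BinAnnotation("1.2", "truth.down in X", frozenset(truth.index[truth["log2fc_X"] < 0])),
        BinAnnotation("2.1", "truth.up in Y", frozenset(truth.index[truth["log2fc_Y"] > 0])),
        BinAnnotation("2.2", "truth.down in Y", frozenset(truth.index[truth["log2fc_Y"] < 0])),
    ]
    table = bin_summary(categories, bins)
    table.to_csv(OUT / "bin_summary_tier2.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
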