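"""Reference summary values from the two-cultivar sunlight-exclusion study.

Printed aggregate counts from the original grape berry-skin experiment
(cultivar X = 'Jingxiu', sunlight-dependent coloration; cultivar Y =
'Jingyan', sunlight-independent). The raw tag data were never deposited,
so these aggregates are the study-level inputs available for bookkeeping
validation: the nine-way category counts at the twofold tier, the tier-1
per-cultivar up/down totals, and the functional-bin cross-tabulation.
"""

from __future__ import annotations

# Twofold-tier (|log2 ratio| >= 2, P < 1e-4) response-category gene counts.
FIG1_TIER2_CATEGORY_COUNTS: dict[str, int] = {
    "Xup-Yup": 123,
    "Xdown-Ydown": 62,
    "Xup": 2383,
    "Xdown": 82,
    "Yup": 344,
    "Ydown": 172,
    "Xup-Ydown": 149,
    "Xdown-Yup": 61,
}

# Tier-1 (|log2 ratio| >= 1) per-cultivar up/down totals.
TIER1_UP_DOWN: dict[str, int] = {
    "x_up": 3254,
    "x_down": 388,
    "y_up": 959,
    "y_down": 747,
}

# Number of predicted genes in the reference grape genome annotation.
GENOME_GENE_COUNT = 26346

# Functional-bin cross-tabulation at the twofold tier (label -> gene count),
# with the totals as printed; blanks in the source table are zeros.
TABLE4_BIN_ROWS: list[dict] = [
    {"bin_id": "27.3.6", "bin_name": "RNA.regulation of transcription.bHLH family",
     "Xup": 10, "Xup-Yup": 1, "Xdown-Yup": 1, "Yup": 1, "printed_total": 13},
    {"bin_id": "27.3.25", "bin_name": "RNA.regulation of transcription.MYB domain family",
     "Xup": 12, "Xdown": 3, "Xdown-Yup": 2, "Xdown-Ydown": 2, "Yup": 7, "printed_total": 26},
    {"bin_id": "35.1", "bin_name": "not assigned.no ontology.WD40 repeat",
     "Xup": 10, "Xup-Yup": 1, "Yup": 3, "printed_total": 14},
    {"bin_id": "29.5.11.1", "bin_name": "protein.degradation.ubiquitin.ubiquitin",
     "Xup": 9, "Xdown-Yup": 1, "printed_total": 10},
    {"bin_id": "29.5.11.2", "bin_name": "protein.degradation.ubiquitin.E1",
     "Xup": 2, "printed_total": 2},
    {"bin_id": "29.5.11.3", "bin_name": "protein.degradation.ubiquitin.E2",
     "Xup": 20, "Xup-Yup": 3, "Yup": 1, "Ydown": 1, "printed_total": 25},
    {"bin_id": "29.5.11.4.1", "bin_name": "protein.degradation.ubiquitin.E3.HECT",
     "Xup": 3, "Xup-Yup": 1, "printed_total": 4},
    {"bin_id": "29.5.11.4.2", "bin_name": "protein.degradation.ubiquitin.E3.RING",
     "Xup": 65, "Xup-Yup": 2, "Xup-Ydown": 2, "Yup": 7, "Ydown": 4, "printed_total": 80},
    {"bin_id": "29.5.11.4.3.1", "bin_name": "protein.degradation.ubiquitin.E3.SCF.SKP",
     "Xup": 1, "printed_total": 1},
    {"bin_id": "29.5.11.4.3.2", "bin_name": "protein.degradation.ubiquitin.E3.SCF.FBOX",
     "Xup": 27, "Xup-Yup": 1, "Xup-Ydown": 3, "Xdown": 1, "Yup": 4, "Ydown": 1,
     "printed_total": 37},
    {"bin_id": "29.5.11.4.3.3", "bin_name": "protein.degradation.ubiquitin.E3.SCF.cullin",
     "Xup": 5, "printed_total": 5},
    {"bin_id": "29.5.11.4.5", "bin_name": "protein.degradation.ubiquitin.E3.BTB/POZ Cullin3",
     "Xup": 3, "printed_total": 3},
    {"bin_id": "29.5.11.5", "bin_name": "protein.degradation.ubiquitin.ubiquitin protease",
     "Xup": 5, "Yup": 1, "printed_total": 6},
    {"bin_id": "29.5.11.20", "bin_name": "protein.degradation.ubiquitin.proteasome",
     "Xup": 21, "Xup-Yup": 1, "printed_total": 22},
    {"bin_id": "30.11", "bin_name": "Signalling.light",
     "Xup": 6, "Xup-Ydown": 1, "Xdown-Ydown": 1, "Yup": 1, "Ydown": 1, "printed_total": 10},
]
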