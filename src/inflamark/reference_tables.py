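"""Curated reference tables for liver and adipose low-grade inflammation
biomarkers.

These tables hold the published knowledge the pipeline's arithmetic
operates on when no database snapshot is available: the per-parent GO term
selection (child-term, gene, and immune-gene counts), the candidate
biomarker lists per parent term, the per-marker expression–histology
Spearman correlations measured in the HFD mouse cohort, and the literature
confirmation level of each marker. Correlations inside the closed band
[-0.60, 0.60] were reported as "no relation" and are stored as ``None``.
"""

from __future__ import annotations

from .ontology import SelectionSummaryRow

# ---------------------------------------------------------------------------
# Per-parent GO term selection: (accession, parent name, n_children, n_genes,
# n_immune). Totals per tissue are sums over rows (genes under several
# parents count once per parent).

GO_SELECTION = {
    "adipose": [
        ("GO:0070162", "adiponectin secretion", 2, 6, 3),
        ("GO:0060612", "adipose tissue development", 4, 38, 19),
        ("GO:0005901", "caveola", 5, 83, 30),
        ("GO:1904606", "fat cell apoptotic process", 1, 1, 1),
        ("GO:0045444", "fat cell differentiation", 9, 213, 94),
        ("GO:0070341", "fat cell proliferation", 2, 10, 2),
        ("GO:0044321", "response to leptin", 5, 24, 11),
    ],
    "liver": [
        ("GO:0034382", "chylomicron remnant clearance", 1, 8, 3),
        ("GO:0002384", "hepatic immune response", 1, 2, 2),
        ("GO:0035733", "hepatic stellate cell activation", 2, 6, 3),
        ("GO:0061868", "hepatic stellate cell migration", 1, 2, 1),
        ("GO:1990922", "hepatic stellate cell proliferation", 1, 2, 1),
        ("GO:0097284", "hepatocyte apoptotic process", 1, 12, 6),
        ("GO:0001889", "liver development", 5, 130, 60),
        ("GO:0034379", "very-low-density lipoprotein particle assembly", 1, 12, 3),
    ],
}

#: number of atlas-specific immune genes that were a unique addition to the
#: ontology-derived sets (per tissue); GO total + addition = candidate pool.
ATLAS_UNIQUE_ADDITIONS = {"adipose": 29, "liver": 131}

#: number of tissue-specific genes retrieved from the expression atlas.
ATLAS_SPECIFIC_GENES = {"adipose": 79, "liver": 359}


def selection_summary_rows(tissue: str) -> list[SelectionSummaryRow]:
    return [
        SelectionSummaryRow(
            tissue=tissue, accession=acc, name=name, n_children=nc, n_genes=ng, n_immune=ni
        )
        for acc, name, nc, ng, ni in GO_SELECTION[tissue]
    ]


# ---------------------------------------------------------------------------
# Candidate biomarkers per parent term (the atlas additions form the last
# row of each tissue). A gene may appear under several parents; the
# deduplicated union defines the candidate count.

CANDIDATES_BY_PARENT = {
    "adipose": [
        ("GO:0070162", "adiponectin secretion", ("IL1B",)),
        ("GO:0060612", "adipose tissue development",
         ("NAMPT", "SORL1", "LEP", "FTO", "PIK3CA", "GHRL")),
        ("GO:0005901", "caveola",
         ("ADCY8", "SELE", "INSR", "IRS1", "TFPI", "HMOX1", "FASLG", "NOS3")),
        ("GO:1904606", "fat cell apoptotic process", ("LEP",)),
        ("GO:0045444", "fat cell differentiation",
         ("LEP", "FTO", "FRZB", "ADIPOQ", "SORT1", "SREBF1", "LPL", "RARRES2", "FABP4",
          "TGFB1", "TNF", "METRNL", "GPX1", "FABP3", "RETN", "FNDC5", "IL6", "PPARG")),
        ("GO:0070341", "fat cell proliferation", ("FTO",)),
        ("GO:0044321", "response to leptin", ("LEP", "LEPR", "FGF23", "EDN1")),
        ("HPA", "additional from expression atlas",
         ("ACP5", "CD36", "CHIT1", "GPNMB", "ITLN1", "MMP9", "PLA2G7", "PRG4", "PTX3", "SAA1")),
    ],
    "liver": [
        ("GO:0034382", "chylomicron remnant clearance",
         ("LDLR", "LIPC", "APOB", "APOC3", "APOC2", "APOC1", "APOE")),
        ("GO:0002384", "hepatic immune response", ("IL6R", "IL6")),
        ("GO:0035733", "hepatic stellate cell activation", ("LEP", "GCLC")),
        ("GO:0061868", "hepatic stellate cell migration", ()),
        ("GO:1990922", "hepatic stellate cell proliferation", ()),
        ("GO:0097284", "hepatocyte apoptotic process", ("GSN", "KRT18")),
        ("GO:0001889", "liver development",
         ("FGL1", "HAMP", "CPB2", "EGFR", "PIK3CA", "REG1A", "HMOX1", "VTN", "IL10",
          "PCSK9", "FGF1")),
        ("GO:0034379", "very-low-density lipoprotein particle assembly",
         ("APOB", "APOC3", "APOC1")),
        ("HPA", "additional from expression atlas",
         ("A1BG", "A2M", "ADAMTS13", "AGT", "AHSG", "AMBP", "APOA1", "AZGP1", "CAT",
          "CD14", "CHI3L1", "CLU", "AGTR1", "CPN2", "F7", "FST", "GDF2", "HP", "HRG",
          "ICAM1", "IGFBP2", "IL18BP", "IL27", "KLKB1", "KNG1", "LBP", "LEPR", "LRG1",
          "MASP1", "MBL2", "ORM1", "PLA2G2A", "PLG", "PRDX4", "PRG4", "PROC", "PROS1",
          "RARRES2", "RBP4", "SAA1", "SDC1", "SERPINA1", "SERPINA3", "SERPINC1", "SOD1",
          "TF", "SERPING1", "TNFSF14", "TTR")),
    ],
}


# ---------------------------------------------------------------------------
# Measured expression-histology correlations per marker in the HFD cohort
# and the literature confirmation level. ``None`` marks a correlation inside
# the [-0.60, 0.60] "no relation" band.

CORRELATION_TABLE = [
    # (gene, rho vs hepatic inflammation, rho vs adipose inflammation, level)
    ("MMP9", None, -0.76, 3),
    ("RETN", None, -0.70, 3),
    ("CAT", -0.69, None, 1),
    ("F7", -0.68, None, 1),
    ("HP", 0.85, None, 3),
    ("IGFBP2", -0.65, None, 2),
    ("IL18BP", 0.75, None, 3),
    ("KRT18", 0.79, None, 2),
    ("LDLR", -0.64, None, 3),
    ("LEPR", 0.64, None, 3),
    ("LIPC", -0.65, None, 1),
    ("LRG1", 0.63, None, 2),
    ("MBL2", -0.67, None, 3),
    ("PCSK9", -0.83, None, 1),
    ("SAA1", 0.82, None, 3),
    ("SERPINA1", -0.63, None, 3),
    ("SERPINA3", 0.77, None, 3),
    ("SERPINC1", -0.64, None, 3),
]

#: biological function category of the level-3 markers
FUNCTION_CATEGORIES = {
    "MMP9": "remodeling extracellular matrix",
    "LEPR": "lipid metabolism",
    "LDLR": "lipid metabolism",
    "RETN": "lipid metabolism",
    "SAA1": "mediators immune activation",
    "HP": "mediators immune activation",
    "MBL2": "mediators immune activation",
    "IL18BP": "mediators immune activation",
    "SERPINA1": "serine protease inhibitors",
    "SERPINA3": "serine protease inhibitors",
    "SERPINC1": "serine protease inhibitors",
}
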