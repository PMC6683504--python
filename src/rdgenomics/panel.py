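"""Targeted panel and regional gene annotations.

The copy-number analyses in this package run over a 70-gene targeted
oncology panel spanning 21 chromosomes (no targets on chr6 or chr21),
roughly three genes per chromosome, mirroring the copy-number subset of a
commercial amplicon cancer panel. The panel below is the default used by
the synthetic-cohort generator; real data may carry any gene set as long
as per-assay reference ranges cover it.
"""

from __future__ import annotations

# gene -> cytoband for the 70 copy-number loci
PANEL_CYTOBANDS: dict[str, str] = {
    "MCL1": "1q21.3",
    "BCL9": "1q21.2",
    "NRAS": "1p13.2",
    "ARID1A": "1p36.11",
    "MTOR": "1p36.22",
    "ALK": "2p23.2",
    "IDH1": "2q34",
    "ERBB4": "2q34",
    "PIK3CA": "3q26.32",
    "VHL": "3p25.3",
    "MLH1": "3p22.2",
    "CTNNB1": "3p22.1",
    "KIT": "4q12",
    "PDGFRA": "4q12",
    "FGFR3": "4p16.3",
    "FBXW7": "4q31.3",
    "APC": "5q22.2",
    "TERT": "5p15.33",
    "EGFR": "7p11.2",
    "BRAF": "7q34",
    "MET": "7q31.2",
    "SMO": "7q32.1",
    "CDK6": "7q21.2",
    "MYC": "8q24.21",
    "FGFR1": "8p11.23",
    "CDKN2A": "9p21.3",
    "ABL1": "9q34.12",
    "NOTCH1": "9q34.3",
    "JAK2": "9p24.1",
    "TSC1": "9q34.13",
    "GATA3": "10p14",
    "RET": "10q11.21",
    "PTEN": "10q23.31",
    "FGFR2": "10q26.13",
    "ATM": "11q22.3",
    "BIRC2": "11q22.2",
    "BIRC3": "11q22.2",
    "HRAS": "11p15.5",
    "CCND1": "11q13.3",
    "WT1": "11p13",
    "KRAS": "12p12.1",
    "CDK4": "12q14.1",
    "MDM2": "12q15",
    "PTPN11": "12q24.13",
    "BRCA2": "13q13.1",
    "FLT3": "13q12.2",
    "RB1": "13q14.2",
    "AKT1": "14q32.33",
    "PNP": "14q11.2",
    "IDH2": "15q26.1",
    "MAP2K1": "15q22.31",
    "CDH1": "16q22.1",
    "TSC2": "16p13.3",
    "TP53": "17p13.1",
    "ERBB2": "17q12",
    "NF1": "17q11.2",
    "BRCA1": "17q21.31",
    "SMAD4": "18q21.2",
    "BCL2": "18q21.33",
    "STK11": "19p13.3",
    "AKT2": "19q13.2",
    "SRC": "20q11.23",
    "AURKA": "20q13.2",
    "GNAS": "20q13.32",
    "NF2": "22q12.2",
    "CHEK2": "22q12.1",
    "EP300": "22q13.2",
    "SMARCB1": "22q11.23",
    "AR": "Xq12",
    "KDM6A": "Xp11.3",
}

PANEL_GENES: list[str] = list(PANEL_CYTOBANDS)

# Genes annotated to the ~10 Mb 18q21.1-18q21.2 window around SMAD4,
# used by the regional expression screen. Coding flag per RefSeq status;
# one long non-coding RNA is included so coding filters are exercised.
REGION_18Q21: dict[str, tuple[str, bool]] = {
    "SMAD2": ("18q21.1", True),
    "SMAD4": ("18q21.2", True),
    "SMAD7": ("18q21.1", True),
    "DCC": ("18q21.2", True),
    "TCF4": ("18q21.2", True),
    "ME2": ("18q21.2", True),
    "MBD2": ("18q21.2", True),
    "POLI": ("18q21.2", True),
    "MEX3C": ("18q21.2", True),
    "MYO5B": ("18q21.1", True),
    "RAB27B": ("18q21.2", True),
    "CCDC68": ("18q21.2", True),
    "KATNAL2": ("18q21.1", True),
    "PIAS2": ("18q21.1", True),
    "ST8SIA5": ("18q21.1", True),
    "ELAC1": ("18q21.2", True),
    "MAPK4": ("18q21.1", True),
    "EPG5": ("18q21.1", True),
    "STARD6": ("18q21.1", True),
    "LINC01924": ("18q21.2", False),
}
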