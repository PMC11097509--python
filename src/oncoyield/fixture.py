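"""Packaged real-world cohort fixture: 23 consecutively enrolled cancer
patients with matched germline blood, tumor tissue (16 patients) and
plasma cfDNA (all 23), their clinically reported variants, copy-number
fold-changes, knowledge-base classifications, prior-testing registry,
and tissue-vs-plasma collection-interval flags.

Genomic coordinates are assigned here (the clinical report identifies
variants by gene + HGVS protein change only); they are internally
consistent and GRCh37-flavored but serve purely as set identities.
Printed VAF percentages are stored as fractions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .cnv import gistic_category as _gistic
from .model import (
    Cohort,
    CopyNumberCall,
    KnowledgeBase,
    PatientRecord,
    SampleRecord,
    VariantCall,
    VariantKey,
)

__all__ = ["Fixture", "paper_fixture", "HEREDITARY_PANEL_GENES"]

#: Hereditary-cancer germline panel gene content (subset relevant here).
#: CHEK1 is deliberately absent: the germline panel does not cover it,
#: so its pathogenic variant is only reachable via tumor/cfDNA analysis.
HEREDITARY_PANEL_GENES = frozenset({
    "BRCA1", "BRCA2", "VHL", "ATM", "MSH3", "MUTYH", "MLH1", "MSH2",
    "MSH6", "PMS2", "TP53", "CDKN2A", "PALB2", "CHEK2", "APC",
})

PLASMA_DATE = _dt.date(2022, 6, 1)
TISSUE_DATE_IN_WINDOW = _dt.date(2022, 5, 2)     # 30 days before plasma
TISSUE_DATE_OUT_WINDOW = _dt.date(2021, 6, 1)    # 365 days before plasma

#: Patients whose tumor tissue was collected within 4 months of plasma.
IN_WINDOW = frozenset({"GE01", "GE06", "GE08", "GE10", "GE12", "GE14",
                       "GE19", "GE22", "GE24"})

#: Patients with a profiled tumor-tissue sample (16 of 23).
TISSUE_PATIENTS = frozenset({"GE01", "GE03", "GE06", "GE07", "GE08", "GE09",
                             "GE10", "GE12", "GE14", "GE15", "GE16", "GE19",
                             "GE21", "GE22", "GE23", "GE24"})

INCLUSION_CRITERIA = {
    "GE01": {3}, "GE02": {4}, "GE03": {1, 6}, "GE04": {1, 3}, "GE05": {3},
    "GE06": {1}, "GE07": {1, 3}, "GE08": {1}, "GE09": {1, 3}, "GE10": {3, 5},
    "GE11": {1, 3}, "GE12": {2, 4}, "GE13": {1}, "GE14": {1}, "GE15": {2},
    "GE16": {1}, "GE17": {1}, "GE18": {4}, "GE19": {6}, "GE21": {2, 5},
    "GE22": {2, 5}, "GE23": {5}, "GE24": {3, 5},
}

# variant catalog: name -> (gene, chrom, pos, ref, alt, hgvs_c, hgvs_p)
_CATALOG = {
    "BRAF_V600E":  ("BRAF",  "chr7",  140453136, "A",  "T",  "c.1799T>A",        "p.V600E"),
    "BRAF_V600R":  ("BRAF",  "chr7",  140453136, "AC", "CT", "c.1798_1799GT>AG", "p.V600R"),
    "BRAF_V600K":  ("BRAF",  "chr7",  140453136, "AC", "TT", "c.1798_1799GT>AA", "p.V600K"),
    "NRAS_Q61K":   ("NRAS",  "chr1",  115256530, "G",  "T",  "c.181C>A",         "p.Q61K"),
    "NRAS_G13D":   ("NRAS",  "chr1",  115258744, "C",  "T",  "c.38G>A",          "p.G13D"),
    "IDH2_R140Q":  ("IDH2",  "chr15", 90631934,  "C",  "T",  "c.419G>A",         "p.R140Q"),
    "IDH2_R172S":  ("IDH2",  "chr15", 90631839,  "C",  "A",  "c.516G>T",         "p.R172S"),
    "FANCA_FS":    ("FANCA", "chr16", 89837000,  "CA", "C",  "c.2731del",        "p.W911Dfs*31"),
    "BRCA1_C64R":  ("BRCA1", "chr17", 41258474,  "A",  "G",  "c.190T>C",         "p.C64R"),
    "VHL_N131T":   ("VHL",   "chr3",  10188258,  "A",  "C",  "c.392A>C",         "p.N131T"),
    "CHEK1_FS":    ("CHEK1", "chr11", 125525195, "AG", "A",  "c.958delG",        "p.E336Nfs*36"),
    "ATM_S1993FS": ("ATM",   "chr11", 108175463, "TC", "T",  "c.5975del",        "p.S1993Rfs*23"),
    "ATM_A1299FS": ("ATM",   "chr11", 108155171, "TG", "T",  "c.3894del",        "p.A1299Cfs*3"),
    "ATM_R1730X":  ("ATM",   "chr11", 108173629, "C",  "T",  "c.5188C>T",        "p.R1730*"),
    "MSH3_Q29X":   ("MSH3",  "chr5",  79950500,  "C",  "T",  "c.85C>T",          "p.Q29X"),
    "MUTYH_G368D": ("MUTYH", "chr1",  45797228,  "C",  "T",  "c.1103G>A",        "p.G368D"),
}

#: Germline pathogenic/likely-pathogenic variants confirmed in blood.
_GERMLINE_PLP = {
    "GE05": ["BRCA1_C64R"],
    "GE11": ["MSH3_Q29X"],
    "GE12": ["VHL_N131T"],
    "GE14": ["CHEK1_FS"],
    "GE15": ["ATM_S1993FS"],
    "GE19": ["MUTYH_G368D"],
    "GE21": ["ATM_A1299FS"],
}
_PLP_NAMES = {v for vs in _GERMLINE_PLP.values() for v in vs}

# (patient, material) -> [(catalog name, VAF fraction)]
_CALLS: dict[tuple[str, str], list[tuple[str, float]]] = {
    ("GE01", "tumor_tissue"): [("BRAF_V600E", 0.514)],
    ("GE02", "cfDNA"): [("FANCA_FS", 0.0066)],
    ("GE05", "cfDNA"): [("BRCA1_C64R", 0.450)],
    ("GE06", "cfDNA"): [("BRAF_V600R", 0.0013)],
    ("GE06", "tumor_tissue"): [("BRAF_V600R", 0.248)],
    ("GE10", "cfDNA"): [("BRAF_V600K", 0.0011)],
    ("GE11", "cfDNA"): [("IDH2_R172S", 0.0083), ("NRAS_Q61K", 0.0038),
                        ("MSH3_Q29X", 0.473)],
    ("GE12", "cfDNA"): [("VHL_N131T", 0.517)],
    ("GE12", "tumor_tissue"): [("VHL_N131T", 0.623)],
    ("GE14", "cfDNA"): [("IDH2_R140Q", 0.0026), ("CHEK1_FS", 0.475)],
    ("GE14", "tumor_tissue"): [("BRAF_V600E", 0.287), ("CHEK1_FS", 0.468)],
    ("GE15", "cfDNA"): [("NRAS_Q61K", 0.0019), ("ATM_S1993FS", 0.315)],
    ("GE15", "tumor_tissue"): [("NRAS_Q61K", 0.700), ("ATM_S1993FS", 0.771)],
    ("GE16", "tumor_tissue"): [("BRAF_V600E", 0.466)],
    ("GE17", "cfDNA"): [("NRAS_Q61K", 0.389)],
    ("GE19", "cfDNA"): [("MUTYH_G368D", 0.486)],
    ("GE19", "tumor_tissue"): [("MUTYH_G368D", 0.496)],
    ("GE21", "cfDNA"): [("ATM_A1299FS", 0.500)],
    ("GE21", "tumor_tissue"): [("ATM_R1730X", 0.054), ("ATM_A1299FS", 0.442)],
    ("GE22", "cfDNA"): [("NRAS_G13D", 0.0043)],
}

# copy-number calls: (patient, material) -> [(gene, fold-change)]
# Four tissue amplifications at FC >= 2 and four cfDNA amplifications
# at FC >= 1.5; only ERBB2 (GE19) is knowledge-base actionable.
_CNVS: dict[tuple[str, str], list[tuple[str, float]]] = {
    ("GE19", "cfDNA"): [("ERBB2", 1.5)],
    ("GE19", "tumor_tissue"): [("ERBB2", 7.2)],
    ("GE03", "tumor_tissue"): [("MYC", 2.8)],
    ("GE09", "tumor_tissue"): [("FGF3", 2.4)],
    ("GE24", "tumor_tissue"): [("CCND1", 2.1)],
    ("GE04", "cfDNA"): [("MYC", 1.8)],
    ("GE13", "cfDNA"): [("CCND1", 1.6)],
    ("GE18", "cfDNA"): [("FGF3", 1.7)],
}

#: Alterations already known from routine somatic testing, per patient.
_PRIOR_DETECTED = {
    "GE06": {("BRAF", "p.V600R")},
    "GE10": {("BRAF", "p.V600K")},
    "GE14": {("BRAF", "p.V600E")},
    "GE19": {("ERBB2", "amplification")},
}

# knowledge base: gene, descriptor, OncoKB level, AMP/ASCO/CAP tier
_KB_ROWS = [
    ("BRAF", "p.V600E", "1", "IA"),
    ("BRAF", "p.V600R", "1", "IA"),
    ("BRAF", "p.V600K", "3B", "IIC"),
    ("NRAS", "p.Q61K", "3A", "IB"),
    ("NRAS", "p.G13D", "3B", "IIC"),
    ("IDH2", "p.R172S", "3B", "IIC"),
    ("IDH2", "p.R140Q", "3B", "IIC"),
    ("FANCA", "p.W911Dfs*31", "3B", "IIC"),
    ("BRCA1", "p.C64R", "3B", "IIC"),
    ("VHL", "p.N131T", "3B", "IIC"),
    ("CHEK1", "p.E336Nfs*36", "3B", "IIC"),
    ("ATM", "p.S1993Rfs*23", "3B", "IIC"),
    ("ATM", "p.A1299Cfs*3", "3B", "IIC"),
    ("ATM", "p.R1730*", "3B", "IIC"),
    ("ERBB2", "amplification", "1", "IA"),
]

#: Per-row classifications as clinically reported, including the
#: tumor-type-dependent AMP tier variations for NRAS p.Q61K.
DISPLAY_CLASSIFICATIONS = {
    ("GE11", "NRAS", "p.Q61K"): ("3B", "IIC"),
    ("GE15", "NRAS", "p.Q61K"): ("3A", "IB"),
    ("GE17", "NRAS", "p.Q61K"): ("3A", "IIB"),
}

_DEPTH = {"tumor_tissue": 800, "cfDNA": 3000, "germline_blood": 300}
_COSMIC = {"BRAF_V600E": 30000, "BRAF_V600R": 500, "BRAF_V600K": 2000,
           "NRAS_Q61K": 4000, "NRAS_G13D": 2500, "IDH2_R140Q": 900,
           "IDH2_R172S": 300, "ATM_R1730X": 12}


@dataclass
class Fixture:
    cohort: Cohort
    kb: KnowledgeBase
    in_window: frozenset[str] = IN_WINDOW
    msi_status: dict[str, str] = field(default_factory=dict)


def _make_call(name: str, vaf: float, sample_id: str, material: str) -> VariantCall:
    gene, chrom, pos, ref, alt, hgvs_c, hgvs_p = _CATALOG[name]
    return VariantCall(
        key=VariantKey(chrom, pos, ref, alt),
        gene=gene,
        vaf=vaf,
        depth=_DEPTH[material],
        sample_id=sample_id,
        hgvs_p=hgvs_p,
        hgvs_c=hgvs_c,
        consequence="nonsynonymous",
        cosmic_count=_COSMIC.get(name, 0),
        pathogenicity="P" if name in _PLP_NAMES else "none",
    )


def paper_fixture() -> Fixture:
    """The packaged 23-patient study cohort with its knowledge base.

    Every reported variant, fold-change, classification, prior-testing
    mark and collection-window flag appears exactly once; running the
    yield accounting on this cohort reproduces the published cohort
    fractions bit-exactly.
    """
    kb = KnowledgeBase()
    for gene, desc, level, tier in _KB_ROWS:
        kb.add(gene, desc, level, tier)

    patients = []
    msi_status: dict[str, str] = {}
    for pid in sorted(INCLUSION_CRITERIA):
        samples = []
        materials = ["germline_blood", "cfDNA"]
        if pid in TISSUE_PATIENTS:
            materials.append("tumor_tissue")
        for material in materials:
            suffix = {"germline_blood": "G", "cfDNA": "LB", "tumor_tissue": "T"}[material]
            sid = f"{pid}-{suffix}"
            if material == "germline_blood":
                date = PLASMA_DATE
                calls = [
                    _make_call(name, 0.5, sid, material)
                    for name in _GERMLINE_PLP.get(pid, [])
                ]
            else:
                date = (
                    PLASMA_DATE if material == "cfDNA"
                    else TISSUE_DATE_IN_WINDOW if pid in IN_WINDOW
                    else TISSUE_DATE_OUT_WINDOW
                )
                calls = [
                    _make_call(name, vaf, sid, material)
                    for name, vaf in _CALLS.get((pid, material), [])
                ]
            cnvs = [
                CopyNumberCall(gene, fc, material, gistic_category=_gistic(fc, material))
                for gene, fc in _CNVS.get((pid, material), [])
            ]
            samples.append(SampleRecord(
                sample_id=sid, patient_id=pid, material=material,
                collection_date=date, calls=calls, cnv_calls=cnvs,
            ))
            if material in ("tumor_tissue", "cfDNA"):
                msi_status[sid] = "MSS"  # no sample showed instability
        patients.append(PatientRecord(
            patient_id=pid,
            inclusion_criteria=set(INCLUSION_CRITERIA[pid]),
            samples=samples,
            prior_detected=set(_PRIOR_DETECTED.get(pid, set())),
            panel_membership=set(HEREDITARY_PANEL_GENES),
        ))
    return Fixture(Cohort(patients), kb, IN_WINDOW, msi_status)
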