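"""Therapeutic actionability: knowledge-base annotation, highest-evidence
selection, temporal tissue/cfDNA integration, and cohort yield accounting.

An alteration is *actionable* when its OncoKB level is 1-3B or its
AMP/ASCO/CAP tier is IA-IID.  Per patient, the somatic evidence base is
the union of tissue and cfDNA actionable alterations when the tissue
was collected within the integration window (default 122 days ~ 4
months) of plasma collection; otherwise cfDNA alone.  Confirmed
germline-origin variants are routed to the germline yield, never to the
somatic one.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import pandas as pd

from .concordance import flag_indel_artifacts
from .germline import classify_sample
from .model import (
    ACTIONABLE_AMP,
    ACTIONABLE_ONCOKB,
    ONCOKB_LEVELS,
    Cohort,
    CopyNumberCall,
    KnowledgeBase,
    PatientRecord,
    VariantCall,
    VariantKey,
)

__all__ = [
    "ActionabilityRecord",
    "YieldReport",
    "DEFAULT_WINDOW_DAYS",
    "annotate",
    "select_highest_evidence",
    "tissue_in_window",
    "integrate_patient",
    "compute_yields",
    "oncoprint_matrix",
]

DEFAULT_WINDOW_DAYS = 122  # "4 months", fixed at 122 days

#: Working VAF cut-offs applied before yield accounting (tissue single
#: threshold; cfDNA split SNV/MNV vs InDel).
TISSUE_VAF_MIN = 0.05
CFDNA_SNV_VAF_MIN = 0.001
CFDNA_INDEL_VAF_MIN = 0.005

_LEVEL_RANK = {lvl: i for i, lvl in enumerate(ONCOKB_LEVELS)}


@dataclass(frozen=True)
class ActionabilityRecord:
    gene: str
    descriptor: str          # hgvs_p or "amplification"
    oncokb_level: str
    amp_tier: str
    material: str
    key: VariantKey | None = None   # None for copy-number targets

    @property
    def actionable(self) -> bool:
        return self.oncokb_level in ACTIONABLE_ONCOKB or self.amp_tier in ACTIONABLE_AMP

    @property
    def identity(self):
        """Deduplication identity across materials."""
        return self.key if self.key is not None else (self.gene, self.descriptor)


def annotate(
    target: VariantCall | CopyNumberCall,
    kb: KnowledgeBase,
    material: str = "",
) -> ActionabilityRecord:
    """Deterministic knowledge-base lookup for a mutation or an
    amplification call; unlisted targets come back not actionable."""
    if isinstance(target, CopyNumberCall):
        entry = kb.lookup(target.gene, "amplification")
        return ActionabilityRecord(
            target.gene, "amplification", entry.oncokb_level, entry.amp_tier,
            material or target.material,
        )
    entry = kb.lookup(target.gene, target.hgvs_p)
    return ActionabilityRecord(
        target.gene, target.hgvs_p, entry.oncokb_level, entry.amp_tier,
        material, key=target.key,
    )


def select_highest_evidence(records: list[ActionabilityRecord]) -> list[ActionabilityRecord]:
    """Order by strength of OncoKB drug-response evidence
    (1 > 2 > 3A > 3B > 4 > none), ties broken by (gene, descriptor)."""
    return sorted(records, key=lambda r: (_LEVEL_RANK[r.oncokb_level], r.gene, r.descriptor))


def tissue_in_window(patient: PatientRecord, window_days: int = DEFAULT_WINDOW_DAYS) -> bool:
    """Was the tumor tissue collected within the integration window of
    plasma collection?  False when there is no tissue sample."""
    tissue, plasma = patient.tissue, patient.cfdna
    if tissue is None:
        return False
    if plasma is None or plasma.collection_date is None or tissue.collection_date is None:
        raise ValueError(f"{patient.patient_id}: missing collection date for the 4-month rule")
    return abs((plasma.collection_date - tissue.collection_date).days) <= window_days


def _germline_keys(patient: PatientRecord, sample) -> set[VariantKey]:
    """Keys of germline-origin calls in a tumor/cfDNA sample (blood
    confirmation when available, prediction otherwise)."""
    flags = classify_sample(sample, patient.germline)
    return {k for k, f in flags.items() if f.origin == "germline"}


def _sample_actionable(
    patient: PatientRecord,
    sample,
    kb: KnowledgeBase,
    artifact_keys: set[VariantKey],
) -> list[ActionabilityRecord]:
    """Actionable somatic records of one tumor/cfDNA sample, after VAF
    cut-offs, artifact exclusion and germline routing."""
    germline = _germline_keys(patient, sample)
    records: list[ActionabilityRecord] = []
    for call in sample.calls:
        cut = (
            TISSUE_VAF_MIN
            if sample.material == "tumor_tissue"
            else (CFDNA_INDEL_VAF_MIN if call.is_indel else CFDNA_SNV_VAF_MIN)
        )
        if call.vaf < cut or call.key in artifact_keys or call.key in germline:
            continue
        rec = annotate(call, kb, sample.material)
        if rec.actionable:
            records.append(rec)
    for cnv in sample.cnv_calls:
        if cnv.gistic_category == 2:
            rec = annotate(cnv, kb, sample.material)
            if rec.actionable:
                records.append(rec)
    return records


def integrate_patient(
    patient: PatientRecord,
    kb: KnowledgeBase,
    window_days: int = DEFAULT_WINDOW_DAYS,
    artifact_keys: set[VariantKey] | None = None,
) -> list[ActionabilityRecord]:
    """Integrated actionable somatic set for one patient.

    Tissue and cfDNA actionable alterations are pooled when the tissue
    is within the window; otherwise only cfDNA counts.  Deduplicated by
    variant key (gene+"amplification" for copy number), keeping the
    record of strongest evidence.  Idempotent.
    """
    artifact_keys = artifact_keys or set()
    records: list[ActionabilityRecord] = []
    plasma = patient.cfdna
    if plasma is not None:
        records += _sample_actionable(patient, plasma, kb, artifact_keys)
    if patient.tissue is not None and tissue_in_window(patient, window_days):
        records += _sample_actionable(patient, patient.tissue, kb, artifact_keys)
    out: dict = {}
    for rec in select_highest_evidence(records):
        out.setdefault(rec.identity, rec)
    return list(out.values())


@dataclass
class YieldReport:
    per_patient: dict[str, dict] = field(default_factory=dict)
    fractions: dict[str, tuple[int, int]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def fraction(self, name: str) -> float:
        num, den = self.fractions[name]
        return num / den if den else 0.0

    def to_dict(self) -> dict:
        return {
            "per_patient": self.per_patient,
            "fractions": {
                k: {"numerator": n, "denominator": d, "fraction": (n / d if d else 0.0)}
                for k, (n, d) in self.fractions.items()
            },
            "counts": dict(self.counts),
        }


def _germline_actionable(
    patient: PatientRecord, kb: KnowledgeBase
) -> list[ActionabilityRecord]:
    """Actionable records among the patient's confirmed germline P/LP
    variants (from blood, or germline-classified tumor/cfDNA calls)."""
    blood = patient.germline
    seen: dict[tuple[str, str], ActionabilityRecord] = {}
    for sample in patient.samples:
        for call in sample.calls:
            if call.pathogenicity not in ("P", "LP"):
                continue
            if sample.material == "germline_blood":
                is_germline = True
            elif blood is not None:
                is_germline = call.key in blood.keys()
            else:
                is_germline = False
            if not is_germline:
                continue
            rec = annotate(call, kb, "germline_blood")
            if rec.actionable:
                seen.setdefault((call.gene, call.hgvs_p), rec)
    return list(seen.values())


def compute_yields(
    cohort: Cohort,
    kb: KnowledgeBase,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> YieldReport:
    """Cohort actionability yields.

    Fractions reported (numerator/denominator):

    * ``any_actionable``        — >= 1 somatic-integrated or germline
      actionable alteration, over all patients
    * ``somatic_integrated``    — >= 1 actionable alteration in the
      temporally integrated somatic set, over all patients
    * ``tissue_level``          — >= 1 actionable somatic alteration in
      the tissue sample, over tissue-profiled patients
    * ``cfdna_level``           — likewise for cfDNA samples
    * ``germline_plp``          — >= 1 germline P/LP variant, over all
    * ``germline_actionable``   — >= 1 actionable (level-3B) germline
      variant, over all
    * ``novel_any_actionable``  — any-actionable after excluding
      alterations already known from routine testing

    Counts: hereditary-panel-detectable germline P/LP variants, and
    distinct actionable somatic mutations found in cfDNA.
    """
    artifact_keys = flag_indel_artifacts(
        [p.cfdna for p in cohort if p.cfdna is not None]
    )
    report = YieldReport()
    n_all = len(cohort)
    n_tissue = sum(1 for p in cohort if p.tissue is not None)
    n_cfdna = sum(1 for p in cohort if p.cfdna is not None)

    panel_plp: set[tuple[str, str, str]] = set()
    cfdna_mutations: set[tuple[str, VariantKey]] = set()
    tallies = {k: 0 for k in (
        "any_actionable", "somatic_integrated", "tissue_level", "cfdna_level",
        "germline_plp", "germline_actionable", "novel_any_actionable",
    )}

    for patient in cohort:
        integrated = integrate_patient(patient, kb, window_days, artifact_keys)
        germ_recs = _germline_actionable(patient, kb)
        tissue_recs = (
            _sample_actionable(patient, patient.tissue, kb, artifact_keys)
            if patient.tissue is not None else []
        )
        cfdna_recs = (
            _sample_actionable(patient, patient.cfdna, kb, artifact_keys)
            if patient.cfdna is not None else []
        )
        blood = patient.germline
        plp = sorted({
            (c.gene, c.hgvs_p)
            for c in (blood.calls if blood else [])
            if c.pathogenicity in ("P", "LP")
        })
        for gene, hgvs_p in plp:
            if gene in patient.panel_membership:
                panel_plp.add((patient.patient_id, gene, hgvs_p))
        for rec in cfdna_recs:
            if rec.key is not None:
                cfdna_mutations.add((patient.patient_id, rec.key))

        novel = [
            r for r in list(integrated) + germ_recs
            if (r.gene, r.descriptor) not in patient.prior_detected
        ]
        flags = {
            "has_somatic_actionable": bool(integrated),
            "has_germline_actionable": bool(germ_recs),
            "has_any_actionable": bool(integrated) or bool(germ_recs),
            "has_novel_actionable": bool(novel),
            "tissue_actionable": bool(tissue_recs),
            "cfdna_actionable": bool(cfdna_recs),
            "tissue_in_window": patient.tissue is not None
            and tissue_in_window(patient, window_days),
            "integrated_targets": [
                f"{r.gene} {r.descriptor} [{r.oncokb_level}/{r.amp_tier}] ({r.material})"
                for r in integrated
            ],
            "germline_targets": [
                f"{r.gene} {r.descriptor} [{r.oncokb_level}/{r.amp_tier}]" for r in germ_recs
            ],
        }
        report.per_patient[patient.patient_id] = flags
        tallies["any_actionable"] += flags["has_any_actionable"]
        tallies["somatic_integrated"] += flags["has_somatic_actionable"]
        tallies["tissue_level"] += flags["tissue_actionable"]
        tallies["cfdna_level"] += flags["cfdna_actionable"]
        tallies["germline_plp"] += bool(plp)
        tallies["germline_actionable"] += flags["has_germline_actionable"]
        tallies["novel_any_actionable"] += flags["has_novel_actionable"]

    report.fractions = {
        "any_actionable": (tallies["any_actionable"], n_all),
        "somatic_integrated": (tallies["somatic_integrated"], n_all),
        "tissue_level": (tallies["tissue_level"], n_tissue),
        "cfdna_level": (tallies["cfdna_level"], n_cfdna),
        "germline_plp": (tallies["germline_plp"], n_all),
        "germline_actionable": (tallies["germline_actionable"], n_all),
        "novel_any_actionable": (tallies["novel_any_actionable"], n_all),
    }
    report.counts = {
        "hereditary_panel_plp_variants": len(panel_plp),
        "cfdna_actionable_mutations": len(cfdna_mutations),
    }
    return report


def oncoprint_matrix(cohort: Cohort, kb: KnowledgeBase, material: str) -> pd.DataFrame:
    """Gene x patient matrix of actionable somatic alterations in one
    material, cells like ``"p.V600E (1/IA)"`` or ``"amplification (1/IA)"``.

    A non-empty patient column marks a sample carrying at least one
    actionable alteration; empty cells are empty strings.
    """
    artifact_keys = flag_indel_artifacts(
        [p.cfdna for p in cohort if p.cfdna is not None]
    )
    cells: dict[str, dict[str, str]] = {}
    patient_ids = []
    for patient in cohort:
        sample = patient.sample(material)
        if sample is None:
            continue
        patient_ids.append(patient.patient_id)
        for rec in _sample_actionable(patient, sample, kb, artifact_keys):
            label = f"{rec.descriptor} ({rec.oncokb_level}/{rec.amp_tier})"
            row = cells.setdefault(rec.gene, {})
            row[patient.patient_id] = (
                label if patient.patient_id not in row else row[patient.patient_id] + ";" + label
            )
    genes = sorted(cells)
    return pd.DataFrame(
        [[cells[g].get(pid, "") for pid in patient_ids] for g in genes],
        index=genes,
        columns=patient_ids,
    )
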