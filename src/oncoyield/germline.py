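"""Tumor-only germline flagging and germline-focused analysis.

Two orthogonal predictors flag a tumor- or cfDNA-detected variant as
probably germline:

* the *database* rule — the variant is common in at least two of three
  germline population databases (observation count > 50) with a VAF
  compatible with heterozygous (~50%) or homozygous (~100%) zygosity
  and without strong somatic (COSMIC) evidence;
* the *proximal-VAF* rule — an exact binomial test does not reject the
  hypothesis that the call's alt-read count was drawn at the expected
  germline allele fraction estimated from surrounding database-flagged
  germline variants.

When a matched germline-blood sample exists, presence there is the
confirmation standard and overrides both predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .model import Cohort, SampleRecord, VariantCall

__all__ = [
    "GermlineFlags",
    "GermlineFinding",
    "database_flag",
    "proxi_flag",
    "classify_origin",
    "classify_sample",
    "germline_focused_analysis",
]

#: VAF bands compatible with heterozygous / homozygous germline zygosity.
DEFAULT_ZYGOSITY_BANDS = ((0.40, 0.60), (0.90, 1.00))
DB_COUNT_THRESHOLD = 50   # "> 50 times"
MIN_DATABASES = 2         # "in at least 2 germline databases"
COSMIC_CEILING = 50       # somatic-evidence ceiling for the germline call
PROXI_WINDOW_BP = 1_000_000
PROXI_MIN_NEIGHBORS = 5
PROXI_P_THRESHOLD = 0.01


@dataclass(frozen=True)
class GermlineFlags:
    database_flag: bool
    proxi_flag: bool
    origin: str                      # germline | somatic | ambiguous
    predicted: bool = False          # origin inferred without blood confirmation
    note: str = ""


def database_flag(
    call: VariantCall,
    zygosity_bands: tuple[tuple[float, float], ...] = DEFAULT_ZYGOSITY_BANDS,
    db_threshold: int = DB_COUNT_THRESHOLD,
    min_databases: int = MIN_DATABASES,
    cosmic_ceiling: int = COSMIC_CEILING,
) -> bool:
    """Population-database germline rule (GermlineFilterDatabase-style)."""
    n_db = sum(1 for c in call.db_counts.values() if c > db_threshold)
    zygosity_ok = any(lo <= call.vaf <= hi for lo, hi in zygosity_bands)
    return n_db >= min_databases and zygosity_ok and call.cosmic_count < cosmic_ceiling


def proxi_flag(
    call: VariantCall,
    neighbor_calls: list[VariantCall],
    window_bp: int = PROXI_WINDOW_BP,
    min_neighbors: int = PROXI_MIN_NEIGHBORS,
    p_threshold: float = PROXI_P_THRESHOLD,
) -> tuple[bool, str]:
    """Proximal-VAF germline rule (GermlineFilterProxi-style).

    ``neighbor_calls`` are same-sample calls already database-flagged as
    germline.  The expected germline allele fraction is the median VAF
    of neighbors on the same chromosome within ``window_bp``; the
    call's alt-read count is tested against it with an exact two-sided
    binomial test.  Non-significant (p >= threshold) means the call
    looks germline.  Returns ``(flag, note)``.
    """
    if call.depth == 0:
        raise ValueError("proxi_flag needs depth > 0")
    near = [
        n for n in neighbor_calls
        if n.key.chrom == call.key.chrom
        and abs(n.key.pos - call.key.pos) <= window_bp
        and n.key != call.key
    ]
    if len(near) < min_neighbors:
        return False, "insufficient-neighbors"
    expected_af = sorted(n.vaf for n in near)[len(near) // 2]
    expected_af = min(max(expected_af, 1e-9), 1 - 1e-9)
    k = round(call.vaf * call.depth)
    p = binomtest(k, call.depth, expected_af, alternative="two-sided").pvalue
    return p >= p_threshold, ""


def classify_origin(
    call: VariantCall,
    flags: tuple[bool, bool],
    germline_sample: SampleRecord | None = None,
) -> GermlineFlags:
    """Assign germline/somatic origin.

    With a matched blood sample, presence of the key there is decisive
    (confirmation standard); otherwise either predictor flags the call
    germline, marked ``predicted``.
    """
    db, proxi = flags
    if germline_sample is not None:
        origin = "germline" if call.key in germline_sample.keys() else "somatic"
        return GermlineFlags(db, proxi, origin, predicted=False)
    if db or proxi:
        return GermlineFlags(db, proxi, "germline", predicted=True)
    return GermlineFlags(db, proxi, "somatic", predicted=True)


def classify_sample(
    sample: SampleRecord,
    germline_sample: SampleRecord | None = None,
    **proxi_kwargs,
) -> dict:
    """Flags + origin for every call of a tumor or cfDNA sample,
    keyed by the call's variant key."""
    db_flags = {c.key: database_flag(c) for c in sample.calls}
    germline_neighbors = [c for c in sample.calls if db_flags[c.key]]
    out = {}
    for call in sample.calls:
        if call.depth > 0:
            proxi, _note = proxi_flag(call, germline_neighbors, **proxi_kwargs)
        else:
            proxi = False
        out[call.key] = classify_origin(call, (db_flags[call.key], proxi), germline_sample)
    return out


@dataclass(frozen=True)
class GermlineFinding:
    patient_id: str
    gene: str
    hgvs_p: str
    pathogenicity: str
    panel_covered: bool
    materials: tuple[str, ...]

    @property
    def secondary_finding_label(self) -> str:
        return "panel-covered" if self.panel_covered else "panel-uncovered secondary finding"


def germline_focused_analysis(cohort: Cohort) -> dict[str, list[GermlineFinding]]:
    """Per patient, germline-origin pathogenic / likely-pathogenic
    variants detected in tumor tissue, cfDNA or blood, annotated with
    hereditary-panel coverage.

    Pathogenicity is an input classification (ACMG P/LP), not computed.
    A finding whose gene is absent from the hereditary panel is a
    secondary finding the dedicated germline panel could never return.
    """
    results: dict[str, list[GermlineFinding]] = {}
    for patient in cohort:
        blood = patient.germline
        found: dict[tuple[str, str], set[str]] = {}
        meta: dict[tuple[str, str], VariantCall] = {}
        for sample in patient.samples:
            flags = (
                classify_sample(sample, blood)
                if sample.material in ("tumor_tissue", "cfDNA")
                else None
            )
            for call in sample.calls:
                if call.pathogenicity not in ("P", "LP"):
                    continue
                if sample.material == "germline_blood":
                    is_germline = True
                else:
                    is_germline = flags[call.key].origin == "germline"
                if is_germline:
                    ident = (call.gene, call.hgvs_p)
                    found.setdefault(ident, set()).add(sample.material)
                    meta[ident] = call
        findings = [
            GermlineFinding(
                patient_id=patient.patient_id,
                gene=gene,
                hgvs_p=hgvs_p,
                pathogenicity=meta[(gene, hgvs_p)].pathogenicity,
                panel_covered=gene in patient.panel_membership,
                materials=tuple(sorted(mats)),
            )
            for (gene, hgvs_p), mats in sorted(found.items())
        ]
        results[patient.patient_id] = findings
    return results
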