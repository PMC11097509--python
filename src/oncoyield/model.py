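"""Domain types for matched germline / tumor-tissue / cfDNA cohorts.

The central identity object is :class:`VariantKey` — a normalized
(chrom, pos, ref, alt) tuple in VCF convention (1-based, indels carry a
single anchor base).  All set operations in the concordance and
integration machinery compare variants by this key; gene symbols and
HGVS strings are display metadata only, because HGVS representations
differ across annotators for the same genomic change.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

__all__ = [
    "DB_NAMES",
    "MATERIALS",
    "CONSEQUENCES",
    "VARIANT_CLASSES",
    "ONCOKB_LEVELS",
    "AMP_TIERS",
    "VariantKey",
    "VariantCall",
    "CopyNumberCall",
    "MsiLocusProfile",
    "SampleRecord",
    "PatientRecord",
    "Cohort",
    "KbEntry",
    "KnowledgeBase",
    "normalize_variant",
    "infer_variant_class",
]

#: The three germline population databases consulted by the tumor-only
#: germline filter (gnomAD-exome-like, gnomAD-genome-like, 1000G-like).
DB_NAMES: tuple[str, ...] = ("db_gnomad_exome", "db_gnomad_genome", "db_1000g")

MATERIALS = ("tumor_tissue", "cfDNA", "germline_blood")
CONSEQUENCES = ("synonymous", "nonsynonymous", "other-coding", "noncoding")
VARIANT_CLASSES = ("SNV", "MNV", "InDel")

#: Therapeutic evidence scales.  Order matters: lower index = stronger
#: drug-response evidence.
ONCOKB_LEVELS = ("1", "2", "3A", "3B", "4", "none")
AMP_TIERS = ("IA", "IB", "IIC", "IIB", "IID", "III", "IV", "none")

#: The actionability window: OncoKB level 1-3B or AMP/ASCO/CAP Tier IA-IID.
ACTIONABLE_ONCOKB = frozenset({"1", "2", "3A", "3B"})
ACTIONABLE_AMP = frozenset({"IA", "IB", "IIB", "IIC", "IID"})

_DNA_RE = re.compile(r"^[ACGT]+$")


class FormatError(ValueError):
    """Raised for malformed variant representations or table rows."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a small variant (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not _DNA_RE.match(allele):
                raise FormatError(f"{name} is not a nonempty ACGT string: {allele!r}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def infer_variant_class(ref: str, alt: str) -> str:
    """SNV / MNV / InDel from allele lengths."""
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "InDel"


def normalize_variant(raw: VariantKey, reference: dict[str, str] | None = None) -> VariantKey:
    """Return the canonical minimal (and, given a reference, left-aligned)
    representation of ``raw``.

    Normalization trims shared suffix bases, then shared prefix bases
    (keeping the single anchor base for indels).  If ``reference`` maps
    ``chrom`` to its full 1-based sequence, indels are additionally
    left-shifted through repeat tracts, as ``vt normalize`` would.
    Idempotent.
    """
    chrom, pos, ref, alt = raw.chrom, raw.pos, raw.ref, raw.alt
    seq = reference.get(chrom) if reference else None

    changed = True
    while changed:
        changed = False
        # trim identical trailing bases
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        # left-extend through the reference when the variant still ends
        # on a shared base (repeat tract): prepend the preceding base
        if seq is not None and ref[-1] == alt[-1] and pos > 1:
            prev = seq[pos - 2].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            changed = True
    # trim identical leading bases, keeping one anchor for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class VariantCall:
    """One called alteration in one sample."""

    key: VariantKey
    gene: str
    vaf: float
    depth: int
    sample_id: str = ""
    hgvs_p: str = ""
    hgvs_c: str = ""
    variant_class: str = ""
    consequence: str = "nonsynonymous"
    cosmic_count: int = 0
    db_counts: dict[str, int] = field(default_factory=lambda: {n: 0 for n in DB_NAMES})
    pathogenicity: str = "none"  # ACMG class taken as input: P, LP, VUS, LB, B, none
    repeat_context: bool = False  # indel lies in a homopolymer run (annotation input)

    def __post_init__(self) -> None:
        if not self.variant_class:
            self.variant_class = infer_variant_class(self.key.ref, self.key.alt)
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_class != infer_variant_class(self.key.ref, self.key.alt):
            raise FormatError(
                f"variant_class {self.variant_class} inconsistent with alleles "
                f"{self.key.ref}>{self.key.alt}"
            )
        if self.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise FormatError(f"vaf outside [0,1]: {self.vaf}")
        if self.depth < 0:
            raise FormatError(f"negative depth: {self.depth}")
        if self.cosmic_count < 0:
            raise FormatError(f"negative cosmic_count: {self.cosmic_count}")
        if set(self.db_counts) != set(DB_NAMES):
            raise FormatError(
                f"db_counts must carry exactly the keys {DB_NAMES}, got {sorted(self.db_counts)}"
            )

    @property
    def is_indel(self) -> bool:
        return self.variant_class == "InDel"


@dataclass
class CopyNumberCall:
    """Gene-level copy-number call expressed as a coverage fold-change."""

    gene: str
    fold_change: float
    material: str
    gistic_category: int | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise FormatError(f"fold_change must be > 0, got {self.fold_change}")
        if self.material not in MATERIALS:
            raise FormatError(f"unknown material {self.material!r}")
        if self.gistic_category is not None and self.gistic_category not in (-2, -1, 0, 1, 2):
            raise FormatError(f"gistic_category outside {{-2..2}}: {self.gistic_category}")


@dataclass
class MsiLocusProfile:
    """Repeat-length read-count distribution at one microsatellite locus."""

    locus_id: str
    length_counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.length_counts.values()):
            raise FormatError(f"negative count at locus {self.locus_id}")
        if not any(c > 0 for c in self.length_counts.values()):
            raise FormatError(f"all-zero profile at locus {self.locus_id}")

    @property
    def total(self) -> int:
        return sum(self.length_counts.values())


@dataclass
class SampleRecord:
    sample_id: str
    patient_id: str
    material: str
    collection_date: _dt.date | None = None
    calls: list[VariantCall] = field(default_factory=list)
    cnv_calls: list[CopyNumberCall] = field(default_factory=list)
    msi_profiles: list[MsiLocusProfile] | None = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise FormatError(f"unknown material {self.material!r}")
        if self.material in ("tumor_tissue", "cfDNA") and self.collection_date is None:
            raise FormatError(
                f"collection_date required for {self.material} sample {self.sample_id}"
            )

    def keys(self) -> set[VariantKey]:
        return {c.key for c in self.calls}


@dataclass
class PatientRecord:
    patient_id: str
    inclusion_criteria: set[int] = field(default_factory=set)
    samples: list[SampleRecord] = field(default_factory=list)
    prior_detected: set[tuple[str, str]] = field(default_factory=set)
    panel_membership: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.inclusion_criteria or not self.inclusion_criteria <= set(range(1, 7)):
            raise FormatError(
                f"inclusion_criteria must be a nonempty subset of 1..6 "
                f"({self.patient_id}: {sorted(self.inclusion_criteria)})"
            )
        if len([s for s in self.samples if s.material == "germline_blood"]) > 1:
            raise FormatError(f"{self.patient_id}: more than one germline_blood sample")

    def sample(self, material: str) -> SampleRecord | None:
        for s in self.samples:
            if s.material == material:
                return s
        return None

    @property
    def germline(self) -> SampleRecord | None:
        return self.sample("germline_blood")

    @property
    def tissue(self) -> SampleRecord | None:
        return self.sample("tumor_tissue")

    @property
    def cfdna(self) -> SampleRecord | None:
        return self.sample("cfDNA")


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# Actionability knowledge base


@dataclass(frozen=True)
class KbEntry:
    oncokb_level: str
    amp_tier: str

    def __post_init__(self) -> None:
        if self.oncokb_level not in ONCOKB_LEVELS:
            raise FormatError(f"unknown OncoKB level {self.oncokb_level!r}")
        if self.amp_tier not in AMP_TIERS:
            raise FormatError(f"unknown AMP/ASCO/CAP tier {self.amp_tier!r}")


_POSITIONAL_RE = re.compile(r"^(p\.[A-Za-z]{1,3}\d+)")


class KnowledgeBase:
    """Local gene+alteration -> (OncoKB level, AMP/ASCO/CAP tier) lookup.

    Descriptors, most specific first: an exact ``hgvs_p`` string, a
    positional class (``p.V600`` — any substitution at that codon), or
    ``"amplification"``.  Lookup is deterministic; unlisted targets
    resolve to ``(none, none)``.
    """

    def __init__(self, entries: dict[tuple[str, str], KbEntry] | None = None):
        self.entries: dict[tuple[str, str], KbEntry] = dict(entries or {})

    def add(self, gene: str, descriptor: str, oncokb_level: str, amp_tier: str) -> None:
        k = (gene, descriptor)
        if k in self.entries:
            raise FormatError(f"duplicate knowledge-base entry {k}")
        entry = KbEntry(oncokb_level, amp_tier)
        if entry == _NONE_ENTRY:
            raise FormatError(f"knowledge-base entry {k} has no classification")
        self.entries[k] = entry

    def lookup(self, gene: str, descriptor: str) -> KbEntry:
        """Most-specific-first lookup for a protein change or 'amplification'."""
        hit = self.entries.get((gene, descriptor))
        if hit is not None:
            return hit
        m = _POSITIONAL_RE.match(descriptor)
        if m and m.group(1) != descriptor:
            hit = self.entries.get((gene, m.group(1)))
            if hit is not None:
                return hit
        return _NONE_ENTRY


_NONE_ENTRY = KbEntry("none", "none")
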