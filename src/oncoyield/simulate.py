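"""Synthetic matched germline / tumor-tissue / cfDNA cohorts with truth labels.

The generator emulates the statistical structure the analysis assumes:

* germline heterozygous variants at true allele fraction 0.5, present
  in all three materials, common in population databases;
* clonal somatic variants with Beta-distributed tissue allele fraction,
  diluted into cfDNA by a per-patient tumor fraction;
* low-VAF SNV artifacts and homopolymer-context indel artifacts drawn
  from a shared pool so that the same artifact recurs across samples;
* observed VAFs are binomial draws at the true allele fraction given a
  Poisson-distributed sequencing depth.

Coverage tables for copy-number estimation and microsatellite
repeat-length profiles are simulated by dedicated helpers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .cnv import CoverageTable
from .model import (
    DB_NAMES,
    Cohort,
    MsiLocusProfile,
    PatientRecord,
    SampleRecord,
    VariantCall,
    VariantKey,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "generate_cohort",
    "simulate_gene_coverage",
    "simulate_msi_cohort",
]

_BASES = "ACGT"
_START_DATE = _dt.date(2022, 1, 1)


@dataclass
class SimulationConfig:
    n_patients: int = 10
    n_germline_het: int = 20
    n_somatic_clonal: int = 12
    tissue_vaf_beta: tuple[float, float] = (8.0, 16.0)  # mean 1/3, clonal-ish
    tumor_fraction: float = 0.3
    tumor_fraction_range: tuple[float, float] | None = None  # overrides scalar
    depth_mean: dict[str, float] = field(default_factory=lambda: {
        "tumor_tissue": 800.0, "cfDNA": 5000.0, "germline_blood": 300.0,
    })
    snv_artifact_rate: float = 5.0          # mean artifacts per cfDNA sample
    snv_artifact_vaf: tuple[float, float] = (0.0005, 0.01)
    indel_artifact_rate: float = 2.0
    indel_artifact_vaf: tuple[float, float] = (0.001, 0.005)
    artifact_pool_size: int = 20            # shared pool -> recurrence
    germline_db_count: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        tf = self.tumor_fraction
        if not 0.0 <= tf <= 1.0:
            raise ValueError(f"tumor_fraction outside [0,1]: {tf}")
        if self.tumor_fraction_range is not None:
            lo, hi = self.tumor_fraction_range
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"bad tumor_fraction_range {self.tumor_fraction_range}")
        if any(v <= 0 for v in self.depth_mean.values()):
            raise ValueError("depth_mean must be positive for every material")
        for rate in (self.snv_artifact_rate, self.indel_artifact_rate):
            if rate < 0:
                raise ValueError("artifact rates must be >= 0")


@dataclass
class TruthLabels:
    #: (patient_id, VariantKey) -> germline | somatic | artifact
    origin: dict[tuple[str, VariantKey], str] = field(default_factory=dict)
    #: patient_id -> cfDNA tumor fraction used
    tumor_fraction: dict[str, float] = field(default_factory=dict)
    #: (patient_id, VariantKey) -> true tissue allele fraction (somatic)
    true_af: dict[tuple[str, VariantKey], float] = field(default_factory=dict)


def _observed(rng: np.random.Generator, true_af: float, mean_depth: float) -> tuple[float, int]:
    depth = int(rng.poisson(mean_depth))
    depth = max(depth, 1)
    alt = int(rng.binomial(depth, min(max(true_af, 0.0), 1.0)))
    return alt / depth, depth


def _snv_key(rng: np.random.Generator, chrom: str, pos: int) -> VariantKey:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return VariantKey(chrom, pos, ref, alt)


def _indel_key(rng: np.random.Generator, chrom: str, pos: int) -> VariantKey:
    # homopolymer-context single-base deletion: anchor + repeated base
    b = _BASES[rng.integers(4)]
    return VariantKey(chrom, pos, b + b, b)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthLabels]:
    """Generate a matched cohort; identical config (incl. seed) yields an
    identical cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthLabels()

    # shared cfDNA artifact pool: recurrence across samples comes from
    # drawing each sample's artifacts out of this fixed pool
    pool: list[tuple[VariantKey, float, bool]] = []  # (key, true vaf, is_indel)
    n_snv_pool = max(config.artifact_pool_size, 1)
    for i in range(n_snv_pool):
        key = _snv_key(rng, "chr3", 3_000_000 + i * 1_000)
        vaf = float(rng.uniform(*config.snv_artifact_vaf))
        pool.append((key, vaf, False))
    for i in range(max(config.artifact_pool_size // 2, 1)):
        key = _indel_key(rng, "chr3", 4_000_000 + i * 1_000)
        vaf = float(rng.uniform(*config.indel_artifact_vaf))
        pool.append((key, vaf, True))
    snv_pool = [p for p in pool if not p[2]]
    indel_pool = [p for p in pool if p[2]]

    zero = {n: 0 for n in DB_NAMES}
    germ_counts = {n: config.germline_db_count for n in DB_NAMES}

    patients = []
    for pi in range(config.n_patients):
        pid = f"SIM{pi + 1:03d}"
        if config.tumor_fraction_range is not None:
            tf = float(rng.uniform(*config.tumor_fraction_range))
        else:
            tf = config.tumor_fraction
        truth.tumor_fraction[pid] = tf

        germline_vars = []
        for gi in range(config.n_germline_het):
            key = _snv_key(rng, "chr1", 1_000_000 + pi * 5_000_000 + gi * 10_000)
            germline_vars.append(key)
            truth.origin[(pid, key)] = "germline"
        somatic_vars = []
        for si in range(config.n_somatic_clonal):
            key = _snv_key(rng, "chr2", 2_000_000 + pi * 5_000_000 + si * 10_000)
            af = float(rng.beta(*config.tissue_vaf_beta))
            somatic_vars.append((key, af))
            truth.origin[(pid, key)] = "somatic"
            truth.true_af[(pid, key)] = af

        samples = []
        for material in ("germline_blood", "tumor_tissue", "cfDNA"):
            suffix = {"germline_blood": "G", "tumor_tissue": "T", "cfDNA": "LB"}[material]
            sid = f"{pid}-{suffix}"
            mean_depth = config.depth_mean[material]
            calls: list[VariantCall] = []
            for gi, key in enumerate(germline_vars):
                vaf, depth = _observed(rng, 0.5, mean_depth)
                calls.append(VariantCall(
                    key=key, gene=f"GLG{gi:03d}", vaf=vaf, depth=depth,
                    sample_id=sid, consequence="nonsynonymous",
                    db_counts=dict(germ_counts),
                ))
            if material in ("tumor_tissue", "cfDNA"):
                for si, (key, af) in enumerate(somatic_vars):
                    true_af = af if material == "tumor_tissue" else af * tf
                    vaf, depth = _observed(rng, true_af, mean_depth)
                    calls.append(VariantCall(
                        key=key, gene=f"SOM{si:03d}", vaf=vaf, depth=depth,
                        sample_id=sid, consequence="nonsynonymous",
                        db_counts=dict(zero),
                    ))
            if material == "cfDNA":
                for sub_pool, rate in (
                    (snv_pool, config.snv_artifact_rate),
                    (indel_pool, config.indel_artifact_rate),
                ):
                    if not sub_pool or rate <= 0:
                        continue
                    n_art = min(int(rng.poisson(rate)), len(sub_pool))
                    chosen = rng.choice(len(sub_pool), size=n_art, replace=False)
                    for ci in sorted(chosen):
                        key, true_vaf, is_indel = sub_pool[ci]
                        vaf, depth = _observed(rng, true_vaf, mean_depth)
                        if vaf == 0.0:
                            continue  # artifact not observed at this depth
                        truth.origin.setdefault((pid, key), "artifact")
                        calls.append(VariantCall(
                            key=key, gene="ARTF", vaf=vaf, depth=depth,
                            sample_id=sid, consequence="noncoding",
                            db_counts=dict(zero), repeat_context=is_indel,
                        ))
            samples.append(SampleRecord(
                sample_id=sid, patient_id=pid, material=material,
                collection_date=_START_DATE, calls=calls,
            ))
        patients.append(PatientRecord(
            patient_id=pid, inclusion_criteria={1}, samples=samples,
        ))
    return Cohort(patients), truth


def artifact_flood_config(seed: int) -> SimulationConfig:
    """Study condition with a planted cfDNA artifact flood.

    Low-VAF SNV artifacts are concentrated just above the lowest cfDNA
    cut-off (true VAF 0.0012-0.003, below 0.005), so the variant sets
    at cut-off 0.001 are swamped while those at 0.005 and above remain
    clean: the concordance-driven selection should recover the
    (tissue 0.05, cfDNA 0.005) working pair.
    """
    return SimulationConfig(
        n_patients=6,
        n_germline_het=10,
        n_somatic_clonal=12,
        tissue_vaf_beta=(8.0, 16.0),
        tumor_fraction=0.3,
        snv_artifact_rate=25.0,
        snv_artifact_vaf=(0.0012, 0.003),
        indel_artifact_rate=0.0,
        artifact_pool_size=40,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Copy-number coverage simulation


def simulate_gene_coverage(
    genes: dict[str, float],
    n_targets_per_gene: int = 20,
    depth_mean: float = 500.0,
    n_normals: int = 8,
    gc_slope: float = 0.0,
    seed: int = 0,
) -> tuple[CoverageTable, list[CoverageTable]]:
    """Simulate per-target coverage for a sample with per-gene true
    fold-changes ``genes`` (1.0 = diploid) plus a panel of diploid
    normals.  ``gc_slope`` adds a linear GC bias to the sample's
    log2-coverage, which the caller's GC correction should remove."""
    rng = np.random.default_rng(seed)
    gene_names = [g for g in genes for _ in range(n_targets_per_gene)]
    n = len(gene_names)
    gc = rng.uniform(0.3, 0.7, size=n)
    true_fc = np.array([genes[g] for g in gene_names])
    bias = 2.0 ** (gc_slope * (gc - 0.5))
    sample_depth = rng.poisson(depth_mean * true_fc * bias)
    sample = CoverageTable(gene_names, gc, sample_depth, role="sample")
    normals = [
        CoverageTable(gene_names, gc, rng.poisson(depth_mean, size=n), role="normal")
        for _ in range(n_normals)
    ]
    return sample, normals


# ---------------------------------------------------------------------------
# Microsatellite profile simulation


def simulate_msi_cohort(
    n_loci: int = 120,
    depth: int = 400,
    n_normals: int = 12,
    unstable: bool = False,
    shifted_locus_fraction: float = 0.3,
    shift: int = 2,
    seed: int = 0,
) -> tuple[list[MsiLocusProfile], list[list[MsiLocusProfile]]]:
    """Simulate a sample's microsatellite locus profiles and a panel of
    normals.  Stable loci have a shared modal repeat length with
    stutter; an unstable sample shifts the mode shorter by ``shift``
    repeats at ``shifted_locus_fraction`` of loci."""
    rng = np.random.default_rng(seed)
    modes = rng.integers(10, 25, size=n_loci)
    stutter = np.array([0.05, 0.15, 0.60, 0.15, 0.05])  # around the mode
    offsets = np.arange(-2, 3)

    def draw_profile(locus: int, mode: int) -> MsiLocusProfile:
        counts = rng.multinomial(depth, stutter)
        return MsiLocusProfile(
            locus_id=f"L{locus:03d}",
            length_counts={int(mode + o): int(c) for o, c in zip(offsets, counts) if c > 0},
        )

    normals = [[draw_profile(i, int(modes[i])) for i in range(n_loci)]
               for _ in range(n_normals)]
    shifted = rng.random(n_loci) < shifted_locus_fraction if unstable else np.zeros(n_loci, bool)
    sample = [
        draw_profile(i, int(modes[i]) - (shift if shifted[i] else 0))
        for i in range(n_loci)
    ]
    return sample, normals
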