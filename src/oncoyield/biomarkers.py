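"""Panel biomarkers: tumor mutational burden and microsatellite status.

TMB counts the *eligible* variants of a sample — coding, VAF >= 5%,
coverage >= 50x, SNVs and short indels only (MNVs excluded), both
synonymous and nonsynonymous, hotspots with COSMIC count >= 50
excluded — divided by the panel coding size in megabases.

MSI compares each locus's repeat-length read distribution to the mean
distribution of a panel of normals via total-variation distance.  The
sample-level score is the mean over loci of the excess distance beyond
the panel's own self-distance; instability is called when the score
reaches 0.1 with a resampling p-value <= 0.01 (both inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MsiLocusProfile, VariantCall

__all__ = [
    "TmbResult",
    "MsiResult",
    "MsiBaseline",
    "tmb_eligible",
    "compute_tmb",
    "build_msi_baseline",
    "msi_call",
    "msi_status",
]

TMB_VAF_MIN = 0.05
TMB_DEPTH_MIN = 50
TMB_COSMIC_MAX = 50          # COSMIC count >= 50 excluded
SHORT_INDEL_MAX_BP = 25      # length bound for a "short" indel
DEFAULT_PANEL_SIZE_MB = 1.2  # panel coding size in Mb

MSI_DIFF_THRESHOLD = 0.1
MSI_P_THRESHOLD = 0.01


@dataclass(frozen=True)
class TmbResult:
    eligible_count: int
    panel_size_mb: float
    tmb: float


def tmb_eligible(call: VariantCall) -> bool:
    """Eligibility filter for the TMB numerator."""
    if call.consequence == "noncoding":
        return False
    if call.variant_class == "MNV":
        return False
    if call.is_indel:
        indel_len = abs(len(call.key.ref) - len(call.key.alt))
        if indel_len > SHORT_INDEL_MAX_BP:
            return False
    return (
        call.vaf >= TMB_VAF_MIN
        and call.depth >= TMB_DEPTH_MIN
        and call.cosmic_count < TMB_COSMIC_MAX
    )


def compute_tmb(calls: list[VariantCall], panel_size_mb: float = DEFAULT_PANEL_SIZE_MB) -> TmbResult:
    if panel_size_mb <= 0:
        raise ValueError(f"panel_size_mb must be > 0, got {panel_size_mb}")
    n = sum(1 for c in calls if tmb_eligible(c))
    return TmbResult(n, panel_size_mb, n / panel_size_mb)


# ---------------------------------------------------------------------------
# MSI


@dataclass
class MsiBaseline:
    """Panel-of-normals reference: per-locus mean length distribution
    and the panel's mean self-distance to it."""

    mean_dist: dict[str, dict[int, float]]
    self_distance: dict[str, float]


@dataclass
class MsiResult:
    locus_distances: dict[str, float]
    mean_distance_difference: float
    p_value: float
    status: str  # MSI | MSS


def _normalize(counts: dict[int, int] | dict[int, float]) -> dict[int, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def _tv_distance(a: dict[int, float], b: dict[int, float]) -> float:
    lengths = set(a) | set(b)
    return 0.5 * sum(abs(a.get(l, 0.0) - b.get(l, 0.0)) for l in lengths)


def build_msi_baseline(normals: list[list[MsiLocusProfile]]) -> MsiBaseline:
    """Mean normalized length distribution per locus across normals, and
    each locus's mean normal-to-baseline distance (the self-distance)."""
    if not normals:
        raise ValueError("empty panel of normals")
    by_locus: dict[str, list[dict[int, float]]] = {}
    for sample in normals:
        for prof in sample:
            by_locus.setdefault(prof.locus_id, []).append(_normalize(prof.length_counts))
    mean_dist: dict[str, dict[int, float]] = {}
    self_distance: dict[str, float] = {}
    for locus, dists in by_locus.items():
        lengths = sorted({l for d in dists for l in d})
        mean = {l: float(np.mean([d.get(l, 0.0) for d in dists])) for l in lengths}
        mean_dist[locus] = mean
        self_distance[locus] = float(np.mean([_tv_distance(d, mean) for d in dists]))
    return MsiBaseline(mean_dist, self_distance)


def msi_status(
    mean_diff: float,
    p_value: float,
    diff_threshold: float = MSI_DIFF_THRESHOLD,
    p_threshold: float = MSI_P_THRESHOLD,
) -> str:
    """Call rule with inclusive boundaries on both thresholds."""
    return "MSI" if (mean_diff >= diff_threshold and p_value <= p_threshold) else "MSS"


def msi_call(
    sample_profiles: list[MsiLocusProfile],
    baseline: MsiBaseline,
    n_resamples: int = 10_000,
    seed: int = 0,
    diff_threshold: float = MSI_DIFF_THRESHOLD,
    p_threshold: float = MSI_P_THRESHOLD,
) -> MsiResult:
    """Sample-level microsatellite score against a panel of normals.

    Per locus the score contribution is the total-variation distance of
    the sample's normalized length distribution to the baseline mean,
    minus the panel's self-distance at that locus.  The p-value is the
    fraction of null scores — obtained by redrawing each locus's read
    counts multinomially from the baseline mean at the sample's depth —
    at least as large as the observed score (seeded, add-one corrected).
    """
    if not baseline.mean_dist:
        raise ValueError("empty baseline")
    shared = [p for p in sample_profiles if p.locus_id in baseline.mean_dist]
    if not shared:
        raise ValueError("no loci shared between sample and baseline")

    locus_distances: dict[str, float] = {}
    diffs = []
    for prof in shared:
        d = _tv_distance(_normalize(prof.length_counts), baseline.mean_dist[prof.locus_id])
        locus_distances[prof.locus_id] = d
        diffs.append(d - baseline.self_distance[prof.locus_id])
    observed = float(np.mean(diffs))

    rng = np.random.default_rng(seed)
    null_diffs = np.zeros((n_resamples, len(shared)))
    for j, prof in enumerate(shared):
        mean = baseline.mean_dist[prof.locus_id]
        lengths = sorted(mean)
        probs = np.array([mean[l] for l in lengths], dtype=float)
        probs = probs / probs.sum()
        depth = prof.total
        draws = rng.multinomial(depth, probs, size=n_resamples) / depth  # n_resamples x L
        tv = 0.5 * np.abs(draws - probs).sum(axis=1)
        null_diffs[:, j] = tv - baseline.self_distance[prof.locus_id]
    null_scores = null_diffs.mean(axis=1)
    p = float((1 + np.sum(null_scores >= observed)) / (1 + n_resamples))

    return MsiResult(
        locus_distances,
        observed,
        p,
        msi_status(observed, p, diff_threshold, p_threshold),
    )
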