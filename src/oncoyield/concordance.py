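"""Tissue vs cfDNA variant-calling concordance over a VAF cut-off grid.

For each patient with paired tumor-tissue and plasma sequencing, the
variant sets surviving every (tissue cut-off, cfDNA cut-off) pair are
intersected and a Jaccard index computed, yielding a per-patient
concordance grid.  Across patients, the JI distributions of all cut-off
pairs are compared with paired t-tests (Benjamini–Hochberg adjusted),
and the working cut-off pair is the most permissive pair whose
concordance is not significantly inferior to any stricter pair.

A recurrent low-VAF indel filter removes homopolymer-context indels
observed between the lower and upper cfDNA indel cut-offs in more than
one sample — the signature of a sequencing artefact rather than a
tumor-derived variant.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import SampleRecord, VariantCall, VariantKey

__all__ = [
    "CutoffGrid",
    "ConcordanceGrid",
    "CutoffSelection",
    "PairComparison",
    "filter_by_cutoff",
    "jaccard_index",
    "concordance_grid",
    "select_cutoff_pair",
    "flag_indel_artifacts",
]


@dataclass(frozen=True)
class CutoffGrid:
    """Ordered (strictly decreasing) VAF cut-off ladders per material."""

    tissue_cutoffs: tuple[float, ...] = (0.10, 0.05)
    cfdna_cutoffs: tuple[float, ...] = (0.10, 0.05, 0.01, 0.005, 0.001)

    def __post_init__(self) -> None:
        for name, cuts in (("tissue", self.tissue_cutoffs), ("cfdna", self.cfdna_cutoffs)):
            if not all(0 < c < 1 for c in cuts):
                raise ValueError(f"{name} cutoffs must lie in (0,1): {cuts}")
            if list(cuts) != sorted(cuts, reverse=True) or len(set(cuts)) != len(cuts):
                raise ValueError(f"{name} cutoffs must be strictly decreasing: {cuts}")

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return [(t, c) for t in self.tissue_cutoffs for c in self.cfdna_cutoffs]


@dataclass
class ConcordanceGrid:
    patient_id: str
    ji: dict[tuple[float, float], float]
    empty_flagged: set[tuple[float, float]] = field(default_factory=set)


@dataclass
class PairComparison:
    pair_a: tuple[float, float]
    pair_b: tuple[float, float]
    t_statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class CutoffSelection:
    chosen: tuple[float, float]
    comparisons: list[PairComparison]
    summary: dict[tuple[float, float], tuple[float, float]]  # pair -> (median JI, sd)


def filter_by_cutoff(
    calls: list[VariantCall],
    material: str,
    snv_cutoff: float,
    indel_cutoff: float | None = None,
) -> set[VariantKey]:
    """Variant keys whose VAF meets the class-appropriate cut-off
    (inclusive ``>=``).  Tissue uses a single threshold for all classes;
    cfDNA may split SNV/MNV vs InDel thresholds."""
    if indel_cutoff is None:
        indel_cutoff = snv_cutoff
    if material == "tumor_tissue" and indel_cutoff != snv_cutoff:
        raise ValueError("tissue uses a single VAF threshold for all variant classes")
    for c in (snv_cutoff, indel_cutoff):
        if not 0 < c < 1:
            raise ValueError(f"cutoff outside (0,1): {c}")
    out = set()
    for call in calls:
        cut = indel_cutoff if call.is_indel else snv_cutoff
        if call.vaf >= cut:
            out.add(call.key)
    return out


def jaccard_index(a: set[VariantKey], b: set[VariantKey]) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both sets are empty (flagged upstream)."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def concordance_grid(
    tissue_calls: list[VariantCall],
    cfdna_calls: list[VariantCall],
    grid: CutoffGrid = CutoffGrid(),
    patient_id: str = "",
) -> ConcordanceGrid:
    """One Jaccard index per (tissue cut-off, cfDNA cut-off) pair."""
    ji: dict[tuple[float, float], float] = {}
    flagged: set[tuple[float, float]] = set()
    for t_cut, c_cut in grid.pairs:
        t_set = filter_by_cutoff(tissue_calls, "tumor_tissue", t_cut)
        c_set = filter_by_cutoff(cfdna_calls, "cfDNA", c_cut)
        if not t_set and not c_set:
            flagged.add((t_cut, c_cut))
        ji[(t_cut, c_cut)] = jaccard_index(t_set, c_set)
    return ConcordanceGrid(patient_id, ji, flagged)


def _stricter_pairs(pair: tuple[float, float], pairs: list[tuple[float, float]]):
    t, c = pair
    return [p for p in pairs if p != pair and p[0] >= t and p[1] >= c]


def select_cutoff_pair(grids: list[ConcordanceGrid], alpha: float = 0.05) -> CutoffSelection:
    """Pick the most permissive cut-off pair not significantly inferior
    to any stricter pair.

    All pairwise paired t-tests between cut-off pairs are computed
    across patients and BH-FDR adjusted.  Candidates are scanned from
    the most permissive (lowest tissue cut-off, then lowest cfDNA
    cut-off); a candidate is rejected if, versus any componentwise
    stricter pair, its mean JI is lower with adjusted p < alpha.
    """
    if len(grids) < 2:
        raise ValueError("paired testing requires at least 2 patients")
    pairs = sorted(grids[0].ji.keys(), key=lambda p: (-p[0], -p[1]))
    mat = np.array([[g.ji[p] for p in pairs] for g in grids])  # patients x pairs

    comparisons: list[PairComparison] = []
    raw_p: list[float] = []
    idx = {p: i for i, p in enumerate(pairs)}
    for i, a in enumerate(pairs):
        for b in pairs[i + 1:]:
            xa, xb = mat[:, idx[a]], mat[:, idx[b]]
            if np.allclose(xa, xb):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(xa, xb)
            comparisons.append(PairComparison(a, b, float(t), float(p), np.nan))
            raw_p.append(float(p))
    adjusted = multipletests(raw_p, method="fdr_bh")[1]
    for comp, padj in zip(comparisons, adjusted):
        comp.p_adjusted = float(padj)
    lookup = {frozenset((c.pair_a, c.pair_b)): c for c in comparisons}

    def inferior(cand: tuple[float, float], stricter: tuple[float, float]) -> bool:
        comp = lookup[frozenset((cand, stricter))]
        mean_c = mat[:, idx[cand]].mean()
        mean_s = mat[:, idx[stricter]].mean()
        return mean_c < mean_s and comp.p_adjusted < alpha

    candidates = sorted(pairs, key=lambda p: (p[0], p[1]))  # most permissive first
    chosen = candidates[-1]  # strictest pair is always admissible
    for cand in candidates:
        if not any(inferior(cand, s) for s in _stricter_pairs(cand, pairs)):
            chosen = cand
            break

    summary = {
        p: (float(statistics.median(mat[:, idx[p]])), float(np.std(mat[:, idx[p]], ddof=1)))
        for p in pairs
    }
    return CutoffSelection(chosen, comparisons, summary)


def flag_indel_artifacts(
    cfdna_samples: list[SampleRecord],
    lower: float = 0.001,
    upper: float = 0.005,
    min_samples: int = 2,
) -> set[VariantKey]:
    """Recurrent repeat-context indel artefacts across a cfDNA cohort.

    Flags indel keys with ``lower <= vaf < upper``, homopolymer repeat
    context, and presence in at least ``min_samples`` distinct samples.
    Flagged keys are excluded from actionable sets downstream.
    """
    seen: dict[VariantKey, set[str]] = {}
    for sample in cfdna_samples:
        for call in sample.calls:
            if (
                call.is_indel
                and call.repeat_context
                and lower <= call.vaf < upper
            ):
                seen.setdefault(call.key, set()).add(sample.sample_id)
    return {k for k, sids in seen.items() if len(sids) >= min_samples}
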