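"""Gene-level copy-number fold-changes from target coverage, and the
fold-change -> GISTIC actionability mapping.

Coverage is library-median normalized, ratioed against the median of a
panel of normals per target, GC-corrected by residualizing a lowess
trend of log2-ratio on GC fraction, and summarized per gene as the
median corrected ratio.

GISTIC categories (tissue): FC < 0.2 -> -2 (homozygous deletion),
< 0.7 -> -1 (hemizygous deletion), < 1.5 -> 0 (neutral), < 2 -> 1
(gain), >= 2 -> 2 (high-level amplification).  Shared boundary values
go to the higher category.  For cfDNA — where the non-tumor fraction
dilutes the signal — FC >= 1.5 already counts as high-level
amplification (category 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import CopyNumberCall

__all__ = ["CoverageTable", "estimate_fold_changes", "gistic_category"]

MIN_TARGETS_PER_GENE = 3
GC_LOWESS_FRAC = 0.5


@dataclass
class CoverageTable:
    """Per-target coverage: parallel arrays of gene, GC fraction, depth."""

    genes: list[str]
    gc_fraction: np.ndarray
    depth: np.ndarray
    role: str = "sample"  # sample | normal

    def __post_init__(self) -> None:
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if not (len(self.genes) == len(self.gc_fraction) == len(self.depth)):
            raise ValueError("gene/gc/depth arrays must be parallel")
        if np.any(self.depth < 0):
            raise ValueError("negative depth")
        if np.any((self.gc_fraction < 0) | (self.gc_fraction > 1)):
            raise ValueError("gc_fraction outside [0,1]")


def estimate_fold_changes(
    sample: CoverageTable,
    normals: list[CoverageTable],
    material: str = "tumor_tissue",
    min_targets: int = MIN_TARGETS_PER_GENE,
    gc_frac: float = GC_LOWESS_FRAC,
) -> list[CopyNumberCall]:
    """Panel-of-normals normalized, GC-corrected gene fold-changes.

    Targets are matched positionally between the sample and every
    normal (same panel design assumed).  Genes with fewer than
    ``min_targets`` targets or absent from the normals are skipped with
    a warning.
    """
    if len(normals) < 2:
        raise ValueError("need at least 2 normal samples")
    for n in normals:
        if len(n.depth) != len(sample.depth):
            raise ValueError("sample and normals must share the panel design")

    def libnorm(depth: np.ndarray) -> np.ndarray:
        med = np.median(depth[depth > 0])
        return depth / med

    s = libnorm(sample.depth)
    normal_mat = np.vstack([libnorm(n.depth) for n in normals])
    ref = np.median(normal_mat, axis=0)
    ok = ref > 0
    if not np.all(ok):
        warnings.warn(f"{np.sum(~ok)} targets with zero normal coverage excluded")
    ratio = np.full_like(s, np.nan)
    ratio[ok] = np.maximum(s[ok], 1e-9) / ref[ok]
    log2r = np.log2(ratio[ok])
    gc = sample.gc_fraction[ok]

    # GC correction: remove the lowess trend of log2-ratio on GC while
    # preserving the overall coverage level
    if len(np.unique(gc)) > 2:
        trend = lowess(log2r, gc, frac=gc_frac, return_sorted=False)
        corrected = log2r - trend + np.median(log2r)
    else:
        corrected = log2r

    corrected_full = np.full_like(ratio, np.nan)
    corrected_full[ok] = 2.0 ** corrected

    calls: list[CopyNumberCall] = []
    seen: dict[str, list[float]] = {}
    for gene, val in zip(sample.genes, corrected_full):
        if np.isfinite(val):
            seen.setdefault(gene, []).append(val)
    for gene in dict.fromkeys(sample.genes):  # preserve panel order
        vals = seen.get(gene, [])
        if len(vals) < min_targets:
            warnings.warn(f"gene {gene}: only {len(vals)} usable targets, skipped")
            continue
        fc = float(np.median(vals))
        calls.append(CopyNumberCall(gene=gene, fold_change=fc, material=material,
                                    gistic_category=gistic_category(fc, material)))
    return calls


def gistic_category(fc: float, material: str) -> int:
    """Map a coverage fold-change to a GISTIC copy-number category.

    Boundary values go to the higher category; cfDNA amplification is
    called at FC >= 1.5 to compensate for dilution by non-tumor DNA.
    """
    if fc <= 0:
        raise ValueError(f"fold-change must be > 0, got {fc}")
    if material == "cfDNA" and fc >= 1.5:
        return 2
    if fc < 0.2:
        return -2
    if fc < 0.7:
        return -1
    if fc < 1.5:
        return 0
    if fc < 2.0:
        return 1
    return 2
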