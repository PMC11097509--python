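# Methods

This note documents the models, rules, parameters and design choices
behind `oncoyield`, in the order the pipeline applies them.

## Variant identity

All set operations (concordance, integration, deduplication) compare
variants by a normalized `(chrom, pos, ref, alt)` key in VCF
convention: 1-based coordinates, indels carrying a single anchor base.
Normalization trims shared suffix then prefix bases and, when a
reference sequence is supplied, left-shifts indels through repeat
tracts (`vt normalize` style). Gene symbols and HGVS strings are
display metadata only: the same genomic change can carry different
HGVS strings under different transcripts (the packaged cohort itself
records one frameshift under two transcript names), so protein-level
identity is used only where the data are inherently protein-level —
the prior-testing registry and the knowledge base.

## Concordance-driven VAF cut-off selection

For each patient with paired tissue and plasma sequencing, variant
sets are taken at every combination of tissue cut-offs (10%, 5%) and
cfDNA cut-offs (10%, 5%, 1%, 0.5%, 0.1%), with inclusive (≥)
comparison; the Jaccard index of each of the 10 pairs forms the
patient's concordance grid. The degenerate empty-vs-empty case is
defined as JI = 1 and flagged; it never arises in real data.

Across patients, all 45 pairwise paired t-tests between cut-off pairs
are computed and Benjamini–Hochberg adjusted (two-sided, alpha 0.05).
Candidates are scanned from the most permissive (lowest tissue, then
lowest cfDNA cut-off); a candidate loses only to a componentwise
stricter pair with higher mean JI at adjusted p < alpha. This
implements non-inferiority selection: the chosen pair is the loosest
one whose concordance has not measurably degraded. The working
thresholds applied downstream are tissue 5% for all classes and, for
cfDNA, 0.1% for SNVs/MNVs but 0.5% for indels, because low-VAF indels
between those bounds that sit in homopolymer runs and recur in ≥ 2
samples are flagged as sequencing artefacts and excluded (repeat
context defaults to a homopolymer run ≥ 4 of the affected base;
recurrence threshold 2; all configurable).

## Tumor-only germline flagging

*Database rule*: flagged germline when observed > 50 times in at least
2 of the 3 population databases (gnomAD-exome-like, gnomAD-genome-like,
1000G-like; configurable names, integer counts), the VAF falls in a
zygosity-compatible band (default [0.40, 0.60] ∪ [0.90, 1.00]; the
bands are our quantification of "around 50% or 100%"), and somatic
hotspot evidence is weak (COSMIC count < 50, mirroring the TMB
exclusion constant).

*Proximal-VAF rule*: the expected germline allele fraction is the
median VAF of ≥ 5 database-flagged germline neighbors within ±1 Mb on
the same chromosome; the call's alt-read count is tested against it
with an exact two-sided binomial test, and p ≥ 0.01 (i.e. *failure* to
reject) marks the call germline-like. Fewer than 5 neighbors yields
`False` with an "insufficient-neighbors" note. The vendor pipelines
that inspired this annotation do not publish their statistic; the
binomial formulation is this package's own, and its three parameters
(window, minimum neighbors, p-threshold) are configuration.

*Origin*: when a matched blood sample exists, presence of the key
there is decisive and overrides both predictions; otherwise either
flag yields a `germline` origin marked `predicted`. The
germline-focused analysis then reports, per patient, the confirmed
germline pathogenic/likely-pathogenic variants (ACMG class is an
input, never computed) annotated with hereditary-panel coverage;
off-panel genes are labeled as secondary findings a dedicated germline
panel could never have returned.

## TMB and MSI

TMB counts eligible variants — coding consequence, VAF ≥ 5%, depth
≥ 50x, SNVs and indels ≤ 25 bp (MNVs excluded; "short indel" has no
published bound, 25 bp is our default), COSMIC count < 50 — divided by
the panel coding size (default 1.2 Mb, the printed coding footprint of
the 523-gene panel; the vendor's exact eligible region is not public).
Both synonymous and nonsynonymous variants count.

MSI compares each locus's normalized repeat-length read distribution
to the mean distribution of a panel of normals by total-variation
distance. The sample score is the mean over loci of the distance in
excess of the panel's own mean self-distance. Instability is called at
score ≥ 0.1 and p ≤ 0.01, both inclusive. The p-value comes from a
seeded Monte Carlo null: each locus's counts are redrawn multinomially
from the baseline mean at the sample's observed depth (10,000
resamples by default). A swap-based permutation against the panel
itself cannot resolve p ≤ 0.01 with realistic panel sizes (the null
has resolution 1/(n+1)), which is why the resampling null is used.
The vendor's proprietary score scale is treated as opaque; the
packaged cohort stores reported statuses (all stable) rather than
recomputing vendor numbers.

## Copy number

Per-target depth is library-median normalized and ratioed against the
median of ≥ 2 normals; a lowess trend of log2-ratio on GC fraction
(frac = 0.5) is subtracted and the global median added back, so GC
bias is removed without shifting the overall level; the gene
fold-change is the median corrected target ratio (minimum 3 usable
targets per gene). GISTIC mapping for tissue: FC < 0.2 → −2, < 0.7 →
−1, < 1.5 → 0, < 2 → +1, ≥ 2 → +2, with shared boundaries assigned to
the higher category. For cfDNA, FC ≥ 1.5 already maps to +2: tumor
DNA is diluted by non-tumor cfDNA, and the boundary convention is
chosen so that a reported cfDNA amplification at exactly FC 1.5
reproduces its reported high-level call. No tumor-fraction
deconvolution is attempted; the thresholds are material-specific
constants, as in the source protocol.

## Actionability and temporal integration

A local knowledge base maps (gene, descriptor) to an OncoKB level and
an AMP/ASCO/CAP tier; descriptors are matched most-specific-first
(exact protein change, then positional class such as `p.V600`, then
`amplification`), and duplicates are rejected at load. Actionable
means level ∈ {1, 2, 3A, 3B} or tier ∈ {IA, IB, IIB, IIC, IID}.
Evidence ordering for reporting is 1 > 2 > 3A > 3B > 4 > none, ties
broken lexicographically. Because the same protein change can carry
different tiers in different tumor types, the knowledge base stores
one row per descriptor at the highest reported evidence; all reported
classifications for such variants fall inside the actionable window,
so yield accounting is unaffected, and the per-sample reported tiers
are kept as display metadata in the fixture.

Per patient, the integrated somatic set is the key-deduplicated union
of actionable tissue and cfDNA alterations when |plasma date − tissue
date| ≤ 122 days ("4 months"; a month is never defined in clinical
protocols, so the window is a configurable day count), and the cfDNA
set alone otherwise. Copy-number targets enter at GISTIC +2 only.
Confirmed germline-origin variants are excluded from the somatic set
and counted in the germline yield — a patient can appear in the
actionable cohort purely through a germline level-3B variant without
contributing to the somatic-integrated fraction. The novel-only yield
excludes targets whose protein-level identity appears in the patient's
prior routine-testing registry.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with
truth labels for every call: germline heterozygous variants at true
allele fraction 0.5 present in all three materials and assigned
population-database counts of 100; clonal somatic variants with
Beta(8, 16) tissue allele fraction (mean ≈ 0.33), diluted into cfDNA
by a per-patient tumor fraction (default 0.3, optionally drawn from a
range); artifacts drawn from a shared pool (SNVs uniform VAF
0.0005–0.01, homopolymer-context indels 0.001–0.005) so the same
artifact recurs across samples; Poisson depth per material (defaults
800x tissue, 5,000x cfDNA, 300x blood) with binomially sampled
observed VAFs. The `artifact_flood_config` study condition
concentrates SNV artifacts at true VAF 0.0012–0.003 — just above the
lowest cfDNA rung but safely below 0.5% — so the concordance-driven
selection should recover (5%, 0.5%).

What the generator does **not** model: subclonal structure (cfDNA
dilution is a single factor — sufficient because the cut-off machinery
only needs presence/absence across thresholds), read-level errors,
mappability, FFPE deamination spectra, CNV-driven VAF distortion, or
clinical timelines beyond collection dates. Passing recovery tests on
these cohorts therefore validates the decision logic and its
statistics, not caller-level performance on real sequencing data.

## Problem sizes and numerics

Simulation-based tests use cohorts of 5–25 patients with 20–40
variants each (1,000 labeled variants for the classifier checks), 100
replicate cohorts of 6 patients for cut-off recovery, 20 targets per
gene at Poisson depth 500 for copy-number recovery, and 120
microsatellite loci at depth 400 with 12 normals. MSI resampling uses
500–10,000 draws depending on context. All randomness flows through
seeded `numpy` generators; paired t-tests on numerically identical JI
columns short-circuit to p = 1 to avoid 0/0 degeneracy; binomial
expected allele fractions are clipped away from {0, 1}.

## Known limitations

The per-patient concordance values of any specific real cohort are not
reproducible from this package (raw calls are not public); the fixture
reproduces the reported *decisions and fractions*, not raw sequencing.
The proximal-VAF statistic is a declared stand-in for an unpublished
vendor annotation. Deletion actionability (GISTIC −2) is not looked up
in the knowledge base because no packaged entry requires it. The VCF
reader is deliberately minimal: one sample per file, no breakends or
multi-sample support.
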