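# oncoyield

Integrated germline / tumor-tissue / cfDNA comprehensive genomic
profiling for matched cancer cohorts: concordance-driven VAF cut-off
selection, tumor-only germline flagging, TMB/MSI/CNV biomarker rules,
and therapeutic actionability-yield accounting.

## The problem

Precision-oncology programs increasingly profile three materials per
patient — germline blood DNA, tumor-tissue DNA, and plasma cell-free
DNA (cfDNA) — with large targeted panels. Turning those three variant
streams into a single answer ("does this patient carry at least one
therapeutically actionable alteration, and is it new?") requires a
chain of statistical and rule-based decisions:

1. **Where to cut on VAF.** For each patient with paired tissue and
   plasma sequencing, the Jaccard index J(A,B) = |A∩B| / |A∪B| between
   the variant sets surviving each (tissue, cfDNA) VAF cut-off pair
   (tissue 10%/5% x cfDNA 10%/5%/1%/0.5%/0.1%) measures concordance.
   Paired t-tests with Benjamini–Hochberg FDR across patients pick the
   most permissive pair not significantly inferior to any stricter
   pair. Recurrent low-VAF homopolymer-context indels seen in more
   than one cfDNA sample are flagged as sequencing artefacts.
2. **Germline vs somatic in tumor-only data.** A variant observed
   > 50 times in at least 2 of 3 germline population databases with a
   VAF near 50% or 100% (database rule), or whose alt-read count is
   binomially compatible with the allele fraction of surrounding
   germline variants (proximal-VAF rule), is flagged as probably
   germline; matched blood, when available, is the confirmation
   standard and overrides both.
3. **Biomarkers.** Panel TMB = eligible mutations (coding, VAF ≥ 5%,
   depth ≥ 50x, SNVs/short indels, COSMIC count < 50) per megabase of
   coding panel (1.2 Mb default). MSI is called when the mean
   total-variation distance of per-locus repeat-length distributions
   to a panel of normals exceeds 0.1 with p ≤ 0.01.
4. **Copy number.** Panel-of-normals-normalized, GC-corrected coverage
   fold-changes map to GISTIC categories (FC ≥ 2 = high-level
   amplification in tissue; FC ≥ 1.5 already counts in cfDNA, where
   non-tumor DNA dilutes the signal).
5. **Actionability and integration.** Alterations annotated from a
   local knowledge base (OncoKB level 1–3B / AMP-ASCO-CAP Tier IA–IID
   = actionable) are pooled across tissue and cfDNA only when the
   tissue was collected within 4 months (122 days) of plasma;
   otherwise cfDNA alone counts. Confirmed germline variants are
   routed to the germline yield, never the somatic one.

The package ships a 23-patient real-world cohort fixture with all its
reported variants, classifications and collection-window flags, plus a
seeded synthetic-cohort generator with truth labels for validating
every statistical component.

## Worked example

```bash
oncoyield fixture --out cohort/
oncoyield yield --cohort cohort/ --kb cohort/kb.tsv --out report/
```

prints

```
any_actionable: 13/23 (56.5%)
somatic_integrated: 10/23 (43.5%)
tissue_level: 7/16 (43.8%)
cfdna_level: 9/23 (39.1%)
```

i.e. integrated tissue+cfDNA+germline profiling finds at least one
actionable alteration in 13 of 23 patients; the temporally integrated
somatic analysis alone covers 10; tissue-only and cfDNA-only
sample-level yields are 7/16 and 9/23. `report/` additionally contains
the per-patient table, the full JSON report (germline P/LP 7/23,
level-3B germline 5/23, and the novel-only yield 10/23 after removing
alterations already known from routine testing) and gene-by-patient
oncoprint matrices for both materials.

The same pipeline runs end-to-end on simulated data:

```bash
oncoyield run --simulate --seed 7 --out bundle/
```

which generates a matched cohort, computes the concordance grid and
cut-off selection, writes germline flags and per-sample TMB, and is
byte-reproducible under a fixed seed.

## Layout

| module | responsibility |
|---|---|
| `oncoyield.model` | domain types, variant normalization, knowledge base |
| `oncoyield.io` | TSV/VCF/YAML readers and writers |
| `oncoyield.simulate` | seeded synthetic cohorts with truth labels |
| `oncoyield.fixture` | the packaged 23-patient study cohort |
| `oncoyield.concordance` | Jaccard grid, cut-off selection, artifact filter |
| `oncoyield.germline` | tumor-only germline flagging, secondary findings |
| `oncoyield.biomarkers` | TMB and MSI rules |
| `oncoyield.cnv` | fold-change estimation, GISTIC mapping |
| `oncoyield.actionability` | annotation, temporal integration, yields |
| `oncoyield.cli` | `oncoyield` command-line pipeline |

See `docs/methods.md` for the statistical details and design choices.
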