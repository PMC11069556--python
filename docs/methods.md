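# Methods

`clonedivergence` analyses paired somatic-alteration profiles from a primary
tumor and a metastatic lesion of the same patient. It was built around the
comparative genomics of gastric cancer with ovarian metastasis — a setting
where the primary gastric lesion and the ovarian metastasis are both exome
sequenced — but every stage is generic over the input tables. This note
records the models, parameter choices, numerical conventions and known
limitations.

## Data model

An alteration table is tab-separated with one row per somatic event in one
lesion of one patient. Events belong to one of five classes: substitution /
indel, gene amplification, truncation, fusion / rearrangement, homozygous
deletion. Coordinates are 1-based and inclusive (MAF convention); a MAF
dialect reader maps `Variant_Classification` strings onto the five classes
via an explicit lookup. Unknown or missing clinical categories are kept as
explicit `unknown` / missing states and never imputed.

Events are matched across lesions by an identity key. For substitutions and
indels the default key is the full allele, `(gene, chrom, pos, ref, alt)`;
copy-number and fusion events are matched at gene level,
`(gene, class[, partner])`, with the fusion pair unordered. Gene-level
matching for substitutions is available (`key_level="gene"`) because
gene-level sharing is how oncoprint-style displays are usually annotated;
allele-level is the default since it is the stricter and better-defined
notion of "the same mutation".

## Shared-status labelling and landscape comparisons

For a paired patient every key in the union of the two lesions' key sets is
labelled S (shared, present in both), P (primary-only) or M
(metastasis-only); these labels partition the union by construction.
Per-gene frequencies count a patient at most once per gene regardless of
how many events hit it.

Group-versus-group frequency screens build a mutated/unmutated 2×2 table
per gene and test it with Fisher's exact test when any expected cell count
is below 5, otherwise with the Pearson chi-squared statistic **without**
continuity correction. Both choices are deliberate: the two-sided Fisher p
is the sum of hypergeometric point probabilities no larger than the
observed table's (the `fisher.test` convention), which reproduces published
values such as p = 0.059 on the 13/18-versus-8/20 response table, and the
uncorrected chi-squared reproduces published statistics of the form
χ² = 0.009 that a Yates-corrected statistic cannot. Raw p-values are
primary (that is how the source results are reported); Benjamini–Hochberg
q-values are always appended. The default screen requires at least 3
mutated patients overall, to avoid vacuous tests.

Paired-lesion similarity is summarised per patient by the Pearson
correlation between lesion feature vectors over the key union: VAFs for
substitutions (0 where a key is absent from a lesion; presence/absence
vectors when VAFs are missing, flagged in the output) and signed gene-level
indicators for copy-number events (+1 amplification, −1 deletion). The
vectorisation used by the original analyses is not published; this default
is documented as the package's own choice. The correlation is undefined
(with a reason code) below 3 union keys or at zero variance.

## Mutational-signature refitting

Single-base substitutions are folded onto the pyrimidine strand and binned
into the standard 96 trinucleotide channels, ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G) with flanking bases alphabetical within each
type. Folding is idempotent and conserves counts; a spectrum always sums to
the number of SNVs whose context could be resolved (from the record or a
reference FASTA).

Exposures to a fixed, column-stochastic 96×S reference matrix (COSMIC-style
TSV) are obtained by nonnegative least squares
(min ‖y − Ae‖₂ s.t. e ≥ 0, active-set solver). Refitting against a known
catalogue — not de-novo NMF extraction — is the method implemented, because
the analysis this package supports compares observed spectra against the
COSMIC catalogue rather than discovering novel signatures. Fit quality is
the cosine similarity between the observed spectrum and its reconstruction;
a signature enters the cohort report when it carries nonzero exposure in at
least one sample whose cosine is **strictly** greater than the threshold
(default 0.85). Cosine is scale-invariant, so raw counts are used directly.
Both per-sample and pooled-cohort fitting are available (`fit_level`),
since the level at which the source analysis fit is not stated.

## Pathway scores

For each patient group the top-k genes by mutated-patient frequency
(default k = 100; ties cut alphabetically, or kept with
`tie_policy="keep-all"`) are tested against a GMT gene-set collection with
the upper-tail hypergeometric distribution, P(X ≥ k), and BH FDR control;
FDR < 0.05 is the significance gate. The background universe defaults to
all genes in the collection. The hypergeometric + BH implementation
replaces web-service enrichment so runs are reproducible offline.

The Pathway Score of a pathway in a patient group is

    score = (total mutations on the pathway's genes in the group)
            / (pathway gene count × group size)

counting alteration records by default; `dedup_per_patient=True` counts
each (patient, gene) once, since the published formula's wording admits
both readings. Scores are binned for heatmap display at the 0.25 pivot
(below: blue range; exactly 0.25: white; above: red), and the score matrix
is ordered by average-linkage hierarchical clustering on Euclidean distance
followed by descending mean score — the published description ("clustered
and ranked") does not pin the linkage, so this choice is the package's own.

## Trunk/branch evolution classification

With exactly two lesions per patient the phylogeny degenerates to a shared
trunk plus one private branch per lesion, so no multi-sample tree
reconstruction is needed. The genomic distance between lesions is
summarised as the shared proportion |trunk| / |union| over
substitution/indel keys; CNVs and fusions are excluded by default because
their cross-lesion concordance is characteristically low (configurable).
Patients with fewer than 10 union SNVs (configurable) are unclassifiable.

Class calls threshold the shared proportion: parallel below t_low = 0.30,
linear at or above t_high = 0.50, intermediate between. The published
group ranges overlap (parallel up to 29.3%, linear from 25.6%), so **no**
threshold pair can reproduce that grouping exactly; the defaults separate
the published group medians (8.0% parallel, 62.7% linear) and are mandatory
in the config and echoed into the run manifest so the choice is always
visible. The call is monotone in the shared proportion by construction.

Mutation-composition differences between clinical subtypes (synchronous vs
metachronous metastasis) are tested per component (primary-only,
metastasis-only, shared proportions) with classical one-way ANOVA,
F = MS_between/MS_within on (k−1, N−k) degrees of freedom.

## Response and survival

Treatment response is dichotomised by RECIST: CR/PR effective, SD/PD
ineffective; patients without a label are excluded from response analyses
and their number reported, never imputed. Gene-response screens use the
same 2×2 machinery as the landscape comparisons. Overall survival is in
months; curves use the Kaplan–Meier product-limit estimator and groups are
compared with the k-sample log-rank test (observed-minus-expected with
hypergeometric variance, df = k−1); 5-year OS is S(60).

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
a per-patient truth table (generating class, drawn and realised trunk
fraction, signature exposures) so recovery is measurable exactly. Defaults
are the study conditions of the motivating cohort:

- 64 paired patients; evolution-class mix 18/17/20 (of 55 classifiable).
- Trunk fraction per class ~ Beta with means 0.08 / 0.40 / 0.63 (the
  published per-class median genomic distances) and small variance —
  Beta(4, 46), Beta(60, 90), Beta(63, 37) — so class supports are
  essentially separated by the default cutoffs.
- Union SNV burden ~ negative binomial, mean 120, dispersion 8, floor 12.
  No per-patient burden distribution is published; this is a modelling
  choice sized so per-lesion spectra support signature refitting.
- Trinucleotide contexts drawn per mutation from the patient's
  Dirichlet-mixed exposures over a sparse synthetic reference-signature
  matrix (pairwise cosine < 0.7 for identifiability); mutations are
  recorded on either strand at random to exercise folding. Positions are
  uniform over a toy genome — adequate because no stage uses positional
  clustering.
- Trunk mutations are clonal (VAF ~ Beta(16, 24), jittered between
  lesions); branch mutations subclonal (VAF ~ Beta(6, 24)).
- Effective-response probability by class: 0.722 / 0.647 / 0.40 (published
  parallel / intermediate / linear rates). Survival is exponential per
  class with hazards matched to the published 5-year OS (24.9% parallel,
  30.2% intermediate; linear median ≈ 10 months), administrative censoring
  at 60 months plus a small random loss-to-follow-up hazard.
- Metachronous-subtype probability rises with the class (0.15 / 0.35 /
  0.45), emulating the published enrichment of linear evolution among
  metachronous metastases.
- Gene-level CNVs, truncations and fusions: amplifications cluster on
  chromosomes 7/11/16/17; deletions in the metastasis are biased to
  chromosome 9 at a rate (0.01 per union SNV) chosen so the
  CNV-distribution comparison has a detectable generated effect; recurrent
  fusion pairs (CLDN18–ARHGAP26/42, TCF3–MBD3) are shared across lesions
  with probability 0.4.

What the generator does **not** emulate: genomic position structure
(hotspots, clustered mutations), subclonal VAF mixtures beyond the
two-level trunk/branch model, copy-number segments (events are gene-level
labels), sequencing noise or calling error. Passing tests therefore show
the pipeline's statistics behave correctly under the assumed generative
structure — not that the calling upstream of the input tables is sound.

The mixture median of the trunk-fraction distribution implied by the
default class weights and Betas is ≈ 0.40, and tests check the empirical
cohort median against this config-implied target (±0.03) rather than the
published 24.9% overall median, which averages over unclassifiable and
low-burden patients that the per-class Beta mixture does not represent.

## Numerical conventions and problem sizes

- Fisher two-sided p: point-probability rule; a doubled-one-tail variant
  is available behind a method flag for cross-checking.
- NNLS: scipy active-set solver; local optimality is verified in tests by
  single-coordinate perturbation (no nonnegative perturbation of the
  returned exposures reduces the residual).
- BH q-values: standard step-up, capped at 1, mapped back to input order.
- Determinism: all simulation randomness flows from one
  `numpy.random.Generator` seeded from the config; identical configs give
  bit-identical cohorts and byte-identical pipeline outputs.
- Test problem sizes were chosen as the smallest at which the statistical
  assertions are stable: 300-patient cohorts for recovery rates, 1000
  replicates for log-rank null calibration, exhaustive 2×2 enumeration up
  to table total 40.

## Known limitations

- The two-lesion trunk/branch partition cannot resolve multi-clone
  phylogenies; it is exactly the object displayed in paired-lesion
  phylogeny figures, no more.
- The evolution cutoffs are a documented substitute for an unpublished
  classification rule; borderline patients (shared proportion near 0.3 or
  0.5) are sensitive to them.
- Pathway Scores depend on the gene-set collection supplied; no automatic
  de-redundancy of overlapping pathways is attempted — the caller restricts
  the scored pathway set explicitly (`pathway_score_table(pathways=...)`).
- The chi-squared path requires nonzero margins; degenerate tables raise
  rather than silently returning p = 1.
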