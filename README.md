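# clonedivergence

Comparative genomics of paired primary tumors and their metastases, built
for the setting of gastric cancer with ovarian metastasis: each patient
contributes a somatic-alteration profile from the primary gastric lesion
and one from the ovarian metastasis, and the questions are how the two
lesions relate clonally and whether that relationship predicts treatment
response and survival.

The package implements, as a tested library with a CLI:

- **Alteration landscape** — class tallies, per-gene mutated-patient
  frequencies, shared / primary-only / metastasis-only (S/P/M) labelling of
  each mutation across a pair, group-vs-group frequency screens (Fisher
  exact / Pearson χ² without continuity correction), paired-lesion Pearson
  correlations, CNV chromosome distributions, fusion concordance.
- **Mutational signatures** — 96-channel trinucleotide spectra
  (strand-folded onto the pyrimidine reference), nonnegative least-squares
  refitting against a COSMIC-style reference matrix, and cohort signature
  selection gated on cosine similarity > 0.85 between each spectrum and
  its reconstruction.
- **Pathway scores** — top-k mutated genes per group, upper-tail
  hypergeometric gene-set enrichment with Benjamini–Hochberg FDR
  (significant at FDR < 0.05), and the group-level score
  `mutations on pathway genes / (pathway gene count × group size)` with
  heatmap binning at the 0.25 pivot.
- **Clonal evolution** — trunk/branch partition of each pair, genomic
  distance as the shared-mutation proportion |trunk|/|union|, and
  classification into **parallel** (early dissemination, low sharing),
  **intermediate**, and **linear** (late dissemination, high sharing)
  evolution.
- **Response and survival** — per-gene mutated × effective (CR/PR vs
  SD/PD) screens, clinical-factor associations, Kaplan–Meier curves and
  k-sample log-rank tests by evolution class.
- **Synthetic cohorts** — a generator that emulates the assumed structure
  (shared trunk clone, lesion-private branches, signature-mixed spectra,
  class-linked response and survival) and emits a ground-truth table, so
  every stage is testable without restricted patient data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 64-pair cohort under the default study conditions, classify
each patient's evolution pattern, and relate the pattern to outcome:

```python
from clonedivergence import (
    Contingency2x2, GeneratorConfig, generate_cohort, km_curve,
    logrank_test, test_2x2,
)
from clonedivergence.evolution import (
    cohort_evolution_calls, cohort_evolution_summary,
)

cohort, truth, signatures = generate_cohort(GeneratorConfig(n_patients=64, seed=7))
calls = cohort_evolution_calls(cohort)
subtype = {p.patient_id: p.clinical.metastasis_subtype.value for p in cohort.pairs}
summary, _ = cohort_evolution_summary(calls, subtype)
print(summary)
print("median shared proportion:", round(calls["shared_proportion"].median(), 3))
```

```
        call   n  proportion  n_synchronous  n_metachronous
    parallel  26     0.40625             22               4
intermediate  22     0.34375             14               8
      linear  16     0.25000              6              10
median shared proportion: 0.364
```

Each patient's mutations are split into a shared trunk and two private
branches; the shared proportion drives the class call (parallel < 0.30 ≤
intermediate < 0.50 ≤ linear), and linear evolution is enriched among
metachronous metastases, as generated. Survival then separates by class:

```python
times, events = {}, {}
call_of = calls.set_index("patient_id")["call"]
for pair in cohort.pairs:
    c = call_of[pair.patient_id]
    if c != "unclassifiable":
        times.setdefault(c, []).append(pair.clinical.os_months)
        events.setdefault(c, []).append(pair.clinical.os_event)

for c in ("parallel", "linear"):
    print(c, "5-year OS:", round(km_curve(times[c], events[c]).survival_at(60), 3))
lr = logrank_test(times, events)
print("log-rank chi2:", round(lr.chi2, 2), "df:", lr.df, "p:", round(lr.p_value, 4))
```

```
parallel 5-year OS: 0.322
linear 5-year OS: 0.0
log-rank chi2: 16.56 df: 2 p: 0.0003
```

Parallel-evolution patients — whose metastasis diverged early and shares
few mutations with the primary — survive longest, while no
linear-evolution patient reaches five years. A published-scale response
contrast is one function call: 13/18 responders among parallel patients
versus 8/20 among linear gives

```python
test_2x2(Contingency2x2(13, 5, 8, 12), method="fisher").p_value  # 0.058
```

## Command line

```bash
clonedivergence simulate --out sim/ --seed 7          # variants/clinical/truth/signatures TSVs
clonedivergence evolution --variants sim/variants.tsv --clinical sim/clinical.tsv
clonedivergence run --config pipeline.yaml            # full pipeline + manifest.json
```

`run` executes landscape → signatures → pathways → evolution →
association/survival, writes one TSV per result plus a `manifest.json`
recording the seed, every threshold and a config hash; reruns of the same
config are byte-identical.

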