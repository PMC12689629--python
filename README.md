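# drugtrace

Empirical drug-exposure readout from untargeted LC-MS/MS metabolomics.

Clinical metadata rarely records what drugs a person was actually exposed to
at sampling time. Untargeted metabolomics can, in principle, read exposure
directly from the samples: a drug, its metabolites, and related analog ions
leave MS/MS signatures that can be matched against a curated spectral
library. `drugtrace` implements the machinery for that readout:

- **Drug spectral libraries** with controlled-vocabulary pharmacologic
  metadata (exposure source, pharmacologic class, therapeutic area,
  indication, mechanism of action), metabolite linking by name containment,
  and parent-metadata inheritance.
- **Precursor-shift-aware analog search.** The modified cosine aligns
  fragments either directly (|Δm/z| ≤ tol) or shifted by the precursor mass
  difference, with a one-to-one greedy peak assignment on square-root-scaled
  intensities. Analog hits require a score ≥ 0.8 and ≥ 6 matched ions within
  a ±200 Da precursor window.
- **Four-stage analog curation**: drop analogs of endogenous/dietary
  compounds; keep only mass offsets explainable by a curated table of
  metabolism deltas and adduct spacings (packaged, user-replaceable CSV);
  drop spectra that already match the reference library; drop analogs with
  implausibly high detection frequency in test datasets. The filters are
  pure set operations and commute; a conservation-checked report accounts
  for every input match.
- **Ion-form classification** of analogs as isotope / adduct / in-source
  fragment / candidate derivative: named mass spacings first (+1.00/+2.00
  isotopes; +21.98 Na, +37.95 Ca, +37.96 K), then extracted-ion-chromatogram
  peak-shape correlation across co-occurring runs (max R² > 0.9 ⇒ co-eluting
  artifact), then MS/MS fragment cross-evidence.
- **Exposure readout**: 3-fold blank filtering, a 1e4 noise floor, grouping
  of drug/metabolite/analog annotations onto parent drugs (an analog-only
  detection still flags the parent), removal of endogenous/food compounds,
  ontology-level summaries counted once per individual, and detection rates
  normalized by 10-year age bin and sex.
- **Cohort stratification**: Ward/Euclidean hierarchical clustering of
  log(1+area) exposure profiles, with Kruskal–Wallis + pairwise Wilcoxon +
  Benjamini–Hochberg tests for downstream metabolite differences.
- **A synthetic-data generator** producing libraries, cohorts, feature
  tables and MS1 runs with full ground truth, so every stage is testable
  without repository-scale downloads.

## Worked example

```python
from drugtrace import ion_mz, adduct_offset, modified_cosine, Spectrum

print(f"omeprazole [M+H]+  : {ion_mz('C17H19N3O3S', '[M+H]+'):.3f}")
print(f"Na vs H spacing    : {adduct_offset('[M+Na]+', '[M+H]+'):+.2f}")

drug = Spectrum("drug", 346.122,
                [(136.10, 30), (198.07, 100), (255.10, 20), (271.08, 15), (312.00, 10)])
metabolite = Spectrum("met", 360.138,
                      [(136.10, 30), (198.07, 100), (269.12, 20), (285.10, 15), (312.00, 10)])
match = modified_cosine(drug, metabolite)
print(f"modified cosine    : {match.score:.3f} ({match.matched_peaks} matched, "
      f"{match.shifted_pairs} shifted, offset {match.mass_offset:+.4f} Da)")
```

prints

```
omeprazole [M+H]+  : 346.122
Na vs H spacing    : +21.98
modified cosine    : 1.000 (5 matched, 2 shifted, offset +14.0160 Da)
```

The protonated omeprazole ion lands at m/z 346.122; a sodiated form would
sit +21.98 Da above it. The "metabolite" here is the same spectrum with the
precursor and two fragments shifted by +14.016 Da (methylation): the
modified cosine still scores 1.0 because the two moved fragments match
through the precursor-shift channel.

End-to-end on the default synthetic cohort (50 drugs, 60 samples, 6 blanks):

```python
from drugtrace import generate_library, generate_cohort
from drugtrace.pipeline import evaluate_recovery
from drugtrace.config import RunConfig

library, _ = generate_library(50, seed=1)
table, truth = generate_cohort(library, n_samples=60, n_blanks=6, seed=1)
result = evaluate_recovery(table, truth, library, RunConfig(seed=1))
print(f"exposure recall    : {result['recall']:.3f} over {result['n_planted']} planted exposures")
print(f"false detections   : {result['n_false_pairs']}")
print(f"cluster ARI        : {result['adjusted_rand']:.1f}")
```

```
exposure recall    : 1.000 over 1410 planted exposures
false detections   : 0
cluster ARI        : 1.0
```

All 1410 planted (sample, drug) exposures are recovered at the acceptance
thresholds (cosine ≥ 0.9, ≥ 5 matched peaks) with no false drug-level
detections, and Ward clustering of the exposure matrix recovers the two
planted cohort groups exactly (adjusted Rand index 1.0).

## Command line

```sh
drugtrace simulate --drugs 50 --samples 60 --blanks 6 --seed 7 -o fixtures/
drugtrace search --library lib.mgf --meta lib.csv --input run.mgf -o annotations.csv
drugtrace search --analog --library lib.mgf --meta lib.csv --input run.mgf -o analogs.csv
drugtrace curate --matches analogs.csv --spectra run.mgf --library lib.mgf --meta lib.csv -o curated.csv
drugtrace ionform --pairs curated.csv --library lib.mgf --meta lib.csv --spectra run.mgf -o labels.csv
drugtrace readout --features quant.csv --meta samples.csv --annotations ann.csv \
    --library lib.mgf --library-meta lib.csv --level pharmacologic_class -o exposure.csv
drugtrace stratify --exposure exposure.csv --k 4 -o clusters.csv
drugtrace test --clusters clusters.csv --targets lipids.csv -o stats.csv
```

Every subcommand writes a `<output>.report.json` with the resolved
configuration, seed and input hashes, sufficient to reproduce the run.
Defaults can be set in a TOML file passed with `--config`; command-line
flags take precedence.

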