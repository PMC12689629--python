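# Methods

## The problem and the model

Untargeted LC-MS/MS of biological samples records thousands of MS/MS
spectra, a fraction of which originate from drugs, their metabolites, and
related ion species. `drugtrace` turns those spectra into per-sample drug
exposure records in three layers: spectral annotation against a curated
drug library, curation and classification of *analogs* (spectra related to
a drug by a precursor mass shift), and cohort-level summarization and
stratification.

### Modified cosine

For spectra *a*, *b* with precursors *p_a*, *p_b*, a fragment pair (i, j)
is eligible when |m_i − m_j| ≤ τ (direct) or |m_j − m_i − (p_b − p_a)| ≤ τ
(shifted), with fragment tolerance τ = 0.02 Da by default. Intensities are
square-root scaled (the convention of the large public spectral-network
infrastructure; configurable to `none`), eligible pairs are assigned
one-to-one greedily by descending intensity product with ties broken by
smaller residual |Δm/z|, and the score is the assigned dot product divided
by the product of the scaled intensity norms. The score of a spectrum
against itself is exactly 1, as is the score against a version of itself in
which any subset of fragments shifts with the precursor — the property that
makes the statistic a metabolite detector. Greedy assignment is not optimal
in adversarial eligibility graphs; the test suite checks it against an
exhaustive branch-and-bound maximum-weight assignment on 1000 randomized
spectra (≤ 8 peaks each, with deliberately planted near-coincident peaks)
and observes exact agreement, and against the community implementation in
`matchms` on unambiguous pairs.

### Search thresholds

Analog search accepts hits with score ≥ 0.8 and ≥ 6 matched ions within a
±200 Da precursor window. Library annotation is two-tier: candidates are
collected at score ≥ 0.7 with ≥ 2 matched peaks and |Δprecursor| ≤ 0.02 Da,
and accepted at score ≥ 0.9 with ≥ 5 matched peaks; each query keeps its
best accepted entry (score, then matched peaks, then lexicographic entry
id). Spectrum preprocessing removes fragments within ±17 Da of the
precursor and keeps a peak only if it ranks among the 6 most intense within
±50 Da of itself.

### Analog curation

Four pure filters reduce raw analog matches to a curated analog library:

1. **source** — analogs of drugs with endogenous or dietary exposure
   sources are removed (their presence cannot establish medication);
2. **mass offset** — the precursor shift must sit within 0.01 Da (absolute,
   configurable) of an entry in a signed, curated offset table. The
   packaged table carries 47 entries: common phase-I/II transformations
   with their elemental compositions (±CH2, ±C2H4, ±O, ±H2O, ±H2,
   glucuronide, sulfate, acetyl, glycine/taurine conjugation, ...), adduct
   spacings (Na−H +21.981945, K−H +37.955882, Ca−2H +37.946941, NH3,
   acetonitrile, methanol, formate, acetate) and isotope spacings
   (+1.003355, +2.006710). Gains and losses are distinct rows;
3. **library match** — analog spectra matching any reference entry at
   score ≥ 0.7 with ≥ 6 peaks and precursor agreement are removed (these
   are known compounds, typically same-class siblings);
4. **frequency** — analogs detected in more than 50% of any test dataset
   are removed (per-dataset thresholds configurable).

Each filter returns a subset of its input and depends only on the
candidate itself, so the four commute; the curation report labels every
input match with the first filter that removed it and checks count
conservation. Near-duplicate analog spectra are then collapsed by greedy
single-linkage (precursors within 0.02 Da, offset-zero cosine ≥ 0.95,
highest-total-intensity representative). This dedup stands in for
repository-scale spectrum clustering; the 0.95 threshold corresponds
approximately to the eps = 0.05 used by density-based spectrum clustering
tools, a stated mapping rather than a claimed equivalence.

### Ion-form classification

Each curated analog is labeled isotope / adduct / in-source fragment /
derivative by a fixed-order decision:

1. **mass offset**: +1.00/+2.00 Da ⇒ isotope; +21.98/+37.95/+37.96 Da ⇒
   Na/Ca/K adduct (tolerance 0.01 Da). The stage order follows the
   procedure description; offsets are compared to the exact spacings, and
   the nearest named spacing wins within tolerance.
2. **peak shape**: for pairs co-occurring in at least one run, extracted
   ion chromatograms of drug and analog are taken over 10 consecutive MS1
   scans centered on the drug's apex (truncated with a warning at run
   boundaries), and the maximum squared Pearson correlation across files
   decides: R² > 0.9 ⇒ co-eluting artifact (adduct if the offset is
   positive, in-source fragment if negative); otherwise derivative. R²
   exactly at the threshold counts as derivative (the artifact call
   requires strictly greater). Constant traces have undefined correlation
   and are skipped with a warning.
3. **fragment evidence** (no co-occurrence): an analog heavier than the
   drug whose fragment hits the drug's precursor m/z is an adduct; an
   analog lighter than the drug whose precursor hits a drug fragment is an
   in-source fragment. No intensity filtering is applied. Anything left is
   a derivative by default.

### Exposure readout

Features failing a 3-fold blank rule (mean sample area < 3 × mean blank
area) are dropped, and cells below 3 × blank mean are not counted as
detections; areas below 1e4 are zeroed. The two rules address different
acquisition settings and are independent switches; when both apply the
order is blank filter → noise floor (the orders agree on detection flags
whenever the floor is below the blank threshold). Annotations are grouped
by parent drug — the summed area runs over drug, metabolite, and analog
members, and an analog-only detection still flags the parent. Parents with
endogenous/food sources are removed with a report. Ontology summaries
(pharmacologic class, therapeutic area, indication, mechanism) count each
value once per sample; missing metadata routes to an `unclassified` bucket
with a warning. Demographic normalization divides detections by group size
within 10-year age bins (0–90) × sex; samples with missing demographics or
age ≥ 90 are excluded and reported.

### Stratification

Samples are clustered on log(1 + summed area) — the +1 offset accommodates
zeros, which a bare log transform cannot — with Ward linkage on Euclidean
distances, cut at a user-chosen k (no automatic k selection); labels are
renumbered by decreasing cluster size for reproducible reports. Group
differences use the Kruskal–Wallis omnibus followed by all pairwise
two-sided Mann–Whitney tests (normal approximation with tie correction)
adjusted by Benjamini–Hochberg over the pairwise family; groups smaller
than 2 are excluded with a warning. A Pearson chi-square (no continuity
correction) serves frequency comparisons across cohorts.

## Synthetic study conditions

The generator emulates the input formats and signal structure of a cohort
study; its defaults are the package's reference study conditions.

- **Library**: 50 drugs with random but valid molecular formulas
  (C10–35, H ≥ C, N ≤ 3, O ≤ 7, S ≤ 1), theoretical [M+H]+ precursors
  (proton 1.007276 Da), and 8–20 fragments drawn as random neutral losses
  from the precursor, kept 25 Da below the precursor so preprocessing never
  removes them. 10% of drugs receive an endogenous or food source; half
  gain one metabolite entry built from the first ten packaged metabolism
  offsets (precursor shift plus shifting a random half of the fragments,
  with out-of-range states falling back to the unshifted position). Those
  ten offsets are all ≥ 9 mDa away from the isotope and Na/Ca/K spacings,
  so planted metabolites can never satisfy the stage-1 ion-form rule.
  Formulas are resampled until every ion value a drug can spawn (precursor,
  isotopes, sodium adduct, metabolite shifts) keeps 0.05 Da from all
  previously claimed values — 2.5× the precursor tolerance — so annotations
  on the synthetic cohort are unambiguous by construction.
- **Cohort**: 60 samples in two groups exposed to disjoint halves of the
  library, 6 blanks. Exposed samples carry the drug's spectrum perturbed
  by ≤ ±0.005 Da m/z jitter (a quarter of the fragment tolerance) and
  lognormal intensity noise (σ = 0.2); areas are lognormal around
  5×10⁵. Planted companions per drug (probabilities 0.35/0.35/0.35/0.6):
  a sodium adduct (+21.981945 Da, parent fragments plus the protonated
  precursor as a fragment), a +1 isotope, an in-source fragment (precursor
  equal to a mid-list drug fragment, fragments the sub-spectrum below it),
  and the library metabolite. 20 decoy spectra with precursors ≥ 0.1 Da
  from every library ion and 5 contaminant features present in blanks and
  samples at similar level complete the feature table.
- **MS1 runs**: Gaussian elution profiles (σ = 1.5 scans) on a 30-scan
  grid. Adducts, isotopes, and in-source fragments share the parent's apex
  and differ only by scale, giving peak-shape R² = 1 by construction;
  metabolites elute 5 scans later, which puts their R² against the parent
  far below 0.9 in a 10-scan apex window (≈ 0.16 for these widths). Runs
  can be written as minimal uncompressed mzML and re-read through the
  package's mzML reader.

All randomness in an artifact flows from a single
`numpy.random.default_rng(seed)` stream, so regeneration from (seed,
parameters) is identical.

### What the generator does not emulate

Chromatographic noise and peak-shape asymmetry, retention-time drift
between runs, co-eluting isobaric interferences, multiply charged ions,
isotope-pattern envelopes beyond the +1/+2 spacings, missing MS2 coverage,
and batch effects. Passing the end-to-end tests therefore demonstrates the
correctness of the pipeline's logic under clean, well-separated signals —
not annotation performance on real repository data, where score
distributions are broader and precursor collisions are common.

## Numerical choices

- Atomic masses hard-coded to 6 dp (NIST most-abundant isotopes); electron
  mass carried inside per-adduct deltas so spacings are exact; display
  rounding 2 dp for offsets, 3 dp for m/z.
- The +2 isotope row stores the exact 2 × 1.003355 = 2.006710 Da; the 0.01
  Da matching tolerance absorbs the difference from the unit-mass label.
- The calcium adduct is modeled as [M+Ca−H]⁺, the only charge-1 form
  consistent with a +37.95 Da spacing from [M+H]⁺.
- Greedy pair assignment breaks product ties by smaller residual |Δm/z|,
  then by peak index, making the scorer fully deterministic.
- A peak eligible through both the direct and shifted channel is counted
  as direct and used at most once.
- Ward clustering is deterministic given input order; identical rows at
  k = n yield singleton clusters by construction.
- "Major fragment" judgments in manual curation have no operational
  definition; matches carry the fraction of query intensity explained as a
  review flag instead of an automated call.

## Problem sizes in the test suite

The suite exercises the default 50-drug / 60-sample / 6-blank cohort for
the end-to-end checks, a 30-drug / 20-sample cohort for ion-form recovery,
1000 randomized spectra for the assignment oracle, and 1000 replicates for
the null calibration of the Kruskal–Wallis test; the whole suite runs in
well under a minute on one CPU. These sizes were chosen as the smallest
conditions that exercise every planted structure with stable statistics.

## Known limitations

- The frequency filter consumes externally computed detection fractions;
  the package does not re-run repository-scale screens.
- Library-match filtering reuses the analog-search thresholds by default;
  the correspondence to any particular public search workflow's settings
  is configurable, not fixed.
- The classifier assigns exactly one label per analog; chimeric cases
  (e.g. an adduct of a metabolite) resolve to the first matching stage.
- Structure handling is limited to validation (InChIKey shape, first-block
  matching); no standardization chemistry is performed, and registry
  matching operates on user-supplied tables only.
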