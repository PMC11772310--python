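# Methods

## Scope and model

The package implements two computational procedures around lupin alkaloid
pathway engineering — candidate-gene selection from bulk transcriptomes, and
chromatographic quantification of alkaloid profiles — together with a
synthetic-data layer that emulates the statistical structure both procedures
assume. Real sequencing and instrument data enter only through generic
formats (expression TSV, 12-column BLAST tabular, long-format run CSV); the
synthetic layer exists so that every operation can be validated against known
ground truth.

## Candidate selection

Both cascades are deterministic filters; the order of stages matters only for
the bookkeeping (each stage's survivors are a subset of the previous one),
not for the final set.

* **Expression floor.** `TPM >= tpm_min` (default 10) in one reference sample
  (young leaves of the bitter cultivar). Values exactly at the floor are
  retained, since the published rule removes "< 10 TPM".
* **Co-expression.** Pearson correlation against the LDC bait, strict
  `r > pcc_min` (default 0.9). The correlation is computed over the bitter
  cultivar's samples by default: the two source datasets come from different
  cultivars and there is no stated basis for mixing them into one profile;
  the sample subset is configurable (`pcc_cultivar` / `pcc_samples`) for
  users who prefer the joint layout. Constant profiles have no defined
  correlation and are dropped with a logged count rather than scored 0.
* **Lineage specificity.** Among the first `top_n = 30` hits (ranked by
  descending bit score, ties by ascending e-value then subject id — BLAST's
  native ordering), count hits with `%ID < 70` strictly; `>= 10` such hits
  means *specific*. The window counts alignment rows, not distinct subjects.
  A transcript with no hits at all is classified specific: absence of
  homologues is the strongest form of the criterion; these are listed
  separately in the report (`no_hit_ids`).
* **Keywords.** Case-insensitive substring match. The oxidase vocabulary
  (cytochrome, P450, oxidase, oxygenase, monooxygenase, peroxidase,
  dioxygenase) is a config default, overridable and recorded in the report;
  strategy B uses the single keyword "dehydrogenase".
* **Cultivar enrichment (strategy B).** Mean TPM within (cultivar, organ) —
  arithmetic mean across replicates — then remove transcripts with
  sweet/bitter ratio > 1. `0/0` counts as ratio 0 (survives); positive over
  zero is removed.

The reports keep per-stage survivor counts, per-candidate scores and the
matched keyword. Survivor curation (e.g. discarding a conserved
dehydrogenase-complex fragment) is deliberately manual: the report flags, a
human decides.

## Chromatographic quantification

* **XIC/TIC.** m/z windows are closed intervals; a centroid exactly on the
  boundary is included. The scan time axis is always preserved, so XICs over
  a disjoint cover of the m/z axis sum exactly to the TIC.
* **Peak detection.** Local maxima above `k·noise_sd` (default `k = 3`) with
  a prominence guard of the same magnitude, so noise wiggles riding on peak
  flanks do not count as apices. When not supplied, the noise scale is the
  larger of `1.4826·MAD` and the upper-quartile spread `(q75 − q50)/0.6745`;
  the MAD alone collapses on centroided traces whose baseline is
  zero-inflated (detectors drop near-zero centroids). Boundaries sit at the
  nearest of (a) return-to-baseline below the noise floor and (b) the valley
  towards the neighbouring apex; a valley is trusted only if it dips below
  half the lower apex, otherwise the neighbour is treated as a shoulder.
  Peak regions never overlap.
* **Integration.** Trapezoidal on the native scan grid, no resampling and no
  baseline subtraction by default (the synthetic baselines are flat). Height
  is the raw apex intensity.
* **Readouts.** Residual percent and fold change use arithmetic means across
  biological replicates (matching mean-based bar-chart reporting).
  %Area purity excludes sample peaks that match a blank-run peak within an
  rt tolerance; if the analyte itself matches the blank that is raised as a
  contradiction, never silently absorbed. ee is signed, positive when the
  designated (−)-channel dominates; the CLI prints magnitude plus the
  dominant label.

## Synthetic data

* **Expression.** Two cultivars: a bitter one with 8 organ samples and a
  sweet one with 5, one library per organ. The bait template is high in
  biosynthetic organs (young leaf 220 TPM) of the bitter cultivar and
  near-silent in the sweet one. Planted genes hit their target correlation to
  the bait *exactly*: the profile is built from the unit-centred bait
  direction plus an orthogonal unit residual as `ρ·x̂ + sqrt(1−ρ²)·ẑ`, then
  mapped affinely (positive slope) into non-negative TPM space — simpler and
  verifiable post hoc compared with calibrating a noise scale. Background
  transcripts are i.i.d. log-normal (median ≈ 6 TPM, long tail) and
  rejection-sampled until every |PCC| to the bait stays below the cap
  (default 0.8 < the 0.9 selection threshold, which guarantees separability
  of the planted module). The canonical fixture plants three specific
  oxidases at ρ = 0.97, an SDR at 0.62, a conserved-fragment decoy at 0.55
  and a conserved high-PCC oxidase decoy at 0.97.
* **BLAST tables.** Percent-identity profiles realize a class by
  construction: "specific" tables put 12–25 of the first 30 hits below 70%,
  "general" at most 5; bit scores are sorted descending.
* **Runs.** Centroided scans (profile-mode spectra are out of scope: the
  ±0.01 Th window logic is what the analysis exercises). Each analyte is a
  Gaussian elution profile with true area `amplitude·σ·sqrt(2π)`; additive
  per-centroid noise is clipped at zero (negative intensities do not exist in
  centroided data); optional multiplicative log-normal amplitude noise
  (`amplitude_cv`) models run-to-run abundance variation; blank features
  (column bleed) appear in both sample and blank runs and share one width
  (`blank_sigma`, 0.05 min). Enantiomer pairs share an m/z channel and split
  one amplitude over two retention times. Not modelled: isotope patterns,
  adducts, in-source fragmentation, retention-time drift. Consequently,
  passing tests demonstrate correctness of the arithmetic and the filter
  logic under the stated noise model — not robustness to matrix effects,
  drifting baselines or misannotated libraries in real data.

All generators draw from a single explicit seed (`numpy` SeedSequence
spawning, no global state); identical spec + seed gives bit-identical output.

## Study-condition experiments

`experiments.py` pins the simulated conditions to the published readouts so
they double as recovery tests: knockout abundance ratios
{lupanine 0.006, 13-hydroxylupanine 0.023, angustifoline 0.014,
multiflorine 13} with n = 3 replicates per genotype and 5% multiplicative
amplitude noise; minor-enantiomer fractions 0.005 and 0.015 (ee 99% and 97%);
contaminant area fractions 0.39 / 0.02 for the crude and purified extracts
(61% / 98%); minor alkaloids totalling 4% of knockout seed alkaloid area
(96% sparteine share). Blank-peak calling in the purity experiment uses a
stricter `k = 5` threshold: only confident blank features may veto sample
peaks from the denominator. The sparteine content as percent of seed weight
is not reproduced: it required an external calibration curve, which is
outside the normalized-abundance contract modelled here.

Problem sizes (5000-transcript fixtures, 800–2250-scan runs, 20–50 seeds per
recovery check) were chosen so the full suite and the acceptance script each
run in well under two minutes on one CPU while keeping the binomial pass/fail
bounds meaningful.

## Known limitations

* The specificity filter sees whatever hit ranking the input file provides;
  `ensure_ranked` restores BLAST's native order, but ties in bit score and
  e-value are resolved by subject id, which may differ from a particular
  BLAST build's internal order.
* Peak detection assumes roughly symmetric, baseline-resolved peaks; strongly
  tailing or heavily overlapping peaks (valley above half the lower apex) are
  merged by design.
* The cultivar-ratio stage averages replicates arithmetically; with highly
  skewed replicate distributions a log-scale mean could behave differently.
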