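# Methods

## The prediction model

`gradr` treats RNA–protein interaction prediction as evidence
intersection, not model fitting. Three independent experimental layers
each veto or support a candidate (RNA, protein) pair:

* **Co-sedimentation** — sample Pearson correlation between the two
  molecules' abundance vectors across the gradient fractions (22 by
  default, top of the gradient first). Correlation is computed on raw
  linear-scale profiles; since Pearson *r* is invariant to per-profile
  affine transforms, row-Z-scoring the profiles (the usual visualization
  transform) changes nothing, and the test suite asserts this
  numerically. No significance is attached to *r* itself: the gate is
  the fixed threshold *r* ≥ `r_min` (default 0.5), and ranking is by
  descending *r* with protein id as a deterministic tie-break.
* **RNA binding (OOPS)** — per protein, fold-change = ratio of
  linear-scale replicate means of RNase+ eluate over no-RNase control,
  and a two-sample two-tailed Student's t-test (pooled variance; Welch
  available via `equal_var=False`) on log2-transformed abundances.
  Working in log space is the standard convention for LFQ intensities;
  a raw-scale mode (`log_transform=False`) is provided because either
  choice is defensible. Zeros are replaced before the log transform by
  an abundance floor of half the smallest nonzero value in the table —
  a conventional minimum-based floor. The RBP gate is fold-change ≥ 2
  AND p ≤ 0.05, on raw p-values; Benjamini–Hochberg q-values can be
  reported as an extra column but do not gate.
* **Localization** — fractionation RNA-seq RPKMs are first divided by
  each sample's E. coli spike-in read percentage. Division (not
  multiplication) is the chosen direction: with an equal mass of spike-in
  RNA added to every sample, a sample with less endogenous RNA has a
  larger spike share and should be scaled down. The opposite reading is
  available (`mode="multiply"`). An RNA is cytoplasmic when its mean
  percent-cytoplasmic signal across usable replicates exceeds 50%
  (configurable; an exact 50/50 tie goes to nuclear, and zero-signal
  replicates are excluded from the mean). A protein is eligible for a
  compartment when detected (signal > 0) there in all replicates and not
  ≥ 60% in the opposing compartment in all replicates; the nuclear rule
  is the exact mirror of the cytoplasmic one. The two rules are
  deliberately not a partition: a protein near 50/50 can serve both
  branches. Mitochondrial proteins (user-supplied list) are removed in
  the nuclear branch only, since nuclear–mitochondrial interactions are
  implausible while cytoplasmic ones are not.

Degenerate (constant) profiles have no defined correlation; such
entities are skipped and logged, never imputed, because the
sedimentation *shape* is the entire signal. Profiles must be complete —
there is no minimum-detected-fraction relaxation. Constancy is detected
by an exact range check (`max == min`) rather than `std == 0`, because
the floating-point standard deviation of a constant vector can be a
nonzero ~1e-16.

### ChIRP-MS zero-control rule

For capture-style (ChIRP-MS) tables, proteins detected exclusively in
the capture would have an undefined fold-change; their all-zero control
group is set to a mean of 100 (every control value replaced by 100,
row flagged `ctrl_imputed`). Groups with any nonzero control value are
untouched. A protein that is zero everywhere ends with fold-change 0 and
is excluded by the fold-change gate downstream.

### Expressed-RNA filter

An RNA is reliably detected when its RPKM is ≥ 0.5 in *all* replicates
of at least one condition AND its read support reaches 10 reads. The
read rule is applied to the largest single-sample count by default; a
per-condition replicate-sum mode (`reads_rule="condition_sum"`) is
provided because either reading of "detected under at least one
condition" is plausible. A user-supplied exemption list (focal
transcripts that must survive regardless) is honored and defaults to
empty. The filter is idempotent and monotone in both thresholds.

## Conservation scoring

Input is standard 12-column BLASTN tabular output for one lncRNA query
(already clipped of protein-coding overlap — clipping is upstream of
this module) against one target genome.

1. **Retention.** A hit is kept when its matched bases —
   `round(align_length × pct_identity / 100)` — reach 20. Matching on
   identical bases rather than raw alignment length is the default
   because a long, weak alignment carries fewer conserved nucleotides
   than its length suggests; a raw-length mode exists.
2. **Orthologous window.** Among windows of ≤ 100 kb on one subject
   sequence, pick the one whose hits jointly cover the most query bases
   (union of query intervals). Candidate windows are anchored at each
   hit's lowest subject coordinate; this is sufficient because any
   feasible hit subset's window can be slid left until it touches its
   leftmost hit, and the anchored window contains a superset of that
   subset. Ties break toward smaller span, then subject id, then window
   start — fully deterministic. When a synteny hint interval is given
   and at least one candidate overlaps it, only overlapping candidates
   compete (syntenic loci take precedence over raw coverage).
3. **Percent conservation.** Each query position covered by ≥ 1 hit in
   the window contributes the best identity fraction of any covering
   hit (avoiding double counting of overlaps); the score is the summed
   contribution over the query length, ×100, capped at 100. An
   unweighted mode counts covered positions instead; identity weighting
   is the default. A species with no retained hits scores 0%.

Both the window choice and the percent score are tested against
brute-force oracles (exhaustive subset enumeration; per-position
re-evaluation).

## The synthetic co-sedimentome

The simulator generates every input table the pipeline consumes, plus
the planted truth, from a single RNG stream seeded by one integer
(identical spec + seed ⇒ byte-identical files).

* **Profiles.** Each complex is a Gaussian bump over fractions:
  member value at fraction f is `A·exp(−(f−peak)²/2w²)`, with a
  per-entity log-normal amplitude A (median 500, σ = 0.5 in log space)
  and multiplicative log-normal noise `exp(N(0, noise_sd))` per
  fraction. Members of a complex share peak and width, so at
  `noise_sd = 0` their correlation is exactly 1. Background proteins
  get random peaks (uniform over the gradient) and widths (1–3
  fractions). Gaussian bumps are the simplest unimodal sedimentation
  shape; no physical sedimentation-coefficient modelling is attempted.
* **OOPS tables.** Per protein, a log-normal base intensity (median
  1e5, σ = 0.7 — typical LFQ dynamic range); true RBPs get the base ×
  `oops_effect` (default 8) in the RNase+ eluate, non-RBPs ratio ~1,
  with `noise_sd` log-normal replicate noise in both groups.
* **Localization.** Every entity holds 80–95% of its signal (drawn per
  replicate) in its home compartment, so planted entities are cleanly
  eligible under the 60% rule while still noisy.
* **Spike-in.** Each fractionation sample draws a spike read share from
  `spike_fraction_range` (default 1–5%); emitted RPKM tables are the
  true signals multiplied by the spike percentage, so the pipeline's
  divide-mode normalization exactly recovers the truth.
* **Confounders.** `n_mito_rbps` mitochondrial RBPs (default 2)
  co-sediment with the first nuclear complex but are not planted
  interactors, exercising the mitochondrial exclusion end to end; a
  default 30% of background proteins are RBPs, giving the compartment
  and correlation gates real work.

Default study conditions: two complexes — cytoplasmic at fraction 5,
nuclear at fraction 18, width 1.5, 4 proteins + 3 RNAs each — 30
background proteins, `noise_sd = 0.1`, 3 replicates. These sizes keep
every test and the acceptance script in seconds while leaving dozens of
decoy proteins per branch.

**What the simulator does not emulate:** multi-complex (bimodal) RNAs
beyond what a user configures, missing values and match-between-runs
artifacts in proteomics, count overdispersion beyond Poisson in the
expression table, correlated noise between fractions, or partially
detected profiles. Passing the planted-truth tests therefore shows the
*logic and statistics* of the pipeline are correct under its own model
assumptions; it does not certify performance on real co-sedimentomes,
where profile noise is structured and complex membership overlaps.

## Scoring

Predictions are scored as set overlap on passed (RNA, protein) pairs
against the planted interactions: precision, recall, F1. An empty
prediction set reports precision 0 with an `empty_prediction` flag
(rather than an undefined ratio). Disjoint entity universes between
prediction and truth are rejected as a usage error.

## Numerical and degenerate-input conventions

* Two constant replicate groups: p = 1 if the means are equal, p = 0
  otherwise (no within-group variance to test against).
* Fewer than 2 finite values in a group: an error, not a NaN.
* Fold-change with a zero control mean (no imputation requested):
  `inf`, which still gates correctly.
* `percent_compartment(0, 0)` is NaN/ambiguous and excluded downstream.
* TSV writers emit floats with `%.17g` and readers parse with
  round-trip precision, so write→read→write is bit-identical.
* All thresholds live in a single `Config` whose defaults are the
  published values (2, 0.05, 0.5, 60%, 0.5 RPKM, 10 reads, 20 nt,
  100 kb, 22 fractions).

## Known limitations

* The pipeline predicts *candidates*; co-sedimentation plus RNA-binding
  plus co-localization is consistent with, but does not demonstrate,
  direct physical contact.
* The RNA compartment call (majority of mean signal) is a simple
  stand-in for curated per-RNA annotations; the threshold is
  configurable for users with better priors.
* Percent conservation weights positions by BLAST percent identity,
  which slightly over-credits gapped alignments (identity is per
  aligned column, positions are query bases).
* No multiple-testing correction gates the RBP call; with thousands of
  proteins at p ≤ 0.05 a few percent of non-RBPs will pass the p gate
  (the fold-change gate removes most).
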