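# Methods

This note documents the models, parameters and numerical choices behind
`teploop`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

A tetrapeptide inserted between the initiator methionine and the SecM arrest
peptide (AP) of an `M-XXXX-SecM AP-sfGFP` reporter can relieve AP-induced
ribosome stalling and raise downstream sfGFP output.  Activity is read out as
fluorescence and expressed relative to the Ser-Lys-Ile-Lys (SKIK) reference
tetrapeptide, fixed at 1.  The design space is all 20^4 = 160,000
tetrapeptides; experimentally it is sampled with an (NNK)x4 degenerate codon
library (32 codons per position: N = A/C/G/T, K = G/T; all 20 residues plus
the amber stop TAG).

The package implements the full in-silico loop around this assay: peptide
featurization, cross-validated tree-ensemble regression, exhaustive scoring
of the space, diversity-aware batch selection, and iterative retraining —
exercised end to end against a synthetic activity landscape because no
measured fluorescence table is distributed for reuse.

## Feature encoding (157 variables)

Four published amino-acid descriptor sets are bundled as plain-text tables
(provenance in each file header): Z-scale (5 components), T-scale (5),
ST-scale (8) and VHSE-scale (8) — 26 components per residue.  Each component
is evaluated at the five positions of the expressed peptide (position 0 is
the initiator Met, positions 1–4 the variable residues) and as the sequence
average, giving 26 x 6 = 156 amino-acid-based features; the mRNA ensemble
energy of the ORF prefix adds the 157th ("energy").  Naming: `z1_3` is
Z-scale component 1 at position 3; the unsuffixed `z1` is the sequence
average.

Choices worth flagging:

* The sequence average includes the constant Met at position 0.  This is
  isolated in one function and could be flipped; it only shifts every
  average by a constant and is irrelevant to tree models.
* Position-0 features are constant across all peptides and are deliberately
  retained so the feature count identity (130 positional + 26 averages + 1
  energy = 157) holds; a forest simply never splits on them.
* No feature scaling is applied — tree ensembles are invariant to monotone
  per-feature transforms.
* The bundled descriptor tables were transcribed from the cited source
  publications; users with authoritative table editions can point
  `load_scales(data_dir=...)` at their own TSVs, which are validated for
  coverage (20 residues) and width (5/5/8/8) at load time.

## The "energy" feature

The mRNA-level feature is the ensemble free energy −RT·ln Z of the 33-nt ORF
prefix: ATG + the 12-nt randomized region + the fixed first six SecM AP
codons (TTCAGCACGCCCGTCTGG, taken verbatim from the library construct).  For
designed peptides the randomized region is reverse-translated with
CAI-optimal codons from a bundled genome-wide E. coli K-12 usage table
(relative adaptiveness w = f / max f per amino acid; exact ties broken
alphabetically).  An explicit DNA override exists for users who want the NNK
codons actually observed by sequencing instead.

Z is computed by a McCaskill-style interval dynamic program over all
pseudoknot-free structures with a deliberately simple pair-additive model:

* pair energies GC −3, AU −2, GU −1 kcal/mol; no stacking terms;
* minimum hairpin loop 3 nt; RT = 0.616 kcal/mol (310 K);
* DNA input transcribed T→U (coding-strand convention);
* open chain included at energy 0, so Z ≥ 1 and the energy is ≤ 0.

This is a consistent, documented proxy for folding stability near the start
codon, not a thermodynamically calibrated predictor: absolute energies are
not comparable to nearest-neighbor programs, and no settings are claimed to
reproduce any published energy value.  The backend is pluggable (external
command, or a precomputed two-column table reproduced verbatim) for users
who want full Turner-style parameters.  Correctness of the built-in DP is
established against a brute-force enumerator that explicitly generates every
valid structure (leftmost-base decomposition) and sums Boltzmann factors;
the two agree to better than 1e-9 relative on all tested sequences, and the
DP is jitted so the full 160,000-prefix space folds in seconds.

## Regression models

Relative fluorescence is regressed on the 157 features with either a random
forest (default: 1000 trees, features-per-split chosen by grid search over
{√p, p/3, p/2}) or gradient-boosted trees (XGBoost; small documented grid
over learning rate and depth, 300 rounds, 0.8 row/column subsampling).
Model selection and evaluation use 5-fold cross-validation with shuffled,
seeded folds:

* for each grid point, out-of-fold predictions are collected over the same
  split; the point with the lowest pooled RMSE wins (ties keep grid order);
* reported metrics are the Pearson r and RMSE of the *pooled* out-of-fold
  predictions (per-fold values are also kept); pooling is the documented
  standardization wherever a single per-round r is quoted;
* a constant response leaves r undefined — it is reported as NaN with an
  explicit flag rather than a number;
* the winning configuration is refit on all rows for full-space prediction
  and importance ranking (impurity/gain importances, normalized to sum 1,
  ties broken by feature name).

Averaging tree ensembles cannot extrapolate beyond the observed response
range; this is asserted as a property test, not worked around.

## Candidate selection and the campaign loop

Each round scores every enumerated peptide and assembles a batch of
`batch_size` (default 50) unseen candidates from three strata: the `n_top`
(25) highest predictions; `n_cluster_reps` (15) diversity picks — one
highest-predicted representative per k-means cluster (k = 15, standardized
156 descriptor features, energy excluded) computed over the top
`pool_size` (5000) predictions; and `n_random` (10) uniform draws.  Ranking
ties break lexicographically; any stratum that cannot be filled falls back
to the next-best-ranked peptides so the batch-size contract always holds.
Previously measured peptides are excluded before anything else, and the
training table grows strictly across rounds.  The canned three-round replay
uses +50/+40 batch accounting (158 → 208 → 248 training records when started
from a 158-record screen).

One campaign seed fans out to per-round model/selection seeds through
`numpy.random.SeedSequence`, so a campaign is reproducible end to end while
rounds stay independently randomized.

## The synthetic landscape

No measured activity table ships with the package, so the oracle module
draws a hidden ground truth over the whole space:

* a sparse linear score: 5% of the 104 positional descriptor features
  (26 components x 4 variable positions, standardized over the alphabet)
  get i.i.d. normal weights, rescaled so the score SD over uniform random
  peptides is 0.4;
* a planted positional rule: +0.6 on the score for aspartate at peptide
  position 4 (the screening's most conspicuous signature);
* a right-skewing transform: activity = exp(score), normalized so
  SKIK = 1 — high performers are rare, most mass sits at low activity
  (softplus is available as a milder alternative);
* measurement: additive Gaussian noise (SD 0.1 in relative units) per
  replicate, triplicates by default, reported as replicate mean and SD,
  clipped at zero because fluorescence cannot be negative.

The emulated round-1 screen measures 3000 random peptides once, keeps the
100 brightest plus 57 random dimmer clones plus SKIK, and re-measures the
158 in triplicate — mirroring a colony screen that recovers all positives
and some negatives.

What the defaults do **not** emulate: with the planted +0.6 bonus and 0.1
noise the landscape is substantially more learnable than the real assay —
round-1 pooled r sits near 0.95 rather than the ~0.5 seen with real
measurements, and pushing it down to that regime would require an order of
magnitude more noise than the stated measurement structure.  The multi-seed
replication therefore validates the *qualitative* claims — pooled r does not
degrade as rounds add data (median round-3 r ≥ round-1 r over 20 seeds),
aspartate dominates position 4 of the top-100 logo, and position-4
descriptors reach the top-10 importances — not any absolute correlation
value.  Passing these tests shows the pipeline recovers planted structure
from noisy data; it says nothing about predictive accuracy on real CFPS
measurements.

Read simulation for the extraction module embeds each peptide's randomized
region (NNK codon drawn uniformly per residue) between the true amplicon
flanks inside an 81-bp read, with optional uniform substitution errors; the
downstream filler past the fixed 18-nt SecM context is synthetic plausible
coding sequence.

## Problem sizes in tests and the acceptance script

The default test run and `scripts/acceptance.py` use the following sizes,
chosen so a complete run stays comfortably on one CPU: oracle-equivalence on
200 random sequences of length ≤ 14; a 10,000-read / 50-peptide extraction
round trip; and a 20-seed campaign replication on the full 160,000-peptide
space with a 250-tree forest and a two-point mtry grid (the package default
stays at 1000 trees; tree count changes runtime, not the round-over-round
comparison).  Unit tests exercise campaigns on a six-letter restricted
alphabet (1296 peptides) for speed.

## Known limitations

* The energy model is a folding-stability proxy; do not interpret its
  absolute values thermodynamically.
* The fourth-residue property regression ships only a generic Kyte-Doolittle
  hydropathy table as a demo; the original side-chain parameter set is not
  reproduced, so users must supply their own property tables for real
  analyses.
* Composition-level duplicate pooling (`by="composition"`) destroys the
  positional information logos rely on; the default deduplicates identical
  sequences only.
* The synthetic oracle is linear-plus-bonus in descriptor space; epistasis
  between positions is not modeled, which is one reason tree ensembles find
  it easy.
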