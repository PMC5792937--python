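# Methods

## Model

Each species' distribution is modelled as the maximum-entropy (Gibbs)
distribution over the grid cells of the study area,

    P(cell) = exp(λ · f(cell)) / Z(λ),

the distribution closest to uniform whose expected feature values match
their empirical averages over the presence localities. Fitting
maximises the presence log-likelihood with a per-feature L1 penalty,

    max_λ  (1/m) Σ_i λ·f(x_i) − log Z(λ) − Σ_j β_j |λ_j|,

which is concave; Z is computed over the background cells. The raw
output (relative occurrence probability, summing to 1 over valid
cells) is the quantity all downstream overlap computations use.

Assumptions worth keeping in mind: presence records are treated as an
unbiased sample of the species' occupied environment within the study
extent; one record per species per grid cell (coarser duplicates are
discarded); no detection model and no absence information.

## Features and regularisation

Continuous layers are min-max scaled to [0, 1] over the valid domain.
Under "auto" features, classes switch on with the presence count m:
linear always, quadratic at m ≥ 10, hinge at m ≥ 15, threshold and
product at m ≥ 80 — the long-standing defaults of the reference Maxent
implementation. Hinge features use 50 knots per layer, evenly spaced on
[0, 1], half forward (max(0, v−k)/(1−k)) and half reverse; threshold
features are 50 step indicators. Categorical layers expand to one 0/1
indicator per observed code; single-code layers are dropped with a
warning.

The penalty is β_j = reg · β_class · s_j / √m, where s_j is the
presence-sample standard deviation of feature j and β_class is a
per-class constant (linear/quadratic/product 1.0, hinge 0.5, threshold
1.0, category 0.25; configurable). s_j is floored at 1/√m: a feature
constant across presences would otherwise carry no penalty, and when
its presence mean sits at the boundary of the attainable moment set the
weight diverges. Complete separation under a genuinely zero penalty is
detected by exactly that boundary condition (presence mean at the
background minimum or maximum of an unpenalised non-constant feature);
the fit is then flagged non-converged, with weights bounded at |λ| ≤ 100.

## Optimisation

The L1 kink is removed by splitting λ = λ⁺ − λ⁻ with λ± ≥ 0, giving a
smooth bound-constrained concave problem solved with L-BFGS-B
(analytic gradient, log-sum-exp normaliser). Stopping: projected
gradient ≤ 1e-5 (default) or 500 iterations (the conventional Maxent
cap, which is also the pipeline default). With zero penalty and linear
features the optimum satisfies E_model[f] = mean_presence[f]; the test
suite checks this to 1e-3 and the two-cell closed form (λ = ln 3) to
1e-4.

Background: all valid cells when there are ≤ 10,000, otherwise a
seed-controlled uniform sample of 10,000 — determinism over fidelity to
any particular reference tool.

## Null-model test

AUC (rank-based, ties 0.5) can flatter models built on few records, so
significance is judged against a target-group null: R replicate models
(default 100) are fitted to draws of n localities (without replacement
within a replicate, independent across replicates) from the pooled
unique collection localities of a reference clade, and the
ceil(0.95·R)-th smallest replicate AUC is the threshold — exactly the
95th element at R = 100, no interpolation. Significance requires the
observed AUC to be strictly greater. The modelled species' own
localities are not excluded from the pool (an option exists): the pool
represents collecting effort, and exclusion would bias small pools.
Under exchangeability the expected type-I error is 3/(R+1) at R = 50
(≈5.9%), converging to 5% at large R; the acceptance check verifies
the realised rate over 200 simulated species stays inside the exact
binomial 95% envelope around 5%.

## Overlap and conservatism

Hellinger's I = 1 − ½ Σ(√p−√q)² is computed on raw normalised
surfaces (the metric is defined on probability distributions). When two
maps carry different valid-cell sets they are restricted to the
intersection and renormalised. Clade summaries report mean ± standard
error over pairs (SE matches the magnitudes conventionally reported;
SD available via an option); singleton clades carry no within value.

The conservatism statistic is the Pearson correlation of I against
patristic distance over all unordered species pairs, p from the t
transform with n_pairs − 2 df, treating pairs as independent — the
field's conventional test, reproduced deliberately. Because pairs from
the same matrices are not independent, a Mantel permutation test
(labels of the distance matrix permuted; p = (1+#{|r_perm| ≥ |r_obs|})
/(1+n_perm)) is provided as a companion, off by default. Species whose
SDMs fail the null-model test are excluded before pairing by default.

## Alignment accounting

Sites are classified counting unambiguous nucleotides only (gaps, '?'
and IUPAC ambiguity codes treated as missing — the conservative common
convention): constant (≤1 state), parsimony-informative (≥2 states each
in ≥2 taxa), else variable-uninformative. Indels follow simple indel
coding: each distinct internal gap (identical start and end columns)
becomes one binary character; exact-match taxa score 1, taxa with
contiguous determined sequence across the span score 0, and a
different overlapping gap — or missing data in the span — scores '?'.
Terminal gaps are treated as missing, not indels, since they usually
reflect incomplete sequencing. An indel character counts as informative
when ≥2 taxa score 1 and ≥2 score 0. Marker summaries restrict all
markers to their shared taxon set (echoed in the output) so counts are
comparable.

## Trees

Patristic distance is the sum of branch lengths on the unique path
between two tips (dendropy's distance matrix underneath; the test suite
cross-checks against an independent path-walking oracle).
Ultrametricity is auto-detected with a relative tolerance of 1e-6 of
tree depth, absorbing chronogram rounding. Crown age = age of the MRCA
of the clade's tips; stem age = age of the MRCA's parent; single-tip
clades have a stem only, and a clade spanning the whole tree has no
stem. Branch-length and chronogram estimation are out of scope — trees
are inputs.

## Synthetic worlds

The generator emulates the structure of the real study inputs:
Gaussian-blurred noise fields min-max scaled to [0, 1] (smoothness 6
cells; spatially autocorrelated like interpolated climate), Voronoi
patch categorical layers (like soil class maps), a Yule tree rescaled
to depth 1, Brownian-motion niche optima on its branches (rate σ² =
0.05 per unit depth, i.e. tip spread sd ≈ 0.22 on the [0,1] layer
scale), Gaussian suitability with breadth τ = 0.15, 30 records per
species on a 64×64 grid, and a target-group pool formed by the union of
all species' unique cells. σ² and τ were chosen so that optimum
divergence is comparable to niche breadth — overlap then varies over
most of [0, 1] across pairs, the regime the conservatism test is meant
to detect; τ → ∞ or σ² → 0 would make all surfaces identical and the
test undefined.

What the generator does **not** emulate: spatial sampling bias,
spatially aggregated collections, niche dimensions tied to categorical
variables (optional), non-Brownian (OU, multi-regime) trait evolution,
and real covariance structure among climate variables. Passing tests
therefore show the machinery is correct and calibrated under clean
conditions, not that any particular empirical dataset will yield an
unbiased answer.

## Problem sizes and numerical choices

Simulation-based checks use desk-scale problems: 24×24 grids with
linear features for type-I calibration (200 species, R = 50), the
64×64 default world with 16 tips for conservatism recovery (20 seeds,
with matched tip-shuffled nulls). Tolerances: optimiser gradient 1e-5;
suitability normalisation exact by construction (softmax); Hellinger
values clipped to [0, 1] against rounding; probability surfaces more
than 1e-6 from unit mass are renormalised with a warning. Ties in AUC
count 0.5; the variable-pruning tie-break drops the later-listed layer
of a correlated pair (the cutoff, 0.7, is configurable — standard ENM
practice rather than a fixed community constant).

## Known limitations

- The Pearson conservatism p-value inherits the non-independence of
  pairwise data; use the Mantel companion for inference you intend to
  defend.
- Raw Maxent output depends on the background definition; overlap
  values are comparable only among models sharing a domain.
- The L1 table is a convention, not a law; results at small sample
  sizes are sensitive to it (it is recorded in the model metadata).
- ESRI ASCII is the only raster format read; reproject and resample
  upstream.
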