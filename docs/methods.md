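# Methods

## The estimation problem

Invasion surveillance for zebra mussel (ZM) and Eurasian watermilfoil (EWM)
is passive: members of the public report suspected infestations, the agency
confirms them, and confirmed waterbodies enter the infested-waters list.
Specificity is effectively 1 (reports are confirmed before listing), but
sensitivity is not: remote, low-traffic waterbodies are less likely to be
visited, so true infestations there go unreported. The package estimates,
for every waterbody, the probability that a species has been (or will be)
introduced, using the spatial pattern of confirmed reports *plus*
well-sampled correlated covariates that remain informative where
surveillance is weak.

## Probability co-kriging

The primary variable is the reported presence indicator. Kriging an
indicator yields its conditional expectation, i.e. a presence probability;
predictions are clamped to [0, 1]. We implement **ordinary indicator
co-kriging**: the technique is sometimes labelled "probability kriging"
with a rank-transform of the primary added as a secondary; absent any
specification of those internals, plain indicator co-kriging is the
standard, defensible reading, and the covariate slots that matter
scientifically (traffic, road access, connectivity) are explicit
secondaries here.

Waterbodies without a report enter as indicator 0 data (`zeros: include`,
the default). This is an assumption, not an observation — under-reporting
makes some of those zeros false — but without absence data the estimator is
undefined; the secondaries are what compensates. An alternative
`exclude-subsample` policy keeps all positives and a seeded subsample of
zeros for sensitivity analyses.

### Variograms and the joint model

Empirical direct and cross semivariograms use the Matheron estimator over
distance bins of width `lag_size` with `n_lags = 12`. Small lags and few
lags deliberately limit how far an infested location's influence reaches.
On real-data (state) scales the conventional lag is 0.04 km; on a synthetic
extent the default is auto-scaled (largest extent dimension / 25) so the
12 bins span a comparable fraction of the domain — a convention of this
package, configurable via `lag_size`. Anisotropy is supported as an
elliptical transform (factor ≥ 1, azimuth angle) applied to separation
vectors before binning and inside the fitted model; the default is
isotropic (factor 1) because the clustered synthetic landscapes are
direction-neutral.

Single variograms are fit by iterated weighted least squares with Cressie
weights `N(h) / γ_model(h)²` (4 reweighting passes), bounds `nugget ≥ 0`,
`range ∈ [lag_size, 4 × max lag]`. The joint model is a **linear model of
coregionalization** with two shared structures — a nugget and one bounded
family (spherical default; exponential and Gaussian available, practical-
range convention) — whose range is taken from an independent fit of the
primary's direct variogram (the primary drives prediction). Per-structure
coefficients come from a weighted linear solve per variable pair
(non-negative for direct variograms), and each coefficient matrix is
projected to the nearest positive semidefinite matrix by eigenvalue
clipping. PSD coefficient matrices guarantee every co-kriging system is
solvable regardless of how noisy the cross estimates are.

### Prediction

The ordinary co-kriging system enforces unbiasedness (primary weights sum
to 1, each secondary's to 0) through Lagrange multipliers. Neighborhoods
are the nearest 32 data per variable within a search radius of 12 lag
units; singular systems get one retry with 1e-10 diagonal jitter. Surfaces
are predicted at cell centers of a regular grid (cell = lag size by
default) and a **water mask** forces probability 0 in cells containing no
waterbody — introduction probability is only defined where there is water.
Per-waterbody probabilities are read from the containing cell.

When scoring waterbodies (validation, ranking at data locations) the
target's own primary indicator datum is left out (leave-one-out); its
co-located secondary data are kept — collocated co-kriging. Without the
leave-out, a test waterbody's own "no report yet" datum dominates the
neighborhood and forces its score toward 0, erasing exactly the signal the
method exists to use.

## Networks and covariates

Each eligible watercraft-inspection interview contributes two undirected
edges (previous→station, station→next); repeated pairs accumulate integer
multiplicities used as weights. The network is undirected because a trip
implies physical transport opportunity both ways, and direction is not
recorded reliably. Self-loops are dropped. Eigenvector centrality is
computed by power iteration (tolerance 1e-10, Perron shift to avoid
bipartite oscillation) on the largest connected component — the dominant
eigenvector is ill-defined across components — with zeros elsewhere and
unit Euclidean norm; betweenness uses unweighted hop counts (multiplicities
encode frequency, not distance) and degree is the weighted edge-endpoint
count. Among the three measures, the one with the highest mean Pearson
correlation against the two species' statuses is used as the traffic
covariate (ties break eigenvector > betweenness > degree); unsurveyed
waterbodies score 0, the centrality of an isolated node.

Stream connectivity: a waterbody collects the route ("Kittle") identifiers
of stream polylines it intersects; an invaded waterbody intersecting none
is assigned its nearest stream within a 100 m buffer. A waterbody sharing
any identifier with an invaded waterbody is flagged connected — up- and
downstream alike, since both drift and watercraft can carry propagules
either way. Flags are recomputed per species and census. Road access is
the inverse Euclidean distance to the nearest major-road polyline, floored
at 0.01 km so waterbodies on a road keep a finite score.

Screening uses the full 6 × 6 Pearson matrix (binary columns as 0/1
numerics, i.e. point-biserial); secondaries with r ≥ 0.1 against a primary
are candidates, the other species' status included (the two invasions
co-occur). Zero-variance columns are excluded with a warning.

## Validation

**Temporal (true) validation** fits on census-1 reports and scores every
waterbody not then infested; positives are waterbodies newly reported by
census 2, negatives are waterbodies never reported. The negative
definition is an assumption forced by presence-only surveillance — some
negatives are undetected positives, which biases AUC toward 0.5, so
measured discrimination is conservative. AUC is the Mann–Whitney
concordance (ties ½). Sensitivity/specificity are evaluated at threshold
risk rank 3 on the quintile ranking of test scores; an auto-threshold mode
maximizes Youden's J. **Model selection** evaluates every two-way
combination of screened secondaries by temporal-validation AUC (ties to
the first pair in covariate order). **k-fold cross-validation** (k = 5)
partitions infested locations into seeded folds; each fold's indicator-1
data are withheld from the fitting data and scored by the remainder, while
never-infested waterbodies are scored once leave-one-out; variogram/LMC
parameters are fit once and held fixed across folds, mirroring the
practice of carrying the temporally validated parameters into
cross-validation.

## The synthetic landscape

The generator emulates the study system at desk scale; defaults were fixed
once and are the conditions under which all stochastic tests run.

| parameter | default | rationale |
|---|---|---|
| waterbodies | 600 in 30 × 30 km | desk scale; full 18,411-waterbody runs remain possible |
| point process | Thomas cluster, 40 parents, σ = 1.2 km | lakes are spatially clustered |
| river points | 5 % | river midpoints in the real register |
| census-1 prevalence | ZM 0.05, EWM 0.08 | raised from the real 0.3 %/1.4 %: at n = 600 true prevalence would leave ~2 positives, unable to support variogram estimation or 5-fold CV; the ZM < EWM ordering is preserved |
| census growth | ZM × 2.2, EWM × 1.2 | the reported census growth magnitudes (57→125, 251→304) |
| latent risk effects | traffic 1.2, road 0.8, spatial field 1.0 (range 3 km) on standardized scores | strong positive human-mediated-dispersal effects |
| new-infestation weights | exp(5.0 · e^(−d/2 km) + 1.5 · connectivity) | new invasions concentrate near existing ones; a waterbody adjacent to an infestation has ~150× the odds of a remote one |
| reporting | logistic(1.5 + 1.0 · (z_road + z_traffic)) | accessible, high-traffic waterbodies detected preferentially; no false positives; a missed infestation gets a second chance at census 2 |
| surveys | 5,000 records, 45 stations, 21 % eligible | the real eligibility rate; gravity-style station/link choice (size × inverse distance) |

Census-1 intercepts are calibrated by bisection so expected prevalence
equals the target exactly; the spatially autocorrelated field uses a
random-Fourier-feature approximation (256 features) so state-scale runs
stay O(n). All randomness flows from one seed through named per-process
streams, so adding a generator never perturbs another and every output is
byte-reproducible.

**What the generator does not emulate:** real hydrological routing and
flow direction, lake polygons (points only), seasonal traffic dynamics,
magnitude of infestation, and cross-border invasion pressure. Passing
tests therefore demonstrate that the machinery recovers structure it is
pointed at under a plausible data-generating process — not that the
real-data covariate correlations or AUCs would take any particular value.

## Numerical conventions

- Percentages in summaries follow the surveillance-report convention:
  truncation at 2 decimals (125/18,411 → 0.67 %); rounding is available as
  an option.
- Quintile boundaries use linear-interpolation percentiles; boundary values
  go to the lower class, so a constant probability vector is all rank 1.
- Co-located points are points within 1e-9 km; the nugget applies only at
  exactly-zero lag.
- Exact interpolation holds at primary data under a zero nugget; weight
  constraint sums hold to 1e-12.
- Tie-breaks are deterministic everywhere (centrality order, secondary-pair
  order, lower threshold rank).

## Known limitations

- Co-kriging treats introduction probability as a spatially continuous
  field; it is defined only at waterbodies. The water mask zeroes dry
  cells but within-cell position is lost at coarse grids.
- The negatives-are-unreported convention biases all validation metrics
  conservative under heavy under-reporting.
- The LMC shares a single range across variables; genuinely multi-scale
  cross-dependence is projected onto that structure.
- Variogram estimation on a rare indicator is noisy: with few positives the
  cross-coefficients rely heavily on the PSD projection. EWM's slow census
  growth (~×1.2) leaves few test positives per landscape, so single-seed
  AUCs for EWM are volatile even though the 20-seed mean is stable.
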