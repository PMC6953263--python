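# Methods

This note documents the models, the synthetic data the package validates
itself against, the numerical choices, and the limits of what the tests
demonstrate.

## Scope and data flow

The pipeline estimates landscape resistance for two groups of large
tropical-forest mammals — a disturbance-*sensitive* group (white-lipped
peccary, tapir, giant anteater) and a *tolerant* group (puma, ocelot and
other generalists) — from two independent data types: community camera-trap
detection histories (occupancy) and individual GPS tracks (step selection).
Six covariates drive both models: elevation, forest cover (FCOV), forest
loss, distance to the nearest road, density of human settlements (village),
and depth inside protected areas (DWPA; zero outside protected polygons,
interior distance-to-boundary inside — the exterior value is a package
convention, chosen so the covariate is continuous at the boundary). All
rasters live on a 30 m grid; covariates are centered and scaled before
fitting, and pairs with Spearman |rho| > 0.6 are screened (dropping, per
offending pair, the layer with the larger mean absolute correlation to the
rest — deterministic and conventional; the choice only matters for nearly
tied layers).

## Hierarchical multi-species occupancy

Species-level intercepts, slopes, and detection intercepts are random
effects of community-level normal distributions. Priors: community means
~ Normal(0, 1.5), community sds ~ half-Normal(1.5), weakly informative on
the logit scale. The detection submodel is the minimal one consistent with
separating non-detection from absence: y_ijk ~ Bernoulli(z_ij · p_i) with a
species-level logit intercept under the same community hyperprior;
occasion-level detection covariates are out of scope.

The sampler is Metropolis-within-Gibbs: exact conjugate updates for the
latent presence z (site-species pairs with any detection are pinned at
z = 1), coordinate-wise random-walk Metropolis over species coefficients
(vectorized across species), conjugate normal draws for community means,
and log-scale random-walk updates for community sds. Step sizes adapt
toward ~44% acceptance during burn-in only, so the post-burn-in chain is a
valid time-homogeneous MCMC. API defaults are 3 chains × 20,000 iterations
(10,000 burn-in, thin 10); the pipeline demo and the validation studies use
shorter, empirically converged runs (see below). Split-R-hat and effective
sample size come from arviz; R-hat > 1.1 raises a recorded warning, never a
silent pass.

Prediction averages ilogit(α_i + Σ α_in V_n) over (thinned) posterior
draws. Group surfaces for core-area delineation are the unweighted mean of
member-species posterior-mean Ψ surfaces; the combination rule is a package
convention. Core areas are 8-connected components of {Ψ ≥ t*}, with t*
chosen where the occupancy-area curve A(t) is steepest (finite differences
on a 0.01 grid; ties resolve to the smallest t), and patches below a
minimum area dropped. Reference thresholds of ψ = 0.2 (tolerant) and 0.3
(sensitive) are available when the curve step is skipped.

## Step-selection functions

Steps are consecutive hourly fixes (tolerance ±5 min; gapped intervals are
dropped, and turn angles are undefined across gaps). Availability is K=100
control steps per stratum sharing the observed start point: lengths from a
gamma fitted by MLE to the individual's observed lengths, angles uniform on
(−π, π]. Turn angle is deliberately not used to classify behavior; travel
mode instead keeps strata whose observed step is at least 100/150/200 m
(ocelot / white-lipped peccary / puma). Controls landing off the grid or on
nodata are excluded from their stratum's denominator; strata with more than
10% invalid controls are dropped (an artifact-choice guard against
extent-edge bias, logged per step set).

The conditional-logistic likelihood is maximized by Newton-Raphson with
analytic gradient and Hessian and step halving; convergence at gradient
norm < 1e-6; standard errors from the inverse observed information.
Complete separation is detected when any |β| escapes 15 and reported as an
error, as are covariates constant within every stratum. The implementation
is cross-checked against an independent conditional-logit fitter in the
test suite (agreement to ~1e-8).

**Movement-kernel correction.** Because the availability gamma is fitted to
*selected* (observed) lengths, it is only a tentative kernel; when habitat
covariates correlate with step length (always, on autocorrelated
landscapes) habitat coefficients fitted without correction attenuate
toward zero. Including the step length (km) and its log as additional
covariates spans any reweighting within the gamma family and removes the
bias — the standard integrated-SSA device. `sample_random_steps` therefore
always attaches `sl` and `log_sl` columns, recovery studies fit with
`covariates + LENGTH_ADJUSTMENT`, and `predict_suitability` excludes the
kernel terms from the habitat map.

Per-individual models only, no pooling: group surfaces are combined later
on the resistance scale. AICc (sample size = number of strata) ranks
candidate covariate sets, ties to fewer parameters then listed order.

## Resistance

Suitability HS ∈ [0, 1] (occupancy Ψ directly, or min-max-rescaled SSF
scores) maps to resistance by R = 100 − 100·HS or
R = 100 − 99(1 − e^(−c·HS))/(1 − e^(−c)), c ∈ {3, 8}; larger c keeps
resistance low until suitability is very poor. Out-of-range HS raises
rather than clamps, to surface standardization bugs. Group surfaces
z-score each member (species or individual) surface over valid cells,
average cellwise, and rescale to span exactly [1, 1000]; "standardize" is
interpreted as z-scoring, which is what makes occupancy- and SSF-derived
members commensurable. Barriers (roads/urban cells) are burned afterward at
0.85/0.95 × the pre-burn maximum, i.e. 850/950 on a [1, 1000] surface —
burning after the rescale keeps the burn level interpretable as a fraction
of the realized maximum.

## Connectivity

The cost graph connects valid cells to their 8 neighbors with edge cost =
mean endpoint resistance × center distance (×√2 on diagonals), the
Linkage-Mapper convention. Cost-weighted distance (CWD) from a core is a
multi-source Dijkstra with every core cell a zero-cost source (free
within-core travel). A pair's corridor is {CWD_A + CWD_B − LCP ≤ cutoff};
the cutoff defaults to 25,000 cost units (resistance × meters) and is
exposed as a flag. Pairs whose least-cost path crosses a third core are
skipped by default ("adjacent" rule; "all" is available) — the adjacency
rule itself is a package convention.

Circuit solves use per-edge conductance 1/cost and a direct sparse
symmetric solve of the reduced graph Laplacian (SuperLU; residuals at
interior nodes < 1e-8 by construction). All-to-one mode grounds each core
in turn while every other core injects 1 A split over its cells; per-cell
current is half the sum of absolute incident edge currents, **averaged**
over ground iterations so that two single-cell cores joined by one chain
carry unit current — summing the two symmetric iterations would
double-count. Cores disconnected from the ground are reported per
iteration and their component excluded from the solve. Pinch points are
corridor cells at or above the 95th within-corridor current percentile.

## Synthetic landscapes and what they do (not) show

The generator produces spatially autocorrelated covariates by Gaussian
smoothing of white noise (default range 300 m on a 30 m grid) — any
stationary autocorrelated field serves. Forest fraction is matched exactly
by quantile thresholding; roads are straight transects; villages are
uniform points (density within 2 km); protected areas are random discs.
Detection histories come from the same hierarchical model the sampler
fits; tracks come from a discrete-choice step-selection simulator (J
candidates per step, gamma lengths, uniform angles, softmax selection on
exp(β'x) at candidate end points, out-of-extent candidates resampled).
J is a fidelity parameter: the discrete choice converges to the continuous
SSF density as J → ∞ and coefficients attenuate by O(1/J) below it, so J
defaults to 200 and the recovery studies use 500.

What passing recovery tests show: the estimators are correctly implemented
and approximately unbiased *under their own assumptions* (gamma lengths,
uniform angles, Markov steps, perfectly registered covariates). What they
do not show: robustness to GPS error, irregular fix schedules, behavioral
heterogeneity, home-range attraction, or covariate misregistration — real
data carry all of these. The generator exposes a fix-dropout probability
(default 0) but no structured gap model.

## Problem sizes used by the shipped studies

Chosen to hold Monte Carlo error well below the quantities of interest:

- SSF recovery (validation.recover_ssf): 300×300-cell landscape, one track
  of 3,000 steps (6,000 in `scripts/acceptance.py`), J = 500 simulator
  candidates, K = 100 controls. Across-seed sd of a recovered coefficient
  is ~0.03–0.05 at 3,000 steps and ~0.02–0.03 at 6,000.
- Occupancy coverage study: 20 replicates × (10 species, 500 sites, 8
  occasions, 3 slope covariates), 2 chains × 2,500 iterations (1,000
  burn-in); nominal-vs-empirical CI coverage agrees to within binomial
  noise.
- Pipeline demo: 100×100-cell landscape, 200 camera sites × 6 occasions,
  2×4,000 MCMC, 350-step tracks, the full 2×3×3 scenario matrix.

## Known limitations

- No spatial random effects in occupancy; residual spatial autocorrelation
  inflates confidence in dense camera grids.
- The SSF [0, 1] rescale (and hence resistance) is extent-dependent;
  surfaces from different extents are not comparable.
- The conditional-logit SE treats strata as independent; consecutive steps
  share landscape, so SEs are mildly optimistic for strongly site-faithful
  animals.
- Corridor width is an emergent property of the cutoff and the data; it is
  reported, not enforced.
- Circuit solves are direct; grids beyond ~10^6 valid cells need an
  iterative solver, which is out of scope.
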