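# Methods

`settlemate` implements two linked analyses of conspecific attraction in a
territorial songbird, plus a synthetic-data generator that reproduces their
statistical structure end to end. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Analysis 1 — settlement point-process models

Settled-male locations in a site-year are treated as an inhomogeneous
Poisson point pattern with loglinear intensity

    lambda(u) = exp(beta0 + sum_k beta_k S_k(u)),

over two covariate families on a 10 m planar grid:

* **Habitat attractiveness (`hab`)** — a Gaussian kernel-density surface of
  cumulative nest locations. Nests from the focal site-year are excluded
  (leave-one-site-year-out), so the covariate carries no same-year social
  information; nest sites are chosen by females and therefore proxy habitat
  features attractive to them. The kernel is an isotropic Gaussian with a
  configurable bandwidth; the surface is computed on the intensity scale
  (nests per m²; the pipeline rescales to nests/ha so coefficients act on a
  range of order 10). A small positive floor (1e-6 × max cell) keeps powers
  H^alpha defined everywhere.
* **Playback proximity (`prox.all`, `prox.lc`)** — exp(−d/200) where d is
  the distance from each cell centre to the nearest playback-station
  midpoint (the midpoint of the paired speakers is the simulated territory
  centre); `prox.lc` restricts to low-song-rate stations.

**Likelihood.** The Poisson process log-likelihood
`sum_i log lambda(x_i) − ∫_W lambda(u) du` is approximated by the
Berman–Turner device: the window is tiled by a regular dummy grid (default
spacing 10 m, equal to the covariate cell — finer dummies cannot add
covariate information), each data or dummy point receives the counting
weight w_j = tile area / points in tile, and the weighted Poisson
regression `sum_j w_j (y_j log lambda_j − lambda_j)` with y_j = z_j / w_j is
maximised by Newton/IRLS with step-halving, converging when the score norm
falls below 1e-8. Edge tiles are clipped so weights sum exactly to the
window area; tile membership uses the half-open convention
[x0, x0+cell). Coefficient covariance is the inverse Fisher information.
Because the covariates are cell-constant and the dummy grid is aligned with
the raster, the quadrature integral is essentially exact, which the test
suite confirms against a 1 m brute-force grid.

Multiple site-year patterns are fitted **jointly with fully shared
coefficients including a single common intercept** — the literal reading of
fitting one common model to all patterns. AICc uses n = total number of
data points across patterns (the study-scale n is ~50); the appropriate n
for point-process AICc is genuinely ambiguous, but only relative AICc
within the candidate set matters here.

Separation (a covariate perfectly separating data from dummy points, or an
empty-window intercept ridge) cannot converge to a finite optimum; any
converged coefficient beyond ±20 log-intensity units is reported as a
`ConvergenceError`, since physically observable settlement densities keep
log-intensities within roughly ±14.

Range-standardised effect sizes are reported as exp(beta × range): the
multiplicative change in predicted density across the observed span of a
covariate.

## Analysis 2 — conditional-logit mate choice

Each settling female chooses among the males present in her site when she
began nesting. Male i's attractiveness is

    A_i = H_i^alpha1 * C_i^alpha2,    p_i = A_i / sum_j A_j,

with H_i the habitat value at his territory centre (nearest cell, no
interpolation) and C_i = sum_{j≠i} exp(−d_ij / decay) his connectivity — a
metapopulation-style, distance-weighted count of competitors. Playback
stations can enter the competitor sum (raising real males' C) but are never
choosable. The likelihood is `sum_events ln p_chosen`; single-candidate
events contribute exactly zero. Four models — null (both exponents fixed at
0), habitat only, connectivity only, full — are fitted by Nelder–Mead with
five multi-starts per free parameter from {−1, −0.5, 0, 0.5, 1}
(unconstrained; the log-likelihood is that of a conditional logit in
(log H, log C) and is concave, so the multi-start is belt and braces), and
compared by AICc with n = number of choice events.

**Connectivity decay.** The literal exp(−d_ij) with d in metres underflows
at realistic spacings (hundreds of metres), so the decay length is an
explicit parameter, default 200 m to match the proximity covariate's
exp(−d/200); decay = 1 reproduces the literal formula. Only relative
connectivities matter for p_i — a common factor on every C (or H) cancels,
which is asserted numerically in the tests.

Exponent model averages (conditional, full, or restricted to the
substantial-support set ΔAICc ≤ 2) are taken on the exponent scale, as the
percent-change translation 100 × (1.1^alpha − 1) per 10% covariate step
implies.

## Preprocessing rules

* A male is **settled** if his site presence spans ≥ 5 days (inclusive day
  count from first to last observation).
* Singing locations ≥ 150 m apart are distinct territories; territories are
  built by single-linkage clustering at a strict 150 m threshold (the most
  permissive reading — exactly 150 m splits), with the centre taken as the
  member centroid (the field definition leaves the centre rule open).
* Polyterritorial males contribute the longest-tenure territory; tenure
  ties go to the chronologically first.
* Nest timing: clutch initiation = clutch completion − (clutch size − 1)
  days (one egg per day); nest initiation = clutch initiation − 7 days;
  incubation spans 14 days from completion.
* A female's candidate snapshot is the survey nearest in time to her nest
  initiation; ties go to the earlier survey (females typically begin
  building the day they arrive, so earlier information is the safer proxy).
  Already-paired males remain candidates (polygyny occurs). When the data
  do not name the chosen male (`mate_id`), the candidate nearest the nest
  is used — a pragmatic stand-in; real analyses should supply the mate.

## Synthetic generator — what it emulates

The generator produces, from one forked seed per sub-generator: a latent
attractiveness surface (isotropic Gaussian hotspots on a constant floor —
the simplest strictly positive heterogeneous surface); nests accumulated
over 11 seasons placed proportionally to that surface; a playback array of
paired speakers 100 m apart with randomised high/low song-rate labels;
male settlement patterns drawn by thinning a dominating homogeneous process
at the exact grid upper bound exp(beta0 + max(beta_hab·hab) +
max(beta_prox·prox)); and sequential female choices drawn from the
conditional-logit model, with each male independently present in a given
female's snapshot with probability 0.9 (survey-to-survey turnover).

Default study conditions: 100 ha window, 6 hotspots of sd 40 m and
amplitude 25, 18 nests/year, KDE bandwidth 25 m, settlement coefficients
(beta_hab, beta_prox) = (0.109, 1.773), choice exponents
(alpha1, alpha2) = (0.625, −0.06), 59 choice events per study, ~10 expected
males per site-year (five site-years per study). The hotspot geometry was
chosen once so the habitat covariate spans roughly 20 nests/ha — the range
over which the settlement coefficient 0.109 produces a density factor near
10, matching the scale on which that coefficient is meaningful. The
intercept beta0 is solved from a target expected male count, since its
absolute value is site-specific and uninteresting.

What the generator does **not** emulate: within-season territory shifts and
re-survey error, detection failure, inter-site heterogeneity in effect
sizes, temporal autocorrelation of female arrivals, and any behavioural
response of real males to playback beyond the loglinear proximity effect.
Passing recovery tests therefore show the estimators are correct for the
assumed data-generating process, not that the field estimates are free of
confounding.

## Simulation-study design choices

* **Choice-exponent recovery** uses 2,000 events for the asymptotic check
  and the study's own 59 events for the small-sample check; at n = 59 the
  connectivity exponent is very noisy (SD ≈ 0.6) but median-unbiased,
  which is exactly the regime the study's data occupy.
* **Wald coverage for beta_hab** draws a fresh scene per replicate and one
  pattern with ~150 expected males, so coverage error is not confounded
  with small-sample effects or with conditioning on a single landscape.
  With a shared-intercept model, the generating intercept must itself be
  common across patterns fitted jointly; the helper calibrates it that way.
* **Model-ranking under a pure habitat effect**: with alpha2 truly zero,
  the full model beats habitat-only whenever twice the log-likelihood gain
  exceeds the AICc penalty gap (~2.004 at n = 2000), which happens with
  probability ~P(chi²₁ > 2) ≈ 0.157; habitat-only therefore ranks best in
  ~84% of replicates. This is a property of AICc itself, not of the
  implementation.

## Numerical details and degenerate inputs

* Rasters are row-major south-to-north; sampling is nearest-cell with
  half-open cells, and a point even marginally outside the extent is an
  error rather than an extrapolation.
* KDE with zero nests returns the floor everywhere; proximity with an
  empty station subset is an error.
* Choice events with a single candidate contribute zero likelihood and are
  excluded from the packed arrays; a multi-candidate event with zero
  connectivity is rejected when alpha2 is free (co-located males imply
  C > 0 by construction).
* AICc requires n > k + 1 and raises otherwise.
* All dates are timezone-free ISO-8601 at day resolution.

## Known limitations

Windows are rectangles (polygon or mask windows would change only the
dummy-grid clipping); raster I/O is ESRI ASCII grid; per-pattern intercepts
are available in principle by fitting patterns separately but the joint
fitter deliberately shares one intercept; the KDE has no edge correction by
default (the bandwidth is small relative to the window, and the choice is
configurable).
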