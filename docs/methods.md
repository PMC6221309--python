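# Methods

`osteotex` implements a quantitative pipeline for studying how bone surfaces
wear: synthetic generation of experimental scan data, metrological
preprocessing of height maps, four ISO 25178 areal texture parameters, and a
multilevel multivariate Bayesian mixed model of the resulting 4-vectors.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data can and cannot show.

## Height maps and texture parameters

A scan is a regular grid of heights in µm with a boolean measured-cell mask
(confocal instruments fail on steep or poorly reflective cells).  All
statistics use measured cells only.

**Sa** (arithmetic mean height, µm) is the mean absolute deviation of heights
from their mean.

**Sal** (autocorrelation length, µm).  The areal autocorrelation is estimated
by FFT of the mean-removed, mask-zero-filled surface, zero-padded to avoid
circular wrap-around, and normalised by its lag-0 value; on full masks this
equals the direct sum estimator exactly.  Sal is the minimum Euclidean lag
distance over the discrete grid of lags at which the normalised ACF first
falls to the threshold `s = 0.2` (the ISO 25178-3 default).  We chose the
discrete lag search rather than interpolating between lags: interpolation
near the origin mixes the lag-0 value (always 1) into the estimate and
yields sub-spacing autocorrelation lengths for white noise, whereas the
discrete search correctly reports one sample spacing for uncorrelated
surfaces and matches the analytic inversion of a cosine ACF within the grid
resolution.  If no lag qualifies (possible only for thresholds below the ACF
minimum) the maximum searchable lag is returned with a warning.  The
discrete search also makes exact agreement with a brute-force lag scan a
testable property.

**Spc** (arithmetic mean peak curvature, 1/µm).  Hills are the catchment
basins of the inverted surface.  Significance is decided by Wolf pruning: a
hill whose peak-to-saddle height (topographic prominence) is below 5 % of
`Sz = max − min` is merged into its neighbour.  Prominence is computed by a
union-find sweep over cells in descending height order — the watershed-merge
level at which a hill first connects to a higher hill is exactly its saddle.
Curvature at each surviving peak is −½(∂²z/∂x² + ∂²z/∂y²) by 3-point central
differences; border peaks and peaks lacking four measured neighbours are
discarded because the stencil is undefined there.  Spc is the mean over
surviving peaks.  The 5 % pruning level is the ISO default; the source data
for this kind of analysis never state it, so it is exposed as a parameter.

**Smr1** (upper material ratio, %).  The areal material ratio curve
smr(c) = 100·#{z ≥ c}/N is sampled on 1024 height levels.  The equivalent
line of the Sk construction (ISO 13565-2 / 25178-2) is found by sliding a
40 %-wide window along the material-ratio axis at 0.5 % increments, taking
the window with the smallest secant slope (first window wins ties), fitting
a least-squares line to the curve inside it, and evaluating that line at
mr = 0 %.  Smr1 is the material ratio at which the curve descends to that
height (linearly interpolated; 0 if the curve starts at or below it).  A
linear ramp therefore yields exactly 0 %, and plateau-with-pits surfaces
yield values below their pit fraction.

Degenerate inputs (zero variance, too few measured points, no surviving
peaks) raise errors rather than returning 0, so the downstream log transform
can never silently receive a non-positive value.

## Preprocessing chain

The metrological chain runs, in order: least-squares leveling → y/z
mirroring for molds → robust outlier removal → neighbor-smoothing fill-in →
Gaussian low-pass S-filter → degree-2 polynomial form removal (F-operator).
A scan is accepted only if at least 95 % of its cells are measured
(inclusive bound).

* *Outliers*: residuals from a 5×5 median-filtered surface are tested with a
  robust z-score, |r| > k·1.4826·MAD with k = 3 ("normal strength"); the
  border ring participates through nearest-replication of the median filter.
  Flagged cells become non-measured.
* *Hole fill*: 8-connected non-measured components strictly smaller than 225
  cells are filled by iterative neighbor-mean (harmonic) relaxation to a
  1e-6 µm tolerance; harmonic interpolation reproduces planes exactly.
  Larger holes stay non-measured.
* *S-filter*: Gaussian weighting with 50 % amplitude transmission at the
  cutoff wavelength, a(λ) = exp(−π(α·cutoff/λ)²), α = √(ln2/π)
  (ISO 16610-61), implemented as separable Gaussian smoothing with
  σ = α·cutoff/√(2π); masked cells are handled by normalised convolution.
  The default cutoff is 5 µm (≈3 sample spacings of the 0.8 mm / 512-pixel
  reference field); the cutoff is configuration, not a claim about any
  particular commercial software's default.
* *Form removal*: least-squares fit of the 6-term bivariate quadratic on
  centred, scaled coordinates, subtracted.  Leveling is the degree-1 case of
  the same operator, so both are idempotent and leave residuals orthogonal
  to the removed monomials.

## Synthetic experiment

**Registry.**  The default design is 37 bone specimens in 5 acquisition lots
(sizes 8, 8, 7, 7, 7), each specimen in one of three manufacturing states
(unworked UW, ground with sandstone GS, scraped with flint SF) crossed with
one of three wear materials (fresh skin FS, processed leather PL, dry bark
DB); all 9 cells hold ≥ 4 specimens.  Molds are taken at 0, 30, 60, 90 min
and every 90 min thereafter up to the specimen's total duration.  Durations
are assigned deterministically as 26 specimens at 180 min (5 molds), 8 at
270 min (6 molds) and 3 at 450 min (8 molds), giving 202 molds and 239
samples in total — the structural counts the design targets.  Five crosswise
scan locations (C, D, P, L, R) are modeled per sample, grouped to three
levels (C, D+P, L+R) in the statistical design; a configurable subset of
time-0 molds is "re-scanned a year later" to give the rescan control factor
non-degenerate support.

**Surface simulator.**  Bone microtopography is anisotropic 1/f-like
texture (correlation ~5 µm across, ~14 µm along the fibre direction,
Sa ≈ 0.25 µm) plus Poisson-placed Gaussian pore depressions (60 /mm²,
0.8–2.5 µm deep).  GS adds dense transverse scratches 25–45 µm wide; SF adds
sparse deep furrows 55–100 µm wide with raised shoulders, at the wide end of
the 30–100 µm range typical of manufacturing traces.  Wear progresses as
w(t) = 1 − exp(−rate·t) and acts through three height-dependent mechanisms
in material-specific mixture: summit truncation (plateaus under rigid
contact — dominant for dry bark), overall rounding toward a 5 µm-smoothed
copy weighted toward the lower surface (supple polish — skin and leather),
and valley blunting (moist skin penetrating and polishing furrow bottoms —
fresh skin only).  Fine 5–10 µm striations accumulate with w.  Rates
(FS 0.004, DB 0.002, PL 0.0008 /min) were calibrated once so that fresh skin
reduces the Sa of unworked bone by roughly 40 % over 450 min while leather
and bark change it much less — the rate ordering, not its absolute size, is
the property the study design fixes.  Molding flips y, negates z, applies
sub-pixel registration jitter and rounds the sharpest summits slightly, so
mirrored-back molds show lower Spc than their bones.

The simulator emulates the *statistical geometry* of worn bone surfaces —
state orderings at time 0, material-dependent wear rates, mold bias — not
tribological contact mechanics.  Passing trend tests therefore shows the
pipeline recovers the qualitative structure it was pointed at; it says
nothing about how real bone wears.

**Parametric generator.**  For model tests the surface stage is bypassed:
log-scale 4-vectors are drawn directly from Y = XB + ZU + E with a known
effect matrix, Gaussian specimen/lot intercepts (default SDs 0.25 / 0.15)
and multivariate Student-t noise (default scales ≈0.35–0.5, ν = 5).  The
built-in effect matrix reproduces the qualitative geometry above on the log
scale.

## Statistical model

Observations are the natural logs of the 4 texture parameters; time enters
as log(t + 1) min so time-0 rows form the baseline.  Dummy coding uses
location C, state UW and material DB as baselines; materials have no main
effect (they enter only ×log-time), so the three materials coincide exactly
at time 0 by construction.  The ladder is M0 (intercept), M1 (+ grouped
location, bone-vs-mold, rescan, log time), M2 (+ state main effects, state
and material × log-time), M3 (+ state × material × log-time) — column-nested,
with k = 16 for M3 under this coding.

The likelihood is row-wise multivariate Student-t with scale Σ = DΩD;
specimen and lot random intercepts are multivariate Gaussian with their own
DΩD decompositions.  Priors: N(0, 5²) on fixed effects, half-Cauchy(2.5) on
scale entries, LKJ(1.5) on correlations, Gamma(2, 0.1) truncated at 2 on the
degrees of freedom.

**Sampling.**  The Student-t is represented as a Gaussian scale mixture with
per-row Gamma(ν/2, ν/2) precision weights, making all location parameters
conditionally Gaussian.  The sampler is blocked Gibbs: conjugate updates for
the weights, vec(B) and the 4-dimensional specimen/lot intercept rows;
componentwise adaptive random-walk Metropolis for each (log D, atanh partial
correlation) block, where the LKJ prior is written exactly in its C-vine
form (partial correlations at tree level k are Beta(η + (d−1−k)/2) on
(−1, 1)); and a random walk on log(ν − 2).  Two extra exact moves improve
mixing: a "ridge" shift trading a constant between the intercept row and a
random-effect block (the likelihood is flat along that direction, so the
Metropolis ratio is the prior ratio), and an interweaved non-centered update
of the random-effect scale blocks (with U = ηL(θ)ᵀ held fixed in η), which
breaks the funnel coupling between scales and intercepts.  Step sizes adapt
toward 0.44 acceptance during warmup only.  Defaults are 2 chains × (500
warmup + 500 draws) = 1000 stored samples.  Split-R̂ is computed for every
scalar; fits with max R̂ above 1.05 are returned flagged, not rejected, so
ladder runs always complete.  Metropolis-within-Gibbs at this chain length
typically lands near R̂ ≈ 1.03–1.1 on the fixture sizes used here.

**WAIC** uses one observation row (one 4-vector) as the pointwise unit,
matching the multivariate likelihood: WAIC = −2(lppd − p_waic) with p_waic
the ddof-1 posterior variance of the pointwise log-likelihood.

**ICC** per texture parameter j decomposes the unstructured variance into
d²_lot,j + d²_spec,j + d²_err,j·ν/(ν−2); the Student-t variance correction
puts the error scale on the same footing as the Gaussian components.

**Goodness of fit**: with posterior-mean parameters, the scaled squared
Mahalanobis residual d²/p of a p-variate Student-t follows F(p, ν), giving
the theoretical quantiles for the QQ comparison.

## Calibration tests and their problem sizes

The recovery and selection properties are checked at sizes a single CPU
handles in minutes, chosen once: fixed-effect coverage on n = 600 rows from
the default 37-specimen registry; ICC recovery at generator ICC 0.2 on
n = 2000 rows from an enlarged design with 40 lots × 5 specimens — with only
5 lots the realized lot variance of a single draw scatters by a factor of
~3 around its expectation (χ²₄ behaviour), so the nominal ICC is not an
identified estimand at the original design size and recovery is tested where
it is; WAIC selection between M1 and M3 on 20 replicates of n = 150 with
strengthened three-way interactions; trend reproduction on 20-seed means of
128×128 surfaces (0.8 mm field sampling at 1.5625 µm is represented at a
quarter of the linear extent to keep the suite fast; the parameters are
intensive, so the orderings are unchanged).

## Known limitations

* The Sal/Spc/Smr1 construction parameters (decay threshold, pruning level,
  equivalent-line window) follow ISO conventions; exact numerical agreement
  with any specific commercial metrology package is not claimed.
* The ACF estimator zero-fills non-measured cells; for masks near the 95 %
  acceptance bound the bias is negligible, but heavily masked surfaces would
  need a per-lag pair-count correction.
* The Gibbs sampler's scale blocks mix more slowly than a gradient-based
  sampler would; for final inference on real data one would run longer
  chains than the test defaults.
* Wear is modeled phenomenologically (quantile truncation, smoothing blends);
  it reproduces the direction and ordering of texture-parameter trends, not
  removal volumes or contact pressures.
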