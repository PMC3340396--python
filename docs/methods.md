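# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic generator does and
does not emulate.

## Synthetic rivers

The generator produces the statistical structure the analysis assumes — a
directional network carrying downstream-mixed constituents that set the
light field, which in turn sets the community — without attempting
hydrodynamics.

**Network.** Stations are arranged as `n_transects` cross-river transects
of `stations_per_transect` lateral lanes; each lane is a downstream chain.
One virtual origin feeds every lane head of the main stem (its discharge
split equally among lanes) and each tributary is its own origin attached at
one station. The graph is acyclic by construction and every station is
reachable from an origin. Edge weights default to 1 (presence/absence
connectivity).

**Mixing.** Concentrations (a_CDOM340 in m⁻¹, tripton in mg L⁻¹, SRP in
µg L⁻¹) propagate in topological order. At a confluence the concentration
is the discharge-weighted mean of the inflows, so the mass flux
(concentration × discharge) is conserved exactly; outflow discharge is the
sum of inflows. An optional first-order loss per edge applies to a_CDOM and
tripton only (photobleaching/settling analogue); SRP stays conservative.
The mixing model is deliberately the simplest one consistent with the
formation and downstream dilution of tributary water masses; no lateral
exchange between lanes is modelled, so lateral contrasts persist
indefinitely rather than eroding.

**Optics.** Band attenuation is linear in the constituents,
K_d(band) = k_w + s_CDOM·a_CDOM340 + s_trip·tripton, with defaults (m⁻¹;
s_CDOM in m⁻¹ per m⁻¹, s_trip in m⁻¹ per mg L⁻¹):

| band  | k_w  | s_CDOM | s_trip |
|-------|------|--------|--------|
| blue  | 0.05 | 0.045  | 0.30   |
| green | 0.04 | 0.020  | 0.28   |
| red   | 0.30 | 0.006  | 0.25   |

chosen so that clear water attenuates red fastest (pure-water absorption)
while CDOM-stained water attenuates blue fastest — the crossover that makes
the blue/red ratio informative. The config validates
s_CDOM(blue) > s_CDOM(red). The spectral curve K_d(λ) is piecewise
constant: each wavelength takes the K_d of the nearest color band, with
steps at the midpoints of the gaps between bands. Constancy within a band
means the log-linear fit recovers the band K_d exactly at zero noise; the
step structure is a simplification of a smooth attenuation spectrum and is
the main respect in which the synthetic spectra are idealised.

**Profiles.** Ed(λ, z) = Ed₀·exp(−K_d(λ)·z) on a 0.02 m depth grid and a
351–750 nm, 3 nm wavelength grid (the sampling of a profiling
spectroradiometer). The surface spectrum defaults to a flat
100 µW cm⁻² nm⁻¹; noise is multiplicative lognormal (keeps irradiance
positive) with default log-sd 0.05, a typical profiling repeatability.
Default profile depth is 4 m (a shallow fluvial-lake water column); tests
and scripts that only consume the community fields use shallower profiles
to keep array sizes small.

**Community.** ln(cyano/euk) = β₀ + β_color·ln(blue/red) + β_srp·ln(SRP) + ε
with defaults β₀ = 0.5, β_color = 1.2, β_srp = −0.4, sd(ε) = 0.15. The
signs encode the field expectation: picocyanobacteria gain where blue/green
light persists, eukaryotes where nutrient-rich stained water prevails.
With autocorrelation ρ > 0, ε propagates downstream
(ε_child = ρ·mean(ε_parents) + √(1−ρ²)·innovation), giving the
partitioning stage a genuine pure-spatial fraction to detect; ρ = 0 gives
white noise. Counts are back-transformed to cells mL⁻¹ around a lognormal
eukaryote baseline (~2×10⁴ cells mL⁻¹), split into pico/nano fractions
(0.81 of cyanobacteria are pico-sized; 0.35 of eukaryotes), and a Chl *a*
proxy weights nano cells ten-fold per cell. These splits are illustrative
plumbing, not calibrated biology.

**Seeding.** One integer seed drives a single NumPy generator; draws occur
in documented order (profile noise per station, then community residuals in
topological order, then count baselines). Same config + seed reproduces
every output byte-identically.

The `demo_config()` river — five tributaries with contrasting endmembers
(two brownwater, two turbid agricultural, one clear) on a 16-transect,
3-lane stem — is the canonical study condition used by the examples and the
acceptance script; its tributary chemistry spans the a_CDOM (1–28 m⁻¹) and
SRP (4–70 µg L⁻¹) ranges of a temperate river receiving mixed land use.

What passing tests on these rivers shows: the estimators are consistent and
unbiased *under the generator's assumptions* (log-linear attenuation,
conservative mixing, log-linear community response). They do not establish
robustness to instrument tilt, wave focusing, inelastic scattering,
non-conservative DOM processing, or community responses outside the
log-linear family.

## Bio-optics

Waveband photon flux is ∫ₐᵇ Ed(λ)·λ/(hc) dλ / N_A by the trapezoid rule on
the measured grid, with irradiance converted from µW cm⁻² nm⁻¹ to SI
first; band limits falling between grid points enter as partial bins with
Ed linearly interpolated, so the integral covers exactly [a, b]. Default
bands: PAR 400–700, blue 435–500, green 520–565, red 625–740 nm.

K_d is −slope of the OLS regression of ln(band photon flux) on depth,
fitted on the band-integrated flux (not per-wavelength and averaged).
Depths with nonpositive integrated flux are excluded and counted rather
than ε-substituted; fewer than three usable depths is an error, and a
nonnegative slope returns a result flagged invalid instead of a silent
negative K_d. The regression is unweighted and untruncated.

The 1% penetration depth uses the conventional constant 4.6 (the field's
rounding of −ln 0.01), and the photic fraction (z₁%/depth × 100) is capped
at 100 because the photic zone cannot exceed the water column. Color
ratios are defined on attenuation: blue/red = K_d(red)/K_d(blue), i.e. the
ratio of 1% penetration depths, > 1 when blue penetrates deeper. An
irradiance-ratio-at-depth definition would order waters the same way but
differ numerically; the K_d-based form is used because it is
depth-independent.

a_CDOM(340) = 2.303·(A₃₄₀ − A₆₉₀)/ℓ converts decadic absorbance to a
Napierian absorption coefficient; A₆₉₀ is the near-infrared baseline
(temperature-insensitive) and ℓ defaults to the 10 mm quartz cell.

## Riverscape metrics

Mean depth Z_m = V/A with the km³/km² ratio converted to metres;
confluence density = tributary count / channel length (the operation takes
channel length explicitly because a navigation channel can be longer than
the reach); THI = tributary discharge / receiving-zone mean depth;
cumulated watershed area is a running sum in flow order; wetland proportion
is wetland area / water area × 100. Report rounding is half-up at the
table's printed precision; raw values are retained. The bundled table
flags rows whose printed confluence density cannot be reproduced from the
printed columns (the channel length actually used in the source is not
recoverable); one wetland percentage in the source disagrees with its
inputs in the last printed digit.

## Asymmetric eigenvector maps

The incidence matrix has a row per station and a column per directed edge;
entry (i, j) is the weight of edge j if it lies on a path from an origin to
station i (union of edges over all paths for braided reaches; multiple
origins behave as children of a single super-origin whose bookkeeping edges
carry no influence and contribute no columns). The AEM eigenfunctions are
the left singular vectors of the column-centered incidence matrix with
positive singular values; columns are zero-mean, orthonormal, and ordered
from broad downstream gradients to fine structure. Signs are fixed
deterministically (largest-magnitude element positive) so outputs do not
depend on the linear-algebra backend; when that element is tied across
sites the convention is still deterministic but not permutation-invariant,
which is inherent to any elementwise rule.

Eigenfunction selection is forward selection with a permutation test and an
adjusted-R² stopping rule: candidates are scanned in singular-value order,
the best R² gain is tested against the permutation null of the current
model's residuals using the same best-of-remaining statistic (so the null
accounts for selection bias), and selection stops when p > α or adjusted R²
stops increasing. Because the basis is orthonormal and centered, R² gains
are independent of the already-selected set, which makes both the scan and
the permutation null a single matrix product. The number of retained
eigenfunctions is always an output, never a constant.

## Model selection

Box-Cox chooses λ by profile maximum likelihood on the fixed grid [−3, 3]
in steps of 0.01 (resolution 0.01 is finer than any interpretable
difference in λ). VIF screening computes VIF_j = 1/(1 − R²_j) from
definitional regressions and iteratively drops the largest while any
exceeds the threshold (default 5); perfect collinearity gives an infinite
VIF and an immediate drop, and every round is reported.

Best-subsets enumerates all C(p, k) subsets per size k (feasible to p = 20)
and returns the minimum-RSS subset of each size, ties broken
lexicographically by predictor name; the search itself applies no size
penalty. AIC then arbitrates across sizes using the profile-Gaussian form
AIC = n·ln(RSS/n) + 2(p+1) with p counting the intercept and the +1 the
estimated error variance. Additive constants cancel in the Akaike
differences Δᵢ = AIC_i − min AIC, which is the quantity treated as
meaningful; AICs from models fitted on different n are refused.

## Variation partitioning and lmg

For spatial table X₁ and environmental table X₂, the three OLS fits give
pure_spatial = R²(X₁∪X₂) − R²(X₂), pure_environmental = R²(X₁∪X₂) − R²(X₁),
shared = R²(X₁) + R²(X₂) − R²(X₁∪X₂), residual = 1 − R²(X₁∪X₂). The Venn
fractions use Ezekiel-adjusted R² by default (standard in two-table
ecological partitioning, debiasing unequal predictor counts); raw R² is a
flag away and is what the model-report tables use. Small negative adjusted
fractions are reported as-is, never clipped.

lmg shares are computed exactly via the subset reformulation: share_j =
Σ_S w(|S|)·[R²(S∪{j}) − R²(S)] over subsets S of the other predictors with
w(k) = k!(p−1−k)!/p!, identical to averaging sequential contributions over
all p! orderings but needing 2^p subset fits. Exact enumeration is limited
to p ≤ 10; beyond that the function raises and suggests sampling orderings
rather than silently approximating. Shares are fractions of total variance
and sum to the model's R².

Despatialized importance residualizes the response *and* each environmental
predictor on the spatial basis (true partial regression, per the
Frisch–Waugh logic) and applies lmg to the residualized system. Shares are
reported both as fractions of the residualized variance and rescaled to
fractions of total variance; in raw-R² mode the rescaled shares sum exactly
to the pure-environmental Venn fraction. A response spanned by the spatial
basis yields a flagged degenerate result. The community ratio is modelled
on the log scale by default (it is a ratio of counts); this is switchable.

## Pipeline

Stages run in order (simulate → optics → metrics → AEM → selection →
partitioning); any failure names its stage. Stations flagged `zone=ETZ`
(estuarine transition zone) are excluded from the spatial stages by
default: its tidal regime and marine dilution violate the directional
advection model. Outputs carry a provenance record (package version, seed,
SHA-256 config hash excluding the output directory), so reruns with the
same config are byte-identical. Longitudinal loess curves (local linear,
tricube weights; default span 0.5) are descriptive only and never feed
inference. The default permutation count is 199 in the pipeline (999 in
the standalone AEM command); selection decisions at α = 0.05 are stable at
either.

## Problem sizes

The test and acceptance runs use: 200 replicate profiles of ~100 depths for
attenuation recovery; 201-station rivers (67 transects × 3 lanes) for
community-coefficient recovery and for the 100-seed despatialized-ranking
check (99 permutations per selection); 8 seeds per ρ level for the
pure-spatial trend; brute-force oracles at p = 6 (subsets), p = 4 (lmg,
all 24 orderings) and 12-site trees (AEM). These sizes give Monte-Carlo
errors comfortably inside the tolerances being checked while keeping the
full suite in tens of seconds.

## Known limitations

* No radiative transfer: profiles are single-exponential per wavelength
  with no Raman scattering, no surface wave focusing, no solar-angle
  effects.
* No hydrodynamics: mixing is instantaneous and conservative; tides,
  momentum, and the estuarine salt wedge are out of scope (hence the ETZ
  exclusion switch).
* The lane topology carries tributary influence strictly downstream within
  a lane; real water masses spread laterally over tens of kilometres.
* Exact lmg and best-subsets are exponential in p; both guard their limits
  explicitly rather than degrading silently.
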