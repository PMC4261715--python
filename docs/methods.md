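# Methods

This note documents the model equations as implemented, the defaults and
why they were chosen, the numerical choices, what the synthetic-weather
generator does and does not emulate, and the known limitations.

## Radiation transport

**Geometry and attenuation.**  The canopy is a periodic row of porous
cuboids: width *L*, height *H*, base *S* above the soil, row distance *D*,
infinite along the row.  Leaf area is assumed homogeneously dispersed, so
transmission over a foliage path *x* is *p(x) = p₀^(x/L)* with extinction
*k = −ln p₀ / L*; *p₀* (the porosity of a vertical foliage wall seen
perpendicularly) and *L* are both field-measurable, which is the point of
this parameterisation.  *p(x)* satisfies *p(0)=1*, *p(L)=p₀* and the
semigroup property *p(x₁+x₂)=p(x₁)p(x₂)* (property-tested).

**Photon tracing.**  Photons enter the top plane of one unit cell
(periodic in the cross-row coordinate, translation-invariant along the
row; directions are full 3-D vectors).  Free paths inside foliage are
exponential with rate *k*.  On interaction a photon is absorbed with
probability *α_v = 1 − ρ_l − τ*; otherwise it scatters backward with
probability *ρ_l/(ρ_l+τ)* or forward with *τ/(ρ_l+τ)*, cosine-distributed
about the incident axis — the absorptance/transmittance are physical
inputs, the phase function is a modelling choice since only single-photon
absorptance and transmittance are specified by the underlying data.  The
soil absorbs with *α_s = 1 − ρ_s*, else reflects Lambertian.  Default
optics *ρ_l = 0.20, τ = 0.10, ρ_s = 0.18* are typical broadband values for
green foliage and dry vineyard soil; all are configurable per site.
Tracing is analog (no photon weights); a 50-bounce cap terminates the
vanishingly rare survivor by assigning it to the medium it occupies.
Fates are integer counts, so *a_v + a_s + a_escaped = 1* holds exactly and
the standard error of each fraction is the binomial
*sqrt(a(1−a)/N)* ≤ *sqrt(0.25/N)*.

**Terrain.**  The simulation runs in the vineyard-local frame: slope
normal up, rows along one axis.  The sun is rotated into this frame by an
orthonormal-basis construction (rows projected into the slope plane); at
zero inclination the code takes an exact identity branch, so a flat
"slope" is bit-for-bit the horizontal pipeline — a tested invariant, since
it guards against silent convention errors in the rotation.  The diffuse
sky is sampled cosine-weighted over the hemisphere above the slope plane.

**Irradiance per step.**  Daily global radiation is spread over 30-min
steps proportionally to extraterrestrial irradiance (normalised so the
daily total is conserved exactly), split into direct and diffuse by an
Erbs-type piecewise clearness-index correlation, and projected onto the
slope with the anisotropic HDKR model.  The correlation's coefficients are
configurable; the default Erbs quartic is clipped from below at its
clear-sky floor (0.165), which removes a shallow spurious dip of the raw
polynomial near the upper piece boundary and makes the curve monotone
non-increasing — the physically expected shape.  The HDKR beam ratio caps
cos θ_z at cos 85° to avoid sunrise blow-up.  The directional output
component (beam + circumsolar) is intercepted with the direct-beam
fractions; the isotropic + horizon-brightening + ground-reflected
component with the diffuse fractions.

**Interception tables.**  Geometry changes slowly (phenology), so
absorbed fractions are tabulated per canopy state on a
(local zenith × row-relative azimuth) grid — 0–85° × 0–90°, exploiting
mirror symmetry — with one diffuse scalar per state, and queried by
bilinear interpolation.  Canopy states are quantised (0.1 m in H and L,
0.05 in p₀) so a season builds a few dozen tables.  A bare state
(no foliage) is evaluated analytically: every photon strikes the soil
once, so the absorbed fraction is exactly *α_s*.  Tables serialise to a
documented CSV (angles in degrees, fractions, standard errors, N, seed).

**Opaque-face comparator.**  The antecedent geometric model treats the
horizontal faces of the cuboid as opaque.  It is implemented as a
deterministic entry-point average: beams over the canopy footprint are
fully intercepted (the opaque top face); gap-entering beams attenuate
along their true 3-D within-foliage path using the same porosity law.
The gap term therefore equals the Monte Carlo expectation exactly, making
the comparator an upper bound on interception by construction — which is
precisely the overestimation the Monte Carlo replacement corrects.  The
pointwise difference is the footprint term *(L/D)·E[transmission of
footprint entries]*: measured on the reference comparison day
(D 1.6 m, L 0.4 m, H 1.1 m, S 0.8 m) it stays below ~0.03 in *a_v* near
noon but reaches ~0.10 at p₀ = 0.25 and ~0.16 at p₀ = 0.5 for afternoon
positions where corner-clipping beams keep substantial transmission.  The
two models' diurnal absorbed-energy curves remain close at p₀ = 0.25
because those differences carry moderate irradiance weight, but a uniform
pointwise 0.05 agreement bound is not attainable for any comparator that
genuinely keeps the opaque-face assumption; the acceptance suite states
the strict bound and reports its honest failure rather than weakening the
comparator.

## Phenology

Canopy height, width and porosity develop piecewise-linearly in thermal
time (degree days above a base temperature, default 10 °C — standard for
grapevine — accumulated from 1 January): zero foliage before budburst,
linear growth to the site targets between the budburst and hedging
thresholds (porosity falling from 1 to its site minimum), constant
thereafter, and a linear return to bare (p₀ → 1, envelope shrinking to
zero) across the leaf-fall window.  Shrinking the envelope during
abscission keeps the state continuous in thermal time.  Default
thresholds (120 / 600 / 1600 / 1900 °C·d) produce budburst in April,
hedging in late June and leaf fall in late October under the default
climate; they are free per-site configuration, as no printed values
constrain them.

## Soil water balance

Daily, in mm of horizontal equivalent (so fluxes are commensurate with
precipitation).  State: total transpirable soil water TSW in a profile of
capacity TTSW; a cover-crop sub-reservoir of capacity
TTSW_cc = TTSW(1 m)·f_cc (cover-crop roots reach ~1 m on the area
fraction f_cc they occupy); and the depletions De ≤ TEW and
De_skin ≤ REW of the evaporation layer and its skin.

Fluxes, computed from the start-of-day state:

* **Bare-soil evaporation.**  Rain refills the skin first, then the
  evaporation layer.  While the skin holds water the reduction
  coefficient K_r is 1 (energy-limited stage); once dry,
  K_r = (TEW − De)/(TEW − REW), clipped to [0, 1].  E = K_e·f_R,s·ET₀
  with K_e = K_r — a single coefficient, because the available energy is
  already scaled by f_R,s·ET₀.  The vineyard's bare-soil share is
  E_s = E·(1 − f_cc).  Vine and cover-crop extraction from the
  evaporation layer is neglected in this bookkeeping, following standard
  dual-coefficient practice.
* **Vine transpiration.**  T₀,v = f_R,v·ET₀;
  T_a,v = k_c,v·k_s·T₀,v.  k_c,v = 0.56 is the mean measured ratio of
  actual (sap-flow) to radiation-partitioned potential transpiration
  under non-limiting water across the three reference sites (0.57, 0.68,
  0.42); k_s = min(1, FTSW/p_FTSW) with p_FTSW = 0.4.
* **Cover crop.**  ET_a,cc = f_cc·(f_g·k_s,cc·f_R,s·ET₀ + (1 − f_g)·E),
  with k_s,cc the same bilinear stress function of FTSW_cc at threshold
  0.4.  The ground-cover coefficient f_g follows a frost calendar: season
  start 7 days before the last spring frost at or below −4 °C (April/May
  frosts ignored; frost-free winters default to 1 March, flagged), end 7
  days after the first autumn frost (default 1 December); f_g is 0 for 30
  days (initial), ramps 0→1 over 50 days (development), is 1 in
  mid-season and 0 after the season end.
* **Extraction split.**  The vine's k_s is split between sub-reservoirs
  (k_s = k_s,v,cc + k_s,v,r) by a four-case rule: under overall stress
  proportionally to the cover-crop share of remaining water
  (TSW_cc/(p·TTSW)); with no stress anywhere by capacity share
  (TTSW_cc/TTSW); and when exactly one sub-reservoir is stressed, shifted
  toward the unstressed one.  The split is clipped to [0, k_s] so both
  parts stay non-negative.

**Update and closure.**  Rain and fluxes apply simultaneously: the
cover-crop reservoir receives P·f_cc and loses ET_a,cc plus its share of
vine extraction; its overflow cascades into the remaining reservoir,
which receives P·(1 − f_cc) and loses E_s plus the remaining vine
extraction; overflow beyond TTSW is lost, with no distinction between
surface runoff and deep percolation (appropriate for light-precipitation
climates with cover crops, where measured surface runoff is negligible).
If a sub-reservoir cannot supply its demand, its outgoing fluxes are
scaled to the available water — this replaces silent clipping and makes
the ledger identity TSW′ − TSW = P − ET_a − overflow hold to machine
precision every day (property-tested from arbitrary states, and verified
to < 1e-9 mm over multi-year coupled runs).  Initial state: full
reservoirs on 1 January, reflecting winter refill in the target climate;
configurable for drier spin-ups.

With f_cc = 0 and k_c,v = 1 the model degenerates exactly to the
vine + bare-soil structure of the antecedent formulation (tested).

## Reference evapotranspiration on slopes

FAO-56 Penman–Monteith, daily, with net radiation evaluated on the slope
plane: short-wave from the HDKR-transposed solar sum with reference-crop
albedo 0.23; long-wave from the standard clear-sky-emissivity expression
driven by the slope-plane relative clearness Rs/Rso (clipped to
[0.25, 1]), with terrain long-wave exchange neglected (sky-view
simplification; ≲1 % effect on potential evapotranspiration for slopes up
to ~35°).  ET₀ = ET₀s / cos β converts to the horizontal equivalent.  On
south aspects at 50° N this raises annual ET₀ by roughly a quarter to a
third between 0° and 30° inclination, and lowers it on north aspects —
the slope-sensitivity experiment (`et0_slope_aspect_matrix`, CLI
`slope-et0`) reproduces this pattern on synthetic weather; its printed
absolute values depend on the weather series used.

## Drought risk

Drought days are growing-season days (1 May–30 September, inclusive — 153
calendar days) with FTSW ≤ 0.15, the soil-moisture equivalent of a predawn
leaf water potential of about −0.6 MPa; the threshold comparison is
inclusive.  Annual counts are smoothed with plain centred 30-year running
means (shortened to full windows) and tested with the Mann–Kendall test:
S = Σ_{i<j} sgn(x_j − x_i), tie-corrected variance, continuity-corrected
normal z, tau-b.  Applied to annual counts (not the smoothed series,
whose autocorrelation would invalidate the test).  Under a stationary
synthetic climate the test's type-I error is at its nominal 5 % level
within binomial bounds over 200 replicate 40-year runs, despite the
zero-inflation of drought-day counts in wet years.

## Synthetic weather generator

Emulates a humid-temperate summer-rainfall climate: two-state Markov
precipitation occurrence (wet-day frequency 0.40, persistence 0.55) with
gamma amounts scaled to monthly normals summing 544 mm/yr (July max
60 mm, April min 35 mm); seasonal-sinusoid temperatures with AR(1) noise
(annual mean 10.8 °C, amplitude 9 °C); humidity and wind from simple
seasonal/wet-day rules; radiation as the extraterrestrial daily total
times a 0.75 clear-sky ceiling times beta-distributed transmission,
sunnier on dry days.  The transmission, humidity and wind parameters were
set so that long runs reproduce the climate normals the model targets:
~544 mm/yr precipitation with about two thirds from <10 mm days, and
April–September reference evapotranspiration near 605 mm on flat terrain.

What it does *not* emulate — and hence what passing tests do not show
about real data: multi-day synoptic spell structure beyond first-order
persistence, temperature–precipitation cross-correlation beyond the
wet-day effects, observed inter-annual variance and long-memory of
precipitation, hail/extreme events, or any climate-change signal.  It is
a stationary test climate, which is exactly what the trend-validity
check requires.  Temperature and humidity are not disaggregated
sub-daily; only radiation is, which is all the radiation module needs,
since ET₀ uses daily means.

## Site fixtures

Three bundled configurations (EF, BU, WI) encode the reference steep-slope
vineyards: TTSW 85/115/160 mm, canopy 1.00/1.10/1.35 m × 0.40 m at row
distances 2.50/1.60/1.60 m, minimum porosity 0.40/0.25/0.25,
slope/aspect 35°/8°, 27°/4°, 15°/−21°, cover fraction 0.84/0.40/0.75,
TEW 26.9/21.5/21.4 mm, REW 11.0/9.2/9.1 mm.  Two quantities are not
printed anywhere and are package choices: TTSW(1 m) defaults to
TTSW·(1.0/1.6) (uniform extractable water over the 1.6 m measured
profile), and stem height S = 0.60 m (typical vertical-shoot-positioning
trellis; the radiation comparison experiment uses 0.80 m per its stated
geometry).  Row azimuth defaults to the aspect azimuth, i.e. rows running
up- and down-slope as is usual on German steep slopes.  REW is an
independent input with the tabulated defaults; no functional REW(TEW)
relation is assumed.

## Numerical choices and degenerate inputs

* Angles are radians internally; degrees only in config files and CLI.
* p₀ = 0 is handled as the opaque limit (interaction on entry); p₀ = 1 or
  zero envelope as "no canopy".
* Sun below the local horizon yields zero-flagged interception fractions;
  dark timesteps are flagged undefined and all-dark days reuse the
  previous day's partition fractions (bare winter days resolve to
  f_R,v = 0 anyway).
* Monte Carlo standard error scales as 1/√N (tested); default N = 2·10⁴
  per table node for season runs (se ≤ 0.0035), 10⁵ for single-angle
  comparisons.
* The CSV reader uses correctly-rounded float parsing so weather
  round-trips are bit-exact.
* Default problem sizes in the test and acceptance runs (two-year coupled
  runs at 2000 photons per node, 200 × 40-year trend replicates, 10⁵
  photons per comparator position) were chosen as the smallest sizes at
  which the Monte Carlo error is far below every tolerance asserted.

## Known limitations

No longwave transport or fruit-zone radiance; no terrain horizon shading
or inter-terrace shading; no leaf angle distributions or organ-level
architecture; no within-season leaf drop in response to drought (porosity
follows thermal time only); no vapour-pressure-deficit down-regulation of
stomata (site-specific responses exist in reality and are not modelled);
no irrigation, lateral subsurface flow, or CO₂ response; single-site
engine (no gridded runs).  The drought analysis accepts any daily FTSW
series, but performs no bias correction of climate-model input.
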