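# Methods

## Model and unit system

Cells are spheres whose water volume exchanges across a membrane of fixed
area.  All quantities use the unit system conventional in cryobiology
volumetry: µm / µm² / µm³, minutes, atm, Kelvin, osmoles.  The gas constant
is 8.21×10¹³ µm³·atm/(mol·K); °C→K conversion adds 273.15.  Osmolality
(Osm/kg water) is treated as osmolarity (Osm/L) — the standard dilute-
solution approximation, also used when converting the isotonic water volume
to litres for the osmole content N = M_iso·V_iso·10⁻¹⁵.

The transport law is the classical single-parameter (hydraulic-conductivity)
model:

    dV/dt = -Lp·A·R·T·(M_ext - N·10¹⁵/V)·10⁻¹⁵ ,   Ve = N·10¹⁵/M_ext.

A and N are constant within a run: the membrane is not assumed to stretch,
and no solute permeates.  Temperature is constant within a run; the brief
cooling excursion during mixing in a real experiment appears only as a
pre-imaging dead time.  The ODE is separable; its implicit integral

    t₂-t₁ = Ve·[(V₁-V₂) + Ve·ln((V₁-Ve)/(V₂-Ve))] / (Lp·A·R·T·N)

is implemented as the exact inverse of the simulator, and the two are held
to <10⁻⁶ mutual relative error in the tests (an anti-drift safeguard: any
algebra slip in either form breaks the duality check).  Numerical
integration uses adaptive RK45 with rtol 10⁻⁹ / atol 10⁻⁶ µm³ so that
integration error sits far below that comparison tolerance.

## Boyle–van't Hoff analysis

The BVH fit regresses ABSOLUTE mean cell volumes on reciprocal osmolality
(ordinary least squares, unweighted by default).  Fitting absolute rather
than normalised volumes keeps slope and intercept independent parameters;
normalised fits couple them and bias the intercept.  Negative fitted
intercepts are reported with a flag, never clamped, so simulation studies
can detect estimator bias.  The non-osmotic fraction v_b divides the
intercept by a caller-chosen reference volume: the measured mean isotonic
volume (preferred when many cells were measured) or the fitted line's own
isotonic-osmolality volume.  Weighted variants (by cell count or inverse
squared SE) are available but off by default.

## Averaged curves and the two averaging conventions

Shrink/swell curves are built the way volumetry data are reduced in
practice: per time point, the mean of the alive cells' *diameters* is taken
first and the mean diameter is then cubed into a volume.  The volume SE
follows from the diameter SE by the delta method (πd̄²/2·se_d).

Two conventions coexist and must not be mixed:

* equilibrium statics (BVH points, v_b normalisation) use the mean of
  individual volumes;
* kinetics (averaged curves) use the volume of the mean diameter.

For a wide population these differ substantially (≈25% at diameter CV 0.22,
since E[d³] > E[d]³).  The pipeline therefore builds the per-temperature
"pseudo-cell" parameters (V_c_iso, V_b, A, N) from the volume of the mean
isotonic diameter — the same convention as the curve it analyses — while
keeping the mean of volumes as the v_b reference.  Mixing the scales biases
Lp by the ratio to the 5/3 power (A·N ∝ V^{5/3}), roughly −30% at the
default population spread.

## Equilibrium detection

`detect_equilibrium` declares a plateau at the first sample after which
every successive volume change over a `window` of samples (default 4) stays
below max(rel_tol·|V_first − V_last|, 3√2·σ̂), with rel_tol default 0.03 and
σ̂ a robust per-point noise floor estimated from median absolute second
differences (second differences annihilate locally linear trends, so a
noise-free ramp of any slope still raises a no-plateau error).  The plateau
volume V_eq averages the SECOND half of the detected plateau: the plateau
onset still carries the tail of the approach transient, and folding it into
Ve biases the log term of the pair estimator by 15–20% at near-freezing
temperatures, where the approach is slow.

## Pairwise Lp estimation

Cell volumes are converted to water volumes (−V_b) and Ve is taken either
from the measured plateau (default) or from the BVH prediction N·10¹⁵/M_ext
(`Ve_mode="bvh"`).  The dynamic region keeps samples whose distance to Ve
exceeds both eps·|V_start − Ve| (eps = 0.02) and noise_z·σ̂ (noise_z = 4):
the log term amplifies noise without bound as V → Ve, so samples
statistically indistinguishable from equilibrium carry no kinetic
information.  Six "knot" samples are placed at geometrically spaced excess
levels from 100% down to 20% of the first dynamic sample's excess, each knot
a ±2-sample local average where sampling is dense, and all C(6,2) = 15 knot
pairs are evaluated — the top of the conventional 12–15-pair range.  The
per-pair guard rejects pairs with an endpoint within 2% of Ve (log blow-up)
or straddling Ve.  The estimate is the plain mean over pair values, with the
SE across pairs reported and every pair value kept for audit.

Why the deep tail (<20% excess) is excluded: on an averaged curve the tail
is doubly unreliable.  Statistically, noise there passes through the
diverging log term.  Structurally, a population of different-sized cells has
per-cell time constants τ ∝ d, so the ensemble mean-diameter curve is a
mixture of time-scaled trajectories: every cell has the same initial
*diameter rate* regardless of size (the early curve therefore tracks a
single-cell trajectory), while the tail is dominated by the slowest, largest
cells.  Restricting pairs to the early-to-mid curve keeps the residual
heterogeneity bias at ≈ −2 to −4% at the default population spread
(diameter sd 4 µm), versus ≈ −6 to −9% when the tail is used.  This bias is
a property of curve-level analysis of a heterogeneous population, not of the
pair formula, and it largely cancels in activation energies (which depend on
Lp ratios across temperatures measured on the same population).

22 °C caveat: with an influx activation energy of 12 kcal/mol, the true
hypotonic Lp at 22 °C is ≈ 4 µm/(min·atm) and the swelling transient is
essentially over within the 25–40 s pre-imaging dead time.  Room-temperature
estimates from dead-time data are therefore unreliable or unavailable, and
they are excluded from Arrhenius fits by default (an explicit, logged flag)
— in real cells they are additionally contaminated by regulatory volume
decrease.

## Thermal analysis

E_a = −R′·slope of ln Lp on 1/T (least squares; the exact two-point formula
ln(Lp₂/Lp₁)/(1/T₁ − 1/T₂) when n = 2), reported in cal/mol with a kcal/mol
formatting helper rounded to one decimal.  Rectification is the plain ratio
Lp(hypotonic)/Lp(hypertonic) at one temperature.

## Curve-shift validation

A simulated trajectory started from the isotonic volume is overlaid on an
observed averaged curve by minimising Σ[V_obs(t) − V_sim(t − dt) − dv]².
For fixed dt the optimal dv is the mean residual, so the search is
one-dimensional: a coarse grid over the feasible dt range (default bounds
0–1.5 min, the plausible mixing dead-time scale) followed by bounded local
refinement; the dense (1-s grid) simulated curve is linearly interpolated
at the shifted observed times rather than re-simulated per candidate.  Note
that the synthetic generator models the dead time as *missing early frames
on an honest clock*, so shift fits on synthetic bundles correctly return
dt ≈ 0; injected-shift tests exercise the fitter itself.

## Synthetic data generator

The generator emulates a microscopy volumetry study:

* population: truncated-normal isotonic diameters, mean 18.5 µm, sd 4.0 µm,
  bounds 9–33 µm (sd is the one free population default; it places the
  stated bounds at roughly ±3.5 sd), non-osmotic fraction 0.29, dead-cell
  fraction 0.05;
* true membrane parameters: influx Lp 1.73 and efflux Lp 0.21 µm/(min·atm)
  at the 10 °C reference, each following its own Arrhenius law with
  E_a 12,000 / 10,700 cal/mol.  Rectification is generated as
  direction-dependent Lp; an osmolality-dependent alternative mode exists
  because equilibrium data cannot distinguish the two hypotheses, and an
  optional linear relaxation term (`rvd_rate`) can emulate regulatory volume
  decrease at room temperature;
* protocol: abrupt transfer to 157 or 602 mOsm/kg at 0/10/22 °C, a
  uniform 25–40 s dead time before the first frame, 10-s frames for 5 min
  then 30-s frames to 20 min, Gaussian noise (sd 0.3 µm) added to the
  *diameters* after the volume→diameter conversion (diameters are what a
  microscope measures);
* plus an equilibrium (BVH) series at 157/242/308/602/986 mOsm/kg and
  isotonic reference measurements per temperature, recorded under both
  averaging conventions.

Ground truth lives only in the bundle metadata, never in the data tables,
so recovery tests are blind.  Everything is reproducible from one seed via
spawned child seeds per experiment.

What the generator does NOT emulate — and hence what passing tests do not
establish about real data: optical/segmentation error structure (noise is
i.i.d. Gaussian on diameters), non-spherical or shape-changing cells,
active volume regulation (off by default), solute leakage, and the
systematic equilibrium-volume offsets seen in real measurements (available
only as an explicit `equilibrium_offset_frac` with no mechanistic claim).

## Problem sizes and reproducibility

The test suite and acceptance script use: 100 random parameter sets for the
closed-form/ODE duality check; 200 replicates for BVH intercept recovery;
100 replicates for noisy shift-fit recovery; and five replicate 50-cell
bundles for noisy Lp/E_a recovery, with per-condition Lp pooled across
replicates — replication mirrors how multiple runs per condition are pooled
in practice, and a single 50-cell bundle sits at the information floor for
the 10 °C conditions (the dead time leaves only ~8 usable 10-s frames, so a
single-bundle estimate has ≈8% intrinsic scatter with occasional larger
outliers).  All randomness is seeded; identical configurations reproduce
byte-identical outputs.

## Known limitations

* Curve-level analysis of a heterogeneous population biases Lp low by a few
  percent even with perfect data (see above); per-cell fitting would avoid
  this but is not this pipeline's method.
* The measured-plateau Ve requires the run to actually reach equilibrium
  within the recorded window; for very slow kinetics the BVH Ve mode is the
  safer choice.
* The published 22 °C surface area (1021 µm²) is not the sphere area of the
  22 °C isotonic volume (which is ≈1077 µm²); the packaged reference table
  records the published value as a constant but all computed areas use the
  sphere formula.
* The two-point estimator assumes strictly monotone approach; regulatory
  volume decrease violates this and must be handled by excluding affected
  conditions (the default 22 °C exclusion).
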