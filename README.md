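# osmovol

Osmotic single-cell volumetry analysis: Boyle–van't Hoff osmometry,
shrink/swell kinetics, hydraulic-conductivity (Lp) estimation, Arrhenius
activation energies and water-permeability rectification — plus a synthetic
volumetry data generator so the whole pipeline is testable end to end.

## Who this is for

Cryobiologists and membrane biophysicists who measure cell volumes under
osmotic challenge (microscopy volumetry, Coulter-type sizing) and need the
standard osmotic parameters of a cell type: the non-osmotic volume fraction
*v_b*, the hydraulic conductivity *Lp* in each flow direction, and the
activation energy *E_a* of water transport.  The built-in defaults describe
COS-7 fibroblasts (mean isotonic diameter 18.5 µm, isotonic osmolality
0.308 Osm/kg), but every parameter is configurable.

## The model

Cells are treated as spherical ideal osmometers.  At equilibrium the cell
volume is linear in reciprocal osmolality (Boyle–van't Hoff):

    V_c = a / M + V_b

where the intercept `V_b` is the non-osmotic volume (solids + bound water)
and `v_b = V_b / V_c,iso` its fraction of the isotonic cell volume.

Out of equilibrium, the cell water volume V (µm³) follows the classical
single-parameter transport law

    dV/dt = -Lp · A · R · T · (M_ext - N/V)

with membrane area A (µm², held constant), intracellular osmoles N,
external osmolality M_ext, and R = 8.21×10¹³ µm³·atm/(mol·K).  Because the
equation is separable it has an exact implicit solution; between two sampled
water volumes V₁ (at t₁) and V₂ (at t₂) on one monotone curve,

    Lp = Ve · [(V₁ - V₂) + Ve · ln((V₁ - Ve)/(V₂ - Ve))] / (A·R·T·N·(t₂ - t₁))

where `Ve = N/M_ext` is the equilibrium water volume.  This *integrated*
two-point form depends only on the time difference t₂ − t₁, so the mixing
dead time before the first microscope frame cannot bias it.  `osmovol`
estimates Lp by averaging this expression over 12–15 sample pairs from the
dynamic part of an averaged shrink/swell curve, exactly as done at the
bench, and checks the closed form against direct numerical integration of
the ODE (each is the other's oracle).

Temperature dependence follows the Arrhenius law: `E_a = -R'·slope` of
ln Lp against 1/T, with R' = 1.987 cal/(mol·K).  Rectification is the ratio
of the hypotonic (water influx) to hypertonic (water efflux) Lp at one
temperature.

## Worked example

```python
import osmovol as ov

# equilibrium analysis: v_b from the published COS-7 reference volumes
vb = ov.nonosmotic_fraction(963.0, 3324.0)          # -> 0.2897  (≈ 0.29)

# equilibrium swelling prediction for half-isotonic medium
ve = ov.bvh_equilibrium_water(2626.0, 0.308, 0.157, ratio_decimals=2)
print(round(ve), round(ve + 963))                    # 5147 6110  (µm³)

# activation energy of water influx from the 0 °C / 10 °C Lp pair
fit = ov.arrhenius_ea([(273.15, 0.79), (283.15, 1.73)])
print(ov.format_ea_kcal(fit.Ea))                     # 12.0 kcal/mol

# rectification at 10 °C
print(round(ov.rectification_ratio(1.73, 0.21), 1))  # 8.2

# full synthetic study -> report
cfg = ov.SyntheticStudyConfig(seed=1)
report = ov.run_report({"synthetic": cfg.to_dict()})
print(round(report.v_b_fraction, 2))                 # 0.29
print(round(report.lp_table["602mOsm_10C"].lp_mean, 2))  # 0.19 (true 0.21)
```

The numbers mean: COS-7 cells are ~29% non-osmotic by volume; a cell with
2626 µm³ of isotonic water swells to a 6110 µm³ cell in half-isotonic
medium; water influx needs ~12 kcal/mol of activation energy; and influx is
~8× more permeable than efflux at 10 °C.  The last two lines run the whole
pipeline on a generated 50-cell study and recover the generating parameters
from the noisy data.

There is also a CLI:

```bash
osmovol synth --out-dir study/ --seed 1       # write a synthetic bundle
osmovol validate study/kinetics_602mOsm_10C.csv
osmovol report --out-dir results/ --seed 1    # full analysis -> report.json
```

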