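# encapkin

Modeling toolkit for the stability and controlled release of essential-oil
emulsions stabilised by hydrocolloids (guar gum / xanthan gum) and
encapsulated by spray drying.

Formulation scientists working on encapsulated volatiles face three linked
questions: how fast does an emulsion destabilise in storage, how much oil
survives drying inside the powder, and how fast does the oil escape a solid
dosage form.  `encapkin` implements the standard modeling chain for all
three on tidy tabular data, plus a seeded synthetic-data generator so every
stage can be validated against known ground truth.

## Models

**Stability kinetics.**  Emulsion turbidity (absorbance at 600 nm) is
tracked daily; the stability index is S(t) = A_t/A_0 × 100 %.  The absolute
trajectory is fit by both a zero-order law and a first-order law,

    P(t) = P0 − k·t            (zero order, k in AU·day⁻¹)
    P(t) = P0·exp(−k·t)        (first order, k in day⁻¹)

the line by ordinary least squares, the exponential by nonlinear least
squares on the original scale (log-linear initialised).  A rate-peak
detector classifies the temperature profile of the fitted rates
(peaked / monotone / flat), flagging non-Arrhenius behaviour.

**Release and effective diffusivity.**  A powder-loaded disc monolith is
weighed every 30 min; after plateau trimming and normalisation to the
remaining oil fraction, two independent routes give an effective
diffusivity for oil transport through the matrix:

* *kinetic route*: fit M(t) = M0·exp(−k·t), then D = k·L²/π²;
* *Fickian route*: fit the one-term slab eigenfunction
  f(t) = A·exp(−D·π²·t/L²) for D over its long-time validity window
  τ = Dπ²t/L² ≥ ln(4/π), with A either 4/π (surface-concentration
  convention) or 8/π² (leading mass-average coefficient).

The characteristic length L is always an explicit argument — the numeric
value of D depends strongly on the geometric convention, so the package
refuses to guess one.  The synthetic generator evaluates the *untruncated*
slab solution to machine precision (eigenfunction series at long times,
image/erfc form at short times).

**Powder metrics and correlations.**  Process yield, linear 260 nm
calibration, encapsulation efficiency, and the Pearson correlation matrix
of the per-sample parameter table (activity, rates, both diffusivities,
EE) with an explicit, recorded temperature-aggregation mode.

## Worked example

```python
import encapkin as ek
from encapkin import studydata

# pure-xanthan sample stored at 5 degC: activity 233 AU,
# daily stability 72 / 48 / 36 %
traj = ek.reconstruct_trajectory(233, [72, 48, 36])
z = ek.fit_zero_order(traj)
f = ek.fit_first_order(traj)
print(f"zero order:  P0={z.intercept:.1f} AU  slope={z.signed_rate:.1f}/day  R2={z.r_squared:.3f}")
print(f"first order: P0={f.intercept:.1f} AU  k={f.rate:.3f}/day  R2={f.r_squared:.3f}")

# kinetic-route diffusivity from a released-rate constant of 6.69e-4 min^-1
d = ek.k_to_diffusivity(6.69e-4 / 60, L=0.020)
print(f"D_k = {d:.2e} m^2/s")

# one-term slab model: remaining fraction after 150 min at D_eff = 2.4e-10
print(f"remaining = {ek.truncated_remaining_fraction(2.4e-10, 0.005, 9000):.3f}")

# agreement between the two diffusivity routes across the six formulations
rf = studydata.release_fits_table()
print(f"r(D_k, D_eff) = {ek.pearson_r(rf.d_k_1e10, rf.d_eff_1e10):.3f}")
```

prints

```
zero order:  P0=224.6 AU  slope=-50.3/day  R2=0.972
first order: P0=233.7 AU  k=0.350/day  R2=0.998
D_k = 4.52e-10 m^2/s
remaining = 0.543
r(D_k, D_eff) = 0.995
```

The zero-order fit says this emulsion loses ≈ 50 AU of turbidity per day
from a starting level of ≈ 225 AU; the first-order view gives a 35 %/day
fractional loss.  The slab relation turns a per-minute release constant
into an effective diffusivity of a few 10⁻¹⁰ m²/s, and the two routes rank
the six formulations almost identically (r = 0.995).

A command-line interface drives the same chain on CSV files:

```bash
encapkin simulate --seed 7 --model first_order --dt 1 --p0 200 --k 0.3 \
    --noise-sd 5 --n-replicates 10 --out sim.csv
encapkin run-all --config run.yaml --seed 1 --aggregation mean --out results/
```

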