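# golgiflux

Self-organizing vesicular flux in a maturing Golgi stack.

The Golgi apparatus consists of 6–8 non-identical cisternae that mature
continuously — a new cisterna forms at the *cis* face every period while
the *trans*-most one dissolves — yet each position in the stack keeps a
distinct composition of glycosylation enzymes and SNARE fusion proteins.
`golgiflux` implements a deterministic kinetic model showing how this
steady inhomogeneity can self-organize from two ingredients and no
built-in asymmetry:

* **Loss-seeded retrograde flux.**  Vesicle–cisterna fusion is
  proportional to the cognate v-SNARE × t-SNARE concentration product
  (summed over the pairs present).  Any first-order loss of active
  SNAREs makes older cisternae poorer fusion targets, so vesicles
  preferentially fuse retrograde; the flux transports the SNAREs
  themselves and self-enhances the gradient until cisternal progression
  balances it.
* **Competitive vesicle loading.**  All cargo (SNAREs and enzymes)
  competes by mass action for a fixed concentration of vesicular binding
  sites, `v_j = n (C_j/K_j)/(1 + Σ_m C_m/K_m)`.  Strong binders
  monopolize vesicles leaving young cisternae and recycle through the
  ER; weak binders only board vesicles once the strong ones are
  depleted, and peak progressively later in the stack.

The package is aimed at modellers of organelle identity and membrane
traffic: it provides the full hybrid dynamics (continuous explicit-Euler
kinetics between discrete cisternal-shift events), an analytic solver
for the asymptotic steady-state gradient exponent — the interior profile
decays as `a^i` with `ln a = −κT − (ωnT/K)(1−a)²/(1+a+a²)` — preset
scenarios for the canonical setups (single SNARE pair, enzyme
competition with open/closed ER boundary, the full two-pair mammalian
Golgi, unrestricted non-stacked fusion, and a long stack for asymptotic
analysis), plus a CLI, TOML configs and tidy CSV/JSON output.

## Worked example

```python
from golgiflux import GolgiModel

model = GolgiModel.from_scenario("full_mammalian")   # two SNARE pairs + 3 enzymes
result = model.run()
print(result.summary())
```

```
scenario: full_mammalian   converged: True (231 periods, residual 8.48e-09)
species    argmax       peak      total  er_frac  monotonicity
er_v            1     0.1397     0.1811   1.0000  decreasing
alpha_t         1     0.4966     0.6706   1.0000  decreasing
alpha_v         1     0.4966     0.6706   1.0000  decreasing
beta_t          1     0.9695     1.9024   0.7617  decreasing
beta_v          7     1.9529    10.8639   0.2478  unimodal
enz_cis         2     1.5513     5.2990   0.9986  unimodal
enz_med         5     3.1824    16.7521   0.7065  unimodal
enz_trans       7     1.9529    10.8639   0.2478  unimodal
```

Reading the table: the stack converged to a periodic steady state after
231 maturation periods.  The alpha t-SNARE falls steeply from the cis
face (peak in cisterna 1) while its beta counterpart decays more
shallowly, and the beta v-SNARE runs *counter-current*, rising to a peak
in the penultimate cisterna — the experimentally observed pattern.  The
three enzyme classes peak in order of their binding strength (cisternae
2, 5, 7), and the ER-recycled fraction falls from ~1.0 for the ER
v-SNARE and alpha SNAREs through 0.70 for the medial enzyme to 0.25 for
the trans enzyme: vesicles from young cisternae recycle through the ER,
vesicles from old cisternae hardly reach it.

The same run from the shell, plus the analytic gradient exponent:

```sh
golgiflux run --scenario full_mammalian --out out/   # profiles.csv, report.json
golgiflux analyze-exponent --decay 0.1 --transport 1.0
# a = 0.9016167636
```

A 30-cisterna `long_stack` simulation fitted over interior cisternae
5–25 reproduces that root to within 0.01%.

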