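# psicascade

Kinetic modelling and process evaluation of the one-pot, two-enzyme
rearrangement of UMP into pseudouridine 5′-phosphate (ΨMP) — a route to the
core building block of N1-methylpseudouridine-containing mRNA therapeutics.

A nucleotide nucleosidase (PpnN, EC 3.2.2.10, or its R341A-Y347A variant
"RY") cleaves UMP into uracil and ribose 5-phosphate (Rib5P); the
C-glycosidase YeiN (EC 4.2.1.70), run in the condensation direction, joins
them back into the C-riboside ΨMP. Rib5P is a competitive product inhibitor
of the nucleosidase,

    v = Vmax·[UMP] / (Km·(1 + [Rib5P]/Ki) + [UMP]),   Vmax = kcat·[E],

so the cascade is engineered around *kinetic pull*: YeiN in mass excess
removes Rib5P as fast as it is released. The package provides, for anyone
analysing or designing such product-inhibited cascades:

* **units** — enzyme descriptors, subunit molarity, specific-activity ↔ kcat
  conversion, Beer–Lambert quantification, a versioned constants table;
* **ratelaws** — the competitive rate law, its closed-form integrated
  progress curve, stiff ODE simulation of hydrolysis and of the coupled
  cascade, and an enzyme-ratio sweep at constant total protein;
* **estimation** — Michaelis–Menten and global competitive-inhibition fits
  of initial-rate grids, per-inhibitor-level apparent-Km analysis, Ki
  estimation from progress curves, asymptotic and bootstrap uncertainty;
* **metrics** — yield, space-time yield, mass-based TON, E-factor, scale-up
  volume, and a route-comparison table with consistency checking;
* **synth** — synthetic initial-rate grids and time courses at the
  characterized parameter presets with a seeded multiplicative noise model;
* a `psicascade` CLI (`generate`, `fit`, `simulate`, `metrics`,
  `route-table`) over the library.

## Worked example

```python
import numpy as np
from psicascade import (get_preset, gen_initial_rates, simulate_hydrolysis,
                        fit_competitive_inhibition_global)

# global competitive fit of a noiseless synthetic substrate x inhibitor grid
data = gen_initial_rates("RY")          # S in {2..80} mM, Rib5P in {0,2,10} mM
fit = fit_competitive_inhibition_global(data)
print(fit.summary())

# simulate 100 mM UMP hydrolysis by RY at 2.0 mg/mL
ry = get_preset("RY")
curve = simulate_hydrolysis(ry.enzyme, ry.params, 100.0, np.linspace(0, 120, 121))
print(f"conversion at 120 min: {100 * curve.conversion()[-1]:.1f}%")
```

prints

```
converged = True   n = 18   residual_norm = 1.08281e-14 mM/min
kcat = 13.4 1/s (se 1.7e-15)
Km   = 15.5 mM  (se 5.7e-15)
Ki   = 1.2 mM  (se 4.4e-16)
Km/Ki = 12.92
kcat/Km = 0.8645 1/(s mM)
conversion at 120 min: 97.7%
```

i.e. the fit recovers the generating constants exactly (kcat 13.4 s⁻¹,
Km 15.5 mM, Ki 1.2 mM, so Km/Ki ≈ 13 — product inhibition is strong), and
the simulated reaction passes 92% conversion well inside 120 min. The
analogous wild-type preset (kcat 2.6, Km 1.1, Ki 0.1) is 12-fold more
inhibited and visibly slower at the same protein loading, which is why the
RY variant is the enzyme of choice for the cascade.

```python
from psicascade import default_cascade_config, simulate_cascade
cfg = default_cascade_config(ump0=100.0, ry_load=0.5, yein_load=1.0, t_end=240.0)
print(f"final product: {simulate_cascade(cfg).psimp[-1]:.1f} mM")   # 100.0 mM
```

With YeiN in twofold mass excess the cascade converts essentially all of the
substrate into product (≥95% yield); the ratio sweep
(`enzyme_ratio_sweep`) shows a plateau for YeiN:RY ≥ 1 and a sharp drop when
YeiN is sub-stoichiometric in mass.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline numbers of the analysis end-to-end — catalytic
efficiencies from noiseless generate→fit round trips, Km/Ki ratios from
global competitive fits, the Ki fold-difference from progress-curve
refitting, the 120-min hydrolysis conversion, and the final cascade yield —
and writes them as JSON. Everything is regenerated at run time from the
parameter presets; nothing is read from disk.

See `docs/methods.md` for the model assumptions, numerical choices,
the synthetic-data noise model, and documented discrepancies.
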