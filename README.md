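# mibikinetics

Compartmental kinetics of tumor-imaging radiotracers such as
⁹⁹ᵐTc-MIBI (sestamibi), for researchers in nuclear-medicine modelling who
need to simulate time-activity curves, compute washout diagnostics, and
recover transport rates from sparse scintigraphy measurements.

## The model

After a bolus intravenous injection the tracer occupies three first-order
compartments — blood `z(t)`, tumor cells `x(t)` and normal (background)
cells `y(t)`:

```
dx/dt = β_zx z − (β_xz + λ) x
dy/dt = β_zy z − (β_yz + λ) y
dz/dt = β_xz x + β_yz y − (β_zx + β_zy + E + λ) z
```

with initial condition `x(0) = y(0) = 0`, `z(0) = n₀`.  Here `β_zx`, `β_zy`
are the capture rates of tumor and normal cells, `β_xz`, `β_yz` the return
(washout) rates back into blood, `E` the first-order elimination constant
acting on the blood pool, and `λ = ln2 / T½` the radioactive decay constant
(`T½ = 6 h` for the ⁹⁹ᵐTc label).  Summing the equations gives
`d(x+y+z)/dt = −λ(x+y+z) − Ez`, so without elimination the total activity
follows the decay envelope `n₀e^{−λt}` exactly.

The system is linear and is solved in closed form by eigendecomposition of
the 3×3 rate matrix (`simulate_closed_form`), with a fixed-step RK4
integrator (`simulate_numeric`) as an independent numerical oracle.

On top of the solver the package computes the clinical washout rate
coefficient

```
K_WOR = 1 − (A₂ − F₂) / (A₁ − F₁)
```

from tumor (`A`) and normal-tissue (`F`) concentrations at an early and a
late scan time, classifies P-glycoprotein (PGP) expression by the standard
0.45 threshold (`K_WOR < 0.45` → low PGP, otherwise high), computes
clearance (injected activity over area under the curve), segments
time-activity curves into vascular/secretory/excretory phases, subtracts
tissue background, and fits transport rates to noisy concentration
measurements by seeded multi-start bounded least squares.

## Worked example

Compute the washout coefficient of the two published reference scenarios,
which differ only in the elimination constant (`fig6a`: E = 0.1 h⁻¹,
`fig6b`: E = 1 h⁻¹):

```
$ mibikinetics kwor --scenario fig6b --stop 8
{
  "a1": 0.20017381926170605,
  "a2": 0.1571978018169415,
  "classification": "low_pgp",
  "f1": 0.05326217505199006,
  "f2": 0.025213870170279647,
  "k_wor": 0.10161013882429115,
  "t1_h": 2.29,
  "t2_h": 4.0,
  "threshold": 0.45
}
```

The early time `t1` is placed automatically at the maximum of the
tumor-minus-normal contrast (2.29 h here), the late time at 4 h; the
contrast dropped from 0.147 to 0.132, i.e. `K_WOR ≈ 0.102`, below the 0.45
threshold, hence the low-PGP call.  The same protocol on the
weak-elimination scenario gives `K_WOR ≈ 0.0034` — tenfold stronger
elimination washes out roughly thirty times more contrast.

Blood-pool clearance of the weak-elimination scenario over a 24 h study:

```
$ mibikinetics clearance --scenario fig6a --stop 24
0.5426199106
```

i.e. an effective blood elimination rate of 0.54 h⁻¹ — dominated by cellular
capture and decay rather than by E itself.

The same computations are available as library calls:

```python
import numpy as np
from mibikinetics import get_scenario, simulate_closed_form, k_wor_from_trajectory

grid = np.arange(0, 8.01, 0.01)
traj = simulate_closed_form(get_scenario("fig6b").params, grid)
result = k_wor_from_trajectory(traj, t2=4.0)
print(result.k_wor, result.classification.value)   # 0.10161013882429115 low_pgp
```

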