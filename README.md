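# fibrilkit

Kinetic analysis of amyloid fibril formation and its modulation by
molecular chaperones — for biophysicists dissecting *which* microscopic
step of aggregation an inhibitor acts on, not just *whether* it slows
aggregation down.

Amyloid-β (Aβ42) fibril formation proceeds through three microscopic
processes: primary nucleation from monomers (rate constant k_n, order n_c),
elongation of fibril ends (k₊), and secondary nucleation of new aggregates
on existing fibril surfaces (k₂, order n₂). The package implements the
standard moment equations for the fibril number concentration P and fibril
mass concentration M,

```
dP/dt = k_n m^n_c + k₂ M m^n₂
dM/dt = 2 k₊ m P,        m = m₀ + M₀ − M
```

together with the integrated closed-form rate law for the unseeded
reaction, written in terms of the combined rates λ = √(2k₊k_n·m₀^n_c) and
κ = √(2k₊k₂·m₀^(n₂+1)):

```
M(t)/M(∞) = 1 − [ (B₊+C₊)(B₋+C₊e^{κt}) / ((B₊+C₊e^{κt})(B₋+C₊)) ]^{k∞²/(κ·k̃∞)} · e^{−k∞t}
C± = ±λ²/2κ²,  k∞ = √(2κ²/(n₂(n₂+1)) + 2λ²/n_c),
k̃∞ = √(k∞² − 4C₊C₋κ²),  B± = (k∞ ± k̃∞)/2κ
```

On top of the forward model the package provides, as statsmodels-style
Model/Results pairs:

- **ThT trace analysis** (`fibrilkit.tht`): normalization and replicate
  averaging, sigmoidal descriptors F = F₀ + A/(1 + exp[r_max(τ₁/₂ − t)]),
  dose-response summaries (τ₁/₂ linear in inhibitor ratio, r_max
  mono-exponential), and **global fitting** of a whole dose series with a
  *single* free microscopic rate constant (k_n, k₂ or k₊) per condition —
  the χ² of the competing single-constant fits identifies the inhibited
  step (`GlobalRateLawModel`).
- **Nucleation-unit (toxic oligomer) flux** (`fibrilkit.kinetics`): the
  nucleation rate r_n(t) = k_n·m^n_c + k₂·M·m^n₂ integrated over the
  reaction, and fold changes between conditions. Blocking elongation
  *increases* the total number of oligomers generated; suppressing
  secondary nucleation decreases it.
- **Seeded elongation analysis** (`fibrilkit.seeding`): initial slopes of
  highly seeded (20% monomer-equivalent) traces, which are directly
  proportional to k₊, and relative elongation rates across a dose series.
- **SPR binding kinetics** (`fibrilkit.spr`): global biexponential
  dissociation (shared k_d1, k_d2, fast fraction x), per-concentration
  monoexponential association, k_obs = c·k_a + k_d regression, kinetic
  K_D = k_d2/k_a and steady-state (Langmuir) K_D.
- **pH titrations** (`fibrilkit.titration`): single-site
  Henderson–Hasselbalch fits with bootstrap confidence intervals for the
  apparent pKa of chaperone conformational transitions.
- **Synthetic data** (`fibrilkit.simulate`): seeded generators for every
  assay class (unseeded/seeded ThT, sensorgrams, titrations, amorphous
  turbidity) at the study conditions — 3 μmol/L Aβ42, inhibitor molar
  ratios 0–100%, 0.6 μmol/L seeds, 6.25–100 μmol/L SPR analyte series.

## Worked example

Simulate a dose series in which a chaperone suppresses only secondary
nucleation, then ask the global fit which microscopic constant explains it:

```python
from fibrilkit import (ThTDatasetSpec, simulate_tht_dataset, wildtype_like_effect,
                       normalize_and_average, fit_sigmoid, GlobalRateLawModel)

spec = ThTDatasetSpec(seed=42, effect=wildtype_like_effect(),
                      ratios=(0.0, 30.0, 70.0), replicates=3)
traces = simulate_tht_dataset(spec)

by = {}
for tr in traces:
    by.setdefault(tr.condition.ratio_percent, []).append(tr)
avg = [normalize_and_average(v) for _, v in sorted(by.items())]

print(fit_sigmoid(avg[0]).summary())
print(GlobalRateLawModel(avg, free_parameter="k_2", normalize=False).fit().summary())
```

```
Sigmoidal transition fit
  F0 (base value)      : -0.0363074
  A (amplitude)        : 1.03453
  r_max (growth rate)  : 0.000437463 s^-1  (1.575 h^-1)
  tau_1/2 (half time)  : 10967.6 s  (3.047 h)
  SSE (401 points)   : 0.0622374

Global rate-law fit  (free parameter: k_2)
  traces: 3   chi2: 0.000133268
  baseline (0%): k_n=2.793e-05, k_plus=3e+06, k_2=2074 (m0=3e-06 M)
  ratio   30.0%: k_2 = 1276.61   (x0.6154 of baseline)
  ratio   70.0%: k_2 = 681.553   (x0.3285 of baseline)
```

The uninhibited reaction half-completes at 3.0 h; the k₂-free global fit
recovers the simulated suppression (truth at 30% and 70% ratio:
exp(−ratio/60) = 0.61 and 0.31) and achieves a lower χ² than the same fit
with k_n or k₊ free — correctly attributing the mechanism. The same
workflow is available from the shell:

```
fibrilkit simulate --assay tht --seed 42 --out sim
fibrilkit global-fit sim/plate.csv sim/conditions.yaml --all-parameters --out fit
```

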