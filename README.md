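# minwave

Simulation and analysis of Min-protein pole-to-pole oscillation in
*Escherichia coli*.

The MinD and MinE proteins oscillate between the poles of a rod-shaped
bacterium, leaving a time-averaged MinD concentration minimum at midcell
that licenses division there. `minwave` is a complete, tested pipeline
around a one-dimensional five-species reaction-diffusion model of this
system, for modelers who want to screen kinetic rate constants against
oscillation phenotypes and for microscopists who want the matching
intensity-profile analysis:

- **`model_core`** — the reaction network: cytosolic MinD-ADP/MinD-ATP,
  cytosolic MinE, membrane MinD, and the membrane MinDE complex, with
  mass-action kinetics (attachment `k_D`, cooperative recruitment
  `k_dD`, MinE recruitment `k_dE`, hydrolysis-driven dissociation
  `k_de`, nucleotide exchange `k_ADP→ATP`) and the homogeneous steady
  state;
- **`simulator`** — explicit finite-difference integration on a 0.2-µm
  grid with no-flux boundaries (numba-compiled inner loop), producing
  kymographs of the membrane-bound MinD signal;
- **`linstab`** — linear stability of the uniform state via the 5×5
  Jacobian `A_q = A − D q²` at wavenumber `q = π/L`;
- **`metrics`** — oscillation period, gradient steepness λ_N from the
  fit `I(x) = a·e^(−λ_N x) + c`, midcell-to-pole ratio
  `I_Ratio = I_min/I_max`, pattern classification, and the biphasic
  λ_N-versus-length fit;
- **`screening`** — random log-normal parameter search through the
  four-filter funnel (linear instability → spatiotemporal pattern →
  period/pattern thresholds → λ_N range);
- **`profile_analysis`** — the measured-intensity algorithms:
  photobleaching normalization, biexponential snapshot correction,
  midcell center fraction, and a robust two-sided exponential I_Ratio
  estimator;
- **`synthetic_data`** — seeded generators of kymographs, profile
  series, and snapshot series with machine-readable ground truth.

See `docs/methods.md` for the model, numerics, and design choices.

## Worked example

Simulate the reference kinetic parameter set (the screen survivor that
matches experimental oscillation features) in a 3.0-µm cell and extract
its oscillation descriptors:

```python
from minwave import (
    REFERENCE_PARAMS, REFERENCE_DIFFUSION, SimulationConfig, simulate,
)
from minwave.metrics import analyze, pole_profile_symmetry

kymo = simulate(REFERENCE_PARAMS, REFERENCE_DIFFUSION, SimulationConfig(length=3.0))
m = analyze(kymo, (40, 140))
print(f"period_s={m.period:.3f} lambda_N={m.lambda_N:.3f} "
      f"i_ratio={m.i_ratio:.3f} class={m.pattern_class}")
print(f"symmetry={pole_profile_symmetry(kymo, (40, 140)):.5f}%")
```

output:

```
period_s=17.406 lambda_N=2.010 i_ratio=0.493 class=pole_to_pole
symmetry=0.00334%
```

Read: the cell oscillates pole-to-pole every ~17.4 s; the time-averaged
membrane MinD gradient decays with steepness λ_N ≈ 2.0 on the
normalized cell length; midcell retains ~49% of the pole intensity (the
MinC-derepressed zone is forming but not yet deep); and the left- and
right-pole profiles are mirror images to within 0.003%, i.e. the
oscillation is fully symmetric after the 40-s burn-in.

A command-line interface wraps the same functions:

```sh
minwave simulate --length 3.0 --out kymo.tsv
minwave metrics --traj kymo.tsv --out metrics.csv
minwave screen --n 100 --seed 1 --dt 6.25e-4 --t-end 100 --out screen.csv
minwave synth profiles --seed 7 --out synth/
minwave profiles --in synth/profiles.csv --out profile_metrics.csv
```

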