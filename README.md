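# hydronmr

Quantitative analysis toolkit for gaseous-phase hydration studies of
desiccation-tolerant organisms (lichens and similar systems), combining:

- **Sorption kinetics** — one/two-component exponential hydration courses and
  mono-exponential dehydration, with model-order selection (AICc);
- **Sorption isotherms** — GAB (Dent) and BET multilayer models, fitted either
  directly or through the classical parabolic linearisation
  `h/(Δm/m₀) = A + Bh − Ch²` with exact analytic inversion;
- **¹H-NMR relaxometry** — free-induction-decay decomposition into a Gaussian
  solid component plus one or two exponential liquid components (optional
  Abragam beat variant, receiver dead-time exclusion);
- **¹H-NMR spectroscopy** — deconvolution into one Gaussian and one or two
  Lorentzian lines with tabulated mobile/solid area ratios;
- **Water-soluble solid fraction** — the rational L/S dissolution law and the
  L1/L pool-partition law, fitted jointly, plus rational-to-linear changepoint
  detection in the L/S hydration dependence;
- **Synthetic data** — seeded forward simulators for all five observables with
  per-species parameter presets for *Niebla tigrina* and
  *Umbilicaria antarctica*, so every estimator is testable round-trip.

## Layout

| module | role |
| --- | --- |
| `hydronmr.core_models` | pure model equations and parameter bundles |
| `hydronmr.estimation`  | least-squares fitting, model selection, uncertainties, changepoints |
| `hydronmr.synthetic_data` | simulators, noise spec, species presets |
| `hydronmr.pipeline_io` | CSV/YAML/JSON formats, batch pipeline, CLI |

## Library quick start

```python
import numpy as np
from hydronmr import core_models as cm, estimation as est, synthetic_data as sd

preset = sd.get_preset("N. tigrina")
course = sd.simulate_hydration_course(
    preset.kinetics_params(), np.arange(0, 100.0001, 0.1),
    sd.NoiseSpec(sigma=0.002, seed=1),
)
fit = est.fit_kinetics(course, order="auto")
print(fit.summary())          # e.g. {'t1': '0.51(2)', 't2': '15.0(8)', ...}
print(cm.total_hydration(fit.params))
```

## Command line

```bash
# write a synthetic CSV bundle + config for one species
hydronmr simulate --species "U. antarctica" --out-dir sim/

# run the whole pipeline on it
hydronmr run-all sim/config.yaml --output report.json

# or fit individual files
hydronmr fit-kinetics sim/hydration_course.csv --order 2
hydronmr fit-isotherm sim/isotherm.csv --method parabolic
hydronmr fit-fid sim/fid.csv --order auto
hydronmr fit-spectrum sim/spectrum.csv
hydronmr fit-solute sim/solute_ratios.csv --gamma 0.5
```

CSV column conventions: `time_h,dm_over_m0` (courses); `p_over_p0,c_h`
(isotherms, humidity as a fraction unless `--humidity-unit percent`);
`time_us,amplitude` (FID); `freq_hz,amplitude` (spectra);
`dm_over_m0,l_over_s,l1_over_l` (ratio data).

## A note on the combined solute fit

From `(L/S, L1/L)` data alone the solute proton-density ratio γ and the
saturation concentration `cs` are only jointly identifiable through
`γ·cs/(1−cs)`; `δ`, `k` and `m1` are individually identified. The
`gamma_mode="free"` fit therefore reports very wide, flagged uncertainties
for γ and `cs`, while `gamma_mode="fixed"` (at a known or literature
proton-density ratio such as `constants.GAMMA_MIXED`) makes `cs` itself
recoverable. This is documented in `estimation.fit_solute_combined`.
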