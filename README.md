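# vasoionics

Analysis toolkit for ion-channel biophysics and vascular myography:

- **`coupled_markov`** — partially coupled binary Markov model of
  multi-channel gating over the aggregate open count, with three parameters
  (coupling coefficient `kappa`, open-to-open `rho`, closed-to-closed
  `sigma_c`): matrix construction `T = (1-kappa)*T_unc + kappa*T_cpl`,
  stationary analysis, seeded simulation, exact log-likelihood, and
  maximum-likelihood fitting by multi-start gradient ascent.
- **`idealization`** — half-amplitude idealization of cell-attached
  single-channel sweeps (unitary threshold 0.5 x amplitude), dwell
  segmentation with a minimum-dwell merge, and activity statistics: nPo,
  channel count n (max simultaneous level), Po = nPo/n, ensemble average,
  and coupled-opening frequency/strength (level jumps >= 2).
- **`ephys`** — whole-cell K⁺ step families to current-density I–V curves
  (pA/pF), digital IBTx subtraction into I_BK and I_Kv (additivity exact),
  and gap-free Vm metrics (stable-window resting Vm, drug-induced ΔVm).
- **`myography`** — percent myogenic tone
  `100 * (D_passive - D_active)/D_passive`, KCl viability (default 30%
  threshold), and tone–pressure curves with stability flags.
- **`quantification`** — PLA puncta density (puncta/µm²), qPCR relative
  expression (2^-ΔΔCt, GAPDH reference), densitometry normalization.
- **`synthetic_data`** — seeded generators for all six modalities with
  programmed ground truth (Markov-gated sweeps with Gaussian noise,
  Boltzmann-activated K⁺ conductances with removable BK component,
  OU/white-noise Vm traces with drug steps, bell-shaped tone profiles,
  Poisson puncta, Ct tables).
- **`stats`** — Shapiro-gated two-group comparison (t vs Mann–Whitney),
  one-way/two-way ANOVA and Kruskal–Wallis with Bonferroni/Tukey/Dunn
  posthoc tests.

## CLI

```sh
vasoionics simulate --modality single_channel --seed 1 --out out/sim
vasoionics idealize --in out/sim/sweeps.csv --out out/ideal
vasoionics fit-markov --in levels.csv --n-channels 2 --out fit.json
vasoionics iv --control control.csv --ibtx ibtx.csv --cm 10 --out out/iv
vasoionics vm --in vm.csv --onset 30 --out vm.json
vasoionics tone --in myo_timeseries.csv --out out/tone
vasoionics quant --qpcr qpcr.csv --calibrator FA --out out/quant
vasoionics stats --in values.csv --design two_group --out stats.json
vasoionics report --seed 1 --out out/report
```

Inputs are plain CSV (tidy trace tables, Ct tables, diameter time series);
outputs are CSV/JSON. `vasoionics report` runs a deterministic end-to-end
synthetic pipeline.

## Example

```python
import vasoionics as vi
from vasoionics.synthetic_data import gen_single_channel, params_for_p_inf

params = params_for_p_inf(n_channels=2, p_inf=0.40)   # rho=0.9 held fixed
sweeps = gen_single_channel(params, sweeps=50, noise_sd_pa=0.1, seed=1)
stats = vi.activity_stats(vi.idealize_sweeps(sweeps), sweeps.unitary_current)
print(stats.nPo, stats.n_channels, stats.Po)

fit = vi.fit_params(vi.simulate_chain(params, 100_000, seed=1), n_channels=2)
print(fit.params.kappa, fit.params.rho, fit.params.sigma_c)
```
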