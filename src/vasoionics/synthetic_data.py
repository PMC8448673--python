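"""Seeded synthetic-data generators for every analysis modality.

Each generator emits the same objects the analyzers consume, with ground
truth known by construction, so every generator/analyzer pair forms a
round trip: exact at zero noise, within stated tolerance otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .coupled_markov import CoupledMarkovParams, simulate_sweeps
from .ephys import StepRecording, VmTrace
from .idealization import SweepSet
from .myography import DiameterDataset

__all__ = [
    "gen_single_channel",
    "gen_wholecell",
    "wholecell_steady_current",
    "gen_vm",
    "gen_myography",
    "gen_puncta",
    "gen_qpcr",
    "params_for_p_inf",
]

# Boltzmann activation defaults for the two conductances; only the +80 mV
# densities are contractually exact.
BK_V_HALF, BK_SLOPE = 20.0, 18.0
KV_V_HALF, KV_SLOPE = 0.0, 15.0
E_K_DEFAULT = -84.0  # mV, from 6/140 mM K+ at room temperature


def params_for_p_inf(
    n_channels: int,
    p_inf: float,
    rho: float = 0.9,
    kappa: float = 0.0,
    unitary_current: float = 1.0,
    dt: float = 1e-4,
) -> CoupledMarkovParams:
    """Parameters with a prescribed single-channel stationary open probability.

    Holds ``rho`` fixed and solves for sigma_c from
    p_inf = (1 - sigma_c) / ((1 - sigma_c) + (1 - rho)).
    """
    if not 0.0 < p_inf < 1.0:
        raise ValueError("p_inf must lie in (0, 1)")
    sigma_c = 1.0 - p_inf / (1.0 - p_inf) * (1.0 - rho)
    if not 0.0 < sigma_c < 1.0:
        raise ValueError("no valid sigma_c for this (p_inf, rho) pair")
    return CoupledMarkovParams(n_channels, kappa, rho, sigma_c, unitary_current, dt)


def gen_single_channel(
    params: CoupledMarkovParams,
    sweeps: int = 50,
    duration_s: float = 2.0,
    fs: float = 10_000.0,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    lowpass_hz: float | None = None,
    initial_level: int | None = 0,
) -> SweepSet:
    """Simulated cell-attached sweep set: levels x unitary + Gaussian noise.

    Mirrors the standard pulse protocol (2 s step, 10 kHz, ~50 sweeps).
    The simulated level paths are kept on the returned set as
    ``true_levels`` for round-trip testing.  An optional zero-phase 2 kHz
    Butterworth low-pass emulates the analog filter.
    """
    n_steps = int(round(duration_s * fs))
    levels = simulate_sweeps(params, sweeps, n_steps, seed, initial_level=initial_level)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    current = levels.astype(float) * params.unitary_current
    if noise_sd_pa > 0:
        current = current + rng.normal(0.0, noise_sd_pa, size=current.shape)
    if lowpass_hz is not None:
        sos = butter(4, lowpass_hz, fs=fs, output="sos")
        current = sosfiltfilt(sos, current, axis=1)
    return SweepSet(
        current,
        fs=fs,
        unitary_current=params.unitary_current,
        step_s=duration_s,
        true_levels=levels,
    )


def _boltzmann(v: np.ndarray | float, v_half: float, slope: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / slope))


def wholecell_steady_current(
    v_mv,
    bk_density_at_80: float,
    kv_density_at_80: float,
    cm_pf: float,
    ibtx: bool = False,
    e_k: float = E_K_DEFAULT,
) -> np.ndarray:
    """Steady-state model current (pA) at test potential(s) ``v_mv``.

    I(V) = [g_BK * b(V) + g_Kv * w(V)] * (V - E_K) with Boltzmann
    activations, conductances scaled so the programmed +80 mV densities are
    exact; the IBTx flag removes the BK term.
    """
    g_bk = bk_density_at_80 * cm_pf / (_boltzmann(80.0, BK_V_HALF, BK_SLOPE) * (80.0 - e_k))
    g_kv = kv_density_at_80 * cm_pf / (_boltzmann(80.0, KV_V_HALF, KV_SLOPE) * (80.0 - e_k))
    v = np.asarray(v_mv, dtype=float)
    g = g_kv * _boltzmann(v, KV_V_HALF, KV_SLOPE)
    if not ibtx:
        g = g + g_bk * _boltzmann(v, BK_V_HALF, BK_SLOPE)
    return g * (v - e_k)


def gen_wholecell(
    bk_density_at_80: float,
    kv_density_at_80: float,
    cm_pf: float = 10.0,
    voltages_mv: np.ndarray | None = None,
    pulse_ms: float = 600.0,
    fs: float = 20_000.0,
    ibtx: bool = False,
    e_k: float = E_K_DEFAULT,
    cap_transient_pa: float = 200.0,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
) -> StepRecording:
    """Synthetic voltage-step family (holding -70, steps -70..+80 mV).

    Traces are flat at the steady model current; a decaying capacitive
    transient (tau 0.3 ms) is confined to the first 2 ms.
    """
    if bk_density_at_80 < 0 or kv_density_at_80 < 0:
        raise ValueError("programmed densities must be >= 0")
    if voltages_mv is None:
        voltages_mv = np.arange(-70.0, 80.0 + 1e-9, 10.0)
    v = np.asarray(voltages_mv, dtype=float)
    n = int(round(pulse_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    steady = wholecell_steady_current(
        v, bk_density_at_80, kv_density_at_80, cm_pf, ibtx=ibtx, e_k=e_k
    )
    traces = np.tile(steady[:, None], (1, n))
    if cap_transient_pa > 0:
        mask = t < 2e-3
        holding = -70.0
        for i, vv in enumerate(v):
            amp = cap_transient_pa * (vv - holding) / 150.0
            traces[i, mask] += amp * np.exp(-t[mask] / 0.3e-3)
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd_pa, size=traces.shape)
    return StepRecording(
        v,
        traces,
        capacitance_pf=cm_pf,
        fs=fs,
        condition="IBTx" if ibtx else "control",
    )


def gen_vm(
    mean_mv: float,
    noise_sd_mv: float = 0.0,
    drug_delta_mv: float | None = None,
    onset_s: float | None = None,
    duration_s: float = 30.0,
    fs: float = 1_000.0,
    tau_s: float = 0.5,
    drug_name: str = "IBTx",
    seed: int = 0,
) -> VmTrace:
    """Synthetic gap-free Vm trace with optional drug step.

    Fluctuations follow an Ornstein-Uhlenbeck process (stationary sd
    ``noise_sd_mv``, correlation time ``tau_s``); ``tau_s = 0`` selects
    white Gaussian noise of the same sd.  ``drug_delta_mv`` adds a step at
    ``onset_s``.
    """
    if drug_delta_mv is not None:
        if onset_s is None or not 0.0 < onset_s < duration_s:
            raise ValueError("drug step requires 0 < onset_s < duration_s")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    if noise_sd_mv <= 0:
        noise = np.zeros(n)
    elif tau_s <= 0:
        noise = rng.normal(0.0, noise_sd_mv, size=n)
    else:
        a = np.exp(-1.0 / (fs * tau_s))
        innov_sd = noise_sd_mv * np.sqrt(1.0 - a * a)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, noise_sd_mv)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            noise[i] = a * noise[i - 1] + eps[i - 1]
    vm = mean_mv + noise
    if drug_delta_mv is not None:
        vm[int(round(onset_s * fs)) :] += drug_delta_mv
        return VmTrace(vm, fs=fs, drug_name=drug_name, drug_onset_s=onset_s)
    return VmTrace(vm, fs=fs)


def gen_myography(
    pressures_mmhg=(10.0, 20.0, 40.0, 60.0, 80.0, 100.0),
    passive_d0_um: float = 60.0,
    passive_dmax_um: float = 130.0,
    passive_p_half_mmhg: float = 25.0,
    tone_peak_percent: float = 22.0,
    tone_center_mmhg: float = 60.0,
    tone_width_mmhg: float = 45.0,
    kcl_constriction_pct: float = 64.4,
    tone_profile: dict | None = None,
    noise_um: float = 0.0,
    stability_drift_percent: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> DiameterDataset:
    """Synthetic artery: saturating passive curve, bell-shaped active tone.

    D_pass(P) = d0 + (dmax - d0) * P / (P + P_half);
    tone(P) = peak * exp(-((P - center) / width)^2), overridable per
    pressure with ``tone_profile``;
    D_act(P) = D_pass(P) * (1 - tone(P)/100).
    The KCl segment starts from the 60 mmHg active diameter and is scaled to
    the programmed constriction.
    """
    p = np.asarray(pressures_mmhg, dtype=float)
    d_pass = passive_d0_um + (passive_dmax_um - passive_d0_um) * p / (
        p + passive_p_half_mmhg
    )
    if tone_profile is not None:
        tone = np.array([float(tone_profile[float(x)]) for x in p])
    else:
        tone = tone_peak_percent * np.exp(
            -(((p - tone_center_mmhg) / tone_width_mmhg) ** 2)
        )
    d_act = d_pass * (1.0 - tone / 100.0)
    if noise_um > 0:
        rng = np.random.default_rng(seed)
        d_act = d_act + rng.normal(0.0, noise_um, size=d_act.shape)
        d_pass = d_pass + rng.normal(0.0, noise_um, size=d_pass.shape)
    i60 = int(np.argmin(np.abs(p - 60.0)))
    kcl_pre = float(d_act[i60])
    kcl_post = kcl_pre * (1.0 - kcl_constriction_pct / 100.0)
    tone60 = float(tone[i60])
    return DiameterDataset(
        pressures_mmhg=p,
        d_active_um=d_act,
        d_passive_um=d_pass,
        kcl_pre_um=kcl_pre,
        kcl_post_um=kcl_post,
        stability_tone_start=tone60,
        stability_tone_end=tone60 + stability_drift_percent,
        label=label,
    )


def gen_puncta(
    density_per_um2: float,
    n_cells: int,
    area_mean_um2: float = 400.0,
    area_sd_um2: float = 100.0,
    condition: str = "FA",
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson puncta counts over gamma-distributed cell areas."""
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (area_mean_um2 / area_sd_um2) ** 2
    scale = area_sd_um2**2 / area_mean_um2
    areas = rng.gamma(shape, scale, size=n_cells)
    counts = rng.poisson(density_per_um2 * areas)
    return pd.DataFrame(
        {
            "cell_id": [f"{condition}_{i:03d}" for i in range(n_cells)],
            "puncta_count": counts,
            "cell_area_um2": areas,
            "condition": condition,
        }
    )


def gen_qpcr(
    true_folds: dict,
    calibrator_group: str = "FA",
    groups: tuple = ("FA", "SHS"),
    replicates: int = 6,
    ct_sd: float = 0.0,
    ref_ct: float = 18.0,
    delta_ct_base: float = 5.0,
    reference_gene: str = "GAPDH",
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table with programmed fold changes.

    ``true_folds`` maps gene -> {group: fold relative to the calibrator}.
    Ct_target = Ct_ref + delta_ct_base - log2(fold) + noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for r in range(replicates):
            sample = f"{group}_{r:02d}"
            ct_ref = ref_ct + rng.normal(0.0, ct_sd) if ct_sd > 0 else ref_ct
            rows.append(
                {"sample_id": sample, "group": group, "gene": reference_gene, "ct": ct_ref}
            )
            for gene, per_group in true_folds.items():
                fold = float(per_group.get(group, 1.0))
                if fold <= 0:
                    raise ValueError("fold changes must be > 0")
                ct = ct_ref + delta_ct_base - np.log2(fold)
                if ct_sd > 0:
                    ct += rng.normal(0.0, ct_sd)
                rows.append(
                    {"sample_id": sample, "group": group, "gene": gene, "ct": float(ct)}
                )
    return pd.DataFrame(rows)
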