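"""Whole-cell K+ current processing and current-clamp membrane-potential metrics.

Voltage-step families recorded before and after BK-channel block (IBTx) are
reduced to current-density I-V curves (pA/pF), and the IBTx-sensitive
component is obtained by digital subtraction:

    I_BK(V) = I_K,control(V) - I_K,IBTx(V);   I_Kv(V) = I_K,IBTx(V)

so the decomposition identity I_BK + I_Kv = I_K holds exactly.  Gap-free
membrane-potential traces yield a resting Vm (mean over the most stable
10-s window) and a drug-induced Vm change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepRecording",
    "IVCurve",
    "VmTrace",
    "VmMetrics",
    "extract_iv",
    "subtract_ibtx",
    "vm_metrics",
]


@dataclass
class StepRecording:
    """One voltage-step family: one current trace per test potential.

    Default protocol: holding -70 mV, steps -70..+80 mV in +10 mV
    increments, 20 kHz sampling.  ``traces`` is (n_voltages, n_samples) pA.
    """

    voltages_mv: np.ndarray
    traces: np.ndarray
    capacitance_pf: float
    fs: float = 20_000.0
    condition: str = "control"
    holding_mv: float = -70.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mv, dtype=float)
        tr = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if v.ndim != 1 or tr.shape[0] != v.size:
            raise ValueError("need exactly one trace per voltage")
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.capacitance_pf <= 0:
            raise ValueError("membrane capacitance must be > 0")
        self.voltages_mv = v
        self.traces = tr

    @property
    def pulse_s(self) -> float:
        return self.traces.shape[1] / self.fs


@dataclass
class IVCurve:
    """Current densities (pA/pF) per test potential for one component."""

    voltages_mv: np.ndarray
    densities_pa_per_pf: np.ndarray
    component: str = "I_K"
    raw_pa: np.ndarray | None = None
    excluded_mv: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mv, dtype=float)
        d = np.asarray(self.densities_pa_per_pf, dtype=float)
        if v.shape != d.shape:
            raise ValueError("voltages and densities must have equal length")
        self.voltages_mv, self.densities_pa_per_pf = v, d

    def density_at(self, voltage_mv: float) -> float:
        i = np.flatnonzero(np.isclose(self.voltages_mv, voltage_mv))
        if i.size == 0:
            raise KeyError(f"voltage {voltage_mv} mV not on the grid")
        return float(self.densities_pa_per_pf[i[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "voltage_mV": self.voltages_mv,
                "density_pA_per_pF": self.densities_pa_per_pf,
                "component": self.component,
            }
        )
        if self.raw_pa is not None:
            df["current_pA"] = np.asarray(self.raw_pa, dtype=float)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class VmTrace:
    """Gap-free membrane potential (mV) with optional drug annotation."""

    vm_mv: np.ndarray
    fs: float = 1_000.0
    drug_name: str | None = None
    drug_onset_s: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.vm_mv, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("Vm trace contains non-finite samples")
        self.vm_mv = x

    @property
    def duration_s(self) -> float:
        return self.vm_mv.size / self.fs


@dataclass
class VmMetrics:
    resting_vm_mv: float
    delta_vm_mv: float | None
    unstable: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "resting_vm_mV": self.resting_vm_mv,
                "delta_vm_mV": self.delta_vm_mv,
                "unstable": self.unstable,
            }
        )


def extract_iv(
    rec: StepRecording,
    blank_ms: float = 5.0,
    statistic: str = "peak",
    clip_limit_pa: float | None = None,
    late_ms: float = 50.0,
) -> IVCurve:
    """Per-voltage current statistic over the pulse, as density in pA/pF.

    The first ``blank_ms`` of each trace is blanked (capacitive transient);
    ``statistic`` is ``"peak"`` (signed value of maximal absolute current)
    or ``"mean_late"`` (mean of the final ``late_ms``).  Traces reaching
    ``clip_limit_pa`` are flagged as saturated and excluded (density NaN).
    """
    if statistic not in ("peak", "mean_late"):
        raise ValueError("statistic must be 'peak' or 'mean_late'")
    i0 = int(round(blank_ms * 1e-3 * rec.fs))
    if i0 >= rec.traces.shape[1]:
        raise ValueError("blank_ms must be shorter than the pulse")
    raw = np.empty(rec.voltages_mv.size)
    excluded: list[float] = []
    for i, v in enumerate(rec.voltages_mv):
        seg = rec.traces[i, i0:]
        if clip_limit_pa is not None and np.any(np.abs(seg) >= clip_limit_pa):
            warnings.warn(f"trace at {v:+.0f} mV saturated; excluded", RuntimeWarning)
            excluded.append(float(v))
            raw[i] = np.nan
            continue
        if statistic == "peak":
            raw[i] = seg[np.argmax(np.abs(seg))]
        else:
            n_late = max(int(round(late_ms * 1e-3 * rec.fs)), 1)
            raw[i] = seg[-n_late:].mean()
    return IVCurve(
        rec.voltages_mv.copy(),
        raw / rec.capacitance_pf,
        component="I_K",
        raw_pa=raw,
        excluded_mv=excluded,
    )


def subtract_ibtx(control: IVCurve, ibtx: IVCurve) -> tuple[IVCurve, IVCurve]:
    """Digital subtraction of the IBTx family from control.

    Returns ``(I_BK, I_Kv)`` with I_BK = control - IBTx and I_Kv = IBTx, on
    the shared voltage grid.  Additivity I_BK + I_Kv = I_K is exact.
    """
    if control.voltages_mv.shape != ibtx.voltages_mv.shape or not np.allclose(
        control.voltages_mv, ibtx.voltages_mv, atol=1e-9
    ):
        raise ValueError("control and IBTx voltage grids differ")
    v = control.voltages_mv.copy()
    bk_raw = None
    if control.raw_pa is not None and ibtx.raw_pa is not None:
        bk_raw = np.asarray(control.raw_pa) - np.asarray(ibtx.raw_pa)
    i_bk = IVCurve(
        v,
        control.densities_pa_per_pf - ibtx.densities_pa_per_pf,
        component="I_BK",
        raw_pa=bk_raw,
    )
    i_kv = IVCurve(
        v,
        ibtx.densities_pa_per_pf.copy(),
        component="I_Kv",
        raw_pa=None if ibtx.raw_pa is None else np.asarray(ibtx.raw_pa).copy(),
    )
    return i_bk, i_kv


def _stable_window_mean(x: np.ndarray, fs: float, window_s: float) -> float:
    """Mean of the length-``window_s`` window with minimal variance."""
    w = int(round(window_s * fs))
    if w >= x.size or w < 2:
        return float(x.mean())
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = s2 / w - (s1 / w) ** 2
    i = int(np.argmin(var))
    return float(s1[i] / w)


def vm_metrics(
    trace: VmTrace,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    stable_s: float = 10.0,
    drift_limit_mv: float = 5.0,
) -> VmMetrics:
    """Resting Vm and drug-induced Vm change from a gap-free trace.

    The resting potential is the mean over the most stable (minimum rolling
    variance) ``stable_s`` window of the pre-drug data.  With a drug
    annotation (or explicit windows), delta_vm = mean(post) - mean(pre).
    A pre-window drift beyond ``drift_limit_mv`` sets the instability flag.
    """
    x = trace.vm_mv
    fs = trace.fs
    dur = trace.duration_s
    if pre_window is None:
        pre_end = trace.drug_onset_s if trace.drug_onset_s is not None else dur
        pre_window = (0.0, pre_end)
    if post_window is None and trace.drug_onset_s is not None:
        post_window = (trace.drug_onset_s, dur)
    for name, win in (("pre_window", pre_window), ("post_window", post_window)):
        if win is not None and not (0.0 <= win[0] < win[1] <= dur + 1e-9):
            raise ValueError(f"{name} {win} outside the trace")

    pre = x[int(round(pre_window[0] * fs)) : int(round(pre_window[1] * fs))]
    if pre.size < 2:
        raise ValueError("pre window too short")
    resting = _stable_window_mean(pre, fs, stable_s)

    # drift check: compare means of the first and last second of the pre window
    edge = max(int(round(fs)), 1)
    drift = abs(pre[-edge:].mean() - pre[:edge].mean())
    unstable = bool(drift > drift_limit_mv)
    if unstable:
        warnings.warn(
            f"pre-window drift {drift:.2f} mV exceeds {drift_limit_mv} mV", RuntimeWarning
        )

    delta = None
    if post_window is not None:
        post = x[int(round(post_window[0] * fs)) : int(round(post_window[1] * fs))]
        if post.size < 1:
            raise ValueError("post window too short")
        delta = float(post.mean() - pre.mean())
    return VmMetrics(resting_vm_mv=resting, delta_vm_mv=delta, unstable=unstable)
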