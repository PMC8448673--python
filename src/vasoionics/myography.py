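"""Pressure-myography analysis: myogenic tone, KCl viability, tone-pressure curves.

Tone at a pressure is the active diameter relative to the maximally dilated
(Ca2+-free) passive diameter at the same pressure:

    tone% = 100 * (D_passive - D_active) / D_passive

Arteries qualify for analysis when they constrict robustly to high-K+
solution (default threshold 30%) and maintain stable tone at 60 mmHg
(absolute tone drift < 5% over 1 h).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiameterDataset",
    "ToneResult",
    "KclResult",
    "percent_tone",
    "kcl_viability",
    "tone_pressure_curve",
    "diameters_from_timeseries",
]


@dataclass
class DiameterDataset:
    """Per-artery pressure-myography summary.

    Diameters in um; ``d_passive`` measured in Ca2+-free + nifedipine.
    ``stability_tone_start/end`` are % tone at 60 mmHg at the start and end
    of the 1-h stabilization period.
    """

    pressures_mmhg: np.ndarray
    d_active_um: np.ndarray
    d_passive_um: np.ndarray
    kcl_pre_um: float
    kcl_post_um: float
    stability_tone_start: float = 0.0
    stability_tone_end: float = 0.0
    label: str = "artery"

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures_mmhg, dtype=float)
        a = np.asarray(self.d_active_um, dtype=float)
        d = np.asarray(self.d_passive_um, dtype=float)
        if not (p.shape == a.shape == d.shape):
            raise ValueError("pressure/active/passive arrays must align")
        if np.any(a[np.isfinite(a)] <= 0) or np.any(d[np.isfinite(d)] <= 0):
            raise ValueError("diameters must be positive")
        self.pressures_mmhg, self.d_active_um, self.d_passive_um = p, a, d


@dataclass
class KclResult:
    constriction_percent: float
    viable: bool
    dilation_flag: bool = False


@dataclass
class ToneResult:
    pressures_mmhg: np.ndarray
    tone_percent: np.ndarray
    clipped: np.ndarray  # True where negative tone was clipped to 0
    kcl_constriction_percent: float
    viable: bool
    stable: bool
    label: str = "artery"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pressure_mmHg": self.pressures_mmhg,
                "tone_percent": self.tone_percent,
                "clipped": self.clipped,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "pressures_mmHg": self.pressures_mmhg.tolist(),
                "tone_percent": self.tone_percent.tolist(),
                "clipped": self.clipped.tolist(),
                "kcl_constriction_percent": self.kcl_constriction_percent,
                "viable": self.viable,
                "stable": self.stable,
            }
        )


def percent_tone(d_active: float, d_passive: float, clip: bool = True) -> float:
    """Myogenic tone: 100 * (d_passive - d_active) / d_passive.

    Negative values (active wider than passive) are clipped to 0 with a
    warning when ``clip`` is true.
    """
    if d_passive <= 0:
        raise ValueError("passive diameter must be > 0")
    if d_active <= 0:
        raise ValueError("active diameter must be > 0")
    tone = 100.0 * (d_passive - d_active) / d_passive
    if tone < 0 and clip:
        warnings.warn(
            f"negative tone {tone:.2f}% clipped to 0 (active > passive)", RuntimeWarning
        )
        return 0.0
    return tone


def kcl_viability(
    d_pre: float, d_kcl: float, threshold_percent: float = 30.0
) -> KclResult:
    """High-K+ constriction and the viability decision.

    constriction% = 100 * (d_pre - d_kcl) / d_pre; the artery is viable when
    the constriction reaches ``threshold_percent``.  Dilation (d_kcl >
    d_pre) yields a negative constriction, non-viable, with a flag.
    """
    if d_pre <= 0:
        raise ValueError("pre-KCl diameter must be > 0")
    constriction = 100.0 * (d_pre - d_kcl) / d_pre
    dilated = constriction < 0
    return KclResult(
        constriction_percent=constriction,
        viable=bool(constriction >= threshold_percent) and not dilated,
        dilation_flag=bool(dilated),
    )


def tone_pressure_curve(
    ds: DiameterDataset,
    viability_threshold: float = 30.0,
    stability_drift_max: float = 5.0,
) -> ToneResult:
    """Percent tone per pressure plus viability and stability flags.

    Pressures whose passive reference is missing (NaN) are omitted with a
    warning.  Stability requires an absolute tone drift at 60 mmHg below
    ``stability_drift_max`` over the 1-h window.
    """
    keep = np.isfinite(ds.d_passive_um) & np.isfinite(ds.d_active_um)
    if not keep.all():
        dropped = ds.pressures_mmhg[~keep]
        warnings.warn(
            f"missing diameter reference at {dropped.tolist()} mmHg; omitted",
            RuntimeWarning,
        )
    p = ds.pressures_mmhg[keep]
    tone = np.empty(p.size)
    clipped = np.zeros(p.size, dtype=bool)
    for i, (a, d) in enumerate(zip(ds.d_active_um[keep], ds.d_passive_um[keep])):
        raw = 100.0 * (d - a) / d
        if raw < 0:
            tone[i] = 0.0
            clipped[i] = True
        else:
            tone[i] = raw
    kcl = kcl_viability(ds.kcl_pre_um, ds.kcl_post_um, viability_threshold)
    drift = abs(ds.stability_tone_end - ds.stability_tone_start)
    if clipped.any():
        warnings.warn("negative tone clipped to 0 at some pressures", RuntimeWarning)
    return ToneResult(
        pressures_mmhg=p,
        tone_percent=tone,
        clipped=clipped,
        kcl_constriction_percent=kcl.constriction_percent,
        viable=kcl.viable,
        stable=bool(drift < stability_drift_max),
        label=ds.label,
    )


def diameters_from_timeseries(
    df: pd.DataFrame, window_s: float = 30.0
) -> pd.DataFrame:
    """Collapse a (time_s, pressure_mmHg, diameter_um, condition) table.

    The diameter at each (condition, pressure) step is the mean over the
    final ``window_s`` seconds recorded at that step.
    """
    required = {"time_s", "pressure_mmHg", "diameter_um", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"timeseries table needs columns {sorted(required)}")
    rows = []
    for (cond, p), g in df.groupby(["condition", "pressure_mmHg"]):
        t_end = g["time_s"].max()
        tail = g[g["time_s"] >= t_end - window_s]
        rows.append(
            {
                "condition": cond,
                "pressure_mmHg": p,
                "diameter_um": tail["diameter_um"].mean(),
            }
        )
    return pd.DataFrame(rows)
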