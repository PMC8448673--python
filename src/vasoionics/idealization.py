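"""Half-amplitude idealization of single-channel sweeps and activity statistics.

Raw cell-attached current sweeps (openings oriented positive; flip inward
currents at ingestion) are quantized to integer open-channel levels with the
half-amplitude criterion: a sample sits at level ``k`` when its baseline-
subtracted amplitude is at least ``(k - 0.5) * unitary_current``.  Dwells
shorter than a minimum duration are merged into a flanking level to suppress
noise-driven flickers.  From idealized sweeps the module computes nPo, the
channel count n (maximum simultaneous level), Po = nPo / n, the ensemble
average current, and coupled-opening metrics (frequency and strength of
level jumps >= 2 within one sampling interval).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SweepSet",
    "IdealizedSweep",
    "ChannelActivityStats",
    "CoupledEventMetrics",
    "estimate_baseline",
    "idealize_sweep",
    "idealize_sweeps",
    "activity_stats",
    "coupled_event_metrics",
]


@dataclass
class SweepSet:
    """A set of equal-length current sweeps from one patch.

    ``sweeps`` is an (n_sweeps, n_samples) array in pA with channel openings
    positive-going.  Protocol metadata mirrors the standard cell-attached
    pulse protocol (2 s step to 0 mV from -80 mV every 5 s, 10 kHz sampling,
    2 kHz low-pass).
    """

    sweeps: np.ndarray
    fs: float = 10_000.0
    unitary_current: float = 1.0
    filter_hz: float = 2_000.0
    holding_mv: float = -80.0
    test_mv: float = 0.0
    step_s: float = 2.0
    interval_s: float = 5.0
    true_levels: np.ndarray | None = None  # ground truth when synthetic

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if a.ndim != 2:
            raise ValueError("sweeps must form a 2-D array")
        if self.fs <= 2.0 * self.filter_hz:
            raise ValueError("fs must exceed twice the low-pass corner")
        if self.unitary_current <= 0:
            raise ValueError("unitary_current must be > 0")
        self.sweeps = a

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    def to_csv(self, path) -> None:
        """Write tidy (time_s, sweep_id, current_pA) CSV."""
        t = np.arange(self.n_samples) / self.fs
        frames = [
            pd.DataFrame(
                {"time_s": t, "sweep_id": i, "current_pA": self.sweeps[i]}
            )
            for i in range(self.n_sweeps)
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 10_000.0, **kwargs) -> "SweepSet":
        df = pd.read_csv(path)
        ids = sorted(df["sweep_id"].unique())
        sweeps = np.stack(
            [df.loc[df["sweep_id"] == i, "current_pA"].to_numpy() for i in ids]
        )
        return cls(sweeps, fs=fs, **kwargs)


@dataclass
class IdealizedSweep:
    """Level-quantized sweep with dwell segmentation."""

    levels: np.ndarray
    fs: float
    baseline: float
    dwells: list = field(default_factory=list)  # (level, start_sample, n_samples)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size and self.levels.min() < 0:
            raise ValueError("levels must be non-negative")


@dataclass
class CoupledEventMetrics:
    """Coupled-opening summary over a sweep set."""

    frequency_hz: float  # coupled openings per second of analyzed depolarization
    strength: float  # mean level jump of coupled openings (0 when none)
    fraction: float  # coupled openings / all upward transitions
    n_coupled: int
    n_openings: int


@dataclass
class ChannelActivityStats:
    nPo: float
    n_channels: int
    Po: float
    ensemble_average: np.ndarray
    coupled_frequency: float
    coupled_strength: float
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["ensemble_average"] = np.asarray(self.ensemble_average).tolist()
        return json.dumps(d)


def estimate_baseline(
    trace: np.ndarray, unitary_current: float, bin_pa: float = 0.05
) -> float:
    """Closed-level baseline: histogram mode of the lowest-amplitude cluster.

    The search window is ``[min(trace), min(trace) + 0.8 * unitary_current)``
    so that a patch spending most of its time open (where the global
    histogram mode sits at an open level) still anchors on the closed level.
    Fails if the patch never visits the closed level.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 10:
        raise ValueError("trace too short for baseline estimation")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if np.ptp(x) == 0.0:
        raise ValueError("flat trace: baseline undefined")
    lo = x.min()
    window = x[x < lo + 0.8 * unitary_current]
    nbins = max(int(np.ceil((window.max() - window.min()) / bin_pa)), 1)
    counts, edges = np.histogram(window, bins=nbins)
    top = counts.max()
    modes = np.flatnonzero(counts == top)
    if modes.size > 1:
        warnings.warn("baseline histogram is multimodal; lower mode chosen", RuntimeWarning)
    i = modes[0]
    center = 0.5 * (edges[i] + edges[i + 1])
    # refine beyond bin resolution: mean of the closed cluster around the mode
    cluster = x[np.abs(x - center) <= 0.25 * unitary_current]
    return float(cluster.mean()) if cluster.size else float(center)


def _run_length_encode(levels: np.ndarray) -> list[list[int]]:
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [levels.size]))
    return [[int(levels[s]), int(e - s)] for s, e in zip(starts, ends)]


def _merge_short_dwells(levels: np.ndarray, min_dwell: int) -> np.ndarray:
    """Merge dwells shorter than ``min_dwell`` into a flanking level.

    Single left-to-right pass over the run-length encoding: a short interior
    run is absorbed by the neighbor with the closer level (tie: previous).
    Short leading/trailing runs are absorbed by their only neighbor.
    """
    if min_dwell <= 1 or levels.size == 0:
        return levels
    runs = _run_length_encode(levels)
    if len(runs) == 1:
        return levels
    out: list[list[int]] = []

    def push(level: int, length: int) -> None:
        if out and out[-1][0] == level:
            out[-1][1] += length
        else:
            out.append([level, length])

    for level, length in runs:
        # resolve the previous run now that it has a right neighbor
        while out and out[-1][1] < min_dwell:
            short_level, short_len = out.pop()
            if out:
                prev_level = out[-1][0]
                if abs(prev_level - short_level) <= abs(level - short_level):
                    push(prev_level, short_len)
                    continue
            # absorbed by the incoming run
            length += short_len
            break
        push(level, length)
    # trailing short run: absorb into its left neighbor
    while len(out) > 1 and out[-1][1] < min_dwell:
        short_level, short_len = out.pop()
        push(out[-1][0], short_len)
    merged = np.concatenate([np.full(n, lv, dtype=np.int64) for lv, n in out])
    return merged


def idealize_sweep(
    sweep: np.ndarray,
    unitary_current: float,
    n_max: int | None = None,
    fs: float = 10_000.0,
    min_dwell_samples: int = 2,
    baseline: float | None = None,
) -> IdealizedSweep:
    """Quantize one sweep to integer levels with the half-amplitude rule.

    level(t) is the largest k with ``|I(t) - baseline| >= (k - 0.5) *
    unitary_current``, clipped to [0, n_max].  The baseline defaults to the
    per-sweep estimate from :func:`estimate_baseline`.
    """
    x = np.asarray(sweep, dtype=float)
    if x.size <= 10:
        raise ValueError("trace must be longer than 10 samples")
    if unitary_current <= 0:
        raise ValueError("unitary_current must be > 0")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    flags: list[str] = []
    if baseline is None:
        baseline = estimate_baseline(x, unitary_current)
    amp = np.abs(x - baseline)
    levels = np.floor(amp / unitary_current + 0.5).astype(np.int64)
    if n_max is not None:
        levels = np.clip(levels, 0, int(n_max))
    merged = _merge_short_dwells(levels, min_dwell_samples)
    if not np.array_equal(merged, levels):
        flags.append("short_dwells_merged")
    dwells = [
        (lv, int(start), int(n))
        for (lv, n), start in zip(
            _run_length_encode(merged),
            np.cumsum([0] + [n for _, n in _run_length_encode(merged)[:-1]]),
        )
    ]
    return IdealizedSweep(merged, fs=fs, baseline=baseline, dwells=dwells, flags=flags)


def idealize_sweeps(
    sweep_set: SweepSet,
    n_max: int | None = None,
    min_dwell_samples: int = 2,
    baseline: float | None = None,
) -> list[IdealizedSweep]:
    """Idealize every sweep of a :class:`SweepSet`."""
    return [
        idealize_sweep(
            sweep_set.sweeps[i],
            sweep_set.unitary_current,
            n_max=n_max,
            fs=sweep_set.fs,
            min_dwell_samples=min_dwell_samples,
            baseline=baseline,
        )
        for i in range(sweep_set.n_sweeps)
    ]


def _window_slice(n_samples: int, fs: float, window: tuple[float, float] | None):
    if window is None:
        edge = 0.005  # exclude 5 ms capacitive transients at each end
        window = (edge, n_samples / fs - edge)
        if window[1] <= window[0]:  # short trace: use everything
            window = (0.0, n_samples / fs)
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    return slice(max(i0, 0), min(i1, n_samples))


def activity_stats(
    idealized: list[IdealizedSweep],
    unitary_current: float,
    window: tuple[float, float] | None = None,
) -> ChannelActivityStats:
    """nPo, channel count, Po, ensemble average and coupled metrics.

    nPo is the time-average of level(t) over the analysis window, averaged
    across sweeps; the channel count n is the maximum simultaneous level
    observed in the patch; Po = nPo / n.  With no openings at all, n = 1 by
    convention and the result is flagged.
    """
    if not idealized:
        raise ValueError("need at least one idealized sweep")
    fs = idealized[0].fs
    n_samples = idealized[0].levels.size
    sl = _window_slice(n_samples, fs, window)
    flags: list[str] = []
    per_sweep = np.array([sw.levels[sl].mean() for sw in idealized])
    npo = float(per_sweep.mean())
    n_channels = int(max(sw.levels.max(initial=0) for sw in idealized))
    if n_channels == 0:
        n_channels = 1
        flags.append("no_openings")
    po = npo / n_channels
    stack = np.stack([sw.levels for sw in idealized])
    ensemble = stack.mean(axis=0) * unitary_current
    coupled = coupled_event_metrics(idealized, window=window)
    return ChannelActivityStats(
        nPo=npo,
        n_channels=n_channels,
        Po=po,
        ensemble_average=ensemble,
        coupled_frequency=coupled.frequency_hz,
        coupled_strength=coupled.strength,
        flags=flags,
    )


def coupled_event_metrics(
    idealized: list[IdealizedSweep],
    window: tuple[float, float] | None = None,
) -> CoupledEventMetrics:
    """Frequency and strength of coupled openings (level jumps >= 2).

    A coupled opening is an upward level transition of at least two channels
    within one sampling interval.  Frequency is expressed as events per
    second of analyzed depolarization; the fraction of all openings that are
    coupled is reported as a secondary quantity.
    """
    if not idealized:
        raise ValueError("need at least one idealized sweep")
    fs = idealized[0].fs
    n_samples = idealized[0].levels.size
    sl = _window_slice(n_samples, fs, window)
    total_time = 0.0
    n_coupled = 0
    n_openings = 0
    jump_sum = 0.0
    for sw in idealized:
        seg = sw.levels[sl]
        total_time += seg.size / sw.fs
        d = np.diff(seg)
        ups = d[d >= 1]
        n_openings += ups.size
        coupled = ups[ups >= 2]
        n_coupled += coupled.size
        jump_sum += float(coupled.sum())
    freq = n_coupled / total_time if total_time > 0 else 0.0
    strength = jump_sum / n_coupled if n_coupled else 0.0
    fraction = n_coupled / n_openings if n_openings else 0.0
    return CoupledEventMetrics(freq, strength, fraction, n_coupled, n_openings)
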