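"""Molecular quantification: PLA puncta density, qPCR ddCt, densitometry."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PunctaMeasurement",
    "puncta_density",
    "puncta_density_table",
    "relative_expression",
    "expression_group_summary",
    "densitometry_ratio",
    "densitometry_table",
]


@dataclass(frozen=True)
class PunctaMeasurement:
    """Puncta count over a measured cell area for one condition."""

    cell_id: str
    puncta_count: int
    cell_area_um2: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")
        if self.cell_area_um2 <= 0:
            raise ValueError("cell_area_um2 must be > 0")


def puncta_density(m: PunctaMeasurement) -> float:
    """Puncta per um^2: count / area."""
    return m.puncta_count / m.cell_area_um2


def puncta_density_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``density_per_um2`` column to a puncta table.

    Requires columns cell_id, puncta_count, cell_area_um2 (and optionally
    condition).
    """
    if (df["cell_area_um2"] <= 0).any():
        raise ValueError("all cell areas must be > 0")
    out = df.copy()
    out["density_per_um2"] = out["puncta_count"] / out["cell_area_um2"]
    return out


def relative_expression(
    ct: pd.DataFrame,
    calibrator_group: str,
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Per-sample fold change by the 2^-ddCt method.

    ``ct`` is long-format with columns sample_id, group, gene, ct.  For each
    target gene: dCt = Ct_target - Ct_reference (same sample), ddCt = dCt -
    mean dCt of the calibrator group, fold = 2^-ddCt.  Samples lacking a
    reference Ct are dropped with a warning.  By construction the calibrator
    group has geometric-mean fold 1 for every gene.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = (
        ct[ct["gene"] == reference_gene]
        .set_index("sample_id")["ct"]
        .groupby(level=0)
        .mean()
    )
    targets = ct[ct["gene"] != reference_gene].copy()
    missing = ~targets["sample_id"].isin(ref.index)
    if missing.any():
        dropped = sorted(targets.loc[missing, "sample_id"].unique())
        warnings.warn(f"samples without reference Ct dropped: {dropped}", RuntimeWarning)
        targets = targets[~missing]
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[
        targets["sample_id"]
    ].to_numpy()
    out = []
    for gene, g in targets.groupby("gene"):
        cal = g[g["group"] == calibrator_group]
        if cal.empty:
            raise ValueError(f"no calibrator-group samples for gene {gene!r}")
        base = cal["delta_ct"].mean()
        gg = g.copy()
        gg["delta_delta_ct"] = gg["delta_ct"] - base
        gg["fold"] = 2.0 ** (-gg["delta_delta_ct"])
        out.append(gg)
    return pd.concat(out, ignore_index=True)


def expression_group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean fold per (gene, group)."""
    return (
        folds.groupby(["gene", "group"])["fold"]
        .apply(lambda x: float(np.exp(np.mean(np.log(x)))))
        .rename("geometric_mean_fold")
        .reset_index()
    )


def densitometry_ratio(band_intensity: float, loading_intensity: float) -> float:
    """Band intensity normalized to a loading signal (scale invariant)."""
    if loading_intensity <= 0:
        raise ValueError("loading intensity must be > 0")
    return band_intensity / loading_intensity


def densitometry_table(df: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Normalized ratios, expressed relative to the control-group mean.

    Requires columns sample_id, group, band_intensity, loading_intensity.
    """
    required = {"sample_id", "group", "band_intensity", "loading_intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"densitometry table needs columns {sorted(required)}")
    out = df.copy()
    out["ratio"] = [
        densitometry_ratio(b, l)
        for b, l in zip(out["band_intensity"], out["loading_intensity"])
    ]
    ctrl = out.loc[out["group"] == control_group, "ratio"]
    if ctrl.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["relative_to_control"] = out["ratio"] / ctrl.mean()
    return out
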