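"""Melting-curve QC and signal-dependent quantile-spline normalization of Cp data.

qPCR crossing-point (Cp) values carry smooth, signal-dependent plate biases:
the distortion a sample suffers depends on where on the Cp scale a feature
sits.  A single scale-and-shift cannot remove it.  The normalization here maps
each sample's Cp distribution onto a common target distribution (the
across-sample mean of per-sample quantiles) through a cubic smoothing spline
of offset versus signal, so that the correction applied to a Cp value varies
smoothly with the value itself.  The final per-sample map is made
non-decreasing by isotonic regression, which preserves within-sample ranks.

Melting-curve QC flags assays whose primers amplify more than one product:
such assays show multiple peaks in the negative derivative of fluorescence
with respect to temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import isotonic_regression
from scipy.signal import find_peaks

__all__ = [
    "MeltCurve",
    "NormalizationModel",
    "count_melt_peaks",
    "fit_qspline",
    "apply_normalization",
    "sem_reduction",
]

MIN_MELT_POINTS = 20
MIN_DETECTED_FEATURES = 30


@dataclass
class MeltCurve:
    """Fluorescence vs. temperature trace for one qPCR assay."""

    assay_id: str
    temperatures: np.ndarray  # degrees C, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError(f"assay {self.assay_id!r}: grid/fluorescence length mismatch")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError(f"assay {self.assay_id!r}: temperatures must be strictly increasing")


def count_melt_peaks(
    curve: MeltCurve,
    prominence_fraction: float = 0.2,
    smooth_window: int = 3,
) -> int:
    """Count melt peaks: local maxima of -dF/dT above a prominence threshold.

    Fluorescence is smoothed by a centered moving average (default 3 grid
    points) before differentiation.  A peak is kept when its prominence is at
    least ``prominence_fraction`` of the tallest peak's height, so small
    ripples riding on a dominant melt transition are not counted.  Assays
    with more than one peak indicate non-specific amplification and should be
    excluded downstream.
    """
    if len(curve.temperatures) < MIN_MELT_POINTS:
        raise ValueError(
            f"assay {curve.assay_id!r}: need >= {MIN_MELT_POINTS} grid points, "
            f"got {len(curve.temperatures)}"
        )
    smoothed = (
        pd.Series(curve.fluorescence)
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    neg_deriv = -np.gradient(smoothed, curve.temperatures)
    peaks, props = find_peaks(neg_deriv, prominence=0.0)
    if len(peaks) == 0:
        return 0
    threshold = prominence_fraction * float(neg_deriv[peaks].max())
    return int(np.sum(props["prominences"] >= threshold))


@dataclass
class NormalizationModel:
    """Per-sample smooth offset maps and the shared target quantile vector.

    ``offset_grids`` maps sample -> (signal grid, additive offset at grid).
    Offsets are interpolated linearly within the fitted range and held
    constant outside it (boundary clamping), so the full map ``x + offset(x)``
    stays non-decreasing everywhere.
    """

    target_quantiles: np.ndarray
    anchor_probs: np.ndarray
    offset_grids: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def offset(self, sample: str, values: np.ndarray) -> np.ndarray:
        grid, off = self.offset_grids[sample]
        return np.interp(values, grid, off)

    def to_dict(self) -> dict:
        return {
            "target_quantiles": self.target_quantiles.tolist(),
            "anchor_probs": self.anchor_probs.tolist(),
            "offset_grids": {
                s: {"grid": g.tolist(), "offset": o.tolist()}
                for s, (g, o) in self.offset_grids.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        return cls(
            target_quantiles=np.asarray(d["target_quantiles"], dtype=float),
            anchor_probs=np.asarray(d["anchor_probs"], dtype=float),
            offset_grids={
                s: (np.asarray(g["grid"], dtype=float), np.asarray(g["offset"], dtype=float))
                for s, g in d["offset_grids"].items()
            },
        )


def _monotone_offsets(x: np.ndarray, raw_offsets: np.ndarray, grid_size: int = 256):
    """Smooth offsets vs. signal, then isotonize the implied map x + offset(x)."""
    order = np.argsort(x)
    x_s, off_s = x[order], raw_offsets[order]
    # collapse duplicate abscissae (identical quantiles) by averaging
    ux, inverse = np.unique(x_s, return_inverse=True)
    uoff = np.bincount(inverse, weights=off_s) / np.bincount(inverse)
    grid = np.linspace(ux[0], ux[-1], grid_size)
    if len(ux) >= 4:
        spline = make_smoothing_spline(ux, uoff)  # smoothing chosen by GCV
        off_grid = spline(grid)
    else:  # degenerate sample: fall back to linear interpolation
        off_grid = np.interp(grid, ux, uoff)
    mapped = isotonic_regression(grid + off_grid).x
    return grid, mapped - grid


def fit_qspline(
    cp: pd.DataFrame,
    target: np.ndarray | str = "mean",
    n_anchors: int = 101,
) -> NormalizationModel:
    """Fit the signal-dependent quantile-spline normalization model.

    For each sample, offsets are computed at a ladder of quantile anchors as
    (target quantile - sample quantile) and a cubic smoothing spline (GCV
    smoothing) interpolates offset versus Cp signal.  The target distribution
    defaults to the across-sample mean of per-sample quantiles.

    Parameters
    ----------
    cp : feature x sample Cp matrix; NaN marks undetected assays.
    target : "mean" or an explicit quantile vector of length ``n_anchors``.
    n_anchors : number of quantile anchors (default 101).
    """
    if cp.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    detected = cp.notna().sum(axis=0)
    for sample, n in detected.items():
        if n < MIN_DETECTED_FEATURES:
            raise ValueError(
                f"sample {sample!r} has only {n} detected features "
                f"(need >= {MIN_DETECTED_FEATURES})"
            )
    probs = np.linspace(0.0, 1.0, n_anchors)
    quantiles = np.column_stack(
        [np.nanquantile(cp[s].to_numpy(dtype=float), probs) for s in cp.columns]
    )
    if isinstance(target, str):
        if target != "mean":
            raise ValueError(f"unknown target {target!r}")
        target_q = quantiles.mean(axis=1)
    else:
        target_q = np.asarray(target, dtype=float)
        if target_q.shape != probs.shape:
            raise ValueError("explicit target must have one value per anchor")
    model = NormalizationModel(target_quantiles=target_q, anchor_probs=probs)
    for j, sample in enumerate(cp.columns):
        x = quantiles[:, j]
        grid, off = _monotone_offsets(x, target_q - x)
        model.offset_grids[str(sample)] = (grid, off)
    return model


def apply_normalization(cp: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Add each sample's fitted offset to its raw Cp values.

    Missing values stay missing.  Values outside the fitted signal range
    receive the boundary offset (clamped extrapolation).
    """
    out = cp.copy().astype(float)
    for sample in cp.columns:
        key = str(sample)
        if key not in model.offset_grids:
            raise KeyError(f"model has no offset map for sample {sample!r}")
        vals = out[sample].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        vals[mask] = vals[mask] + model.offset(key, vals[mask])
        out[sample] = vals
    return out


def _mean_sem(cp: pd.DataFrame, condition_map: dict[str, str]) -> float:
    sems = []
    conditions = sorted(set(condition_map.values()))
    for cond in conditions:
        samples = [s for s in cp.columns if condition_map.get(s) == cond]
        if len(samples) < 2:
            continue
        sub = cp[samples]
        n = sub.notna().sum(axis=1)
        sd = sub.std(axis=1, ddof=1)
        sem = (sd / np.sqrt(n))[n >= 2]
        sems.append(sem.dropna())
    if not sems:
        raise ValueError("no condition has >= 2 replicate samples")
    return float(pd.concat(sems).mean())


def sem_reduction(
    raw: pd.DataFrame,
    normalized: pd.DataFrame,
    condition_map: dict[str, str],
) -> float:
    """Percent reduction in mean replicate standard error after normalization.

    Averages the per-(feature, condition) SEM over all replicated conditions
    and returns ``100 * (1 - after / before)``.
    """
    before = _mean_sem(raw, condition_map)
    after = _mean_sem(normalized, condition_map)
    if before == 0:
        return 0.0
    return 100.0 * (1.0 - after / before)
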