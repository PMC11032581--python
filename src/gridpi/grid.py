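"""Directionally modulated (grid-code) GLM analysis of an ROI time series.

The analysis quantifies n-fold rotational symmetry (6-fold for grid-cell-
like signal) in how an ROI's BOLD response depends on movement heading:

1. On the *estimation* partition of translation events (odd/even
   interleaved by default), a GLM with parametric sin(n*phi) and cos(n*phi)
   modulators is fit per voxel; the voxel orientation is
   theta_v = atan2(beta_sin, beta_cos) / n, reported in [0, 360/n).
2. On the held-out *test* partition, a GLM with a single aligned modulator
   cos(n*(phi - theta_hat)) quantifies the *magnitude* of grid-code signal
   at the ROI-mean orientation theta_hat. Magnitude may legitimately be
   negative (anti-aligned or unstable orientations).

Secondary metrics: *spatial stability* (Rayleigh test of voxel orientations
mapped to the full circle), *temporal stability* (percentage of voxels
whose orientation changes by less than 15 degrees between the first and
second temporal halves of the run; chance is 50% in 60-degree space), tSNR,
and control symmetries (1-, 4-, 5-, 7-fold re-runs of the whole pipeline).

The model/results API follows the statsmodels convention:
``GridDirectionModel(series, events, n_fold=6).fit()`` returns a
:class:`GridDirectionResults` carrying estimates and diagnostics, with a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pingouin import circ_rayleigh
from scipy import stats

from ._angles import circular_mean_deg, wrap_to_period
from .events import EventTable
from .hrf import convolve_events

__all__ = [
    "RoiTimeSeries",
    "build_design",
    "estimate_orientation",
    "quantify_magnitude",
    "spatial_stability",
    "temporal_stability",
    "control_symmetries",
    "tsnr",
    "group_stats",
    "GridDirectionModel",
    "GridDirectionResults",
]

#: GLM1 parameter count (event boxcar, sin and cos modulators, intercept);
#: nuisance columns come on top of these.
N_TASK_PARAMS = 4

TEMPORAL_STABILITY_THRESHOLD_DEG = 15.0


@dataclass
class RoiTimeSeries:
    """Voxels-by-timepoints ROI signal matrix plus nuisance regressors."""

    data: np.ndarray  # (n_voxels, n_timepoints)
    tr_s: float
    voxel_ids: np.ndarray | None = None
    nuisance: np.ndarray | None = None  # (n_timepoints, k), e.g. motion

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.data.shape[0])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.size != self.data.shape[0]:
                raise ValueError("voxel_ids must match the number of voxels")
        if self.nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if self.nuisance.shape[0] != self.data.shape[1]:
                raise ValueError(
                    "nuisance must have one row per timepoint "
                    f"({self.nuisance.shape[0]} != {self.data.shape[1]})"
                )
        constant = np.ptp(self.data, axis=1) == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} all-constant voxel row(s) flagged; "
                "they are excluded from orientation statistics",
                stacklevel=2,
            )
        self.valid_voxels = ~constant

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def build_design(
    events: EventTable,
    n_fold: int,
    tr_s: float,
    n_timepoints: int,
    nuisance: np.ndarray | None = None,
    hrf: str = "spm",
    aligned_orientation_deg: float | None = None,
):
    """Design matrix for the directional GLMs, with column names.

    Without an aligned orientation the task columns are the event boxcar
    plus mean-centered sin(n*phi) and cos(n*phi) parametric modulators
    (GLM1); with one, a single mean-centered cos(n*(phi - theta_hat))
    modulator (GLM2). All task columns are convolved with the canonical
    response function and sampled at the TR; nuisance regressors and an
    intercept are appended unconvolved. Raises ``ValueError`` on a
    rank-deficient design, naming the collinear columns.
    """
    if len(events) == 0:
        raise ValueError("cannot build a design from an empty event table")
    if events.onset_s[-1] + events.duration_s[-1] > n_timepoints * tr_s:
        raise ValueError("events extend beyond the scan duration")
    phi = np.radians(events.heading_deg)
    cols, names = [], []
    box = convolve_events(
        events.onset_s, events.duration_s, np.ones(len(events)), tr_s, n_timepoints, hrf
    )
    cols.append(box)
    names.append("boxcar")
    if aligned_orientation_deg is None:
        for fn, nm in ((np.sin, "sin"), (np.cos, "cos")):
            mod = fn(n_fold * phi)
            mod = mod - mod.mean()
            cols.append(
                convolve_events(
                    events.onset_s, events.duration_s, mod, tr_s, n_timepoints, hrf
                )
            )
            names.append(f"{nm}({n_fold}*phi)")
    else:
        mod = np.cos(n_fold * (phi - np.radians(aligned_orientation_deg)))
        mod = mod - mod.mean()
        cols.append(
            convolve_events(
                events.onset_s, events.duration_s, mod, tr_s, n_timepoints, hrf
            )
        )
        names.append(f"cos({n_fold}*(phi-theta_hat))")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(f"nuisance{k}")
    cols.append(np.ones(n_timepoints))
    names.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        culprits = _collinear_columns(X, names)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear/degenerate columns: {culprits}"
        )
    return X, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = {names[i] for i in range(X.shape[1]) if np.ptp(X[:, i]) == 0 and names[i] != "intercept"}
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    ok = sd > 0
    Zn = Z[:, ok] / sd[ok]
    corr = Zn.T @ Zn / X.shape[0]
    idx = np.array(names, dtype=object)[ok]
    for i in range(corr.shape[0]):
        for j in range(i + 1, corr.shape[1]):
            if abs(corr[i, j]) > 0.999:
                bad.update((idx[i], idx[j]))
    return sorted(bad) or ["<unidentified>"]


def _fit_glm(
    series: RoiTimeSeries,
    events: EventTable,
    n_fold: int,
    hrf: str,
    aligned_orientation_deg: float | None = None,
    other_events: EventTable | None = None,
) -> dict:
    """Per-voxel OLS of the directional GLM for one event set.

    ``other_events`` (the held-out partition) are modeled as regressors of
    no interest — their own boxcar plus sin/cos modulators — so their
    overlapping hemodynamic responses do not bias the estimates of the
    partition under analysis.
    """
    n_params = N_TASK_PARAMS if aligned_orientation_deg is None else 3
    if series.nuisance is not None:
        n_params += series.nuisance.shape[1]
    if len(events) < n_params:
        raise ValueError(
            f"only {len(events)} events for a {n_params}-parameter GLM"
        )
    X, names = build_design(
        events,
        n_fold,
        series.tr_s,
        series.n_timepoints,
        nuisance=series.nuisance,
        hrf=hrf,
        aligned_orientation_deg=aligned_orientation_deg,
    )
    if other_events is not None and len(other_events) > 0:
        Xo, names_o = build_design(
            other_events, n_fold, series.tr_s, series.n_timepoints, hrf=hrf
        )
        keep = [i for i, nm in enumerate(names_o) if nm != "intercept"]
        X = np.column_stack([X, Xo[:, keep]])
        names = names + [f"other:{names_o[i]}" for i in keep]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient composite design (rank {rank} < {X.shape[1]}); "
                f"collinear columns: {_collinear_columns(X, names)}"
            )
    betas, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    return {"betas": betas, "names": names}


@dataclass
class OrientationEstimate:
    """Per-voxel orientations (deg, in [0, 360/n)) with amplitude weights."""

    theta_v: np.ndarray
    weights: np.ndarray
    roi_mean_deg: float
    n_fold: int


def _orientations_from_betas(betas: np.ndarray, names: list[str], n_fold: int):
    b_sin = betas[names.index(f"sin({n_fold}*phi)")]
    b_cos = betas[names.index(f"cos({n_fold}*phi)")]
    theta = np.degrees(np.arctan2(b_sin, b_cos)) / n_fold % (360.0 / n_fold)
    return theta, np.hypot(b_sin, b_cos)


def estimate_orientation(
    series: RoiTimeSeries,
    events: EventTable,
    n_fold: int = 6,
    partition: str = "estimation",
    weighted: bool = True,
    hrf: str = "spm",
) -> OrientationEstimate:
    """GLM1: per-voxel orientations and the ROI mean orientation.

    The ROI mean is the circular mean of n*theta_v (mapped back to
    [0, 360/n)), amplitude-weighted by sqrt(beta_sin^2 + beta_cos^2) unless
    ``weighted=False``.
    """
    other = "test" if partition == "estimation" else "estimation"
    fit = _fit_glm(
        series, events.half(partition), n_fold, hrf,
        other_events=events.half(other),
    )
    theta, amp = _orientations_from_betas(fit["betas"], fit["names"], n_fold)
    valid = series.valid_voxels
    w = amp[valid] if weighted else None
    roi_mean = circular_mean_deg(n_fold * theta[valid], weights=w) / n_fold
    return OrientationEstimate(theta, amp, roi_mean % (360.0 / n_fold), n_fold)


def quantify_magnitude(
    series: RoiTimeSeries,
    events: EventTable,
    orientation_deg: float,
    n_fold: int = 6,
    partition: str = "test",
    hrf: str = "spm",
):
    """GLM2: cross-validated grid-code magnitude at the estimated orientation.

    Fits the aligned regressor cos(n*(phi - theta_hat)) on the held-out
    partition; returns (roi mean beta, per-voxel betas). Negative values
    are reported as-is.
    """
    other = "test" if partition == "estimation" else "estimation"
    fit = _fit_glm(
        series,
        events.half(partition),
        n_fold,
        hrf,
        aligned_orientation_deg=orientation_deg,
        other_events=events.half(other),
    )
    voxel_betas = fit["betas"][fit["names"].index(f"cos({n_fold}*(phi-theta_hat))")]
    return float(np.mean(voxel_betas[series.valid_voxels])), voxel_betas


def spatial_stability(theta_v: np.ndarray, n_fold: int = 6):
    """Rayleigh test of voxel-orientation coherence.

    Orientations are mapped to the full circle (multiplied by n) before the
    test. Returns (resultant length R, Rayleigh z, p).
    """
    theta_v = np.asarray(theta_v, dtype=float)
    if theta_v.size < 2:
        raise ValueError("spatial stability needs at least 2 voxels")
    alpha = np.radians(n_fold * theta_v)
    r = float(np.hypot(np.mean(np.sin(alpha)), np.mean(np.cos(alpha))))
    z, p = circ_rayleigh(alpha)
    return r, float(z), float(p)


def temporal_stability(
    series: RoiTimeSeries,
    events: EventTable,
    n_fold: int = 6,
    threshold_deg: float = TEMPORAL_STABILITY_THRESHOLD_DEG,
    hrf: str = "spm",
) -> float:
    """Percentage of voxels with orientation change < 15 degrees between the
    first and second temporal halves of the run.

    With independent uniform orientations the expected value is 50% (the
    change is uniform on [0, 180/n] degrees in n-fold space), which is the
    chance level the group test compares against.
    """
    first, second = events.temporal_halves()
    t1 = _voxel_orientations(series, first, n_fold, hrf, other=second)
    t2 = _voxel_orientations(series, second, n_fold, hrf, other=first)
    delta = wrap_to_period(t1 - t2, 360.0 / n_fold)
    valid = series.valid_voxels
    return float(100.0 * np.mean(np.abs(delta[valid]) < threshold_deg))


def _voxel_orientations(series, events, n_fold, hrf, other=None):
    fit = _fit_glm(series, events, n_fold, hrf, other_events=other)
    theta, _ = _orientations_from_betas(fit["betas"], fit["names"], n_fold)
    return theta


def tsnr(series: RoiTimeSeries):
    """Temporal SNR: voxel-wise mean time series divided by its SD.

    Returns (per-voxel tsnr with NaN for zero-variance voxels, ROI mean
    over valid voxels). Zero-variance voxels are excluded with a warning.
    """
    mean = series.data.mean(axis=1)
    sd = series.data.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance voxel(s) excluded from tSNR",
            stacklevel=2,
        )
    out = np.where(zero, np.nan, mean / np.where(zero, 1.0, sd))
    return out, float(np.nanmean(out))


class GridDirectionModel:
    """n-fold directional-modulation model for one ROI run.

    Parameters
    ----------
    series : RoiTimeSeries
        Voxels-by-timepoints matrix with TR and optional nuisance matrix.
    events : EventTable
        Translation events with headings; the odd/even partition drives
        the estimation/test cross-validation.
    n_fold : int
        Rotational symmetry to quantify (6 = grid-cell-like).
    """

    def __init__(
        self,
        series: RoiTimeSeries,
        events: EventTable,
        n_fold: int = 6,
        hrf: str = "spm",
        weighted_mean: bool = True,
    ) -> None:
        self.series = series
        self.events = events
        self.n_fold = int(n_fold)
        self.hrf = hrf
        self.weighted_mean = weighted_mean

    def fit(self) -> "GridDirectionResults":
        est = estimate_orientation(
            self.series,
            self.events,
            self.n_fold,
            weighted=self.weighted_mean,
            hrf=self.hrf,
        )
        magnitude, voxel_mags = quantify_magnitude(
            self.series, self.events, est.roi_mean_deg, self.n_fold, hrf=self.hrf
        )
        return GridDirectionResults(model=self, orientation=est,
                                    magnitude=magnitude, voxel_magnitudes=voxel_mags)


@dataclass
class GridDirectionResults:
    """Fitted grid-code metrics for one ROI/participant/run."""

    model: GridDirectionModel
    orientation: OrientationEstimate
    magnitude: float
    voxel_magnitudes: np.ndarray

    @property
    def n_fold(self) -> int:
        return self.model.n_fold

    @property
    def mean_orientation_deg(self) -> float:
        return self.orientation.roi_mean_deg

    @property
    def orientations_deg(self) -> np.ndarray:
        return self.orientation.theta_v

    @property
    def preferred_direction_deg(self) -> float:
        """Full-circle preferred direction; meaningful for n_fold == 1."""
        return self.mean_orientation_deg % 360.0

    def spatial_stability(self):
        valid = self.model.series.valid_voxels
        return spatial_stability(self.orientation.theta_v[valid], self.n_fold)

    def temporal_stability(
        self, threshold_deg: float = TEMPORAL_STABILITY_THRESHOLD_DEG
    ) -> float:
        return temporal_stability(
            self.model.series,
            self.model.events,
            self.n_fold,
            threshold_deg=threshold_deg,
            hrf=self.model.hrf,
        )

    def tsnr(self):
        return tsnr(self.model.series)

    def metrics(self) -> dict:
        """Flat dict of the standard outcome metrics."""
        r, z, p = self.spatial_stability()
        _, roi_tsnr = self.tsnr()
        return {
            "n_fold": self.n_fold,
            "magnitude": self.magnitude,
            "mean_orientation_deg": self.mean_orientation_deg,
            "spatial_resultant": r,
            "spatial_rayleigh_z": z,
            "spatial_rayleigh_p": p,
            "temporal_stability_pct": self.temporal_stability(),
            "tsnr": roi_tsnr,
        }

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            f"{self.n_fold}-fold directional modulation "
            f"({self.model.series.n_voxels} voxels, "
            f"{len(self.model.events)} events)",
            "-" * 58,
            f"magnitude (cross-validated beta) {m['magnitude']:12.4f}",
            f"mean orientation [0, {360 // self.n_fold}) deg"
            f"{m['mean_orientation_deg']:17.2f}",
            f"spatial stability Rayleigh z     {m['spatial_rayleigh_z']:12.3f}"
            f"  (p = {m['spatial_rayleigh_p']:.3g})",
            f"temporal stability (< 15 deg)    {m['temporal_stability_pct']:11.1f}%"
            "  (chance 50%)",
            f"ROI mean tSNR                    {m['tsnr']:12.2f}",
        ]
        return "\n".join(lines)

    def plot_orientations(self, ax=None):
        """Rose plot of voxel orientations in n-fold space (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        angles = np.radians(self.n_fold * self.orientations_deg)
        ax.hist(angles, bins=24)
        ax.set_title(f"{self.n_fold}-fold voxel orientations (x{self.n_fold})")
        return ax


def control_symmetries(
    series: RoiTimeSeries,
    events: EventTable,
    folds=(1, 4, 5, 7),
    hrf: str = "spm",
    weighted_mean: bool = True,
) -> dict[int, GridDirectionResults]:
    """Re-run the full pipeline at control symmetries.

    4-, 5- and 7-fold magnitudes act as specificity controls for a 6-fold
    signal; 1-fold indexes a unidirectional (head-direction-like) signal,
    for which ``preferred_direction_deg`` spans the full circle.
    """
    return {
        int(n): GridDirectionModel(
            series, events, n_fold=int(n), hrf=hrf, weighted_mean=weighted_mean
        ).fit()
        for n in folds
    }


def group_stats(
    metrics: pd.DataFrame,
    group_col: str | None = None,
    continuous_cols: tuple = (),
    chance_temporal: float = 50.0,
) -> dict[str, pd.DataFrame]:
    """Group-level tests over per-participant grid metrics.

    One-sample t tests (magnitude and spatial Rayleigh z against 0,
    temporal stability against the 50% chance level), Welch two-sample t
    tests for a binary grouping column, and Pearson correlations with
    continuous covariates. Requires n >= 3 participants.
    """
    if len(metrics) < 3:
        raise ValueError("group statistics need at least 3 participants")
    one_sample = []
    for col, null in (
        ("magnitude", 0.0),
        ("spatial_rayleigh_z", 0.0),
        ("temporal_stability_pct", chance_temporal),
    ):
        if col in metrics:
            x = metrics[col].dropna()
            if np.ptp(x) == 0:  # degenerate: no sampling variability
                t, p = (0.0, 1.0) if x.iloc[0] == null else (np.inf, 0.0)
            else:
                t, p = stats.ttest_1samp(x, null)
            one_sample.append(
                {"metric": col, "null": null, "mean": x.mean(),
                 "t": float(t), "df": len(x) - 1, "p": float(p)}
            )
    out = {"one_sample": pd.DataFrame(one_sample)}
    if group_col is not None:
        rows = []
        levels = metrics[group_col].dropna().unique()
        if len(levels) != 2:
            raise ValueError("Welch t tests need a binary grouping column")
        a = metrics[metrics[group_col] == levels[0]]
        b = metrics[metrics[group_col] == levels[1]]
        for col in ("magnitude", "spatial_rayleigh_z", "temporal_stability_pct"):
            if col in metrics:
                t, p = stats.ttest_ind(
                    a[col].dropna(), b[col].dropna(), equal_var=False
                )
                rows.append({"metric": col, "group": group_col,
                             "t": float(t), "p": float(p)})
        out["welch"] = pd.DataFrame(rows)
    if continuous_cols:
        rows = []
        for cov in continuous_cols:
            for col in ("magnitude", "spatial_rayleigh_z", "temporal_stability_pct"):
                if col in metrics:
                    sub = metrics[[col, cov]].dropna()
                    r, p = stats.pearsonr(sub[col], sub[cov])
                    rows.append({"metric": col, "covariate": cov,
                                 "r": float(r), "p": float(p)})
        out["pearson"] = pd.DataFrame(rows)
    return out
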