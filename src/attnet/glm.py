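"""Finite-impulse-response (deconvolution) GLM for task runs.

One predictor per post-onset volume per condition, over a 20 s window at
TR = 2 s (10 lags per condition), plus intercept and linear drift.  The
response-shape betas are estimated by ordinary least squares without assuming
a hemodynamic response function; condition contrasts average the four
lag-betas bracketing the response peak (the 2-8 s lags by default) and are
tested against baseline with a t statistic per unit, thresholded by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import fdr_bh


@dataclass(frozen=True)
class FirDesignSpec:
    tr: float = 2.0
    window_seconds: float = 20.0
    conditions: tuple[str, ...] = ("OD", "TOJ")
    peak_lag_seconds: float = 4.0
    peak_window_volumes: int = 4

    def __post_init__(self) -> None:
        n_lags = self.window_seconds / self.tr
        if abs(n_lags - round(n_lags)) > 1e-9:
            raise ValueError("window_seconds must be an integer multiple of tr")
        if self.peak_window_volumes > self.n_lags:
            raise ValueError("peak window exceeds the lag range")

    @property
    def n_lags(self) -> int:
        return int(round(self.window_seconds / self.tr))

    def peak_lags(self) -> list[int]:
        """The ``peak_window_volumes`` lags bracketing the peak.

        Default (peak at 4 s, 4 volumes, TR 2 s) selects lags 1-4, i.e. the
        2-8 s window around the hemodynamic peak.
        """
        peak_idx = self.peak_lag_seconds / self.tr
        lags = sorted(
            range(self.n_lags),
            key=lambda l: (abs(l - peak_idx), -l),  # prefer later lag on ties
        )[: self.peak_window_volumes]
        lags = sorted(lags)
        if any(l < 0 or l >= self.n_lags for l in lags):
            raise ValueError("peak window falls outside the lag range")
        return lags


def validate_events(events: pd.DataFrame, n_frames: int, spec: FirDesignSpec) -> pd.DataFrame:
    ev = events.copy()
    if not {"onset_frame", "condition"} <= set(ev.columns):
        raise ValueError("events need columns onset_frame and condition")
    if (ev["onset_frame"] < 0).any() or (ev["onset_frame"] >= n_frames).any():
        raise ValueError("event onsets must lie within the run")
    unknown = set(ev["condition"]) - set(spec.conditions)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    return ev.sort_values("onset_frame").reset_index(drop=True)


def build_fir_design(
    events: pd.DataFrame,
    spec: FirDesignSpec,
    n_frames: int,
    *,
    add_drift: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """FIR design matrix: one column per (condition, lag) plus baseline columns.

    Entry (onset + lag, column(condition, lag)) is 1; events whose window
    runs past the end of the run are truncated with a warning.  Returns the
    matrix and its column names (FIR columns first, then ``intercept`` and
    ``drift``).
    """
    import warnings

    ev = validate_events(events, n_frames, spec)
    names = [f"{c}_lag{l}" for c in spec.conditions for l in range(spec.n_lags)]
    X = np.zeros((n_frames, len(names)))
    col = {name: j for j, name in enumerate(names)}
    truncated = 0
    for _, row in ev.iterrows():
        onset = int(row["onset_frame"])
        for l in range(spec.n_lags):
            t = onset + l
            if t >= n_frames:
                truncated += 1
                break
            X[t, col[f"{row['condition']}_lag{l}"]] = 1.0
    if truncated:
        warnings.warn(
            f"{truncated} event window(s) truncated at the end of the run",
            RuntimeWarning,
            stacklevel=2,
        )
    baseline = [np.ones(n_frames)]
    base_names = ["intercept"]
    if add_drift:
        drift = np.linspace(-1.0, 1.0, n_frames)
        baseline.append(drift)
        base_names.append("drift")
    X = np.hstack([X] + [b[:, None] for b in baseline])
    return X, names + base_names


@dataclass
class GlmFit:
    betas: np.ndarray  # regressors x units
    column_names: list[str]
    residual_variance: np.ndarray  # per unit, df-adjusted
    df_resid: int
    xtx_inv: np.ndarray


def fit_glm(data: np.ndarray, design: np.ndarray, column_names: list[str] | None = None) -> GlmFit:
    """Ordinary least squares betas per unit, with residual variance.

    Raises on rank deficiency, listing the collinear columns.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    X = np.asarray(design, dtype=float)
    if data.shape[0] != X.shape[0]:
        raise ValueError("data and design must share the frame count")
    names = column_names or [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns greedily
        keep: list[int] = []
        bad: list[str] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ beta
    df_resid = X.shape[0] - X.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmFit(
        betas=beta,
        column_names=names,
        residual_variance=sigma2,
        df_resid=df_resid,
        xtx_inv=xtx_inv,
    )


@dataclass
class ContrastResult:
    condition: str
    estimate: np.ndarray  # per unit
    t: np.ndarray
    p: np.ndarray
    df: int
    peak_lags: list[int]


def contrast_peak(fit: GlmFit, spec: FirDesignSpec, condition: str) -> ContrastResult:
    """Mean of the peak-window lag betas versus baseline, with per-unit t.

    The contrast vector places 1/4 on each of the four peak-window lags of
    ``condition`` and 0 elsewhere; the t statistic uses the unit's residual
    variance and the design's (X'X)^-1.
    """
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    lags = spec.peak_lags()
    c = np.zeros(len(fit.column_names))
    for l in lags:
        name = f"{condition}_lag{l}"
        if name not in fit.column_names:
            raise ValueError(f"column {name!r} missing from the fit")
        c[fit.column_names.index(name)] = 1.0 / len(lags)
    est = c @ fit.betas
    var_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.residual_variance * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    return ContrastResult(
        condition=condition, estimate=est, t=t, p=p, df=fit.df_resid, peak_lags=lags
    )


def threshold_map(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    mask, _ = fdr_bh(p, q)
    return mask


def lag_profile(fit: GlmFit, spec: FirDesignSpec, condition: str) -> np.ndarray:
    """The estimated lags x units response profile for one condition."""
    rows = [fit.column_names.index(f"{condition}_lag{l}") for l in range(spec.n_lags)]
    return fit.betas[rows]
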