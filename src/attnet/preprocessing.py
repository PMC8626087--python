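"""Censoring-aware cleaning of ROI BOLD time series.

The pipeline mirrors a motion-robust resting-state workflow: drop initial
non-steady-state volumes, regress out 12 motion regressors (6 realignment
parameters + first derivatives) and a ventricle signal, detrend, flag
high-motion frames by framewise displacement, fill censored frames with a
least-squares spectral (Lomb-Scargle-style) fit so a band-pass filter can be
applied to a regularly sampled series, band-pass 0.009-0.08 Hz, and finally
delete the censored frames again.  Runs keep an ordered provenance trail and
the stage order is enforced: running a stage after a later one raises.

Motion tables are 6-column frames x (trans_x, trans_y, trans_z, rot_x, rot_y,
rot_z) with translations in mm and rotations in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

#: canonical stage order; each op may be skipped but never run out of order
STAGE_ORDER = [
    "drop_initial",
    "nuisance_regression",
    "detrend",
    "lssd_interpolate",
    "bandpass",
    "censor_removed",
]

#: head-radius (mm) used to convert rotation (radians) to displacement
FD_ROTATION_RADIUS_MM = 50.0


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was applied out of canonical order."""


@dataclass
class RunTimeSeries:
    """A frames x ROIs matrix with sampling interval, censor mask and provenance.

    ``censor_mask`` is True for *retained* frames.
    """

    data: np.ndarray
    tr: float
    roi_names: list[str] = field(default_factory=list)
    censor_mask: np.ndarray | None = None
    steps_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x ROIs)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_frames, dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (self.n_frames,):
            raise ValueError("censor_mask length must equal frame count")
        if not self.roi_names:
            self.roi_names = [f"roi{i}" for i in range(self.data.shape[1])]
        if len(self.roi_names) != self.data.shape[1]:
            raise ValueError("roi_names length must equal ROI count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.censor_mask.sum())

    def with_step(self, data: np.ndarray, step: str, *, censor_mask=None) -> "RunTimeSeries":
        return RunTimeSeries(
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            roi_names=list(self.roi_names),
            censor_mask=self.censor_mask.copy() if censor_mask is None else censor_mask,
            steps_applied=self.steps_applied + [step],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.roi_names)


def _require_stage(run: RunTimeSeries, stage: str) -> None:
    rank = STAGE_ORDER.index(stage)
    for applied in run.steps_applied:
        if applied in STAGE_ORDER and STAGE_ORDER.index(applied) >= rank:
            raise PipelineOrderError(
                f"cannot apply {stage!r} after {applied!r}; canonical order is "
                + " -> ".join(STAGE_ORDER)
            )


@dataclass
class NuisanceSet:
    """12 motion-derived regressors plus one ventricle (global) signal."""

    motion: np.ndarray
    motion_derivatives: np.ndarray
    ventricle_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        self.motion_derivatives = np.atleast_2d(
            np.asarray(self.motion_derivatives, dtype=float)
        )
        self.ventricle_signal = np.asarray(self.ventricle_signal, dtype=float).reshape(-1, 1)
        if self.motion.shape[1] != 6 or self.motion_derivatives.shape[1] != 6:
            raise ValueError("motion and derivatives must each have 6 columns")
        n = self.motion.shape[0]
        if self.motion_derivatives.shape[0] != n or self.ventricle_signal.shape[0] != n:
            raise ValueError("nuisance tables must share the frame count")

    @property
    def n_frames(self) -> int:
        return self.motion.shape[0]

    def design(self) -> np.ndarray:
        """Frames x 13 matrix: 12 motion regressors + ventricle signal."""
        return np.hstack([self.motion, self.motion_derivatives, self.ventricle_signal])

    def sliced(self, idx) -> "NuisanceSet":
        return NuisanceSet(
            motion=self.motion[idx],
            motion_derivatives=self.motion_derivatives[idx],
            ventricle_signal=self.ventricle_signal[idx],
        )


@dataclass(frozen=True)
class CensorConfig:
    """Frame- and run-level motion exclusion rules.

    ``fd_threshold`` is the framewise-displacement scrub threshold in mm
    (a declared default; the frame-level criterion is a pipeline choice).
    ``run_discard_mm`` is the per-dimension instantaneous motion that discards
    a whole run.  ``min_retained_seconds`` is the minimum data worth keeping
    a run (3 min), boundary inclusive.
    """

    fd_threshold: float = 0.5
    run_discard_mm: float = 3.0
    initial_volumes_dropped: int = 4
    min_retained_seconds: float = 180.0

    def __post_init__(self) -> None:
        if min(self.fd_threshold, self.run_discard_mm, self.min_retained_seconds) <= 0:
            raise ValueError("censor thresholds must be positive")
        if self.initial_volumes_dropped < 0:
            raise ValueError("initial_volumes_dropped must be >= 0")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification (Hz) plus the spectral-fit oversampling factor."""

    low_hz: float = 0.009
    high_hz: float = 0.08
    basis_oversampling: int = 8
    butter_order: int = 4

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must lie inside "
                f"(0, Nyquist={nyquist:g}) Hz at TR={tr} s"
            )


def drop_initial_volumes(
    run: RunTimeSeries,
    config: CensorConfig,
    motion: pd.DataFrame | None = None,
):
    """Remove the first ``initial_volumes_dropped`` frames (non-steady-state).

    Trims data, censor mask and (if given) the motion table consistently.
    Returns the trimmed run, or ``(run, motion)`` when a motion table is given.
    """
    _require_stage(run, "drop_initial")
    k = config.initial_volumes_dropped
    if run.n_frames <= k:
        raise ValueError(f"run has {run.n_frames} frames; cannot drop {k}")
    out = run.with_step(run.data[k:], "drop_initial", censor_mask=run.censor_mask[k:].copy())
    if motion is None:
        return out
    return out, motion.iloc[k:].reset_index(drop=True)


def build_nuisance_set(
    motion: pd.DataFrame | np.ndarray,
    ventricle_signal: np.ndarray | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> NuisanceSet:
    """Assemble the 13-column nuisance set from a 6-column motion table.

    Derivatives are backward differences with the first frame set to 0.  When
    no ventricle signal is supplied one is generated (synthetic mode) from
    ``rng``, or set to zeros if no generator is given.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {m.shape}")
    deriv = np.zeros_like(m)
    deriv[1:] = np.diff(m, axis=0)
    if ventricle_signal is None:
        if rng is not None:
            ventricle_signal = rng.standard_normal(m.shape[0])
        else:
            ventricle_signal = np.zeros(m.shape[0])
    return NuisanceSet(motion=m, motion_derivatives=deriv, ventricle_signal=ventricle_signal)


def regress_nuisance(run: RunTimeSeries, nuisance: NuisanceSet) -> RunTimeSeries:
    """Residualize the series against [intercept | 13 nuisance regressors].

    Collinear columns are dropped (with a warning) so the projection is well
    defined; residuals are orthogonal to every retained regressor.
    """
    import warnings

    _require_stage(run, "nuisance_regression")
    if nuisance.n_frames != run.n_frames:
        raise ValueError(
            f"nuisance has {nuisance.n_frames} frames but run has {run.n_frames}"
        )
    X = np.hstack([np.ones((run.n_frames, 1)), nuisance.design()])
    # drop collinear columns by greedy rank check (intercept always kept)
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} collinear nuisance column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, run.data, rcond=None)
    resid = run.data - Xk @ beta
    return run.with_step(resid, "nuisance_regression")


def detrend(run: RunTimeSeries) -> RunTimeSeries:
    """Remove the per-ROI least-squares linear trend."""
    _require_stage(run, "detrend")
    if run.n_frames < 3:
        raise ValueError("detrend needs at least 3 frames")
    out = signal.detrend(run.data, axis=0, type="linear")
    return run.with_step(out, "detrend")


def framewise_displacement(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Power-style FD: sum |delta translations| + 50 mm * sum |delta rotations|."""
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    d = np.zeros_like(m)
    d[1:] = np.diff(m, axis=0)
    return np.abs(d[:, :3]).sum(axis=1) + FD_ROTATION_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)


def compute_censoring(motion: pd.DataFrame | np.ndarray, config: CensorConfig):
    """Frame scrubbing mask plus whole-run discard flag.

    Returns ``(censor_mask, run_discard_flag)``: the mask is True for retained
    frames (FD <= fd_threshold); the flag is True when any single-frame change
    in any of the 6 motion dimensions exceeds ``run_discard_mm`` (rotations
    converted to mm at a 50 mm radius).
    """
    m = np.asarray(motion, dtype=float)
    fd = framewise_displacement(m)
    mask = fd <= config.fd_threshold
    d = np.zeros_like(m)
    d[1:] = np.diff(m, axis=0)
    d_mm = np.abs(d).copy()
    d_mm[:, 3:] *= FD_ROTATION_RADIUS_MM
    discard = bool((d_mm > config.run_discard_mm).any())
    return mask, discard


def _lssd_basis(
    times: np.ndarray, n_frames: int, tr: float, spec: FilterSpec, fmax_frac: float
) -> np.ndarray:
    """Sine/cosine basis at oversampled Fourier frequencies.

    Frequencies are spaced 1/(oversampling * run duration) apart up to
    ``fmax_frac`` of Nyquist: columns at the Nyquist edge are nearly
    degenerate on a regular grid and would dominate the interpolant with
    broadband artifacts, so they are excluded (the band-pass that follows
    removes everything near Nyquist anyway).
    """
    os_ = spec.basis_oversampling
    nyquist = 1.0 / (2.0 * tr)
    fund = 1.0 / (n_frames * tr * os_)
    freqs = np.arange(1, int(np.floor(fmax_frac * nyquist / fund)) + 1) * fund
    w = 2.0 * np.pi * freqs[None, :] * times[:, None]
    return np.hstack([np.cos(w), np.sin(w)])


def lssd_interpolate(
    run: RunTimeSeries,
    censor_mask: np.ndarray | None = None,
    filter_spec: FilterSpec = FilterSpec(),
    *,
    min_retained_fraction: float = 0.5,
    fmax_frac: float = 0.5,
    ridge: float = 1e-3,
) -> RunTimeSeries:
    """Replace censored frames with a least-squares spectral fit prediction.

    An oversampled sine/cosine basis is fit jointly to the retained frames
    only (per ROI), with a small ridge penalty (``ridge * n_retained`` on the
    normal equations) that resolves the collinearity the oversampling
    introduces; censored frames take the fit's prediction while retained
    frames are left bit-identical.  Predictions are clamped to the retained
    data's per-ROI range: with boundary or clustered censored frames the
    unconstrained fit can swing far outside the data range, and since the
    filled frames exist only so the band-pass sees a regular grid (they are
    deleted afterwards), they must not inject energy that leaks into
    retained neighbors.  With an empty censor mask this is a no-op, so
    interpolate-then-filter equals direct filtering exactly.
    """
    _require_stage(run, "lssd_interpolate")
    mask = run.censor_mask if censor_mask is None else np.asarray(censor_mask, dtype=bool)
    if mask.shape != (run.n_frames,):
        raise ValueError("censor mask length must equal frame count")
    n_ret = int(mask.sum())
    if n_ret < 2:
        raise ValueError("need at least 2 retained frames for spectral fit")
    if n_ret / run.n_frames < min_retained_fraction:
        raise ValueError(
            f"only {n_ret}/{run.n_frames} frames retained; below the "
            f"{min_retained_fraction:.0%} floor — apply the run-retention rule instead"
        )
    out = run.data.copy()
    if not mask.all():
        times = np.arange(run.n_frames) * run.tr
        basis = _lssd_basis(times, run.n_frames, run.tr, filter_spec, fmax_frac)
        A = basis[mask]
        y = run.data[mask]
        mu = y.mean(axis=0)
        lam = ridge * n_ret
        gram = A.T @ A + lam * np.eye(A.shape[1])
        coef = np.linalg.solve(gram, A.T @ (y - mu))
        pred = basis @ coef + mu
        pred = np.clip(pred, y.min(axis=0), y.max(axis=0))
        out[~mask] = pred[~mask]
    return run.with_step(out, "lssd_interpolate", censor_mask=mask.copy())


def bandpass(run: RunTimeSeries, filter_spec: FilterSpec = FilterSpec()) -> RunTimeSeries:
    """Zero-phase Butterworth band-pass over the (regularly sampled) series."""
    _require_stage(run, "bandpass")
    filter_spec.validate(run.tr)
    sos = signal.butter(
        filter_spec.butter_order,
        [filter_spec.low_hz, filter_spec.high_hz],
        btype="bandpass",
        fs=1.0 / run.tr,
        output="sos",
    )
    out = signal.sosfiltfilt(sos, run.data, axis=0)
    return run.with_step(out, "bandpass")


@dataclass
class RetentionResult:
    """Outcome of censor removal plus the 3-minute retention rule."""

    run: RunTimeSeries | None
    excluded: bool
    retained_frames: int
    retained_seconds: float
    censored_frames: int


def apply_censor_and_retention(
    run: RunTimeSeries,
    censor_mask: np.ndarray | None = None,
    config: CensorConfig = CensorConfig(),
) -> RetentionResult:
    """Delete censored frames; exclude the run if < ``min_retained_seconds`` remain.

    The boundary is inclusive: exactly 180 s of retained data is kept.
    """
    _require_stage(run, "censor_removed")
    mask = run.censor_mask if censor_mask is None else np.asarray(censor_mask, dtype=bool)
    if mask.shape != (run.n_frames,):
        raise ValueError("censor mask length must equal frame count")
    retained = int(mask.sum())
    seconds = retained * run.tr
    censored = run.n_frames - retained
    if seconds < config.min_retained_seconds:
        return RetentionResult(None, True, retained, seconds, censored)
    kept = run.with_step(
        run.data[mask], "censor_removed", censor_mask=np.ones(retained, dtype=bool)
    )
    return RetentionResult(kept, False, retained, seconds, censored)


def preprocess_run(
    run: RunTimeSeries,
    motion: pd.DataFrame | np.ndarray,
    censor_config: CensorConfig = CensorConfig(),
    filter_spec: FilterSpec = FilterSpec(),
    *,
    ventricle_signal: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> RetentionResult:
    """Full cleaning pipeline for one run.

    Returns a :class:`RetentionResult`; ``excluded`` is True either when the
    run-level motion rule fires (instantaneous motion > 3 mm in any dimension)
    or when fewer than 3 min of data survive scrubbing.
    """
    motion = pd.DataFrame(np.asarray(motion, dtype=float), columns=MOTION_COLUMNS)
    mask_full, discard = compute_censoring(motion, censor_config)
    if discard:
        return RetentionResult(None, True, 0, 0.0, run.n_frames)
    run2, motion2 = drop_initial_volumes(run, censor_config, motion)
    mask = mask_full[censor_config.initial_volumes_dropped :]
    if mask.sum() * run.tr < censor_config.min_retained_seconds:
        return RetentionResult(
            None, True, int(mask.sum()), float(mask.sum() * run.tr),
            run2.n_frames - int(mask.sum()),
        )
    if ventricle_signal is not None and len(ventricle_signal) == run.n_frames:
        ventricle_signal = np.asarray(ventricle_signal)[
            censor_config.initial_volumes_dropped :
        ]
    nuis = build_nuisance_set(motion2, ventricle_signal, rng=rng)
    run3 = regress_nuisance(run2, nuis)
    run4 = detrend(run3)
    run5 = lssd_interpolate(run4, mask, filter_spec)
    run6 = bandpass(run5, filter_spec)
    return apply_censor_and_retention(run6, mask, censor_config)
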