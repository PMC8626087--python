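"""Synthetic cohorts, BOLD data, motion traces and psychophysical observers.

The generators state the study's world: three stimulation groups (Parietal,
hMT+, Sham) of 10 subjects, two fMRI sessions, resting runs of 120 volumes at
TR = 2.0 s over the 10-seed attention network plus a 10-seed default-mode
control network, and two interleaved threshold-level tasks (orientation
discrimination, temporal-order judgment).

Generative model for ROI series: multivariate Gaussian innovations with the
target correlation imposed via Cholesky, then colored by an identical AR(1)
recursion per ROI.  Because every ROI shares the same AR coefficient, the
stationary cross-correlation matrix of the colored series equals the
innovation correlation matrix, so targets are preserved by construction.

Connectivity effects are injected in Fisher-z space on within-network edges;
if the implied correlation matrix leaves the positive-semidefinite cone it is
repaired by eigenvalue clipping and the achieved (post-repair) increment is
recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import MOTION_COLUMNS, RunTimeSeries
from .rois import RoiSpec

DEFAULT_GROUPS = ("Parietal", "hMT+", "Sham")


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Group structure of a simulated cohort."""

    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 10
    sessions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("group labels must be unique")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.sessions < 1:
            raise ConfigurationError("sessions must be >= 1")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Randomly assign subjects to groups, reproducibly from the seed.

    Returns a table with one row per subject: subject id, group, and the
    session labels the subject participates in.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.groups) * spec.n_per_group
    labels = np.repeat(list(spec.groups), spec.n_per_group)
    labels = labels[rng.permutation(n)]
    return pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(n)],
            "group": labels,
            "sessions": [
                ",".join(f"ses-{s + 1}" for s in range(spec.sessions)) for _ in range(n)
            ],
        }
    )


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------


def check_correlation_target(corr: np.ndarray) -> None:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ConfigurationError("base_correlation must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ConfigurationError("base_correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ConfigurationError("base_correlation must have unit diagonal")
    w = np.linalg.eigvalsh(corr)
    if w[0] < -1e-10:
        raise ConfigurationError(
            f"base_correlation is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3e})"
        )


def nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and re-normalize the diagonal."""
    corr = np.asarray(corr, dtype=float)
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass(frozen=True)
class EffectSpec:
    """A within-network connectivity increment for one group and session.

    ``delta_z`` is applied in Fisher-z space to every unique within-network
    edge of ``target_network`` for ``target_group`` in session
    ``session_index`` (0-based).
    """

    target_group: str = "Parietal"
    target_network: str = "DVAN"
    session_index: int = 1
    delta_z: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_z):
            raise ConfigurationError("delta_z must be finite")
        if self.session_index < 0:
            raise ConfigurationError("session_index must be >= 0")


@dataclass(frozen=True)
class BoldSimSpec:
    """Parameters of a simulated ROI-level resting run."""

    n_frames: int = 120
    tr: float = 2.0
    base_correlation: np.ndarray | None = None
    noise_sd: float = 1.0
    ar_coeff: float = 0.4
    spike_rate: float = 0.0
    network: str = "DVAN"

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ConfigurationError("ar_coeff must be in [0, 1)")
        if not (0.0 <= self.spike_rate < 1.0):
            raise ConfigurationError("spike_rate must be in [0, 1)")
        if self.base_correlation is not None:
            check_correlation_target(self.base_correlation)

    @property
    def duration_seconds(self) -> float:
        return self.n_frames * self.tr

    def resolve_correlation(self, n_rois: int) -> np.ndarray:
        if self.base_correlation is None:
            return np.eye(n_rois)
        corr = np.asarray(self.base_correlation, dtype=float)
        if corr.shape != (n_rois, n_rois):
            raise ConfigurationError(
                f"base_correlation is {corr.shape} but ROI set has {n_rois} regions"
            )
        return corr


def uniform_network_correlation(n_rois: int, r_within: float = 0.3) -> np.ndarray:
    """A simple exchangeable within-network target: every edge at ``r_within``."""
    corr = np.full((n_rois, n_rois), float(r_within))
    np.fill_diagonal(corr, 1.0)
    check_correlation_target(corr)
    return corr


def simulate_roi_timeseries(
    spec: BoldSimSpec,
    roi_set: list[RoiSpec] | list[str],
    seed: int | np.random.Generator,
) -> RunTimeSeries:
    """Draw a frames x ROIs series with the target stationary correlation.

    Innovations e_t ~ N(0, C) (Cholesky of the target C), then per ROI
    x_t = phi * x_{t-1} + e_t with a shared phi, scaled to ``noise_sd``.
    A burn-in of 50 frames removes transients.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [r.name if isinstance(r, RoiSpec) else str(r) for r in roi_set]
    p = len(names)
    corr = spec.resolve_correlation(p)
    check_correlation_target(corr)
    # eigenvalue-based factor tolerates semidefinite targets
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    burn = 50
    eps = rng.standard_normal((spec.n_frames + burn, p)) @ factor.T
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -spec.ar_coeff], eps, axis=0)[burn:]
    # rescale to unit marginal variance, then to noise_sd
    x *= np.sqrt(1.0 - spec.ar_coeff**2) * spec.noise_sd
    return RunTimeSeries(data=x, tr=spec.tr, roi_names=names)


def inject_connectivity_effect(
    base: BoldSimSpec,
    effect: EffectSpec,
    cohort: CohortSpec,
    *,
    repair: bool = True,
) -> dict[tuple[str, int], BoldSimSpec]:
    """Per (group, session) simulation specs with the effect confined to one cell.

    Only ``(effect.target_group, effect.session_index)`` differs from ``base``,
    and only when the spec's network matches ``effect.target_network``; all
    other cells share the base spec.  The z-space increment is applied to all
    unique off-diagonal edges; the result is PSD-repaired when needed (or an
    error is raised with ``repair=False``).
    """
    if effect.target_group not in cohort.groups:
        raise ConfigurationError(f"unknown target group {effect.target_group!r}")
    if effect.session_index >= cohort.sessions:
        raise ConfigurationError("effect session_index beyond cohort sessions")
    specs: dict[tuple[str, int], BoldSimSpec] = {}
    shifted = base
    if effect.delta_z != 0.0 and base.network == effect.target_network:
        corr = base.resolve_correlation(
            base.base_correlation.shape[0] if base.base_correlation is not None else 0
        )
        if base.base_correlation is None:
            raise ConfigurationError(
                "effect injection requires an explicit base_correlation"
            )
        z = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
        off = ~np.eye(corr.shape[0], dtype=bool)
        z[off] += effect.delta_z
        target = np.tanh(z)
        np.fill_diagonal(target, 1.0)
        wmin = np.linalg.eigvalsh((target + target.T) / 2)[0]
        if wmin < -1e-10:
            if not repair:
                raise ConfigurationError(
                    f"injected effect makes the target non-PSD "
                    f"(smallest eigenvalue {wmin:.3e}) and repair is disabled"
                )
            target = nearest_psd_correlation(target)
        shifted = replace(base, base_correlation=target)
    for g in cohort.groups:
        for s in range(cohort.sessions):
            key = (g, s)
            specs[key] = (
                shifted
                if (g == effect.target_group and s == effect.session_index)
                else base
            )
    return specs


def achieved_delta_z(base: BoldSimSpec, shifted: BoldSimSpec) -> np.ndarray:
    """Ground-truth per-edge z increment between two specs (post-repair)."""
    cb = np.asarray(base.base_correlation, dtype=float)
    cs = np.asarray(shifted.base_correlation, dtype=float)
    return np.arctanh(np.clip(cs, -1 + 1e-12, 1 - 1e-12)) - np.arctanh(
        np.clip(cb, -1 + 1e-12, 1 - 1e-12)
    )


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------


def simulate_motion(
    n_frames: int,
    spike_rate: float = 0.02,
    spike_amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    drift_sd: float = 0.02,
    rot_scale: float = 0.002,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Smooth low-amplitude drift plus Bernoulli motion spikes.

    Returns the 6-column motion table (mm / radians) and the ground-truth
    array of spike frame indices.  Drift is a random walk with per-frame
    standard deviation ``drift_sd`` mm (rotations scaled by ``rot_scale``);
    a spike adds ``spike_amplitude`` mm to one translation axis for a single
    frame.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    if not (0.0 <= spike_rate < 1.0):
        raise ConfigurationError("spike_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, 6)) * drift_sd
    steps[:, 3:] *= rot_scale / drift_sd if drift_sd > 0 else 0.0
    motion = np.cumsum(steps, axis=0)
    spikes = np.flatnonzero(rng.random(n_frames - 1) < spike_rate) + 1 if n_frames > 1 else np.array([], int)
    for t in spikes:
        axis = int(rng.integers(0, 3))
        motion[t, axis] += spike_amplitude * (1 if rng.random() < 0.5 else -1)
    return pd.DataFrame(motion, columns=MOTION_COLUMNS), spikes


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned voxel grid in the ROI coordinate space (RAS mm)."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = self.origin
        return aff


def grid_covering(rois: list[RoiSpec], voxel_size_mm: float = 3.0, margin_mm: float = 9.0) -> GridSpec:
    """Smallest grid whose voxel centers cover all ROI spheres plus a margin."""
    centers = np.array([r.center for r in rois])
    radii = np.array([r.radius_mm for r in rois])
    lo = (centers - (radii + margin_mm)[:, None]).min(axis=0)
    hi = (centers + (radii + margin_mm)[:, None]).max(axis=0)
    shape = tuple(int(np.ceil((h - l) / voxel_size_mm)) + 1 for l, h in zip(lo, hi))
    return GridSpec(shape=shape, voxel_size_mm=voxel_size_mm, origin=tuple(lo))


def roi_voxel_mask(roi: RoiSpec, grid: GridSpec) -> np.ndarray:
    """Boolean voxel mask: centers within ``radius_mm`` of the ROI center."""
    idx = np.indices(grid.shape).reshape(3, -1).T
    world = idx * grid.voxel_size_mm + np.asarray(grid.origin)
    dist2 = ((world - np.asarray(roi.center)) ** 2).sum(axis=1)
    return (dist2 <= roi.radius_mm**2).reshape(grid.shape)


def render_volume(
    series: RunTimeSeries,
    roi_set: list[RoiSpec],
    grid: GridSpec | None = None,
    *,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Paint ROI time courses into a 4-D volume; background is pure noise.

    Every voxel whose center lies within an ROI sphere carries that ROI's
    time course plus i.i.d. Gaussian noise.  Overlapping spheres are an
    error.  Returns ``(data4d, affine)`` suitable for ``nibabel.Nifti1Image``.
    """
    if len(roi_set) != series.n_rois:
        raise ValueError("roi_set size must match the series ROI count")
    if grid is None:
        grid = grid_covering(roi_set)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = []
    occupancy = np.zeros(grid.shape, dtype=int)
    for roi in roi_set:
        m = roi_voxel_mask(roi, grid)
        if not m.any():
            raise ValueError(f"ROI {roi.name!r} covers no voxel centers in the grid")
        masks.append(m)
        occupancy += m
    if (occupancy > 1).any():
        raise ValueError("ROI spheres overlap on the voxel grid")
    data = np.zeros(grid.shape + (series.n_frames,))
    if noise_sd > 0:
        data += rng.standard_normal(data.shape) * noise_sd
    for roi_i, m in enumerate(masks):
        data[m] += series.data[:, roi_i]
    return data, grid.affine


def to_nifti(data4d: np.ndarray, affine: np.ndarray):
    """Wrap a rendered 4-D volume as a NIfTI-1 image (RAS affine)."""
    import nibabel as nib

    return nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), np.asarray(affine))


# ---------------------------------------------------------------------------
# psychophysical observers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverModel:
    """Cumulative-Gaussian observer for same/different judgments.

    Psi(x) = Phi((x - pse) / slope) is the probability of registering a
    difference at offset ``x``; Psi(pse) = 0.5 by construction.  Reported
    'different' probability is ``guess + (1 - guess - lapse) * Psi(x)``.
    Units are task stimulus units (degrees for orientation, ms for asynchrony).
    """

    pse: float
    slope: float
    lapse_rate: float = 0.0
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("slope must be positive")
        for r in (self.lapse_rate, self.guess_rate):
            if not (0.0 <= r <= 0.2):
                raise ConfigurationError("lapse/guess rates must be in [0, 0.2]")

    def psi(self, offset: float | np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        return norm.cdf((np.asarray(offset, dtype=float) - self.pse) / self.slope)

    def p_report_different(self, offset: float | np.ndarray) -> np.ndarray:
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * self.psi(offset)


def simulate_observer_response(
    model: ObserverModel,
    offset: float,
    is_different: bool,
    rng: np.random.Generator,
) -> bool:
    """One same/different response.  Returns True for a 'different' report.

    On 'same' trials the physical offset is 0, so the false-alarm rate is the
    same model evaluated at offset 0.
    """
    p = float(model.p_report_different(offset if is_different else 0.0))
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# behavioral cohort
# ---------------------------------------------------------------------------

#: session labels in temporal order: pre-test, 4 training days, post-test
SESSION_LABELS = ["pre", "T1", "T2", "T3", "T4", "post"]

#: training-time codes: learning accrues over the 4 training days and is
#: retained at post-test (measured 24 h after the last training session)
_SESSION_TIME = {"pre": 0.0, "T1": 1.0, "T2": 2.0, "T3": 3.0, "T4": 4.0, "post": 4.0}

#: stated per-group total pre-to-post accuracy changes (proportion correct)
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "OD": {"Parietal": 0.298, "hMT+": 0.022, "Sham": -0.031},
    "TOJ": {"Parietal": 0.031, "hMT+": -0.041, "Sham": -0.078},
}


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def learning_rates_from_effects(
    effects: dict[str, dict[str, float]], baseline: float = 0.5
) -> dict[str, dict[str, float]]:
    """Convert total pre-to-post accuracy changes into per-day logit drifts."""
    rates: dict[str, dict[str, float]] = {}
    for task, per_group in effects.items():
        rates[task] = {
            g: (_logit(min(max(baseline + d, 0.05), 0.95)) - _logit(baseline)) / 4.0
            for g, d in per_group.items()
        }
    return rates


def simulate_behavioral_cohort(
    cohort: pd.DataFrame,
    *,
    group_effects: dict[str, dict[str, float]] | None = None,
    baseline_accuracy: float = 0.5,
    subject_sd: float = 0.15,
    n_trials: int = 120,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-subject accuracies for both tasks over pre, T1-T4 and post sessions.

    Tasks run at individually thresholded difficulty, so baseline expected
    accuracy is 0.5.  Group-level learning is a linear drift in logit-accuracy
    per training day (rate chosen so the group mean reaches baseline + the
    configured total change at post-test); subjects get a Gaussian random
    offset in logit space, and observed accuracies are binomial draws over
    ``n_trials`` trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = DEFAULT_GROUP_EFFECTS if group_effects is None else group_effects
    rates = learning_rates_from_effects(effects, baseline_accuracy)
    base_logit = _logit(baseline_accuracy)
    rows = []
    for _, subj in cohort.iterrows():
        for task, per_group in rates.items():
            rate = per_group.get(subj["group"], 0.0)
            offset = rng.normal(0.0, subject_sd)
            for label in SESSION_LABELS:
                p = float(
                    _inv_logit(np.array(base_logit + offset + rate * _SESSION_TIME[label]))
                )
                k = rng.binomial(n_trials, p)
                rows.append(
                    {
                        "subject": subj["subject"],
                        "group": subj["group"],
                        "task": task,
                        "session": label,
                        "n_trials": n_trials,
                        "accuracy": k / n_trials,
                        "true_p": p,
                    }
                )
    return pd.DataFrame(rows)
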