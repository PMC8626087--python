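"""Adaptive thresholding and cross-task session construction.

Thresholding uses a 3-down-1-up staircase on same/different judgments: one
incorrect response eases the task (larger offset), three consecutive correct
responses harden it (smaller offset), and the run terminates after 30
direction reversals.  Two threshold read-outs are provided:

``reversal_mean``
    mean of the last ``reversal_window`` reversal levels — the staircase's
    own convergence point, which for a 3-down-1-up rule tracks the ~79.4%
    correct level rather than the 50% point;

``pse_fit``
    maximum-likelihood cumulative-Gaussian fit to the full trial log, read
    out at its 50% point.  This is the procedure's point of subjective
    equality (PSE): presenting different-type trials at this level yields
    ~50% 'different' responses, which is what the threshold is defined to
    achieve and what the 15 validation trials check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .synthetic import ObserverModel, simulate_observer_response

HARDER = "harder"
EASIER = "easier"
NONE = "none"


@dataclass(frozen=True)
class StaircaseConfig:
    n_down: int = 3
    n_up: int = 1
    step_size: float = 0.5
    n_reversals_stop: int = 30
    max_trials: int = 400
    start_level: float = 8.0
    reversal_window: int = 8
    min_level: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_down < 1 or self.n_up < 1:
            raise ValueError("n_down and n_up must be >= 1")
        if self.n_reversals_stop < 2:
            raise ValueError("n_reversals_stop must be >= 2")
        if self.max_trials <= self.n_reversals_stop:
            raise ValueError("max_trials must exceed n_reversals_stop")
        if self.step_size <= 0 or self.start_level <= 0:
            raise ValueError("step_size and start_level must be positive")


@dataclass
class StaircaseState:
    current_level: float
    consecutive_correct: int = 0
    direction: str = NONE
    reversal_levels: list[float] = field(default_factory=list)
    trial_log: list[tuple[float, bool, bool]] = field(default_factory=list)
    terminated: bool = False

    def n_reversals(self) -> int:
        return len(self.reversal_levels)


@dataclass
class ThresholdEstimate:
    task: str
    value: float
    method: str
    converged: bool
    n_trials: int
    validation_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("threshold value must be positive")


def step_staircase(state: StaircaseState, correct: bool, config: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one scored trial (mutates and returns ``state``).

    Incorrect -> level moves easier (up) by one step and the run counter
    resets; the ``n_down``-th consecutive correct -> level moves harder
    (down) and the counter resets.  A reversal is logged whenever the
    movement direction flips; the reversal level is the level at which the
    flip occurred.
    """
    if state.terminated:
        raise RuntimeError("cannot step a terminated staircase")
    state.trial_log.append((state.current_level, correct, correct))
    moved = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= config.n_down:
            moved = HARDER
            state.consecutive_correct = 0
    else:
        moved = EASIER
        state.consecutive_correct = 0
    if moved is not None:
        if state.direction != NONE and moved != state.direction:
            state.reversal_levels.append(state.current_level)
        state.direction = moved
        delta = -config.step_size if moved == HARDER else config.step_size
        state.current_level = max(config.min_level, state.current_level + delta)
        if state.n_reversals() >= config.n_reversals_stop:
            state.terminated = True
    if len(state.trial_log) >= config.max_trials:
        state.terminated = True
    return state


def count_reversals(responses: list[bool], config: StaircaseConfig) -> int:
    """Reversal count for an explicit correct/incorrect sequence from scratch."""
    st = StaircaseState(current_level=config.start_level)
    for r in responses:
        if st.terminated:
            break
        step_staircase(st, r, config)
    return st.n_reversals()


def fit_psychometric(levels: np.ndarray, reported_different: np.ndarray):
    """ML cumulative-Gaussian fit Psi(x) = Phi((x - pse) / slope).

    Returns ``(pse, slope)``.  Probabilities are clipped away from 0/1 for a
    finite likelihood; optimization is over (pse, log slope) from a moment
    start.
    """
    levels = np.asarray(levels, dtype=float)
    y = np.asarray(reported_different, dtype=float)
    if len(levels) < 5:
        raise ValueError("need at least 5 trials to fit a psychometric function")

    def nll(theta):
        pse, log_slope = theta
        p = norm.cdf((levels - pse) / np.exp(log_slope))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    start = np.array([np.median(levels), np.log(max(levels.std(), 1e-3))])
    best = None
    for jitter in (0.0, -0.5, 0.5):
        res = minimize(nll, start + np.array([0.0, jitter]), method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    pse, log_slope = best.x
    return float(pse), float(np.exp(log_slope))


def run_staircase(
    observer: ObserverModel,
    config: StaircaseConfig = StaircaseConfig(),
    *,
    task: str = "OD",
    method: str = "pse_fit",
    seed: int | np.random.Generator = 0,
) -> tuple[ThresholdEstimate, StaircaseState]:
    """Run the staircase on different-type trials until 30 reversals.

    Each trial presents a physical difference at the current level; the
    response is correct when the observer reports 'different'.  The threshold
    read-out depends on ``method`` (see module docstring); the estimate is
    flagged unconverged if ``max_trials`` is hit before the reversal quota.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = StaircaseState(current_level=config.start_level)
    while not state.terminated:
        reported = simulate_observer_response(observer, state.current_level, True, rng)
        step_staircase(state, reported, config)
    converged = state.n_reversals() >= config.n_reversals_stop
    levels = np.array([t[0] for t in state.trial_log])
    resp = np.array([t[1] for t in state.trial_log])
    if method == "reversal_mean":
        if state.reversal_levels:
            window = state.reversal_levels[-config.reversal_window :]
            value = float(np.mean(window))
        else:
            value = float(state.current_level)
    elif method == "pse_fit":
        try:
            pse, _slope = fit_psychometric(levels, resp)
            value = float(pse)
        except ValueError:
            value = float(np.mean(state.reversal_levels[-config.reversal_window :]) if state.reversal_levels else state.current_level)
        if value <= 0:
            value = config.min_level
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    est = ThresholdEstimate(
        task=task,
        value=max(value, config.min_level),
        method=method,
        converged=converged,
        n_trials=len(state.trial_log),
    )
    return est, state


def validate_threshold(
    observer: ObserverModel,
    estimate: ThresholdEstimate,
    n_trials: int = 15,
    *,
    band: tuple[float, float] = (0.3, 0.7),
    seed: int | np.random.Generator = 0,
) -> tuple[float, bool]:
    """Present ``n_trials`` different-type trials at the estimated level.

    Returns the proportion of 'different' reports and a pass flag against a
    configurable band around the expected 50%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = sum(
        simulate_observer_response(observer, estimate.value, True, rng)
        for _ in range(n_trials)
    )
    acc = hits / n_trials
    estimate.validation_accuracy = acc
    return acc, band[0] <= acc <= band[1]


# ---------------------------------------------------------------------------
# session construction and scoring
# ---------------------------------------------------------------------------

CATCH_OFFSETS = {"TOJ": 150.0, "OD": 20.0}  # easy above-threshold offsets


@dataclass(frozen=True)
class SessionSpec:
    """Trial-parameter layout of one cross-task session.

    Defaults give 120 standard trials per task (240 total) in 4 blocks with 6
    catch trials per block (24 per session).
    """

    trials_per_task: int = 120
    n_blocks: int = 4
    catch_per_block: int = 6
    catch_offsets: dict[str, float] = field(default_factory=lambda: dict(CATCH_OFFSETS))
    side_balance: bool = True
    tasks: tuple[str, ...] = ("OD", "TOJ")

    def __post_init__(self) -> None:
        if self.trials_per_task < 1 or self.n_blocks < 1 or self.catch_per_block < 0:
            raise ValueError("invalid session counts")
        if self.trials_per_task % self.n_blocks:
            raise ValueError("trials_per_task must divide evenly into blocks")
        if self.side_balance and self.trials_per_task % 2:
            raise ValueError("side balancing requires an even trials_per_task")

    @property
    def total_standard(self) -> int:
        return self.trials_per_task * len(self.tasks)

    @property
    def total_catch(self) -> int:
        return self.n_blocks * self.catch_per_block


def build_session(
    spec: SessionSpec,
    thresholds: dict[str, float],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomly interleave the two tasks' trials (plus catch trials) per block.

    Standard trials run at the task's threshold offset with same/different
    truth balanced; the test side is left/right balanced per task.  Catch
    trials use the easy above-threshold offsets.  The cue column records the
    attended feature.
    """
    missing = [t for t in spec.tasks if t not in thresholds]
    if missing:
        raise ValueError(f"missing thresholds for tasks: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_block = spec.trials_per_task // spec.n_blocks
    rows = []
    for block in range(spec.n_blocks):
        block_rows = []
        for task in spec.tasks:
            sides = ["left", "right"] * (per_block // 2) + (
                ["left"] if per_block % 2 else []
            )
            truths = ["different", "same"] * (per_block // 2) + (
                ["different"] if per_block % 2 else []
            )
            rng.shuffle(truths)
            for side, truth in zip(sides, truths):
                block_rows.append(
                    {
                        "block": block + 1,
                        "task": task,
                        "cue": "Orientation" if task == "OD" else "Time",
                        "side": side,
                        "offset": thresholds[task] if truth == "different" else 0.0,
                        "is_catch": False,
                        "truth": truth,
                    }
                )
        for c in range(spec.catch_per_block):
            task = spec.tasks[c % len(spec.tasks)]
            block_rows.append(
                {
                    "block": block + 1,
                    "task": task,
                    "cue": "Orientation" if task == "OD" else "Time",
                    "side": "left" if c % 4 < 2 else "right",
                    "offset": spec.catch_offsets[task],
                    "is_catch": True,
                    "truth": "different",
                }
            )
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    return df


@dataclass
class BehavioralRecord:
    """Per subject/task/session scored accuracies."""

    subject: str
    group: str
    task: str
    session: str
    accuracy: float
    catch_accuracy: float | None = None
    n_scored: int = 0
    n_missing: int = 0
    chance_on_catch: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must be in [0, 1]")


def score_session(
    trial_log: pd.DataFrame,
    *,
    subject: str = "",
    group: str = "",
    session: str = "",
    chance_alpha: float = 0.05,
) -> list[BehavioralRecord]:
    """Per-task accuracy over standard trials, catch accuracy separately.

    ``trial_log`` needs columns task, is_catch, correct (nullable: missing
    responses are dropped from the denominator and counted).  A subject is
    flagged ``chance_on_catch`` when catch accuracy is not significantly
    above 0.5 (one-sided binomial test at ``chance_alpha``).
    """
    from scipy.stats import binomtest

    records = []
    for task, sub in trial_log.groupby("task", sort=False):
        std = sub[~sub["is_catch"]]
        catch = sub[sub["is_catch"]]
        resp = std["correct"].dropna().astype(bool)
        n_missing = int(std["correct"].isna().sum())
        acc = float(resp.mean()) if len(resp) else 0.0
        catch_resp = catch["correct"].dropna().astype(bool)
        if len(catch_resp):
            catch_acc = float(catch_resp.mean())
            p = binomtest(int(catch_resp.sum()), len(catch_resp), 0.5, alternative="greater").pvalue
            at_chance = p > chance_alpha
        else:
            catch_acc, at_chance = None, False
        records.append(
            BehavioralRecord(
                subject=subject,
                group=group,
                task=str(task),
                session=session,
                accuracy=acc,
                catch_accuracy=catch_acc,
                n_scored=len(resp),
                n_missing=n_missing,
                chance_on_catch=at_chance,
            )
        )
    return records


def compute_improvement(pre: float, post: float) -> float:
    """Post-test minus pre-test accuracy (may be negative)."""
    for v in (pre, post):
        if not (0.0 <= v <= 1.0):
            raise ValueError("accuracies must be in [0, 1]")
    return post - pre
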