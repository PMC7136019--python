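"""Synthetic first-level GLM machinery: event timing, parametric-modulator
design matrices, BOLD-like signal simulation, OLS fitting, collinearity
diagnostics, and ridge-regularized regressor-specific signal decoding.

Each simulated run lasts 12 minutes at TR = 1.5 s (480 frames). Per run the
design contains a self-choice onset regressor (8 events), a guess onset
regressor (24 events), the guess regressor scaled by a model's parametric
modulator (not mean-centered and not orthogonalized against the unmodulated
guess regressor), photo-onset regressors for Agents A and B preceding the
ally-choice trial, and a run intercept. All event regressors are stick
functions convolved with the canonical double-gamma HRF.

The decoder isolates the signal attributable to one regressor by removing
every other regressor's fitted contribution and rescaling by the target's
beta under L2 shrinkage:

    signal = (Y - sum_{i != target} b_i X_i) * b_t / (b_t^2 + lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level import glover_hrf

from .similarity import ModulatorSeries
from .task import TaskSession, event_table

TR_DEFAULT = 1.5  # seconds
N_SCANS_DEFAULT = 480  # 12-minute run at TR 1.5 s
JITTER_RANGE = (3.0, 16.0)  # inter-event fixation, seconds
_OVERSAMPLE = 10

#: durations (s) advancing the clock after each modelled event onset, and
#: whether a jittered fixation follows. Feedback appears on the guess screen
#: itself, so the fixation follows the feedback, not the guess.
_EVENT_ADVANCE = {
    "self_choice": (4.5, True),
    "guess": (4.5, False),
    "feedback": (3.0, True),
    "photo": (2.5, True),
    "ally_choice": (4.5, True),
}


def canonical_hrf(tr: float, oversampling: int = 1, time_length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr / oversampling`` s,
    peak-normalized. Zero at t = 0, peak near 5 s, undershoot near 15 s."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    kernel = glover_hrf(tr, oversampling=oversampling, time_length=time_length)
    return kernel / kernel.max()


def schedule_onsets(
    session: TaskSession,
    seed: int,
    jitter: tuple[float, float] = JITTER_RANGE,
    run_duration: float = N_SCANS_DEFAULT * TR_DEFAULT,
) -> pd.DataFrame:
    """Assign within-run onsets to every modelled event of a session.

    Events follow the trial structure (self-choice, then guess + feedback
    per agent in the within-trial order, then the two photo onsets and the
    ally choice) with uniform fixation jitter between modelled events. The
    per-run jitter vector is resampled in the rare case the run would
    overrun ``run_duration`` minus a 24 s HRF tail.
    """
    lo, hi = jitter
    if not 0 <= lo <= hi:
        raise ValueError("invalid jitter range")
    rng = np.random.default_rng(seed)
    events = event_table(session)
    onsets = np.empty(len(events))
    for run_id, idx in events.groupby("run", sort=True).groups.items():
        rows = events.loc[idx]
        for _ in range(1000):
            t = 0.0
            run_onsets = []
            for etype in rows["event_type"]:
                run_onsets.append(t)
                advance, jittered = _EVENT_ADVANCE[etype]
                t += advance + (rng.uniform(lo, hi) if jittered else 0.0)
            if run_onsets[-1] + _EVENT_ADVANCE["ally_choice"][0] + 24.0 <= run_duration:
                break
        else:
            raise RuntimeError(f"could not fit run {run_id} events into {run_duration} s")
        onsets[np.asarray(idx)] = run_onsets
    out = events.copy()
    out["onset_s"] = onsets
    return out


@dataclass(frozen=True)
class DesignMatrix:
    """First-level design: frames x regressors, runs concatenated."""

    matrix: pd.DataFrame  # index = frame time (s), columns = regressors
    tr: float
    n_scans_per_run: int
    run_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("design matrix must not contain NaNs")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    @property
    def frame_times(self) -> np.ndarray:
        return self.matrix.index.to_numpy(dtype=float)


def _convolve_sticks(
    onsets: np.ndarray, amplitudes: np.ndarray, tr: float, n_scans: int, kernel: np.ndarray
) -> np.ndarray:
    dt = tr / _OVERSAMPLE
    grid = np.zeros(n_scans * _OVERSAMPLE)
    idx = np.round(np.asarray(onsets) / dt).astype(int)
    if len(idx) and ((idx < 0).any() or (idx >= len(grid)).any()):
        raise ValueError("event onset outside the scan window")
    np.add.at(grid, idx, amplitudes)
    conv = np.convolve(grid, kernel)[: len(grid)]
    return conv[::_OVERSAMPLE]


def build_design(
    events: pd.DataFrame,
    modulators: Mapping[int, ModulatorSeries] | ModulatorSeries,
    tr: float = TR_DEFAULT,
    n_scans: int = N_SCANS_DEFAULT,
    drift_order: int = 0,
) -> DesignMatrix:
    """Build the parametric-modulator design from an onset-stamped event
    table (one or several runs).

    The modulator column is the guess-onset stick train scaled by the
    modulator value of each guess event (matched on trial and agent order;
    raw values, no mean-centering, no orthogonalization) and HRF-convolved.
    Runs are concatenated with one intercept column per run; optional
    polynomial drift columns per run model slow trends.
    """
    if isinstance(modulators, ModulatorSeries):
        modulators = {modulators.run_id: modulators}
    kernel = canonical_hrf(tr, oversampling=_OVERSAMPLE)
    run_ids = sorted(events["run"].unique())
    blocks = []
    for r, run_id in enumerate(run_ids):
        rows = events[events["run"] == run_id]
        cols: dict[str, np.ndarray] = {}
        self_on = rows.loc[rows.event_type == "self_choice", "onset_s"].to_numpy()
        guesses = rows[rows.event_type == "guess"]
        if run_id not in modulators:
            raise ValueError(f"no modulator series for run {run_id}")
        series = modulators[run_id]
        observed = list(zip(guesses["trial"], guesses["agent"]))
        if observed != list(series.events):
            raise ValueError(
                f"modulator series for run {run_id} is misaligned with the guess events"
            )
        cols["self_onset"] = _convolve_sticks(self_on, np.ones_like(self_on), tr, n_scans, kernel)
        guess_on = guesses["onset_s"].to_numpy()
        cols["guess_onset"] = _convolve_sticks(guess_on, np.ones_like(guess_on), tr, n_scans, kernel)
        cols["guess_x_modulator"] = _convolve_sticks(
            guess_on, np.asarray(series.values, dtype=float), tr, n_scans, kernel
        )
        for agent in ("A", "B"):
            on = rows.loc[
                (rows.event_type == "photo") & (rows.agent == agent), "onset_s"
            ].to_numpy()
            cols[f"photo_{agent}"] = _convolve_sticks(on, np.ones_like(on), tr, n_scans, kernel)
        block = pd.DataFrame(cols)
        for d in range(1, drift_order + 1):
            block[f"drift{d}_run{run_id}"] = np.linspace(-1.0, 1.0, n_scans) ** d
        block[f"intercept_run{run_id}"] = 1.0
        block.index = (np.arange(n_scans) + r * n_scans) * tr
        blocks.append(block)
    matrix = pd.concat(blocks).fillna(0.0)
    return DesignMatrix(
        matrix=matrix, tr=tr, n_scans_per_run=n_scans, run_ids=tuple(int(r) for r in run_ids)
    )


@dataclass(frozen=True)
class VoxelData:
    """Simulated voxel signals with stored ground truth."""

    Y: np.ndarray  # frames x voxels
    true_betas: np.ndarray  # regressors x voxels
    noise_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.Y).all():
            raise ValueError("voxel data must be finite")


def simulate_bold(
    design: DesignMatrix,
    true_betas: Sequence[float] | np.ndarray,
    noise_sd: float,
    seed: int,
    n_voxels: int = 1,
) -> VoxelData:
    """Y = X beta + white Gaussian noise, with ground truth retained."""
    x = design.values
    betas = np.asarray(true_betas, dtype=float)
    if betas.ndim == 1:
        betas = np.tile(betas[:, None], (1, n_voxels))
    if betas.shape[0] != x.shape[1]:
        raise ValueError("one true beta per design column required")
    rng = np.random.default_rng(seed)
    y = x @ betas + rng.normal(0.0, noise_sd, size=(x.shape[0], betas.shape[1]))
    return VoxelData(Y=y, true_betas=betas, noise_sd=float(noise_sd))


@dataclass(frozen=True)
class GLMResult:
    """Per-voxel OLS estimates for a design."""

    betas: pd.DataFrame  # regressors x voxels
    residuals: np.ndarray
    rank_deficient: bool


def fit_glm(design: DesignMatrix, y: np.ndarray) -> GLMResult:
    """Ordinary least squares per voxel; warns (naming the columns involved)
    and falls back to the pseudo-inverse if the design is rank-deficient."""
    x = design.values
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != x.shape[0]:
        y = y.T
    if y.shape[0] != x.shape[0]:
        raise ValueError("signal and design frame counts differ")
    rank = np.linalg.matrix_rank(x)
    deficient = rank < x.shape[1]
    if deficient:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        corr = np.nan_to_num(corr)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        warnings.warn(
            "rank-deficient design (pseudo-inverse used); most collinear columns: "
            f"{design.names[i]} ~ {design.names[j]}",
            UserWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return GLMResult(
        betas=pd.DataFrame(beta, index=design.names),
        residuals=resid,
        rank_deficient=bool(deficient),
    )


@dataclass(frozen=True)
class CollinearityReport:
    """Pairwise modulator correlations and VIFs, per participant and
    averaged over the cohort."""

    per_participant: pd.DataFrame  # columns: participant, pair, r, vif
    mean_r: pd.Series  # by pair
    mean_vif: pd.Series  # by pair


def vif_from_r(r: float) -> float:
    """Variance inflation factor 1/(1 - r^2); +inf for |r| = 1 (within
    floating-point resolution of the correlation)."""
    r2 = r * r
    return float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)


def collinearity_report(
    cohort_series: Sequence[Mapping[str, np.ndarray]],
) -> CollinearityReport:
    """Collinearity diagnostics across models from per-participant modulator
    value series (pre-convolution), aligned on the same guess events.

    Each element of ``cohort_series`` maps model name to that participant's
    concatenated modulator values (e.g. 6 runs x 24 = 144 values).
    """
    rows = []
    for p, series in enumerate(cohort_series):
        models = sorted(series)
        if len(models) < 2:
            raise ValueError("need at least two modulator series per participant")
        for i, a in enumerate(models):
            for b in models[i + 1 :]:
                xa = np.asarray(series[a], dtype=float)
                xb = np.asarray(series[b], dtype=float)
                if len(xa) != len(xb):
                    raise ValueError("modulator series must be aligned on guess events")
                if np.std(xa) == 0 or np.std(xb) == 0:
                    raise ValueError(f"zero-variance modulator series ({a} or {b})")
                r = float(np.corrcoef(xa, xb)[0, 1])
                rows.append({"participant": p, "pair": f"{a}-{b}", "r": r, "vif": vif_from_r(r)})
    frame = pd.DataFrame(rows)
    return CollinearityReport(
        per_participant=frame,
        mean_r=frame.groupby("pair")["r"].mean(),
        mean_vif=frame.groupby("pair")["vif"].mean(),
    )


def decode_signal(
    design: DesignMatrix,
    y: np.ndarray,
    target: str,
    lam: float = 1.0,
    fit: GLMResult | None = None,
) -> np.ndarray:
    """Regressor-specific signal via the L2-shrunk GLM inversion.

    Removes every non-target regressor's fitted contribution from Y and
    rescales the remainder by b_t / (b_t^2 + lambda) per voxel. Returns an
    array shaped like Y (frames x voxels).
    """
    if target not in design.names:
        raise ValueError(f"unknown target regressor '{target}'")
    if fit is None:
        fit = fit_glm(design, y)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != design.values.shape[0]:
        y = y.T
    others = [n for n in design.names if n != target]
    x_others = design.matrix[others].to_numpy()
    b_others = fit.betas.loc[others].to_numpy()
    b_t = fit.betas.loc[target].to_numpy()  # per voxel
    cleaned = y - x_others @ b_others
    return cleaned * (b_t / (b_t**2 + lam))


def event_amplitudes(
    decoded: np.ndarray,
    frame_times: np.ndarray,
    photo_onsets: Mapping[str, float],
    window: tuple[float, float] = (3.0, 7.0),
    voxels: Sequence[int] | None = None,
) -> dict[str, float]:
    """Average decoded signal around each agent's photo onset.

    The decoded signal is averaged over the ROI voxels and then over the
    peri-onset window (default 3-7 s after onset, the HRF peak). Returns
    one amplitude per agent.
    """
    decoded = np.atleast_2d(np.asarray(decoded, dtype=float))
    if decoded.shape[0] != len(frame_times):
        decoded = decoded.T
    if voxels is not None:
        decoded = decoded[:, list(voxels)]
    roi_mean = decoded.mean(axis=1)
    out = {}
    for agent, onset in photo_onsets.items():
        lo, hi = onset + window[0], onset + window[1]
        in_win = (frame_times >= lo) & (frame_times <= hi)
        if not in_win.any():
            raise ValueError(f"peri-onset window for agent {agent} lies outside the scan")
        out[agent] = float(roi_mean[in_win].mean())
    return out


def log_difference(amp_a: np.ndarray, amp_b: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """log(amplitude_A) - log(amplitude_B) per run, with a participant-level
    positivity shift.

    Decoded amplitudes can be negative; when any is non-positive, one global
    affine shift (-min + eps over both agents' amplitudes) is applied to all
    values before taking logs. Amplitude sets that are already positive are
    left untouched.
    """
    a = np.asarray(amp_a, dtype=float).copy()
    b = np.asarray(amp_b, dtype=float).copy()
    m = min(a.min(), b.min())
    if m <= 0:
        shift = -m + eps
        a += shift
        b += shift
    return np.log(a) - np.log(b)
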