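"""Per-subject model scoring and random-effects Bayesian model selection.

Each candidate model is scored per subject by the BIC of a Gaussian GLM of
the ROI-mean time series (n ln(RSS/n) + k ln n), converted to an approximate
log model evidence as -BIC/2. The group-level analysis treats the model
identity as a random effect across subjects: model frequencies r get a
Dirichlet prior, per-subject model assignments are inferred variationally,
and the posterior Dirichlet yields

* expected model frequencies,
* exceedance probabilities (EP): P(model k is the most frequent), estimated
  by seeded Monte-Carlo sampling of the posterior Dirichlet,
* Bayesian omnibus risk (BOR): the posterior probability of the null that
  all models are equally frequent, from the free-energy comparison of the
  null and the random-effects model,
* protected exceedance probabilities: PXP = EP (1 - BOR) + BOR / K.

A leave-one-subject-out harness assembles one evidence row per held-out
subject and pools them through the group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from . import latent as _latent
from . import neural as _neural
from . import similarity as _similarity
from . import task as _task

MODELS = ("dyadic", "feature", "latent")


def glm_bic(design: _neural.DesignMatrix, y: np.ndarray) -> float:
    """BIC of the Gaussian GLM of a single (ROI-mean) time series.

    BIC = n ln(RSS / n) + k ln(n) with k estimated coefficients over n
    frames; RSS is floored at machine epsilon (with a warning) to keep the
    value finite for perfect fits.
    """
    x = design.values
    y = np.asarray(y, dtype=float).ravel()
    n, k = x.shape
    if len(y) != n:
        raise ValueError("time series length must match the design")
    if n <= k:
        raise ValueError(f"need more frames than regressors (n={n}, k={k})")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(((y - x @ beta) ** 2).sum())
    if rss < np.finfo(float).eps:
        import warnings

        warnings.warn("perfect fit: RSS floored at machine epsilon", UserWarning, stacklevel=2)
        rss = float(np.finfo(float).eps)
    return float(n * np.log(rss / n) + k * np.log(n))


def bic_to_lme(bic: float) -> float:
    """Log model evidence approximation: -BIC / 2."""
    if not np.isfinite(bic):
        raise ValueError("BIC must be finite")
    return -0.5 * float(bic)


@dataclass(frozen=True)
class BMSResult:
    """Random-effects Bayesian model selection summary."""

    models: tuple[str, ...]
    alpha: np.ndarray  # posterior Dirichlet concentrations
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    protected_exceedance_prob: np.ndarray
    free_energy: float  # F1 of the random-effects model
    free_energy_null: float  # F0 of the equal-frequency null

    def __post_init__(self) -> None:
        if not 0.0 <= self.bor <= 1.0:
            raise ValueError("BOR must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "bor": self.bor,
            "pxp": self.protected_exceedance_prob.tolist(),
            "free_energy": self.free_energy,
            "free_energy_null": self.free_energy_null,
        }


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """Variational posterior over model frequencies and assignments."""
    alpha = alpha0.copy()
    g = np.full_like(lme, 1.0 / lme.shape[1])
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        done = np.max(np.abs(alpha_new - alpha)) < tol
        alpha = alpha_new
        if done:
            break
    return alpha, g


def _free_energy(lme: np.ndarray, alpha: np.ndarray, g: np.ndarray, alpha0: np.ndarray) -> float:
    """Variational free energy of the random-effects model."""
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    elj = (
        gammaln(alpha0.sum())
        - gammaln(alpha0).sum()
        + ((alpha0 - 1.0) * e_log_r).sum()
        + (g * (lme + e_log_r[None, :])).sum()
    )
    ent_r = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1.0) * e_log_r).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        glogg = np.where(g > 0, g * np.log(g), 0.0)
    return float(elj + ent_r - glogg.sum())


def _free_energy_null(lme: np.ndarray) -> float:
    """Free energy of the null: every model equally frequent."""
    k = lme.shape[1]
    return float((logsumexp(lme, axis=1) - np.log(k)).sum())


def rfx_bms(
    evidence: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models log
    evidence matrix.

    Only within-subject evidence differences matter; adding a per-subject
    constant leaves the result unchanged. EP is estimated from ``n_samples``
    seeded draws of the posterior Dirichlet.
    """
    if isinstance(evidence, pd.DataFrame):
        models = tuple(str(c) for c in evidence.columns)
        lme = evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(evidence, dtype=float)
        models = tuple(f"model_{i}" for i in range(lme.shape[1]))
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    if not np.isfinite(lme).all():
        raise ValueError("log evidences must be finite")
    lme = lme - lme.max(axis=1, keepdims=True)  # per-subject shift, invariant
    k = lme.shape[1]
    a0 = np.full(k, float(alpha0))
    alpha, g = _vb_dirichlet(lme, a0)
    f1 = _free_energy(lme, alpha, g, a0)
    f0 = _free_energy_null(lme)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    rng = np.random.default_rng(seed)
    ep = np.zeros(k)
    remaining = int(n_samples)
    while remaining > 0:  # draw in blocks to bound memory
        block = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=block)
        ep += np.bincount(draws.argmax(axis=1), minlength=k)
        remaining -= block
    ep /= n_samples
    pxp = ep * (1.0 - bor) + bor / k
    return BMSResult(
        models=models,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance_prob=ep,
        bor=bor,
        protected_exceedance_prob=pxp,
        free_energy=f1,
        free_energy_null=f0,
    )


@dataclass(frozen=True)
class SubjectRoiData:
    """One subject's ROI-mean time series plus the per-model designs that
    compete to explain it."""

    participant: str
    designs: dict[str, _neural.DesignMatrix]  # model -> design
    roi_series: np.ndarray  # frames
    generator: str = "unknown"


def simulate_roi_cohort(
    n_subjects: int,
    generator: str | dict[str, float],
    noise_sd: float,
    seed: int,
    n_runs: int = 2,
    betas: Sequence[float] = (1.0, 1.0, 2.0, 0.5, 0.5),
    n_scans: int = _neural.N_SCANS_DEFAULT,
) -> list[SubjectRoiData]:
    """Simulate a cohort whose ROI-mean signals are generated from the
    models' modulators.

    ``generator`` is a single model name (every subject's ROI tracks that
    model) or a model -> population-frequency mapping: subjects are assigned
    generating models in those proportions, which is the random-effects
    null scenario when the frequencies are equal. ``betas`` are the
    ground-truth amplitudes for (self_onset, guess_onset, guess_x_modulator,
    photo_A, photo_B). ``n_runs`` of the six-run session enter the design;
    two runs already identify the generating model and keep the harness
    light.
    """
    weights = {generator: 1.0} if isinstance(generator, str) else dict(generator)
    unknown = set(weights) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown generator models: {sorted(unknown)}")
    # deterministic proportional assignment of generating models to subjects
    quota = {m: w / sum(weights.values()) for m, w in weights.items()}
    assignment = []
    counts = dict.fromkeys(quota, 0)
    for s in range(n_subjects):
        m = min(quota, key=lambda mm: (counts[mm] - quota[mm] * (s + 1), MODELS.index(mm)))
        counts[m] += 1
        assignment.append(m)
    rng = np.random.default_rng(seed)
    names = ["self_onset", "guess_onset", "guess_x_modulator", "photo_A", "photo_B"]
    base_b = dict(zip(names, np.asarray(betas, dtype=float)))
    cohort = []
    for s in range(n_subjects):
        session = _task.simulate_session(f"sub{s:02d}", int(rng.integers(2**31)))
        events = _neural.schedule_onsets(
            session, seed=int(rng.integers(2**31)), run_duration=n_scans * _neural.TR_DEFAULT
        )
        events = events[events["run"] < n_runs]
        runs = session.runs[:n_runs]
        series = {
            "dyadic": {r.run_id: _similarity.dyadic_series(r) for r in runs},
            "feature": {r.run_id: _similarity.feature_series(r) for r in runs},
            "latent": {r.run_id: _latent.latent_series(r) for r in runs},
        }
        designs = {
            m: _neural.build_design(events, series[m], n_scans=n_scans) for m in MODELS
        }
        ref = designs[MODELS[0]]
        signal = np.zeros(n_runs * n_scans)
        for col in ("self_onset", "guess_onset", "photo_A", "photo_B"):
            signal += base_b[col] * ref.matrix[col].to_numpy()
        gen_model = assignment[s]
        signal += base_b["guess_x_modulator"] * designs[gen_model].matrix[
            "guess_x_modulator"
        ].to_numpy()
        signal = signal + rng.normal(0.0, noise_sd, len(signal))
        cohort.append(
            SubjectRoiData(
                participant=session.participant_id,
                designs=designs,
                roi_series=signal,
                generator=gen_model,
            )
        )
    return cohort


def loso_harness(
    cohort: Sequence[SubjectRoiData],
    models: Sequence[str] = MODELS,
    roi_selector: Callable[[Sequence[SubjectRoiData]], object] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, BMSResult]:
    """Leave-one-subject-out model scoring pooled through group BMS.

    For each fold the ROI is defined from all subjects but one (in
    simulation the selector sees only the training subjects; the default
    keeps the ground-truth ROI-mean series, which is what training-set
    voxel selection reduces to when all ROI voxels share one generator) and
    the held-out subject's per-model GLMs are scored by BIC -> log evidence.
    Returns the subjects x models evidence matrix and the pooled BMS
    result; the fold count equals the number of subjects.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    rows = []
    for i, held_out in enumerate(cohort):
        train = [s for j, s in enumerate(cohort) if j != i]
        if roi_selector is not None:
            roi = roi_selector(train)
            if roi is None:
                raise ValueError("ROI selector returned a degenerate (empty) ROI")
        row = {m: bic_to_lme(glm_bic(held_out.designs[m], held_out.roi_series)) for m in models}
        rows.append(pd.Series(row, name=held_out.participant))
    evidence = pd.DataFrame(rows)
    return evidence, rfx_bms(evidence, alpha0=alpha0, n_samples=n_samples, seed=seed)
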