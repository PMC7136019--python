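"""Choice-behavior analysis: end-of-learning model predictions, ally-choice
logistic regressions with likelihood-ratio tests, and the neural-signal
augmented choice model.

The ally-choice outcome is whether the participant aligned with Agent B.
Fixed-effects logistic regressions relate it to Agent B's and Agent C's
agreement with the participant; nested models are compared with
likelihood-ratio tests. The augmented model asks whether a per-run neural
log-difference signal (A vs B), orthogonalized against the corresponding
model prediction, improves the fit beyond the model prediction alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from . import latent as _latent
from . import similarity as _similarity
from .task import RunSchedule

FORMULAS: dict[str, str] = {
    "B_only": "chose_B ~ agree_B",
    "B_and_C": "chose_B ~ agree_B + agree_C",
    "full_interaction": "chose_B ~ agree_B * agree_C",
    "condition_only": "chose_B ~ C(condition)",
}

EPS_LOG = 1e-6  # clip before logs of endpoint values


@dataclass(frozen=True)
class GLMFit:
    """Summary of a maximum-likelihood logistic fit."""

    formula: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    conf_int: pd.DataFrame  # columns (lower, upper), Wald 95%
    pvalues: pd.Series
    llf: float
    nobs: int
    separation: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.llf):
            raise ValueError("log-likelihood must be finite")
        lo, hi = self.conf_int.iloc[:, 0], self.conf_int.iloc[:, 1]
        if not ((lo <= self.params + 1e-9) & (self.params <= hi + 1e-9)).all():
            raise ValueError("confidence bounds must bracket the coefficients")

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "coefficients": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "z": self.zvalues.to_dict(),
            "ci_lower": self.conf_int.iloc[:, 0].to_dict(),
            "ci_upper": self.conf_int.iloc[:, 1].to_dict(),
            "p": self.pvalues.to_dict(),
            "llf": self.llf,
            "n_obs": self.nobs,
            "separation": self.separation,
        }


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of nested logistic models."""

    chi2: float
    df: int
    pvalue: float
    full_formula: str
    reduced_formula: str

    def __post_init__(self) -> None:
        if self.chi2 < -1e-8:
            raise ValueError("chi2 must be nonnegative")


@dataclass(frozen=True)
class ModelPrediction:
    """End-of-learning allyship estimates for Agents A and B under one model.

    ``log_diff = log(value_A) - log(value_B)``; a positive value favors
    Agent A, and the outcome modelled against it is "chose B".
    """

    model: str
    run_id: int
    value_A: float
    value_B: float
    log_diff: float = field(init=False)

    def __post_init__(self) -> None:
        for v in (self.value_A, self.value_B):
            if not 0.0 < v <= 1.0:
                raise ValueError("endpoint values must lie in (0, 1]")
        object.__setattr__(
            self,
            "log_diff",
            float(
                np.log(np.clip(self.value_A, EPS_LOG, None))
                - np.log(np.clip(self.value_B, EPS_LOG, None))
            ),
        )


def endpoint_predictions(
    run: RunSchedule,
    model: str,
    alpha: float = _latent.DEFAULT_ALPHA,
    gamma: float = _latent.DEFAULT_GAMMA,
) -> ModelPrediction:
    """Allyship estimates for A and B after all eight learning trials.

    Dyadic and feature values are evaluated at t = 9 (full history); the
    feature value is reported on the (0, 1) scale (before the log-odds
    transform) so its log difference is well-defined. The latent value is
    the posterior co-membership probability given the complete run.
    """
    if model == "dyadic":
        values = {
            agent: _similarity.dyadic_similarity(run.participant_agreement(agent), 9)
            for agent in ("A", "B")
        }
    elif model == "feature":
        m = _similarity.build_similarity_matrix(run, 9)
        values = {}
        for agent in ("A", "B"):
            log_odds = _similarity.feature_similarity(m, agent)
            values[agent] = float(1.0 / (1.0 + np.exp(-log_odds)))  # back to S_f scale
    elif model == "latent":
        post = _latent.partition_posterior(run.choice_matrix(), alpha=alpha, gamma=gamma)
        values = {
            agent: _latent.comembership_prob(post, "P", agent) for agent in ("A", "B")
        }
    else:
        raise ValueError("model must be 'dyadic', 'feature' or 'latent'")
    return ModelPrediction(
        model=model, run_id=run.run_id, value_A=values["A"], value_B=values["B"]
    )


def _fit_logit(formula: str, data: pd.DataFrame, tag: str) -> GLMFit:
    separation = False
    if data["chose_B"].nunique() < 2:
        separation = True
        warnings.warn(
            "outcome is constant: coefficients are not identified (degenerate fit)",
            UserWarning,
            stacklevel=3,
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = smf.logit(formula, data=data).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation or a failed Newton step
            separation = True
            res = smf.glm(formula, data=data, family=sm.families.Binomial()).fit(maxiter=200)
        if any("separat" in str(w.message).lower() for w in caught):
            separation = True
    if separation:
        warnings.warn(
            f"possible separation in logistic fit '{tag}': Wald statistics unreliable",
            UserWarning,
            stacklevel=3,
        )
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return GLMFit(
        formula=tag,
        params=res.params,
        bse=res.bse,
        zvalues=res.params / res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        llf=float(res.llf),
        nobs=int(res.nobs),
        separation=separation,
    )


def fit_allychoice_glm(data: pd.DataFrame, formula: str = "full_interaction") -> GLMFit:
    """Fixed-effects logistic regression of ally choice.

    ``data`` needs columns ``chose_B`` (0/1) plus ``agree_B``/``agree_C``
    (or ``condition`` for the condition-only model). ``formula`` is one of
    ``B_only``, ``B_and_C``, ``full_interaction``, ``condition_only``.
    Wald 95% CIs; perfect separation is flagged on the fit and warned about.
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {sorted(FORMULAS)}")
    if len(data) == 0:
        raise ValueError("no choice data to fit")
    return _fit_logit(FORMULAS[formula], data, formula)


def likelihood_ratio_test(full: GLMFit, reduced: GLMFit) -> LRTResult:
    """LRT of nested logistic fits: chi2 = 2(ll_full - ll_reduced)."""
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError(
            "reduced model is not nested in the full model "
            f"({reduced.formula} vs {full.formula})"
        )
    df = len(full.params) - len(reduced.params)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(
        chi2=chi2, df=df, pvalue=p, full_formula=full.formula, reduced_formula=reduced.formula
    )


def orthogonalize(x: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residual of regressing ``x`` on ``against`` plus an intercept."""
    x = np.asarray(x, dtype=float)
    design = np.column_stack([np.ones_like(x), np.asarray(against, dtype=float)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def augmented_choice_model(
    predictions: pd.DataFrame,
    neural_logdiff: pd.DataFrame,
    choices: pd.DataFrame,
) -> tuple[LRTResult, GLMFit, GLMFit]:
    """Does per-run neural signal improve the choice model beyond the
    behavioral model's predictions?

    ``predictions`` carries per-run ``log_diff`` of the model's endpoint
    allyship estimates (A vs B); ``neural_logdiff`` a per-run ``log_diff``
    of the decoded neural amplitudes; ``choices`` the per-run ``chose_B``.
    All are aligned on (participant, run) keys. The neural series is
    orthogonalized against the model log-difference before entering the
    augmented fit, so the LRT isolates genuinely extra-model signal.

    Returns ``(lrt, base_fit, augmented_fit)``.
    """
    keys = ["participant", "run"]
    preds = predictions.rename(columns={"log_diff": "model_logdiff"})
    neural = neural_logdiff.rename(columns={"log_diff": "neural_logdiff"})
    merged = preds.merge(neural, on=keys, validate="one_to_one").merge(
        choices[keys + ["chose_B"]], on=keys, validate="one_to_one"
    )
    if len(merged) != len(predictions):
        raise ValueError("misaligned (participant, run) keys across inputs")
    merged["neural_orth"] = orthogonalize(
        merged["neural_logdiff"].to_numpy(), merged["model_logdiff"].to_numpy()
    )
    base = _fit_logit("chose_B ~ model_logdiff", merged, "base")
    augmented = _fit_logit("chose_B ~ model_logdiff + neural_orth", merged, "augmented")
    return likelihood_ratio_test(augmented, base), base, augmented
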