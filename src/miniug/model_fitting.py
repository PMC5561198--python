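"""Per-subject maximum-likelihood fitting, BIC, and the reciprocity index.

The reciprocity index is the per-subject BIC difference
``BIC(inequity aversion) - BIC(reciprocity)``: positive values mean the
reciprocity model fits that subject's trial-by-trial choices better after
penalizing complexity (the reciprocity model has one fewer free parameter
at fixed softmax temperature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .games import ChoiceModelConfig
from .models import InequityAversionModel, ReciprocityModel, check_games_frame, encode_actions

__all__ = [
    "MODELS",
    "SubjectFit",
    "ReciprocityIndex",
    "log_likelihood",
    "fit_subject",
    "bic",
    "reciprocity_index",
    "grid_max_log_likelihood",
    "fit_cohort",
    "write_fits_tsv",
]

MODELS = ("inequity_aversion", "reciprocity")

_ESTIMATORS = {
    "inequity_aversion": InequityAversionModel,
    "reciprocity": ReciprocityModel,
}


@dataclass(frozen=True)
class SubjectFit:
    """One subject × one model maximum-likelihood fit summary."""

    subject_id: str
    model: str
    params: Mapping[str, float]
    log_likelihood: float
    n_trials: int
    n_params: int
    bic: float

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.log_likelihood > 1e-9:
            raise ValueError("log likelihood of binary choices cannot be positive")


@dataclass(frozen=True)
class ReciprocityIndex:
    """BIC(IE) − BIC(RC) for one subject; > 0 favors reciprocity."""

    subject_id: str
    value: float


def _make_estimator(model, config: ChoiceModelConfig | None, n_starts, tol, seed):
    if model not in _ESTIMATORS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    config = config or ChoiceModelConfig()
    kwargs = dict(
        temperature=config.temperature,
        free_temperature=config.free_temperature,
        n_starts=n_starts,
        tol=tol,
        random_state=seed,
    )
    if model == "reciprocity":
        kwargs["symmetric_kindness"] = config.symmetric_kindness
    return _ESTIMATORS[model](**kwargs)


def log_likelihood(trials, params, model, config: ChoiceModelConfig | None = None):
    """Log likelihood (nats) of observed accept/reject actions.

    Parameters
    ----------
    trials
        Games table with an ``action`` column, or a (games, actions) pair.
    params
        Mapping of parameter names to values (``alpha``/``beta`` for the
        inequity-aversion model, ``theta`` for reciprocity; ``inverse_temperature``
        additionally when the config frees the temperature).
    """
    X, y = _split_trials(trials)
    est = _make_estimator(model, config, n_starts=1, tol=1e-8, seed=0)
    order = list(est._param_names)
    if config is not None and config.free_temperature:
        order.append("inverse_temperature")
    try:
        vec = np.array([params[name] for name in order], dtype=float)
    except KeyError as e:
        raise ValueError(f"missing parameter {e.args[0]!r} for model {model}") from None
    return est.log_likelihood(X, y, params=vec)


def _split_trials(trials):
    if isinstance(trials, tuple) and len(trials) == 2:
        X, y = trials
        return check_games_frame(X), encode_actions(y)
    trials = pd.DataFrame(trials)
    if "action" not in trials.columns:
        raise ValueError("trials table needs an 'action' column (or pass (games, actions))")
    return check_games_frame(trials), encode_actions(trials["action"])


def fit_subject(trials, model, config: ChoiceModelConfig | None = None,
                n_starts: int = 20, tol: float = 1e-8, seed=None,
                subject_id: str = "") -> SubjectFit:
    """Fit one model to one subject's trials by multi-start constrained MLE."""
    X, y = _split_trials(trials)
    est = _make_estimator(model, config, n_starts=n_starts, tol=tol, seed=seed)
    est.fit(X, y)
    params = dict(est.params_)
    if getattr(est, "free_temperature", False):
        params["inverse_temperature"] = est.inverse_temperature_
    return SubjectFit(
        subject_id=str(subject_id),
        model=model,
        params=params,
        log_likelihood=est.log_likelihood_,
        n_trials=est.n_trials_,
        n_params=est.n_params_,
        bic=est.bic_,
    )


def bic(log_likelihood: float, n_params: int, n_trials: int) -> float:
    """Bayesian Information Criterion ``k*ln(n) - 2*ll`` (natural log)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return n_params * float(np.log(n_trials)) - 2.0 * log_likelihood


def reciprocity_index(fit_ie: SubjectFit, fit_rc: SubjectFit) -> ReciprocityIndex:
    """BIC difference BIC(IE) − BIC(RC); positive favors reciprocity."""
    if fit_ie.model != "inequity_aversion" or fit_rc.model != "reciprocity":
        raise ValueError("pass (inequity-aversion fit, reciprocity fit) in that order")
    if fit_ie.subject_id != fit_rc.subject_id or fit_ie.n_trials != fit_rc.n_trials:
        raise ValueError("fits must come from the same subject and trials")
    return ReciprocityIndex(subject_id=fit_ie.subject_id,
                            value=fit_ie.bic - fit_rc.bic)


def grid_max_log_likelihood(trials, model, config: ChoiceModelConfig | None = None,
                            step: float = 0.01):
    """Exhaustive grid maximum of the log likelihood over the unit box.

    Serves as the verification benchmark for :func:`fit_subject`: the
    optimizer's reported optimum must not fall below this grid maximum
    (minus numerical slack).  Only defined for the fixed-temperature models.
    """
    if config is not None and config.free_temperature:
        raise ValueError("grid verification is defined for fixed-temperature models")
    X, y = _split_trials(trials)
    est = _make_estimator(model, config, n_starts=1, tol=1e-8, seed=0)
    base, F = est._features(X)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    temperature = (config or ChoiceModelConfig()).temperature
    y = np.asarray(y)
    if F.shape[1] == 1:
        params = grid[:, None]
    else:
        a, b = np.meshgrid(grid, grid, indexing="ij")
        params = np.column_stack([a.ravel(), b.ravel()])
    u = base[None, :] + params @ F.T           # (n_grid, n_trials)
    z = u / temperature
    p_acc = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                     np.exp(np.minimum(z, 0)) / (1.0 + np.exp(np.minimum(z, 0))))
    p_obs = np.where(y[None, :] == 1, p_acc, 1.0 - p_acc)
    ll = np.log(np.maximum(p_obs, 1e-12)).sum(axis=1)
    i = int(np.argmax(ll))
    return float(ll[i]), dict(zip(est._param_names, params[i]))


def fit_cohort(trials: pd.DataFrame, config: ChoiceModelConfig | None = None,
               n_starts: int = 20, seed=None) -> pd.DataFrame:
    """Fit both models to every subject in a long trials table.

    ``trials`` needs columns ``subject_id``, the game columns, and ``action``.
    Returns one row per subject with parameters, log likelihoods, BICs and
    the reciprocity index.
    """
    if "subject_id" not in trials.columns:
        raise ValueError("trials table needs a 'subject_id' column")
    ss = np.random.SeedSequence(seed)
    rows = []
    subjects = list(pd.unique(trials["subject_id"]))
    child_seeds = ss.generate_state(2 * len(subjects)) % (2**31)
    for i, sid in enumerate(subjects):
        sub = trials[trials["subject_id"] == sid]
        fit_ie = fit_subject(sub, "inequity_aversion", config, n_starts=n_starts,
                             seed=int(child_seeds[2 * i]), subject_id=str(sid))
        fit_rc = fit_subject(sub, "reciprocity", config, n_starts=n_starts,
                             seed=int(child_seeds[2 * i + 1]), subject_id=str(sid))
        idx = reciprocity_index(fit_ie, fit_rc)
        rows.append({
            "subject_id": sid,
            "alpha": fit_ie.params["alpha"],
            "beta": fit_ie.params["beta"],
            "theta": fit_rc.params["theta"],
            "ll_ie": fit_ie.log_likelihood,
            "ll_rc": fit_rc.log_likelihood,
            "n_trials": fit_ie.n_trials,
            "bic_ie": fit_ie.bic,
            "bic_rc": fit_rc.bic,
            "reciprocity_index": idx.value,
        })
    return pd.DataFrame(rows)


def write_fits_tsv(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)
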