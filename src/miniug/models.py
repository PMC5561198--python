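"""Scikit-learn style estimators for mini-UG responder choice models.

Both models map a table of games (columns ``x_i, x_j, x_i_alt, x_j_alt,
condition``) and binary accept/reject outcomes to maximum-likelihood
parameter estimates under a two-action softmax.  The accept utility of each
model is *linear* in its free parameters given per-game features, so the
likelihood is evaluated on aggregated unique games for speed.

Fitting maximizes the log likelihood ``ll = sum_t log p(choice_t)`` over the
unit box by multi-start L-BFGS-B, with starts drawn from a seeded Latin
hypercube.  Fits are summarized by BIC ``k*ln(n) - 2*ll`` (natural log).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .games import (
    CONDITIONS,
    NO_ALTERNATIVE,
    context_switch,
    kindness_to_proposer,
    kindness_to_responder,
)

__all__ = [
    "InequityAversionModel",
    "ReciprocityModel",
    "PROB_FLOOR",
    "check_games_frame",
    "encode_actions",
]

PROB_FLOOR = 1e-12  # keeps the log likelihood finite at boundary parameters

# box for the free inverse-temperature parameter (dimensionless)
_INVTEMP_BOUNDS = (1e-3, 50.0)
_INVTEMP_START_RANGE = (0.05, 10.0)

GAME_COLUMNS = ("x_i", "x_j", "x_i_alt", "x_j_alt", "condition")


def check_games_frame(X) -> pd.DataFrame:
    """Validate a games table and return it as a DataFrame.

    Enforces the mini-UG invariants: non-negative payoffs, equal stakes for
    the chosen and alternative divisions, known condition labels, and
    no-alternative games having alternative == chosen.
    """
    X = pd.DataFrame(X)
    missing = [c for c in GAME_COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"games table is missing columns {missing}")
    if len(X) == 0:
        raise ValueError("games table is empty")
    bad = ~X["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(
            f"unknown condition labels: {sorted(X.loc[bad, 'condition'].unique())}"
        )
    pay = X[["x_i", "x_j", "x_i_alt", "x_j_alt"]].to_numpy(dtype=float)
    if not np.isfinite(pay).all() or (pay < 0).any():
        raise ValueError("payoffs must be finite and non-negative")
    if not np.allclose(pay[:, 0] + pay[:, 1], pay[:, 2] + pay[:, 3]):
        raise ValueError("chosen and alternative divisions must split the same stake")
    no_alt = X["condition"].to_numpy() == NO_ALTERNATIVE
    same = (pay[:, 0] == pay[:, 2]) & (pay[:, 1] == pay[:, 3])
    if (no_alt != same).any():
        raise ValueError(
            "condition must be no_alternative exactly when the alternative "
            "division equals the chosen one"
        )
    return X


def encode_actions(y) -> np.ndarray:
    """Encode accept/reject outcomes as 1/0 integers.

    Accepts integers/booleans or the strings ``accept``/``reject``.
    """
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        mapping = {"accept": 1, "reject": 0}
        try:
            y = np.array([mapping[str(v)] for v in y])
        except KeyError as e:
            raise ValueError(f"unknown action label {e.args[0]!r}") from None
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("actions must be binary accept(1)/reject(0)")
    return y


def _aggregate(features: np.ndarray, y: np.ndarray):
    """Collapse trials to unique (feature row, outcome) pairs with counts."""
    key = np.column_stack([features, y])
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq[:, :-1], uniq[:, -1].astype(int), counts.astype(float)


class _BaseUGModel(ClassifierMixin, BaseEstimator):
    """Shared machinery: feature extraction, softmax likelihood, multi-start
    bounded maximum-likelihood fitting, BIC."""

    _param_names: tuple[str, ...] = ()

    def __init__(self, temperature=1.0, free_temperature=False, n_starts=20,
                 tol=1e-8, random_state=None):
        self.temperature = temperature
        self.free_temperature = free_temperature
        self.n_starts = n_starts
        self.tol = tol
        self.random_state = random_state

    # subclasses provide the accept-utility feature map: u = base + F @ params
    def _features(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _accept_utility(self, base, F, params):
        return base + F @ np.asarray(params, dtype=float)

    def _nll(self, theta_full, base, F, y, counts):
        k = len(self._param_names)
        u = self._accept_utility(base, F, theta_full[:k])
        if self.free_temperature:
            scaled = theta_full[k] * u
        else:
            scaled = u / self.temperature
        # p(accept) with u_reject = 0, stable logistic
        p_acc = np.where(scaled >= 0,
                         1.0 / (1.0 + np.exp(-scaled)),
                         np.exp(scaled) / (1.0 + np.exp(scaled)))
        p_obs = np.where(y == 1, p_acc, 1.0 - p_acc)
        return -np.sum(counts * np.log(np.maximum(p_obs, PROB_FLOOR)))

    def log_likelihood(self, X, y, params=None):
        """Log likelihood (nats) of accept/reject outcomes given parameters.

        ``params`` defaults to the fitted parameter vector; pass an explicit
        sequence (ordered as ``param_names_``, plus the inverse temperature
        last when ``free_temperature``) to evaluate elsewhere.
        """
        X = check_games_frame(X)
        y = encode_actions(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        base, F = self._features(X)
        if params is None:
            check_is_fitted(self, "params_")
            params = self._theta_full_
        params = np.asarray(params, dtype=float)
        self._check_box(params)
        return -self._nll(params, base, F, y, np.ones(len(y)))

    def _check_box(self, theta_full):
        k = len(self._param_names)
        expected = k + (1 if self.free_temperature else 0)
        if theta_full.shape != (expected,):
            raise ValueError(
                f"expected {expected} parameters ({self._param_names}"
                f"{' + inverse temperature' if self.free_temperature else ''})"
            )
        if (theta_full[:k] < 0).any() or (theta_full[:k] > 1).any():
            raise ValueError("model parameters must lie in [0, 1]")
        if self.free_temperature and theta_full[k] <= 0:
            raise ValueError("inverse temperature must be positive")

    def _starts(self, rng_seed, n_free):
        sampler = qmc.LatinHypercube(d=n_free, seed=rng_seed)
        pts = sampler.random(self.n_starts)
        if self.free_temperature:
            lo, hi = _INVTEMP_START_RANGE
            pts[:, -1] = lo + pts[:, -1] * (hi - lo)
        return pts

    def fit(self, X, y):
        """Maximum-likelihood fit over the unit parameter box.

        Multi-start bounded L-BFGS-B from a seeded Latin hypercube; the best
        start wins.  With ``free_temperature`` the fixed-temperature optimum
        is added as an extra start, so freeing the temperature can never
        decrease the maximized log likelihood.
        """
        X = check_games_frame(X)
        y = encode_actions(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        base, F = self._features(X)
        feats = np.column_stack([base, F])
        agg_feats, agg_y, counts = _aggregate(feats, y)
        agg_base, agg_F = agg_feats[:, 0], agg_feats[:, 1:]

        k = len(self._param_names)
        n_free = k + (1 if self.free_temperature else 0)
        bounds = [(0.0, 1.0)] * k
        if self.free_temperature:
            bounds.append(_INVTEMP_BOUNDS)

        seed = self.random_state
        starts = self._starts(seed, n_free)
        if self.free_temperature:
            fixed = type(self)(temperature=self.temperature,
                               free_temperature=False,
                               n_starts=self.n_starts, tol=self.tol,
                               random_state=self.random_state).fit(X, y)
            extra = np.append(fixed._theta_full_, 1.0 / self.temperature)
            starts = np.vstack([starts, extra])

        best = None
        failures = []
        args = (agg_base, agg_F, agg_y, counts)
        for x0 in starts:
            res = optimize.minimize(
                self._nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "gtol": 1e-10, "maxiter": 500},
            )
            if not np.isfinite(res.fun):
                failures.append(res.message)
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"optimizer failed from every start: {failures[:3]}"
            )

        self._theta_full_ = np.asarray(best.x, dtype=float)
        self.params_ = dict(zip(self._param_names, self._theta_full_[:k]))
        for name, value in self.params_.items():
            setattr(self, f"{name}_", float(value))
        if self.free_temperature:
            self.inverse_temperature_ = float(self._theta_full_[k])
        self.log_likelihood_ = float(-best.fun)
        self.n_trials_ = int(len(y))
        self.n_params_ = int(n_free)
        self.bic_ = float(self.n_params_ * np.log(self.n_trials_)
                          - 2.0 * self.log_likelihood_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(GAME_COLUMNS)
        return self

    def predict_proba(self, X):
        """Per-game [p(reject), p(accept)] under the fitted parameters."""
        check_is_fitted(self, "params_")
        X = check_games_frame(X)
        base, F = self._features(X)
        k = len(self._param_names)
        u = self._accept_utility(base, F, self._theta_full_[:k])
        scale = (self.inverse_temperature_ if self.free_temperature
                 else 1.0 / self.temperature)
        z = scale * u
        p_acc = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                         np.exp(z) / (1.0 + np.exp(z)))
        return np.column_stack([1.0 - p_acc, p_acc])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-trial log likelihood (nats)."""
        return self.log_likelihood(X, y) / len(pd.DataFrame(X))


class InequityAversionModel(_BaseUGModel):
    """Fehr–Schmidt inequity-aversion responder model.

    Accept utility ``x_j - alpha*max(x_i - x_j, 0) - beta*max(x_j - x_i, 0)``
    depends only on the chosen division, so the model predicts identical
    acceptance of a given offer across all alternative-set conditions.

    Fitted attributes: ``alpha_``, ``beta_``, ``log_likelihood_``, ``bic_``,
    ``n_params_`` (2, or 3 with a free inverse temperature).
    """

    _param_names = ("alpha", "beta")

    def _features(self, X):
        x_i = X["x_i"].to_numpy(dtype=float)
        x_j = X["x_j"].to_numpy(dtype=float)
        F = np.column_stack([
            -np.maximum(x_i - x_j, 0.0),  # weight alpha
            -np.maximum(x_j - x_i, 0.0),  # weight beta
        ])
        return x_j, F


class ReciprocityModel(_BaseUGModel):
    """Intention-based reciprocity responder model.

    Accept utility ``x_j + c*theta*k_i*k_j`` with kindness terms computed
    from the proposer's declined alternative; one free parameter ``theta``.

    Fitted attributes: ``theta_``, ``log_likelihood_``, ``bic_``,
    ``n_params_`` (1, or 2 with a free inverse temperature).
    """

    _param_names = ("theta",)

    def __init__(self, temperature=1.0, free_temperature=False, n_starts=20,
                 tol=1e-8, random_state=None, symmetric_kindness=False):
        super().__init__(temperature=temperature,
                         free_temperature=free_temperature,
                         n_starts=n_starts, tol=tol, random_state=random_state)
        self.symmetric_kindness = symmetric_kindness

    def _features(self, X):
        x_j = X["x_j"].to_numpy(dtype=float)
        k_i = kindness_to_responder(X)
        k_j = kindness_to_proposer(X, k_i, symmetric=self.symmetric_kindness)
        c = context_switch(X, k_j)
        return x_j, (c * k_i * k_j)[:, None]
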