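"""Model simulation: predicted acceptance over parameter grids, and
stochastic choice generation.

The grid simulation sweeps each model's parameters over [0, 1] (step 0.01 by
default) and reports the softmax probability of accepting an unfair offer in
each alternative-set condition, plus the grid average per condition.  The
inequity-aversion model ignores the declined alternative, so its predicted
acceptance of a given offer is identical across conditions; the reciprocity
model predicts the highest acceptance when the proposer had no alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .games import (
    CONDITIONS,
    FAIR_ALTERNATIVE,
    HYPERFAIR_ALTERNATIVE,
    NO_ALTERNATIVE,
    ChoiceModelConfig,
    Game,
    IEParams,
    RCParams,
    choice_probability,
    utility_inequity_aversion,
    utility_reciprocity,
)

__all__ = [
    "default_game_menu",
    "SimulationGrid",
    "simulate_acceptance_grid",
    "simulate_choices",
]


def default_game_menu(offers=((8, 2), (7, 3))) -> dict[str, list[Game]]:
    """Per-condition menus of unfair-offer games.

    For each unfair division (proposer, responder): the fair-alternative
    condition pits it against 5/5, the hyperfair-alternative condition
    against its mirror image, and the no-alternative condition against
    itself.  The exact trial composition of the original task is not
    published, so the menu is configurable.
    """
    menu: dict[str, list[Game]] = {c: [] for c in CONDITIONS}
    for x_i, x_j in offers:
        stake = x_i + x_j
        menu[NO_ALTERNATIVE].append(
            Game(x_i, x_j, x_i, x_j, NO_ALTERNATIVE))
        menu[FAIR_ALTERNATIVE].append(
            Game(x_i, x_j, stake / 2, stake / 2, FAIR_ALTERNATIVE))
        menu[HYPERFAIR_ALTERNATIVE].append(
            Game(x_i, x_j, x_j, x_i, HYPERFAIR_ALTERNATIVE))
    return menu


@dataclass(frozen=True)
class SimulationGrid:
    """Long-format grid of predicted acceptance probabilities.

    ``table`` has one row per (grid point, condition, game) with columns for
    the parameter values and ``p_accept``; ``condition_means`` averages
    ``p_accept`` over the grid per condition (the headline simulation
    summary).
    """

    model: str
    table: pd.DataFrame
    condition_means: pd.Series

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _accept_utility(model, game, params_row, symmetric=False):
    if model == "inequity_aversion":
        return utility_inequity_aversion(game, IEParams(*params_row))
    if model == "reciprocity":
        return utility_reciprocity(game, RCParams(*params_row),
                                   symmetric=symmetric)
    raise ValueError(f"unknown model {model!r}")


def simulate_acceptance_grid(model: str, games: dict[str, list[Game]] | None = None,
                             config: ChoiceModelConfig | None = None,
                             start: float = 0.0, stop: float = 1.0,
                             step: float = 0.01) -> SimulationGrid:
    """Predicted p(accept) per condition over a parameter grid.

    ``games`` maps condition → list of games; by default only the 8/2 offer
    enters (the headline simulation sweeps acceptance of the 8/2 offer).
    The reciprocity model sweeps ``theta``; the inequity-aversion model
    sweeps ``alpha`` and ``beta`` over the full 2-D grid.
    """
    config = config or ChoiceModelConfig()
    if games is None:
        games = default_game_menu(offers=((8, 2),))
    if not games or any(len(v) == 0 for v in games.values()):
        raise ValueError("each condition needs at least one game")
    grid = np.arange(start, stop + step / 2, step)
    if model == "reciprocity":
        param_cols = ["theta"]
        points = grid[:, None]
    elif model == "inequity_aversion":
        param_cols = ["alpha", "beta"]
        a, b = np.meshgrid(grid, grid, indexing="ij")
        points = np.column_stack([a.ravel(), b.ravel()])
    else:
        raise ValueError(f"unknown model {model!r}")

    rows = []
    for condition, game_list in games.items():
        for g_idx, game in enumerate(game_list):
            for pt in points:
                u = _accept_utility(model, game, pt,
                                    symmetric=config.symmetric_kindness)
                p = choice_probability(u, 0.0, config)
                row = dict(zip(param_cols, pt))
                row.update(model=model, condition=condition, game=g_idx,
                           p_accept=p)
                rows.append(row)
    table = pd.DataFrame(rows)
    means = table.groupby("condition")["p_accept"].mean()
    return SimulationGrid(model=model, table=table, condition_means=means)


def simulate_choices(trials, model: str, params,
                     config: ChoiceModelConfig | None = None,
                     seed=None) -> np.ndarray:
    """One Bernoulli accept/reject draw per trial at the model's p(accept).

    ``trials`` is a games table (or iterable of :class:`Game`); ``params``
    is an ``IEParams``/``RCParams`` instance or a mapping.  Reproducible
    given ``seed``.
    """
    from .games import games_to_frame
    from .models import check_games_frame

    config = config or ChoiceModelConfig()
    if not isinstance(trials, pd.DataFrame):
        trials = games_to_frame(trials)
    trials = check_games_frame(trials)

    if isinstance(params, dict):
        if model == "inequity_aversion":
            params = IEParams(params["alpha"], params["beta"])
        else:
            params = RCParams(params["theta"])
    if model == "inequity_aversion":
        u = utility_inequity_aversion(trials, params)
    elif model == "reciprocity":
        u = utility_reciprocity(trials, params,
                                symmetric=config.symmetric_kindness)
    else:
        raise ValueError(f"unknown model {model!r}")
    p = np.atleast_1d(choice_probability(u, 0.0, config))
    rng = np.random.default_rng(seed)
    return (rng.random(len(trials)) < p).astype(int)
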