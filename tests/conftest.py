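import numpy as np
import pandas as pd
import pytest

from miniug.games import (
    FAIR_ALTERNATIVE,
    HYPERFAIR_ALTERNATIVE,
    NO_ALTERNATIVE,
    Game,
)


@pytest.fixture
def unfair_games():
    """The 8/2 offer in each alternative-set condition."""
    return {
        NO_ALTERNATIVE: Game(8, 2, 8, 2, NO_ALTERNATIVE),
        FAIR_ALTERNATIVE: Game(8, 2, 5, 5, FAIR_ALTERNATIVE),
        HYPERFAIR_ALTERNATIVE: Game(8, 2, 2, 8, HYPERFAIR_ALTERNATIVE),
    }


@pytest.fixture
def trials_frame(unfair_games):
    """A small balanced games table (no actions)."""
    rows = []
    for g in unfair_games.values():
        for _ in range(4):
            rows.append({"x_i": g.x_i, "x_j": g.x_j, "x_i_alt": g.x_i_alt,
                         "x_j_alt": g.x_j_alt, "condition": g.condition})
    return pd.DataFrame(rows)


@pytest.fixture
def small_config():
    from miniug.synthetic_data import GeneratorConfig

    return GeneratorConfig(n_subjects=8, n_boot=1000, n_perm=200, seed=7)
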