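"""Meta-analytic reverse-inference decoding of a statistic map.

A brain statistic map (e.g. signed -log10 p of a thickness–behavior
correlation) is characterized by its Spearman rank correlation with each map
in a library of meta-analytic topic-association maps, over the voxels common
to both masks.  Each correlation gets a permutation p-value (voxel-wise
shuffling of the statistic map within the joint mask, two-sided on |rho|);
topics are then ranked by correlation and each rank gets a stability
p-value; finally Benjamini–Hochberg FDR at q < 0.05 flags significant
topics.

The voxel-shuffling null assumes exchangeable voxels; it does not preserve
spatial autocorrelation, so p-values on smooth maps are optimistic (see the
methods note).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "as_volume",
    "intersect_mask",
    "spatial_correlation",
    "permutation_p",
    "rank_stability",
    "fdr_adjust",
    "decode",
]


def as_volume(obj) -> np.ndarray:
    """Return the voxel data of a map given an ndarray, a nibabel image, or
    a NIfTI file path."""
    if isinstance(obj, np.ndarray):
        return obj
    if isinstance(obj, (str,)) or hasattr(obj, "__fspath__"):
        import nibabel as nib

        obj = nib.load(str(obj))
    if hasattr(obj, "get_fdata"):
        return np.asarray(obj.get_fdata())
    raise TypeError(f"cannot interpret {type(obj).__name__} as a volume")


def intersect_mask(stat, topic) -> np.ndarray:
    """Boolean mask of voxels valid in both maps.

    A voxel is valid when its value is finite and nonzero (zero is the
    conventional out-of-mask background).  Raises on grid mismatch or an
    empty intersection.
    """
    stat = as_volume(stat)
    topic = as_volume(topic)
    if stat.shape != topic.shape:
        raise ValueError(f"grid mismatch: {stat.shape} vs {topic.shape}")
    mask = (np.isfinite(stat) & (stat != 0)
            & np.isfinite(topic) & (topic != 0))
    if not mask.any():
        raise ValueError("empty mask intersection")
    return mask


def spatial_correlation(stat, topic, mask: np.ndarray | None = None) -> float:
    """Spearman rank correlation between two maps over their joint mask
    (ties mid-ranked)."""
    stat = as_volume(stat)
    topic = as_volume(topic)
    if mask is None:
        mask = intersect_mask(stat, topic)
    a, b = stat[mask], topic[mask]
    if a.size < 10:
        raise ValueError(f"need >= 10 intersection voxels, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map within the mask")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def permutation_p(stat, topic, n_perm: int = 10_000, seed=None,
                  mask: np.ndarray | None = None) -> float:
    """Two-sided permutation p-value for the Spearman correlation.

    The statistic map's voxel values are shuffled within the joint mask;
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1).  Since a
    permutation of values permutes their ranks, each null draw reduces to a
    Pearson correlation of shuffled rank vectors.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stat = as_volume(stat)
    topic = as_volume(topic)
    if mask is None:
        mask = intersect_mask(stat, topic)
    a, b = stat[mask], topic[mask]
    rho_obs = spatial_correlation(stat, topic, mask=mask)

    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = (ra - ra.mean()) / ra.std()
    rb = (rb - rb.mean()) / rb.std()
    nv = ra.size
    rng = np.random.default_rng(seed)
    hits = 0
    thresh = abs(rho_obs) - 1e-12
    for _ in range(n_perm):
        rho_p = float(rng.permutation(ra) @ rb) / nv
        if abs(rho_p) >= thresh:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def rank_stability(correlations, n_perm: int = 10_000, seed=None,
                   direction: str = "negative") -> pd.DataFrame:
    """Stability of each topic's rank in the sorted correlation vector.

    Topics are ranked from most extreme in ``direction`` ('negative' sorts
    smallest-first, the convention when the statistic map correlates
    negatively with the variable of interest).  For the topic at rank r, the
    correlation vector is permuted ``n_perm`` times and the topic's own
    correlation is compared with the mean of the permuted values occupying
    all lower ranks; the empirical p counts the permutations in which it
    fails to exceed that mean (ties count one half), with an add-one rule.
    A dominant rank-1 topic therefore gets p = 1/(n_perm+1), and a fully
    tied vector gives uninformative p ≈ 0.5.

    ``correlations`` is a mapping or Series topic → rho.  Ties in rho are
    broken by topic-name order (a warning notes it).
    """
    s = pd.Series(correlations, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 topics")
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    if s.duplicated().any():
        warnings.warn("tied correlations; ranks broken by topic-name order",
                      stacklevel=2)
    oriented = -s if direction == "negative" else s
    order = sorted(s.index, key=lambda t: (-oriented[t], str(t)))
    vals = oriented.loc[order].to_numpy()  # descending extremeness
    n = len(vals)
    rng = np.random.default_rng(seed)
    not_exceeded = np.zeros(n)
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        # suffix means: mean of permuted values at ranks below each position
        csum = np.cumsum(perm[::-1])[::-1]
        lower_n = np.arange(n - 1, -1, -1, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lower_mean = np.where(lower_n > 0, (csum - perm) / np.maximum(lower_n, 1),
                                  np.nan)
        diff = vals - lower_mean
        not_exceeded[:-1] += np.where(diff[:-1] > 1e-12, 0.0,
                                      np.where(diff[:-1] < -1e-12, 1.0, 0.5))
    p = (1.0 + not_exceeded) / (n_perm + 1.0)
    p[-1] = 1.0  # last rank has no lower ranks to exceed
    return pd.DataFrame({"topic": order,
                         "rank": np.arange(1, n + 1),
                         "rank_p": p}).set_index("topic")


def fdr_adjust(p_values, q: float = 0.05):
    """Benjamini–Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(pd.Series(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    flags = multipletests(p, alpha=q, method="fdr_bh")[0]
    if isinstance(p_values, (pd.Series, dict)):
        return pd.Series(flags, index=pd.Series(p_values).index)
    return flags


def decode(stat, topic_maps: dict, n_perm: int = 10_000, seed=None,
           direction: str = "negative", q: float = 0.05) -> pd.DataFrame:
    """Full decoding of one statistic map against a topic-map library.

    Returns a DataFrame indexed by topic with columns ``rho``, ``p``
    (voxel-permutation), ``rank``, ``rank_p`` (rank-stability permutation)
    and ``significant`` (BH-FDR on the first-stage p at level ``q``),
    sorted by rank (most extreme in ``direction`` first).
    """
    stat = as_volume(stat)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(topic_maps) + 1) % (2**31)
    names = list(topic_maps)
    rhos, ps = {}, {}
    for i, name in enumerate(names):
        topic = as_volume(topic_maps[name])
        mask = intersect_mask(stat, topic)
        rhos[name] = spatial_correlation(stat, topic, mask=mask)
        ps[name] = permutation_p(stat, topic, n_perm=n_perm,
                                 seed=int(seeds[i]), mask=mask)
    ranks = rank_stability(rhos, n_perm=n_perm, seed=int(seeds[-1]),
                           direction=direction)
    out = pd.DataFrame({"rho": pd.Series(rhos), "p": pd.Series(ps)})
    out = out.join(ranks)
    out["significant"] = fdr_adjust(out["p"], q=q)
    return out.sort_values("rank")
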