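"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates a developmental mini-UG study: ~84 subjects aged
9–23 play 168 single-shot games split evenly across the three
alternative-set conditions, with unfair chosen offers about two thirds of
the time.  Other-regarding preferences shift with age: the latent
reciprocity concern ``theta`` rises along a logistic curve crossing over in
late adolescence, while inequity-aversion weights stay flat, and each
subject's generating model (inequity aversion vs. reciprocity) is drawn
with an age-dependent probability.  Regional cortical thickness declines
linearly with age, and a constructed reciprocity index depends on thickness
(plus an optional direct age term), so the true mediation paths are known
by construction.  Volumetric fixture maps place a shared signal region in
the statistic map and one designated topic map.

Everything is reproducible from one master seed; each stage derives its own
stream so stages can also be rerun independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .games import (
    CONDITIONS,
    FAIR_ALTERNATIVE,
    HYPERFAIR_ALTERNATIVE,
    NO_ALTERNATIVE,
    ChoiceModelConfig,
)

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "generate_trials",
    "generate_choices",
    "generate_thickness",
    "true_mediation_effects",
    "generate_maps",
    "run_pipeline",
    "save_maps_nifti",
]

# fixed per-stage tags so stage streams are independent of call order
_STAGE = {"cohort": 1, "trials": 2, "choices": 3, "thickness": 4,
          "maps": 5, "fitting": 6, "mediation": 7, "decoding": 8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic world.

    Defaults encode the emulated design: 84 analyzed subjects aged 9–23,
    168 trials each, two-thirds unfair chosen offers, a preference
    crossover around age 17.5, age-thinning cortex (0.05 mm/yr) whose
    thickness fully mediates the constructed age → index relation
    (direct effect 0).
    """

    # cohort
    n_subjects: int = 84
    age_min: float = 9.0
    age_max: float = 23.0
    iq_mean: float = 105.0
    iq_sd: float = 12.0
    # latent preferences
    crossover_age: float = 17.5
    theta_scale: float = 2.0      # yr; logistic slope of theta(age)
    theta_max: float = 0.8
    theta_noise: float = 0.08
    alpha_mean: float = 0.7
    alpha_sd: float = 0.15
    beta_mean: float = 0.15
    beta_sd: float = 0.08
    model_scale: float = 2.0      # yr; logistic slope of P(reciprocity|age)
    # trials
    trials_per_subject: int = 168
    unfair_fraction: float = 2.0 / 3.0
    offers: tuple = ((8, 2), (7, 3))
    # thickness / mediation (units: mm, yr, index units)
    rois: tuple = ("right_mpfc", "left_mpfc")
    thickness_baseline: float = 3.6
    thickness_slope: float = 0.05     # mm per yr decline (path a = -slope)
    thickness_noise: float = 0.15
    mediation_roi: str = "right_mpfc"
    index_intercept: float = 300.0
    thickness_to_index: float = -100.0  # path b, index units per mm
    direct_effect: float = 0.0          # residual age -> index path
    index_noise: float = 20.0
    # volumetric maps
    grid_shape: tuple = (20, 20, 20)
    n_topics: int = 41
    target_topic: str = "social_inference"
    region_origin: tuple = (4, 4, 4)
    region_size: int = 8
    map_signal: float = 4.0
    map_noise_sd: float = 1.0
    map_smooth_sigma: float = 1.0
    # analysis knobs used by run_pipeline
    n_starts: int = 20
    n_boot: int = 2000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.trials_per_subject <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.unfair_fraction <= 1.0:
            raise ValueError("unfair_fraction must lie in [0, 1]")
        if self.trials_per_subject % len(CONDITIONS):
            raise ValueError("trials_per_subject must divide evenly into "
                             f"{len(CONDITIONS)} conditions")
        if self.mediation_roi not in self.rois:
            raise ValueError("mediation_roi must be one of rois")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("offers", "rois", "grid_shape", "region_origin"):
            if key in raw:
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key]) if key == "offers" else tuple(raw[key])
        return cls(**raw)


def _rng(config: GeneratorConfig, stage: str, seed=None) -> np.random.Generator:
    if seed is not None:
        return np.random.default_rng(seed)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGE[stage],)))


def generate_cohort(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Ages, sex, IQ and latent preference parameters per subject.

    theta rises with age along a logistic curve (plus noise, clipped to
    [0, 1]); alpha and beta are age-flat; each subject's generating model is
    reciprocity with probability logistic((age - crossover)/scale).
    """
    rng = _rng(config, "cohort", seed)
    n = config.n_subjects
    cols = ["subject_id", "age", "sex", "iq", "theta_true", "alpha_true",
            "beta_true", "gen_model"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    age = rng.uniform(config.age_min, config.age_max, n)
    sex = rng.integers(0, 2, n)
    iq = rng.normal(config.iq_mean, config.iq_sd, n)
    theta = config.theta_max * expit((age - config.crossover_age) / config.theta_scale)
    theta = np.clip(theta + rng.normal(0, config.theta_noise, n), 0, 1)
    alpha = np.clip(rng.normal(config.alpha_mean, config.alpha_sd, n), 0, 1)
    beta = np.clip(rng.normal(config.beta_mean, config.beta_sd, n), 0, 1)
    p_rc = expit((age - config.crossover_age) / config.model_scale)
    gen_model = np.where(rng.random(n) < p_rc, "reciprocity", "inequity_aversion")
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "age": age, "sex": sex, "iq": iq,
        "theta_true": theta, "alpha_true": alpha, "beta_true": beta,
        "gen_model": gen_model,
    })


def _subject_trials(config: GeneratorConfig, rng) -> pd.DataFrame:
    per_cond = config.trials_per_subject // len(CONDITIONS)
    # chosen offer is unfair with this probability inside the two
    # alternative conditions, so the overall unfair fraction matches config
    # (no-alternative trials are always unfair)
    p_unfair_alt = np.clip((len(CONDITIONS) * config.unfair_fraction - 1)
                           / (len(CONDITIONS) - 1), 0, 1)
    rows = []
    for condition in CONDITIONS:
        for _ in range(per_cond):
            x_i, x_j = config.offers[rng.integers(len(config.offers))]
            stake = x_i + x_j
            if condition == NO_ALTERNATIVE:
                chosen, alt = (x_i, x_j), (x_i, x_j)
            else:
                if condition == FAIR_ALTERNATIVE:
                    other = (stake / 2, stake / 2)
                else:
                    other = (x_j, x_i)
                if rng.random() < p_unfair_alt:
                    chosen, alt = (x_i, x_j), other
                else:
                    chosen, alt = other, (x_i, x_j)
            rows.append((condition, *chosen, *alt))
    rng.shuffle(rows)  # pseudorandom condition order
    return pd.DataFrame(rows, columns=["condition", "x_i", "x_j",
                                       "x_i_alt", "x_j_alt"])


def generate_trials(config: GeneratorConfig, seed=None,
                    subject_ids=None) -> pd.DataFrame:
    """Per-subject game schedules: equal condition counts in seeded
    pseudorandom order, chosen-offer unfairness per config."""
    rng = _rng(config, "trials", seed)
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(config.n_subjects)]
    frames = []
    for sid in subject_ids:
        df = _subject_trials(config, rng)
        df.insert(0, "subject_id", sid)
        df.insert(1, "trial", np.arange(len(df)))
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["subject_id", "trial", "condition",
                                     "x_i", "x_j", "x_i_alt", "x_j_alt"])
    return pd.concat(frames, ignore_index=True)


def generate_choices(trials: pd.DataFrame, cohort: pd.DataFrame,
                     config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Simulate each subject's accept/reject actions under their generating
    model and latent parameters; returns trials with an ``action`` column."""
    from .simulation import simulate_choices

    rng = _rng(config, "choices", seed)
    sub_seeds = rng.integers(0, 2**31, len(cohort))
    pieces = []
    for (sid, row), s in zip(cohort.set_index("subject_id").iterrows(), sub_seeds):
        sub = trials[trials["subject_id"] == sid].copy()
        if row["gen_model"] == "reciprocity":
            params = {"theta": row["theta_true"]}
        else:
            params = {"alpha": row["alpha_true"], "beta": row["beta_true"]}
        sub["action"] = simulate_choices(sub, row["gen_model"], params,
                                         ChoiceModelConfig(), seed=int(s))
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)


def generate_thickness(cohort: pd.DataFrame, config: GeneratorConfig,
                       seed=None) -> pd.DataFrame:
    """ROI thickness declining with age, plus a constructed reciprocity
    index with known mediation structure.

    thickness = baseline - slope*age + noise for every ROI; the index is
    intercept + b*thickness(mediation ROI) + direct*age + noise, so the
    true indirect effect is (-slope)*b and the true direct effect is the
    config's ``direct_effect``.
    """
    rng = _rng(config, "thickness", seed)
    n = len(cohort)
    out = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})
    age = cohort["age"].to_numpy(float)
    for roi in config.rois:
        out[roi] = (config.thickness_baseline - config.thickness_slope * age
                    + rng.normal(0, config.thickness_noise, n))
    out["reciprocity_index"] = (
        config.index_intercept
        + config.thickness_to_index * out[config.mediation_roi].to_numpy()
        + config.direct_effect * age
        + rng.normal(0, config.index_noise, n)
    )
    return out


def true_mediation_effects(config: GeneratorConfig) -> dict:
    """Ground-truth mediation paths implied by the generator config."""
    a = -config.thickness_slope
    b = config.thickness_to_index
    return {"path_a": a, "path_b": b, "indirect": a * b,
            "direct": config.direct_effect,
            "total": a * b + config.direct_effect}


def generate_maps(config: GeneratorConfig, seed=None):
    """Statistic map + topic-map library with one shared signal region.

    All maps are smoothed Gaussian noise on the config grid.  A contiguous
    cubic region carries negative signal in the statistic map and positive
    signal in the designated target topic, so the target attains the most
    negative spatial correlation.  Returns (stat, topics, truth) where
    ``truth`` records the target topic and region bookkeeping.
    """
    rng = _rng(config, "maps", seed)
    shape = tuple(config.grid_shape)
    o, s = config.region_origin, config.region_size
    region = tuple(slice(o[d], o[d] + s) for d in range(3))

    def noise():
        x = rng.normal(0, config.map_noise_sd, shape)
        if config.map_smooth_sigma > 0:
            x = gaussian_filter(x, config.map_smooth_sigma)
            x *= config.map_noise_sd / x.std()
        return x

    stat = noise()
    stat[region] -= config.map_signal
    topics = {}
    names = [config.target_topic] + [f"topic_{i:02d}"
                                     for i in range(1, config.n_topics)]
    for name in names:
        t = noise()
        if name == config.target_topic:
            t[region] += config.map_signal
        topics[name] = t
    truth = {
        "target_topic": config.target_topic,
        "region_origin": list(o),
        "region_size": s,
        "n_region_voxels": int(np.prod([s] * 3)),
    }
    return stat, topics, truth


def save_maps_nifti(stat, topics, outdir) -> None:
    """Write the statistic map and topic maps as uncompressed NIfTI files."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(stat, dtype=np.float32), affine),
             str(outdir / "stat_map.nii"))
    for name, vol in topics.items():
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                 str(outdir / f"{name}.nii"))


def run_pipeline(config: GeneratorConfig, outdir=None) -> dict:
    """Full synthetic analysis: generate → simulate → fit → index →
    regress → mediate → decode, reproducible from ``config.seed``.

    Mediation is reported twice: on the behaviorally fitted reciprocity
    index (the analysis route) and on the generator-constructed index whose
    true paths are known (the recovery route).  Returns a JSON-serializable
    results dict; with ``outdir`` the tables are also written to disk.
    """
    from .group_analysis import acceptance_by_condition, mediate, regress_index_on_age
    from .model_fitting import fit_cohort
    from .neuro_decoding import decode

    cohort = generate_cohort(config)
    trials = generate_trials(config)
    trials = generate_choices(trials, cohort, config)

    fit_seed = int(_rng(config, "fitting").integers(2**31))
    fits = fit_cohort(trials, n_starts=config.n_starts, seed=fit_seed)
    cohort_full = cohort.merge(fits, on="subject_id")

    acc = acceptance_by_condition(trials)
    reg = regress_index_on_age(cohort_full)

    thick = generate_thickness(cohort, config)
    fitted_tbl = cohort_full.merge(
        thick.drop(columns="reciprocity_index"), on="subject_id")
    constructed_tbl = cohort[["subject_id", "age", "sex", "iq"]].merge(
        thick, on="subject_id")
    med_seed = int(_rng(config, "mediation").integers(2**31))
    roi = config.mediation_roi
    med_fit = mediate(fitted_tbl, roi, n_boot=config.n_boot, seed=med_seed)
    med_con = mediate(constructed_tbl, roi, n_boot=config.n_boot,
                      seed=med_seed + 1)

    stat, topics, truth = generate_maps(config)
    dec_seed = int(_rng(config, "decoding").integers(2**31))
    decoding = decode(stat, topics, n_perm=config.n_perm, seed=dec_seed)

    sign = np.where(fits["reciprocity_index"] > 0, "reciprocity",
                    "inequity_aversion")
    recovery = float(np.mean(sign == cohort["gen_model"].to_numpy()))

    def _med(m):
        return {"roi": m.roi, "path_a": m.path_a, "path_b": m.path_b,
                "direct": m.direct, "total": m.total, "indirect": m.indirect,
                "ratio_indirect_total": m.ratio_indirect_total,
                "indirect_ci": list(m.indirect_ci),
                "direct_ci": list(m.direct_ci), "n": m.n, "n_boot": m.n_boot}

    results = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_subjects": int(len(cohort)),
        "acceptance_by_condition_mean": {
            c: float(acc[c].mean()) for c in acc.columns},
        "age_regression": {"slope": reg.slope, "se": reg.se, "t": reg.t,
                           "p": reg.p, "n": reg.n},
        "model_recovery_accuracy": recovery,
        "mediation_fitted_index": _med(med_fit),
        "mediation_constructed_index": _med(med_con),
        "true_mediation": true_mediation_effects(config),
        "decoding": {
            "target_topic": truth["target_topic"],
            "target_rank": int(decoding.loc[truth["target_topic"], "rank"]),
            "target_rho": float(decoding.loc[truth["target_topic"], "rho"]),
            "target_significant": bool(
                decoding.loc[truth["target_topic"], "significant"]),
            "n_significant": int(decoding["significant"].sum()),
        },
        "fits": fits.to_dict(orient="list"),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trials.to_csv(outdir / "trials.csv", index=False)
        cohort_full.merge(thick.drop(columns="reciprocity_index"),
                          on="subject_id").to_csv(outdir / "cohort.csv",
                                                  index=False)
        thick.to_csv(outdir / "thickness.csv", index=False)
        fits.to_csv(outdir / "fits.tsv", sep="\t", index=False)
        decoding.to_csv(outdir / "decoding.tsv", sep="\t")
        save_maps_nifti(stat, topics, outdir / "maps")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({**truth, "true_mediation": true_mediation_effects(config)},
                      fh, indent=2)
        with open(outdir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
    return results
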