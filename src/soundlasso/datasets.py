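"""Synthetic two-level sound-evaluation survey data with known ground truth.

The generator emulates the structure of a retrospective listening-situation
survey: each participant (cluster) contributes one to three observations
(listening situations); the outcome is an annoyance score on a 1-5 scale
composed of two 5-point items; predictors are a mix of continuous scores,
Likert items, binary indicators, and categorical factors, some varying per
situation and some constant within a participant.  The outcome follows a
random-intercept model

    y_ij = b0 + sum_k beta_k x_ijk + u_i + e_ij,
    u_i ~ N(0, tau00),  e_ij ~ N(0, sigma2),

so every generated dataset carries its own ground truth (fixed effects and
variance components) for parameter-recovery and selection-recovery tests.

Also provides a nominal rating-matrix generator for inter-rater
reliability fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "Predictor",
    "GeneratorConfig",
    "SurveyDataset",
    "RatingMatrix",
    "default_config",
    "generate_survey",
    "generate_ratings",
]


@dataclass(frozen=True)
class Predictor:
    """Descriptor of one predictor column.

    kind:
        "continuous"  - standard normal score
        "likert"      - k-point item from a latent normal cut at
                        equal-probability thresholds (values 1..k)
        "binary"      - Bernoulli(p) indicator (values 0/1)
        "categorical" - label drawn from `levels` with probabilities
                        `prevalences`
    level:
        "observation" - redrawn for every listening situation
        "cluster"     - drawn once per participant and repeated
    """

    name: str
    kind: str
    k: int = 5
    p: float = 0.5
    levels: tuple[str, ...] = ()
    prevalences: tuple[float, ...] = ()
    level: str = "observation"

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "likert", "binary", "categorical"}:
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.level not in {"observation", "cluster"}:
            raise ValueError(f"unknown predictor level {self.level!r}")
        if self.kind == "likert" and self.k < 2:
            raise ValueError("likert predictors need k >= 2")
        if self.kind == "binary" and not 0.0 <= self.p <= 1.0:
            raise ValueError("binary prevalence must be in [0, 1]")
        if self.kind == "categorical":
            if len(self.levels) < 2 or len(self.levels) != len(self.prevalences):
                raise ValueError("categorical predictors need matching levels/prevalences")
            if abs(sum(self.prevalences) - 1.0) > 1e-8:
                raise ValueError(f"prevalences of {self.name!r} must sum to 1")


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of a synthetic survey.

    beta maps predictor names (or "factor[level]" for categorical levels)
    to effects on the outcome scale; unspecified entries are zero.
    tau00 is the between-participant variance, sigma2 the residual
    variance, both in squared outcome units.
    """

    n_clusters: int = 1301
    obs_per_cluster_probs: tuple[float, float, float] = (0.28, 0.29, 0.43)
    roster: tuple[Predictor, ...] = ()
    beta: dict[str, float] = field(default_factory=dict)
    intercept: float = 2.3
    tau00: float = 0.21
    sigma2: float = 0.60
    outcome_mode: str = "continuous"  # or "items"
    clip_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.obs_per_cluster_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("obs_per_cluster_probs must be 3 nonnegative values summing to 1")
        if self.tau00 < 0:
            raise ValueError("tau00 must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.outcome_mode not in {"continuous", "items"}:
            raise ValueError("outcome_mode must be 'continuous' or 'items'")
        names = [p.name for p in self.roster]
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names in roster")


@dataclass
class SurveyDataset:
    """Long-format survey table plus factor metadata and ground truth."""

    data: pd.DataFrame
    factor_metadata: dict[str, dict]
    truth: dict
    clip_policy: str

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_clusters(self) -> int:
        return self.data["cluster_id"].nunique()

    def to_csv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write `<prefix>.csv` (one row per observation) and a
        `<prefix>.truth.json` sidecar with ground truth and metadata."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".truth.json")
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "truth": self.truth,
            "factor_metadata": self.factor_metadata,
            "clip_policy": self.clip_policy,
        }
        json_path.write_text(json.dumps(sidecar, indent=2, default=float))
        return csv_path, json_path


@dataclass
class RatingMatrix:
    """Units x raters table of nominal category labels (NaN = missing)."""

    ratings: pd.DataFrame
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ratings.shape[1] < 2:
            raise ValueError("need at least 2 raters")
        if (self.ratings.notna().sum(axis=1) < 1).any():
            raise ValueError("every unit must be rated by at least one rater")


# --------------------------------------------------------------------------
# Default study-conditions roster


def default_roster() -> tuple[Predictor, ...]:
    """Predictor roster mirroring a sound-evaluation survey.

    Situational affect (9-point self-assessment manikin scales), the eight
    DIAMONDS situation dimensions, fade-out abilities, active coping, sound
    character (loudness/timbre/tonality), a 3-level macro sound category, a
    6-level location, and person-level demographics/traits.
    """
    obs, cl = "observation", "cluster"
    return (
        Predictor("valence", "likert", k=9, level=obs),
        Predictor("arousal", "likert", k=9, level=obs),
        Predictor("control", "likert", k=9, level=obs),
        Predictor("duty", "likert", k=5, level=obs),
        Predictor("intellect", "likert", k=5, level=obs),
        Predictor("adversity", "likert", k=5, level=obs),
        Predictor("mating", "likert", k=5, level=obs),
        Predictor("positivity", "likert", k=5, level=obs),
        Predictor("negativity", "likert", k=5, level=obs),
        Predictor("deception", "likert", k=5, level=obs),
        Predictor("sociality", "likert", k=5, level=obs),
        Predictor("specific_fadeout", "likert", k=5, level=obs),
        Predictor("active_coping", "binary", p=0.4, level=obs),
        Predictor("loudness", "likert", k=5, level=obs),
        Predictor("timbre", "likert", k=5, level=obs),
        Predictor("tonality", "likert", k=5, level=obs),
        Predictor(
            "macro_category",
            "categorical",
            levels=("natural", "human", "technical"),
            prevalences=(0.32, 0.20, 0.48),
            level=obs,
        ),
        Predictor(
            "location",
            "categorical",
            levels=(
                "home_indoors",
                "garden_nature",
                "undefined",
                "other_indoors",
                "work_office",
                "other_outdoors",
            ),
            prevalences=(0.5925, 0.1654, 0.0925, 0.0757, 0.0461, 0.0278),
            level=obs,
        ),
        Predictor("general_fadeout", "likert", k=5, level=cl),
        Predictor("liveliness", "likert", k=5, level=cl),
        Predictor("noise_sensitivity", "continuous", level=cl),
        Predictor("neuroticism", "continuous", level=cl),
        Predictor("extraversion", "continuous", level=cl),
        Predictor("gender_male", "binary", p=0.48, level=cl),
        Predictor(
            "age_class",
            "categorical",
            levels=("20_40", "41_60", "61_80"),
            prevalences=(0.33, 0.34, 0.33),
            level=cl,
        ),
        Predictor(
            "education_class",
            "categorical",
            levels=("isced_le2", "isced_3", "isced_ge4"),
            prevalences=(0.29, 0.35, 0.36),
            level=cl,
        ),
        Predictor("persons", "likert", k=6, level=cl),
        Predictor("net_income", "continuous", level=cl),
    )


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-conditions configuration: 1,301 participants, 1-3 situations
    each (expected total ~2,800), tau00 = 0.21, sigma2 = 0.60, and a
    moderate set of true effects dominated by situational variables."""
    beta = {
        "valence": -0.20,
        "arousal": 0.08,
        "positivity": -0.15,
        "negativity": 0.10,
        "specific_fadeout": -0.15,
        "active_coping": 0.25,
        "loudness": 0.15,
        "tonality": -0.03,
        "macro_category[natural]": -0.65,
        "macro_category[human]": -0.15,
        "location[garden_nature]": -0.30,
        "general_fadeout": -0.08,
    }
    # intercept calibrated so the expected outcome mean is ~2.84 given the
    # default effects and predictor means (neutral annoyance just below 3)
    cfg = dict(roster=default_roster(), beta=beta, intercept=4.06, seed=seed)
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


# --------------------------------------------------------------------------
# Generation


def _likert_from_latent(z: np.ndarray, k: int) -> np.ndarray:
    from scipy.stats import norm

    # equal-probability cut points on the latent normal
    thresholds = norm.ppf(np.arange(1, k) / k)
    return (np.searchsorted(thresholds, z, side="right") + 1).astype(float)


def _draw_predictor(p: Predictor, n: int, rng: np.random.Generator):
    if p.kind == "continuous":
        return rng.standard_normal(n)
    if p.kind == "likert":
        return _likert_from_latent(rng.standard_normal(n), p.k)
    if p.kind == "binary":
        return (rng.random(n) < p.p).astype(float)
    return rng.choice(np.asarray(p.levels, dtype=object), size=n, p=np.asarray(p.prevalences))


def generate_survey(config: GeneratorConfig) -> SurveyDataset:
    """Generate one two-level survey dataset from `config`.

    Deterministic given `config.seed`; each predictor, the cluster
    structure, and the noise terms use independent named substreams.
    """
    seed = config.seed
    rng_structure = substream(seed, "structure")
    sizes = rng_structure.choice([1, 2, 3], size=config.n_clusters,
                                 p=np.asarray(config.obs_per_cluster_probs))
    cluster_id = np.repeat(np.arange(config.n_clusters), sizes)
    n = int(sizes.sum())

    columns: dict[str, np.ndarray] = {"cluster_id": cluster_id}
    eta = np.full(n, float(config.intercept))
    factor_metadata: dict[str, dict] = {}

    for p in config.roster:
        rng_p = substream(seed, f"predictor:{p.name}")
        if p.level == "cluster":
            vals = np.asarray(_draw_predictor(p, config.n_clusters, rng_p))[cluster_id]
        else:
            vals = np.asarray(_draw_predictor(p, n, rng_p))
        columns[p.name] = vals
        if p.kind == "categorical":
            factor_metadata[p.name] = {"levels": list(p.levels)}
            for lev in p.levels:
                b = config.beta.get(f"{p.name}[{lev}]", 0.0)
                if b:
                    eta = eta + b * (vals == lev)
        else:
            b = config.beta.get(p.name, 0.0)
            if b:
                eta = eta + b * vals.astype(float)

    unknown = [k for k in config.beta
               if k.split("[")[0] not in {p.name for p in config.roster}]
    if unknown:
        raise ValueError(f"beta refers to predictors not in roster: {unknown}")

    rng_noise = substream(seed, "noise")
    u = rng_noise.normal(0.0, np.sqrt(config.tau00), size=config.n_clusters)
    mu = eta + u[cluster_id]

    if config.outcome_mode == "items":
        # two 5-point items whose mean-of-(reversed pleasant, annoying)
        # composite carries the model signal; each item gets residual
        # variance 2*sigma2 so the composite residual variance is sigma2
        e_items = rng_noise.normal(0.0, np.sqrt(2.0 * config.sigma2), size=(2, n))
        pleasant = np.clip(np.rint((6.0 - mu) + e_items[0]), 1, 5)
        annoying = np.clip(np.rint(mu + e_items[1]), 1, 5)
        outcome = ((6.0 - pleasant) + annoying) / 2.0
        columns["pleasant_agreement"] = pleasant
        columns["annoying_agreement"] = annoying
        clip_policy = "items rounded to integers and clipped to [1, 5]"
    else:
        e = rng_noise.normal(0.0, np.sqrt(config.sigma2), size=n)
        outcome = mu + e
        if config.clip_outcome:
            outcome = np.clip(outcome, 1.0, 5.0)
            clip_policy = "continuous outcome clipped to [1, 5]"
        else:
            clip_policy = "none (continuous outcome, unclipped)"
    columns["annoyance"] = outcome

    data = pd.DataFrame(columns)
    truth = {
        "intercept": config.intercept,
        "beta": dict(config.beta),
        "tau00": config.tau00,
        "sigma2": config.sigma2,
        "outcome_mode": config.outcome_mode,
        "seed": seed,
        "n_obs": n,
        "n_clusters": int(config.n_clusters),
    }
    return SurveyDataset(data=data, factor_metadata=factor_metadata,
                         truth=truth, clip_policy=clip_policy)


def generate_ratings(
    n_units: int,
    n_raters: int,
    agreement: float,
    n_categories: int,
    seed: int,
) -> RatingMatrix:
    """Nominal rating matrix under a copy-noise model.

    Each unit has a true category; every rater independently reports it
    with probability `agreement`, otherwise a uniform draw from the other
    categories.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    rng = substream(seed, "ratings")
    truth = rng.integers(0, n_categories, size=n_units)
    copy = rng.random((n_units, n_raters)) < agreement
    offsets = rng.integers(1, n_categories, size=(n_units, n_raters))
    noisy = (truth[:, None] + offsets) % n_categories
    values = np.where(copy, truth[:, None], noisy)
    labels = np.array([f"C{c}" for c in range(n_categories)], dtype=object)
    df = pd.DataFrame(labels[values],
                      columns=[f"rater{r + 1}" for r in range(n_raters)])
    df.index.name = "unit"
    return RatingMatrix(ratings=df, truth=truth)
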