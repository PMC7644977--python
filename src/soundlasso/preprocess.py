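"""Data preparation for the annoyance models.

Implements the survey's preparation rules: the composite annoyance score
from the reversed "pleasant" and the "annoying" item, the binary loudness
grouping, the liveliness median split, income per household member, dummy
coding with the most frequent level as reference, and z-standardization of
all predictors (dummies included) with a retained record so coefficients
can be mapped back to the raw scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PreparedDesign",
    "compute_annoyance",
    "binarize_loudness",
    "median_split",
    "income_per_person",
    "dummy_encode",
    "z_standardize",
    "prepare_design",
]

INTERCEPT = "(Intercept)"


@dataclass
class PreparedDesign:
    """Response, standardized design matrix, and bookkeeping.

    groups maps each model term to the design columns it owns: one column
    for a continuous predictor, k-1 dummy columns for a k-level factor.
    The intercept column is unpenalized and belongs to no group.
    standardization maps column -> (mean, sd) on the raw scale.
    """

    y: np.ndarray
    X: pd.DataFrame
    groups: dict[str, list[str]]
    cluster_ids: np.ndarray
    standardization: dict[str, tuple[float, float]]
    n_dropped: int = 0
    outcome: str = "annoyance"

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_ids))

    @property
    def penalized_columns(self) -> list[str]:
        return [c for c in self.X.columns if c != INTERCEPT]

    def subset_terms(self, terms: list[str]) -> "PreparedDesign":
        """Design restricted to `terms` (group structure preserved)."""
        cols = [INTERCEPT] + [c for t in terms for c in self.groups[t]]
        return PreparedDesign(
            y=self.y,
            X=self.X[cols],
            groups={t: list(self.groups[t]) for t in terms},
            cluster_ids=self.cluster_ids,
            standardization={c: self.standardization[c]
                             for c in cols if c in self.standardization},
            n_dropped=self.n_dropped,
            outcome=self.outcome,
        )

    def destandardize(self, beta: pd.Series) -> pd.Series:
        """Map coefficients on the standardized scale back to raw-scale
        coefficients (intercept adjusted accordingly)."""
        raw = {}
        intercept = beta.get(INTERCEPT, 0.0)
        for col, b in beta.items():
            if col == INTERCEPT:
                continue
            mean, sd = self.standardization[col]
            raw[col] = b / sd
            intercept -= b * mean / sd
        raw[INTERCEPT] = intercept
        return pd.Series(raw)[list(beta.index)]

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".design.csv")
        json_path = prefix.with_suffix(".design.json")
        out = self.X.copy()
        out.insert(0, "cluster_id", self.cluster_ids)
        out.insert(1, self.outcome, self.y)
        out.to_csv(csv_path, index=False)
        json_path.write_text(json.dumps({
            "groups": self.groups,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "n_dropped": self.n_dropped,
            "outcome": self.outcome,
        }, indent=2))
        return csv_path, json_path


def compute_annoyance(pleasant_agreement, annoying_agreement):
    """Composite annoyance: mean of the reversed pleasant-agreement item
    and the annoying-agreement item, both on 1-5 agreement scales
    (5 = strongly agree). 1 = very pleasant, 5 = very annoying."""
    p = np.asarray(pleasant_agreement, dtype=float)
    a = np.asarray(annoying_agreement, dtype=float)
    for name, v in (("pleasant_agreement", p), ("annoying_agreement", a)):
        if np.any((v < 1) | (v > 5)):
            raise ValueError(f"{name} must lie in [1, 5]")
    out = ((6.0 - p) + a) / 2.0
    return out if out.ndim else float(out)


def binarize_loudness(loudness_level):
    """Group 1-5 loudness ratings: 1-3 -> 'low_level', 4-5 -> 'mid_high_level'."""
    lv = np.asarray(loudness_level)
    if np.any((lv < 1) | (lv > 5)):
        raise ValueError("loudness level must lie in {1..5}")
    out = np.where(lv <= 3, "low_level", "mid_high_level")
    return out if out.ndim else str(out)


def median_split(values, high_label: str = "high", low_label: str = "low",
                 ties: str = "high"):
    """Split an ordinal vector at its sample median.

    Returns (labels, median). Values >= median get `high_label` when
    ties="high" (default; values equal to the median join the upper
    class), values > median when ties="low".
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot median-split an empty vector")
    med = float(np.median(v))
    mask = v >= med if ties == "high" else v > med
    labels = np.where(mask, high_label, low_label)
    return labels, med


def income_per_person(net_income_midpoint, persons):
    """Household net-income interval midpoint divided by household size.

    Missing income (NaN) propagates to missing; persons must be >= 1
    ("6 or more" is coded as 6 upstream).
    """
    inc = np.asarray(net_income_midpoint, dtype=float)
    per = np.asarray(persons, dtype=float)
    if np.any(per < 1):
        raise ValueError("persons must be >= 1")
    out = inc / per
    return out if out.ndim else float(out)


def dummy_encode(factor_column: pd.Series, reference: str | None = None):
    """Treatment-code a factor into k-1 dummy columns.

    The reference defaults to the most frequent level; ties break to the
    lexicographically first tied level. Returns (dummies, group_record)
    where group_record = {factor_name: [dummy column names]}.
    """
    s = pd.Series(factor_column)
    name = s.name or "factor"
    counts = s.value_counts()
    if len(counts) < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 observed levels")
    if reference is None:
        top = counts.max()
        reference = sorted(str(l) for l in counts.index[counts == top])[0]
    elif reference not in set(map(str, counts.index)):
        raise ValueError(f"reference level {reference!r} not observed in {name!r}")
    levels = sorted(str(l) for l in counts.index if str(l) != str(reference))
    dummies = pd.DataFrame(
        {f"{name}[{lev}]": (s.astype(str) == lev).astype(float) for lev in levels},
        index=s.index,
    )
    return dummies, {name: list(dummies.columns)}


def z_standardize(columns: pd.DataFrame):
    """Standardize each column to mean 0, SD 1 (denominator n-1).

    Returns (standardized, record) with record[col] = (mean, sd).
    Raises on zero-SD columns, naming the offender.
    """
    df = pd.DataFrame(columns)
    record: dict[str, tuple[float, float]] = {}
    out = {}
    for col in df.columns:
        x = df[col].astype(float)
        mean, sd = float(x.mean()), float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - mean) / sd
        record[col] = (mean, sd)
    return pd.DataFrame(out, index=df.index), record


def prepare_design(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str = "cluster_id",
    factors: list[str] | None = None,
    references: dict[str, str] | None = None,
    standardize: bool = True,
) -> PreparedDesign:
    """Build a modeling design from a long-format survey table.

    Columns listed in `factors` (default: every non-numeric predictor)
    are treatment-coded with the most frequent level as reference; all
    predictor columns, dummies included, are then z-standardized. Rows
    with missing values in the outcome or any modeled column are dropped
    and counted.
    """
    references = references or {}
    missing = [c for c in [outcome, cluster, *predictors] if c not in data.columns]
    if missing:
        raise ValueError(f"columns not found in data: {missing}")
    if factors is None:
        factors = [c for c in predictors
                   if not pd.api.types.is_numeric_dtype(data[c])]

    used = data[[outcome, cluster, *predictors]]
    keep = used.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    used = used.loc[keep]

    blocks: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    for name in predictors:
        if name in factors:
            dummies, rec = dummy_encode(used[name], references.get(name))
            blocks.append(dummies)
            groups.update(rec)
        else:
            blocks.append(used[[name]].astype(float))
            groups[name] = [name]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=used.index)

    if standardize and len(X.columns):
        X, record = z_standardize(X)
    else:
        record = {c: (0.0, 1.0) for c in X.columns}
    X.insert(0, INTERCEPT, 1.0)

    return PreparedDesign(
        y=used[outcome].to_numpy(dtype=float),
        X=X.reset_index(drop=True),
        groups=groups,
        cluster_ids=used[cluster].to_numpy(),
        standardization=record,
        n_dropped=n_dropped,
        outcome=outcome,
    )
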