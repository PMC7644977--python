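"""Krippendorff's alpha for nominal codings, with bootstrap CIs.

Used to quantify inter-rater reliability of categorical codings (sound
categories, locations). Alpha is chance-corrected agreement,
1 - D_o/D_e, computed from the coincidence matrix of pairable values;
units rated by fewer than two raters contribute no coincidences.
Conventional interpretation bands: alpha >= 0.800 is considered
reliable, 0.667-0.800 supports only tentative conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AlphaResult", "krippendorff_alpha", "bootstrap_alpha",
           "reliability_label"]


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    B: int
    n_pairable_values: int
    n_excluded_resamples: int = 0
    seed: int = 0


def _as_matrix(ratings) -> np.ndarray:
    if hasattr(ratings, "ratings"):  # RatingMatrix
        ratings = ratings.ratings
    arr = pd.DataFrame(ratings).to_numpy(dtype=object)
    mask = pd.isna(arr)
    out = np.where(mask, None, arr.astype(str))
    out[mask] = None
    return out


def _coincidences(arr: np.ndarray):
    """Coincidence matrix over pairable values (units with >= 2 ratings)."""
    values = sorted({v for row in arr for v in row if v is not None})
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    o = np.zeros((k, k))
    for row in arr:
        vals = [index[v] for v in row if v is not None]
        m = len(vals)
        if m < 2:
            continue
        counts = np.bincount(vals, minlength=k).astype(float)
        pairs = np.outer(counts, counts) - np.diag(counts)
        o += pairs / (m - 1)
    return o, values


def krippendorff_alpha(ratings, metric: str = "nominal") -> float:
    """Point estimate of Krippendorff's alpha for nominal data.

    alpha = 1 - D_o/D_e with observed disagreement D_o the off-diagonal
    mass of the coincidence matrix and expected disagreement D_e its
    value under random pairing of the marginal totals.
    """
    if metric != "nominal":
        raise ValueError("only the nominal metric is implemented")
    arr = _as_matrix(ratings)
    o, _ = _coincidences(arr)
    n = o.sum()
    if n <= 1:
        raise ValueError("no pairable values: every unit has fewer than 2 ratings")
    n_c = o.sum(axis=1)
    d_o = n - np.trace(o)
    # D_e for nominal data: sum_{c != k} n_c n_k / (n - 1)
    d_e = (n * n - float(n_c @ n_c)) / (n - 1.0)
    if d_e == 0:
        raise ValueError("expected disagreement is zero (single observed category)")
    return 1.0 - d_o / d_e


def bootstrap_alpha(ratings, B: int = 1000, seed: int = 0,
                    level: float = 0.95) -> AlphaResult:
    """Unit-level bootstrap CI for alpha.

    Resamples units (rows) with replacement B times; resamples on which
    alpha is undefined (no pairable values, or a single observed
    category) are excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arr = _as_matrix(ratings)
    point = krippendorff_alpha(arr)
    o, _ = _coincidences(arr)
    n_pairable = int(round(o.sum()))
    rng = np.random.default_rng(seed)
    stats = []
    excluded = 0
    for _ in range(B):
        rows = rng.integers(0, arr.shape[0], size=arr.shape[0])
        try:
            stats.append(krippendorff_alpha(arr[rows]))
        except ValueError:
            excluded += 1
    if not stats:
        raise ValueError("alpha undefined on every bootstrap resample")
    a = (1.0 - level) / 2.0
    return AlphaResult(
        alpha=point,
        ci_low=float(np.percentile(stats, 100 * a)),
        ci_high=float(np.percentile(stats, 100 * (1 - a))),
        B=B,
        n_pairable_values=n_pairable,
        n_excluded_resamples=excluded,
        seed=seed,
    )


def reliability_label(alpha: float) -> str:
    """Conventional interpretation band for an alpha value."""
    if alpha >= 0.800:
        return "reliable"
    if alpha >= 0.667:
        return "tentative"
    return "unreliable"
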