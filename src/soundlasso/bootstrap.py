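"""Cluster bootstrap for estimated marginal means.

Observations within a participant are dependent, so resampling draws
whole participants (clusters) with replacement: if one observation of a
person enters a resample, all of that person's observations do, as many
times as the person was drawn. Estimated marginal means (EMMs) of the
outcome for the levels of one or two additive categorical factors come
from an ordinary linear model on the factor dummies; percentile
2.5/97.5 bounds over B resamples give the confidence intervals. With a
second additive factor the fitted difference between its levels is by
construction identical across the levels of the first factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EmmResult", "resample_clusters", "estimate_emm", "bootstrap_emm"]


@dataclass
class EmmResult:
    """Per-cell marginal means with percentile bootstrap CIs."""

    table: pd.DataFrame  # factor level columns, estimate, ci_low, ci_high,
    # n_obs, excluded_resamples
    B: int
    seed: int
    level: float = 0.95


def resample_clusters(data: pd.DataFrame, cluster: str = "cluster_id",
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """One cluster bootstrap resample.

    Draws n_clusters cluster IDs with replacement and concatenates their
    rows; cluster multiplicity is preserved through fresh replicate IDs
    in the cluster column, with the drawn original ID retained in a
    `source_<cluster>` column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clusters = data[cluster].unique()
    draws = rng.integers(0, len(clusters), size=len(clusters))
    by_cluster = {c: idx.to_numpy() for c, idx in data.groupby(cluster).groups.items()}
    pieces = []
    for rep, d in enumerate(draws):
        rows = data.loc[by_cluster[clusters[d]]].copy()
        rows[f"source_{cluster}"] = rows[cluster]
        rows[cluster] = f"rep{rep}"
        pieces.append(rows)
    return pd.concat(pieces, ignore_index=True)


def _design(data: pd.DataFrame, factors: list[str]):
    """Additive treatment-coded design and the cell rows to predict."""
    levels = {f: sorted(map(str, data[f].unique())) for f in factors}
    cols = []
    blocks = [np.ones((len(data), 1))]
    for f in factors:
        vals = data[f].astype(str).to_numpy()
        for lev in levels[f][1:]:
            cols.append((f, lev))
            blocks.append((vals == lev).astype(float)[:, None])
    D = np.hstack(blocks)
    cells = list(itertools.product(*(levels[f] for f in factors)))
    C = np.zeros((len(cells), D.shape[1]))
    C[:, 0] = 1.0
    for i, cell in enumerate(cells):
        for f, lev in zip(factors, cell):
            if (f, lev) in cols:
                C[i, 1 + cols.index((f, lev))] = 1.0
    return D, C, cells, levels


def estimate_emm(data: pd.DataFrame, outcome: str, factors: list[str] | str) -> pd.DataFrame:
    """Marginal means of `outcome` for one or two additive categorical
    factors, via an ordinary linear model on the factor dummies.

    For a single factor this equals the per-level arithmetic means. Cells
    of an additive two-factor design are predicted even when empty.
    """
    factors = [factors] if isinstance(factors, str) else list(factors)
    if not 1 <= len(factors) <= 2:
        raise ValueError("EMMs support one or two factors")
    D, C, cells, _ = _design(data, factors)
    y = data[outcome].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    est = C @ beta
    counts = [
        int(np.all([data[f].astype(str).to_numpy() == lev
                    for f, lev in zip(factors, cell)], axis=0).sum())
        for cell in cells
    ]
    out = pd.DataFrame(cells, columns=factors)
    out["estimate"] = est
    out["n_obs"] = counts
    return out


def bootstrap_emm(data: pd.DataFrame, outcome: str, factors: list[str] | str,
                  B: int = 50_000, seed: int = 0, cluster: str = "cluster_id",
                  level: float = 0.95) -> EmmResult:
    """Cluster-bootstrap EMMs with percentile CIs.

    Resamples participants B times; each resample's EMMs come from the
    same additive linear model, assembled from per-cluster sufficient
    statistics so the loop is cheap. Resampled cells involving a factor
    level absent from that resample are recorded as missing, excluded
    from the percentile computation, and counted per cell.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    factors = [factors] if isinstance(factors, str) else list(factors)
    point = estimate_emm(data, outcome, factors)
    D, C, cells, levels = _design(data, factors)
    y = data[outcome].to_numpy(dtype=float)
    _, inv = np.unique(data[cluster].to_numpy(), return_inverse=True)
    n_clusters = int(inv.max()) + 1
    p = D.shape[1]

    G = np.zeros((n_clusters, p, p))
    H = np.zeros((n_clusters, p))
    np.add.at(G, inv, D[:, :, None] * D[:, None, :])
    np.add.at(H, inv, D * y[:, None])
    # per-cluster observation counts of every factor level, to detect
    # levels that vanish from a resample
    lev_pairs = [(f, lev) for f in factors for lev in levels[f]]
    L = np.zeros((n_clusters, len(lev_pairs)))
    for j, (f, lev) in enumerate(lev_pairs):
        np.add.at(L[:, j], inv, (data[f].astype(str).to_numpy() == lev).astype(float))
    cell_needs = np.array([[1.0 if (f, lev) in zip(factors, cell) else 0.0
                            for (f, lev) in lev_pairs] for cell in cells])

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_clusters, size=(B, n_clusters))
    est = np.empty((B, len(cells)))
    for b in range(B):
        counts = np.bincount(draws[b], minlength=n_clusters).astype(float)
        A = np.tensordot(counts, G, axes=1)
        rhs = counts @ H
        lev_counts = counts @ L
        try:
            beta = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        est[b] = C @ beta
        absent = lev_counts == 0
        if absent.any():
            est[b, (cell_needs[:, absent] > 0).any(axis=1)] = np.nan

    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanpercentile(est, 100 * alpha, axis=0)
        hi = np.nanpercentile(est, 100 * (1 - alpha), axis=0)
    table = point.copy()
    table["ci_low"] = lo
    table["ci_high"] = hi
    table["excluded_resamples"] = np.isnan(est).sum(axis=0)
    return EmmResult(table=table, B=B, seed=seed, level=level)
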