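"""Abundance-based beta diversity: Bray-Curtis partitioning and SCBD.

For a pair of units j and k with species abundances x_ij, x_ik the
shared and unique abundance components are

    A = sum_i min(x_ij, x_ik)
    B = sum_i (x_ij - min(x_ij, x_ik))      (abundance unique to j)
    C = sum_i (x_ik - min(x_ij, x_ik))      (abundance unique to k)

and Bray-Curtis dissimilarity beta_BC = (B + C) / (2A + B + C) is
partitioned (Baselga's abundance-based decomposition) into

    beta_bal = min(B, C) / (A + min(B, C))                 balanced
               variation (turnover: shoots of some species substituted
               by equal numbers of shoots of other species), and
    beta_gra = |B - C| / (2A + B + C) * A / (A + min(B, C))
               abundance gradients (nestedness: shoots lost from one
               unit without substitution),

with beta_bal + beta_gra = beta_BC exactly.  All three lie in [0, 1].

SCBD (species contribution to beta diversity) is each species' share of
the total among-unit sum of squares of raw abundances:

    SCBD_i = SS_i / sum_i SS_i,   SS_i = sum_j (x_ij - xbar_i)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .community import CommunityMatrix


@dataclass(frozen=True)
class BetaPartition:
    """A/B/C components and the partitioned Bray-Curtis dissimilarity.

    ``beta_bc``/``beta_bal``/``beta_gra`` are NaN when both units are empty
    (the dissimilarity is undefined, not zero).
    """

    A: float
    B: float
    C: float
    beta_bc: float
    beta_bal: float
    beta_gra: float


def bray_curtis_partition(x_j: Iterable[float], x_k: Iterable[float]) -> BetaPartition:
    """Partition the dissimilarity between two abundance vectors.

    The vectors must index the same species list.  When one unit is empty
    the pair is pure abundance gradient (beta_bc = beta_gra = 1, beta_bal = 0).
    """
    xj = np.asarray(x_j, dtype=float)
    xk = np.asarray(x_k, dtype=float)
    if xj.shape != xk.shape:
        raise ValueError("abundance vectors must cover the same species list")
    if (xj < 0).any() or (xk < 0).any():
        raise ValueError("abundances must be non-negative")
    a = float(np.minimum(xj, xk).sum())
    b = float(xj.sum() - a)
    c = float(xk.sum() - a)
    denom = 2 * a + b + c
    if denom == 0:
        return BetaPartition(a, b, c, float("nan"), float("nan"), float("nan"))
    bc = (b + c) / denom
    m = min(b, c)
    if a + m == 0:  # one unit empty: no shared abundance, nothing balanced
        return BetaPartition(a, b, c, bc, 0.0, bc)
    bal = m / (a + m)
    gra = (abs(b - c) / denom) * (a / (a + m))
    return BetaPartition(a, b, c, bc, bal, gra)


def _pairwise_matrices(x: np.ndarray):
    """Dense n x n matrices (bc, bal, gra) for the rows of ``x``.

    Entries where both units are empty are NaN; the diagonal is 0 for
    non-empty units.
    """
    a = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=-1)
    t = x.sum(axis=1)
    b = t[:, None] - a
    c = t[None, :] - a
    denom = 2 * a + b + c
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        bc = np.where(denom > 0, (b + c) / denom, np.nan)
        bal = np.where(a + m > 0, m / (a + m), 0.0)
        bal = np.where(denom > 0, bal, np.nan)
        gra = bc - bal
    return bc, bal, gra


class PairwiseBeta(NamedTuple):
    pairs: pd.DataFrame


def pairwise_partition_table(counts: pd.DataFrame) -> pd.DataFrame:
    """All unordered unit pairs of a count matrix with their partitions."""
    x = counts.to_numpy(dtype=float)
    names = [
        "|".join(str(v) for v in key) if isinstance(key, tuple) else str(key)
        for key in counts.index
    ]
    rows = []
    for j in range(len(x)):
        for k in range(j + 1, len(x)):
            p = bray_curtis_partition(x[j], x[k])
            rows.append(
                {
                    "unit_j": names[j],
                    "unit_k": names[k],
                    "A": p.A,
                    "B": p.B,
                    "C": p.C,
                    "beta_bc": p.beta_bc,
                    "beta_bal": p.beta_bal,
                    "beta_gra": p.beta_gra,
                }
            )
    return pd.DataFrame(rows)


class BetaTables(NamedTuple):
    units: pd.DataFrame
    summary: pd.DataFrame


#: Index levels defining the comparison group of a unit at each scale:
#: cells are compared within their quadrat, quadrats within their plot,
#: and exclosure-scale plots within their treatment (cross-treatment
#: pairs are never formed).
GROUP_LEVELS = {
    "cell": ["pair_id", "treatment", "plot_id", "quadrat_id"],
    "quadrat": ["pair_id", "treatment", "plot_id"],
    "exclosure": ["treatment"],
}


def per_unit_beta(matrix: CommunityMatrix) -> BetaTables:
    """Mean pairwise beta components of each unit against its comparison group.

    A unit's value is the mean of its pairwise partitions against every
    other unit in the same comparison group.  Pairs where both units are
    empty contribute nothing (their dissimilarity is undefined); groups of
    size one are skipped with a warning.
    """
    levels = GROUP_LEVELS[matrix.scale]
    unit_rows = []
    n_skipped_groups = 0
    n_empty_pairs = 0
    group_level = levels if len(levels) > 1 else levels[0]
    for key, grp in matrix.counts.groupby(level=group_level, sort=False):
        if len(grp) < 2:
            n_skipped_groups += 1
            continue
        x = grp.to_numpy(dtype=float)
        bc, bal, gra = _pairwise_matrices(x)
        np.fill_diagonal(bc, np.nan)
        np.fill_diagonal(bal, np.nan)
        np.fill_diagonal(gra, np.nan)
        n_empty_pairs += int(np.isnan(bc[np.triu_indices(len(x), 1)]).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mean_bc = np.nanmean(bc, axis=1)
            mean_bal = np.nanmean(bal, axis=1)
            mean_gra = np.nanmean(gra, axis=1)
        meta = grp.index.to_frame(index=False)
        meta.insert(0, "scale", matrix.scale)
        meta["beta_bc"] = mean_bc
        meta["beta_bal"] = mean_bal
        meta["beta_gra"] = mean_gra
        unit_rows.append(meta)
    if n_skipped_groups:
        warnings.warn(
            f"skipped {n_skipped_groups} comparison group(s) of size 1 "
            f"at scale {matrix.scale!r}"
        )
    if not unit_rows:
        raise ValueError("no comparison group with >= 2 units")
    units = pd.concat(unit_rows, ignore_index=True)
    units.attrs["n_empty_pairs"] = n_empty_pairs

    rows = []
    for treatment, grp in units.groupby("treatment", sort=False):
        row = {"scale": matrix.scale, "treatment": treatment, "n_units": len(grp)}
        for metric in ("beta_bc", "beta_bal", "beta_gra"):
            ok = grp[metric].dropna()
            row[f"{metric}_mean"] = ok.mean() if len(ok) else np.nan
            row[f"{metric}_se"] = (
                ok.std(ddof=1) / np.sqrt(len(ok)) if len(ok) > 1 else np.nan
            )
        rows.append(row)
    return BetaTables(units=units, summary=pd.DataFrame(rows))


def scbd(matrix: CommunityMatrix | pd.DataFrame) -> pd.Series:
    """Species contributions to beta diversity over the units of a matrix.

    Returns a Series over species summing to 1.  Raises ``ValueError`` when
    there are fewer than 2 units or all units are identical (zero total sum
    of squares).
    """
    counts = matrix.counts if isinstance(matrix, CommunityMatrix) else matrix
    if len(counts) < 2:
        raise ValueError("SCBD requires at least 2 units")
    x = counts.to_numpy(dtype=float)
    ss = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    total = ss.sum()
    if total == 0:
        raise ValueError("all units identical: total sum of squares is zero")
    return pd.Series(ss / total, index=counts.columns, name="scbd")
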