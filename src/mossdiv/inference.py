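"""Permutation inference and growth-form summaries.

Two permutation tests are provided:

* :func:`permanova` — the pseudo-F test of compositional differences on a
  pairwise (Bray-Curtis) distance matrix, with Monte-Carlo label
  permutations, optionally restricted within strata (e.g. the plot pairs
  of a paired design).
* :func:`paired_permutation_contrast` — a paired sign-flip test for the
  treatment effect on any per-unit statistic, respecting the paired
  exclosure/control blocks.  This is the package's treatment-effect test;
  it replaces model-based (GLMM) inference with an exact design-respecting
  permutation scheme.

Both use the add-one rule p = (#{extreme} + 1) / (n_perm + 1), so p-values
never reach 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import SCALE_KEYS, CommunityDataset, CommunityMatrix, aggregate


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    p_perm: float
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class ContrastResult:
    effect: float
    p_perm: float
    n_blocks: int
    n_perm: int
    seed: int | None
    exact: bool


def bray_curtis_matrix(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Square Bray-Curtis distance matrix over the rows of a count matrix."""
    x = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    return squareform(pdist(x, metric="braycurtis"))


def _within_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(
    dist: np.ndarray | pd.DataFrame,
    labels: Iterable,
    n_perm: int = 999,
    seed: int | None = None,
    strata: Iterable | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with Monte-Carlo permutations.

    ``dist`` must be a square symmetric matrix with zero diagonal.  The
    pseudo-F statistic partitions the total sum of squared distances into
    among- and within-group components; its null distribution comes from
    ``n_perm`` random permutations of the group labels (within ``strata``
    blocks when given).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(list(labels))
    if len(labels) != n:
        raise ValueError("labels length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d**2
    if not d2.any():
        raise ValueError("all distances are zero: pseudo-F undefined")

    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    df_between = len(groups) - 1
    df_within = n - len(groups)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_w = _within_ss(d2, lab, groups)
        ss_b = ss_total - ss_w
        return (ss_b / df_between) / (ss_w / df_within)

    f_obs = pseudo_f(labels)

    rng = np.random.default_rng(seed)
    perm = np.tile(labels, (n_perm, 1))
    if strata is None:
        perm = rng.permuted(perm, axis=1)
    else:
        strata = np.asarray(list(strata))
        if len(strata) != n:
            raise ValueError("strata length must match the distance matrix")
        for block in np.unique(strata):
            idx = np.flatnonzero(strata == block)
            perm[:, idx] = rng.permuted(perm[:, idx], axis=1)
    # vectorized within-group SS across all permutations
    ss_w_perm = np.zeros(n_perm)
    for g, n_g in zip(groups, counts):
        z = (perm == g).astype(float)
        ss_w_perm += np.einsum("pi,ij,pj->p", z, d2, z) / (2 * n_g)
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ss_w_perm) / df_between) / (ss_w_perm / df_within)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        df_between=df_between,
        df_within=df_within,
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def paired_permutation_contrast(
    values: Iterable[float],
    treatment: Iterable,
    pair: Iterable,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> ContrastResult:
    """Paired sign-flip test of a presence-vs-absence effect.

    Unit values are first averaged per (pair, treatment) arm, so each pair
    contributes one within-block difference d_b = mean(presence) -
    mean(absence); the observed effect is mean_b(d_b).  The null flips the
    sign of each d_b independently (equivalently, swaps the treatment
    labels within the block).  With ``exact=True`` all 2^B sign patterns
    are enumerated (B <= 20) and the p-value is the exact tail proportion;
    otherwise ``n_perm`` random flips with the add-one rule.
    """
    df = pd.DataFrame(
        {"value": np.asarray(list(values), dtype=float),
         "treatment": list(treatment),
         "pair": list(pair)}
    )
    arm_means = df.groupby(["pair", "treatment"])["value"].mean().unstack("treatment")
    missing = arm_means.index[arm_means.isna().any(axis=1)]
    if set(arm_means.columns) != {"absence", "presence"} or len(missing):
        raise ValueError(
            f"every pair must contain both treatments; offending pairs: "
            f"{list(missing) if len(missing) else list(arm_means.columns)}"
        )
    d = (arm_means["presence"] - arm_means["absence"]).to_numpy()
    n_blocks = len(d)
    effect = float(d.mean())

    if exact:
        if n_blocks > 20:
            raise ValueError("exact enumeration limited to 20 blocks")
        signs = np.array(list(product((1.0, -1.0), repeat=n_blocks)))
        perm_eff = signs @ d / n_blocks
        p = float(np.count_nonzero(np.abs(perm_eff) >= abs(effect)) / len(signs))
        return ContrastResult(effect, p, n_blocks, len(signs), seed, True)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n_blocks)) * 2 - 1
    perm_eff = signs @ d / n_blocks
    p = float((np.count_nonzero(np.abs(perm_eff) >= abs(effect)) + 1) / (n_perm + 1))
    return ContrastResult(effect, p, n_blocks, n_perm, seed, False)


class GrowthFormTables(NamedTuple):
    units: pd.DataFrame
    summary: pd.DataFrame


def growth_form_summary(dataset: CommunityDataset, scale: str) -> GrowthFormTables:
    """Relative abundance and richness of each growth form per unit.

    Relative abundance is each form's share of the unit's total shoots (the
    shares over forms sum to 1 for non-empty units); richness is the number
    of species of that form present.  The summary reports treatment x form
    means +/- SE at the given scale.
    """
    if dataset.registry is None:
        raise ValueError("growth-form analyses need a species registry")
    form_of = dict(zip(dataset.registry["species"], dataset.registry["growth_form"]))
    matrix = aggregate(dataset, scale)
    missing = sorted(set(matrix.species) - set(form_of))
    if missing:
        raise ValueError(f"species missing from registry: {missing}")

    counts = matrix.counts
    forms = sorted(set(form_of[sp] for sp in counts.columns))
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    rows = counts.index.to_frame(index=False)
    rows.insert(0, "scale", scale)
    parts = []
    for form in forms:
        cols = [sp for sp in counts.columns if form_of[sp] == form]
        sub = counts.loc[:, cols]
        block = rows.copy()
        block["growth_form"] = form
        with np.errstate(invalid="ignore", divide="ignore"):
            block["rel_abundance"] = np.where(
                totals > 0, sub.sum(axis=1).to_numpy(float) / totals, np.nan
            )
        block["richness"] = (sub > 0).sum(axis=1).to_numpy()
        parts.append(block)
    units = pd.concat(parts, ignore_index=True)

    summ = []
    for (treatment, form), grp in units.groupby(["treatment", "growth_form"], sort=True):
        rel = grp["rel_abundance"].dropna()
        ric = grp["richness"].astype(float)
        summ.append(
            {
                "scale": scale,
                "treatment": treatment,
                "growth_form": form,
                "n_units": len(grp),
                "rel_abundance_mean": rel.mean() if len(rel) else np.nan,
                "rel_abundance_se": rel.std(ddof=1) / np.sqrt(len(rel))
                if len(rel) > 1
                else np.nan,
                "richness_mean": ric.mean(),
                "richness_se": ric.std(ddof=1) / np.sqrt(len(ric))
                if len(ric) > 1
                else np.nan,
            }
        )
    return GrowthFormTables(units=units, summary=pd.DataFrame(summ))
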