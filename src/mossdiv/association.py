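"""Interspecific association: variance-ratio test and pairwise Spearman.

The variance ratio (Schluter's test) compares the observed variance of
per-plot species richness with its expectation under independent
occurrence.  With presence/absence over N plots and S species,

    p_i  = n_i / N                      (occurrence frequency of species i)
    S_T2 = (1/N) sum_j (T_j - tbar)^2   (variance of per-plot richness)
    d_T2 = sum_i p_i (1 - p_i)          (expected variance under independence)
    VR   = S_T2 / d_T2,   W = VR * N.

VR > 1 indicates overall positive association, VR < 1 negative, VR near 1
independence.  Significance uses the two-sided chi-square criterion on W
with N degrees of freedom: the association is significant when W falls
below the lower 5% critical value or above the upper 5% critical value.

Pairwise associations are Spearman rank correlations of abundances across
units, with multiplicity-adjusted p-values (Holm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommunityMatrix


@dataclass(frozen=True)
class AssociationResult:
    vr: float
    w: float
    n_plots: int
    n_species: int
    st2: float
    dt2: float
    t_bar: float
    chi2_low: float
    chi2_high: float
    verdict: str  # positive | negative | independent


def w_statistic(vr: float, n_plots: int) -> float:
    """The W test statistic, W = VR * N."""
    return vr * n_plots


def variance_ratio(presence: np.ndarray) -> AssociationResult:
    """Variance-ratio test on a plots x species presence/absence array."""
    z = np.asarray(presence, dtype=float)
    if z.ndim != 2:
        raise ValueError("presence must be a 2-D plots x species array")
    z = (z > 0).astype(float)
    n, s_total = z.shape
    if n < 2 or s_total < 2:
        raise ValueError("need at least 2 plots and 2 species")
    occupied = z.sum(axis=0) > 0
    s = int(occupied.sum())
    p = z.mean(axis=0)
    dt2 = float((p * (1 - p)).sum())
    if dt2 == 0:
        raise ValueError(
            "expected variance is zero: every species occurs in all plots or none"
        )
    t = z.sum(axis=1)
    t_bar = float(t.mean())
    st2 = float(((t - t_bar) ** 2).mean())
    vr = st2 / dt2
    w = w_statistic(vr, n)
    # chi2_low is the lower-tail 5% critical value of chi^2 with N df,
    # chi2_high the upper-tail one; df = N (number of plots).
    chi2_low = float(stats.chi2.ppf(0.05, df=n))
    chi2_high = float(stats.chi2.ppf(0.95, df=n))
    if vr > 1 and w > chi2_high:
        verdict = "positive"
    elif vr < 1 and w < chi2_low:
        verdict = "negative"
    else:
        verdict = "independent"
    return AssociationResult(
        vr=vr,
        w=w,
        n_plots=n,
        n_species=s,
        st2=st2,
        dt2=dt2,
        t_bar=t_bar,
        chi2_low=chi2_low,
        chi2_high=chi2_high,
        verdict=verdict,
    )


def variance_ratio_test(
    matrix: CommunityMatrix, treatment: str | None = None
) -> AssociationResult:
    """Variance-ratio test on the units of a CommunityMatrix.

    Presence is derived as count > 0.  With ``treatment`` given, only that
    arm's units enter (the study design: N = 50 quadrats per treatment at
    the default quadrat scale).
    """
    counts = matrix.counts if treatment is None else matrix.for_treatment(treatment)
    return variance_ratio(counts.to_numpy())


def pairwise_spearman(
    matrix: CommunityMatrix,
    treatment: str | None = None,
    alpha: float = 0.05,
    adjust: str = "holm",
    min_occupancy: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlations of abundance for all species pairs.

    Species present in fewer than ``min_occupancy`` units are skipped
    (degenerate ranks); the number of skipped species is stored in
    ``result.attrs['n_species_skipped']``.  Classification is ``positive``
    or ``negative`` only when the adjusted p-value is below ``alpha`` (the
    raw p is also reported); ties get average ranks; a constant species
    yields an undefined (NaN) rho and a ``neutral`` classification.
    """
    counts = matrix.counts if treatment is None else matrix.for_treatment(treatment)
    if len(counts) < 3:
        raise ValueError("need at least 3 units for rank correlations")
    occ = (counts > 0).sum(axis=0)
    kept = [sp for sp in counts.columns if occ[sp] >= min_occupancy]
    if len(kept) < 2:
        raise ValueError("fewer than 2 species pass the occupancy filter")
    x = counts.loc[:, kept].to_numpy(dtype=float)
    rows = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                res = stats.spearmanr(x[:, i], x[:, j])
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"species_a": kept[i], "species_b": kept[j],
                         "rho": rho, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    defined = table["p_raw"].notna()
    if defined.any():
        table.loc[defined, "p_adj"] = multipletests(
            table.loc[defined, "p_raw"], alpha=alpha, method=adjust
        )[1]
    cls = np.where(
        (table["p_adj"] < alpha) & (table["rho"] > 0),
        "positive",
        np.where((table["p_adj"] < alpha) & (table["rho"] < 0), "negative", "neutral"),
    )
    table["classification"] = cls
    table.attrs["n_species_skipped"] = int(len(counts.columns) - len(kept))
    table.attrs["adjust"] = adjust
    table.attrs["alpha"] = alpha
    return table
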