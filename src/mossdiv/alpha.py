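"""Per-unit alpha diversity: richness, Evar evenness, inverse Simpson.

Evenness is the Smith & Wilson Evar index,

    E = 1 - (2/pi) * arctan(V),   V = (1/S) * sum_i (ln x_i - mean ln x)^2,

computed over the S species with positive abundance; it maps the
population variance of log abundances onto [0, 1] (1 = perfectly even).

The inverse Simpson index uses the bias-corrected (sampling without
replacement) concentration

    lambda = sum_i n_i (n_i - 1) / (T (T - 1)),

which is undefined (NaN) when T < 2 or when every species is a singleton
(lambda = 0).  Undefined values propagate as missing and are excluded
from treatment means, never coerced to 0.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .community import SCALES, SCALE_KEYS, CommunityDataset, aggregate


def richness(abundances: Iterable[float]) -> int:
    """Number of species with abundance > 0."""
    x = np.asarray(abundances)
    return int(np.count_nonzero(x > 0))


def evenness(abundances: Iterable[float]) -> float:
    """Evar evenness in [0, 1] over the species present (abundance > 0).

    Raises ``ValueError`` on an all-zero vector.  A single-species unit has
    zero log-variance and hence E = 1 (a degenerate but defined value; see
    :func:`alpha_diversity` for the degenerate flag).
    """
    x = np.asarray(abundances, dtype=float)
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("evenness undefined for an all-zero abundance vector")
    logs = np.log(pos)
    v = float(np.mean((logs - logs.mean()) ** 2))
    return 1.0 - (2.0 / np.pi) * float(np.arctan(v))


def inverse_simpson(abundances: Iterable[float]) -> float:
    """Bias-corrected inverse Simpson index 1/lambda, or NaN when undefined."""
    n = np.asarray(abundances, dtype=float)
    n = n[n > 0]
    t = n.sum()
    if t < 2:
        return float("nan")
    lam = float((n * (n - 1)).sum() / (t * (t - 1)))
    if lam == 0.0:
        return float("nan")
    return 1.0 / lam


class AlphaTables(NamedTuple):
    units: pd.DataFrame
    summary: pd.DataFrame


def _unit_alpha(counts: pd.DataFrame, scale: str) -> pd.DataFrame:
    x = counts.to_numpy(dtype=float)
    s = (x > 0).sum(axis=1)
    t = x.sum(axis=1)
    e = np.full(len(x), np.nan)
    inv = np.full(len(x), np.nan)
    for i, row in enumerate(x):
        if t[i] > 0:
            e[i] = evenness(row)
        inv[i] = inverse_simpson(row)
    out = counts.index.to_frame(index=False)
    out.insert(0, "scale", scale)
    out["S"] = s.astype(int)
    out["E"] = e
    out["inv_simpson"] = inv
    out["T"] = t.astype(int)
    # Evar of a one-species unit is forced to 1 by arctan(0); flag it so the
    # value is not over-interpreted downstream.
    out["degenerate_evenness"] = s <= 1
    return out


def alpha_diversity(matrix) -> pd.DataFrame:
    """Alpha diversity table (S, E, inv_simpson, T) for one CommunityMatrix."""
    return _unit_alpha(matrix.counts, matrix.scale)


def _summarize(units: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (scale, treatment), grp in units.groupby(["scale", "treatment"], sort=False):
        row = {"scale": scale, "treatment": treatment, "n_units": len(grp)}
        for metric in ("S", "E", "inv_simpson", "T"):
            vals = grp[metric].astype(float)
            ok = vals.dropna()
            row[f"{metric}_mean"] = ok.mean() if len(ok) else np.nan
            row[f"{metric}_se"] = (
                ok.std(ddof=1) / np.sqrt(len(ok)) if len(ok) > 1 else np.nan
            )
            row[f"{metric}_n_excluded"] = int(vals.isna().sum())
        rows.append(row)
    return pd.DataFrame(rows)


def alpha_by_scale(
    dataset: CommunityDataset, scales: Iterable[str] = SCALES
) -> AlphaTables:
    """Per-unit alpha diversity at each scale plus treatment means +/- SE.

    Units with undefined inverse Simpson (or evenness, for empty units) are
    excluded from the corresponding mean; the exclusion count is reported in
    the ``*_n_excluded`` columns of the summary.
    """
    parts = []
    for scale in scales:
        matrix = aggregate(dataset, scale)
        parts.append(alpha_diversity(matrix))
    units = pd.concat(parts, ignore_index=True)
    # align hierarchy columns: coarser scales lack quadrat/cell ids
    for col in SCALE_KEYS["cell"]:
        if col not in units.columns:
            units[col] = pd.NA
    return AlphaTables(units=units, summary=_summarize(units))
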