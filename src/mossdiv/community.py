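"""Hierarchical moss-abundance data model, CSV I/O, and aggregation.

The sampling design is three nested spatial scales: 2 x 2 cm *cells*
(4 cm^2, 25 per quadrat, indexed row-major on the 5 x 5 grid) within
10 x 10 cm *quadrats* (5 per plot) within *exclosure-scale plots* (one
goose-exclosure and one adjacent control plot per pair).  Abundance is
the integer number of moss shoots of each species counted in each cell.

Two treatments are distinguished: ``absence`` (inside the exclosure,
geese absent) and ``presence`` (control plot, geese present).

The in-memory containers are thin dataclasses around pandas objects:

* :class:`CommunityDataset` — long-format records plus a species registry.
* :class:`CommunityMatrix` — a units x species count matrix at one scale,
  with the unit hierarchy kept on a pandas MultiIndex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("absence", "presence")
SCALES = ("cell", "quadrat", "exclosure")
GROWTH_FORMS = ("acrocarp", "pleurocarp", "sphagnum")

#: Area of one counting cell in cm^2 (2 cm x 2 cm).
CELL_AREA_CM2 = 4.0

RECORD_COLUMNS = (
    "pair_id",
    "treatment",
    "plot_id",
    "quadrat_id",
    "cell_id",
    "species",
    "count",
)
KEY_COLUMNS = RECORD_COLUMNS[:-1]
REGISTRY_COLUMNS = ("species", "genus", "growth_form")

#: Index levels identifying one sampling unit at each scale.
SCALE_KEYS = {
    "cell": ["pair_id", "treatment", "plot_id", "quadrat_id", "cell_id"],
    "quadrat": ["pair_id", "treatment", "plot_id", "quadrat_id"],
    "exclosure": ["pair_id", "treatment", "plot_id"],
}


class ValidationError(ValueError):
    """Raised when an abundance table or registry violates its contract."""


def _check_scale(scale: str) -> str:
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    return scale


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"abundance table is missing columns: {missing}")
    records = records.loc[:, list(RECORD_COLUMNS)].copy()

    counts = pd.to_numeric(records["count"], errors="coerce")
    bad = records.index[counts.isna()]
    if len(bad):
        raise ValidationError(
            f"non-numeric count in rows {list(bad[:5])}: "
            f"{records.loc[bad[0], 'count']!r}"
        )
    nonint = records.index[(counts % 1) != 0]
    if len(nonint):
        raise ValidationError(
            f"non-integer count in rows {list(nonint[:5])}: "
            f"{records.loc[nonint[0], 'count']!r}"
        )
    neg = records.index[counts < 0]
    if len(neg):
        raise ValidationError(
            f"negative count in rows {list(neg[:5])}: "
            f"{records.loc[neg[0], 'count']!r}"
        )
    records["count"] = counts.astype(np.int64)

    bad_treat = sorted(set(records["treatment"]) - set(TREATMENTS))
    if bad_treat:
        raise ValidationError(
            f"unknown treatment value(s) {bad_treat}; expected {TREATMENTS}"
        )

    dup = records.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = records.loc[dup, list(KEY_COLUMNS)].iloc[0].to_dict()
        raise ValidationError(
            f"duplicate (pair, treatment, plot, quadrat, cell, species) keys; "
            f"first duplicate: {first} (rows {list(records.index[dup][:4])})"
        )
    return records


def _validate_registry(registry: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGISTRY_COLUMNS if c not in registry.columns]
    if missing:
        raise ValidationError(f"species registry is missing columns: {missing}")
    registry = registry.loc[:, list(REGISTRY_COLUMNS)].copy()
    if registry["species"].duplicated().any():
        dups = registry.loc[registry["species"].duplicated(), "species"].tolist()
        raise ValidationError(f"duplicate species in registry: {dups}")
    bad = sorted(set(registry["growth_form"]) - set(GROWTH_FORMS))
    if bad:
        raise ValidationError(
            f"unknown growth form(s) {bad}; expected one of {GROWTH_FORMS}"
        )
    return registry


@dataclass
class CommunityDataset:
    """Long-format shoot counts plus an optional species registry.

    Rows with ``count == 0`` are legal and retained: a zero row records an
    explicit absence (and keeps an otherwise-empty cell in the design), but
    presence always means ``count > 0``.
    """

    records: pd.DataFrame
    registry: pd.DataFrame | None = None
    cell_area: float = CELL_AREA_CM2

    def __post_init__(self) -> None:
        self.records = _validate_records(pd.DataFrame(self.records))
        if self.registry is not None:
            self.registry = _validate_registry(pd.DataFrame(self.registry))

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def treatments(self) -> list[str]:
        return [t for t in TREATMENTS if t in set(self.records["treatment"])]

    def total_count(self) -> int:
        return int(self.records["count"].sum())


@dataclass
class CommunityMatrix:
    """Units x species abundance matrix at one spatial scale.

    ``counts`` is indexed by the unit hierarchy (``SCALE_KEYS[scale]``) and
    has one column per species.  Aggregation conserves totals: the entries
    at a coarser scale are exact integer sums over the contained finer units.
    """

    scale: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_scale(self.scale)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_units(self) -> int:
        return len(self.counts)

    def treatment_labels(self) -> np.ndarray:
        return self.counts.index.get_level_values("treatment").to_numpy()

    def for_treatment(self, treatment: str) -> pd.DataFrame:
        """Rows of ``counts`` belonging to one treatment arm."""
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        mask = self.treatment_labels() == treatment
        if not mask.any():
            raise ValueError(f"treatment {treatment!r} absent from matrix")
        return self.counts.loc[mask]


def read_abundance_table(
    path, registry_path=None, cell_area: float = CELL_AREA_CM2
) -> CommunityDataset:
    """Read a comma-separated abundance table (and optional registry).

    The file must be UTF-8 with a header row naming the record fields
    ``pair_id, treatment, plot_id, quadrat_id, cell_id, species, count``.
    Validation failures name the offending rows (0-based data-row index).
    """
    records = pd.read_csv(path, encoding="utf-8")
    registry = None
    if registry_path is not None:
        registry = pd.read_csv(registry_path, encoding="utf-8")
    return CommunityDataset(records=records, registry=registry, cell_area=cell_area)


def write_abundance_table(dataset: CommunityDataset, path, registry_path=None) -> None:
    """Write the dataset back in the same CSV dialect (bit-exact roundtrip)."""
    dataset.records.to_csv(path, index=False, encoding="utf-8")
    if registry_path is not None:
        if dataset.registry is None:
            raise ValueError("dataset has no registry to write")
        dataset.registry.to_csv(registry_path, index=False, encoding="utf-8")


def aggregate(dataset: CommunityDataset, scale: str) -> CommunityMatrix:
    """Sum raw shoot counts into a units x species matrix at ``scale``.

    Counts are always summed, never averaged, so integer totals are
    conserved across the three scales.  Units whose rows are all zero are
    retained as all-zero rows.
    """
    keys = SCALE_KEYS[_check_scale(scale)]
    counts = (
        dataset.records.groupby(keys + ["species"], sort=True)["count"]
        .sum()
        .unstack("species", fill_value=0)
    )
    counts = counts.loc[:, sorted(counts.columns)]
    return CommunityMatrix(scale=scale, counts=counts)


def relative_frequency(dataset: CommunityDataset) -> pd.DataFrame:
    """Per-species relative frequency over all cells.

    The frequency of a species is the number of cells where it occurs
    (count > 0); relative frequency divides by the sum of all species
    frequencies, so the ``proportion`` column sums to 1.
    """
    cells = aggregate(dataset, "cell").counts
    freq = (cells > 0).sum(axis=0)
    total = int(freq.sum())
    if total == 0:
        raise ValueError("all counts are zero; relative frequency undefined")
    out = pd.DataFrame({"frequency": freq.astype(int), "proportion": freq / total})
    out.index.name = "species"
    return out.sort_values("proportion", ascending=False)


def shoot_density(dataset: CommunityDataset, treatment: str) -> float:
    """Mean shoot density (shoots per cm^2) over the cells of one treatment.

    Every cell present in the records enters the mean, including cells whose
    total count is zero.
    """
    cells = aggregate(dataset, "cell")
    totals = cells.for_treatment(treatment).sum(axis=1)
    return float((totals / dataset.cell_area).mean())
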