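"""Synthetic paired-exclosure moss communities.

The generator emulates the statistical structure of a paired goose
exclosure/control experiment: 10 pairs of plots, one plot per treatment
(``absence`` inside the exclosure, ``presence`` outside), 5 quadrats per
plot and 25 cells per quadrat, with a skewed (lognormal) species
abundance distribution over a ~50-species pool and Poisson shoot counts
per cell.

Generative model (fully deterministic given the seed):

1. Global species relative abundances are drawn from a lognormal SAD
   (shape ``sad_sigma``) and normalized.  Species below the median weight
   are "subordinate".
2. Each plot and each quadrat receives independent lognormal random
   effects (sd ``patchiness_sigma``) multiplying the species weights —
   this is the compositional patchiness of the moss carpet.
3. In presence plots the treatment acts through three knobs:
   * ``evenness_effect`` flattens the global weights (w -> w^(1-effect));
   * ``richness_effect`` adds to the quadrat-occupancy probability of
     subordinate species (baseline ``subordinate_occupancy``; dominant
     species always occupy);
   * ``homogenization`` mixes plot weights toward the shared pool and
     quadrat weights toward their plot's pool, shrinking compositional
     patchiness at both scales.
4. The expected cell total is ``base_density`` shoots per cell
   (36 shoots = 9.0 shoots/cm^2 on a 4 cm^2 cell), multiplied by
   ``density_multiplier`` in presence; per-quadrat weights are
   renormalized so this total is exact in expectation.
5. Cell counts are independent Poisson draws with mean
   (cell total) x (species weight).
6. Growth forms are assigned to the species pool from the configured
   counts (default 34 acrocarps, 16 pleurocarps, 2 Sphagnum).

Randomness uses per-unit substreams spawned from the master seed by fixed
keys, so enlarging the design does not scramble previously generated
units.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .community import GROWTH_FORMS, TREATMENTS, CommunityDataset


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic paired-exclosure design.

    Defaults reproduce the study dimensions (10 pairs x 5 quadrats x
    25 cells x 2 treatments = 2500 cells; 52 species) and the printed
    density contrast of 9.0 vs ~15.3 shoots/cm^2 (multiplier 1.7).
    """

    n_pairs: int = 10
    quadrats_per_plot: int = 5
    cells_per_quadrat: int = 25
    n_species: int = 52
    n_acrocarp: int = 34
    n_pleurocarp: int = 16
    n_sphagnum: int = 2
    sad_sigma: float = 1.5
    base_density: float = 36.0  # expected shoots per 4 cm^2 cell in absence
    density_multiplier: float = 1.7
    richness_effect: float = 0.3
    evenness_effect: float = 0.25
    homogenization: float = 0.5
    patchiness_sigma: float = 0.7
    subordinate_occupancy: float = 0.5
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        for name in ("n_pairs", "quadrats_per_plot", "cells_per_quadrat", "n_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_acrocarp + self.n_pleurocarp + self.n_sphagnum != self.n_species:
            raise ValueError(
                "growth-form counts must sum to n_species "
                f"({self.n_acrocarp}+{self.n_pleurocarp}+{self.n_sphagnum} "
                f"!= {self.n_species})"
            )
        if self.sad_sigma < 0 or self.patchiness_sigma < 0:
            raise ValueError("sad_sigma and patchiness_sigma must be >= 0")
        if self.base_density <= 0 or self.density_multiplier <= 0:
            raise ValueError("base_density and density_multiplier must be > 0")
        if self.richness_effect < 0:
            raise ValueError("richness_effect must be >= 0")
        for name in ("evenness_effect", "homogenization", "subordinate_occupancy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        return self


def default_config() -> SyntheticConfig:
    """The study-design configuration (see :class:`SyntheticConfig`)."""
    return SyntheticConfig()


def null_config(seed: int = 0) -> SyntheticConfig:
    """All treatment effects off: both arms are exchangeable."""
    return replace(
        default_config(),
        density_multiplier=1.0,
        richness_effect=0.0,
        evenness_effect=0.0,
        homogenization=0.0,
        seed=seed,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    # fixed spawn keys -> stable per-unit substreams under design resizing
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _species_names(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _make_registry(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    species = _species_names(cfg.n_species)
    forms = (
        ["acrocarp"] * cfg.n_acrocarp
        + ["pleurocarp"] * cfg.n_pleurocarp
        + ["sphagnum"] * cfg.n_sphagnum
    )
    forms = list(np.asarray(forms)[rng.permutation(cfg.n_species)])
    genus = [f"genus{(i % 12) + 1:02d}" for i in range(cfg.n_species)]
    return pd.DataFrame({"species": species, "genus": genus, "growth_form": forms})


def simulate_dataset(config: SyntheticConfig) -> CommunityDataset:
    """Draw one CommunityDataset from the generative model.

    Deterministic given the config (including its seed).  Cells whose
    draw is entirely zero are retained via an explicit zero-count row so
    the sampled design stays enumerable from the records.
    """
    cfg = config.validate()
    s = cfg.n_species
    species = np.asarray(_species_names(s))

    global_rng = _rng(cfg.seed, 0)
    w = global_rng.lognormal(mean=0.0, sigma=cfg.sad_sigma, size=s)
    w /= w.sum()
    subordinate = w < np.median(w)
    registry = _make_registry(cfg, _rng(cfg.seed, 0, 1))

    frames: list[pd.DataFrame] = []
    for ip in range(cfg.n_pairs):
        pair_id = f"p{ip + 1:02d}"
        for it, treatment in enumerate(TREATMENTS):
            presence = treatment == "presence"
            plot_id = f"{pair_id}_{treatment}"
            if presence and cfg.evenness_effect > 0:
                w_t = w ** (1.0 - cfg.evenness_effect)
                w_t = w_t / w_t.sum()
            else:
                w_t = w
            h = cfg.homogenization if presence else 0.0

            plot_rng = _rng(cfg.seed, 1, ip, it)
            e_plot = plot_rng.lognormal(0.0, cfg.patchiness_sigma, size=s)
            w_plot = w_t * ((1 - h) * e_plot + h)

            occ_p = np.ones(s)
            occ_p[subordinate] = cfg.subordinate_occupancy + (
                cfg.richness_effect if presence else 0.0
            )
            occ_p = np.clip(occ_p, 0.0, 1.0)

            total = cfg.base_density * (cfg.density_multiplier if presence else 1.0)

            for iq in range(cfg.quadrats_per_plot):
                qrng = _rng(cfg.seed, 2, ip, it, iq)
                e_quad = qrng.lognormal(0.0, cfg.patchiness_sigma, size=s)
                w_quad = w_plot * ((1 - h) * e_quad + h)
                occ = qrng.random(s) < occ_p
                v = w_quad * occ
                if v.sum() == 0:  # degenerate tiny configs: keep the dominants
                    v = w_quad
                v = v / v.sum()
                mu = total * v
                counts = qrng.poisson(mu, size=(cfg.cells_per_quadrat, s))

                cell_idx, sp_idx = np.nonzero(counts)
                # keep all-zero cells in the design via an explicit zero row
                empty = np.setdiff1d(
                    np.arange(cfg.cells_per_quadrat), np.unique(cell_idx)
                )
                if len(empty):
                    cell_idx = np.concatenate([cell_idx, empty])
                    sp_idx = np.concatenate([sp_idx, np.zeros(len(empty), int)])
                frames.append(
                    pd.DataFrame(
                        {
                            "pair_id": pair_id,
                            "treatment": treatment,
                            "plot_id": plot_id,
                            "quadrat_id": iq + 1,
                            "cell_id": cell_idx + 1,
                            "species": species[sp_idx],
                            "count": counts[cell_idx, sp_idx],
                        }
                    )
                )
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(
        ["pair_id", "treatment", "plot_id", "quadrat_id", "cell_id", "species"],
        kind="mergesort",
    ).reset_index(drop=True)
    return CommunityDataset(records=records, registry=registry)


def config_from_dict(d: dict) -> SyntheticConfig:
    unknown = set(d) - set(SyntheticConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown SyntheticConfig field(s): {sorted(unknown)}")
    return SyntheticConfig(**d).validate()


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
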