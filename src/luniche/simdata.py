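"""Synthetic grassland communities with a known land-use niche structure.

Generates (a) per-plot per-year land-use component records producing a
realistic land-use intensity gradient and (b) genus-by-sample count tables
for a factorial design of plots x plant species x plant types, where each
genus follows one of four abundance archetypes along the gradient:

* ``winner``         — relative abundance increases monotonically with LUI,
                       proportional to exp(strength * (L - Lbar));
* ``loser``          — mirror image, exp(-strength * (L - Lbar));
* ``mid_specialist`` — Gaussian bump exp(-(L - optimum)^2 / (2 breadth^2));
* ``neutral``        — flat response.

Counts are multinomial draws conditional on a uniformly drawn sequencing
depth, so column sums equal the drawn depths exactly. The ground truth
(archetype per genus) is returned alongside, enabling recovery tests of the
niche classification downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lui import LandUseRecord

__all__ = [
    "NicheArchetype",
    "SimConfig",
    "simulate_landuse",
    "simulate_community",
    "expected_composition",
    "SPECIES",
    "PLANT_TYPES",
]

SPECIES = ("Dactylis_glomerata", "Plantago_lanceolata")
PLANT_TYPES = ("phytometer", "resident")
ARCHETYPES = ("winner", "loser", "mid_specialist", "neutral")


@dataclass(frozen=True)
class NicheArchetype:
    """Ground-truth abundance response of one genus along the LUI gradient."""

    genus_id: str
    kind: str
    strength: float = 0.0
    optimum: float | None = None
    breadth: float | None = None
    base_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.kind == "mid_specialist":
            if self.optimum is None or self.breadth is None or self.breadth <= 0:
                raise ValueError("mid_specialist needs an optimum and a breadth > 0")

    def response(self, lui_values: np.ndarray, lui_mean: float) -> np.ndarray:
        """Relative-abundance multiplier r(L) at each LUI value."""
        lui_values = np.asarray(lui_values, dtype=float)
        if self.kind == "winner":
            return np.exp(self.strength * (lui_values - lui_mean))
        if self.kind == "loser":
            return np.exp(-self.strength * (lui_values - lui_mean))
        if self.kind == "mid_specialist":
            return np.exp(-((lui_values - self.optimum) ** 2) / (2.0 * self.breadth**2))
        return np.ones_like(lui_values)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the field design: 13 plots sampled for 2 plant species
    x 2 plant types (52 samples), a 9-year land-use history (2006-2014), a
    right-skewed intensity gradient, and ~60 genera dominated by neutral
    responders. Depths default to 2,000-5,000 reads per sample — the study's
    per-sample depths are an order of magnitude larger, but the compositional
    structure, not the raw depth, carries the signal.
    """

    n_plots: int = 13
    year_from: int = 2006
    year_to: int = 2014
    n_winners: int = 8
    n_losers: int = 8
    n_mid: int = 8
    n_neutral: int = 36
    strength: float = 2.0
    mid_breadth: float = 0.35
    depth_range: tuple[int, int] = (2000, 5000)
    species_effect: float = 0.5
    plant_type_effect: float = 0.0
    occupancy_prob: float = 1.0
    overdispersion: float | None = None
    # land-use component scales (regional baselines)
    fert_scale: float = 60.0  # kg N ha-1 yr-1 for an average fertilized plot
    mow_rate: float = 1.3  # expected cuts yr-1 at unit intensity
    graze_scale: float = 160.0  # LU grazing days ha-1 yr-1 at unit intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 2:
            raise ValueError("need at least 2 plots")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid depth_range {self.depth_range}")
        if not 0.0 < self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in (0, 1]")

    @property
    def plot_ids(self) -> list[str]:
        return [f"plot{i + 1:02d}" for i in range(self.n_plots)]


def _plot_intensity(config: SimConfig) -> np.ndarray:
    """Latent per-plot management intensity, right-skewed like real gradients."""
    t = np.linspace(0.0, 1.0, config.n_plots)
    return 0.35 + 3.3 * t**2.2


def simulate_landuse(config: SimConfig) -> list[LandUseRecord]:
    """Draw per-plot per-year fertilization, mowing and grazing records.

    Plots sit on a latent intensity scale; low-intensity plots are
    unfertilized (F = 0 exactly) and mowing is a Poisson count, so unmown
    years (M = 0) occur naturally — mirroring extensively grazed pastures.
    Fully reproducible for a fixed config seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    intensity = _plot_intensity(config)
    records: list[LandUseRecord] = []
    years = range(config.year_from, config.year_to + 1)
    for plot, m in zip(config.plot_ids, intensity):
        fertilized = m > 0.8
        grazed = m < 2.6  # the most intensive meadows are mown/fertilized only
        for year in years:
            f = rng.gamma(4.0, config.fert_scale * m / 4.0) if fertilized else 0.0
            mow = float(rng.poisson(config.mow_rate * m))
            g = rng.gamma(3.0, config.graze_scale * m / 3.0) if grazed else 0.0
            records.append(LandUseRecord(plot_id=plot, year=year, F=f, M=mow, G=g))
    return records


def _draw_archetypes(config: SimConfig, rng: np.random.Generator, lui: pd.Series):
    lui_lo, lui_hi = float(lui.min()), float(lui.max())
    mid_center = 0.5 * (lui_lo + lui_hi)
    genera: list[NicheArchetype] = []
    specs = [
        ("win", "winner", config.n_winners),
        ("los", "loser", config.n_losers),
        ("mid", "mid_specialist", config.n_mid),
        ("neu", "neutral", config.n_neutral),
    ]
    for prefix, kind, n in specs:
        for i in range(n):
            base = float(rng.lognormal(0.0, 1.0))
            if kind == "mid_specialist":
                optimum = float(mid_center + 0.15 * (lui_hi - lui_lo) * rng.normal())
                genera.append(
                    NicheArchetype(
                        genus_id=f"{prefix}{i + 1:02d}",
                        kind=kind,
                        strength=config.strength,
                        optimum=optimum,
                        breadth=config.mid_breadth,
                        base_abundance=base,
                    )
                )
            else:
                strength = 0.0 if kind == "neutral" else config.strength
                genera.append(
                    NicheArchetype(
                        genus_id=f"{prefix}{i + 1:02d}",
                        kind=kind,
                        strength=strength,
                        base_abundance=base,
                    )
                )
    return genera


def expected_composition(
    genera: list[NicheArchetype], lui: pd.Series, presence: np.ndarray | None = None
) -> pd.DataFrame:
    """Expected relative abundance of each genus in each plot (rows sum to 1).

    ``presence`` is an optional genus x plot 0/1 matrix of structural
    occupancy (Bernoulli thinning); default all-present.
    """
    lui_values = lui.to_numpy(dtype=float)
    lui_mean = float(lui_values.mean())
    weights = np.stack(
        [g.base_abundance * g.response(lui_values, lui_mean) for g in genera]
    )
    if presence is not None:
        weights = weights * presence
    col_sums = weights.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("a plot ended up with no present genera; lower thinning")
    comp = weights / col_sums
    return pd.DataFrame(comp, index=[g.genus_id for g in genera], columns=lui.index)


def simulate_community(
    config: SimConfig, lui: pd.Series
) -> tuple["CountTable", pd.DataFrame]:
    """Generate the factorial genus-by-sample count table plus ground truth.

    One sample per (plot x species x plant type) cell. Species and
    plant-type effects each multiply a random half of the genera by
    exp(effect) in the second factor level, shifting composition without
    touching the land-use response. Returns ``(CountTable, TruthTable)``
    where the truth table maps genus_id -> archetype parameters.
    """
    from .tables import CountTable  # deferred to avoid an import cycle

    missing = [p for p in config.plot_ids if p not in lui.index]
    if missing:
        raise ValueError(f"LUI table missing plot(s): {missing}")
    lui = lui.loc[config.plot_ids]
    rng = np.random.default_rng([config.seed, 202])
    genera = _draw_archetypes(config, rng, lui)
    n_genera = len(genera)

    presence = np.ones((n_genera, config.n_plots))
    if config.occupancy_prob < 1.0:
        presence = (rng.random((n_genera, config.n_plots)) < config.occupancy_prob).astype(float)
        # every genus must occur somewhere; give empties one random plot
        for row in np.flatnonzero(presence.sum(axis=1) == 0):
            presence[row, rng.integers(config.n_plots)] = 1.0
    comp = expected_composition(genera, lui, presence)

    species_subset = rng.random(n_genera) < 0.5
    type_subset = rng.random(n_genera) < 0.5
    species_mult = np.where(species_subset, np.exp(config.species_effect), 1.0)
    type_mult = np.where(type_subset, np.exp(config.plant_type_effect), 1.0)

    sample_ids, meta_rows, columns = [], [], []
    lo, hi = config.depth_range
    for p_idx, plot in enumerate(config.plot_ids):
        for s_idx, species in enumerate(SPECIES):
            for t_idx, ptype in enumerate(PLANT_TYPES):
                weights = comp.iloc[:, p_idx].to_numpy().copy()
                if s_idx == 1:
                    weights = weights * species_mult
                if t_idx == 1:
                    weights = weights * type_mult
                if config.overdispersion:
                    shape = 1.0 / config.overdispersion
                    weights = weights * rng.gamma(shape, 1.0 / shape, size=n_genera)
                probs = weights / weights.sum()
                depth = int(rng.integers(lo, hi + 1))
                counts = rng.multinomial(depth, probs)
                sample_id = f"{plot}.{species}.{ptype}"
                sample_ids.append(sample_id)
                meta_rows.append((sample_id, plot, species, ptype))
                columns.append(counts)

    counts_df = pd.DataFrame(
        np.column_stack(columns),
        index=[g.genus_id for g in genera],
        columns=sample_ids,
    )
    counts_df.index.name = "genus_id"
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "plot_id", "species", "plant_type"]
    ).set_index("sample_id")

    truth = pd.DataFrame(
        {
            "kind": [g.kind for g in genera],
            "strength": [g.strength for g in genera],
            "optimum": [g.optimum for g in genera],
            "breadth": [g.breadth for g in genera],
            "base_abundance": [g.base_abundance for g in genera],
        },
        index=pd.Index([g.genus_id for g in genera], name="genus_id"),
    )
    return CountTable(counts_df, metadata), truth
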