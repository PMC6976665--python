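"""Land-use niche of fungal genera: optimum, breadth, and a null model.

The niche optimum of genus j is the abundance-weighted mean of the land-use
intensity values of the plots it occupies,

    mu_j = sum_s p_{j,s} * L_s,

where p_{j,s} is the share of the genus's total abundance found on plot s
(the weights sum to 1 per genus) and L_s is the plot's LUI. The
abundance-weighted standard deviation sigma_j is the niche breadth, and
CV_j = sigma_j / mu_j the weighted coefficient of variation.

Observed optima are compared against a randomization null model in which a
genus could occur on any plot of the gradient with equal probability: each
iteration places the genus's observed nonzero abundance profile, in random
order, onto a uniformly chosen subset of as many plots as it actually
occupies. Genera with an optimum significantly above the null are "winners"
of land-use intensification, significantly below are "losers"; among the
remaining genera, those with a significantly narrow CV are specialists of
intermediate intensity ("mid-specialists"), and the rest are "neutrals".
Small instances are enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = [
    "plot_abundance",
    "niche_stats",
    "NullDistribution",
    "null_distribution",
    "null_model",
    "classify",
    "guild_annotate",
    "niche_report",
    "land_use_niche",
]

CATEGORIES = ("winner", "loser", "mid_specialist", "neutral")


def plot_abundance(
    table: CountTable, lui: pd.Series, subset: dict[str, str] | None = None
) -> pd.DataFrame:
    """Aggregate (normalized) abundances per genus per plot.

    ``subset`` filters samples by metadata equality, e.g.
    ``{"plant_type": "phytometer"}``; samples within a plot are summed.
    Every retained sample's plot must have a LUI value. Returns a genus x
    plot DataFrame whose columns follow the LUI table's plot order.
    """
    if table.metadata is None:
        raise ValueError("plot aggregation requires sample metadata")
    meta = table.metadata.loc[table.samples]
    keep = pd.Series(True, index=meta.index)
    if subset:
        for field_name, value in subset.items():
            if field_name not in meta.columns:
                raise ValueError(f"unknown metadata field {field_name!r}")
            keep &= meta[field_name] == value
    samples = keep.index[keep].tolist()
    if not samples:
        raise ValueError(f"sample subset {subset!r} is empty")
    plots = meta.loc[samples, "plot_id"]
    missing = sorted(set(plots) - set(lui.index))
    if missing:
        raise ValueError(f"plot(s) without a LUI value: {missing}")
    summed = table.counts[samples].T.groupby(plots.to_numpy()).sum().T
    plot_order = [p for p in lui.index if p in summed.columns]
    return summed[plot_order]


def niche_stats(abund: pd.DataFrame, lui: pd.Series) -> pd.DataFrame:
    """Abundance-weighted niche optimum, breadth, CV and occupancy per genus.

    Genera with zero total abundance get NaN statistics and occupancy 0; a
    zero optimum (possible only if every occupied plot has LUI 0) flags the
    CV as NaN.
    """
    lvals = lui.loc[abund.columns].to_numpy(dtype=float)
    a = abund.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    totals = a.sum(axis=1)
    rows = []
    for i, genus in enumerate(abund.index):
        if totals[i] == 0:
            rows.append((genus, np.nan, np.nan, np.nan, 0))
            continue
        p = a[i] / totals[i]
        mu = float(p @ lvals)
        sigma = float(math.sqrt(max(p @ (lvals - mu) ** 2, 0.0)))
        cv = sigma / mu if mu > 0 else np.nan
        rows.append((genus, mu, sigma, cv, int((a[i] > 0).sum())))
    return pd.DataFrame(
        rows, columns=["genus", "mu_obs", "sigma_obs", "cv_obs", "occupancy"]
    ).set_index("genus")


@dataclass
class NullDistribution:
    """Randomization distribution of the niche optimum for one genus."""

    genus_id: str
    n_iter: int
    mu_null: np.ndarray
    cv_null: np.ndarray
    mu_exp: float
    p_high: float
    p_low: float
    p_cv_low: float
    exhaustive: bool = field(default=False)


def _placement_stats(weights: np.ndarray, lui_sel: np.ndarray):
    """mu and cv for each row of plot-LUI selections under fixed weights."""
    mu = lui_sel @ weights
    var = ((lui_sel - mu[:, None]) ** 2) @ weights
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sigma / mu, np.nan)
    return mu, cv


def null_distribution(
    abundances: np.ndarray,
    lui_values: np.ndarray,
    n_iter: int = 10000,
    rng: np.random.Generator | int | None = None,
    mode: str = "profile",
    exhaustive_limit: int = 10000,
    genus_id: str = "",
    mu_obs: float | None = None,
    cv_obs: float | None = None,
) -> NullDistribution:
    """Randomization null for one genus's niche optimum and CV.

    ``abundances`` is the genus's per-plot abundance vector (zeros mark
    unoccupied plots). Each iteration keeps the occupancy count k fixed and
    re-places the observed nonzero abundance profile, shuffled, onto k plots
    drawn without replacement — so breadth and CV stay comparable between
    observed and null. ``mode="occupancy"`` discards the profile and weights
    the k plots equally. When the number of distinct ordered placements
    n!/(n-k)! is at most ``exhaustive_limit``, all are enumerated and the
    p-values are exact.

    One-tailed p-values use the +1 permutation correction in Monte-Carlo
    mode; exhaustive mode reports exact proportions (the observed placement
    is itself in the enumeration, so p > 0 always).
    """
    abundances = np.asarray(abundances, dtype=float)
    lui_values = np.asarray(lui_values, dtype=float)
    n = len(lui_values)
    nz = abundances[abundances > 0]
    k = len(nz)
    if k == 0:
        raise ValueError(f"genus {genus_id!r} occupies no plots")
    if k > n:
        raise ValueError(f"occupancy {k} exceeds the number of plots {n}")
    if mode not in ("profile", "occupancy"):
        raise ValueError(f"unknown null-model mode {mode!r}")
    weights = nz / nz.sum() if mode == "profile" else np.full(k, 1.0 / k)

    if mu_obs is None or cv_obs is None:
        obs_w = abundances / abundances.sum()
        mu_obs = float(obs_w @ lui_values)
        sigma_obs = math.sqrt(max(obs_w @ (lui_values - mu_obs) ** 2, 0.0))
        cv_obs = sigma_obs / mu_obs if mu_obs > 0 else np.nan

    n_placements = math.perm(n, k)
    if n_placements <= exhaustive_limit:
        sel = np.array(list(itertools.permutations(range(n), k)), dtype=np.intp)
        mu_null, cv_null = _placement_stats(weights, lui_values[sel])
        mu_exp = float(mu_null.mean())
        p_high = float((mu_null >= mu_obs - 1e-12).mean())
        p_low = float((mu_null <= mu_obs + 1e-12).mean())
        if np.isnan(cv_obs):
            p_cv_low = float("nan")
        else:
            p_cv_low = float((cv_null <= cv_obs + 1e-12).mean())
        return NullDistribution(
            genus_id, len(sel), mu_null, cv_null, mu_exp, p_high, p_low, p_cv_low,
            exhaustive=True,
        )

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    # argsort of uniforms = uniform random permutation; first k columns give
    # a uniformly drawn ordered k-subset of plots
    idx = np.argsort(rng.random((n_iter, n)), axis=1)[:, :k]
    mu_null, cv_null = _placement_stats(weights, lui_values[idx])
    mu_exp = float(mu_null.mean())
    p_high = float((1.0 + (mu_null >= mu_obs - 1e-12).sum()) / (n_iter + 1.0))
    p_low = float((1.0 + (mu_null <= mu_obs + 1e-12).sum()) / (n_iter + 1.0))
    if np.isnan(cv_obs):
        p_cv_low = float("nan")
    else:
        p_cv_low = float((1.0 + (cv_null <= cv_obs + 1e-12).sum()) / (n_iter + 1.0))
    return NullDistribution(
        genus_id, n_iter, mu_null, cv_null, mu_exp, p_high, p_low, p_cv_low
    )


def null_model(
    abund: pd.DataFrame,
    lui: pd.Series,
    n_iter: int = 10000,
    seed: int | None = None,
    mode: str = "profile",
    exhaustive_limit: int = 10000,
) -> pd.DataFrame:
    """Run the randomization null for every genus of a plot-abundance table.

    Returns a per-genus DataFrame with mu_exp, p_high, p_low, p_cv_low and
    whether the exact exhaustive enumeration was used. Genera absent from
    every plot are skipped (NaN row).
    """
    lvals = lui.loc[abund.columns].to_numpy(dtype=float)
    stats = niche_stats(abund, lui)
    rng = np.random.default_rng(seed)
    rows = []
    for genus in abund.index:
        a = abund.loc[genus].to_numpy(dtype=float)
        if a.sum() == 0:
            rows.append((genus, np.nan, np.nan, np.nan, np.nan, False))
            continue
        nd = null_distribution(
            a, lvals, n_iter=n_iter, rng=rng, mode=mode,
            exhaustive_limit=exhaustive_limit, genus_id=str(genus),
            mu_obs=float(stats.at[genus, "mu_obs"]),
            cv_obs=float(stats.at[genus, "cv_obs"]),
        )
        rows.append((genus, nd.mu_exp, nd.p_high, nd.p_low, nd.p_cv_low, nd.exhaustive))
    return pd.DataFrame(
        rows, columns=["genus", "mu_exp", "p_high", "p_low", "p_cv_low", "exhaustive"]
    ).set_index("genus")


def classify(
    stats: pd.DataFrame, null: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Assign winner / loser / mid_specialist / neutral per genus.

    winner if the optimum exceeds the null (p_high < alpha); loser if below
    (p_low < alpha); otherwise mid_specialist when the CV is significantly
    narrow (p_cv_low < alpha) with both optimum tails non-significant; else
    neutral. A genus significant in both optimum tails is impossible for a
    valid permutation p (alpha <= 0.5) and raises.
    """
    if alpha <= 0.5:
        both = (null["p_high"] < alpha) & (null["p_low"] < alpha)
        if both.any():
            raise ValueError(
                f"genera significant in both optimum tails: {list(null.index[both])}"
            )
    out = {}
    for genus in null.index:
        p_high, p_low, p_cv = null.loc[genus, ["p_high", "p_low", "p_cv_low"]]
        if np.isnan(p_high):
            out[genus] = "neutral"
        elif p_high < alpha:
            out[genus] = "winner"
        elif p_low < alpha:
            out[genus] = "loser"
        elif not np.isnan(p_cv) and p_cv < alpha:
            out[genus] = "mid_specialist"
        else:
            out[genus] = "neutral"
    return pd.Series(out, name="category")


def guild_annotate(
    genera: list[str],
    guild_table: pd.DataFrame | None,
    overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Attach a trophic mode to each genus from a guild lookup table.

    ``guild_table`` needs columns ``genus`` and ``trophic_mode``; matching is
    case-insensitive, overrides are applied last, and unmatched genera are
    labeled ``unknown``. Multi-mode strings (e.g. ``pathotroph/saprotroph``)
    are preserved verbatim and flagged ``multi_mode`` so downstream reports
    can leave them uninterpreted.
    """
    lookup: dict[str, str] = {}
    if guild_table is not None:
        for col in ("genus", "trophic_mode"):
            if col not in guild_table.columns:
                raise ValueError(f"guild table missing column {col!r}")
        for _, row in guild_table.iterrows():
            lookup[str(row["genus"]).lower()] = str(row["trophic_mode"])
    overrides = {str(k).lower(): v for k, v in (overrides or {}).items()}
    rows = []
    for genus in genera:
        mode = overrides.get(genus.lower(), lookup.get(genus.lower(), "unknown"))
        rows.append((genus, mode, "/" in mode))
    return pd.DataFrame(rows, columns=["genus", "trophic_mode", "multi_mode"]).set_index(
        "genus"
    )


def niche_report(results: pd.DataFrame, lui: pd.Series) -> dict:
    """Summarize a niche-result table for a dot-and-whisker style figure.

    Returns a dict with the per-genus ``table`` (mu_obs +/- sigma_obs,
    category, trophic mode, p-values), the ``reference_lui`` dotted-line
    value (unweighted mean plot LUI, which equals the large-sample null
    expectation), and ``category_counts``.
    """
    if results.empty:
        raise ValueError("empty niche-result table")
    table = results.sort_values("mu_obs").copy()
    return {
        "table": table,
        "reference_lui": float(lui.mean()),
        "category_counts": results["category"].value_counts().to_dict(),
    }


def land_use_niche(
    table: CountTable,
    lui: pd.Series,
    subset: dict[str, str] | None = None,
    n_iter: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "profile",
    guild_table: pd.DataFrame | None = None,
    overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full niche analysis of a (normalized) genus table for one subset.

    Aggregates samples to plots, computes observed niche statistics, runs
    the randomization null, classifies every genus, and attaches trophic
    modes. Returns one row per genus with all statistics.
    """
    abund = plot_abundance(table, lui, subset=subset)
    occupied = abund.index[abund.sum(axis=1) > 0]
    abund = abund.loc[occupied]
    stats = niche_stats(abund, lui)
    null = null_model(abund, lui, n_iter=n_iter, seed=seed, mode=mode)
    category = classify(stats, null, alpha=alpha)
    guilds = guild_annotate(list(abund.index), guild_table, overrides)
    out = stats.join(null).join(category).join(guilds)
    out.index.name = "genus"
    return out
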