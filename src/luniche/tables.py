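"""Taxa-by-sample count tables: I/O, validation, filtering, normalization.

The central container is :class:`CountTable`, a thin wrapper around a pandas
DataFrame (taxa rows x sample columns) plus per-sample metadata (plot_id,
species, plant_type). Counts are integers until a normalization step
(TMM) turns them into real-valued normalized abundances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_taxonomy",
    "filter_rare",
    "rarefy",
    "min_depth",
    "tmm_normalize",
    "aggregate_rank",
    "venn_partition",
    "round_half_away",
]

METADATA_FIELDS = ("plot_id", "species", "plant_type")
RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class CountTable:
    """Non-negative taxa x samples matrix with sample metadata.

    ``counts``: DataFrame indexed by taxon id, columns are sample ids.
    ``metadata``: DataFrame indexed by sample id with at least the columns
    plot_id, species, plant_type; may be None for bare matrices.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon id(s): {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            row, col = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.counts.index[row]!r}, "
                f"sample {self.counts.columns[col]!r}"
            )
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            absent = [c for c in METADATA_FIELDS if c not in self.metadata.columns]
            if absent:
                raise ValueError(f"metadata missing field(s): {absent}")
            if self.metadata.loc[list(self.counts.columns)].isna().any().any():
                raise ValueError("metadata contains missing values for analyzed samples")

    # -- convenience -------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def is_integer(self) -> bool:
        values = self.counts.to_numpy()
        return bool(np.issubdtype(values.dtype, np.integer) or np.allclose(values, np.round(values)))

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return CountTable(self.counts[sample_ids].copy(), meta)

    def copy(self) -> "CountTable":
        meta = self.metadata.copy() if self.metadata is not None else None
        return CountTable(self.counts.copy(), meta)


# -- I/O -------------------------------------------------------------------

def read_counts(path, metadata: pd.DataFrame | None = None) -> CountTable:
    """Read a counts TSV (first column taxon id, remaining columns samples).

    Ragged rows, duplicate ids, and negative or non-numeric cells raise with
    row/column context.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed counts TSV {path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            taxon = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell in {path} at taxon {taxon!r}, sample {col!r}"
            )
    if df.isna().any().any():
        raise ValueError(f"missing cells in counts TSV {path}")
    df.index = df.index.astype(str)
    if (df.to_numpy() == np.floor(df.to_numpy())).all():
        df = df.astype(np.int64)
    return CountTable(df, metadata)


def write_counts(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    absent = [c for c in METADATA_FIELDS if c not in meta.columns]
    if absent:
        raise ValueError(f"metadata TSV {path} missing field(s): {absent}")
    return meta


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV: taxon_id then the six ranks; blanks become 'unclassified'."""
    tax = pd.read_csv(path, sep="\t", index_col="taxon_id", dtype=str)
    absent = [c for c in RANKS if c not in tax.columns]
    if absent:
        raise ValueError(f"taxonomy TSV {path} missing rank(s): {absent}")
    return tax.fillna("unclassified")


# -- operations ------------------------------------------------------------

def filter_rare(table: CountTable, min_total: int = 4) -> CountTable:
    """Drop taxa whose total count across all samples is below ``min_total``.

    The default removes singletons, doubletons and tripletons (totals 1-3),
    keeping taxa with at least 4 reads overall.
    """
    if not table.is_integer():
        raise ValueError("filter_rare expects integer counts (apply before normalization)")
    totals = table.counts.sum(axis=1)
    kept = table.counts.loc[totals >= min_total].copy()
    return CountTable(kept, table.metadata)


def min_depth(table: CountTable) -> int:
    """Smallest per-sample read total (the usual rarefaction depth)."""
    if table.counts.shape[1] == 0:
        raise ValueError("count table has no samples")
    return int(table.sample_totals().min())


def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator) -> CountTable:
    """Subsample each sample to ``depth`` reads uniformly without replacement.

    Index-permutation subsampling: each read of a sample is an urn ball
    labeled with its taxon; ``depth`` balls are drawn without replacement, so
    per-taxon subsampled counts have exact (multivariate) hypergeometric
    marginals. Column sums of the result equal ``depth`` exactly.
    """
    if not table.is_integer():
        raise ValueError("rarefy expects integer counts")
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1 (got {depth})")
    totals = table.sample_totals()
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"sample(s) below rarefaction depth {depth}: "
            + ", ".join(f"{s} ({int(t)})" for s, t in shallow.items())
        )
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy().astype(np.int64)
    out = np.zeros_like(counts)
    n_taxa = counts.shape[0]
    for j in range(counts.shape[1]):
        column = counts[:, j]
        reads = np.repeat(np.arange(n_taxa), column)
        drawn = rng.permutation(reads)[:depth]
        out[:, j] = np.bincount(drawn, minlength=n_taxa)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(rarefied, table.metadata)


def tmm_normalize(
    table: CountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    do_weighting: bool = True,
) -> tuple[CountTable, pd.Series]:
    """Trimmed-mean-of-M-values normalization of a count table.

    The reference sample is the one whose 75th-percentile count proportion is
    closest to the across-sample mean of those quantiles. For every other
    sample, log2 abundance ratios M and average log2 abundances A are
    computed over taxa nonzero in both sample and reference; the top and
    bottom ``trim_m`` of M values and ``trim_a`` of A values are discarded,
    and the scaling factor is the (inverse-approximate-variance weighted)
    mean of the surviving M values, exponentiated. Factors are rescaled to a
    geometric mean of 1. Normalized abundances are
    ``count / (library_size * factor)`` rescaled to the mean library size, so
    the output is on a common effective-library scale.

    Returns the normalized table and the per-sample factors.
    """
    if table.counts.shape[1] < 2:
        raise ValueError("TMM normalization needs at least 2 samples")
    if not table.is_integer():
        raise ValueError("tmm_normalize expects integer counts")
    counts = table.counts.to_numpy().astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        empty = [s for s, t in zip(table.samples, lib) if t == 0]
        raise ValueError(f"sample(s) with zero total reads: {empty}")
    props = counts / lib
    f75 = np.quantile(props, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        log_factors[j] = _tmm_pair_log2(
            counts[:, j], lib[j], ref, ref_lib, trim_m, trim_a, do_weighting,
            sample_id=table.samples[j],
        )
    factors = 2.0 ** log_factors
    factors = factors / math.exp(np.log(factors).mean())  # geometric mean 1

    mean_lib = lib.mean()
    normalized = counts / (lib * factors) * mean_lib
    norm_df = pd.DataFrame(normalized, index=table.counts.index, columns=table.counts.columns)
    factor_series = pd.Series(factors, index=table.counts.columns, name="tmm_factor")
    return CountTable(norm_df, table.metadata), factor_series


def _tmm_pair_log2(
    obs, obs_lib, ref, ref_lib, trim_m, trim_a, do_weighting, sample_id
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        warnings.warn(
            f"sample {sample_id!r} shares no nonzero taxa with the TMM reference; "
            "factor set to 1",
            stacklevel=3,
        )
        return 0.0
    o, r = obs[both], ref[both]
    p_o, p_r = o / obs_lib, r / ref_lib
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if do_weighting:
        # inverse of the delta-method (binomial) variance of M
        var = (obs_lib - o) / (obs_lib * o) + (ref_lib - r) / (ref_lib * r)
        weights = 1.0 / var[keep]
    else:
        weights = np.ones(keep.sum())
    log2f = float(np.sum(weights * m[keep]) / np.sum(weights))
    if not np.isfinite(log2f):
        return 0.0
    return log2f


def aggregate_rank(table: CountTable, taxonomy: pd.DataFrame, rank: str = "genus") -> CountTable:
    """Sum counts of taxa sharing a taxonomy label at ``rank``.

    Unclassified lineages are pooled into rank-qualified bins like
    ``unclassified_<rank>``; column sums are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = set(table.taxa) - set(taxonomy.index)
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {sorted(missing)[:5]} ...")
    labels = taxonomy.loc[table.taxa, rank].astype(str)
    labels = labels.where(labels != "unclassified", f"unclassified_{rank}")
    grouped = table.counts.groupby(labels.to_numpy()).sum()
    grouped.index.name = table.counts.index.name
    return CountTable(grouped.sort_index(), table.metadata)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (printed-percent style)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def venn_partition(table: CountTable, factor: str) -> pd.DataFrame:
    """Partition taxa by the set of factor levels in which they occur.

    For each taxon, its presence set is the set of levels (e.g. plant types)
    with a nonzero total count. Returns one row per non-empty presence
    region with the taxon count and its integer percentage of all taxa
    present in at least one level (rounded half away from zero). Taxa absent
    everywhere are excluded and reported in the ``n_absent`` attribute.
    """
    if table.metadata is None:
        raise ValueError("venn_partition requires sample metadata")
    if factor not in table.metadata.columns:
        raise ValueError(f"unknown metadata field {factor!r}")
    levels = sorted(table.metadata.loc[list(table.counts.columns), factor].unique())
    if not 2 <= len(levels) <= 4:
        raise ValueError(f"factor {factor!r} has {len(levels)} level(s); need 2-4")
    presence = {}
    for level in levels:
        samples = [s for s in table.samples if table.metadata.at[s, factor] == level]
        presence[level] = table.counts[samples].sum(axis=1) > 0
    presence_df = pd.DataFrame(presence)
    present_any = presence_df.any(axis=1)
    n_absent = int((~present_any).sum())
    total = int(present_any.sum())
    regions = []
    grouped = presence_df[present_any].groupby(levels, sort=False)
    for key, block in grouped:
        key = key if isinstance(key, tuple) else (key,)
        members = tuple(lv for lv, flag in zip(levels, key) if flag)
        regions.append({
            "region": "&".join(members),
            "n_levels": len(members),
            "count": len(block),
            "percent": round_half_away(100.0 * len(block) / total),
        })
    out = pd.DataFrame(regions).sort_values(["n_levels", "region"]).reset_index(drop=True)
    out.attrs["n_absent"] = n_absent
    out.attrs["total_present"] = total
    return out
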