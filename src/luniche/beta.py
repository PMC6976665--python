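"""Community-composition (beta-diversity) statistics.

Bray-Curtis dissimilarities, PERMANOVA with sequential (Type-I) sums of
squares over arbitrary mixes of categorical factors and continuous
covariates, a permutation test of multivariate dispersion homogeneity
(principal-coordinates distances to group centroids), and SIMPER
decomposition of between-group dissimilarity into per-taxon contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable

__all__ = [
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "dispersion_test",
    "simper",
    "top_discriminant_genera",
]


def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    Returns a symmetric sample-by-sample DataFrame with zero diagonal.
    All-zero samples have no defined dissimilarity and raise.
    """
    if table.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    data = table.counts.to_numpy(dtype=float).T
    empty = np.flatnonzero(data.sum(axis=1) == 0)
    if empty.size:
        names = [table.samples[i] for i in empty]
        raise ValueError(f"all-zero sample(s) have undefined Bray-Curtis: {names}")
    dm = squareform(pdist(data, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.samples, columns=table.samples)


# -- PERMANOVA -------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table: one row per term plus a residual row."""

    table: pd.DataFrame  # index: term; columns: df, SS, F, R2, p
    n_perm: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"PermanovaResult(n_perm={self.n_perm})\n{self.table}"


def _gower_center(dist: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix from squared dissimilarities."""
    a = -0.5 * dist**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for one term; `a:b` denotes an interaction."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in metadata.columns:
            raise ValueError(f"term {term!r}: no metadata field {part!r}")
        col = metadata[part]
        if col.isna().any():
            raise ValueError(f"term {term!r}: missing values in {part!r}")
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for nxt in blocks[1:]:  # interaction: elementwise products of columns
        out = np.einsum("ij,ik->ijk", out, nxt).reshape(out.shape[0], -1)
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of x (pseudo-inverse based)."""
    return x @ np.linalg.pinv(x)


def permanova(
    dist: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Terms are fitted in the order given (Type-I), each taking the variation
    left after the preceding ones, as in vegan's ``adonis``. Categorical
    metadata fields become treatment-coded dummies, numeric fields enter as
    covariates, and ``a:b`` denotes an interaction. Significance comes from
    freely permuting sample identities against the metadata: pseudo-F values
    are recomputed for each permutation and
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).

    A term adding no model-matrix rank beyond its predecessors is
    confounded and raises. A constant factor yields SS = 0 with F and p
    reported as NaN.
    """
    samples = list(dist.index)
    if list(dist.columns) != samples:
        raise ValueError("distance matrix index and columns differ")
    meta = metadata.loc[samples]
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    g = _gower_center(d)
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    design_blocks = [ones]
    hats = [_hat(ones)]
    ranks = [1]
    term_df: list[int] = []
    degenerate: list[bool] = []
    for term in terms:
        cols = _term_columns(meta, term)
        if cols.shape[1] == 0 or np.allclose(np.std(cols, axis=0), 0):
            # constant factor: no variation to attribute
            design_blocks.append(np.zeros((n, 0)))
            hats.append(hats[-1])
            ranks.append(ranks[-1])
            term_df.append(0)
            degenerate.append(True)
            continue
        x = np.hstack(design_blocks + [cols])
        rank = np.linalg.matrix_rank(x)
        df = rank - ranks[-1]
        if df == 0:
            raise ValueError(f"term {term!r} is confounded with preceding terms")
        design_blocks.append(cols)
        hats.append(_hat(x))
        ranks.append(rank)
        term_df.append(df)
        degenerate.append(False)

    resid_df = n - ranks[-1]
    if resid_df <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        explained = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_terms = np.diff(explained)
        ss_resid = float(np.trace(gmat)) - explained[-1]
        return ss_terms, ss_resid

    ss_terms, ss_resid = stats_for(g)
    ms_resid = ss_resid / resid_df
    f_obs = np.array(
        [
            (ss / df) / ms_resid if df > 0 else np.nan
            for ss, df in zip(ss_terms, term_df)
        ]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    valid = np.array([df > 0 for df in term_df])
    # ties: a permutation reproducing the observed partition differs from
    # F_obs only by float summation order; count it as an exceedance
    tol = 1e-8 * np.maximum(np.abs(f_obs), 1.0)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_r = stats_for(gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = (ss_p / np.array(term_df, dtype=float)) / (ss_r / resid_df)
        exceed[valid] += f_p[valid] >= (f_obs - tol)[valid]
    p = np.where(valid, (1.0 + exceed) / (n_perm + 1.0), np.nan)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": term_df[i],
                "SS": ss_terms[i],
                "F": f_obs[i],
                "R2": ss_terms[i] / total_ss,
                "p": p[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": resid_df,
            "SS": ss_resid,
            "F": np.nan,
            "R2": ss_resid / total_ss,
            "p": np.nan,
        }
    )
    out = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=out, n_perm=n_perm)


# -- dispersion homogeneity (betadisper-style) ------------------------------

def _pcoa_embedding(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates axes split into real and imaginary parts.

    Eigenvectors of the Gower-centered matrix scaled by sqrt(|eigenvalue|);
    axes with negative eigenvalues span the 'imaginary' space whose squared
    distances subtract rather than add.
    """
    g = _gower_center(dist)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) > 1e-10 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    return coords[:, eigval > 0], coords[:, eigval < 0]


def dispersion_test(
    dist: pd.DataFrame,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Test homogeneity of multivariate dispersion between groups.

    Samples are embedded by principal coordinates; each sample's distance to
    its group centroid is computed with the imaginary-axis correction
    (squared distances in negative-eigenvalue space subtract, truncated at
    zero before the square root). A one-way ANOVA F on those distances is
    compared against ``n_perm`` random permutations of the group labels.

    Returns a dict with keys F, p, distances (per-sample Series), and
    group_means.
    """
    samples = list(dist.index)
    groups = grouping.loc[samples]
    counts = groups.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    real, imag = _pcoa_embedding(dist.to_numpy(dtype=float))
    codes, levels = pd.factorize(groups)
    dist_to_centroid = np.empty(len(samples))
    for k in range(len(levels)):
        members = codes == k
        c_real = real[members].mean(axis=0)
        c_imag = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        sq = ((real[members] - c_real) ** 2).sum(axis=1)
        if imag.size:
            sq = sq - ((imag[members] - c_imag) ** 2).sum(axis=1)
        dist_to_centroid[members] = np.sqrt(np.maximum(sq, 0.0))

    def anova_f(values: np.ndarray, codes: np.ndarray) -> float:
        grand = values.mean()
        ss_between = ss_within = 0.0
        for k in range(len(levels)):
            v = values[codes == k]
            ss_between += len(v) * (v.mean() - grand) ** 2
            ss_within += ((v - v.mean()) ** 2).sum()
        df_b = len(levels) - 1
        df_w = len(values) - len(levels)
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = anova_f(dist_to_centroid, codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    tol = 1e-8 * max(abs(f_obs), 1.0)
    for _ in range(n_perm):
        f_p = anova_f(dist_to_centroid, rng.permutation(codes))
        exceed += f_p >= f_obs - tol
    p = (1.0 + exceed) / (n_perm + 1.0)
    return {
        "F": float(f_obs),
        "p": float(p),
        "distances": pd.Series(dist_to_centroid, index=samples, name="dist_to_centroid"),
        "group_means": pd.Series(
            {lv: dist_to_centroid[codes == k].mean() for k, lv in enumerate(levels)}
        ),
    }


# -- SIMPER ----------------------------------------------------------------

def simper(table: CountTable, grouping: pd.Series) -> pd.DataFrame:
    """Per-taxon contributions to mean between-group Bray-Curtis dissimilarity.

    For every between-group sample pair (a, b), taxon i contributes
    |x_ia - x_ib| / sum_k (x_ka + x_kb); contributions are averaged over all
    such pairs, so per-taxon contributions sum exactly to the mean
    between-group dissimilarity. Rows are sorted by descending contribution
    (ties broken by taxon id) with the cumulative percentage of the total.
    """
    groups = grouping.loc[table.samples]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(
            f"SIMPER needs exactly 2 group levels, got {len(levels)}: {levels}; "
            "run pairwise comparisons explicitly"
        )
    data = table.counts.to_numpy(dtype=float)
    idx_a = np.flatnonzero((groups == levels[0]).to_numpy())
    idx_b = np.flatnonzero((groups == levels[1]).to_numpy())
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both group levels must be non-empty")
    contrib = np.zeros(data.shape[0])
    for a in idx_a:
        xa = data[:, a]
        for b in idx_b:
            xb = data[:, b]
            denom = (xa + xb).sum()
            if denom == 0:
                raise ValueError("a between-group sample pair is entirely zero")
            contrib += np.abs(xa - xb) / denom
    contrib /= len(idx_a) * len(idx_b)
    out = pd.DataFrame({"taxon": table.taxa, "mean_contribution": contrib})
    out = out.sort_values(
        ["mean_contribution", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
    total = out["mean_contribution"].sum()
    out["cumulative_percent"] = 100.0 * out["mean_contribution"].cumsum() / total
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_discriminant_genera(
    simper_table: pd.DataFrame, k: int = 30, exclude: set[str] | None = None
) -> tuple[list[str], float]:
    """The k highest-contribution named genera, excluding unclassified bins.

    Any taxon whose id is in ``exclude`` or starts with ``unclassified`` is
    skipped. Returns the genus list and the cumulative percentage of total
    dissimilarity those k genera carry.
    """
    exclude = exclude or set()
    named = simper_table[
        ~simper_table["taxon"].isin(exclude)
        & ~simper_table["taxon"].str.startswith("unclassified")
    ]
    if k > len(named):
        raise ValueError(f"asked for top {k} but only {len(named)} classified genera")
    top = named.head(k)
    total = simper_table["mean_contribution"].sum()
    cum_pct = float(100.0 * top["mean_contribution"].sum() / total)
    return top["taxon"].tolist(), cum_pct
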