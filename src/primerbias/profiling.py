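"""Alpha diversity, taxon-level primer-bias statistics, abundance distributions,
bias-attribution strategies, and closed-reference collapse.

All operations work on a feature table held as a pandas DataFrame of
non-negative integer counts with samples as rows and taxa as columns, plus a
metadata DataFrame (index sample_id; columns habitat, primer, pair_id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 1e-6  # on the relative-abundance scale


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("table contains an all-zero sample")
    return table.div(totals, axis=0)


def hill_diversity(counts: np.ndarray | pd.Series, q: float) -> float:
    """Hill number of order q: q=0 richness, q=1 exp(Shannon), q=2 inverse Simpson."""
    x = np.asarray(counts, dtype=float)
    if q < 0:
        raise ValueError("q must be >= 0")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero abundance vector")
    if q == 0:
        return float(x.size)
    p = x / x.sum()
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def _detected_names(table: pd.DataFrame, rank: str | None, taxonomy: pd.DataFrame | None):
    present = table.columns[(table.sum(axis=0) > 0)]
    if rank is None:
        return set(present)
    if taxonomy is None or rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} absent from taxonomy")
    return set(taxonomy.loc[list(present), rank])


def taxa_overlap(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    rank: str | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Shared / unique taxon counts and percentages at a taxonomic rank.

    With ``rank=None`` the comparison is at the feature (ASV) level.
    """
    a = _detected_names(table_a, rank, taxonomy)
    b = _detected_names(table_b, rank, taxonomy)
    shared = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    total = shared + only_a + only_b
    if total == 0:
        raise ValueError("no taxa detected in either table")
    return {
        "shared": shared,
        "only_a": only_a,
        "only_b": only_b,
        "shared_pct": 100.0 * shared / total,
        "only_a_pct": 100.0 * only_a / total,
        "only_b_pct": 100.0 * only_b / total,
    }


def _group_means(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    habitat: str,
    primer: str,
    level: str | None,
    taxonomy: pd.DataFrame | None,
) -> pd.Series:
    sel = metadata[(metadata["habitat"] == habitat) & (metadata["primer"] == primer)]
    if sel.empty:
        raise ValueError(f"no samples for habitat {habitat!r} / primer {primer!r}")
    rel = relative_abundance(table.loc[sel.index])
    if level is not None:
        if taxonomy is None or level not in taxonomy.columns:
            raise ValueError(f"rank {level!r} absent from taxonomy")
        rel = rel.T.groupby(taxonomy.loc[rel.columns, level].values).sum().T
    return rel.mean(axis=0)


def bias_vector(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    habitat: str,
    primer_a: str = "V4",
    primer_b: str = "V5V7",
    level: str | None = None,
    taxonomy: pd.DataFrame | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-taxon log2-fold ratio of mean relative abundance, primer A over primer B.

    Positive entries mean the taxon is over-represented in primer A.  A
    pseudocount on the relative-abundance scale keeps ratios finite for taxa
    absent in one data set.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ma = _group_means(table, metadata, habitat, primer_a, level, taxonomy)
    mb = _group_means(table, metadata, habitat, primer_b, level, taxonomy)
    ma, mb = ma.align(mb, fill_value=0.0)
    return np.log2((ma + pseudocount) / (mb + pseudocount)).rename("log2_bias")


def major_taxa(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    level: str | None = None,
    taxonomy: pd.DataFrame | None = None,
    threshold: float = 1e-3,
) -> list[str]:
    """Taxa with mean relative abundance >= threshold in at least one primer data set."""
    keep: set[str] = set()
    for primer in metadata["primer"].unique():
        sel = metadata[metadata["primer"] == primer]
        rel = relative_abundance(table.loc[sel.index])
        if level is not None:
            rel = rel.T.groupby(taxonomy.loc[rel.columns, level].values).sum().T
        m = rel.mean(axis=0)
        keep |= set(m.index[m >= threshold])
    return sorted(keep)


def _paired_log_ratios(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    habitat: str,
    primer_a: str,
    primer_b: str,
    pseudocount: float,
) -> pd.DataFrame:
    """Per-pair log2 relative-abundance ratios (pairs x taxa) within one habitat."""
    sub = metadata[metadata["habitat"] == habitat]
    a = sub[sub["primer"] == primer_a].reset_index().set_index("pair_id")
    b = sub[sub["primer"] == primer_b].reset_index().set_index("pair_id")
    pairs = a.index.intersection(b.index)
    if len(pairs) == 0:
        raise ValueError(f"no paired samples in habitat {habitat!r}")
    rel = relative_abundance(table)
    ra = rel.loc[a.loc[pairs, "sample_id"]]
    rb = rel.loc[b.loc[pairs, "sample_id"]]
    ra.index = pairs
    rb.index = pairs
    return np.log2((ra + pseudocount) / (rb + pseudocount))


def bias_significance(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    habitat: str,
    taxon: str | None = None,
    primer_a: str = "V4",
    primer_b: str = "V5V7",
    n_perm: int = 999,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired sign-flip permutation test on per-pair log2 abundance ratios.

    Two-sided p-value for the mean per-pair log2 ratio of each taxon (or one
    taxon if given), obtained by flipping the sign of each biological pair's
    ratio.  With <= 12 pairs all 2^n sign patterns are enumerated exactly;
    otherwise ``n_perm`` random patterns are drawn and p = (b+1)/(n_perm+1).
    A ``low_power`` flag marks habitats with too few pairs to ever reach
    p < 0.05.  Benjamini-Hochberg q-values are added across taxa.
    """
    R = _paired_log_ratios(table, metadata, habitat, primer_a, primer_b, pseudocount)
    if taxon is not None:
        R = R[[taxon]]
    n_pairs = R.shape[0]
    obs = R.mean(axis=0).to_numpy()
    X = R.to_numpy()
    exhaustive = n_pairs <= 12
    if exhaustive:
        n_pat = 2**n_pairs
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n_pairs)] for k in range(n_pat)],
            dtype=float,
        )
        null = signs @ X / n_pairs  # (n_pat, taxa)
        p = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
    else:
        if n_perm < 999:
            raise ValueError("n_perm must be >= 999")
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pairs))
        null = signs @ X / n_pairs
        b = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
        p = (b + 1) / (n_perm + 1)
    low_power = 2.0 / 2**n_pairs > 0.05 if exhaustive else False
    if low_power:
        warnings.warn(
            f"only {n_pairs} pairs in habitat {habitat!r}: sign-flip test cannot reach p < 0.05",
            stacklevel=2,
        )
    from statsmodels.stats.multitest import multipletests

    q = multipletests(p, method="fdr_bh")[1] if len(p) > 1 else p.copy()
    return pd.DataFrame(
        {"mean_log2_ratio": obs, "p": p, "q": q, "low_power": low_power},
        index=R.columns,
    )


def bias_consistency(
    bias_a: pd.Series, bias_b: pd.Series, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of two bias vectors on their common taxa (Spearman default)."""
    common = bias_a.index.intersection(bias_b.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 common taxa")
    x, y = bias_a.loc[common], bias_b.loc[common]
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class SADensity:
    """Species abundance distribution on a log10 relative-abundance grid."""

    grid: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        s = self.density.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError("density must sum to 1")


def sad_log10_values(table: pd.DataFrame, taxa_subset=None) -> np.ndarray:
    """log10 mean relative abundance per taxon across the table's samples (zeros dropped)."""
    rel = relative_abundance(table)
    if taxa_subset is not None:
        cols = [t for t in taxa_subset if t in rel.columns]
        if not cols:
            raise ValueError("empty taxa subset")
        rel = rel[cols]
    m = rel.mean(axis=0).to_numpy()
    m = m[m > 0]
    if m.size == 0:
        raise ValueError("no taxa with positive abundance")
    return np.log10(m)


def sad_density(
    table: pd.DataFrame,
    taxa_subset=None,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
    n_grid: int = 256,
    label: str = "",
) -> SADensity:
    """Gaussian-kernel SAD on the log10 mean-relative-abundance axis.

    Bandwidth follows Silverman's rule unless given; the default grid spans
    the observed range +/- 3 bandwidths with ``n_grid`` points.  The density
    is renormalized to sum to 1 over the grid.
    """
    x = sad_log10_values(table, taxa_subset)
    if np.std(x) == 0:
        bw = bandwidth if bandwidth else 0.1
        if grid is None:
            grid = np.linspace(x[0] - 3 * bw, x[0] + 3 * bw, n_grid)
        dens = np.exp(-0.5 * ((grid - x[0]) / bw) ** 2)
    else:
        kde = stats.gaussian_kde(x, bw_method="silverman" if bandwidth is None else None)
        if bandwidth is not None:
            kde.set_bandwidth(bandwidth / np.std(x, ddof=1))
        bw = np.sqrt(kde.covariance[0, 0])
        if grid is None:
            grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
        dens = kde(grid)
    dens = dens / dens.sum()
    return SADensity(grid=np.asarray(grid, dtype=float), density=dens, label=label)


def sad_kld(p: SADensity, q: SADensity, epsilon: float = 1e-6) -> float:
    """Kullback-Leibler divergence D(p || q) in bits between two SADs on one grid.

    Both densities are floored at ``epsilon`` and renormalized first so the
    divergence is finite; it is >= 0 and 0 iff the floored densities match.
    """
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise ValueError("SAD grids do not match")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    pp = np.maximum(p.density, epsilon)
    qq = np.maximum(q.density, epsilon)
    pp = pp / pp.sum()
    qq = qq / qq.sum()
    return float(np.sum(pp * np.log2(pp / qq)))


def sad_pair_kld(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    taxa_subset=None,
    n_grid: int = 256,
    epsilon: float = 1e-6,
) -> float:
    """KLD between the two tables' SADs, built on one common grid."""
    xa = sad_log10_values(table_a, taxa_subset)
    xb = sad_log10_values(table_b, taxa_subset)
    lo, hi = min(xa.min(), xb.min()) - 0.5, max(xa.max(), xb.max()) + 0.5
    grid = np.linspace(lo, hi, n_grid)
    da = sad_density(table_a, taxa_subset, grid=grid)
    db = sad_density(table_b, taxa_subset, grid=grid)
    return sad_kld(da, db, epsilon=epsilon)


def restrict_shared_genera(
    table_a: pd.DataFrame, table_b: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only ASVs whose genus is detected (nonzero total) in both data sets.

    This is the first bias-attribution strategy: it removes taxa-coverage
    differences between primers while leaving efficiency differences in place.
    """
    if "genus" not in taxonomy.columns:
        raise ValueError("taxonomy lacks a genus column")

    def detected_genera(t: pd.DataFrame) -> set[str]:
        present = t.columns[t.sum(axis=0) > 0]
        return set(taxonomy.loc[list(present), "genus"])

    shared = detected_genera(table_a) & detected_genera(table_b)
    if not shared:
        raise ValueError("no genera shared between the two data sets")

    def filt(t: pd.DataFrame) -> pd.DataFrame:
        keep = [c for c in t.columns if taxonomy.loc[c, "genus"] in shared]
        return t[keep]

    return filt(table_a), filt(table_b)


def downsample(table: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    The second bias-attribution strategy: equalizing read depth in silico to
    mimic the effect of amplification-efficiency differences on detection.
    Uses the multivariate hypergeometric distribution; deterministic per seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sum(axis=1)
    if (totals < depth).any():
        bad = totals.index[totals < depth][0]
        raise ValueError(f"depth {depth} exceeds total reads of sample {bad!r}")
    rng = np.random.default_rng(seed)
    out = np.vstack(
        [
            rng.multivariate_hypergeometric(row, depth)
            for row in table.to_numpy().astype(np.int64)
        ]
    )
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def cr_collapse(
    table: pd.DataFrame, reference_map: Mapping[str, str | None]
) -> tuple[pd.DataFrame, float]:
    """Closed-reference collapse: sum counts by reference id, drop unmapped taxa.

    ``reference_map`` must cover every taxon; an explicit ``None`` marks a
    taxon absent from the reference database.  Returns the collapsed table and
    the fraction of reads discarded.
    """
    missing = [t for t in table.columns if t not in reference_map]
    if missing:
        raise ValueError(f"reference_map does not cover taxa, e.g. {missing[0]!r}")
    mapped = [t for t in table.columns if reference_map[t] is not None]
    total = float(table.to_numpy().sum())
    kept = float(table[mapped].to_numpy().sum()) if mapped else 0.0
    discarded_fraction = (total - kept) / total if total > 0 else 0.0
    if not mapped:
        warnings.warn("closed-reference collapse discarded every taxon", stacklevel=2)
        return table[[]], discarded_fraction
    refs = [reference_map[t] for t in mapped]
    out = table[mapped].T.groupby(pd.Index(refs, name="reference_id")).sum().T
    return out, discarded_fraction
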