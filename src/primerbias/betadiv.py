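"""Dissimilarity, multi-factor PERMANOVA, Mantel / Procrustes paired-configuration
tests, and Baselga-style beta-diversity partitioning.

Distance matrices are :class:`skbio.DistanceMatrix` objects keyed by sample id.
PERMANOVA here supports sequential (Type-I) sums of squares for two factors
plus their interaction on a Gower-centered distance matrix, with p-values by
free permutation of sample labels — the multi-factor design scikit-bio's
one-way implementation does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.ordination import pcoa as _skbio_pcoa


def bray_curtis(table: pd.DataFrame, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (rows), on relative abundances by default."""
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("table contains an all-zero sample")
    if normalize:
        x = x / x.sum(axis=1, keepdims=True)
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")), ids=list(table.index))


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table: one row per term plus Residual and Total."""

    table: pd.DataFrame  # columns: df, SumOfSqs, R2, F, p
    n_permutations: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Full dummy coding for a main effect or an a:b interaction term."""
    if ":" in term:
        parts = term.split(":")
        combined = metadata[parts[0]].astype(str)
        for p in parts[1:]:
            combined = combined + "\x00" + metadata[p].astype(str)
        values = combined
    else:
        values = metadata[term].astype(str)
    if values.nunique() < 2:
        raise ValueError(f"term {term!r} has a single level")
    return pd.get_dummies(values).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of X (rank-safe via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > s[0] * 1e-10).sum())
    U = U[:, :r]
    return U @ U.T


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA with sequential sums of squares and free label permutation.

    Terms are metadata column names, entered in the given order; ``a:b``
    denotes the interaction of two columns.  The distance matrix is
    Gower-centered; each term's SS is the increment in explained trace when
    its dummy columns join the design.  p = (b + 1) / (n_perm + 1) where b
    counts permuted pseudo-F values >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(dm.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    D = dm.data
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J

    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs = []
    rank_prev = 1
    for term in terms:
        X = np.hstack([X, _design_columns(meta, term)])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(H)
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        tr = np.array([float((H * Gm).sum()) for H in hats])
        ss_total = float(np.trace(Gm))
        tol = 1e-12 * max(abs(ss_total), 1.0)
        ss_terms = np.diff(tr)
        ss_res = ss_total - tr[-1]
        if abs(ss_res) < tol:  # saturated fit: identical points within groups
            ss_res = 0.0
            F = np.where(ss_terms > tol, np.inf, 0.0)
        else:
            # negative sequential SS can occur for non-Euclidean dissimilarities
            F = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = stats_for(G)
    ss_total = float(np.trace(G))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, Fp = stats_for(Gp)
        exceed += Fp >= F_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, term in enumerate(terms):
        rows.append((term, dfs[i], ss_terms[i], ss_terms[i] / ss_total, F_obs[i], pvals[i]))
    rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["term", "df", "SumOfSqs", "R2", "F", "p"]).set_index("term")
    return PermanovaResult(table=out, n_permutations=n_perm)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples."""
    if list(dm1.ids) != list(dm2.ids):
        raise ValueError("distance matrices must share ids and order")
    for d in (dm1, dm2):
        if np.ptp(d.condensed_form()) == 0:
            raise ValueError("degenerate distance matrix: constant off-diagonal")
    r, p, _ = _skbio_mantel(dm1, dm2, method=method, permutations=n_perm, seed=seed)
    return float(r), float(p)


def pcoa_coords(dm: DistanceMatrix, k: int = 2) -> np.ndarray:
    """First k principal-coordinate axes of a distance matrix (rows follow dm.ids)."""
    ord_res = _skbio_pcoa(dm, dimensions=max(k, 3))
    return ord_res.samples.to_numpy()[:, :k]


def procrustes_test(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Procrustes m^2 between two paired configurations with a PROTEST permutation p.

    m^2 is the residual sum of squares after optimal translation, rotation and
    scaling, normalized to [0, 1]; it is invariant to similarity transforms of
    either configuration.  The null permutes the row correspondence of the
    second configuration.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("coordinate dimension must be >= 2")
    _, _, m2 = _scipy_procrustes(A, B)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        _, _, m2p = _scipy_procrustes(A, B[perm])
        if m2p <= m2 + 1e-12:
            b += 1
    return float(m2), (b + 1) / (n_perm + 1)


def beta_partition(table: pd.DataFrame, family: str = "sorensen") -> tuple[pd.DataFrame, dict]:
    """Pairwise beta-diversity partition into turnover and nestedness components.

    ``family='sorensen'`` uses incidence: total Sorensen dissimilarity =
    Simpson turnover + nestedness-resultant fraction.  ``family='bray'`` uses
    the abundance analogue: Bray-Curtis = balanced variation + abundance
    gradient.  Components are non-negative and sum to the total.  Returns the
    per-pair table and multi-site means over pairs.
    """
    x = table.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("table contains an empty sample")
    ids = list(table.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if family == "sorensen":
                pa_i, pa_j = x[i] > 0, x[j] > 0
                a = float(np.sum(pa_i & pa_j))
                b = float(np.sum(pa_i & ~pa_j))
                c = float(np.sum(~pa_i & pa_j))
                total = (b + c) / (2 * a + b + c)
                mn = min(b, c)
                turnover = mn / (a + mn) if (a + mn) > 0 else 0.0
            elif family == "bray":
                mins = np.minimum(x[i], x[j])
                Acomp = float(mins.sum())
                Bcomp = float((x[i] - mins).sum())
                Ccomp = float((x[j] - mins).sum())
                total = (Bcomp + Ccomp) / (2 * Acomp + Bcomp + Ccomp)
                mn = min(Bcomp, Ccomp)
                turnover = mn / (Acomp + mn) if (Acomp + mn) > 0 else 0.0
            else:
                raise ValueError(f"unknown family {family!r}")
            nestedness = total - turnover
            rows.append((ids[i], ids[j], total, turnover, nestedness, 1.0 - total))
    out = pd.DataFrame(
        rows,
        columns=["sample_i", "sample_j", "total", "turnover", "nestedness", "similarity"],
    )
    means = {
        "total": float(out["total"].mean()),
        "turnover": float(out["turnover"].mean()),
        "nestedness": float(out["nestedness"].mean()),
        "similarity": float(out["similarity"].mean()),
    }
    return out, means
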