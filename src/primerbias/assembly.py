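"""Community-assembly inference.

Implements the null-model toolkit used to ask whether community turnover is
driven by deterministic selection or stochastic processes:

* abundance-weighted beta mean-nearest-taxon distance (betaMNTD) and its
  z-score betaNTI against a tip-shuffle null — |betaNTI| > 1.96 signals
  phylogenetically structured selection;
* the abundance-based Raup-Crick index on Bray-Curtis (RCI in [-1, 1])
  against a richness- and depth-preserving null;
* Stegen-style partitioning of sample pairs into assembly processes from the
  joint (betaNTI, RCI) thresholds;
* a normalized stochasticity ratio (NST) per sample group;
* Sloan's neutral community model fit (migration rate m, fit R-squared) with
  per-taxon neutral / above / below classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

SELECTION_THRESHOLD = 1.96
DISPERSAL_THRESHOLD = 0.95

PROCESS_LABELS = (
    "homogeneous selection",
    "heterogeneous selection",
    "homogenizing dispersal",
    "dispersal limitation",
    "undominated",
    "undetermined",
)


def patristic_matrix(tree: dendropy.Tree, taxon_ids: list[str]) -> np.ndarray:
    """Dense tip-to-tip patristic distance matrix ordered by taxon_ids.

    Single post-order pass; at each internal node the distances between tips
    of different child subtrees are the sums of their distances to the node.
    Tree tips absent from ``taxon_ids`` are ignored; a requested taxon missing
    from the tree is an error.
    """
    idx = {t: i for i, t in enumerate(taxon_ids)}
    n = len(taxon_ids)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxon {missing[0]!r} not a tip of the tree")
    D = np.zeros((n, n))
    store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in idx:
                store[id(node)] = (np.array([idx[label]]), np.array([0.0]))
            else:
                store[id(node)] = (np.array([], dtype=int), np.array([]))
        else:
            tips_list, dist_list = [], []
            for child in node.child_nodes():
                t, d = store.pop(id(child))
                d = d + (child.edge.length or 0.0)
                for t2, d2 in zip(tips_list, dist_list):
                    cross = d[:, None] + d2[None, :]
                    D[np.ix_(t, t2)] = cross
                    D[np.ix_(t2, t)] = cross.T
                tips_list.append(t)
                dist_list.append(d)
            store[id(node)] = (np.concatenate(tips_list), np.concatenate(dist_list))
    return D


def _bmntd_from_distance(P: np.ndarray, presence: np.ndarray, D: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given relative abundances and a taxon distance matrix."""
    S = P.shape[0]
    M = np.empty((D.shape[0], S))
    for s in range(S):
        M[:, s] = D[:, presence[s]].min(axis=1)
    PM = P @ M  # PM[x, y] = sum_i p_xi * min_{j in y} d_ij
    return 0.5 * (PM + PM.T)


def beta_mntd(
    table: pd.DataFrame,
    tree: dendropy.Tree | np.ndarray,
    weighted: bool = True,
) -> pd.DataFrame:
    """Between-sample mean nearest-taxon phylogenetic distance (abundance-weighted).

    For samples x, y: 0.5 * [ sum_i p_xi min_{j in y} d_ij +
    sum_j p_yj min_{i in x} d_ij ] with d the patristic distance; a taxon
    shared by both samples has nearest-taxon distance 0.
    """
    taxa = [t for t in table.columns if table[t].sum() > 0]
    sub = table[taxa]
    D = tree if isinstance(tree, np.ndarray) else patristic_matrix(tree, taxa)
    if D.shape != (len(taxa), len(taxa)):
        raise ValueError("distance matrix does not match nonzero taxa")
    x = sub.to_numpy(dtype=float)
    presence = x > 0
    if (~presence.any(axis=1)).any():
        raise ValueError("sample with no taxa on the tree")
    if weighted:
        P = x / x.sum(axis=1, keepdims=True)
    else:
        P = presence / presence.sum(axis=1, keepdims=True)
    B = _bmntd_from_distance(P, presence, D)
    np.fill_diagonal(B, 0.0)
    return pd.DataFrame(B, index=table.index, columns=table.index)


def bnti(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI: z-score of observed betaMNTD against a regional tip-shuffle null.

    The null permutes taxon labels across all tree tips (equivalently,
    permutes rows/columns of the patristic matrix) and recomputes betaMNTD;
    z = (obs - mean_null) / sd_null per sample pair.  Pairs whose null has
    zero spread (e.g. a star tree) are returned as NaN, never +-inf.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    taxa = [t for t in table.columns if table[t].sum() > 0]
    sub = table[taxa]
    D = patristic_matrix(tree, taxa)
    x = sub.to_numpy(dtype=float)
    presence = x > 0
    P = (
        x / x.sum(axis=1, keepdims=True)
        if weighted
        else presence / presence.sum(axis=1, keepdims=True)
    )
    obs = _bmntd_from_distance(P, presence, D)
    rng = np.random.default_rng(seed)
    n = len(taxa)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n)
        Bn = _bmntd_from_distance(P, presence, D[np.ix_(perm, perm)])
        acc += Bn
        acc2 += Bn**2
    mean = acc / n_null
    var = (acc2 - n_null * mean**2) / (n_null - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.index, columns=table.index)


def _pp_null_counts(
    counts: np.ndarray, rng: np.random.Generator,
    occupancy: np.ndarray, regional: np.ndarray,
) -> np.ndarray:
    """One 'proportional-proportional' null table preserving each sample's
    richness and read total: taxa drawn with probability proportional to
    occupancy, reads filled proportional to regional relative abundance."""
    S, T = counts.shape
    null = np.zeros((S, T), dtype=np.int64)
    p_occ = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    for s in range(S):
        chosen = rng.choice(T, size=richness[s], replace=False, p=p_occ)
        null[s, chosen] = 1  # guarantee presence
        remaining = totals[s] - richness[s]
        if remaining > 0:
            w = regional[chosen]
            if w.sum() <= 0:
                w = np.ones_like(w)
            null[s, chosen] += rng.multinomial(remaining, w / w.sum())
    return null


def raup_crick_bray(
    table: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
    occupancy: np.ndarray | None = None,
    regional: np.ndarray | None = None,
) -> pd.DataFrame:
    """Abundance-based Raup-Crick index (RC-bray) in [-1, 1] for all sample pairs.

    RCI compares the observed Bray-Curtis of a pair with its distribution
    under the proportional-proportional null:
    RCI = 2 * [#(null < obs) + 0.5 * #(ties)] / n_null - 1.
    Values near +1 mean communities are less similar than expected by chance
    (dispersal limitation); near -1, more similar (homogenizing dispersal).

    The null's taxon-selection weights (``occupancy``) and read-fill weights
    (``regional``) default to the table's own occupancy and pooled relative
    abundances, but can be supplied from a larger reference community (e.g.
    the whole survey when scoring one habitat's pairs).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    counts = table.to_numpy(dtype=np.int64)
    if occupancy is None:
        occupancy = (counts > 0).mean(axis=0)
    if regional is None:
        regional = counts.sum(axis=0).astype(float)
    regional = np.asarray(regional, dtype=float)
    regional = regional / regional.sum()
    rel = counts / counts.sum(axis=1, keepdims=True)
    obs = pdist(rel, metric="braycurtis")
    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs)
    ties = np.zeros_like(obs)
    for _ in range(n_null):
        null = _pp_null_counts(counts, rng, occupancy, regional)
        nrel = null / null.sum(axis=1, keepdims=True)
        d = pdist(nrel, metric="braycurtis")
        eq = np.isclose(d, obs, rtol=1e-12, atol=1e-12)
        less += (d < obs) & ~eq
        ties += eq
    rci = 2.0 * (less + 0.5 * ties) / n_null - 1.0
    rci = np.clip(rci, -1.0, 1.0)
    out = np.zeros((len(table), len(table)))
    iu = np.triu_indices(len(table), k=1)
    out[iu] = rci
    out = out + out.T
    return pd.DataFrame(out, index=table.index, columns=table.index)


def partition_processes(
    bnti_value: float,
    rci_value: float,
    selection_threshold: float = SELECTION_THRESHOLD,
    dispersal_threshold: float = DISPERSAL_THRESHOLD,
    rc_convention: str = "stegen",
) -> str:
    """Assembly-process label for one sample pair from its betaNTI and RCI.

    betaNTI < -1.96 -> homogeneous selection; > 1.96 -> heterogeneous
    selection.  Otherwise RCI decides: under the standard ("stegen")
    convention RCI > 0.95 -> dispersal limitation and RCI < -0.95 ->
    homogenizing dispersal ("inverted" swaps the two); |RCI| < 0.95 ->
    undominated.  A NaN betaNTI yields "undetermined".
    """
    if rc_convention not in ("stegen", "inverted"):
        raise ValueError("rc_convention must be 'stegen' or 'inverted'")
    if not np.isfinite(bnti_value):
        return "undetermined"
    if bnti_value < -selection_threshold:
        return "homogeneous selection"
    if bnti_value > selection_threshold:
        return "heterogeneous selection"
    if not np.isfinite(rci_value):
        return "undetermined"
    high, low = ("dispersal limitation", "homogenizing dispersal")
    if rc_convention == "inverted":
        high, low = low, high
    if rci_value > dispersal_threshold:
        return high
    if rci_value < -dispersal_threshold:
        return low
    return "undominated"


def process_fractions(labels: list[str] | pd.Series) -> pd.Series:
    """Fraction of sample pairs assigned to each assembly process.

    The largest fraction absorbs the float-division residual so the fractions
    sum to 1 exactly.
    """
    s = pd.Series(labels)
    if s.empty:
        raise ValueError("no pair labels")
    counts = s.value_counts().reindex(PROCESS_LABELS, fill_value=0)
    frac = counts.astype(float) / float(len(s))
    frac.iloc[int(np.argmax(frac.to_numpy()))] += 1.0 - frac.sum()
    return frac


def pairwise_metrics(
    bnti_df: pd.DataFrame, rci_df: pd.DataFrame, rc_convention: str = "stegen"
) -> pd.DataFrame:
    """Long-format per-pair table of betaNTI, RCI and assembly-process label."""
    ids = list(bnti_df.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            bz = float(bnti_df.iloc[i, j])
            rc = float(rci_df.iloc[i, j])
            rows.append(
                (ids[i], ids[j], bz, rc, partition_processes(bz, rc, rc_convention=rc_convention))
            )
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "bnti", "rci", "process"])


def nst(
    table: pd.DataFrame,
    groups: pd.Series,
    dissimilarity: str = "bray",
    n_null: int = 999,
    seed: int | None = None,
) -> pd.Series:
    """Normalized stochasticity ratio per sample group, in [0, 1].

    For each within-group sample pair the observed dissimilarity D is compared
    with its expectation E under the proportional-proportional null.  The
    per-pair ratio is D/E when D < E and (1-D)/(1-E) when D > E, so a pair at
    its null expectation scores 1 (pure stochasticity) and a pair at either
    deterministic extreme (D = 0: selection toward similarity; D = 1:
    selection toward divergence) scores 0; 0.5 is the halfway boundary.  The
    group value is the mean over its pairs.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    rng = np.random.default_rng(seed)
    out = {}
    for g in pd.unique(groups):
        ids = groups.index[groups == g]
        if len(ids) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        sub = table.loc[ids]
        counts = sub.to_numpy(dtype=np.int64)
        if dissimilarity == "bray":
            rel = counts / counts.sum(axis=1, keepdims=True)
            obs = pdist(rel, metric="braycurtis")
        elif dissimilarity == "jaccard":
            obs = pdist(counts > 0, metric="jaccard")
        else:
            raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
        occupancy = (counts > 0).mean(axis=0)
        regional = counts.sum(axis=0).astype(float)
        regional = regional / regional.sum()
        acc = np.zeros_like(obs)
        for _ in range(n_null):
            null = _pp_null_counts(counts, rng, occupancy, regional)
            if dissimilarity == "bray":
                nrel = null / null.sum(axis=1, keepdims=True)
                acc += pdist(nrel, metric="braycurtis")
            else:
                acc += pdist(null > 0, metric="jaccard")
        E = acc / n_null
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(
                obs < E,
                np.divide(obs, E, out=np.ones_like(obs), where=E > 0),
                np.divide(1 - obs, 1 - E, out=np.zeros_like(obs), where=E < 1),
            )
        out[g] = float(np.clip(ratio, 0.0, 1.0).mean())
    return pd.Series(out, name="nst")


@dataclass
class NeutralFit:
    """Sloan neutral-model fit: migration rate m, fit R2, community size N,
    detection limit, and per-taxon statistics (metacommunity p, observed and
    predicted occurrence frequency, Wilson 95% band, neutrality class)."""

    m: float
    r2: float
    N: float
    detection_limit: float
    stats: pd.DataFrame
    at_bound: bool = False

    @property
    def class_fractions(self) -> pd.Series:
        return self.stats["klass"].value_counts(normalize=True).reindex(
            ["neutral", "above", "below"], fill_value=0.0
        )


def _sloan_freq(p: np.ndarray, m: float, N: float, d: float) -> np.ndarray:
    return stats.beta.sf(d, N * m * p, N * m * (1 - p))


def _wilson_band(pred: np.ndarray, n_samples: int, z: float = 1.96):
    pred = np.clip(pred, 0.0, 1.0)
    denom = 1 + z**2 / n_samples
    center = (pred + z**2 / (2 * n_samples)) / denom
    half = z * np.sqrt(pred * (1 - pred) / n_samples + z**2 / (4 * n_samples**2)) / denom
    return center - half, center + half


def classify_neutral(
    observed_freq: np.ndarray,
    predicted_freq: np.ndarray,
    n_samples: int,
    z: float = 1.96,
) -> np.ndarray:
    """Per-taxon class from a Wilson 95% binomial band around the prediction:
    'above' if observed frequency exceeds the upper limit, 'below' if under
    the lower limit, else 'neutral'."""
    lower, upper = _wilson_band(predicted_freq, n_samples, z)
    return np.where(
        observed_freq > upper, "above", np.where(observed_freq < lower, "below", "neutral")
    )


def sloan_fit(table: pd.DataFrame, detection_limit: float | None = None) -> NeutralFit:
    """Fit Sloan's neutral community model to occurrence frequencies.

    A taxon with metacommunity relative abundance p is predicted to occur in a
    fraction 1 - BetaCDF(d; N m p, N m (1-p)) of local communities, with N
    the (mean) community size, m the migration rate and d the detection limit.
    m is fitted by bounded least squares of observed vs predicted frequency;
    R2 = 1 - SSres/SStot may be negative for strongly non-neutral data.

    The default detection limit is ln(2)/N: under depth-N multinomial
    sampling a taxon at relative abundance x is detected with probability
    1 - (1-x)^N, which crosses 1/2 at x = ln(2)/N, so that abundance is where
    the sharp-threshold model best matches discrete read sampling (the naive
    1/N threshold systematically overestimates m on count data).
    """
    counts = table.to_numpy(dtype=float)
    n_samples = counts.shape[0]
    rel = counts / counts.sum(axis=1, keepdims=True)
    p = rel.mean(axis=0)
    keep = p > 0
    if keep.sum() < 10:
        raise ValueError("need at least 10 taxa with nonzero mean abundance")
    p = p[keep]
    freq = (counts[:, keep] > 0).mean(axis=0)
    N = float(counts.sum(axis=1).mean())
    d = detection_limit if detection_limit is not None else np.log(2.0) / N

    def sse(m: float) -> float:
        return float(np.sum((freq - _sloan_freq(p, m, N, d)) ** 2))

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    m_hat = float(res.x)
    at_bound = m_hat < 2e-6 or m_hat > 1 - 1e-6
    pred = _sloan_freq(p, m_hat, N, d)
    ss_res = float(np.sum((freq - pred) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    klass = classify_neutral(freq, pred, n_samples)
    lower, upper = _wilson_band(pred, n_samples)
    st = pd.DataFrame(
        {"p": p, "freq": freq, "pred": pred, "lower": lower, "upper": upper, "klass": klass},
        index=table.columns[keep],
    )
    return NeutralFit(
        m=m_hat, r2=r2, N=N, detection_limit=d, stats=st, at_bound=at_bound
    )
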