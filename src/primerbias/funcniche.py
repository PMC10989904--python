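"""Function-profile aggregation, function-level primer bias, functional
redundancy, and community niche metrics (Levins breadth Bcom, Pianka overlap
Ocom).

The taxon -> function map is a two-column DataFrame (taxon_id, function), one
row per assignment; a taxon may carry several functions and counts fully
toward each.  Taxa with no assignment are collected in an explicit
"unassigned" bucket so function profiles sum to 1 per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiling import DEFAULT_PSEUDOCOUNT, relative_abundance

UNASSIGNED = "unassigned"


def aggregate_functions(table: pd.DataFrame, function_map: pd.DataFrame) -> pd.DataFrame:
    """Sample x function relative-abundance table from a taxon -> function map.

    Each function's abundance is the summed relative abundance of its member
    taxa; a multi-function taxon contributes its full abundance to every one
    of its functions, so rows need not sum to 1 across assigned functions —
    the "unassigned" column makes relative abundance of unmapped taxa explicit.
    """
    rel = relative_abundance(table)
    fmap = function_map[function_map["taxon_id"].isin(rel.columns)]
    functions = sorted(fmap["function"].unique())
    out = pd.DataFrame(0.0, index=rel.index, columns=functions + [UNASSIGNED])
    for fn, grp in fmap.groupby("function"):
        out[fn] = rel[grp["taxon_id"].unique()].sum(axis=1)
    mapped_taxa = fmap["taxon_id"].unique()
    unmapped = [t for t in rel.columns if t not in set(mapped_taxa)]
    out[UNASSIGNED] = rel[unmapped].sum(axis=1) if unmapped else 0.0
    return out


def function_bias(
    ftable: pd.DataFrame,
    metadata: pd.DataFrame,
    habitat: str,
    primer_a: str = "V4",
    primer_b: str = "V5V7",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-function log2 bias (A over B) with Welch t-test p and BH q-values.

    Zero-variance-in-both-groups functions get p = 1 and a degenerate flag.
    """
    sub = metadata[metadata["habitat"] == habitat]
    ia = sub.index[sub["primer"] == primer_a]
    ib = sub.index[sub["primer"] == primer_b]
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("need at least 3 samples per primer group")
    A = ftable.loc[ia]
    B = ftable.loc[ib]
    bias = np.log2((A.mean(axis=0) + pseudocount) / (B.mean(axis=0) + pseudocount))
    pvals, tvals, degenerate = [], [], []
    for fn in ftable.columns:
        x, y = A[fn].to_numpy(), B[fn].to_numpy()
        if np.var(x) == 0 and np.var(y) == 0:
            tvals.append(0.0)
            pvals.append(1.0)
            degenerate.append(True)
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        tvals.append(float(t))
        pvals.append(float(p))
        degenerate.append(False)
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2_bias": bias, "t": tvals, "p": pvals, "q": q, "degenerate": degenerate}
    )


def _function_sets(function_map: pd.DataFrame) -> dict[str, frozenset]:
    return {
        t: frozenset(grp["function"]) for t, grp in function_map.groupby("taxon_id")
    }


def functional_redundancy(
    abundances: pd.Series, function_map: pd.DataFrame, method: str = "jaccard"
) -> float:
    """Functional redundancy of one community, in [0, 1].

    Default: abundance-weighted mean pairwise Jaccard similarity of taxon
    function sets, FR = sum_{i != k} p_i p_k s_ik / sum_{i != k} p_i p_k.
    ``method='rao'`` returns the 1 - FD/TD form, where FD is Rao's quadratic
    functional dissimilarity and TD = Simpson diversity; identical function
    sets give 1 under either form, fully disjoint sets give 0 under 'jaccard'.
    """
    sets = _function_sets(function_map)
    mapped = [t for t in abundances.index if t in sets and abundances[t] > 0]
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped taxa with positive abundance")
    p = abundances[mapped].to_numpy(dtype=float)
    p = p / p.sum()
    fns = sorted({f for t in mapped for f in sets[t]})
    M = np.array([[1.0 if f in sets[t] else 0.0 for f in fns] for t in mapped])
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    W = np.outer(p, p)
    np.fill_diagonal(W, 0.0)
    if method == "jaccard":
        return float((W * sim).sum() / W.sum())
    if method == "rao":
        dis = 1.0 - sim
        fd = float((W * dis).sum())
        td = float(W.sum())  # Simpson diversity: 1 - sum p_i^2
        return 1.0 - fd / td
    raise ValueError(f"unknown method {method!r}")


@dataclass
class NicheMetrics:
    """Per-taxon Levins breadth, community-weighted Bcom, mean pairwise Pianka
    overlap Ocom, and the number of resource states H (so 1 <= B_i <= H)."""

    breadth: pd.Series
    bcom: float
    ocom: float
    n_states: int


def niche_metrics(table: pd.DataFrame, states: pd.Series) -> NicheMetrics:
    """Levins niche breadth and Pianka overlap over resource states.

    ``states`` maps each sample to a resource state (habitats by default in
    the pipeline).  q_ih is the share of taxon i's summed abundance found in
    state h; B_i = 1 / sum_h q_ih^2; Bcom is the regional-abundance-weighted
    mean of B_i.  O_ik is Pianka's overlap of the q-profiles and Ocom its
    abundance-weighted mean over taxon pairs.
    """
    states = states.loc[table.index]
    uniq = list(pd.unique(states))
    if len(uniq) < 2:
        raise ValueError("need at least 2 resource states")
    totals = table.groupby(states.values).sum()  # state x taxon
    col_tot = totals.sum(axis=0)
    taxa = col_tot.index[col_tot > 0]
    if len(taxa) == 0:
        raise ValueError("no taxon with positive total abundance")
    Q = (totals[taxa] / col_tot[taxa]).to_numpy().T  # taxon x state
    B = 1.0 / (Q**2).sum(axis=1)
    w = col_tot[taxa].to_numpy(dtype=float)
    w = w / w.sum()
    bcom = float((w * B).sum())
    norm = np.sqrt((Q**2).sum(axis=1))
    O = (Q @ Q.T) / np.outer(norm, norm)
    W = np.outer(w, w)
    np.fill_diagonal(W, 0.0)
    ocom = float((W * O).sum() / W.sum())
    return NicheMetrics(
        breadth=pd.Series(B, index=taxa, name="levins_breadth"),
        bcom=bcom,
        ocom=ocom,
        n_states=len(uniq),
    )
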