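"""Synthetic multi-habitat communities observed through parameterized primer lenses.

The generator produces a latent "truth" (regional taxon pool, per-habitat
community profiles, a phylogeny, taxonomy, a taxon->function map and a mock
reference-database membership) and then observes it through one or more
:class:`PrimerProfile` objects.  A primer profile distorts the truth through
three mechanisms: a binary taxon coverage mask (taxa the primer cannot
amplify), per-taxon multiplicative amplification-efficiency factors, and an
optional resolution merge that lumps fine taxa into coarser units.  These are
the levers every downstream bias analysis is exercised against.

The default study design mirrors a paired two-primer survey of five habitats
(water 36, sediment 7, soil 79, leaf 40, gut 12 biological samples), each
sample observed once per primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

#: habitat -> number of biological samples in the emulated survey design
DEFAULT_HABITATS: dict[str, int] = {
    "water": 36,
    "sediment": 7,
    "soil": 79,
    "leaf": 40,
    "gut": 12,
}

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class SyntheticTruth:
    """Latent community truth that no primer observes directly.

    ``habitat_profiles`` maps each habitat to a relative-abundance vector over
    ``taxon_ids`` (each sums to 1).  ``pairs`` records the survey design: one
    row per biological sample (pair_id, habitat); every pair is observed once
    under each primer.
    """

    taxon_ids: list[str]
    regional_pool: np.ndarray
    habitat_profiles: dict[str, np.ndarray]
    tree: dendropy.Tree
    taxonomy: pd.DataFrame
    function_map: pd.DataFrame
    reference_members: set[str]
    pairs: pd.DataFrame

    def validate(self) -> None:
        assert abs(self.regional_pool.sum() - 1.0) < 1e-9
        for v in self.habitat_profiles.values():
            assert abs(v.sum() - 1.0) < 1e-9
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        assert tips == set(self.taxon_ids)
        assert self.reference_members <= set(self.taxon_ids)


@dataclass
class PrimerProfile:
    """Observation model for one primer set.

    ``coverage`` is a 0/1 detection mask over the truth's taxa; ``efficiency``
    holds strictly positive amplification factors, either one shared vector
    (the default: bias consistent across habitats) or one vector per habitat.
    ``resolution_merge`` optionally lumps taxa into coarser units (taxon ->
    unit name).
    """

    name: str
    coverage: np.ndarray
    efficiency: np.ndarray | dict[str, np.ndarray]
    resolution_merge: dict[str, str] | None = None

    def efficiency_for(self, habitat: str) -> np.ndarray:
        if isinstance(self.efficiency, dict):
            return self.efficiency[habitat]
        return self.efficiency

    def validate(self) -> None:
        effs = (
            self.efficiency.values()
            if isinstance(self.efficiency, dict)
            else [self.efficiency]
        )
        cov = self.coverage.astype(bool)
        for e in effs:
            if np.any(e[cov] <= 0):
                raise ValueError("efficiency must be strictly positive for covered taxa")


def _spawn(seed: int | np.random.SeedSequence | None, n: int) -> list[np.random.Generator]:
    """Split one root seed into independent, documented child streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_tree(
    taxon_ids: Sequence[str], rng: np.random.Generator, birth_rate: float = 1.0
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times; all branch lengths > 0."""
    n = len(taxon_ids)
    if n < 2:
        raise ValueError("need at least 2 taxa for a tree")
    ns = dendropy.TaxonNamespace([str(t) for t in taxon_ids])
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    active: list[dendropy.Node] = []
    birth: dict[int, float] = {}
    t = 0.0
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append(ch)
        birth[id(ch)] = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            active.append(ch)
            birth[id(ch)] = t
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(n)
    for node, k in zip(active, order):
        node.edge.length = t_end - birth[id(node)]
        node.taxon = ns.get_taxon(str(taxon_ids[int(k)]))
    tree.is_rooted = True
    return tree


def _contiguous_blocks(n_items: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Assign n_items (ordered) to n_blocks contiguous non-empty groups; returns group index per item."""
    n_blocks = max(1, min(n_blocks, n_items))
    if n_blocks == 1:
        return np.zeros(n_items, dtype=int)
    cuts = np.sort(rng.choice(np.arange(1, n_items), size=n_blocks - 1, replace=False))
    return np.searchsorted(cuts, np.arange(n_items), side="right")


def _make_taxonomy(
    taxon_ids: Sequence[str], tree: dendropy.Tree, rng: np.random.Generator
) -> pd.DataFrame:
    """Nested rank labels, contiguous along the tree's leaf order so ranks follow clades."""
    leaf_order = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(leaf_order)
    targets = {"phylum": 8, "class": 16, "order": 32, "family": 64, "genus": max(2, n // 5)}
    tax = pd.DataFrame(index=pd.Index(leaf_order, name="taxon_id"), columns=RANKS, dtype=object)
    tax["kingdom"] = "Bacteria"
    parent = np.zeros(n, dtype=int)
    counter = {}
    prefix = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}
    for rank in ["phylum", "class", "order", "family", "genus"]:
        total = min(targets[rank], n)
        labels = np.empty(n, dtype=object)
        new_parent = np.zeros(n, dtype=int)
        next_id = 0
        for grp in np.unique(parent):
            mask = parent == grp
            size = int(mask.sum())
            k = max(1, int(round(total * size / n)))
            sub = _contiguous_blocks(size, k, rng)
            ids = sub + next_id
            next_id += sub.max() + 1
            new_parent[mask] = ids
        for i, gid in enumerate(new_parent):
            labels[i] = f"{prefix[rank]}{gid + 1:03d}"
        tax[rank] = labels
        parent = new_parent
        counter[rank] = next_id
    tax["species"] = [f"s_{t}" for t in leaf_order]
    return tax.loc[list(taxon_ids)]


def _make_function_map(
    taxonomy: pd.DataFrame,
    rng: np.random.Generator,
    n_functions: int = 20,
    unmapped_genus_fraction: float = 0.15,
) -> pd.DataFrame:
    """Mock taxonomy-to-function annotation: functions assigned per genus, inherited by taxa."""
    functions = [f"fn{k + 1:02d}" for k in range(n_functions)]
    genera = taxonomy["genus"].unique()
    rows: list[tuple[str, str]] = []
    genus_funcs: dict[str, list[str]] = {}
    for g in genera:
        if rng.random() < unmapped_genus_fraction:
            genus_funcs[g] = []
            continue
        k = 1 + int(rng.integers(3))
        genus_funcs[g] = list(rng.choice(functions, size=min(k, n_functions), replace=False))
    for taxon, g in taxonomy["genus"].items():
        for fn in genus_funcs[g]:
            rows.append((taxon, fn))
    return pd.DataFrame(rows, columns=["taxon_id", "function"])


def choose_reference_members(
    taxon_ids: Sequence[str],
    weights: np.ndarray,
    target_unmapped_fraction: float,
    rng: np.random.Generator,
) -> set[str]:
    """Pick reference-database members so unmapped taxa hold ~target fraction of reads.

    Taxa are visited in random order and added to the unmapped set greedily
    whenever their expected read share still fits under the target, so the
    unmapped share lands just below it (within the smallest taxon weight).
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    order = rng.permutation(len(taxon_ids))
    unmapped: set[str] = set()
    acc = 0.0
    for i in order:
        if acc + w[i] <= target_unmapped_fraction:
            unmapped.add(taxon_ids[i])
            acc += w[i]
    return set(taxon_ids) - unmapped


def _clade_indicator(tree: dendropy.Tree, taxon_index: Mapping[str, int],
                     rng: np.random.Generator, lo: float = 0.15, hi: float = 0.4) -> np.ndarray:
    """0/1 vector over taxa marking a random clade holding 15-40% of tips."""
    n = len(taxon_index)
    candidates = []
    for node in tree.preorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if lo * n <= len(tips) <= hi * n:
            candidates.append(tips)
    ind = np.zeros(n)
    if not candidates:  # fall back to a random taxon block
        size = int(lo * n) + 1
        ind[rng.choice(n, size=size, replace=False)] = 1.0
        return ind
    tips = candidates[int(rng.integers(len(candidates)))]
    for t in tips:
        ind[taxon_index[t]] = 1.0
    return ind


def simulate_truth(
    n_taxa: int = 300,
    habitats: Mapping[str, int] | None = None,
    lognormal_sigma: float = 1.5,
    habitat_specialization: float = 0.3,
    phylo_filtering: float = 0.0,
    reference_unmapped_fraction: float = 0.26,
    seed: int | None = None,
) -> SyntheticTruth:
    """Simulate the latent truth for a multi-habitat survey.

    Parameters
    ----------
    n_taxa
        Size of the regional species pool (>= 2).
    habitats
        Mapping habitat -> number of biological samples; defaults to the
        emulated survey design (water 36, sediment 7, soil 79, leaf 40, gut 12
        = 176 pairs).
    lognormal_sigma
        Log-normal shape of the abundance distributions (> 0).
    habitat_specialization
        Mixing weight s in [0, 1]: habitat profile = (1-s) * regional pool +
        s * habitat-specific draw, renormalized.  s = 0 makes every habitat
        identical to the pool.
    phylo_filtering
        In [0, 1]; fraction of each habitat-specific component concentrated in
        one random clade, emulating phylogenetically conserved habitat
        filtering (raises within-habitat phylogenetic clustering).
    reference_unmapped_fraction
        Expected read share of taxa absent from the mock closed-reference
        database.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if lognormal_sigma <= 0:
        raise ValueError("lognormal_sigma must be > 0")
    if not 0 <= habitat_specialization <= 1:
        raise ValueError("habitat_specialization must be in [0, 1]")
    if not 0 <= phylo_filtering <= 1:
        raise ValueError("phylo_filtering must be in [0, 1]")
    habitats = dict(habitats) if habitats is not None else dict(DEFAULT_HABITATS)
    for h, k in habitats.items():
        if k < 2:
            raise ValueError(f"samples_per_habitat must be >= 2 (habitat {h!r})")

    rng_pool, rng_tree, rng_hab, rng_tax, rng_fun, rng_ref = _spawn(seed, 6)
    taxon_ids = [f"t{i + 1:04d}" for i in range(n_taxa)]
    pool = rng_pool.lognormal(0.0, lognormal_sigma, n_taxa)
    pool /= pool.sum()

    tree = simulate_tree(taxon_ids, rng_tree)
    taxon_index = {t: i for i, t in enumerate(taxon_ids)}

    profiles: dict[str, np.ndarray] = {}
    for h in habitats:
        draw = rng_hab.lognormal(0.0, lognormal_sigma, n_taxa)
        draw /= draw.sum()
        if phylo_filtering > 0:
            clade = _clade_indicator(tree, taxon_index, rng_hab)
            inclade = draw * clade
            if inclade.sum() > 0:
                draw = (1 - phylo_filtering) * draw + phylo_filtering * inclade / inclade.sum()
        prof = (1 - habitat_specialization) * pool + habitat_specialization * draw
        profiles[h] = prof / prof.sum()

    taxonomy = _make_taxonomy(taxon_ids, tree, rng_tax)
    function_map = _make_function_map(taxonomy, rng_fun)

    # weight reference membership by the design-averaged community profile
    n_total = sum(habitats.values())
    mean_profile = sum(profiles[h] * k for h, k in habitats.items()) / n_total
    reference_members = choose_reference_members(
        taxon_ids, mean_profile, reference_unmapped_fraction, rng_ref
    )

    pair_rows = []
    i = 0
    for h, k in habitats.items():
        for _ in range(k):
            i += 1
            pair_rows.append((f"pair{i:03d}", h))
    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "habitat"])

    truth = SyntheticTruth(
        taxon_ids=taxon_ids,
        regional_pool=pool,
        habitat_profiles=profiles,
        tree=tree,
        taxonomy=taxonomy,
        function_map=function_map,
        reference_members=reference_members,
        pairs=pairs,
    )
    truth.validate()
    return truth


def make_primer_profile(
    truth: SyntheticTruth,
    name: str,
    coverage_fraction: float = 1.0,
    efficiency_sigma: float = 0.0,
    shared_efficiency: bool = True,
    coverage_by: str = "taxon",
    seed: int | None = None,
) -> PrimerProfile:
    """Draw a primer lens for the truth's taxa.

    ``coverage_fraction`` is the fraction of taxa (or genera with
    ``coverage_by='genus'``) the primer detects; efficiency factors are
    log-normal with the given sigma, one shared vector by default or one
    independent draw per habitat with ``shared_efficiency=False``.
    """
    rng_cov, rng_eff = _spawn(seed, 2)
    n = len(truth.taxon_ids)
    coverage = np.ones(n)
    if coverage_fraction < 1.0:
        if coverage_by == "genus":
            genera = truth.taxonomy["genus"]
            uniq = genera.unique()
            n_drop = int(round((1 - coverage_fraction) * len(uniq)))
            dropped = set(rng_cov.choice(uniq, size=n_drop, replace=False))
            coverage = (~genera.isin(dropped)).to_numpy().astype(float)
        else:
            n_drop = int(round((1 - coverage_fraction) * n))
            coverage[rng_cov.choice(n, size=n_drop, replace=False)] = 0.0
    if efficiency_sigma > 0:
        if shared_efficiency:
            eff: np.ndarray | dict[str, np.ndarray] = rng_eff.lognormal(0.0, efficiency_sigma, n)
        else:
            eff = {
                h: rng_eff.lognormal(0.0, efficiency_sigma, n)
                for h in truth.habitat_profiles
            }
    else:
        eff = np.ones(n)
    profile = PrimerProfile(name=name, coverage=coverage, efficiency=eff)
    profile.validate()
    return profile


def apply_primer(
    truth: SyntheticTruth,
    primer: PrimerProfile,
    depth: int = 20000,
    dispersion: float = 0.0,
    seed: int | None = None,
    biology_seed: int | np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observe every biological sample through one primer.

    With ``dispersion > 0`` each biological sample's true composition is a
    Dirichlet draw around its habitat profile (concentration profile /
    dispersion); passing the same ``biology_seed`` to two apply_primer calls
    reuses the identical per-pair compositions, so the two primers observe
    the same biology — as paired amplification of one DNA extract does.  The
    primer lens then reweights by ``coverage_i * efficiency_i`` and counts
    are multinomial at ``depth`` reads.  Returns (feature table: samples x
    taxa counts, metadata: sample_id, habitat, primer, pair_id).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    (rng,) = _spawn(seed, 1)
    if dispersion > 0:
        if biology_seed is None:  # independent biology, still deterministic per seed
            bio_ss = np.random.SeedSequence(int(rng.integers(2**63)))
        elif isinstance(biology_seed, np.random.SeedSequence):
            bio_ss = biology_seed
        else:
            bio_ss = np.random.SeedSequence(biology_seed)
        bio_children = bio_ss.spawn(len(truth.pairs))
    rows = []
    meta_rows = []
    for k, (pair_id, habitat) in enumerate(truth.pairs.itertuples(index=False)):
        base = truth.habitat_profiles[habitat]
        if dispersion > 0:
            brng = np.random.default_rng(bio_children[k])
            pos = base > 0
            comp = np.zeros_like(base)
            comp[pos] = brng.dirichlet(base[pos] / dispersion)
        else:
            comp = base
        w = comp * primer.coverage * primer.efficiency_for(habitat)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"primer {primer.name!r} covers no taxa in habitat {habitat!r}")
        p = w / total
        counts = rng.multinomial(depth, p)
        rows.append(counts)
        sample_id = f"{pair_id}.{primer.name}"
        meta_rows.append((sample_id, habitat, primer.name, pair_id))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "habitat", "primer", "pair_id"])
    table = pd.DataFrame(
        np.vstack(rows), index=pd.Index(meta["sample_id"], name="sample_id"),
        columns=truth.taxon_ids,
    )
    meta = meta.set_index("sample_id")
    if primer.resolution_merge:
        units = [primer.resolution_merge.get(t, t) for t in table.columns]
        table = table.T.groupby(pd.Index(units, name="taxon_id")).sum().T
    return table, meta


def simulate_neutral_pair_data(
    meta_p: np.ndarray,
    m: float,
    N: int,
    n_samples: int,
    seed: int | None = None,
    taxon_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Local communities under Sloan's neutral model.

    Each sample's relative abundances are drawn from the stationary local
    community distribution, Dirichlet with concentration ``N * m * meta_p``
    (migration rate m, community size N, metacommunity relative abundances
    meta_p), then observed as multinomial counts at depth N.
    """
    meta_p = np.asarray(meta_p, dtype=float)
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    if N < 10:
        raise ValueError("N must be >= 10")
    if abs(meta_p.sum() - 1.0) > 1e-8:
        raise ValueError("meta_p must sum to 1")
    if (meta_p > 0).sum() < 2:
        raise ValueError("meta_p is degenerate (fewer than 2 taxa)")
    (rng,) = _spawn(seed, 1)
    pos = meta_p > 0
    alpha = N * m * meta_p[pos]
    counts = np.zeros((n_samples, meta_p.size), dtype=int)
    for s in range(n_samples):
        p = rng.dirichlet(alpha)
        counts[s, pos] = rng.multinomial(N, p)
    if taxon_ids is None:
        taxon_ids = [f"t{i + 1:04d}" for i in range(meta_p.size)]
    return pd.DataFrame(
        counts,
        index=pd.Index([f"s{j + 1:03d}" for j in range(n_samples)], name="sample_id"),
        columns=list(taxon_ids),
    )
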