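"""End-to-end orchestration of the two-primer comparison.

A :class:`RunConfig` either points at input files (feature table, metadata,
tree, taxonomy, function map) or carries a synthetic-generator block; exactly
one of the two must be active.  :func:`run_pipeline` executes the enabled
analysis stages in the order profiling -> beta-diversity -> assembly ->
function/niche -> closed-reference, collects every result into a
machine-readable report stamped with the config hash and seed, and (optionally)
writes the report as JSON plus per-section TSV tables.  A failing optional
stage is recorded in the report and the remaining stages proceed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, betadiv, funcniche, io, profiling, synthgen

log = logging.getLogger("primerbias")

ALL_STAGES = ("profile", "betadiv", "assembly", "function", "cr")


@dataclass
class SynthBlock:
    """Synthetic-data generator parameters for a pipeline run."""

    n_taxa: int = 300
    habitats: dict | None = None
    lognormal_sigma: float = 1.5
    habitat_specialization: float = 0.8
    phylo_filtering: float = 0.0
    reference_unmapped_fraction: float = 0.26
    depth: int = 20000
    dispersion: float = 0.02
    primer_a: str = "V4"
    primer_b: str = "V5V7"
    coverage_a: float = 1.0
    coverage_b: float = 0.9
    coverage_by: str = "taxon"
    efficiency_sigma: float = 0.4
    shared_efficiency: bool = True


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``synth`` and ``inputs`` are mutually exclusive; thresholds default to the
    conventional |betaNTI| = 1.96 and |RCI| = 0.95 significance cutoffs.
    """

    synth: SynthBlock | None = field(default_factory=SynthBlock)
    inputs: dict | None = None
    seed: int = 7
    n_perm: int = 999
    n_null: int = 199
    pseudocount: float = 1e-6
    selection_threshold: float = 1.96
    dispersal_threshold: float = 0.95
    rc_convention: str = "stegen"
    level: str = "family"
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of synth / inputs must be set")
        for name in ("n_perm", "n_null", "pseudocount", "selection_threshold",
                     "dispersal_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", None)
        if synth is not None:
            synth = SynthBlock(**synth)
        stages = tuple(d.pop("stages", ALL_STAGES))
        return cls(synth=synth, stages=stages, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_config(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_inputs(paths: dict) -> dict:
    """Cross-consistency check of input files.

    Verifies id agreement between table, metadata, tree, taxonomy and function
    map, and pairing completeness (each pair_id present under both primers).
    Unpaired samples are listed as dropped; a table taxon missing from the
    tree is a hard error.  Returns {'issues': [...], 'dropped_unpaired': [...],
    'n_samples': int, 'n_taxa': int, 'ok': bool}.
    """
    issues: list[str] = []
    dropped: list[str] = []
    table = io.read_feature_table(paths["table"])
    meta = io.read_metadata(paths["metadata"])
    missing_meta = [s for s in table.index if s not in meta.index]
    if missing_meta:
        issues.append(f"{len(missing_meta)} samples lack metadata (e.g. {missing_meta[0]!r})")
    primers = list(pd.unique(meta["primer"]))
    if len(primers) != 2:
        issues.append(f"expected 2 primers in metadata, found {primers}")
    else:
        counts = meta.groupby("pair_id")["primer"].nunique()
        unpaired = counts.index[counts < 2]
        for p in unpaired:
            dropped.extend(meta.index[meta["pair_id"] == p].tolist())
        if len(unpaired):
            issues.append(f"{len(unpaired)} pair_ids present under a single primer (dropped)")
        hab = meta.groupby("pair_id")["habitat"].nunique()
        if (hab > 1).any():
            issues.append("habitat differs within a pair_id")
    if "tree" in paths and paths["tree"]:
        tree = io.read_tree(paths["tree"])
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = [t for t in table.columns if table[t].sum() > 0 and t not in tips]
        if missing:
            raise ValueError(f"taxon {missing[0]!r} in table but missing from tree")
    if "taxonomy" in paths and paths["taxonomy"]:
        tax = io.read_taxonomy(paths["taxonomy"])
        missing = [t for t in table.columns if t not in tax.index]
        if missing:
            issues.append(f"{len(missing)} taxa lack taxonomy (e.g. {missing[0]!r})")
    if "function_map" in paths and paths["function_map"]:
        fmap = io.read_function_map(paths["function_map"])
        alien = set(fmap["taxon_id"]) - set(table.columns)
        if alien:
            issues.append(f"{len(alien)} function-map taxa absent from table")
    return {
        "issues": issues,
        "dropped_unpaired": dropped,
        "n_samples": int(table.shape[0]),
        "n_taxa": int(table.shape[1]),
        "ok": not issues,
    }


def _acquire_data(config: RunConfig, ss: np.random.SeedSequence):
    """Return (table, metadata, tree, taxonomy, function_map, truth-or-None,
    primer names)."""
    if config.synth is not None:
        sb = config.synth
        s_truth, s_pa, s_pb, s_oa, s_ob, s_bio = ss.spawn(6)
        truth = synthgen.simulate_truth(
            n_taxa=sb.n_taxa,
            habitats=sb.habitats,
            lognormal_sigma=sb.lognormal_sigma,
            habitat_specialization=sb.habitat_specialization,
            phylo_filtering=sb.phylo_filtering,
            reference_unmapped_fraction=sb.reference_unmapped_fraction,
            seed=s_truth,
        )
        pa = synthgen.make_primer_profile(
            truth, sb.primer_a, coverage_fraction=sb.coverage_a,
            efficiency_sigma=sb.efficiency_sigma,
            shared_efficiency=sb.shared_efficiency, seed=s_pa,
        )
        pb = synthgen.make_primer_profile(
            truth, sb.primer_b, coverage_fraction=sb.coverage_b,
            coverage_by=sb.coverage_by, efficiency_sigma=sb.efficiency_sigma,
            shared_efficiency=sb.shared_efficiency, seed=s_pb,
        )
        # one shared biology seed: both primers observe the same per-pair compositions
        bio_seed = int(s_bio.generate_state(1)[0])
        ta, ma = synthgen.apply_primer(
            truth, pa, depth=sb.depth, dispersion=sb.dispersion, seed=s_oa,
            biology_seed=bio_seed,
        )
        tb, mb = synthgen.apply_primer(
            truth, pb, depth=sb.depth, dispersion=sb.dispersion, seed=s_ob,
            biology_seed=bio_seed,
        )
        table = pd.concat([ta, tb]).fillna(0).astype(int)
        meta = pd.concat([ma, mb])
        return table, meta, truth.tree, truth.taxonomy, truth.function_map, truth, (sb.primer_a, sb.primer_b)
    paths = config.inputs
    table = io.read_feature_table(paths["table"])
    meta = io.read_metadata(paths["metadata"]).loc[table.index]
    tree = io.read_tree(paths["tree"]) if paths.get("tree") else None
    tax = io.read_taxonomy(paths["taxonomy"]) if paths.get("taxonomy") else None
    fmap = io.read_function_map(paths["function_map"]) if paths.get("function_map") else None
    primers = tuple(pd.unique(meta["primer"]))
    if len(primers) != 2:
        raise ValueError(f"expected exactly 2 primers, found {primers}")
    return table, meta, tree, tax, fmap, None, primers


def _paired_subtables(table, meta, primer_a, primer_b):
    """Per-primer tables with rows aligned on pair_id order."""
    a = meta[meta["primer"] == primer_a].reset_index().set_index("pair_id")
    b = meta[meta["primer"] == primer_b].reset_index().set_index("pair_id")
    pairs = a.index.intersection(b.index)
    ta = table.loc[a.loc[pairs, "sample_id"]]
    tb = table.loc[b.loc[pairs, "sample_id"]]
    return ta, tb, list(pairs)


def _stage_profile(table, meta, tax, config, primers, rng):
    pa, pb = primers
    out: dict = {"hill": {}, "overlap": {}, "bias_consistency": {}, "kld": {}}
    habitats = list(pd.unique(meta["habitat"]))
    for primer in primers:
        for h in habitats:
            sel = meta.index[(meta["primer"] == primer) & (meta["habitat"] == h)]
            out["hill"][f"{primer}/{h}"] = {
                f"q{q}": float(np.mean([profiling.hill_diversity(table.loc[s], q) for s in sel]))
                for q in (0, 1, 2)
            }
    ta, tb, _ = _paired_subtables(table, meta, pa, pb)
    for rank in (None, "genus", "family"):
        key = rank or "asv"
        if rank is not None and (tax is None or rank not in tax.columns):
            continue
        out["overlap"][key] = profiling.taxa_overlap(ta, tb, rank=rank, taxonomy=tax)
    major = (
        profiling.major_taxa(table, meta, level=config.level, taxonomy=tax)
        if tax is not None
        else None
    )
    biases = {}
    for h in habitats:
        bias = profiling.bias_vector(
            table, meta, h, pa, pb, level=config.level if tax is not None else None,
            taxonomy=tax, pseudocount=config.pseudocount,
        )
        if major is not None:
            bias = bias.loc[bias.index.isin(major)]
        biases[h] = bias
    out["bias_vectors"] = {h: b.to_dict() for h, b in biases.items()}
    cons = {}
    for i, h1 in enumerate(habitats):
        for h2 in habitats[i + 1:]:
            try:
                r, p = profiling.bias_consistency(biases[h1], biases[h2])
                cons[f"{h1}|{h2}"] = {"r": r, "p": p}
            except ValueError as e:
                cons[f"{h1}|{h2}"] = {"error": str(e)}
    out["bias_consistency"] = cons
    out["kld"]["raw"] = profiling.sad_pair_kld(ta, tb)
    if tax is not None and "genus" in tax.columns:
        ga, gb = profiling.restrict_shared_genera(ta, tb, tax)
        out["kld"]["shared_genera"] = profiling.sad_pair_kld(ga, gb)
    depth = int(min(ta.sum(axis=1).min(), tb.sum(axis=1).min()))
    da = profiling.downsample(ta, depth, seed=int(rng.integers(2**31)))
    db = profiling.downsample(tb, depth, seed=int(rng.integers(2**31)))
    out["kld"]["downsampled"] = profiling.sad_pair_kld(da, db)
    return out


def _stage_betadiv(table, meta, config, primers, rng):
    pa, pb = primers
    out: dict = {}
    dm_all = betadiv.bray_curtis(table)
    res = betadiv.permanova(
        dm_all, meta, ["habitat", "primer", "habitat:primer"],
        n_perm=config.n_perm, seed=int(rng.integers(2**31)),
    )
    out["permanova"] = {
        term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
        for term, row in res.table.iterrows()
    }
    ta, tb, pairs = _paired_subtables(table, meta, pa, pb)
    dma = betadiv.bray_curtis(ta)
    dmb = betadiv.bray_curtis(tb)
    # relabel to pair ids so mantel sees matched orderings
    from skbio import DistanceMatrix

    dma = DistanceMatrix(dma.data, ids=pairs)
    dmb = DistanceMatrix(dmb.data, ids=pairs)
    r, p = betadiv.mantel(dma, dmb, n_perm=config.n_perm, seed=int(rng.integers(2**31)))
    out["mantel"] = {"r": r, "p": p}
    ca = betadiv.pcoa_coords(dma, k=2)
    cb = betadiv.pcoa_coords(dmb, k=2)
    m2, pp = betadiv.procrustes_test(ca, cb, n_perm=config.n_perm, seed=int(rng.integers(2**31)))
    out["procrustes"] = {"m2": m2, "p": pp}
    part = {}
    for primer, t in ((pa, ta), (pb, tb)):
        _, means_sor = betadiv.beta_partition(t, family="sorensen")
        _, means_bray = betadiv.beta_partition(t, family="bray")
        part[primer] = {"sorensen": means_sor, "bray": means_bray}
    out["partition"] = part
    return out


def _stage_assembly(table, meta, tree, config, primers, rng):
    out: dict = {"per_habitat": {}, "nst": {}, "sloan": {}, "failures": []}
    for primer in primers:
        sub_meta = meta[meta["primer"] == primer]
        for h in pd.unique(sub_meta["habitat"]):
            sel = sub_meta.index[sub_meta["habitat"] == h]
            if len(sel) < 3:
                out["failures"].append(f"assembly skipped for {primer}/{h}: <3 samples")
                continue
            sub = table.loc[sel]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            try:
                z = assembly.bnti(sub, tree, n_null=config.n_null, seed=int(rng.integers(2**31)))
                rc = assembly.raup_crick_bray(sub, n_null=config.n_null, seed=int(rng.integers(2**31)))
                pm = assembly.pairwise_metrics(z, rc, rc_convention=config.rc_convention)
                frac = assembly.process_fractions(pm["process"])
                out["per_habitat"][f"{primer}/{h}"] = {
                    "median_bnti": float(pm["bnti"].median()),
                    "median_rci": float(pm["rci"].median()),
                    "process_fractions": frac.to_dict(),
                }
            except Exception as e:  # partial-failure policy
                out["failures"].append(f"bnti/rci failed for {primer}/{h}: {e}")
        try:
            groups = sub_meta["habitat"]
            big = groups.value_counts()
            keep = sub_meta.index[groups.isin(big.index[big >= 3])]
            nst_vals = assembly.nst(
                table.loc[keep], meta.loc[keep, "habitat"],
                n_null=max(99, config.n_null // 2), seed=int(rng.integers(2**31)),
            )
            out["nst"][primer] = {k: float(v) for k, v in nst_vals.items()}
        except Exception as e:
            out["failures"].append(f"NST failed for {primer}: {e}")
        try:
            fit = assembly.sloan_fit(table.loc[sub_meta.index])
            out["sloan"][primer] = {
                "m": fit.m, "r2": fit.r2, "N": fit.N, "at_bound": fit.at_bound,
                "class_fractions": fit.class_fractions.to_dict(),
            }
        except Exception as e:
            out["failures"].append(f"Sloan fit failed for {primer}: {e}")
    return out


def _stage_function(table, meta, fmap, config, primers, rng):
    pa, pb = primers
    out: dict = {}
    ftab = funcniche.aggregate_functions(table, fmap)
    out["function_bias"] = {}
    for h in pd.unique(meta["habitat"]):
        try:
            fb = funcniche.function_bias(ftab, meta, h, pa, pb, pseudocount=config.pseudocount)
            out["function_bias"][h] = {
                "n_significant_q05": int((fb["q"] < 0.05).sum()),
                "mean_abs_bias": float(fb["log2_bias"].abs().mean()),
            }
        except ValueError as e:
            out["function_bias"][h] = {"error": str(e)}
    rel = profiling.relative_abundance(table)
    fr = {}
    niche = {}
    for primer in primers:
        sel = meta.index[meta["primer"] == primer]
        vals = []
        for s in sel:
            try:
                vals.append(funcniche.functional_redundancy(rel.loc[s], fmap))
            except ValueError:
                pass
        fr[primer] = float(np.mean(vals)) if vals else None
        nm = funcniche.niche_metrics(table.loc[sel], meta.loc[sel, "habitat"])
        niche[primer] = {"bcom": nm.bcom, "ocom": nm.ocom, "n_states": nm.n_states}
    out["functional_redundancy"] = fr
    out["niche"] = niche
    return out


def _stage_cr(table, meta, truth, config, primers):
    if truth is None:
        return {"skipped": "closed-reference stage needs the synthetic truth's reference set"}
    ref_map = {t: (t if t in truth.reference_members else None) for t in table.columns}
    collapsed, discarded = profiling.cr_collapse(table, ref_map)
    pa, pb = primers
    same = total = 0
    for h in pd.unique(meta["habitat"]):
        before = profiling.bias_vector(table, meta, h, pa, pb, pseudocount=config.pseudocount)
        after = profiling.bias_vector(collapsed, meta, h, pa, pb, pseudocount=config.pseudocount)
        sb = np.sign(before.loc[after.index].to_numpy())
        sa = np.sign(after.to_numpy())
        same += int((sb == sa).sum())
        total += len(after)
    return {
        "discarded_fraction": discarded,
        "bias_sign_concordance": same / total,
        "n_reference_taxa": int(collapsed.shape[1]),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages and return the comparison report as a dict.

    Deterministic for a fixed config (the report carries the config hash and
    seed).  With ``out_dir`` the report is written to ``report.json`` and the
    resolved config to ``config.yaml``.
    """
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    s_data, *stage_seeds = ss.spawn(1 + len(ALL_STAGES))
    table, meta, tree, tax, fmap, truth, primers = _acquire_data(config, s_data)
    # one independent stream per stage so toggling a stage never perturbs the others
    stage_rngs = {s: np.random.default_rng(sd) for s, sd in zip(ALL_STAGES, stage_seeds)}
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "primers": list(primers),
        "n_samples": int(table.shape[0]),
        "n_taxa": int(table.shape[1]),
        "stage_failures": {},
    }
    stage_fns = {
        "profile": lambda: _stage_profile(table, meta, tax, config, primers, stage_rngs["profile"]),
        "betadiv": lambda: _stage_betadiv(table, meta, config, primers, stage_rngs["betadiv"]),
        "assembly": lambda: _stage_assembly(table, meta, tree, config, primers, stage_rngs["assembly"]),
        "function": lambda: _stage_function(table, meta, fmap, config, primers, stage_rngs["function"]),
        "cr": lambda: _stage_cr(table, meta, truth, config, primers),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s ...", stage)
        t1 = time.time()
        try:
            report[stage] = stage_fns[stage]()
        except Exception as e:
            log.exception("stage %s failed", stage)
            report["stage_failures"][stage] = str(e)
        log.info("stage %s done in %.1fs", stage, time.time() - t1)
    report["elapsed_seconds"] = round(time.time() - t0, 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        io.dump_config(config.to_dict(), out_dir / "config.yaml")
    return report
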