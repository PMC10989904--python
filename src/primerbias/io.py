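"""Plain-text I/O: feature tables, metadata, taxonomy and function maps as
TSV, trees as newick, run configuration as YAML.

On disk a feature table is taxa rows x sample columns (first column
``taxon_id``, header row of sample ids); in memory it is the transposed
samples x taxa DataFrame every module consumes.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
import yaml


def write_feature_table(table: pd.DataFrame, path) -> None:
    out = table.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = df.T
    table.index.name = "sample_id"
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise ValueError(f"duplicate sample or taxon ids in {path}")
    if (table.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return table


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return meta


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    if tax.index.duplicated().any():
        raise ValueError(f"duplicate taxon ids in {path}")
    return tax


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_function_map(fmap: pd.DataFrame, path) -> None:
    fmap.to_csv(path, sep="\t", index=False)


def read_function_map(path) -> pd.DataFrame:
    fmap = pd.read_csv(path, sep="\t")
    expected = {"taxon_id", "function"}
    if not expected <= set(fmap.columns):
        raise ValueError(f"function map must have columns {sorted(expected)}")
    return fmap


def write_distance_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
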