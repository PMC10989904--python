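"""Community-assembly inference per primer data set on the simulated survey.

For each primer and habitat (water and soil, the two best-sampled here after
sub-sampling soil for tractability): betaNTI and Raup-Crick per sample pair,
Stegen process fractions, NST per habitat, and the Sloan neutral-model fit
per primer.  Writes TSVs under results/assembly/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from primerbias import assembly, io

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "assembly"
N_NULL = 199
MAX_SAMPLES = 20  # per habitat/primer, to keep the null loops quick

def main():
    OUT.mkdir(parents=True, exist_ok=True)
    table = io.read_feature_table(ROOT / "data" / "table.tsv")
    meta = io.read_metadata(ROOT / "data" / "metadata.tsv").loc[table.index]
    tree = io.read_tree(ROOT / "data" / "tree.nwk")
    rng = np.random.default_rng(4)

    frac_rows, metric_rows = [], []
    for primer in ("V4", "V5V7"):
        for habitat in ("water", "soil"):
            sel = meta.index[(meta["primer"] == primer) & (meta["habitat"] == habitat)]
            if len(sel) > MAX_SAMPLES:
                sel = pd.Index(rng.choice(sel, size=MAX_SAMPLES, replace=False))
            sub = table.loc[sel]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            z = assembly.bnti(sub, tree, n_null=N_NULL, seed=int(rng.integers(2**31)))
            rc = assembly.raup_crick_bray(sub, n_null=N_NULL, seed=int(rng.integers(2**31)))
            pm = assembly.pairwise_metrics(z, rc)
            pm.insert(0, "habitat", habitat)
            pm.insert(0, "primer", primer)
            metric_rows.append(pm)
            frac = assembly.process_fractions(pm["process"])
            frac_rows.append(pd.Series(frac, name=f"{primer}/{habitat}"))
            print(f"{primer}/{habitat}: median betaNTI {pm['bnti'].median():+.2f}, "
                  f"median RCI {pm['rci'].median():+.2f}, "
                  f"undominated {frac['undominated']:.0%}")
    pd.concat(metric_rows).to_csv(OUT / "pairwise_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(frac_rows).to_csv(OUT / "process_fractions.tsv", sep="\t")

    nst_rows = {}
    for primer in ("V4", "V5V7"):
        sel = meta.index[meta["primer"] == primer]
        groups = meta.loc[sel, "habitat"]
        keep = sel[groups.isin(["water", "gut", "leaf"])]
        vals = assembly.nst(table.loc[keep], meta.loc[keep, "habitat"],
                            n_null=99, seed=int(rng.integers(2**31)))
        nst_rows[primer] = vals
    nst = pd.DataFrame(nst_rows)
    nst.to_csv(OUT / "nst.tsv", sep="\t")
    print("\nNST (stochasticity ratio, 0..1; >0.5 = stochastic-dominated):")
    print(nst.round(3).to_string())

    sloan_rows = []
    for primer in ("V4", "V5V7"):
        sel = meta.index[meta["primer"] == primer]
        fit = assembly.sloan_fit(table.loc[sel])
        cf = fit.class_fractions
        sloan_rows.append((primer, fit.m, fit.r2, cf["neutral"], cf["above"], cf["below"]))
        fit.stats.to_csv(OUT / f"sloan_taxa_{primer}.tsv", sep="\t")
    sloan = pd.DataFrame(sloan_rows, columns=["primer", "m", "r2", "neutral", "above", "below"])
    sloan.to_csv(OUT / "sloan.tsv", sep="\t", index=False)
    print("\nSloan neutral fit per primer:")
    print(sloan.round(3).to_string(index=False))
    return 0

if __name__ == "__main__":
    sys.exit(main())
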