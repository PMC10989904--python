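# primerbias

Marker-gene surveys see a community through the primer pair that amplified
it. Two widely used 16S rRNA primer sets (e.g. V4 vs V5–V7) differ in which
taxa they can amplify at all (coverage), how efficiently they amplify the
ones they do (amplification efficiency), and how finely they resolve them.
`primerbias` is a toolkit for asking, quantitatively, how much those
distortions bend the numbers microbial ecologists actually publish: alpha
diversity, taxon abundances, species abundance distributions,
beta-diversity structure, community-assembly inference (βNTI, Raup–Crick,
NST, Sloan's neutral model), predicted function, and niche metrics.

Because the truth behind real sequencing data is unobservable, the package
pairs every analysis with a synthetic multi-habitat survey generator whose
truth *is* known. A primer is an explicit observation model — a coverage
mask, per-taxon efficiency factors, an optional resolution merge — applied
to latent habitat communities; every downstream statistic can therefore be
validated against the mechanism that is supposed to drive it. The default
design emulates a five-habitat paired survey (water 36, sediment 7, soil
79, leaf 40, gut 12 biological samples, each observed under both primers).

It is written for microbial ecologists and methods developers who want to
stress-test an analysis plan against primer artifacts before trusting it on
real data.

## Core statistics

* Hill diversity `qD`; per-taxon log2 bias `log2((mA+ε)/(mB+ε))` and its
  cross-habitat Spearman consistency; SAD divergence as KLD in bits; the two
  bias-attribution strategies (shared-genus restriction, in-silico
  down-sampling) and closed-reference collapse.
* Bray–Curtis with two-factor sequential-SS PERMANOVA
  (habitat → primer → interaction), Mantel and Procrustes/PROTEST paired
  tests, Baselga turnover/nestedness partitioning.
* Abundance-weighted βMNTD with tip-shuffle nulls: βNTI z-scores
  (|βNTI| > 1.96 ⇒ selection); abundance-based Raup–Crick
  `RCI ∈ [−1, 1]` (|RCI| > 0.95 ⇒ dispersal signal); Stegen process
  fractions; a normalized stochasticity ratio; Sloan's neutral fit
  `freq(p) = 1 − BetaCDF(d; Nmp, Nm(1−p))` with per-taxon
  above/below/neutral classes.
* Function aggregation through a taxon→function map, Welch-t function bias,
  functional redundancy, Levins/Pianka community niche metrics (Bcom, Ocom).

See `docs/methods.md` for formulas, defaults and numerical choices.

## Worked example

```python
import numpy as np
import pandas as pd
from primerbias import synthgen, profiling

truth = synthgen.simulate_truth(n_taxa=120, habitats={"water": 6, "soil": 6}, seed=7)
v4   = synthgen.make_primer_profile(truth, "V4", efficiency_sigma=0.5, seed=1)
v57  = synthgen.make_primer_profile(truth, "V5V7", coverage_fraction=0.8,
                                    efficiency_sigma=0.5, seed=2)
t4,  m4  = synthgen.apply_primer(truth, v4,  depth=20000, seed=3)
t57, m57 = synthgen.apply_primer(truth, v57, depth=20000, seed=4)
table = pd.concat([t4, t57]).fillna(0).astype(int)
meta  = pd.concat([m4, m57])

for primer, t in (("V4", t4), ("V5V7", t57)):
    rich = np.mean([profiling.hill_diversity(t.loc[s], 0) for s in t.index])
    print(f"{primer}: mean richness (Hill q=0) = {rich:.1f}")

bias_w = profiling.bias_vector(table, meta, "water")
bias_s = profiling.bias_vector(table, meta, "soil")
r, p = profiling.bias_consistency(bias_w, bias_s)
print(f"water-vs-soil bias consistency: Spearman r = {r:.3f} (p = {p:.2e})")
print(f"SAD divergence between primers: KLD = {profiling.sad_pair_kld(t4, t57):.3f} bits")
```

prints

```
V4: mean richness (Hill q=0) = 119.9
V5V7: mean richness (Hill q=0) = 96.0
water-vs-soil bias consistency: Spearman r = 0.986 (p = 8.63e-94)
SAD divergence between primers: KLD = 0.469 bits
```

Read: the 80%-coverage primer misses ~24 of 120 taxa per sample; because
both habitats share the same efficiency factors, the taxon-level bias
vector is almost identical between habitats (r ≈ 0.99) — primer bias is a
property of the primer, not the sample; and the two primers' abundance
distributions diverge by ~0.47 bits.

## Analysis pipeline

The numbered drivers under `analysis/` run the full comparison on one
simulated survey and write their tables under `results/`:

```bash
python analysis/01_simulate_survey.py      # paired two-primer survey -> results/data/
python analysis/02_profile_bias.py         # diversity, bias vectors, KLD + attribution
python analysis/03_beta_diversity.py       # PERMANOVA, Mantel/Procrustes, partitioning
python analysis/04_assembly_processes.py   # betaNTI, RCI, process fractions, NST, Sloan
python analysis/05_function_niche.py       # function bias, redundancy, Bcom/Ocom
python analysis/06_closed_reference.py     # CR read loss and bias-sign stability
```

The same machinery is scriptable end-to-end (`primerbias run --config
config.yaml --seed 7 --out results/`) or piecewise (`primerbias simulate /
validate / profile / betadiv / assembly / function`) from the shell.

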