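# coaldate

Coalescent simulation and tree analytics for a recurring mistake in molecular
dating: reading the **TMRCA** of samples from a single taxon — or worse, the
age of the "most basal node" of their tree — as the taxon's **divergence
date** from its sister lineage.

The package is for phylogeneticists and molecular epidemiologists who date
emergence or divergence events from sequence data. It provides:

- a **two-population isolation-model coalescent simulator**: equal constant
  population sizes, no migration, a single backward-in-time population join
  at `t_join`, time in 4·N0-generation units (pairwise coalescence rate 2);
  it parses and reproduces ms-style command strings such as
  `ms 11 1 -t 2.0 -I 2 1 10 -ej 10 1 2 -T` and writes ms-dialect output;
- an **infinite-sites mutation overlay** at rate θ = 4·N0·μ
  (E[S] = θ·Σ 1/i, the Watterson expectation);
- **tree metrics**: TMRCA of a leaf subset, root height (the global TMRCA,
  and the divergence-date estimator once an outgroup is sampled), basal-node
  age (oldest non-root split — always strictly younger than the root), and
  monophyly / lineage-sorting classification, with Newick I/O;
- **exact analytic oracles**: E[TMRCA] = 1 − 1/n, the lineage-count
  distribution of the pure-death chain with rates k(k−1), and the
  single-outgroup monophyly probability
  P(mono) = Σ_j P(j lineages at t_join) · 2/(j(j+1));
- **scenario experiments** contrasting deep (t_join = 10, i.e. 40 N0
  generations) and recent (t_join = 0.01, i.e. 0.04 N0 generations)
  divergence, plus a sweep locating the divergence time at which lineage
  sorting completes (conventionally 4–7 Ne generations);
- a **recombination-masking / SNP-culling utility** that removes alignment
  columns attributed to recombination (ClonalFrameML `importation_status`
  TSV), drops ambiguous/missing columns, and culls to variant positions —
  the step between recombination detection and clock dating.

## Worked example

```python
import coaldate as cd

cfg = cd.parse_ms_command("ms 11 1 -t 2.0 -I 2 1 10 -ej 10 1 2 -T", seed=1)
tree = cd.simulate_genealogy(cfg, 0)
print("root height (divergence est.):", round(cd.root_height(tree), 3))
print("TMRCA of X1..X10:", round(cd.tmrca(tree, cfg.ingroup_labels), 3))
print("basal node age:", round(cd.basal_node_age(tree), 3))

res = cd.run_scenario("recent", n_reps=5000, seed=1)
print("monophyly fraction:", res.summary.monophyly_fraction)
print("mean TMRCA of X:", round(res.summary.tmrca_ingroup_mean, 3),
      " mean root height:", round(res.summary.root_height_mean, 3))
```

prints

```
root height (divergence est.): 10.839
TMRCA of X1..X10: 0.491
basal node age: 0.491
monophyly fraction: 0.0216
mean TMRCA of X: 0.899  mean root height: 0.913
```

Under deep divergence (first four lines) the ten ingroup samples coalesce at
0.49 — close to the panmictic n = 10 expectation of 0.9 and twenty-fold more
recent than the true divergence at 10: equating the ingroup TMRCA (or the
basal-node age) with the divergence date would be off by an order of
magnitude, and only the root height — which requires the outgroup — recovers
it. Under recent divergence (last two lines) the ingroup is monophyletic in
only ~2% of genealogies and the TMRCA and divergence-estimate distributions
are statistically indistinguishable.

The same experiments are available from a shell:

```sh
coaldate scenario deep --reps 5000 --seed 7 --out run_deep/
coaldate sweep --grid 1.0:8.0:0.5 --reps 5000 --seed 7 --out sweep.tsv
coaldate simulate --ms-command "ms 11 1 -t 2.0 -I 2 1 10 -ej 0.01 1 2 -T" --seed 1
coaldate mask --alignment aln.fasta --intervals imports.tsv --out snps.fasta
```

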