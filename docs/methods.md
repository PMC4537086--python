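# Methods

## The model

`coaldate` simulates gene genealogies under a two-population isolation model:
two populations of equal, constant (haploid-effective) size N0 exchange no
migrants and, looking backward in time, merge into a single ancestral
population at a join time `t_join`. Forward in time this is a clean
speciation/divergence event at `t_join`; backward it is the earliest moment
at which lineages from the two populations may coalesce with each other.

Time is measured in units of 4·N0 generations (the ms convention). On that
scale a population holding k lineages waits an Exp(k·(k−1)) time for its next
coalescence; a single pair coalesces after mean 0.5 units. The conversion
helpers in `io_cli` move between this unit and N0 (equivalently Ne)
generations — with equal constant sizes, Ne ≡ N0 — so a join at 10 on the
4N0 scale is 40 N0 generations, and 0.01 is 0.04.

The sampling design is the common one in phylogenetic dating studies: dense
sampling (n = 10) inside a focal taxon X plus a single outgroup lineage Y
that provides polarity and identifies the divergence node. The two named
scenarios differ only in the join time:

| scenario | t_join (4N0) | t_join (N0 = Ne gens) | regime |
|----------|--------------|----------------------|--------|
| deep     | 10           | 40                   | lineage sorting complete |
| recent   | 0.01         | 0.04                 | massive incomplete lineage sorting |

Three per-replicate quantities are contrasted:

- **TMRCA of X** — the age of the MRCA of the ten ingroup leaves;
- **root height** — the age of the whole tree's root (the MRCA of X ∪ Y),
  the only per-replicate random quantity that estimates the divergence date;
- **basal-node age** — the age of the oldest *non-root* internal node,
  formalizing the "most basal node" statistic that is sometimes reported in
  place of a TMRCA. It is strictly younger than the root height on every
  binary tree with ≥ 3 leaves, which is why node age must not be read as a
  TMRCA, and why neither is in general a divergence date.

Under deep divergence the ingroup TMRCA distribution is that of the
panmictic 10-coalescent (mean 0.9 in 4N0 units) while every root height
exceeds 10: the two histograms are disjoint. Under recent divergence the
ingroup is rarely monophyletic and the TMRCA and root-height distributions
nearly coincide (their Kolmogorov–Smirnov distance is ≈ 0.01 at 5000
replicates).

## Mutations

Mutations follow the infinite-sites model at population-scaled rate
θ = 4·N0·μ per locus: the site count is Poisson(θ·L) for total branch length
L (in 4N0 units), sites land on branches proportionally to length, and each
derived allele marks exactly the leaves below its branch. This reproduces the
Watterson expectation E[S] = θ·Σ_{i<n} 1/i (5.658 for n = 10, θ = 2). The
mutation RNG stream is separate from the genealogy stream, so toggling θ
never changes the trees. Positions are decorative uniform(0,1) marks printed
at 4 decimals in the ms-dialect output; the reader resolves 4-decimal ties by
an epsilon nudge so matrices round-trip bit-exactly.

The simulated mutations are not used by the scenario analyses (only tree
shapes matter there); θ = 2.0 is carried for fidelity to the simulation
commands and validated against the closed forms.

## Analytic oracles

The simulator is validated without external tools against:

- E[TMRCA] = 1 − 1/n and E[total length] = H_{n−1} (4N0 units);
- the exact lineage-count distribution P(j ancestral lineages at t | n at 0)
  of the pure-death chain with rates k·(k−1), computed via a matrix
  exponential of the generator. The textbook alternating-sum series is
  numerically catastrophic at small t for moderate n, which is why the
  spectral/`expm` route is used; probabilities are verified to sum to 1
  within 1e−12.
- the exact single-outgroup monophyly probability
  P(mono) = Σ_j P(j at t_join) · q(j), where q(j) = 2/(j·(j+1)) is the
  probability that j exchangeable lineages fully coalesce before any of them
  joins a lone outgroup (telescoping product of C(k,2)/C(k+1,2)); q is
  cross-checked in the tests by exact brute-force enumeration of merge orders
  for j ≤ 4 using rational arithmetic. The oracle is deliberately restricted
  to one outgroup lineage (the study design); a multi-lineage outgroup needs
  a two-dimensional recursion and is out of scope.

An independent coalescent simulator (msprime, haploid populations of size
0.5 so the pairwise rate is 2 per unit time) provides a distributional
cross-check of root heights via a two-sample KS test in the unit tests.

## Lineage-sorting sweep

`lineage_sorting_sweep` varies the join time on a grid expressed in Ne
generations — the unit in which complete lineage sorting is conventionally
expected some 4–7 Ne generations after isolation — and records the fraction
of replicates in which the 10-lineage ingroup is monophyletic, plus the
smallest grid time at which that fraction reaches a caller-chosen threshold.
No canonical threshold defines "complete" sorting, so the threshold is a
parameter (0.90 in the acceptance run, where the crossing lands at ≈ 5.5–6.0
Ne generations, inside the 4–7 window). Each grid point runs fresh
simulations on its own deterministic subseed, so rows are independent of
grid order and length.

## Reproducibility and numerics

- One master seed; replicate i draws from `SeedSequence((seed, i, stream))`
  with stream 0 for the genealogy and 1 for mutations. Replicates are
  therefore invariant to the replicate count, and outputs are byte-identical
  across runs with the same seed. ms's three-number `-seeds a b c` form is
  accepted and folded deterministically (SeedSequence entropy, truncated to
  31 bits) into a single master seed.
- Coalescing pairs are chosen by a single indexed uniform draw over the
  k·(k−1)/2 pairs of the label-sorted lineage list — byte-reproducible across
  platforms. Ties in continuous event times have probability zero; no
  tie-breaking beyond that deterministic ordering exists.
- Newick output carries 9-decimal branch lengths; parsing recovers ages from
  root-to-tip distances and rejects trees that are not ultrametric within
  1e−6 (enough head-room that writing and re-reading a tree never trips the
  check), not strictly binary, or missing branch lengths.
- Default replicate count is 5000 per experiment: binomial standard errors
  below 0.007 on monophyly fractions, with every documented check running in
  seconds. Histograms use Freedman–Diaconis bins with the edges recorded in
  the summary so output is exactly reproducible.

## Recombination masking

`recomb_mask` implements the post-detection step between recombination
inference and molecular dating. Input is a multi-FASTA whole-genome
alignment plus a TSV of imported (recombinant) tracts in the ClonalFrameML
`importation_status` dialect (`Node  Beg  End`, 1-based inclusive). The
pass:

1. removes every alignment column intersecting any tract — by default the
   whole column, regardless of which taxon the tract names, matching the
   practice of removing *positions* from the alignment file; a per-taxon
   mode instead sets only the named taxon's characters to N;
2. removes every column containing a character outside A/C/G/T
   (case-insensitive; gaps and IUPAC ambiguity codes count as missing) when
   `drop_incomplete` is on;
3. keeps the remaining columns with ≥ 2 distinct bases, in original order —
   the SNP matrix — with a sidecar map back to 1-based original coordinates.

The report reconciles exactly: kept + masked-only + incomplete-only +
invariant-only + multiply-flagged equals the alignment length. Tracts
labelled with internal-node names are expanded to descendant taxa when a
Newick tree is supplied; otherwise they fall back, with a loud warning, to
whole-column masking (configurable to an error). Whether the original
masking practice was column-wise or taxon-wise is ambiguous in the field;
both are implemented, column-wise being the default.

## Synthetic fixtures

The fixture generator emulates the *structure* of a post-alignment dataset —
a reference row, independent per-column background substitutions (default
1%), planted tracts of strongly elevated divergence (default rate 0.5) in
designated taxa, and sprinkled Ns — together with the ground-truth tract
intervals. Columns are independent: there is no linkage, no phylogenetic
correlation, and no indel process. Passing tests therefore demonstrate the
masking/culling logic (coordinate bookkeeping, recall of flagged tracts,
column accounting), not performance on real genomes, where recombinant
tracts must first be *detected* and detection errors dominate.

## Known limitations

- Exactly two populations, one join event, no migration, no growth, no
  recombination within the simulated locus, no serial sampling.
- The monophyly oracle assumes a single outgroup lineage.
- The simulator's published-figure counterpart can only be reproduced
  distributionally: the original random seeds of the displayed genealogies
  are unknown.
- Empirical re-analyses that require whole-genome aligners, recombination
  detection and Bayesian dating of real assemblies are outside the package;
  `recomb_mask` covers only the deterministic masking/culling step between
  those tools.
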