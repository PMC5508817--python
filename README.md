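# axanet

Distance-based phylogenetic **network** analysis for categorical
morphological character matrices — built for datasets that mix fossil and
extant taxa, carry heavy missingness, and produce signals too conflicting
for a single tree.

The pipeline, end to end:

1. **Matrix I/O** — NEXUS `DATA`/`CHARACTERS` matrices (missing `?`, gap `-`
   treated as missing, `(..)` ambiguity sets preserved), NEXUS/PHYLIP
   distance matrices, Newick trees, and SplitsTree-compatible `SPLITS`
   blocks.
2. **Derived character coding** — perforations-per-mm-stele-perimeter and
   relative-cortex-thickness ratios from raw axis measurements, with 1-D
   k-median clustering (restart-based and exact DP solvers) behind the
   state thresholds.
3. **Filtering** — exclusion of taxa with more than 60% missing cells,
   named taxon subsets (shipped as a genus-prefix config, user-overridable),
   and removal of invariant characters per focal subset.
4. **Distances** — mean character differences with pairwise deletion
   (ambiguous cells are incomparable), plus max-pair / zero-pair summaries.
5. **Treelikeness** — per-quartet delta values; matrix-level mDV and
   per-taxon iDV by full quartet enumeration (vectorized: ~9.4M quartets in
   a couple of seconds).
6. **Neighbour-net** — the agglomerative circular ordering with the 2/3–1/3
   reduction and nonnegative least-squares split weights (exact active-set
   NNLS for small problems, structured projected-gradient for large ones).
7. **Trees** — BioNJ (variance-weighted NJ) and Fitch parsimony with NNI
   hill-climbing.
8. **Bootstrap** — character resampling with one tree per pseudoreplicate
   (BioNJ or parsimony), split-frequency support tables, and
   frequency-weighted consensus networks with a <10% filter.
9. **Synthetic data** — Mk-like simulation on known trees with tunable
   homoplasy and missingness, so every stage is testable offline.

## Command line

```sh
# full analysis of a matrix (all taxa)
axanet analyze --matrix matrix.nex --bootstrap nj_ls:10000 --seed 1 --out run1

# a named subset with a custom missing-data threshold
axanet analyze --matrix matrix.nex --subset millerocaulis --threshold 0.6 --out run2

# generate a synthetic matrix with known truth
axanet simulate --taxa 16 --characters 45 --change-rate 2 --seed 7 --out sim1

# place a newly coded taxon: nearest neighbours, iDV, genus-group supports
axanet place --matrix matrix.nex --taxon "New species" \
    --row "01?2(01)0110...45 cells..." --subset all --replicates 1000

# bootstrap support for named taxon groups
axanet supports --matrix matrix.nex --replicates 10000 \
    --group "pair=Todea tidwellii;Todea barbara"
```

Stage artifacts (filtered matrix, distances, delta table, splits NEXUS,
support tables, consensus networks, JSON report) are written to the output
directory; runs are deterministic given `--seed`.

## Reference dataset and the acceptance report

The package was specified against a published analysis of 129 fossil and
extant royal-fern axes (45 binary/ternary characters).  That source matrix
is distributed only through the original study's supplementary-data
archive and **cannot be redistributed here**.  To validate against it,
download the NEXUS matrix and either

* place it at `data/published_matrix.nex`, or
* point `AXANET_PUBLISHED_MATRIX` at it.

Then:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes every published target (filter dimensions, worked distances,
mDV/iDV, bootstrap support) from scratch and writes them as JSON.  Without
the file the script exits cleanly with an empty report, and the
data-dependent acceptance tests in `tests/test_acceptance.py` fail with an
explicit "source data unavailable" message (they are deliberately not
skipped).  The self-contained property-based acceptance test passes
regardless.

## Notes and caveats

* Ambiguity sets take part in parsimony scoring but are treated as
  incomparable in distance computation.
* Maximum-likelihood (Mk+Γ) bootstrapping is out of scope; supports are
  available under the least-squares/BioNJ and parsimony criteria.
* The simulator draws characters independently; it does not model
  correlated evolution or variable-only ascertainment of characters.
* No graph layout is performed — splits files are written for viewing in a
  splits-graph viewer.
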