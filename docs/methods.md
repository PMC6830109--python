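# Methods notes

## Model and procedure

The package treats enhancer-associated chromatin signal as a set of mapped
H3K4me1 tag intervals per cell line and asks, gene by gene, what fraction of
that signal is contributed by retroelement (RE) sequence in the 10-kb
window around the reference TSS. The chain is:

1. **Tag assignment.** A tag belongs to a gene's neighborhood iff its
   midpoint, `floor((start+end)/2)`, lies in the strand-aware window
   `[tss − upstream, tss + downstream)` (flipped for − genes, clipped at 0).
   It is RE-linked iff the midpoint lies inside the union-merged RE track.
   The midpoint rule is a deliberate choice: it makes RE-linked/RE-free a
   partition (a tag straddling an RE boundary is counted once on exactly
   one side), which the downstream scores assume. Whether the original
   analyses counted by overlap or containment is not documented anywhere we
   could rely on; the midpoint convention is ours and is stated here. Tags
   in two genes' neighborhoods count for both genes.
2. **Scores.** `GRE = re_tags` (absolute), `NGRE = re_tags / total_tags`
   (relative; undefined when the gene has no neighborhood tags). Zero-tag
   genes are excluded from NGRE-based analyses, not scored 0 — a 0 would
   masquerade as maximal RE deficiency. Pathway scores PII/NPII are the
   arithmetic means of member genes' GRE / defined NGRE; a `sum` option
   exists for PII because the absolute pathway score could defensibly be
   either, but the mean is the default used throughout.
3. **Cell-line aggregation.** Arithmetic mean per gene across cell lines
   (NGRE averaged over the lines where it is defined). Pairwise Pearson
   correlation matrices across lines are provided to check congruence
   before averaging.
4. **Trend classification.** `NGRE = β·GRE` by least squares through the
   origin, `β = Σxy/Σx²`. Distance from the trend is the **vertical**
   residual (the model treats the relative score as a function of the
   absolute one; the absolute score is the abscissa). The extremes are the
   `m = round_half_away(fraction · N)` items per side; rounding half away
   from zero is the unique rule consistent with both published set sizes
   (0.05·24,070 → 1204 and 0.05·3,095 → 155). Ties are broken by item id
   under one total (residual, id) ordering, so labels are deterministic
   and the two extreme sets are disjoint whenever 2m ≤ N.
5. **Representation tests.** Hypergeometric, with the over-tail summed from
   k+1 and the under-tail summed from 1 — exactly the published
   conventions, so `p_over + p_under + p(0) = 1`. Conclusions apply the
   0.05 threshold per tail. In the degenerate case where both tails fall
   below the threshold (requires p(0) > 0.9, never reached in these
   analyses) the smaller p wins. Term enrichment is the same machinery as
   a one-sided tail at k (standard) or k−1 (EASE-style, conservative),
   computed internally rather than through an annotation web service; BH
   FDR is reported next to the raw p, and the default decision stays on
   raw p < 0.05 to mirror the DAVID-style workflow the internal test
   replaces.
6. **Permutation control.** Gene ids are rearranged over the (GRE, NGRE)
   table jointly — the score-pair multiset is invariant — and
   classification + term enrichment re-run per permutation; per-permutation
   seeds derive from the master seed by counter, so runs are reproducible
   and parallelizable. The statistic is the minimum term p-value; the
   empirical q is `(r+1)/(B+1)`, positively biased and consistent with the
   published bound q < 0.002 at r = 0, B = 500. Top-`top_terms` p-value
   lists (padded with 1 when fewer terms exist) are retained for the
   real-vs-null distribution comparison; its "mode" is the midpoint of the
   densest equal-width bin of −log10 p over the pooled real∪null range
   (50 bins by default; the binning behind the original comparison is not
   documented, so it is configurable).
7. **Concordance.** The published consensus-group comparison rests on
   manual biological grouping, which is out of scope. The pipeline's
   automated analogue applies both classification routes to the same
   pathway collection: route 1 labels pathways by their NPII-vs-PII trend
   position; route 2 labels a pathway enriched/deficient when it is
   significantly overrepresented among RRE-enriched/RRE-deficient genes.
   The MCC is computed over pathways called non-intermediate by both
   routes, with `(a·d − b·c)/√((a+b)(a+c)(d+b)(d+c))` defined as 0 on a
   zero marginal.

## Parameters that matter

| parameter | default | unit | note |
|---|---|---|---|
| upstream / downstream | 5000 / 5000 | bp | the 10-kb TSS frame |
| fraction | 0.05 | — | extreme-set share per side |
| alpha | 0.05 | — | per-tail significance threshold |
| B (`n_permutations`) | 500 | — | label permutations |
| top_terms | 100 | — | retained p-values per permutation |
| RE classes kept | LINE, SINE, LTR, SVA/Retroposon | — | DNA transposons excluded, configurable |

All of these are configuration with published defaults; none is hard-coded
inside an algorithm.

## What the synthetic generator emulates — and what it does not

`simulate()` produces a genome of `n_chromosomes × chrom_length` bp with
`n_genes` TSSs laid out so 10-kb neighborhoods never overlap, an RE track
built from 500-bp blocks covering `re_density ≈ 0.4` of each neighborhood
(the genomic RE share) plus a background scatter, per-cell-line tag tracks,
pathway/term GMTs, gene-class labels and a JSON ground-truth manifest. Tags
are 150-bp read-like intervals (width configurable to emulate peak calls),
so the midpoint rule is genuinely exercised.

Planting is **compositional**: every gene's expected RE-linked tag count is
`λ·p0` per cell line, but a planted gene draws its total from
`Poisson(λ·p0/p1)` and places tags on the RE track with probability `p1`
instead of `p0`. Planted genes therefore rise above the NGRE-GRE trend at a
fixed absolute score — precisely the signal the classification measures —
rather than simply having more signal. With `p1 = p0` the construction
collapses to the exact null. Defaults are the study conditions: 2,000
genes, 5 cell lines, λ = 30, p0 = 0.25, p1 = 0.8, 5% planted, 200 pathways
and 200 terms of 20 genes (a reduced-scale stand-in for the thousands of
real pathways), lncRNA/miRNA base rates 0.0614/0.0747 (the real class
rates in a 24,070-gene universe), and `ncrna_bias = 3` as a true odds
multiplier on each ncRNA class for planted genes.

The generator does **not** simulate sequence, chromatin-domain structure,
tag-density correlations between neighboring genes, cell-line-specific
biology (lines differ only by sampling noise), or distal looping
enhancers. Passing tests therefore demonstrate that the statistical chain
recovers planted compositional signal under realistic counting noise — not
that any particular biological conclusion holds on real data.

## Numerical choices and degenerate inputs

- Hypergeometric masses and tails are evaluated in log space
  (`scipy.stats.hypergeom`); the unit tests check them against an exact
  rational enumeration oracle for every parameter combination with M ≤ 12
  and against Monte-Carlo sampling without replacement at larger M.
- The zero-intercept fit requires Σx² > 0 and leaves Σ(x·residual) = 0 to
  ~1e−9 relative, which is tested as an invariant.
- `k` outside the hypergeometric support returns mass 0 rather than
  raising; a term with k = 0 reports p = 1.
- Coordinates are validated on construction (start ≥ 0, end > start);
  malformed input lines raise parse errors naming the file and line.
- Chromosome names match by exact string equality — no "chr" prefix
  normalization. RepeatMasker `.out` (1-based inclusive) is converted to
  0-based half-open on read.
- Multi-transcript genes collapse to the 5′-most TSS per gene (min txStart
  on +, max txEnd−1 on −); pre-collapse the input table to override.
- TSV artifacts are written with a fixed float format and JSON with sorted
  keys, so identical configs and seeds reproduce byte-identical outputs.

## Known limitations

- The strictly-greater over-tail makes the 0.05-level overrepresentation
  call mildly anti-conservative on discrete counts (the call region's exact
  probability can exceed 0.05 by up to one probability mass; e.g. 0.060 at
  M=500, N=50, n=60). This is a property of the published tail convention,
  which the package reproduces deliberately; users wanting a conservative
  call can threshold the EASE-style inclusive tail instead.
- PII's mean-vs-sum ambiguity is resolved as mean by default and exposed as
  an option; results at pathway level depend on that choice when pathway
  sizes vary widely.
- The permutation control assumes exchangeability of gene labels under the
  null; heavy ties among term p-values (tiny universes) make q
  conservative.
- Acceptance-scale runs use the reduced problem sizes stated above for the
  synthetic study; statistics at full genome scale are exercised only
  through the closed-form tests (e.g. the 24,070-gene representation
  analysis).
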