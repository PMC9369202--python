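# Methods

## Scope and data model

The pipeline consumes five kinds of inputs: per-replicate ChIP peak tables
(BED-like TSV with a summit column, MACS-style), gene models (GFF3, 1-based
inclusive, converted to 0-based half-open internally), DE tables for genes
and mature miRNAs (TSV: feature_id, log2fc, pvalue, padj, mutant vs
wild-type), a miRNA→target map (TSV), and promoter FASTA (TSS ± 1 kb,
strand-oriented, TSS at the window centre).  Peak calling, expression
estimation and target prediction are upstream of this package: peaks, DE
values and the map are consumed, never computed.

## ChIP peak consolidation and target assignment

Within a replicate, two peaks merge iff their spans overlap and their
summits are within 600 bp, or their spans are disjoint and the summits are
within 300 bp.  The rule is applied as a transitive closure (union-find over
summit-sorted peaks), which makes merging order-independent and idempotent;
the merged peak takes the union span and inherits the summit and
significance of its most significant member (ties resolved toward the
leftmost summit — the rule needs *a* deterministic choice and the most
significant member is the natural summit carrier).

A merged peak becomes high-confidence when the other replicate has a merged
peak whose summit lies within 600 bp (the same distance as the overlap-merge
rule; no separate value is established for replicate support, and the
parameter is configurable).  The retained peak unions its span with the
nearest supporting partner, takes the pair's maximum −log10 p, and must then
pass p < 1e-5.  Order of operations is merge → replicate support →
significance → window assignment; the order is configurable because
reasonable pipelines differ here.

A gene is a candidate target when a high-confidence summit falls in the
strand-oriented window [TSS − 3 kb, TTS + 1 kb], treated as one contiguous
interval including the gene body.  Summit-to-TSS distances are signed in
gene orientation (negative = upstream).  Two summaries mirror the standard
figures: the nearest-summit histogram around the TSS with the fraction of
candidate targets whose nearest summit is within ±0.5 kb, and the
per-summit genic distribution over {upstream, genic, downstream,
intergenic} with precedence upstream > genic > downstream when windows of
distinct genes collide (ties between genes broken by smaller |summit−TSS|).

## Motif scanning

PWMs are read from MEME minimal files (via Bio.motifs); matrices with zero
cells get a 1e-3 pseudocount and are renormalised.  Scanning scores every
window on both strands with log2-odds against a background base
distribution (uniform 0.25 by default); N scores 0 bits.  The minus strand
is scored by reverse-complementing the matrix rather than the sequence, so
a match's reported offset is always the window start relative to the TSS in
gene orientation.  The default match threshold is 80% of the matrix's
maximum attainable score — a conventional operating point when no threshold
is otherwise established — and IUPAC patterns are matched exactly
(equivalently: their 0/1 PWM at threshold = max score).

Over-representation uses an empirical resampling test: total matches in the
foreground promoters are compared against `n_bg_sets` background sets of
matched cardinality and lengths (uniform-random genomic sequence by
default); p = (#{background ≥ observed} + 1)/(n_bg_sets + 1), so p can
never be 0 and a foreground with no matches gives p = 1.  With 999 sets the
floor is 1/1000, matching the conventional p < 0.001 call.

## DE integration

Significance is adjusted p < α with α = 0.05 (raw p optional).  Edge signs
follow loss-of-function logic: up in the mutant ⇒ the TF represses (−1),
down ⇒ activates (+1); a significant feature with log2fc exactly 0 yields
no edge.  miRNA–target co-expression categories: I = miRNA significantly up
with a strict majority of its significant targets down; II = the mirror;
III = significant miRNA whose targets are not majority-anticorrelated
(including no significant targets); unclassified = miRNA not significant.
Only the members of each category are established externally, not the rule,
so the majority-among-significant-targets rule is this package's modelling
choice; ties do not count as a majority.  Family summaries report family
size, number significant, mean log2fc over significant members only (NaN
when none), and direction tallies.

## FFL enumeration and permutation enrichment

With the miRNA→target edge fixed repressive, the map from (sign TF→miRNA,
sign TF→target) to {I1, I2, C3, C4} is the bijection given in the README;
(−, +) is C4.  Loop instances are (significant miRNA, significant target in
its map) pairs; the TF node is single and fixed.  ChIP evidence does not
filter loops — it annotates them: a loop is "direct" when both the miRNA's
hosting gene and the target are ChIP candidate targets.

The null model permutes whole expression tuples (log2fc, p, padj,
significance) among the miRNA nodes and, independently, among the target
nodes, keeping the map fixed; all measured features participate, not only
the DE ones (permuting only DE features is available behind a flag).  With
10,000 shuffles, p(type) = #{count ≥ observed}/10,000 and the randomized
mean is taken over the same shuffles.  The non-strict comparison is
deliberate: an observed count of 0 yields p = 1 exactly (no network can be
called enriched for loops it does not contain) and the test stays valid —
P(p < α) ≤ α under the null — where a strict comparison is anticonservative
whenever the count distribution has large point masses, which it does at
these network sizes.  No add-one correction is applied, so the smallest
attainable p is 0 (reported as such, meaning p < 1/n_shuffles).

Implementation note: states are reduced per node to {null, up, down};
counts for all 10,000 shuffles are computed vectorised over a
(shuffles × edges) state matrix, so a full test on a 30-miRNA × 200-gene
network runs in well under a second.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, one
TF contrast at a time.  Defaults (the study conditions used throughout the
tests): 2 chromosomes × 1.2 Mb; 200 protein-coding genes and 30 miRNA genes
placed without overlap and with enough intergenic room (3 kb + 1 kb windows
plus a 1 kb spacer) that neighbouring candidate windows never collide; 50
bound loci; replicate ChIP summits at the planted motif position with
N(0, 50 bp) jitter and significance uniform on −log10 p ∈ [8, 30]; 10
noise peaks per replicate, placed uniformly and independently per replicate
with −log10 p ∈ [1, 4.9] so they fail the significance filter; promoters
i.i.d. uniform ACGT (chosen so motif-count expectations are analytic; a
GC-weighted background would be a straightforward extension) with one
concrete expansion of YTAATYAW planted at N(−200, 50) bp from the TSS in
bound promoters; planted log2 effects ±|N(2.0, 0.3)| with adjusted p below
α/10; null features N(0, 0.25) with uniform adjusted p, so ~α of nulls are
flagged (p-values are simulated directly rather than derived from count
models, since DE model fitting is out of scope); 40 planted C4 loops spread
over ceil(40/5) = 8 miRNAs (five loops each, echoing the
one-miRNA-family–many-targets structure of real modules), each miRNA
additionally receiving 6 decoy map edges to genes without planted effects.

Planted loop edges are *additional* to the uniform decoy complement.  This
matters for the permutation test's fairness: because every node carries the
same number of background edges, the observed counts of the non-planted
types are exchangeable with the shuffled counts, and the planted edges can
only inflate the null means of I1/C4 (conservative for I1, and C4 is the
signal).  An optional `bg_de_fraction` knob (default 0) makes a fraction of
non-planted features genuinely DE with random sign, for generators that
should mimic the widespread remodelling a strong TF knockout causes.

Every generator draws from a named random stream derived from (seed, stream
name), so outputs are byte-identical under a seed and independent of the
order generators are called in.

What the generator does **not** emulate: read-level noise, fragment-length
effects, GC-biased backgrounds, correlated DE within pathways, multi-TF
regulation, and miRNA-mediated propagation of expression changes to
targets.  Passing tests therefore demonstrate correctness of the rules and
calibration/power of the statistic under clean planted structure, not
performance on real libraries.

## Test and acceptance problem sizes

The suite checks the merge/support/assignment rules against O(n²)
brute-force oracles (1,000 random peaks), the scanner against naive
per-window rescoring and set-expansion matching, and the Monte-Carlo
permutation statistic against exhaustive enumeration of all joint
permutations on ≤4×4 networks.  Statistical checks use the default study
conditions: planted-enrichment recovery over 20 seeds (p(C4) ≤ 0.001 with
the other types non-significant in ≥18), null calibration over 200
structure-free seeds (per-type false-positive rate ≤ 0.08 at p < 0.05),
ChIP recall ≥ 0.95 over 10 jittered noisy seeds, and ≥95% edge-sign
recovery.  These sizes keep the full suite under a minute of compute while
leaving every statistical margin comfortably wide.

## Known limitations

- The replicate-support distance and the motif score threshold are
  conventions, not established values; both are configurable and logged.
- Whether the ±0.5 kb TSS-proximality statistic should use summit or
  any-overlap membership is not resolvable from available descriptions;
  summit membership is implemented.
- Category III is defined by exclusion; alternative rules (fold-change sign
  only) are a flag away but untested against external data.
- The permutation null fixes the map topology; degree-preserving edge
  rewiring is a different (also defensible) null that is not implemented.
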