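# Methods

`circena` implements a circRNA-centric competing-endogenous-RNA (ceRNA)
discovery analysis as a deterministic, desk-scale pipeline.  This note
describes each stage's model and assumptions, the tunable parameters,
what the synthetic data emulate (and deliberately do not), and the
numerical choices made where the design was open.

## Back-splice junction detection

Circular RNAs arise when a downstream splice donor joins covalently to
an upstream acceptor.  In RNA-seq, the only direct evidence is a read
that crosses the back-splice junction (BSJ): its two parts map to the
same chromosome and strand but in *reverse* genomic order.

Detection proceeds in five steps:

1. **Routing.** A read that places full-length on the genome or on a
   spliced transcript with identity ≥ `min_contiguous_identity`
   (default 0.95) is linear and set aside.  All other reads continue.
2. **Split alignment.** Exact k-mer seeding (`seed_kmer` = 16 nt,
   seeds with more than `max_seed_hits` = 50 genomic hits dropped as
   ambiguous) groups hits by diagonal; on each diagonal the
   maximal-scoring ungapped run (match +1 / mismatch −1) is a segment,
   kept when it scores ≥ `min_segment_score` = 20.  Both read
   orientations are aligned; a reverse-complement hit carries strand
   '−'.
3. **Head-to-tail geometry.** A segment pair from one read is a BSJ
   candidate iff: same chromosome; same strand; reference distance ≤
   `max_junction_span_bp` (1 Mb); the segment earlier on the read maps
   strictly downstream of the later one; and the two segments leave a
   read gap of at most `max_read_gap_nt` = 2 or overlap by at most
   `max_junction_overlap_nt` = 35.  Overlap is the signature of
   micro-homology: canonical splice motifs alone make the bases after
   the donor resemble the bases at the acceptor for 4–6 nt, and the
   ungapped extension of each segment then claims the same read bases
   twice.  When the reference is available the boundary is placed at
   the read's *optimal breakpoint* — the split position maximizing
   per-base agreement with the two diagonals — which confines the
   residual error to genuine homology.
4. **Refinement and strand assignment.** Within ±`refine_radius_nt`
   (15 nt), all shifts consistent with the read evidence (homologous
   up to the mismatch budget an extension could have absorbed,
   `(|shift|−1)//2`) are scored by splice-site strength and the best
   one wins; ties break to the smallest shift, then leftmost.  Both
   strand hypotheses are scored and the stronger kept — junction
   geometry alone cannot determine the transcribed strand from an
   unstranded library, but canonical motifs can.
5. **Reporting and quantification.** Candidates merged on (chromosome,
   strand, donor, acceptor) are reported when supported by ≥
   `min_support_reads` = 2 reads with donor+acceptor splice score ≥
   `min_splice_score` = 10 (both inclusive).  Expression is the number
   of reads aligning across the junction of a pseudo-circular
   reference (the circle's 3′ tail concatenated to its 5′ head,
   flank = read length − `min_overhang_nt`) with the
   `min_overhang_nt` = 6 bases flanking the junction all matching on
   both sides.  Requiring the junction-adjacent bases to match exactly
   (rather than counting matches anywhere in the overhang) prevents
   reads from being credited to a junction they merely brush against.

**Splice-site scoring.** Site strength is a position-weight-matrix
log-odds score over the MaxEntScan window conventions: donor = 9-mer
(3 exonic + 6 intronic), acceptor = 23-mer (20 intronic + 3 exonic),
score = Σ log2(p_column(base)/p_background(base)), uniform background.
The default matrices are estimated (pseudocount 0.5) from the
annotated GT–AG introns of the supplied annotation, so the scorer
adapts to the genome at hand; the `SpliceScorer` interface accepts any
object with the two window-scoring methods, so true maximum-entropy
tables can be dropped in.  The reporting threshold of 10 applies to
the donor+acceptor *sum* (configurable).

Circle IDs follow the convention
`chr{c}_{max}_{min}_-{span}` — larger coordinate first, then smaller,
then the negative span — and `parse_circ_id` inverts it exactly.

## Differential expression

Counts are normalized by **median-of-ratios size factors** (rescaled
to geometric mean 1; a positive-counts pseudo-reference is the
fallback for sparse matrices).  **Dispersion** (variance = μ + αμ²) is
estimated per feature by method-of-moments within each group, pooled,
and shrunk toward a fitted trend α(mean) = a₀ + a₁/mean with weight
0.8 on the trend: at 3 samples per group the per-feature estimate is
nearly unbiased but extremely noisy, so the trend carries most of the
weight while the residual share preserves genuine feature-specific
dispersion.  The **test** is a Wald statistic on the difference of log
normalized group means, with delta-method variance (μ + αμ²)/(n·μ²)
per group on the normalized scale, referred to the standard normal —
with dispersions effectively fixed by the trend, the asymptotic
reference is appropriate, and the normalized-scale variance makes the
p-values exactly invariant to global count rescaling absorbed by the
size factors.  Measured type-I error under the null (α = 0.1, 3 vs 3,
2000 features) is 0.049–0.057 at nominal 0.05.

Calls use the published rule: |fold change| > `fc_threshold` = 2
(strict, linear scale, two-sided) AND Benjamini–Hochberg FDR <
`fdr_threshold` = 0.05.  Fold changes use a 0.5 pseudocount;
all-zero features report p = 1 rather than being dropped.

This workflow is **DESeq-criteria-compatible, not DESeq-identical**:
the calling criteria, not any particular implementation's internals,
define the computation.

Auxiliary operations: `term_enrichment` (two-sided Fisher's exact per
term over a user-supplied term→gene map, BH FDR across terms,
significant at FDR < 0.05) and `relative_expression_ddct` (2^−ΔΔCt
with the control group's mean ΔCt as baseline; technical replicates
averaged when a replicate column is present).

## Co-expression networks

Expression for correlation is log2(normalized count + 1); Pearson on
raw negative-binomial counts is dominated by the mean.  An edge joins
two features when the two-sided t-test on r (df = n − 2) gives p <
`correlation_p_threshold` = 0.05 **and** |r| ≥
`correlation_r_threshold` = 0.9 — at n = 6 a p-only rule admits weak
correlations, so the magnitude gate is part of the default edge
definition (both knobs configurable; signed r is stored).  Degree
centrality is the exact incident-edge count.  The **W-core** is the
maximal subnetwork in which every node keeps ≥ W neighbours,
computed by iterative pruning (the graph-theoretic k-core; unique
regardless of order).  **Core regulators** rank nodes by the absolute
degree difference between the two class-restricted networks (built
with identical thresholds); with 3-sample classes the per-class
p-values rest on one degree of freedom, so that output is flagged
exploratory, and the full-cohort network is the default elsewhere.

## MRE prediction

A site requires an exact Watson–Crick match (no G:U in the seed) of
the miRNA 6mer core (positions 2–7) on the target, classified upward:
position-8 pairing → 7mer-m8, an A opposite position 1 → 7mer-A1,
both → 8mer.  Site strength is a transparent affine-gap local
alignment of the full miRNA against the site's 3′-extended window
(miRNA length + 10 nt): Watson–Crick +5, G:U +1, mismatch −3, gap
open −8, gap extend −2, seed positions 2–8 weighted ×2.  A perfect
duplex of a length-L miRNA scores 70 + 5(L − 7).  Defaults for an
interaction: seed class ≥ 7mer and duplex score ≥ 80, i.e. a seed
match plus some 3′-supplementary support.  The constants are recorded
in output metadata; no free-energy model is computed (the scorer
argument is the hook for one).  circRNA targets are scanned on the
circularized sequence (first 30 nt appended) so junction-spanning
sites are found; wrap duplicates are removed by modular position.

## ceRNA triad assembly

A circRNA–miRNA–mRNA triad survives four gates: (i) the miRNA has ≥ 1
qualifying site on both the circRNA and the mRNA; (ii) the circ–mRNA
expression correlation is significant and positive (a sponge and its
target co-vary); (iii) circRNA and mRNA are called DE in the same
direction; (iv) when miRNA expression is available, the miRNA moves
opposite to the pair.  Gate (iv) is optional because miRNA levels are
often measured only by qPCR outside the RNA-seq; gates (iii)–(iv) can
be disabled (`--no-direction-gate`).  Ranking is score =
|r| × min(site counts), a deliberately simple heuristic — the gates,
not the score, carry the inferential weight.

## Synthetic data: what it emulates, and what it does not

The generator produces the full input set with recorded ground truth:

- **Genome/annotation**: one chromosome, 24 non-overlapping 3-exon
  genes on both strands, exons 150–250 nt, introns 80–150 nt.  Every
  intron carries a canonical donor (CAG|GTAAGT) and acceptor
  (pyrimidine tract + CAG|G), giving the annotation-trained PWM its
  signal.  Background composition is i.i.d. uniform A/C/G/T, which
  makes false seed matches calculable and rare at these lengths.
- **Reads**: 100-nt substrings of spliced transcripts (either
  orientation) plus, per planted junction, reads from the circle's
  pseudo-circular junction sequence with both overhangs ≥ 20 nt —
  long enough to seed a 16-mer split alignment and longer than the
  4–6 nt of motif-driven micro-homology that makes shorter-overhang
  reads formally indistinguishable from linear ones.  Substitution
  errors are injected uniformly at the requested rate; there are no
  indels, no quality-value model, no adapters.
- **Counts**: negative-binomial with mean = s_j·q_i·2^(lfc·group) and
  variance = μ + αμ².  Twelve circles and 24 genes, 3 vs 3 design.
  The planted triad's circRNA and target mRNA are both down-regulated
  (log2 FC −1.5) and coupled by a per-replicate latent factor that
  repeats across groups — creating tight co-expression without
  perturbing group means, so the planted fold change is exact.  The
  coupled pair is abundant and near-Poisson: the sponge model
  presumes a well-quantified, tightly co-expressed pair, and sampling
  noise should not decide whether the planted structure exists.
  Decoy circles and mRNAs are DE in the opposite direction or not DE.
- **Sequences**: two shared 7mer-m8 sites are embedded in the triad
  circle's exon and the target's 3′UTR exon, each with a
  3′-supplementary hexamer (miRNA 13–18) and 4-nt spacer — the
  canonical architecture of a functional site, and what lifts a
  planted site (~70–85 for seed-only) above the default duplex
  threshold of 80.  Incidental seed-core matches in the scanned exons
  are scrubbed, and decoy miRNAs are rejection-sampled to have no
  sites on any scanned sequence.

Passing on these data therefore demonstrates that the machinery
recovers planted structure under its own model assumptions at desk
scale.  It does not demonstrate robustness to the things real tissue
RNA-seq adds: indels and structured error, multi-isoform genes and
alternative circle exon usage, repeat-driven ambiguous mappings,
library-size imbalance, batch effects, or compositional effects from
a large DE fraction.

Default problem sizes (24 genes ≈ 27 kb genome, ~1.5k linear reads,
12 junctions, 2000-feature calibration runs, 5-seed end-to-end
replication) were chosen so a full verification pass completes in
minutes on one CPU while every stage still has non-trivial decoys.

## Degenerate inputs and tie-breaking

- Reads shorter than the seed k-mer produce no segments; all-N reads
  align nowhere.  Poly-A (repeat) seeds exceed `max_seed_hits` and
  are dropped, so fully repetitive reads yield nothing rather than
  arbitrary placements.
- Refinement ties break to the smallest absolute shift, then the
  leftmost position; candidate merging sorts by coordinates, so all
  outputs are order-independent and runs are byte-reproducible.
- A circle shorter than twice the quantification flank is rotated,
  not duplicated, so no read can be counted against fabricated
  sequence.
- Zero-variance features are excluded from correlation with a logged
  count; features absent from a class network count as degree 0.
- Empty inputs short-circuit: no reads → zero circles and the
  downstream circ-dependent stages are skipped with a recorded
  reason.

## Known limitations

- The internal aligner is exact-seed + ungapped extension: reads with
  indels near the junction are lost rather than recovered.
- Strand assignment relies on splice-motif asymmetry; on a genome
  without canonical motifs the reported strand is arbitrary between
  the two hypotheses.
- The duplex score is a similarity heuristic, not a thermodynamic
  model; scores are comparable within a run, not against ΔG scales.
- The NB test's normal reference leans on trend-shrunk dispersions;
  with very few features (< ~10) the trend cannot be fitted and the
  raw moment estimates make the test conservative.
- Triad scoring is heuristic by design; downstream users should treat
  the ranked list as candidates for validation, not inference.
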