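# Methods

## Scope and model

`promomine` operationalizes transcriptome-driven promoter discovery in a
bacterial genome. It deliberately starts downstream of read alignment: the
expression input is a gene-level count (or TPM) table, because alignment and
transcript quantification are solved problems with mature tools and the
screen's logic begins at "which genes are strongly transcribed". The
pipeline's scientific content is the chain of filters and reductions
between that table and a ranked, characterized promoter set.

### Expression

TPM is the length-normalized rate `c_i/l_i` rescaled to sum to 10^6. The
effective length is the annotated gene span (end − start); no fragment-length
correction is applied, since the quantity only drives a rank and a
threshold. The activity threshold (default 1000 TPM) is compared strictly
(`>`): a boundary gene at exactly the threshold is not "higher than" it.
Tables already in TPM can be supplied; their column sum is validated to 1%
(warn, not fail, since quantifiers round differently). The invariant
Σ TPM = 10^6 holds to ≤ 1e−9 relative error whenever any count is positive.

### Candidate mining

Exclusion rules, in order, over genes ranked by TPM descending:

- **Feature class.** tRNA genes are excluded (no σ⁷⁰ mRNA promoter
  architecture to recover), and rRNA genes with them — libraries for this
  kind of screen are rRNA-depleted, so rRNA abundances are artifacts.
- **RBS presence.** A gene with no Shine-Dalgarno signal is unlikely to
  report well through a translational fusion. The detector takes the
  strand-respecting 20 nt before the start codon and finds the longest
  contiguous substring of AGGAGG present; a hit requires ≥ 4 matching
  bases (`min_match`), the loosest rule that still rejects most random
  windows (a random 20-mer passes ≈ 18% of the time). Ties on length go to
  the occurrence closest to the start codon.
- **Transcription units.** Adjacent genes on the same contig and strand
  whose spacer (next.start − prev.end) is strictly < 50 nt and whose
  product descriptions have token-set Jaccard similarity ≥ 0.5 are chained
  greedily left-to-right into clusters. Similarity uses lowercased,
  punctuation-stripped tokens; empty products never match; a
  spacer+strand-only mode is available. Because the joining predicate is
  purely pairwise-adjacent, the greedy chaining provably equals connected
  components of the adjacency graph, and the tests verify that equivalence
  against a brute-force oracle. Cluster members are represented by the
  lead gene (first member for +, last for −); a cluster reached through
  any member contributes one candidate, upstream of the lead, ranked by
  the TPM of the member that reached it.

Surviving genes yield candidates: on `+`, the window
`[max(0, start − 500), start)`; on `−`, `[end, min(L, end + 500))`
reverse-complemented. Windows truncate at contig edges (with a warning);
the window may overlap the upstream neighbor's body — no trimming by
default, since the biological claim is only "the promoter lies within
~500 bp upstream". Both a fixed top-N mode (default 97) and a TPM-cutoff
mode are exposed, and filters are applied before taking the top N, so the
returned set always has the stated size when enough genes survive.

### Motif analysis

Position frequency matrices count bases per column over equal-length
sequences; N contributes 0.25 per base so columns always sum to the number
of sequences. Probabilities apply a pseudocount (default 0.5, avoiding
log 0 in information content on small sets):
`p = (counts + pc) / (n + 4 pc)`. Information content per column is
`2 + Σ_b p log2 p` bits, 0 for uniform and 2 for degenerate columns.

The σ⁷⁰ scan enumerates every (−35 window, −10 window) placement with a
spacer in 15–21 nt and scores it as
`2 × matches(TTG core) + matches(TATAAT)`, maximum 12. Only the TTG
trinucleotide of the −35 reference is scored because it is the conserved
core of that element; the remaining −35 bases are too variable to be
informative at this scale. The best pair wins; ties prefer the pair whose
inferred TSS lies closest to the anchor (default: the sequence end, i.e.
the ORF start), then the leftmost pair — a deterministic rule biased
toward promoters positioned to drive the downstream gene. The TSS is
placed 7 nt downstream of the −10 element's end (canonical σ⁷⁰ geometry)
and its base recorded; purine fraction at TSS positions is reported over a
candidate set. Pairs scoring below 6 of 12 are flagged low-confidence
rather than suppressed: strong bacterial promoters are sometimes served by
alternative sigma factors and lack the σ⁷⁰ −10, and a low score is itself
informative. The scan is exhaustive by construction; a test asserts its
output equals an independent enumeration on random sequences.

### Strength assay

Relative activity is RFU/OD600 per timepoint; points with OD ≤ 0 are
dropped. When a promoterless control series is supplied its activity is
interpolated onto the sample grid, subtracted pointwise and floored at 0
(whether the original assay subtracted the control is not knowable from a
strength table alone, so subtraction is the default only when a control is
given). Replicates sharing a grid are averaged pointwise before peak
detection; per-replicate peaks and their sd are reported alongside. The
promoter's relative strength is the maximum of the (mean) activity series,
ties to the earliest time. Gradient classes are either empirical tertiles
of the peak distribution or fixed bounds (default 2000/6000, splitting a
few-hundred-to-ten-thousand activity range into three occupied bands);
both are monotone in the peak by construction. Fold changes versus
reference promoters are peak ratios, kept at full precision with a
2-significant-figure helper for reporting.

## Synthetic data: what it emulates, and what it does not

`generate_genome` lays transcription units left to right on one circular
contig: per-unit strand is random; ~30% of units are operons of 2–4 genes
with intra-operon spacers of 5–49 nt (inside the clustering rule) and
60–500 nt between units (outside it); ~5% of genes are tRNAs; gene lengths
are uniform 300–1100 nt so 200 genes fit a 200 kb contig with margin
(an infeasible request raises before anything is written). Operon members
share a product family name, so their pairwise Jaccard similarity is
≥ 0.5 by construction. 90% of background genes and every lead of a planted
unit receive an AGGAGG ribosome-binding site starting 6–10 nt before the
start codon — a strong unit without an RBS would be invisible to the
screen the generator emulates, so planting promoters without translation
signals would only manufacture unrecoverable truth. About 6% of units get
a planted promoter cassette upstream of their lead: TTGACA, a 15–21 nt
spacer, TATAAT, and a TSS (purine with probability 0.8) 7 nt further,
ending 20–40 nt before the ORF; each consensus position mutates with
probability 0.1, and the retained-match count (quality, 0–12) maps
monotonically to expression strength `400 × (0.4 + 0.6 q/12)`. Background
strengths are lognormal(0, 0.6). With TPM proportional to strength, these
constants put roughly 5% of genes above 1000 TPM — the heavy-tailed
profile in which a few dozen genes carry most transcription — and were
chosen analytically from that target before being checked empirically.

`generate_expression` draws counts with mean proportional to
strength × length, negative-binomial with dispersion 0.1 (Poisson at 0;
exact expectations with `noiseless=True`), plus a small background
strength so zero-strength genes keep a nonzero mean.

`generate_assay` uses logistic growth (K = 6, r = 0.25/h, 4 h lag,
OD₀ = 0.05) and per-cell reporter activity `s · f(t)` with
`f(t) = (1 − e^(−t/τ))(e^(−δt))`, τ = 14 h maturation and δ = 0.006/h slow
decay. A pure saturation curve would peak at the last sample; the decay
term gives the closed-form continuous peak
`t* = τ ln((1 + δτ)/(δτ)) ≈ 35.8 h`, i.e. in stationary phase, matching
how such reporters behave. RFU adds an autofluorescence background of
50 RFU per OD unit and Gaussian noise scaled by OD (per-cell noise is
homoscedastic; constant-RFU noise would explode after division by the
near-zero early OD). The truth sidecar records each construct's noise-free
control-subtracted peak `s · max f`, its grid peak time, and `t*`.

Passing tests on these fixtures show the pipeline's logic is correct under
its own assumptions. They do not show robustness to real-data features the
generator omits: overlapping genes, leaderless transcripts, non-σ⁷⁰
promoters, operon-internal promoters, condition-dependent expression,
codon-usage/GC structure, or plate-reader drift. The planted-recovery
results in particular are near-ceiling because noiseless expression makes
the strong units unambiguous; they validate the filter chain, not promoter
prediction from sequence.

## Numerical and design notes

- Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
  inclusive) and BED converters do the shifting. Features wrapping a
  circular contig's origin are rejected, not silently mishandled.
- Product text for similarity comes from the GFF3 `product` attribute,
  falling back to `Name`, else empty.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generator outputs are byte-identical across runs at a fixed seed.
- "Exact" strength recovery in the tests means to 1e−9 relative error:
  the simulator multiplies by OD where the pipeline later divides, so
  agreement is to floating-point roundoff, not bit-for-bit.
- Problem sizes in the test suite (200-gene genomes, 500-annotation oracle
  sweeps, 1000 random TPM tables, 40 planted motif sequences) keep the
  full suite under a few seconds while leaving the statistical checks
  well-powered.

## Known limitations

- The clustering similarity metric (token Jaccard on product strings) is a
  transparent stand-in for "similar function"; annotations with
  inconsistent vocabularies will under-cluster. The spacer+strand-only
  mode sidesteps this at the cost of over-clustering.
- The σ⁷⁰ scan is consensus-based and scores nothing about alternative
  sigma factors; it flags weak pairs instead of classifying them.
- The RBS detector is a contiguous-match rule, not a free-energy model;
  it is a presence filter, not a translation-rate predictor.
- Whether a fixed top-N or a TPM cutoff better reflects a given screen is
  a study choice; both are exposed and neither is privileged.
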