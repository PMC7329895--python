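# Methods

This note documents the models and procedures implemented in
`mirpollen`, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the design
choices made where the problem left the design genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open on the forward genomic
strand; GFF3 input/output converts to and from 1-based inclusive at the
file boundary, and degradome cleavage positions are read 1-based (the
convention in published cleavage tables). Spliced SAM alignments are
interpreted with a minimum intron of 35 nt and maximum of 6,000 nt
(configurable); records with more than 2 mismatches (NM tag) are
excluded at load time, and a missing NM tag counts as 0 with a warning.

## 3′-end extension

Coverage is pooled **per strand** — 3′-tag protocols are stranded, and
strand separation prevents antisense genes from bleeding coverage into
each other. Positions with depth ≥ `min_depth` (default 1) form exon
blocks. Junction handling applies two filters in a fixed order: first
overlap resolution (among junctions with intersecting intron spans, the
highest-covered wins; ties resolve to the leftmost then shortest, for
determinism), then the skipped-coverage rule (a junction whose coverage
is lower than the mean depth of the nucleotides it would skip is
removed). Surviving junctions whose flanks coincide exactly with block
boundaries join those blocks into one fragment.

A transcript is extended when a same-strand fragment overlaps or abuts
(within `adjacency_gap`, default 0 nt) its 3′-terminal exon and reaches
beyond the annotated terminus. Requiring contact with the terminal exon
avoids chimeric extensions from unrelated downstream coverage. A single
extension is taken per transcript — the fragment with the longest added
region, ties resolved by higher mean depth then leftmost position.
Extensions are truncated at the nearest downstream exon of another
same-strand gene; this guard is logged and keeps a runaway extension
from swallowing a neighbouring gene model.

Classification continues translation in frame through the extension
when the annotated CDS lacks a terminal stop codon: bases up to and
including the first stop extend the CDS (`CDS+3UTR`), no stop anywhere
gives `CDS`, and a pre-existing stop makes the whole extension `3UTR`.
A CDS whose length is not divisible by 3 is flagged and treated as
stop-less, resuming at the dangling frame offset.

Out of scope by design: 5′-end reannotation, novel-gene discovery, and
alternative 3′-isoform calling (one best extension per transcript).

## RNA folding

The built-in folder is a Zuker-style minimum-free-energy dynamic
program over a deliberately reduced nearest-neighbor parameter set:

- stacking energies for all Watson–Crick and G:U pair combinations
  (Turner-like magnitudes, −0.5 … −3.4 kcal/mol);
- hairpin, bulge and internal-loop penalties tabulated by loop size
  with logarithmic extrapolation; internal/bulge loops are capped at 30
  unpaired nucleotides (larger loops are disallowed by the model, the
  standard cap);
- an internal-loop asymmetry penalty of 0.5 kcal/mol per unpaired-base
  difference, capped at 3.0;
- a linear multibranch penalty (3.4 closing + 0.4 per branch; unpaired
  multiloop bases free);
- no dangling ends, coaxial stacking, or special tetraloops.

Energies are integers in tenths of kcal/mol throughout, so the dynamic
program, the traceback, and the exhaustive enumeration oracle
(`enumerate_structures` / `structure_energy` / `enumerate_mfe`) compare
exactly with no floating-point tie ambiguity. The oracle enumerates
every nested structure with canonical pairs and terminal loops ≥ 3 nt
and scores each by explicit loop decomposition; the test suite holds
the dynamic program to exact agreement with it on random sequences up
to 30 nt.

The MFE threshold for hairpin criterion (v) defaults to −35 kcal/mol.
Because kcal/mol scales are model-dependent, the threshold is bound to
the folding backend: the designed synthetic hairpins (~40 bp GC-rich
stems) score far below −35 under the reduced model, while shuffled
decoys and random 111-nt windows stay well above it, so the absolute
threshold separates the classes cleanly under the built-in model just
as it does under the full Turner model. An `RNAfold` backend can be
swapped in where ViennaRNA is available.

## miRNA discovery

Filter cascade order: length (18–24 nt) → collapse → singleton removal
(total abundance ≥ 2) → contaminant screen → genomic alignment →
exonic-alignment removal → hairpin criteria → replicate filter. Each
stage only removes reads; the per-stage report telescopes and is
asserted to do so in tests.

Decisions worth recording:

- The contaminant screen drops a read only when it is an exact
  substring of a record whose RNA type is not miRNA; matching a
  miRNA-typed record retains the read regardless of other matches.
- Exon-overlap removal is strand-agnostic: degradation fragments of an
  mRNA can align to either strand representation of its locus, and the
  conservative choice is to drop both.
- The built-in small-read aligner is an exact-match scan of both
  strands capped at 20 loci per read. It exists so synthetic runs are
  self-contained; real data can enter as pre-aligned SAM.
- "Positioned in a hairpin" (criterion i) is read as: the read interval
  lies within the extent of a single branch-free stem-loop — a maximal
  chain of singly-nested pairs with one terminal loop. "Not located in
  the loop" (criterion iii) is read as *not fully contained* in the
  terminal loop, since mature miRNAs commonly abut the loop by a few
  bases; `strict_loop=True` switches to zero-overlap.
- Criterion (ii)'s denominator is the actual, possibly
  chromosome-clamped window length.
- The replicate filter requires presence (abundance ≥ 1) in **all three
  replicates of at least one (stage, condition) group**; requiring all
  libraries would conflate reproducibility with ubiquitous expression.
- Multi-locus reads yield one sequence-keyed record carrying all loci.
- Names are assigned in lexicographic sequence order with zero-padded
  indices of width max(3, digits of the total); the prefix
  (`solyc-miR`) is configurable.

## Family assignment

Alignment against the hairpin reference is ungapped, sense-strand only,
scored by mismatch count with a floor of ≤ 3 mismatches; all co-optimal
hits (up to 300) are kept. The family is the modal family among
co-optimal hits, ties resolved lexicographically — so the result is
invariant under permutation of the reference. The seed region is mature
positions 2–8 (the standard plant/animal convention). Category 1 by
default requires the read to fully cover the seed (`seed_mode=
"coverage"`); `seed_mode="terminus"` instead asks whether the read's 5′
terminus falls inside the seed, the other defensible reading.

## Target prediction

The expectation score uses integer half-units internally (mismatch 2,
G:U 1, gap 4, doubled at miRNA positions 2–13 counted 1-based from the
5′ end). Alignments are canonical: they never begin or end with a gap
column (such columns only add penalty). The search runs a small dynamic
program over (position, net-shift, gaps-used) states vectorized across
all cDNA offsets, then retraces survivors exactly; tests hold it to
equality with a brute-force enumeration of every ≤ 2-gap alignment.
Inhibition mode is `translation` iff any mismatch or gap touches miRNA
positions 9–11 (a G:U wobble there still counts as pairing). Filters:
expectation ≤ 3, cleavage mode only (unless `allow_translation`), at
most 500 sites per miRNA keeping the lowest expectations. Multiple
sites of one miRNA–mRNA pair remain distinct records. Imported
psRNATarget-style tables pass through the identical filters, which is
the fidelity path when the web service's exact parameterization
matters; built-in scores are a documented surrogate.

Region labels use the majority of site bases; an exact tie goes to the
more 3′ region.

## Expression integration

mRNA counting is union-mode: a read counts for a gene iff its blocks
overlap exons of that gene and of no other; ambiguous and intergenic
reads are tallied per library (assigned + ambiguous + unassigned =
aligned, asserted in tests). Size factors are median-of-ratios over
features with no zero count, falling back to total-count ratios with a
warning.

The built-in differential test normalizes by size factors, transforms
to log2(x+1), and by default applies a **moderated t-statistic**:
per-feature pooled variances are shrunk toward a scaled-inverse-χ²
prior whose scale and degrees of freedom are estimated by method of
moments (trigamma inversion), and the t reference distribution gains
the prior degrees of freedom. With three replicates per group a plain
per-feature Welch test (available as `method="welch"`) is so noisy in
its variance estimate that genuine four-fold changes rarely survive BH
adjustment; sharing variance information across features is what makes
small-replicate count designs workable and is the same principle the
established count-model tools rely on. The test is labelled `builtin`
in all outputs; imported DE tables (`feature, log2fc, pvalue, padj,
contrast`) are the fidelity path and bypass it entirely.

Contrasts are named `later_vs_earlier`; log2 fold change is positive
when abundance is higher in the first-named group. "Regulated" defaults
to padj < 0.05 with no fold-change floor (`--alpha`, `--min-lfc`
expose both). Inverse pairs require set membership in the target table,
significance of both members, and opposite fold-change signs. Term
summaries count distinct target mRNAs per ontology term split by
direction; multi-term mRNAs count in every term; terms below
`min_genes` (default 5) are excluded from the headline column but kept
in the full table.

## Degradome verification

The site context is the site sequence plus 4 nt of flank on each side
(28–30 nt for 20–22-nt sites; clamping at cDNA ends is recorded).
Verification is strict 100 % identity, N never matches. Two modes exist
because cleavage evidence may be published against a different
annotation version than the one that produced the sites:
`sequence_pair` compares the context to a recorded cleavage-region
sequence; `search_in_cdna` searches the context inside the other
study's cDNA and requires the recorded cleavage position to fall inside
a matched span, which tolerates coordinate drift without weakening the
identity requirement.

## Synthetic data

The generator's defaults mirror the shape of a pollen development and
heat-stress study: 3 stages × 2 conditions × 3 biological replicates
(18 libraries), 3′UTR truncations with a geometric tail of median
160 nt, and negative-binomial counts with dispersion 0.1. Scale
parameters (genome size, gene count, read depth) are desk-sized; the
`tiny` preset (200 genes, 3 libraries, pooled 3′-end depth around 100
reads per gene) is the benchmark configuration, chosen so that pooled
coverage is continuous across the truncated span the way deeply
sequenced 3′-tag libraries are in practice.

Per stage the generator emulates: 3′-biased stranded read pileups with
half the reads ending exactly at the true terminus and spliced reads
over final introns, plus a 2 % intergenic noise fraction; intergenic
stem-loops (40-bp GC-rich perfect stems, 5-nt loop) constructed so the
mature-arm read passes all five criteria under the built-in folder —
asserted at generation time with bounded retries — plus shuffled decoy
inserts whose reads reach the folding stage and fail (an accidental
passer is re-labelled planted truth); background read classes that each
exercise exactly one discovery filter (17/25-nt length rejects,
abundance-1 singletons, rRNA-contaminant fragments, exonic degradation
fragments); perfect complementary target sites patched into 3′UTRs
(preferring untruncated genes so target recovery does not depend on
extension success); planted opposite-sign fold changes for selected
miRNA–target pairs, with the recorded truth including every candidate
pair whose members end up with opposite planted signs so exact-recovery
comparisons are well defined; and cleavage records at the position
opposite miRNA bases 10–11 for a configured fraction (75 %) of planted
sites, plus off-site decoy records.

What it does **not** emulate — and what passing tests therefore do not
show about real data: sequencing errors and quality-score structure,
isomiR heterogeneity, imperfect hairpin stems at the margins of the
five criteria, internal priming and antisense artifacts in 3′-tag data,
overdispersion heterogeneity across features, multi-isoform genes, and
cross-mapping between paralogous loci. Results on real libraries depend
on upstream alignment quality and on the annotation's gene boundaries.

Everything derives from one seed (identical configurations are
byte-identical across runs); per-component sub-generators use fixed
offsets of that seed.

## Numerical and degenerate-input choices

- Energy and penalty arithmetic is integer (tenths of kcal/mol; half
  penalty units) to make optima exactly comparable across
  implementations.
- Junction, fragment and hit orderings all carry explicit deterministic
  tie-breaks (coverage, then position, then identifier).
- Empty inputs degrade quietly where the upstream stage may validly
  produce nothing (empty coverage track, empty miRNA set) and loudly
  where configuration is wrong (library missing from the design,
  malformed GFF3 hierarchy, missing table columns — reported with the
  offending name; config validation reports all violations at once).
- The folding dynamic program rejects sequences under 10 nt and any
  non-ACGTU symbol.

## Known limitations

- The built-in folder's reduced parameter set is not the full Turner
  model; absolute MFE values differ from ViennaRNA's and the −35
  threshold should be recalibrated if the backend is swapped.
- The exact-match small-read aligner does not model mismatches or
  quality trimming; real small-RNA data should arrive pre-aligned.
- The moderated test assumes roughly log-scale homoskedastic replicate
  noise after normalization; strong mean–variance trends are only
  partially absorbed by the common prior.
- Degradome verification consumes published cleavage tables; peak
  calling from raw degradome reads and t-plot classification are out of
  scope.
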