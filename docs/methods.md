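# Methods

## Gap model and merging

A gap is any maximal run of `N` in a target sequence (`min_run` = 1,
configurable). Only `N` denotes unknown sequence; lower-case (soft-masked)
bases and IUPAC ambiguity codes other than N are ordinary bases. Runs on the
same sequence separated by ≤ `max_sep` = 500 bp are merged transitively into
one gap record, because flanks extracted between two nearby gaps would be too
short to anchor uniquely and the intervening islands are usually low-quality.
The annotated length *L*₀ of a merged gap is its full span (Ns plus absorbed
islands). Gaps touching a sequence end are reported but flagged `terminal`
and excluded from closure: no outer flank exists on one side, so two-anchor
geometry is impossible.

Summary statistics report the lower-middle element as the median for even
counts — gap lengths are integers and this keeps the median integer-valued
and deterministic — and an exact integer `total_bp` next to the float mean.

## Anchors and alignment

Each non-terminal gap contributes a left and a right flank of up to
`flank_len` = 10,000 bp, truncated so a flank never contains an N (this
simultaneously handles sequence edges, neighbouring gaps, and sub-threshold
N-runs). The default of 10 kb is a compromise: long enough for unique
placement near repeat-dense gaps, short enough not to swallow neighbouring
gaps at the 500 bp merge distance.

Flanks are placed on the donor by a built-in seed-and-extend aligner: a
sorted-hash exact k-mer index (k = 17) of the donor proposes candidate loci
by diagonal voting over sampled query seeds, and each candidate is refined
with edlib infix (glocal) alignment. MAPQ is estimated from the
edit-distance margin between the best and second-best locus (capped at 60;
unique locus → 60; tie → 0), identity as 1 − ed/|query|. Because infix mode
consumes the whole query, `query_cov` is 1.0 for every reported placement;
partially present anchors surface as low identity instead and are dropped by
the `min_identity` = 0.90 / `min_cov` = 0.80 filters. Candidate loci whose
seeds cover less than half the query are discarded before extension — they
cannot reach useful identity and their exact edit distance is expensive to
certify. Precomputed PAF records may be substituted for the built-in
aligner; multi-mapping anchors are resolved by MAPQ (primary = highest MAPQ,
then identity, then lowest coordinate), with an option to discard MAPQ-0
anchors instead.

A pair of primary placements is **concordant** when both lie on one donor
contig and strand, do not overlap, and appear in the order the gap implies
(left upstream of right on `+`, reversed on `-`). Abutting placements are
concordant — the gap closes to length 0 and is reported, not discarded.
Otherwise the pair is discordant with a recorded reason (different contigs,
inconsistent orientation, overlapping, wrong order).

## Scoring

For a concordant pair, the fill is the donor interval strictly between the
inner anchor ends; its length is the predicted gap length *L*g and
*d* = *L*g − *L*₀. The null model for spurious closures places a half-Cauchy
law on the relative deviation *r* = |*d*|/*L*₀:

    Pg(r) = (2/π) · arctan(r/γ),   γ = 0.10 / tan(π·10⁻³/2) ≈ 63.66

γ is fixed by the calibration constraint Pg(0.10) = 10⁻³, i.e. a 10%
deviation is worth exactly 30 Phred. Working on *r* rather than *d* makes
the score scale-free (doubling both *d* and *L*₀ changes nothing), and the
Cauchy tail deliberately decays slowly: Qg ≈ 15 at *r* = 3, so a closure
whose measured length is triple the annotation is penalized but not
annihilated — annotated gap lengths are themselves often order-of-magnitude
estimates. Pg is floored at 10⁻⁶ (Qg capped at 60) so *d* = 0 cannot produce
an infinite score.

The total closure quality is Q = Qg + Qa, with Qa the minimum of the two
anchor MAPQs (a closure is only as reliable as its weaker anchor; a `sum`
combination mode is available). Candidates with Q ≥ 30 (default threshold,
configurable) are accepted.

One-anchor **extensions** arise from single-sided verdicts and from pairs
split across two donor contigs (a contig break inside the gap leaves each
flank anchored at a different contig's terminus). The donor sequence is
continued from the anchor's inner end into the gap until the contig ends or
*L*₀ is reached; the unfilled remainder stays as `residual_N`. Extensions
carry no length evidence, so Qg = 0 and Q = Qa — conservative, and the
`kind` field lets downstream users filter them. When several candidates
exist for one gap, the single highest-Q one is kept (ties: most filled bp,
then donor name).

## Patching

Accepted closures are spliced into the target: full closures replace the
N-run with the fill (reverse-complemented for `-` strand), extensions
replace their side of the gap and keep the residual Ns. All non-gap target
bases are untouched, and re-scanning the patched assembly yields exactly the
unclosed plus residual gaps. AGP v2.1 rows (1-based inclusive, `W`
components for sequence, `N` rows for remaining gaps) record the provenance
of every segment of each patched object.

## Assembly metrics

**NX.** The largest length L such that sequences of length ≥ L sum to at
least x% of the assembly total (N50 at x = 50), computed from the descending
cumulative sum.

**Consensus identity.** 100 × matches / aligned bases over 1-to-1 filtered
alignment blocks; the caller supplies the blocks (e.g. from PAF).

**Mis-join rate.** Scaffolds are tiled with fixed windows (default 100 kb;
a trailing window shorter than half a window is dropped). Each window is
placed on the trusted reference via two ~10 kb probes near its quarter
points; the window is mapped only if both probes agree on reference
sequence, strand, and implied window origin (probe alignment rather than
whole-window alignment is a cost choice — edit-distance refinement grows
quadratically in query length — and a window straddling a chimeric junction
fails the agreement test, implementing the insufficiently-aligned → unmapped
exclusion). Consecutive mapped windows are both flagged when they disagree
on reference sequence or strand, or their reference spacing deviates from
the expected index spacing by more than 2 windows (the tolerance absorbs
moderate indel drift). Rate = 100 × flagged / mapped windows.

**Repeat enrichment.** For each repeat class, the observed fraction of
closed-gap bases covered by the class is compared with length-matched
intervals dropped uniformly on the genome `n_perm` times (default 999),
avoiding excluded regions — typically the genome's own N-gaps, since repeats
are only annotated on sequenced bases. p = (1 + #{perm ≥ observed}) /
(1 + n_perm), one-sided. Classes are tested without multiplicity correction
by default, matching per-class reporting conventions; a Bonferroni flag is
available. Fixed seed + n_perm gives bit-reproducible p-values.

## Synthetic data

`simulate_pair` builds a gap-free truth genome from a seeded uniform base
sampler, optionally salted with labelled tandem-repeat (motif 2–6 bp) and
satellite-like (motif 50–180 bp) tracts so enrichment analysis can be tested
end to end. Planted gaps default to 20 intervals with log-uniform lengths
between 100 bp and 50 kb — mirroring the wide dynamic range of real gap
tables — kept ≥ 25 kb apart and ≥ 15 kb from ends so default flanks never
collide; the default genome is 2 × 5 Mb. The target replaces each interval
with Ns; the donor keeps the true content, optionally perturbed by a planted
length deviation (insertion/deletion at the fill midpoint), uniform
substitution errors, and contig breaks (including a break placed inside a
chosen gap to exercise the extension path). All randomness flows from one
`numpy` Generator, so (seed, config) is bit-reproducible.

`simulate_misjoin` concatenates segments of distinct reference sequences
(translocation chimeras) and/or inverts internal blocks, recording every
junction.

What the simulations do **not** emulate: real repeat structure at gap flanks
(segmental duplications, satellite arrays that defeat unique anchoring),
indel-dominated error profiles, heterozygosity/alt haplotypes, and GC or
coverage biases. Passing the synthetic suites therefore demonstrates
correctness of the geometry, scoring, and bookkeeping — not expected recall
on a real genome, where flank uniqueness is the binding constraint.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; AGP export
  converts to 1-based inclusive.
- Empty gap lists, empty assemblies, and unmapped anchors are ordinary
  results, not errors; zero aligned bases, empty length lists, or
  zero closed-gap bp are errors.
- Deterministic tie-breaks throughout: primary alignments by (MAPQ,
  identity, coordinate); best candidate per gap by (Q, filled bp, donor
  name); merge and detection outputs sorted by (sequence, start).
- Problem sizes in the test suite (10 Mb recovery genome, 1–4 Mb mis-join
  fixtures, 300 kb enrichment genome with 199 permutations × 200 replicates)
  were chosen as the smallest scales at which each property is
  unambiguous — recovery and calibration results are exact or
  seed-deterministic at these sizes.

## Known limitations

- The built-in aligner targets anchor-scale queries (10²–10⁵ bp) against
  donors up to a few hundred Mb in memory; whole-human-genome donors are
  better served by passing minimap2 PAF via `--alignments`.
- No split/chimeric anchor chaining: an anchor contributes only its primary
  placement.
- No iterative re-closure after patching, no use of raw reads, and no
  alt-haplotype-aware closure.
- MAPQ from the built-in aligner is a margin-based estimate, not a
  probability calibrated against a read simulator; at default settings it
  mainly separates unique (60), ambiguous (0), and intermediate placements.
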