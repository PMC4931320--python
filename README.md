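# gapfill

Close N-gaps in a reference genome assembly using a donor *de novo* assembly,
with a Phred-scaled statistical confidence for every closure — plus the
assembly-evaluation toolkit that goes with it (NX statistics, consensus
identity, windowed mis-join rate, and a permutation test for repeat
enrichment in closed gaps).

## Who this is for

Reference assemblies represent unknown sequence as runs of `N`. When a
long-read *de novo* assembly of the same species (the **donor**) is
available, many of those gaps can be resolved: the sequence flanking a gap is
located on the donor, and if both flanks land concordantly on one donor
contig, the donor sequence between them is a candidate gap fill. `gapfill`
implements this anchor-based procedure end to end — gap detection and
merging, flank alignment, concordance filtering, statistical scoring,
assembly patching with AGP output — and ships a fully ground-truthed
synthetic-assembly generator so every stage can be validated without any
external data.

## The closure score

For a gap annotated at length *L*₀ whose concordant anchors imply a donor
fill of length *L*g, define the deviation *d* = *L*g − *L*₀. Under the null
hypothesis that the closure is spurious (a random locus that happens to
flank-match), the relative deviation *r* = |*d*|/*L*₀ follows a heavy-tailed
half-Cauchy law; the concordance probability is

> *P*g = P(|*D*| ≤ |*d*|) = (2/π)·arctan(*r*/γ)

with the scale γ calibrated so that *P*g(0.10) = 10⁻³. The closure quality is
the Phred sum of two independent components,

> *Q* = *Q*g + *Q*a,  *Q*g = −10·log₁₀ *P*g (capped at 60),
> *Q*a = min(anchor MAPQs),

so a 10% length deviation alone is worth exactly 30 — the default acceptance
threshold — while the heavy tail keeps *Q*g positive even when *L*g deviates
two- to three-fold from the annotation (annotated gap sizes are often crude
estimates). Gaps whose two flanks are discordant (different contigs, strands,
overlapping, or out of order) are not fully closed; where only one flank
anchors — or the donor contig ends inside the gap — the anchor is *extended*
into the gap as far as the donor allows, scored by its mapping quality alone
(*Q*g = 0), leaving residual Ns.

## Worked example

Simulate a 1 Mb single-sequence genome with 4 planted gaps and a perfect
donor, then close the gaps:

```sh
$ gapfill simulate pair --seed 17 --out-dir sim --seq-len 1000000 --n-seqs 1 --n-gaps 4
{"out_dir": "sim", "n_gaps": 4, "n_contigs": 1, "seed": 17}

$ gapfill --quiet fill --target sim/target.fa --donor sim/donor.fa --out-prefix run
{
 "n_closures": 4,
 "n_full": 4,
 "n_extensions": 0,
 "bp_filled": 11236,
 "bp_shortened": 0,
 "gap_bp_resolved": 11236,
 "n_gaps": 4,
 "n_candidates": 4,
 "n_accepted": 4
}
```

All 4 gaps (11,236 bp of Ns) closed fully. The per-gap report
(`run.closures.tsv`) shows the geometry and the score decomposition:

```
gap_id  kind  L0    Lg    d  Pg     Qg      Qa      Q        accepted
gap_1   full  289   289   0  1e-06  60.000  60.000  120.000  1
gap_2   full  556   556   0  1e-06  60.000  60.000  120.000  1
gap_3   full  8534  8534  0  1e-06  60.000  60.000  120.000  1
gap_4   full  1857  1857  0  1e-06  60.000  60.000  120.000  1
```

Every closure has *d* = 0 (donor length agrees exactly with the annotation,
so *P*g sits at its 10⁻⁶ floor, *Q*g = 60) and uniquely placed anchors
(*Q*a = 60), well above the threshold of 30. `run.fasta` is the patched
assembly (gap-free here), and `run.agp` records the provenance of every
patched segment in AGP v2.1. The gap landscape alone is available via:

```sh
$ gapfill --quiet gaps --target sim/target.fa --out sim/gaps.bed
{
 "count": 4, "total_bp": 11236, "mean_bp": 2809.0, "median_bp": 556,
 "histogram": {"[100,1000)": 2, "[1000,10000)": 2}, "n_over_10kb": 0
}
```

Assembly QC lives under `gapfill metrics`:

```sh
$ gapfill metrics nx --fasta sim/donor.fa
{"x": 50.0, "nx_bp": 1000000, "n_seqs": 1}
```

plus `metrics identity` (consensus identity from alignment blocks),
`metrics misjoin` (windowed mis-joining rate of scaffolds against a trusted
reference, 100 kb windows by default), and `metrics enrich` (permutation
test for repeat-class enrichment within closed gaps).

Real-genome usage is identical: pass your reference as `--target`, your
de novo assembly as `--donor`, and optionally precomputed anchor placements
as `--alignments anchors.paf` to use an external mapper instead of the
built-in seed-and-extend aligner.

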