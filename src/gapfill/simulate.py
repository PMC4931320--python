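"""Synthetic target/donor assembly pairs with fully known ground truth.

The generator emulates the inputs of reference gap closing: a gap-free truth
genome; a *target* copy with planted intervals replaced by N-runs (the
reference with its gaps); and a *donor* copy (the de novo assembly) that may
carry planted length deviations at the gaps, random base errors, and contig
breaks.  Truth genomes are seeded uniform base samples, optionally salted
with labelled tandem-repeat and satellite-like tracts so the repeat
enrichment analysis can be exercised end to end.  A separate generator
produces chimeric scaffolds with recorded junctions for mis-join testing.

All randomness flows from one ``numpy`` Generator seeded by the caller, so a
given (seed, config) pair is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .assembly_io import SequenceCollection, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedGap:
    seq_name: str
    start: int
    end: int  # interval on the target (and truth) genome; L0 = end - start
    fill: str  # the donor-side content of the gap (length = L0 + deviation)
    deviation: int

    @property
    def L0(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatTract:
    seq_name: str
    start: int
    end: int
    repeat_class: str  # "Simple_repeat" or "Satellite"


@dataclass
class PairConfig:
    """Study conditions for a simulated target/donor pair.

    Defaults model a small but realistic desk-scale experiment: a 10 Mb
    two-sequence genome carrying 20 gaps with log-uniform lengths between
    100 bp and 50 kb (genome gap tables span this range), a donor with no
    base errors, no length deviations and no contig breaks.  Gaps are kept
    >= 25 kb apart and >= 15 kb from sequence ends so default 10 kb flanks
    never collide.
    """

    n_seqs: int = 2
    seq_len: int = 5_000_000
    n_gaps: int = 20
    gap_len_range: tuple[int, int] = (100, 50_000)
    min_gap_sep: int = 25_000
    end_margin: int = 15_000
    deviation_frac: float = 0.0  # planted |Lg - L0| <= frac * L0
    sub_rate: float = 0.0  # donor substitution rate per base
    n_breaks: int = 0  # random donor contig breaks (outside gap fills)
    break_in_gap: int | None = None  # index of a gap to break the donor inside
    n_repeat_tracts: int = 0
    terminal_gap: bool = False  # additionally open a gap at one sequence start


@dataclass
class SimulationTruth:
    seed: int
    truth: SequenceCollection
    gaps: list[PlantedGap]
    repeats: list[RepeatTract]
    donor_breaks: list[tuple[str, int]]
    config: PairConfig

    def gaps_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, g in enumerate(self.gaps):
                fh.write(f"{g.seq_name}\t{g.start}\t{g.end}\tplanted_{i + 1}\t{g.L0}\n")

    def repeats_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in self.repeats:
                fh.write(f"{t.seq_name}\t{t.start}\t{t.end}\t{t.repeat_class}\n")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "config": asdict(self.config),
            "gaps": [asdict(g) for g in self.gaps],
            "repeats": [asdict(t) for t in self.repeats],
            "donor_breaks": [list(b) for b in self.donor_breaks],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _plant_repeats(rng: np.random.Generator, seqs: dict[str, str],
                   n_tracts: int) -> list[RepeatTract]:
    tracts: list[RepeatTract] = []
    names = list(seqs)
    for _ in range(n_tracts):
        name = names[rng.integers(0, len(names))]
        if rng.random() < 0.5:
            motif_len, cls = int(rng.integers(2, 7)), "Simple_repeat"
        else:
            motif_len, cls = int(rng.integers(50, 180)), "Satellite"
        motif = _random_seq(rng, motif_len)
        copies = int(rng.integers(10, 40))
        tract = (motif * copies)[: motif_len * copies]
        L = len(seqs[name])
        if len(tract) >= L:
            continue
        pos = int(rng.integers(0, L - len(tract)))
        seqs[name] = seqs[name][:pos] + tract + seqs[name][pos + len(tract):]
        tracts.append(RepeatTract(name, pos, pos + len(tract), cls))
    return tracts


def _sample_gap_intervals(rng: np.random.Generator, cfg: PairConfig,
                          names: list[str]) -> list[tuple[str, int, int]]:
    lo, hi = cfg.gap_len_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_gaps))
    lengths = np.maximum(lengths.astype(int), 1)
    chosen: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out = []
    for L in lengths:
        for _attempt in range(1000):
            name = names[rng.integers(0, len(names))]
            span_lo = cfg.end_margin
            span_hi = cfg.seq_len - cfg.end_margin - int(L)
            if span_hi <= span_lo:
                continue
            s = int(rng.integers(span_lo, span_hi))
            e = s + int(L)
            if all(e + cfg.min_gap_sep <= a or b + cfg.min_gap_sep <= s
                   for a, b in chosen[name]):
                chosen[name].append((s, e))
                out.append((name, s, e))
                break
        else:
            raise ValueError("could not place all gaps; genome too small for config")
    return sorted(out)


def simulate_pair(seed: int, config: PairConfig | None = None,
                  ) -> tuple[SequenceCollection, SequenceCollection, SimulationTruth]:
    """Generate (target with N-gaps, donor assembly, truth table)."""
    cfg = config or PairConfig()
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(cfg.n_seqs)]
    seqs = {n: _random_seq(rng, cfg.seq_len) for n in names}
    repeats = _plant_repeats(rng, seqs, cfg.n_repeat_tracts)
    truth = SequenceCollection(dict(seqs), validate=False)

    intervals = _sample_gap_intervals(rng, cfg, names)
    if cfg.terminal_gap:
        intervals = [(names[0], 0, 500)] + [iv for iv in intervals if iv[0] != names[0] or iv[1] > 1000]
        intervals.sort()

    gaps: list[PlantedGap] = []
    target_seqs = dict(seqs)
    donor_parts: dict[str, list[str]] = {}
    # donor is rebuilt per sequence so planted deviations shift later coords only
    gap_fill_spans: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for name in names:
        ivals = [iv for iv in intervals if iv[0] == name]
        t = seqs[name]
        t_parts, d_parts = [], []
        cursor = 0
        for _, s, e in ivals:
            L0 = e - s
            fill = t[s:e]
            dev = 0
            if cfg.deviation_frac > 0:
                dev = int(round(L0 * rng.uniform(-cfg.deviation_frac, cfg.deviation_frac)))
                dev = max(dev, 1 - L0)
            if dev > 0:
                mid = L0 // 2
                fill = fill[:mid] + _random_seq(rng, dev) + fill[mid:]
            elif dev < 0:
                mid = (L0 + dev) // 2
                fill = fill[:mid] + fill[mid - dev:]
            t_parts.append(t[cursor:s])
            t_parts.append("N" * L0)
            d_parts.append(t[cursor:s])
            fill_lo = sum(len(p) for p in d_parts)
            d_parts.append(fill)
            gap_fill_spans[name].append((fill_lo, fill_lo + len(fill)))
            gaps.append(PlantedGap(name, s, e, fill, dev))
            cursor = e
        t_parts.append(t[cursor:])
        d_parts.append(t[cursor:])
        target_seqs[name] = "".join(t_parts)
        donor_parts[name] = d_parts

    donor_seqs = {n: "".join(p) for n, p in donor_parts.items()}

    # donor base errors (substitutions only; the donor stands for a polished
    # long-read consensus, whose residual errors are mostly substitutions here)
    if cfg.sub_rate > 0:
        for name in names:
            arr = np.frombuffer(donor_seqs[name].encode(), dtype=np.uint8).copy()
            n_sub = rng.binomial(arr.size, cfg.sub_rate)
            pos = rng.choice(arr.size, size=n_sub, replace=False)
            shift = rng.integers(1, 4, size=n_sub)
            idx = {65: 0, 67: 1, 71: 2, 84: 3}
            lut = np.zeros(256, dtype=np.uint8)
            for b, v in idx.items():
                lut[b] = v
            new = (lut[arr[pos]] + shift) % 4
            arr[pos] = np.frombuffer(b"ACGT", dtype=np.uint8)[new]
            donor_seqs[name] = arr.tobytes().decode()

    # contig breaks: random positions, plus an optional break inside one gap
    breaks: list[tuple[str, int]] = []
    for _ in range(cfg.n_breaks):
        name = names[rng.integers(0, len(names))]
        breaks.append((name, int(rng.integers(1, len(donor_seqs[name]) - 1))))
    if cfg.break_in_gap is not None:
        g = gaps[cfg.break_in_gap]
        lo, hi = _fill_span(gaps, gap_fill_spans, cfg.break_in_gap)
        breaks.append((g.seq_name, (lo + hi) // 2))

    donor_records: dict[str, str] = {}
    contig_no = 0
    for name in names:
        cuts = sorted(p for n, p in breaks if n == name)
        bounds = [0] + cuts + [len(donor_seqs[name])]
        for a, b in zip(bounds, bounds[1:]):
            if b <= a:
                continue
            contig_no += 1
            donor_records[f"contig_{contig_no}"] = donor_seqs[name][a:b]

    target = SequenceCollection(target_seqs, validate=False)
    donor = SequenceCollection(donor_records, validate=False)
    truth_rec = SimulationTruth(seed=seed, truth=truth, gaps=gaps,
                                repeats=repeats, donor_breaks=breaks, config=cfg)
    return target, donor, truth_rec


def _fill_span(gaps: list[PlantedGap], spans: dict[str, list[tuple[int, int]]],
               gap_index: int) -> tuple[int, int]:
    g = gaps[gap_index]
    same_seq = [i for i, pg in enumerate(gaps) if pg.seq_name == g.seq_name]
    return spans[g.seq_name][same_seq.index(gap_index)]


@dataclass
class MisjoinConfig:
    """Chimeric-scaffold generator settings.

    Each chimeric scaffold concatenates one segment from each of two distinct
    reference sequences; inversion scaffolds flip an internal block of an
    otherwise collinear scaffold.  Junction positions are recorded as truth.
    """

    n_refs: int = 2
    ref_len: int = 2_000_000
    n_chimeric: int = 1
    n_collinear: int = 1
    segment_len: int = 1_000_000
    inversion: tuple[int, int] | None = None  # block on the first collinear scaffold


@dataclass(frozen=True)
class Junction:
    scaffold: str
    pos: int
    kind: str  # "translocation" or "inversion"


def simulate_misjoin(seed: int, config: MisjoinConfig | None = None,
                     ) -> tuple[SequenceCollection, SequenceCollection, list[Junction]]:
    """Generate (scaffolds, reference, truth junctions) for mis-join testing."""
    cfg = config or MisjoinConfig()
    rng = np.random.default_rng(seed)
    refs = {f"ref{i + 1}": _random_seq(rng, cfg.ref_len) for i in range(cfg.n_refs)}
    ref_names = list(refs)
    scaffolds: dict[str, str] = {}
    junctions: list[Junction] = []
    sc_no = 0
    for _ in range(cfg.n_chimeric):
        sc_no += 1
        a, b = rng.choice(cfg.n_refs, size=2, replace=False)
        seg = cfg.segment_len
        name = f"scaffold_{sc_no}"
        scaffolds[name] = refs[ref_names[a]][:seg] + refs[ref_names[b]][-seg:]
        junctions.append(Junction(name, seg, "translocation"))
    for i in range(cfg.n_collinear):
        sc_no += 1
        name = f"scaffold_{sc_no}"
        src = refs[ref_names[int(rng.integers(0, cfg.n_refs))]]
        if i == 0 and cfg.inversion is not None:
            lo, hi = cfg.inversion
            scaffolds[name] = src[:lo] + revcomp(src[lo:hi]) + src[hi:]
            junctions.append(Junction(name, lo, "inversion"))
            junctions.append(Junction(name, hi, "inversion"))
        else:
            scaffolds[name] = src
    return (SequenceCollection(scaffolds, validate=False),
            SequenceCollection(refs, validate=False), junctions)
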