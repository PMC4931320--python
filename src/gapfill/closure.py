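"""Gap closure: geometry inference, concordance scoring, and assembly patching.

A gap of annotated length ``L0`` whose flanks map concordantly to the donor
implies a predicted gap length ``Lg`` (the donor distance between the inner
anchor ends) and a deviation ``d = Lg - L0``.  The closure confidence is the
Phred sum of two independent components:

* ``Qg = -10*log10(Pg)`` — where ``Pg`` is the probability that a *spurious*
  closure would show a relative length deviation ``r = |d|/L0`` at least as
  concordant as observed.  The null on ``r`` is a half-Cauchy, whose scale is
  calibrated so a 10% deviation scores exactly the default acceptance
  threshold of 30; its heavy tail keeps Qg moderate even when the predicted
  length is two to three times the annotation, because annotated gap lengths
  are themselves often crude estimates.
* ``Qa`` — the anchor mapping component: the minimum MAPQ of the two anchors
  (a closure is only as reliable as its weaker anchor).

``Q = Qg + Qa``; candidates with ``Q >=`` the threshold are accepted and
patched into the target.  One-anchor verdicts yield *extensions*: the donor
sequence continues from the inner anchor end into the gap as far as the donor
contig (or L0) allows, carrying no length evidence (Qg = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from scipy.stats import halfcauchy

from .align import Alignment, KmerIndexAligner
from .anchors import (DEFAULT_FLANK_LEN, AnchorPair, DiscordReason, PairStatus,
                      PairVerdict, align_to_source, classify_anchor_pair,
                      extract_anchors)
from .assembly_io import (GapRecord, SequenceCollection, detect_gaps,
                          merge_gaps, revcomp)

DEFAULT_THRESHOLD = 30.0
Q_CAP = 60.0
PG_FLOOR = 1e-6


@dataclass(frozen=True)
class GapNullModel:
    """Half-Cauchy null on the relative deviation r = |d|/L0 of spurious closures.

    ``scale`` is set so that ``Pg(flex) = pg_at_flex``; with the defaults
    (flex 0.10, Pg 1e-3) a 10% deviation is worth exactly 30 Phred.
    ``pg_floor`` caps the evidence from a perfect length match (Qg <= 60).
    """

    flex: float = 0.10
    pg_at_flex: float = 1e-3
    pg_floor: float = PG_FLOOR

    @property
    def scale(self) -> float:
        return self.flex / math.tan(math.pi * self.pg_at_flex / 2.0)


def gap_concordance_prob(d: int, L0: int, model: GapNullModel | None = None) -> float:
    """P(|D| <= |d|) under the spurious-closure null; small = high confidence.

    Symmetric in the sign of ``d`` and depends on it only through the relative
    deviation ``|d|/L0``, so absolute deviations are judged against gap size.
    """
    if L0 < 1:
        raise ValueError(f"L0 must be >= 1, got {L0}")
    model = model or GapNullModel()
    r = abs(d) / L0
    pg = float(halfcauchy.cdf(r, scale=model.scale))
    return min(1.0, max(pg, model.pg_floor))


def phred(p: float, cap: float = Q_CAP) -> float:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return min(cap, -10.0 * math.log10(p))


def closure_quality(pg: float, anchor_mapqs: list[int] | tuple[int, ...],
                    q_cap: float = Q_CAP,
                    combine: str = "min") -> tuple[float, float, float]:
    """(Qg, Qa, Q): Phred-scaled length concordance, anchor mapping, and sum.

    ``combine`` selects how multiple anchor MAPQs collapse into Qa:
    ``min`` (default — weakest link) or ``sum`` (independence across anchors).
    """
    if any(m < 0 for m in anchor_mapqs):
        raise ValueError("MAPQ values must be non-negative")
    qg = phred(pg, cap=q_cap)
    if not anchor_mapqs:
        qa = 0.0
    elif combine == "min":
        qa = float(min(anchor_mapqs))
    elif combine == "sum":
        qa = float(sum(anchor_mapqs))
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    qa = min(qa, q_cap)
    return qg, qa, qg + qa


class ClosureKind(str, Enum):
    FULL = "full"
    EXTEND_LEFT = "extend_left"
    EXTEND_RIGHT = "extend_right"


@dataclass(frozen=True)
class ClosureCandidate:
    gap_id: str
    kind: ClosureKind
    seq_name: str
    target_start: int
    target_end: int
    donor_name: str
    donor_start: int
    donor_end: int
    strand: str
    L0: int
    Lg: int
    d: int
    Pg: float
    Qg: float
    Qa: float
    Q: float
    accepted: bool
    residual_N: int = 0

    def fill_seq(self, donor: SequenceCollection) -> str:
        seq = donor[self.donor_name][self.donor_start:self.donor_end]
        return revcomp(seq) if self.strand == "-" else seq


def infer_gap_length(verdict: PairVerdict, gap: GapRecord) -> tuple[int, int, tuple[str, int, int]]:
    """(Lg, d, donor interval) between the inner anchor ends, strand-normalized.

    On '+' the fill is donor[left.end : right.start]; on '-' the anchors map in
    reversed order and the fill is donor[right.end : left.start] (to be
    reverse-complemented on insertion).
    """
    if verdict.status is not PairStatus.CONCORDANT:
        raise ValueError(f"gap {gap.gap_id}: verdict is {verdict.status.value}, not concordant")
    la, ra = verdict.left, verdict.right
    if la.strand == "+":
        lo, hi = la.donor_end, ra.donor_start
    else:
        lo, hi = ra.donor_end, la.donor_start
    lg = hi - lo
    return lg, lg - gap.L0, (la.donor_name, lo, hi)


@dataclass
class GfaParams:
    """Tunable knobs of the closure pipeline (defaults are the standard run)."""

    min_run: int = 1
    max_sep: int = 500
    flank_len: int = DEFAULT_FLANK_LEN
    threshold: float = DEFAULT_THRESHOLD
    min_identity: float = 0.90
    min_cov: float = 0.80
    mapq_combine: str = "min"
    discard_mapq0: bool = False
    null_model: GapNullModel = field(default_factory=GapNullModel)


@dataclass
class GfaResult:
    gaps: list[GapRecord]
    anchors: list[AnchorPair]
    verdicts: list[PairVerdict]
    candidates: list[ClosureCandidate]

    @property
    def accepted(self) -> list[ClosureCandidate]:
        return [c for c in self.candidates if c.accepted]


def _extension_candidate(aln: Alignment, kind: ClosureKind, gap: GapRecord,
                         donor: SequenceCollection,
                         params: GfaParams) -> ClosureCandidate | None:
    """Extend one mapped anchor into the gap as far as the donor allows."""
    contig_len = len(donor[aln.donor_name])
    L0 = gap.L0
    # the donor continues past the anchor's inner end, toward the gap interior
    inward_right = (kind is ClosureKind.EXTEND_LEFT) == (aln.strand == "+")
    if inward_right:
        lo = aln.donor_end
        hi = min(contig_len, lo + L0)
    else:
        hi = aln.donor_start
        lo = max(0, hi - L0)
    ext_len = hi - lo
    if ext_len <= 0:
        return None
    residual = L0 - ext_len
    if kind is ClosureKind.EXTEND_LEFT:
        t_lo, t_hi = gap.start, gap.start + ext_len
    else:
        t_lo, t_hi = gap.end - ext_len, gap.end
    # one anchor gives no length evidence: Qg = 0, confidence rests on MAPQ
    qg, qa, q = 0.0, min(float(aln.mapq), Q_CAP), 0.0
    q = qg + qa
    return ClosureCandidate(
        gap_id=gap.gap_id, kind=kind, seq_name=gap.seq_name,
        target_start=t_lo, target_end=t_hi,
        donor_name=aln.donor_name, donor_start=lo, donor_end=hi,
        strand=aln.strand, L0=L0, Lg=ext_len, d=ext_len - L0,
        Pg=1.0, Qg=qg, Qa=qa, Q=q,
        accepted=q >= params.threshold, residual_N=residual,
    )


def call_closures(target: SequenceCollection, donor: SequenceCollection,
                  params: GfaParams | None = None,
                  precomputed: dict[str, list[Alignment]] | None = None,
                  engine: KmerIndexAligner | None = None) -> GfaResult:
    """Run the whole closure pipeline: detect → merge → anchor → align →
    classify → infer → score.  Returns every candidate, accepted or not."""
    params = params or GfaParams()
    gaps = merge_gaps(detect_gaps(target, params.min_run), params.max_sep)
    anchors = extract_anchors(target, gaps, params.flank_len)
    if precomputed is None and engine is None and anchors:
        engine = KmerIndexAligner(donor)
    alns = align_to_source(anchors, donor, engine=engine, target=target,
                           precomputed=precomputed,
                           min_identity=params.min_identity,
                           min_cov=params.min_cov)
    if params.discard_mapq0:
        alns = {k: [a for a in v if a.mapq > 0] for k, v in alns.items()}
    gaps_by_id = {g.gap_id: g for g in gaps}
    verdicts, candidates = [], []
    for pair in anchors:
        gap = gaps_by_id[pair.gap_id]
        verdict = classify_anchor_pair(pair.gap_id,
                                       alns.get(f"{pair.gap_id}/L", []),
                                       alns.get(f"{pair.gap_id}/R", []))
        verdicts.append(verdict)
        if verdict.status is PairStatus.CONCORDANT:
            lg, d, (dname, dlo, dhi) = infer_gap_length(verdict, gap)
            pg = gap_concordance_prob(d, gap.L0, params.null_model)
            mapqs = [verdict.left.mapq, verdict.right.mapq]
            qg, qa, q = closure_quality(pg, mapqs, combine=params.mapq_combine)
            candidates.append(ClosureCandidate(
                gap_id=gap.gap_id, kind=ClosureKind.FULL,
                seq_name=gap.seq_name, target_start=gap.start, target_end=gap.end,
                donor_name=dname, donor_start=dlo, donor_end=dhi,
                strand=verdict.left.strand, L0=gap.L0, Lg=lg, d=d,
                Pg=pg, Qg=qg, Qa=qa, Q=q, accepted=q >= params.threshold,
                residual_N=0,
            ))
        else:
            # one-anchor extensions: single-sided verdicts, and pairs split
            # across two donor contigs (a contig break inside the gap leaves
            # each flank anchored at a different contig's terminus)
            sides = []
            if verdict.status is PairStatus.SINGLE_LEFT:
                sides = [(verdict.left, ClosureKind.EXTEND_LEFT)]
            elif verdict.status is PairStatus.SINGLE_RIGHT:
                sides = [(verdict.right, ClosureKind.EXTEND_RIGHT)]
            elif (verdict.status is PairStatus.DISCORDANT
                  and verdict.reason is DiscordReason.DIFFERENT_CONTIGS):
                sides = [(verdict.left, ClosureKind.EXTEND_LEFT),
                         (verdict.right, ClosureKind.EXTEND_RIGHT)]
            for aln, kind in sides:
                cand = _extension_candidate(aln, kind, gap, donor, params)
                if cand is not None:
                    candidates.append(cand)
    # one candidate per gap: highest Q, then most filled bp, then donor name
    best: dict[str, ClosureCandidate] = {}
    for c in candidates:
        cur = best.get(c.gap_id)
        key = (c.Q, c.Lg - c.residual_N, c.donor_name)
        if cur is None or key > (cur.Q, cur.Lg - cur.residual_N, cur.donor_name):
            best[c.gap_id] = c
    kept = sorted(best.values(), key=lambda c: (c.seq_name, c.target_start))
    return GfaResult(gaps=gaps, anchors=anchors, verdicts=verdicts, candidates=kept)


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 component line (1-based inclusive object coordinates)."""

    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # W (sequence) or N (gap of known size)
    # W rows: component_id, component_beg, component_end, orientation
    # N rows: gap_length, gap_type, linkage, linkage_evidence
    fields: tuple

    def to_line(self) -> str:
        return "\t".join(
            str(x) for x in
            (self.object, self.object_beg, self.object_end,
             self.part_number, self.component_type, *self.fields)
        )


def apply_patches(target: SequenceCollection,
                  closures: list[ClosureCandidate],
                  donor: SequenceCollection,
                  all_gaps: list[GapRecord] | None = None,
                  ) -> tuple[SequenceCollection, list[AgpRow], dict]:
    """Splice accepted closures into the target and describe the result as AGP.

    Full closures replace the N-run with the (strand-normalized) donor fill;
    extensions replace the anchored portion of the gap and keep ``residual_N``
    Ns.  All non-gap target bases are untouched.  Returns the patched assembly,
    AGP rows for the patched objects, and a totals report.
    """
    by_seq: dict[str, list[ClosureCandidate]] = {}
    for c in closures:
        if not c.accepted:
            raise ValueError(f"closure for {c.gap_id} was not accepted")
        by_seq.setdefault(c.seq_name, []).append(c)
    for seq_name, cs in by_seq.items():
        cs.sort(key=lambda c: c.target_start)
        for a, b in zip(cs, cs[1:]):
            if b.target_start < a.target_end:
                raise ValueError(
                    f"overlapping closures on {seq_name}: {a.gap_id} and {b.gap_id}")

    gap_ivals: dict[str, list[tuple[int, int]]] = {}
    for g in all_gaps or []:
        gap_ivals.setdefault(g.seq_name, []).append((g.start, g.end))

    patched: dict[str, str] = {}
    agp: list[AgpRow] = []
    bp_filled = 0
    bp_shortened = 0
    n_full = n_ext = 0

    for seq_name, seq in target.records.items():
        cs = by_seq.get(seq_name, [])
        # parts: ("tseq", target interval) | ("fill", candidate) | ("gap", bp)
        parts: list[tuple[str, object]] = []
        cursor = 0
        for c in cs:
            if c.kind is ClosureKind.FULL:
                pre = seq[cursor:c.target_start]
                if pre:
                    parts.append(("tseq", (cursor, c.target_start)))
                parts.append(("fill", c))
                if c.Lg < c.L0:
                    bp_shortened += c.L0 - c.Lg
                bp_filled += c.donor_end - c.donor_start
                n_full += 1
                cursor = c.target_end
            else:
                # extension: donor fill on its side, residual Ns on the other;
                # full gap bounds follow from the candidate geometry
                if c.kind is ClosureKind.EXTEND_LEFT:
                    g_lo, g_hi = c.target_start, c.target_start + c.L0
                else:
                    g_lo, g_hi = c.target_end - c.L0, c.target_end
                if seq[cursor:g_lo]:
                    parts.append(("tseq", (cursor, g_lo)))
                if c.kind is ClosureKind.EXTEND_LEFT:
                    parts.append(("fill", c))
                    if c.residual_N:
                        parts.append(("gap", c.residual_N))
                else:
                    if c.residual_N:
                        parts.append(("gap", c.residual_N))
                    parts.append(("fill", c))
                bp_filled += c.donor_end - c.donor_start
                n_ext += 1
                cursor = g_hi
        if seq[cursor:]:
            parts.append(("tseq", (cursor, len(seq))))

        out_chunks: list[str] = []
        obj_pos = 0
        part_no = 0
        obj_name = seq_name
        for kind, payload in parts:
            part_no += 1
            if kind == "tseq":
                lo, hi = payload
                chunk = seq[lo:hi]
                agp.append(AgpRow(obj_name, obj_pos + 1, obj_pos + len(chunk),
                                  part_no, "W",
                                  (f"{seq_name}", lo + 1, hi, "+")))
            elif kind == "fill":
                c = payload
                chunk = c.fill_seq(donor)
                agp.append(AgpRow(obj_name, obj_pos + 1, obj_pos + len(chunk),
                                  part_no, "W",
                                  (c.donor_name, c.donor_start + 1,
                                   c.donor_end, c.strand)))
            else:  # residual or untouched gap
                chunk = "N" * payload
                agp.append(AgpRow(obj_name, obj_pos + 1, obj_pos + len(chunk),
                                  part_no, "N",
                                  (payload, "scaffold", "yes", "unspecified")))
            out_chunks.append(chunk)
            obj_pos += len(chunk)
        patched[seq_name] = "".join(out_chunks)

    report = {
        "n_closures": len(closures),
        "n_full": n_full,
        "n_extensions": n_ext,
        "bp_filled": bp_filled,
        "bp_shortened": bp_shortened,
        "gap_bp_resolved": sum(c.L0 - c.residual_N for c in closures),
    }
    return SequenceCollection(patched, validate=False), agp, report


def write_agp(rows: list[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def write_closure_report(candidates: list[ClosureCandidate], path: str | Path) -> None:
    """TSV report of every closure candidate, accepted or not."""
    cols = ("gap_id", "kind", "seq_name", "target_start", "target_end",
            "donor_name", "donor_start", "donor_end", "strand",
            "L0", "Lg", "d", "Pg", "Qg", "Qa", "Q", "accepted", "residual_N")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            fh.write("\t".join([
                c.gap_id, c.kind.value, c.seq_name, str(c.target_start),
                str(c.target_end), c.donor_name, str(c.donor_start),
                str(c.donor_end), c.strand, str(c.L0), str(c.Lg), str(c.d),
                f"{c.Pg:.6g}", f"{c.Qg:.3f}", f"{c.Qa:.3f}", f"{c.Q:.3f}",
                str(int(c.accepted)), str(c.residual_N),
            ]) + "\n")
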