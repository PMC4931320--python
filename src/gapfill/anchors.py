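"""Gap-flank anchor extraction, mapping to the donor, and concordance rules.

For each non-terminal gap the sequence immediately upstream (left anchor) and
downstream (right anchor) of the N-run is extracted and placed on the donor
assembly.  A pair is *concordant* when both anchors land on one donor contig,
on the same strand, without overlap, in the order the gap implies; the donor
sequence between their inner ends is then the candidate gap fill.  Pairs are
otherwise discarded as discordant (inconsistent orientation, different
contigs, overlapping, or wrong order), and single-sided placements feed the
one-anchor extension path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .align import Alignment, KmerIndexAligner
from .assembly_io import GapRecord, SequenceCollection

MIN_FLANK_LEN = 50
DEFAULT_FLANK_LEN = 10_000


@dataclass(frozen=True)
class AnchorPair:
    """The two N-free target intervals flanking one gap.

    Flanks are truncated where the sequence edge, an adjacent gap, or any
    stray N lies closer than ``flank_len``; an empty interval (start == end)
    means no usable flank on that side.
    """

    gap_id: str
    seq_name: str
    left_start: int
    left_end: int  # == gap.start
    right_start: int  # == gap.end
    right_end: int
    flank_len: int

    @property
    def left_len(self) -> int:
        return self.left_end - self.left_start

    @property
    def right_len(self) -> int:
        return self.right_end - self.right_start

    def left_seq(self, asm: SequenceCollection) -> str:
        return asm[self.seq_name][self.left_start:self.left_end]

    def right_seq(self, asm: SequenceCollection) -> str:
        return asm[self.seq_name][self.right_start:self.right_end]


class PairStatus(str, Enum):
    CONCORDANT = "concordant_two_anchor"
    SINGLE_LEFT = "single_left"
    SINGLE_RIGHT = "single_right"
    DISCORDANT = "discordant"
    UNMAPPED = "unmapped"


class DiscordReason(str, Enum):
    NONE = "none"
    INCONSISTENT_ORIENTATION = "inconsistent_orientation"
    DIFFERENT_CONTIGS = "different_contigs"
    OVERLAPPING = "overlapping"
    WRONG_ORDER = "wrong_order"


@dataclass(frozen=True)
class PairVerdict:
    gap_id: str
    status: PairStatus
    reason: DiscordReason = DiscordReason.NONE
    left: Alignment | None = None
    right: Alignment | None = None


def extract_anchors(asm: SequenceCollection, gaps: list[GapRecord],
                    flank_len: int = DEFAULT_FLANK_LEN) -> list[AnchorPair]:
    """One anchor pair per non-terminal gap; flanks never contain N.

    The left flank is the longest N-free suffix of the ``flank_len`` window
    upstream of the gap (symmetrically for the right), which truncates at
    sequence edges, adjacent gaps, and sub-threshold N-runs alike.
    """
    if flank_len < MIN_FLANK_LEN:
        raise ValueError(f"flank_len must be >= {MIN_FLANK_LEN}")
    pairs = []
    for gap in gaps:
        if gap.seq_name not in asm:
            raise KeyError(f"gap {gap.gap_id} references unknown sequence {gap.seq_name!r}")
        seq = asm[gap.seq_name]
        if gap.end > len(seq):
            raise ValueError(f"gap {gap.gap_id} extends past the end of {gap.seq_name}")
        if gap.terminal:
            continue
        left_lo = max(0, gap.start - flank_len)
        left = seq[left_lo:gap.start]
        n_pos = max(left.rfind("N"), left.rfind("n"))
        if n_pos >= 0:
            left_lo += n_pos + 1
        right_hi = min(len(seq), gap.end + flank_len)
        right = seq[gap.end:right_hi]
        n_pos = min(p for p in (right.find("N"), right.find("n"), len(right)) if p >= 0)
        right_hi = gap.end + n_pos
        pairs.append(AnchorPair(
            gap_id=gap.gap_id, seq_name=gap.seq_name,
            left_start=left_lo, left_end=gap.start,
            right_start=gap.end, right_end=right_hi,
            flank_len=flank_len,
        ))
    return pairs


def align_to_source(
    anchors: list[AnchorPair],
    donor: SequenceCollection,
    engine: KmerIndexAligner | None = None,
    target: SequenceCollection | None = None,
    precomputed: dict[str, list[Alignment]] | None = None,
    min_identity: float = 0.90,
    min_cov: float = 0.80,
) -> dict[str, list[Alignment]]:
    """Place every anchor on the donor; returns alignments keyed by anchor id.

    Anchor ids are ``<gap_id>/L`` and ``<gap_id>/R``.  Alignments failing the
    identity or query-coverage thresholds are dropped; an anchor with no
    surviving alignment maps to an empty list (unmapped, not an error).
    ``precomputed`` (e.g. from :func:`gapfill.align.read_paf`) bypasses the
    engine; otherwise ``target`` must be given so anchor sequences can be read.
    """
    results: dict[str, list[Alignment]] = {}
    if precomputed is None and engine is None:
        engine = KmerIndexAligner(donor)
    for pair in anchors:
        for side in ("L", "R"):
            anchor_id = f"{pair.gap_id}/{side}"
            seq_len = pair.left_len if side == "L" else pair.right_len
            if precomputed is not None:
                alns = precomputed.get(anchor_id, [])
            else:
                if target is None:
                    raise ValueError("target assembly required when no precomputed alignments are given")
                seq = pair.left_seq(target) if side == "L" else pair.right_seq(target)
                alns = engine.map(seq, query_name=anchor_id) if seq else []
            kept = [a for a in alns
                    if a.identity >= min_identity and a.query_cov >= min_cov]
            if kept and not any(a.is_primary for a in kept):
                kept = [replace(a, is_primary=(i == 0)) for i, a in enumerate(kept)]
            results[anchor_id] = kept
            if seq_len == 0:
                results[anchor_id] = []
    return results


def _primary(alns: list[Alignment]) -> Alignment | None:
    primaries = [a for a in alns if a.is_primary]
    if primaries:
        return primaries[0]
    if alns:
        return sorted(alns, key=lambda a: (-a.mapq, -a.identity,
                                           a.donor_name, a.donor_start))[0]
    return None


def classify_anchor_pair(gap_id: str, left: list[Alignment],
                         right: list[Alignment]) -> PairVerdict:
    """Apply the concordance rules to the primary placements of both anchors.

    Concordant: same donor contig and strand, non-overlapping (abutting is
    allowed: a donor distance of 0 closes the gap to length 0), and ordered so
    the left anchor is upstream of the right on '+' and downstream on '-'.
    """
    la, ra = _primary(left), _primary(right)
    if la is None and ra is None:
        return PairVerdict(gap_id, PairStatus.UNMAPPED)
    if ra is None:
        return PairVerdict(gap_id, PairStatus.SINGLE_LEFT, left=la)
    if la is None:
        return PairVerdict(gap_id, PairStatus.SINGLE_RIGHT, right=ra)
    if la.donor_name != ra.donor_name:
        return PairVerdict(gap_id, PairStatus.DISCORDANT,
                           DiscordReason.DIFFERENT_CONTIGS, la, ra)
    if la.strand != ra.strand:
        return PairVerdict(gap_id, PairStatus.DISCORDANT,
                           DiscordReason.INCONSISTENT_ORIENTATION, la, ra)
    if la.donor_start < ra.donor_end and ra.donor_start < la.donor_end:
        return PairVerdict(gap_id, PairStatus.DISCORDANT,
                           DiscordReason.OVERLAPPING, la, ra)
    upstream_ok = (la.donor_end <= ra.donor_start) if la.strand == "+" \
        else (ra.donor_end <= la.donor_start)
    if not upstream_ok:
        return PairVerdict(gap_id, PairStatus.DISCORDANT,
                           DiscordReason.WRONG_ORDER, la, ra)
    return PairVerdict(gap_id, PairStatus.CONCORDANT, DiscordReason.NONE, la, ra)
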