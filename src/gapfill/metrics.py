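"""Assembly evaluation: NX statistics, consensus identity, windowed mis-join
rate, and a permutation test for repeat enrichment in closed gaps.

The mis-join detector follows the windowed-alignment strategy used to compare
de novo scaffolds against a trusted reference: scaffolds are cut into fixed
windows (default 100 kb), each window is placed on the reference, and a window
is flagged when its neighbouring mapped window lands on a different reference
sequence, a different strand, or at a position inconsistent with the expected
spacing.  The enrichment test asks whether closed-gap intervals carry more
bases of a repeat class than length-matched intervals dropped uniformly on
the sequenced (non-N) portion of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import KmerIndexAligner
from .assembly_io import SequenceCollection


def nx_stat(lengths: list[int], x: float = 50.0) -> int:
    """NX: smallest L in ``lengths`` with sum(lengths >= L) >= x% of the total.

    N50 is the classic contiguity statistic: half the assembly lies in
    sequences at least this long.
    """
    if not lengths:
        raise ValueError("nx_stat requires a non-empty length list")
    if not (0 < x <= 100):
        raise ValueError(f"x must be in (0, 100], got {x}")
    if min(lengths) < 1:
        raise ValueError("sequence lengths must be >= 1")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    need = x / 100.0 * arr.sum()
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, need, side="left"))
    return int(arr[idx])


def alignment_identity(blocks: list[tuple[int, int]]) -> float:
    """Consensus identity in percent from (matches, aligned_bases) blocks."""
    matches = sum(m for m, _ in blocks)
    aligned = sum(a for _, a in blocks)
    if aligned == 0:
        raise ValueError("no aligned bases")
    return 100.0 * matches / aligned


@dataclass(frozen=True)
class WindowVerdict:
    scaffold: str
    index: int
    start: int
    end: int
    mapped_to: str | None
    ref_pos: int | None
    strand: str | None
    flagged_misjoin: bool


def _map_window(engine: KmerIndexAligner, seq: str,
                min_identity: float) -> tuple[str, int, str] | None:
    """Place a window on the reference via two probes near its quarter points.

    The window is mapped only when both probes land on one reference sequence
    and strand with a consistent implied window origin; the returned position
    is that origin (for '-' windows, a virtual coordinate that decreases by
    one window per successive window, so spacing checks are strand-uniform).
    A window straddling a chimeric junction fails the agreement check and is
    reported unmapped, mirroring the insufficient-alignment exclusion rule.
    """
    n = len(seq)
    plen = min(10_000, max(500, n // 4))
    offsets = (n // 8, n - n // 8 - plen)
    if offsets[1] <= offsets[0]:  # short window: single probe
        offsets = (max(0, (n - plen) // 2),)
    placements = []
    for off in offsets:
        alns = engine.map(seq[off:off + plen])
        if not alns or alns[0].identity < min_identity:
            return None
        a = alns[0]
        origin = a.donor_start - off if a.strand == "+" else a.donor_end + off
        placements.append((a, origin))
    first = placements[0][0]
    if any(a.donor_name != first.donor_name or a.strand != first.strand
           for a, _ in placements):
        return None
    origins = [o for _, o in placements]
    if max(origins) - min(origins) > max(2_000, n // 4):
        return None
    return first.donor_name, sum(origins) // len(origins), first.strand


def misjoin_rate(scaffolds: SequenceCollection, reference: SequenceCollection,
                 window: int = 100_000, spacing_tol: float = 2.0,
                 min_identity: float = 0.8,
                 engine: KmerIndexAligner | None = None,
                 ) -> tuple[float, list[WindowVerdict]]:
    """Windowed mis-join rate of ``scaffolds`` against a trusted reference.

    Windows tile each scaffold without overlap (last short window kept if at
    least half a window long) and are placed on the reference by probe
    alignment (see :func:`_map_window`); a window whose probes fail identity
    ``min_identity`` or disagree on placement is unmapped and excluded from
    the denominator — a window straddling a chimeric junction typically falls
    here, while its two neighbours map cleanly to different reference
    sequences and are both flagged.  Consecutive mapped windows are flagged
    when they disagree on reference sequence or strand, or their reference
    spacing deviates from the expected (index difference × window) by more
    than ``spacing_tol`` windows.  Rate = 100 × flagged / mapped.
    """
    if window < 1_000:
        raise ValueError("window must be >= 1 kb")
    engine = engine or KmerIndexAligner(
        reference, max_divergence=min(1.0, 1.0 - min_identity + 0.05))
    verdicts: list[WindowVerdict] = []
    flagged: set[tuple[str, int]] = set()
    for name, seq in scaffolds.records.items():
        placements: list[tuple[int, tuple[str, int, str] | None, int, int]] = []
        idx = 0
        for lo in range(0, len(seq), window):
            hi = min(lo + window, len(seq))
            if hi - lo < window // 2 and idx > 0:
                break  # trailing sliver
            placements.append((idx, _map_window(engine, seq[lo:hi], min_identity), lo, hi))
            idx += 1
        mapped = [(i, p) for i, p, _, _ in placements if p is not None]
        for (i1, (ref1, pos1, s1)), (i2, (ref2, pos2, s2)) in zip(mapped, mapped[1:]):
            bad = False
            if ref1 != ref2 or s1 != s2:
                bad = True
            else:
                expected = (i2 - i1) * window * (1 if s1 == "+" else -1)
                if abs((pos2 - pos1) - expected) > spacing_tol * window:
                    bad = True
            if bad:
                flagged.add((name, i1))
                flagged.add((name, i2))
        for i, p, lo, hi in placements:
            verdicts.append(WindowVerdict(
                scaffold=name, index=i, start=lo, end=hi,
                mapped_to=p[0] if p else None,
                ref_pos=p[1] if p else None,
                strand=p[2] if p else None,
                flagged_misjoin=(name, i) in flagged,
            ))
    n_mapped = sum(1 for v in verdicts if v.mapped_to is not None)
    if n_mapped == 0:
        raise ValueError("no mappable windows")
    rate = 100.0 * len(flagged) / n_mapped
    return rate, verdicts


@dataclass(frozen=True)
class EnrichmentResult:
    repeat_class: str
    observed_frac: float
    expected_frac: float
    p_value: float
    p_adjusted: float
    n_perm: int
    seed: int


def _merge_sorted(ivals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivals = sorted(ivals)
    starts, ends = [], []
    for s, e in ivals:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _coverage_below(starts: np.ndarray, ends: np.ndarray, cum: np.ndarray,
                    x: np.ndarray) -> np.ndarray:
    """Covered bp of the merged interval set lying strictly before each x."""
    j = np.searchsorted(starts, x, side="right") - 1
    jv = np.maximum(j, 0)
    partial = np.clip(x - starts[jv], 0, ends[jv] - starts[jv])
    return np.where(j >= 0, cum[jv] + partial, 0)


def _overlap_bp(starts: np.ndarray, ends: np.ndarray, cum: np.ndarray,
                qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
    """Vectorized bp of overlap of queries [qs, qe) with merged intervals."""
    if starts.size == 0:
        return np.zeros(qs.shape, dtype=np.int64)
    return (_coverage_below(starts, ends, cum, qe)
            - _coverage_below(starts, ends, cum, qs))


class _ClassCoverage:
    """Per-chromosome merged intervals of one repeat class with prefix sums."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in by_chrom.items():
            starts, ends = _merge_sorted(ivals)
            lens = ends - starts
            cum = np.concatenate([[0], np.cumsum(lens)])
            self.data[chrom] = (starts, ends, cum)

    def overlap(self, chrom: np.ndarray, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        out = np.zeros(qs.shape, dtype=np.int64)
        for c in np.unique(chrom):
            if c not in self.data:
                continue
            starts, ends, cum = self.data[c]
            mask = chrom == c
            out[mask] = _overlap_bp(starts, ends, cum[:-1], qs[mask], qe[mask])
        return out


def repeat_enrichment(closed_gaps: list[tuple[str, int, int]],
                      repeat_annotation: list[tuple[str, int, int, str]],
                      genome_lengths: dict[str, int],
                      n_perm: int = 999, seed: int = 0,
                      exclude: list[tuple[str, int, int]] | None = None,
                      bonferroni: bool = False) -> list[EnrichmentResult]:
    """One-sided permutation test for repeat-class enrichment in closed gaps.

    The null drops length-matched intervals uniformly on the genome ``n_perm``
    times, avoiding ``exclude`` regions (typically the genome's own N-gaps,
    where repeats cannot be annotated); ``p = (1 + #{perm >= observed}) /
    (1 + n_perm)``.  Deterministic for a fixed seed and ``n_perm``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    total_bp = sum(e - s for _, s, e in closed_gaps)
    if total_bp == 0:
        raise ValueError("closed gaps cover zero bp")
    for chrom, s, e in closed_gaps:
        if chrom not in genome_lengths or not (0 <= s < e <= genome_lengths[chrom]):
            raise ValueError(f"closed gap {chrom}:{s}-{e} outside genome bounds")

    # allowed segments = complement of the excluded regions, per chromosome
    segments: list[tuple[str, int, int]] = []
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in exclude or []:
        excl_by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, L in genome_lengths.items():
        cursor = 0
        for s, e in sorted(excl_by_chrom.get(chrom, [])):
            if s > cursor:
                segments.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < L:
            segments.append((chrom, cursor, L))
    seg_chrom = np.array([c for c, _, _ in segments])
    seg_lo = np.array([s for _, s, _ in segments], dtype=np.int64)
    seg_len = np.array([e - s for _, s, e in segments], dtype=np.int64)

    rng = np.random.default_rng(seed)
    lengths = np.array([e - s for _, s, e in closed_gaps], dtype=np.int64)
    n_int = lengths.size

    # sample placements: each interval falls wholly inside one allowed segment
    perm_chrom = np.empty((n_perm, n_int), dtype=seg_chrom.dtype)
    perm_start = np.empty((n_perm, n_int), dtype=np.int64)
    for j, L in enumerate(lengths):
        w = np.maximum(seg_len - L + 1, 0).astype(np.float64)
        if w.sum() == 0:
            raise ValueError(f"no allowed segment can host an interval of {L} bp")
        seg_idx = rng.choice(seg_len.size, size=n_perm, p=w / w.sum())
        offset = rng.integers(0, (seg_len[seg_idx] - L + 1))
        perm_chrom[:, j] = seg_chrom[seg_idx]
        perm_start[:, j] = seg_lo[seg_idx] + offset

    classes = sorted({cls for _, _, _, cls in repeat_annotation})
    obs_chrom = np.array([c for c, _, _ in closed_gaps])
    obs_s = np.array([s for _, s, _ in closed_gaps], dtype=np.int64)
    obs_e = np.array([e for _, _, e in closed_gaps], dtype=np.int64)

    results = []
    for cls in classes:
        cov = _ClassCoverage([(c, s, e) for c, s, e, k in repeat_annotation if k == cls])
        observed = cov.overlap(obs_chrom, obs_s, obs_e).sum() / total_bp
        perm_bp = cov.overlap(perm_chrom.ravel(), perm_start.ravel(),
                              (perm_start + lengths[None, :]).ravel())
        perm_frac = perm_bp.reshape(n_perm, n_int).sum(axis=1) / total_bp
        p = (1 + int(np.sum(perm_frac >= observed))) / (1 + n_perm)
        p_adj = min(1.0, p * len(classes)) if bonferroni else p
        results.append(EnrichmentResult(
            repeat_class=cls, observed_frac=float(observed),
            expected_frac=float(perm_frac.mean()), p_value=p,
            p_adjusted=p_adj, n_perm=n_perm, seed=seed,
        ))
    return results
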