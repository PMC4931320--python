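"""Seed-and-extend local alignment of long queries against a multi-contig genome.

The backend contract required by the gap-closing pipeline is small: given a
query string, return scored placements carrying contig, half-open interval,
strand, a Phred-scaled mapping confidence (MAPQ), and an identity estimate.
Two implementations are provided:

* :class:`KmerIndexAligner` — a self-contained aligner: an exact k-mer index
  of the donor (numpy sorted-hash lookup) proposes candidate loci by diagonal
  voting, and edlib infix ("glocal") alignment extends and scores each
  candidate.  Suited to anchor-sized queries (10^2–10^5 bp).
* :func:`read_paf` — import of precomputed alignments as PAF-style records,
  for users who ran an external mapper.

MAPQ here follows the usual convention: the Phred-scaled probability that the
reported position is wrong, estimated from the edit-distance margin between
the best and second-best candidate locus (unique locus → 60).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import edlib
import numpy as np

from .assembly_io import SequenceCollection, revcomp

MAPQ_MAX = 60


@dataclass(frozen=True)
class Alignment:
    """Placement of a query on the donor assembly (0-based half-open)."""

    query_name: str
    donor_name: str
    donor_start: int
    donor_end: int
    strand: str  # '+' or '-'
    mapq: int
    identity: float
    query_cov: float
    edit_distance: int = 0
    is_primary: bool = False


_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lower case


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer hashes; second array flags windows free of non-ACGT."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    four = np.uint64(4)
    for j in range(k):
        window = codes[j : j + n]
        h = h * four + window.astype(np.uint64)
        valid &= window < 4
    return h, valid


class KmerIndexAligner:
    """Exact-k-mer seed index over a donor assembly plus edlib extension.

    Parameters
    ----------
    donor
        The assembly queries are placed on.
    k
        Seed length; 17 gives <1 expected random hit per seed on genomes up
        to ~10 Gb of unique sequence.
    max_candidates
        Number of top-voted candidate loci refined with edlib per query.
    min_seed_votes
        Minimum distinct seeds supporting a candidate locus.
    """

    def __init__(self, donor: SequenceCollection, k: int = 17,
                 max_candidates: int = 5, min_seed_votes: int = 2,
                 max_hits_per_seed: int = 64, min_span_frac: float = 0.5,
                 max_divergence: float | None = None):
        self.donor = donor
        self.k = k
        self.max_candidates = max_candidates
        self.min_seed_votes = min_seed_votes
        self.max_hits_per_seed = max_hits_per_seed
        self.min_span_frac = min_span_frac
        # when set, extension abandons placements over this divergence early
        # instead of computing their exact (useless) edit distance
        self.max_divergence = max_divergence

        # concatenate contigs with a k-wide invalid spacer so no seed spans two
        names = donor.names
        spacer = np.full(k, 4, dtype=np.uint8)
        parts, offsets, pos = [], {}, 0
        for name in names:
            codes = _encode(donor[name])
            offsets[name] = pos
            parts.append(codes)
            parts.append(spacer)
            pos += codes.size + k
        concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self._offsets = offsets
        self._bounds = np.array(
            [offsets[n] for n in names] + [pos], dtype=np.int64
        )
        self._names = names

        hashes, valid = _kmer_hashes(concat, k)
        positions = np.nonzero(valid)[0]
        hv = hashes[positions]
        order = np.argsort(hv, kind="stable")
        self._sorted_hashes = hv[order]
        self._sorted_pos = positions[order]

    def _locate(self, concat_pos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(self._bounds, concat_pos, side="right")) - 1
        name = self._names[idx]
        return name, concat_pos - self._offsets[name]

    def _seed_hits(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, concat_pos) pairs of exact seed matches."""
        k = self.k
        qlen = codes.size
        stride = max(1, min(64, qlen // 32))
        h, valid = _kmer_hashes(codes, k)
        qpos = np.arange(0, h.size, stride)
        qpos = qpos[valid[qpos]]
        if qpos.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qh = h[qpos]
        lo = np.searchsorted(self._sorted_hashes, qh, side="left")
        hi = np.searchsorted(self._sorted_hashes, qh, side="right")
        out_q, out_r = [], []
        for q, a, b in zip(qpos, lo, hi):
            if b - a == 0 or b - a > self.max_hits_per_seed:
                continue  # absent or over-repetitive seed
            out_q.append(np.full(b - a, q, dtype=np.int64))
            out_r.append(self._sorted_pos[a:b].astype(np.int64))
        if not out_q:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(out_q), np.concatenate(out_r)

    def _candidates(self, codes: np.ndarray) -> list[tuple[int, int, int, int, int]]:
        """Diagonal-voting clusters: (votes, diag_lo, diag_hi, query_span, rep).

        ``rep`` is the concatenated-space position of one actual seed hit, so
        it always lies inside the contig the cluster belongs to.
        """
        qpos, rpos = self._seed_hits(codes)
        if qpos.size == 0:
            return []
        band = max(100, codes.size // 8)
        diags = rpos - qpos
        order = np.argsort(diags, kind="stable")
        diags, qs, rs = diags[order], qpos[order], rpos[order]
        clusters: list[tuple[int, int, int, int, int]] = []
        start = 0
        for i in range(1, diags.size + 1):
            if i == diags.size or diags[i] - diags[i - 1] > band:
                votes = np.unique(qs[start:i]).size
                span = int(qs[start:i].max() - qs[start:i].min()) + self.k
                rep = int(rs[(start + i - 1) // 2])
                clusters.append((votes, int(diags[start]), int(diags[i - 1]),
                                 span, rep))
                start = i
        clusters.sort(key=lambda c: (-c[0], c[1]))
        return clusters

    def map(self, query: str, query_name: str = "query") -> list[Alignment]:
        """All refined placements of ``query``, best (primary) first."""
        if len(query) < self.k:
            return []
        raw: list[tuple[int, Alignment]] = []
        for strand, seq in (("+", query), ("-", revcomp(query))):
            codes = _encode(seq)
            min_votes = self.min_seed_votes if len(query) >= 4 * self.k else 1
            # a locus whose seeds cover well under half the query cannot reach
            # useful identity; skipping it spares an expensive failed extension
            min_span = int(self.min_span_frac * len(query))
            for votes, dlo, dhi, span, rep in self._candidates(codes)[: self.max_candidates]:
                if votes < min_votes or span < min_span:
                    continue
                aln = self._extend(seq, strand, dlo, dhi, rep, query_name)
                if aln is not None:
                    raw.append(aln)
        if not raw:
            return []
        raw.sort(key=lambda t: (t[0], t[1].donor_name, t[1].donor_start))
        # deduplicate placements found from overlapping clusters
        seen, uniq = set(), []
        for ed, aln in raw:
            key = (aln.donor_name, aln.strand, aln.donor_start // 50)
            if key in seen:
                continue
            seen.add(key)
            uniq.append((ed, aln))
        best_ed = uniq[0][0]
        second_ed = uniq[1][0] if len(uniq) > 1 else None
        mapq = self._mapq(best_ed, second_ed, len(query))
        out = [replace(uniq[0][1], mapq=mapq, is_primary=True)]
        out += [replace(aln, mapq=0) for _, aln in uniq[1:]]
        return out

    @staticmethod
    def _mapq(best_ed: int, second_ed: int | None, qlen: int) -> int:
        if second_ed is None:
            return MAPQ_MAX
        if second_ed <= best_ed:
            return 0
        return min(MAPQ_MAX, 6 * (second_ed - best_ed))

    def _extend(self, seq: str, strand: str, dlo: int, dhi: int, rep: int,
                query_name: str) -> tuple[int, Alignment] | None:
        qlen = len(seq)
        pad = qlen // 8 + 64
        win_lo = dlo - pad
        win_hi = dhi + qlen + pad
        name, _ = self._locate(rep)  # rep is a real seed hit inside the contig
        off = self._offsets[name]
        rec_len = len(self.donor[name])
        rec_lo = max(0, min(win_lo - off, rec_len))
        rec_hi = max(0, min(win_hi - off, rec_len))
        if rec_hi - rec_lo < self.k:
            return None
        window = self.donor[name][rec_lo:rec_hi]
        max_ed = -1 if self.max_divergence is None \
            else int(self.max_divergence * qlen) + 64
        res = edlib.align(seq, window, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] < 0 or not res["locations"]:
            return None
        s, e = res["locations"][0]
        ed = res["editDistance"]
        identity = max(0.0, 1.0 - ed / qlen)
        aln = Alignment(
            query_name=query_name,
            donor_name=name,
            donor_start=rec_lo + s,
            donor_end=rec_lo + e + 1,
            strand=strand,
            mapq=0,
            identity=identity,
            query_cov=1.0,  # infix mode consumes the whole query
            edit_distance=ed,
        )
        return ed, aln


def read_paf(path: str | Path) -> dict[str, list[Alignment]]:
    """Parse PAF-style records into alignments grouped by query name.

    Expected columns: qname, qlen, qstart, qend, strand, tname, tlen, tstart,
    tend, matches, block_len, mapq.  The best record per query (highest mapq,
    then identity, then lowest target coordinate) is marked primary.
    """
    by_query: dict[str, list[Alignment]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, qlen = f[0], int(f[1])
            qstart, qend, strand = int(f[2]), int(f[3]), f[4]
            tname, tstart, tend = f[5], int(f[7]), int(f[8])
            matches, block, mapq = int(f[9]), int(f[10]), int(f[11])
            aln = Alignment(
                query_name=qname,
                donor_name=tname,
                donor_start=tstart,
                donor_end=tend,
                strand=strand,
                mapq=mapq,
                identity=matches / block if block else 0.0,
                query_cov=(qend - qstart) / qlen if qlen else 0.0,
                edit_distance=block - matches,
            )
            by_query.setdefault(qname, []).append(aln)
    for qname, alns in by_query.items():
        alns.sort(key=lambda a: (-a.mapq, -a.identity, a.donor_name, a.donor_start))
        by_query[qname] = [replace(a, is_primary=(i == 0)) for i, a in enumerate(alns)]
    return by_query
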