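"""Assembly I/O: FASTA access, N-gap detection and merging, interval export.

An *N-gap* is a maximal run of the character ``N`` in an assembly sequence,
representing unknown bases between assembled components.  All coordinates in
this package are 0-based half-open; AGP export (see :mod:`gapfill.closure`)
converts to the format's 1-based inclusive convention.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes; only N denotes unknown sequence (a gap).  Lower-case
# (soft-masked) and ambiguity codes other than N are ordinary bases here.
_IUPAC = "ACGTUNRYSWKMBDHV"
_VALID = frozenset(_IUPAC + _IUPAC.lower())
_GAP_RE = re.compile(r"N+", re.IGNORECASE)

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case and IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """A sequence record contains characters outside the nucleotide alphabet."""


class SequenceCollection:
    """Ordered collection of named nucleotide sequences (an assembly).

    Parameters
    ----------
    records
        Mapping of sequence name to nucleotide string.  Names must be unique
        (guaranteed by dict semantics) and non-empty.
    validate
        If true, reject characters outside the IUPAC nucleotide alphabet.
    """

    def __init__(self, records: dict[str, str], validate: bool = True):
        for name in records:
            if not name:
                raise ValueError("sequence names must be non-empty")
        if validate:
            for name, seq in records.items():
                bad = set(seq) - _VALID
                if bad:
                    raise FastaParseError(
                        f"record {name!r} contains non-nucleotide characters: "
                        f"{sorted(bad)}"
                    )
        self.records: dict[str, str] = dict(records)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    @property
    def names(self) -> list[str]:
        return list(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceCollection) and self.records == other.records

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    @classmethod
    def from_fasta(cls, path: str | Path, validate: bool = True) -> "SequenceCollection":
        """Read a (optionally gzip-compressed) multi-FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        records: dict[str, str] = {}
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in records:
                    raise FastaParseError(f"duplicate sequence name {rec.id!r} in {path}")
                records[rec.id] = str(rec.seq)
        return cls(records, validate=validate)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(
                SeqRecord(Seq(seq), id=name, description="")
                for name, seq in self.records.items()
            )


@dataclass(frozen=True)
class GapRecord:
    """One (possibly merged) N-gap interval on a target sequence.

    ``L0`` is the annotated gap length, ``end - start``.  ``n_merged`` counts
    the raw N-runs coalesced into this record; merged records may absorb short
    stretches of inter-run sequence.  ``terminal`` marks gaps touching a
    sequence end, which cannot be two-anchor closed.
    """

    gap_id: str
    seq_name: str
    start: int
    end: int
    n_merged: int = 1
    terminal: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap interval [{self.start}, {self.end})")

    @property
    def L0(self) -> int:
        return self.end - self.start


def detect_gaps(asm: SequenceCollection, min_run: int = 1) -> list[GapRecord]:
    """Find every maximal N-run of length >= ``min_run``.

    Returns records sorted by (seq_name, start) with sequential gap ids.
    Non-nucleotide characters raise :class:`FastaParseError` naming the record.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out: list[GapRecord] = []
    for name in sorted(asm.names):
        seq = asm[name]
        bad = set(seq) - _VALID
        if bad:
            raise FastaParseError(
                f"record {name!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        for m in _GAP_RE.finditer(seq):
            if m.end() - m.start() >= min_run:
                out.append(
                    GapRecord(
                        gap_id="",
                        seq_name=name,
                        start=m.start(),
                        end=m.end(),
                        n_merged=1,
                        terminal=(m.start() == 0 or m.end() == len(seq)),
                    )
                )
    return [replace(g, gap_id=f"gap_{i + 1}") for i, g in enumerate(out)]


def merge_gaps(gaps: list[GapRecord], max_sep: int = 500) -> list[GapRecord]:
    """Coalesce consecutive gaps on one sequence separated by <= ``max_sep`` bp.

    Merging is transitive; the merged record spans from the first start to the
    last end, ``n_merged`` sums, and ``terminal`` is inherited from either end.
    Gap ids are reassigned sequentially.
    """
    if max_sep < 0:
        raise ValueError("max_sep must be >= 0")
    merged: list[GapRecord] = []
    for g in gaps:
        prev = merged[-1] if merged else None
        if prev is not None and prev.seq_name == g.seq_name and g.start - prev.end <= max_sep:
            merged[-1] = replace(
                prev,
                end=g.end,
                n_merged=prev.n_merged + g.n_merged,
                terminal=prev.terminal or g.terminal,
            )
        else:
            merged.append(g)
    return [replace(g, gap_id=f"gap_{i + 1}") for i, g in enumerate(merged)]


@dataclass(frozen=True)
class GapSummary:
    count: int
    total_bp: int
    mean: float | None
    median: int | None
    histogram: dict[str, int] = field(default_factory=dict)


# log10-spaced bin edges echoing the wide dynamic range of real gap tables
_HIST_EDGES = [0, 100, 1_000, 10_000, 100_000, 1_000_000]


def gap_summary(gaps: list[GapRecord]) -> GapSummary:
    """Count / mean / lower-median / length histogram of annotated gap lengths."""
    if not gaps:
        return GapSummary(count=0, total_bp=0, mean=None, median=None)
    lengths = sorted(g.L0 for g in gaps)
    total = sum(lengths)
    median = lengths[(len(lengths) - 1) // 2]  # lower middle: integer-valued
    hist: dict[str, int] = {}
    edges = _HIST_EDGES + [max(lengths) + 1]
    for lo, hi in zip(edges, edges[1:]):
        if lo >= hi:
            continue
        label = f"[{lo},{hi})"
        n = sum(1 for L in lengths if lo <= L < hi)
        if n:
            hist[label] = n
    return GapSummary(
        count=len(lengths),
        total_bp=total,
        mean=total / len(lengths),
        median=median,
        histogram=hist,
    )


def export_gaps(gaps: list[GapRecord], path: str | Path, format: str = "bed") -> None:
    """Write gaps as 5-column BED (chrom/start/end/gap_id/L0) or headered TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "bed":
            for g in gaps:
                fh.write(f"{g.seq_name}\t{g.start}\t{g.end}\t{g.gap_id}\t{g.L0}\n")
        elif format == "tsv":
            fh.write("gap_id\tseq_name\tstart\tend\tL0\tn_merged\tterminal\n")
            for g in gaps:
                fh.write(
                    f"{g.gap_id}\t{g.seq_name}\t{g.start}\t{g.end}\t{g.L0}\t"
                    f"{g.n_merged}\t{int(g.terminal)}\n"
                )
        else:
            raise ValueError(f"unknown format {format!r} (expected 'bed' or 'tsv')")


def read_gaps(path: str | Path, format: str = "bed") -> list[GapRecord]:
    """Read gaps written by :func:`export_gaps` (lossless round-trip for TSV)."""
    path = Path(path)
    out: list[GapRecord] = []
    with open(path) as fh:
        if format == "bed":
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, name, _score = line.rstrip("\n").split("\t")[:5]
                out.append(GapRecord(gap_id=name, seq_name=chrom,
                                     start=int(start), end=int(end)))
        elif format == "tsv":
            header = fh.readline()
            if header and not header.startswith("gap_id"):
                raise ValueError(f"unexpected TSV header in {path}")
            for line in fh:
                if not line.strip():
                    continue
                gid, chrom, start, end, _l0, n_merged, terminal = line.rstrip("\n").split("\t")
                out.append(GapRecord(gap_id=gid, seq_name=chrom, start=int(start),
                                     end=int(end), n_merged=int(n_merged),
                                     terminal=bool(int(terminal))))
        else:
            raise ValueError(f"unknown format {format!r} (expected 'bed' or 'tsv')")
    return out


def read_bed_classes(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a 4+ column BED with a class label in column 4 (RepeatMasker-style)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            cls = fields[3] if len(fields) > 3 else "."
            out.append((chrom, start, end, cls))
    return out
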