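"""Detection of fusion junction-spanning reads.

A fusion transcript (e.g. the PAX3-FOXO1 oncogene, where the PAX3
DNA-binding domain is joined to the FOXO1 transactivation domain) is
supported by sequencing reads that cross the breakpoint and match both
parent genes.  This module realigns reads against a short known junction
window and applies two filter rules:

1. a junction-spanning read must align to the junction window with no
   mismatch (configurable via ``max_mismatches``), and
2. reads with fewer than ``min_overlap`` (default 6) matching bases on
   either side of the breakpoint are discarded.

Alignment is gapless and full-length: the read (or its reverse
complement) must lie entirely within the junction window.  Callers
should build the window with ``flank >= read_length - min_overlap`` so
every true spanning read is fully contained.

Coordinates are 0-based, half-open; the breakpoint is the index of the
first downstream-gene base in the junction window.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FusionReference",
    "JunctionConfig",
    "JunctionHit",
    "JunctionSupport",
    "build_junction_reference",
    "scan_read",
    "detect_junction_support",
    "reverse_complement",
    "write_hits_tsv",
    "write_support_json",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FusionReference:
    """A fusion junction reference.

    ``junction_window`` is the last ``flank`` bases of the upstream gene
    followed by the first ``flank`` bases of the downstream gene;
    ``breakpoint`` (== ``flank``) is the 0-based index of the first
    downstream base within the window.
    """

    upstream_seq: str
    downstream_seq: str
    junction_window: str
    breakpoint: int
    flank: int


@dataclass(frozen=True)
class JunctionConfig:
    """Filter configuration for junction read scanning.

    min_overlap
        Minimum matching bases required on *each* side of the
        breakpoint (default 6 bp).
    max_mismatches
        Maximum tolerated mismatches over the full read (default 0).
    scan_both_strands
        Also scan the reverse complement of each read (default True).
    """

    min_overlap: int = 6
    max_mismatches: int = 0
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class JunctionHit:
    """One retained junction-spanning read alignment."""

    read_id: str
    offset: int
    left_overlap: int
    right_overlap: int
    strand: str  # "forward" or "reverse"


@dataclass
class JunctionSupport:
    """Per-sample junction support: retained hits and their count."""

    sample_id: str
    n_supporting_reads: int
    hits: list[JunctionHit] = field(default_factory=list)


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_ALPHABET
    if bad:
        raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
    return seq


def build_junction_reference(
    upstream_seq: str, downstream_seq: str, flank: int
) -> FusionReference:
    """Construct a junction window from the two parent gene fragments.

    The window is ``suffix(upstream, flank) + prefix(downstream, flank)``
    with the breakpoint at offset ``flank``.

    Raises
    ------
    ValueError
        If either sequence is shorter than ``flank`` or contains
        characters outside A/C/G/T/N.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    upstream_seq = _check_sequence(upstream_seq, "upstream_seq")
    downstream_seq = _check_sequence(downstream_seq, "downstream_seq")
    if len(upstream_seq) < flank or len(downstream_seq) < flank:
        raise ValueError(
            f"both sequences must be at least flank={flank} bases long "
            f"(got {len(upstream_seq)} and {len(downstream_seq)})"
        )
    window = upstream_seq[-flank:] + downstream_seq[:flank]
    return FusionReference(
        upstream_seq=upstream_seq,
        downstream_seq=downstream_seq,
        junction_window=window,
        breakpoint=flank,
        flank=flank,
    )


def _mismatches(read: str, segment: str, limit: int) -> int:
    """Mismatch count with early exit past ``limit``.

    'N' never matches, in either the read or the window: the filter is
    conservative, consistent with an exact-match rule.
    """
    mm = 0
    for a, b in zip(read, segment):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _scan_oriented(read: str, window: str, breakpoint: int, cfg: JunctionConfig):
    """Smallest qualifying offset for one orientation, or None."""
    n = len(read)
    # only offsets where both per-side overlaps can reach min_overlap
    lo = max(0, breakpoint - (n - cfg.min_overlap))
    hi = min(breakpoint - cfg.min_overlap, len(window) - n)
    clean = cfg.max_mismatches == 0 and "N" not in read
    for offset in range(lo, hi + 1):
        segment = window[offset : offset + n]
        if clean:
            if read != segment or "N" in segment:
                continue
        elif _mismatches(read, segment, cfg.max_mismatches) > cfg.max_mismatches:
            continue
        return offset
    return None


def scan_read(
    read: str, ref: FusionReference, cfg: JunctionConfig | None = None
) -> JunctionHit | None:
    """Scan one read against the junction window.

    Returns a :class:`JunctionHit` iff the read (or, when
    ``scan_both_strands``, its reverse complement) aligns full-length and
    gapless within the window with at most ``max_mismatches`` mismatches
    at an offset whose per-side overlaps both meet ``min_overlap``.
    Forward orientation is preferred when both orientations match; the
    smallest qualifying offset wins among multiple matches.
    """
    if cfg is None:
        cfg = JunctionConfig()
    if len(read) == 0:
        raise ValueError("empty read")
    read = read.upper()
    window = ref.junction_window
    if len(read) > len(window):
        return None
    if len(read) < 2 * cfg.min_overlap:
        return None

    orientations = [("forward", read)]
    if cfg.scan_both_strands:
        orientations.append(("reverse", reverse_complement(read)))
    for strand, oriented in orientations:
        offset = _scan_oriented(oriented, window, ref.breakpoint, cfg)
        if offset is not None:
            left = ref.breakpoint - offset
            return JunctionHit(
                read_id="",
                offset=offset,
                left_overlap=left,
                right_overlap=len(read) - left,
                strand=strand,
            )
    return None


ReadsInput = Union[str, Path, Iterable]


def _iter_reads(reads: ReadsInput) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ path(s), SeqRecords or pairs."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            yield from _parse_fastq(handle)
        return
    for item in reads:
        if isinstance(item, SeqRecord):
            yield item.id, str(item.seq)
        else:
            rid, seq = item
            yield rid, str(seq)


def _parse_fastq(handle) -> Iterator[tuple[str, str]]:
    idx = 0
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq)
            idx += 1
    except ValueError as exc:  # malformed record: name the index
        raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc


def detect_junction_support(
    reads: ReadsInput,
    ref: FusionReference,
    cfg: JunctionConfig | None = None,
    sample_id: str = "sample",
) -> JunctionSupport:
    """Count junction-spanning reads supporting the fusion in a sample.

    ``reads`` may be a FASTQ path (optionally .gz), an iterable of
    Bio.SeqRecord, or an iterable of ``(read_id, sequence)`` pairs.
    Paired-end mates are scanned independently; each physical read
    contributes at most one hit and the support count is the number of
    distinct hit read ids.
    """
    if cfg is None:
        cfg = JunctionConfig()
    hits: list[JunctionHit] = []
    seen: set[str] = set()
    for read_id, seq in _iter_reads(reads):
        if read_id in seen:
            continue
        hit = scan_read(seq, ref, cfg)
        if hit is not None:
            hits.append(replace(hit, read_id=read_id))
            seen.add(read_id)
    return JunctionSupport(
        sample_id=sample_id, n_supporting_reads=len(hits), hits=hits
    )


def write_hits_tsv(support: JunctionSupport, path: str | Path) -> None:
    """Write retained hits as a TSV (read_id, offset, overlaps, strand)."""
    with open(path, "w") as fh:
        fh.write("read_id\toffset\tleft_overlap\tright_overlap\tstrand\n")
        for h in support.hits:
            fh.write(
                f"{h.read_id}\t{h.offset}\t{h.left_overlap}\t"
                f"{h.right_overlap}\t{h.strand}\n"
            )


def write_support_json(support: JunctionSupport, path: str | Path) -> None:
    """Write the per-sample support summary as JSON."""
    with open(path, "w") as fh:
        json.dump(
            {
                "sample_id": support.sample_id,
                "n_supporting_reads": support.n_supporting_reads,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
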