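"""Parsing of droplet read pairs into cell barcodes, antibody tags and UMIs.

Read 1 carries a combinatorial cell barcode: a fixed 5' adapter, then
barcode segments separated by fixed linker sequences. Read 2 of the
antibody library carries an 8 bp antibody barcode followed by a 10 bp
unique molecular identifier (UMI). Observed barcode segments and antibody
tags are error-corrected against a whitelist / panel within a maximum
Hamming distance (1 by default); ambiguous matches (two or more whitelist
entries at the same minimal distance) are discarded rather than assigned.

Quality strings are interpreted as Phred+33.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "BarcodeSchema",
    "Whitelist",
    "AntibodyPanel",
    "ParsedTagRead",
    "MatchResult",
    "correct_sequence",
    "parse_cell_barcode",
    "parse_antibody_tag",
    "parse_tag_read_pair",
    "hamming",
    "read_fastq_pairs",
    "write_parse_log",
]

_ALPHABET = frozenset("ACGT")

# failure reasons emitted by the parsers
REASON_OK = "ok"
REASON_AMBIGUOUS = "ambiguous"
REASON_NO_MATCH = "no_match"
REASON_LENGTH = "length"
REASON_STRUCTURE = "structure"
REASON_UMI_QUALITY = "umi_quality"
REASON_TAG = "tag"


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeSchema:
    """Layout of the combinatorial cell barcode on Read 1.

    Parameters
    ----------
    segment_lengths
        Number of bases in each barcode segment, in read order.
    linker_sequences
        Fixed sequences between consecutive segments; must have exactly
        ``len(segment_lengths) - 1`` entries.
    adapter_5p
        Fixed prefix preceding the first segment (may be empty).
    """

    segment_lengths: tuple[int, ...]
    linker_sequences: tuple[str, ...] = ()
    adapter_5p: str = ""

    def __post_init__(self) -> None:
        if not self.segment_lengths:
            raise ValueError("schema needs at least one segment")
        if any(n <= 0 for n in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if len(self.linker_sequences) != len(self.segment_lengths) - 1:
            raise ValueError(
                "need exactly one linker between consecutive segments"
            )

    @property
    def total_length(self) -> int:
        """Fixed read-1 span: adapter + segments + linkers."""
        return (
            len(self.adapter_5p)
            + sum(self.segment_lengths)
            + sum(len(s) for s in self.linker_sequences)
        )

    @property
    def barcode_length(self) -> int:
        return sum(self.segment_lengths)


class Whitelist:
    """Per-segment sets of allowed barcode sequences.

    Each segment of the combinatorial barcode has its own whitelist of
    fixed-length sequences. The pairwise minimum Hamming distance per
    segment is computed at load time; correction at ``max_dist = 1`` is
    unambiguous only when that minimum is at least 3.
    """

    def __init__(self, segments: Sequence[Sequence[str]]):
        if not segments:
            raise ValueError("whitelist needs at least one segment")
        self.segments: list[frozenset[str]] = []
        self.segment_lengths: list[int] = []
        self.min_pairwise_distance: list[int | None] = []
        for entries in segments:
            entries = list(entries)
            if not entries:
                raise ValueError("empty whitelist segment")
            length = len(entries[0])
            for e in entries:
                if len(e) != length:
                    raise ValueError("whitelist entries differ in length")
                if not set(e) <= _ALPHABET:
                    raise ValueError(f"non-ACGT whitelist entry: {e!r}")
            self.segments.append(frozenset(entries))
            self.segment_lengths.append(length)
            self.min_pairwise_distance.append(_min_pairwise(entries))

    @classmethod
    def from_files(cls, paths: Sequence[str]) -> "Whitelist":
        """Load one-sequence-per-line whitelist files, one per segment."""
        segs = []
        for p in paths:
            opener = gzip.open if str(p).endswith(".gz") else open
            with opener(p, "rt") as fh:
                segs.append([ln.strip().upper() for ln in fh if ln.strip()])
        return cls(segs)

    def __len__(self) -> int:
        return len(self.segments)


def _min_pairwise(entries: list[str]) -> int | None:
    if len(entries) < 2:
        return None
    # quadratic scan is fine at whitelist scale (<= a few thousand entries)
    best = len(entries[0])
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            d = hamming(a, b)
            if d < best:
                best = d
                if best == 1:
                    return best
    return best


@dataclass(frozen=True)
class MatchResult:
    """Outcome of whitelist correction for one observed sequence."""

    sequence: str | None
    distance: int | None
    reason: str

    @property
    def ok(self) -> bool:
        return self.reason == REASON_OK


def correct_sequence(
    observed: str, whitelist_entries: frozenset[str] | set[str], max_dist: int = 1
) -> MatchResult:
    """Match an observed sequence to a whitelist within ``max_dist``.

    Exact matches return at distance 0. Otherwise the unique entry within
    ``max_dist`` is returned; if two or more entries are equidistant at the
    minimal distance the read is ambiguous and discarded, and sequences
    farther than ``max_dist`` from every entry are unmatched. A length
    mismatch rejects the read (reason ``"length"``) rather than raising.
    """
    entries = whitelist_entries
    first = next(iter(entries))
    if len(observed) != len(first):
        return MatchResult(None, None, REASON_LENGTH)
    if observed in entries:
        return MatchResult(observed, 0, REASON_OK)
    best: list[str] = []
    best_d = max_dist + 1
    for entry in entries:
        d = hamming(observed, entry)
        if d < best_d:
            best_d = d
            best = [entry]
        elif d == best_d:
            best.append(entry)
    if best_d > max_dist:
        return MatchResult(None, None, REASON_NO_MATCH)
    if len(best) > 1:
        return MatchResult(None, best_d, REASON_AMBIGUOUS)
    return MatchResult(best[0], best_d, REASON_OK)


def parse_cell_barcode(
    read1_seq: str,
    read1_qual: str,
    schema: BarcodeSchema,
    wl: Whitelist,
    max_dist: int = 1,
) -> tuple[str | None, str]:
    """Extract and correct the combinatorial cell barcode from Read 1.

    Each segment is corrected independently against its whitelist; the
    parse succeeds only if the adapter and every linker are found at their
    fixed positions and every segment resolves. Returns
    ``(corrected_barcode, "ok")`` or ``(None, reason)``.
    """
    if len(wl) != len(schema.segment_lengths):
        raise ValueError("whitelist segment count does not match schema")
    seq = read1_seq.upper()
    if len(seq) < schema.total_length:
        return None, REASON_STRUCTURE
    pos = len(schema.adapter_5p)
    if seq[:pos] != schema.adapter_5p:
        return None, REASON_STRUCTURE
    parts: list[str] = []
    for i, seg_len in enumerate(schema.segment_lengths):
        observed = seq[pos : pos + seg_len]
        pos += seg_len
        if i < len(schema.linker_sequences):
            linker = schema.linker_sequences[i]
            if seq[pos : pos + len(linker)] != linker:
                return None, REASON_STRUCTURE
            pos += len(linker)
        match = correct_sequence(observed, wl.segments[i], max_dist)
        if not match.ok:
            return None, match.reason
        parts.append(match.sequence)  # type: ignore[arg-type]
    return "".join(parts), REASON_OK


class AntibodyPanel:
    """Antibody panel: name, 8 bp tag sequence, isotype-control flag.

    Tags are validated at load to be 8 bp with pairwise Hamming distance
    of at least 3, which makes Hamming-1 correction unambiguous.
    """

    TAG_LENGTH = 8
    MIN_TAG_DISTANCE = 3

    def __init__(self, records: Sequence[tuple[str, str, bool]]):
        if not records:
            raise ValueError("empty antibody panel")
        names = [r[0] for r in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate antibody names in panel")
        tags = [r[1].upper() for r in records]
        for t in tags:
            if len(t) != self.TAG_LENGTH or not set(t) <= _ALPHABET:
                raise ValueError(f"invalid antibody tag {t!r}")
        mind = _min_pairwise(tags)
        if mind is not None and mind < self.MIN_TAG_DISTANCE:
            raise ValueError(
                f"panel tags too close: min pairwise Hamming {mind} < "
                f"{self.MIN_TAG_DISTANCE}"
            )
        self.names: list[str] = names
        self.tags: list[str] = tags
        self.is_isotype: list[bool] = [bool(r[2]) for r in records]
        self._by_tag = {t: n for t, n in zip(tags, names)}
        self._tagset = frozenset(tags)

    @classmethod
    def from_csv(cls, path: str) -> "AntibodyPanel":
        """Load a panel CSV with columns name, sequence, is_isotype_control."""
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    (
                        row["name"],
                        row["sequence"],
                        str(row.get("is_isotype_control", "0")).strip().lower()
                        in {"1", "true", "yes"},
                    )
                )
        return cls(records)

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "sequence", "is_isotype_control"])
            for n, t, iso in zip(self.names, self.tags, self.is_isotype):
                w.writerow([n, t, int(iso)])

    @property
    def isotype_names(self) -> list[str]:
        return [n for n, iso in zip(self.names, self.is_isotype) if iso]

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class ParsedTagRead:
    """One antibody-library read after barcode and tag resolution."""

    cell_barcode: str | None
    antibody: str | None
    umi: str | None
    valid: bool
    reason: str = REASON_OK


UMI_LENGTH = 10
MIN_UMI_QUALITY = 20
_PHRED_OFFSET = 33


def parse_antibody_tag(
    read2_seq: str,
    read2_qual: str,
    panel: AntibodyPanel,
    max_dist: int = 1,
) -> tuple[str | None, str | None, str]:
    """Extract (antibody, UMI) from an antibody-library Read 2.

    The first 8 bases are the antibody tag, corrected at Hamming distance
    <= 1 against the panel; the next 10 bases are the UMI, accepted only
    if every base has Phred quality >= 20 (Phred+33 encoding).
    Returns ``(antibody_name, umi, "ok")`` or ``(None, None, reason)``.
    """
    n = AntibodyPanel.TAG_LENGTH + UMI_LENGTH
    if len(read2_seq) < n or len(read2_qual) < n:
        return None, None, REASON_STRUCTURE
    tag = read2_seq[: AntibodyPanel.TAG_LENGTH].upper()
    match = correct_sequence(tag, panel._tagset, max_dist)
    if not match.ok:
        return None, None, REASON_TAG
    umi = read2_seq[AntibodyPanel.TAG_LENGTH : n].upper()
    quals = read2_qual[AntibodyPanel.TAG_LENGTH : n]
    if any(ord(q) - _PHRED_OFFSET < MIN_UMI_QUALITY for q in quals):
        return None, None, REASON_UMI_QUALITY
    if not set(umi) <= _ALPHABET:
        return None, None, REASON_UMI_QUALITY
    return panel._by_tag[match.sequence], umi, REASON_OK


def parse_tag_read_pair(
    read1_seq: str,
    read1_qual: str,
    read2_seq: str,
    read2_qual: str,
    schema: BarcodeSchema,
    wl: Whitelist,
    panel: AntibodyPanel,
    max_dist: int = 1,
) -> ParsedTagRead:
    """Parse a full antibody-library read pair into a :class:`ParsedTagRead`."""
    cell, reason = parse_cell_barcode(read1_seq, read1_qual, schema, wl, max_dist)
    if cell is None:
        return ParsedTagRead(None, None, None, False, reason)
    ab, umi, reason = parse_antibody_tag(read2_seq, read2_qual, panel, max_dist)
    if ab is None:
        return ParsedTagRead(cell, None, None, False, reason)
    return ParsedTagRead(cell, ab, umi, True, REASON_OK)


def read_fastq_pairs(
    r1_path: str, r2_path: str
) -> Iterator[tuple[str, str, str, str]]:
    """Stream (seq1, qual1, seq2, qual2) tuples from paired FASTQ files.

    Files may be gzip-compressed (``.gz`` suffix). Record pairing is by
    position; ragged files raise.
    """
    open1 = gzip.open if str(r1_path).endswith(".gz") else open
    open2 = gzip.open if str(r2_path).endswith(".gz") else open
    with open1(r1_path, "rt") as f1, open2(r2_path, "rt") as f2:
        while True:
            h1 = f1.readline()
            h2 = f2.readline()
            if not h1 and not h2:
                return
            if not h1 or not h2:
                raise ValueError("paired FASTQ files have unequal record counts")
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            yield s1, q1, s2, q2


def write_parse_log(path: str, reason_counts: dict[str, int]) -> None:
    """Write failure-reason counts of a parsing run as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason in sorted(reason_counts):
            fh.write(f"{reason}\t{reason_counts[reason]}\n")
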