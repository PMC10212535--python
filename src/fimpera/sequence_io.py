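"""I/O and DNA-word primitives.

Reads and writes the external formats the tool touches — counted k-mer
tables (KMC-dump-style TSV, ``<kmer>\\t<count>`` per line) and FASTA/FASTQ
query files, plain or gzipped — and provides the k-mer/s-mer primitives the
index is built on: reverse complement, canonical form (lexicographic minimum
of a word and its reverse complement), positional s-mer enumeration and the
2-bit integer encoding used for hashing.

Coordinates are 0-based with half-open intervals throughout. Input is
case-insensitive (lowercase acgt is uppercased on read). Windows containing
a non-ACGT character are flagged invalid rather than dropped so positional
arithmetic downstream stays aligned.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; A<C<G<T so integer order on codes equals
# lexicographic order on equal-length words.
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _BASE_CODE[ord(_c)] = _i
    _BASE_CODE[ord(_c.lower())] = _i


class FormatError(ValueError):
    """Malformed or unrecognized input file."""


@dataclass
class CountedKmerTable:
    """A counted k-mer multiset: (k-mer, abundance) pairs of uniform length."""

    entries: list[Tuple[str, int]]
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k is None and self.entries:
            self.k = len(self.entries[0][0])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dict(self) -> dict[str, int]:
        return dict(self.entries)


@dataclass
class SequenceRecord:
    id: str
    seq: str
    quality: Optional[str] = None


@dataclass
class SmerEnumeration:
    """All length-s windows of a sequence, with positional validity flags.

    ``smers[i]`` is the window starting at 0-based offset ``i`` (canonical
    form if requested and the window is valid); ``valid[i]`` is False iff
    the window contains a non-ACGT character. Invalid windows are kept so
    that ``len(smers) == max(0, len(seq) - s + 1)`` always holds.
    """

    s: int
    smers: list[str] = field(default_factory=list)
    valid: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.smers)


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def canonical(word: str) -> str:
    """Lexicographic minimum of a word and its reverse complement (A<C<G<T)."""
    for ch in word:
        if ch not in "ACGT":
            raise ValueError(f"non-ACGT character {ch!r} in word")
    return min(word, word.translate(_COMPLEMENT)[::-1])


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to int8 codes A,C,G,T -> 0..3; anything else -> -1."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _BASE_CODE[raw]


def smer_codes(
    seq: str, s: int, canonicalize: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-packed codes of every length-s window of ``seq``.

    Returns ``(codes, valid)`` where ``codes`` is a uint64 array of length
    ``max(0, len(seq)-s+1)`` (big-endian base packing, so codes compare like
    the words) and ``valid`` marks windows free of non-ACGT characters.
    Invalid windows carry an arbitrary code and must be masked by ``valid``.
    With ``canonicalize``, each valid code is the minimum of the forward and
    reverse-complement packing.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if s > 32:
        raise ValueError("2-bit packing supports words up to 32 bases")
    base = encode_bases(seq.upper())
    n = base.size - s + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    bad = (base < 0).astype(np.int32)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[s:] - bad_cum[:-s]) == 0
    b64 = np.where(base < 0, 0, base).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(s):  # Horner: big-endian, O(s) vector passes
        codes = (codes << np.uint64(2)) | b64[j : j + n]
    if canonicalize:
        rc = np.zeros(n, dtype=np.uint64)
        comp = np.uint64(3) - b64
        for j in range(s - 1, -1, -1):  # rc coefficient of position j is 4**j
            rc = (rc << np.uint64(2)) | comp[j : j + n]
        codes = np.minimum(codes, rc)
    return codes, valid


def encode_word(word: str, canonicalize: bool = False) -> int:
    """2-bit pack a single ACGT word (raises on non-ACGT)."""
    codes, valid = smer_codes(word, len(word), canonicalize)
    if codes.size != 1 or not valid[0]:
        raise ValueError(f"word {word!r} is not a pure ACGT word")
    return int(codes[0])


def decode_word(code: int, s: int) -> str:
    out = []
    for j in range(s - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * j)) & 3])
    return "".join(out)


def enumerate_smers(seq: str, s: int, canonicalize: bool = False) -> SmerEnumeration:
    """Every length-s window of ``seq`` in order, invalid windows flagged."""
    if s < 1:
        raise ValueError("s must be >= 1")
    seq = seq.upper()
    n = max(0, len(seq) - s + 1)
    smers: list[str] = []
    valid: list[bool] = []
    for i in range(n):
        w = seq[i : i + s]
        ok = all(c in "ACGT" for c in w)
        smers.append(canonical(w) if (ok and canonicalize) else w)
        valid.append(ok)
    return SmerEnumeration(s=s, smers=smers, valid=valid)


# ---------------------------------------------------------------------------
# counted k-mer TSV (KMC dump dialect)
# ---------------------------------------------------------------------------

def read_counted_kmers(
    path: PathLike, expected_k: Optional[int] = None
) -> CountedKmerTable:
    """Parse a KMC-dump-style TSV of counted k-mers.

    Each non-empty line is ``<kmer>\\t<count>`` with count >= 1. k is
    inferred from the first entry and every other entry must agree; when
    ``expected_k`` is given it is checked too.
    """
    entries: list[Tuple[str, int]] = []
    k = expected_k
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if "\t" not in line:
                raise FormatError(f"{path}:{lineno}: expected '<kmer>\\t<count>'")
            word, _, count_s = line.partition("\t")
            word = word.strip().upper()
            try:
                count = int(count_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: count {count_s!r} is not an integer"
                ) from None
            if count < 1:
                raise FormatError(f"{path}:{lineno}: count must be >= 1, got {count}")
            if k is None:
                k = len(word)
            elif len(word) != k:
                raise FormatError(
                    f"{path}:{lineno}: k-mer length {len(word)} != expected {k}"
                )
            entries.append((word, count))
    return CountedKmerTable(entries=entries, k=k if entries or expected_k else None)


def write_counted_kmers(table: CountedKmerTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for word, count in table.entries:
            fh.write(f"{word}\t{count}\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ streaming with transparent gzip
# ---------------------------------------------------------------------------

def _open_text(path: PathLike) -> io.TextIOBase:
    """Open a possibly-gzipped text file, sniffing the gzip magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def stream_sequences(path: PathLike) -> Iterator[SequenceRecord]:
    """Stream FASTA or FASTQ records (gzipped or not), format auto-detected.

    The format is decided by the first byte after decompression: ``>`` is
    FASTA, ``@`` is FASTQ. Records are yielded in file order without
    loading the whole file; sequences are uppercased.
    """
    fh = _open_text(path)
    try:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        elif first == "":
            return
        else:
            raise FormatError(
                f"{path}: unrecognized leading byte {first!r} (not FASTA/FASTQ)"
            )
        for rec in SeqIO.parse(fh, fmt):
            quality = None
            if fmt == "fastq":
                quality = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), quality=quality)
    finally:
        fh.close()


def write_fasta(records: Sequence[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records: Sequence[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            q = rec.quality if rec.quality is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{q}\n")
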