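"""The fimpera algorithm: index counted k-mers through their s-mers.

A k-mer of length k is represented by its z+1 constituent s-mers
(s = k - z). At build time every s-mer of every counted k-mer is inserted
into a counting filter with the k-mer's (discretized) abundance, keeping
the maximum over collisions — so each stored slot holds at least the
s-abundance s_ab of its s-mer, the maximum abundance over the k-mers
containing it. At query time a k-mer's reported abundance is the minimum of
its z+1 s-mer responses; over a read this is a sliding-window minimum with
window z+1 over the s-mer response vector. A false positive on a k-mer
therefore requires z+1 simultaneous s-mer false positives, which is what
drives the false positive rate down by roughly FPR**(z+1).

Abundances can be discretized before storage (floor-log2 or floor-log10
ranks, or identity) to fit b-bit counters. Stored values are shifted by one
(rank r is stored as r+1, saturating at 2**b - 1) so that a filter response
of 0 unambiguously means "absent" even for abundances whose rank is 0;
reports keep this shifted encoding: 0 = absent, v >= 1 = rank v - 1.

With z = 0 the s-mers are the k-mers themselves and the whole construction
degenerates exactly to the plain counting Bloom filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from . import sequence_io as sio
from .camq import CountingFilter
from .sliding_extrema import sliding_window_min

logger = logging.getLogger("fimpera")

_DISCRETIZATIONS = ("identity", "log2", "log10")
_ABUNDANCE_MODES = ("sab", "raw")


@dataclass(frozen=True)
class FimperaConfig:
    """Parameter bundle of an index.

    k: queried word length; z: shrinkage (indexed s-mers have length
    s = k - z; z = 0 degenerates to the plain counting filter); b: bits per
    counter; nb_slots: filter size in slots; discretization: abundance ->
    rank map stored in the counters; canonical: strand-insensitive indexing
    (each s-mer replaced by its canonical form at build and query);
    abundance_mode: "sab" derives s-abundances from counted k-mers, "raw"
    expects a counted s-mer table as input.
    """

    k: int = 31
    z: int = 3
    b: int = 5
    nb_slots: int = 1 << 20
    discretization: str = "log2"
    canonical: bool = False
    abundance_mode: str = "sab"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.z < self.k:
            raise ValueError("z must satisfy 0 <= z < k")
        if self.s > 32:
            raise ValueError("s = k - z must be <= 32 (2-bit packed hashing)")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.discretization not in _DISCRETIZATIONS:
            raise ValueError(f"discretization must be one of {_DISCRETIZATIONS}")
        if self.abundance_mode not in _ABUNDANCE_MODES:
            raise ValueError(f"abundance_mode must be one of {_ABUNDANCE_MODES}")

    @property
    def s(self) -> int:
        return self.k - self.z

    def spec(self) -> "DiscretizationSpec":
        return DiscretizationSpec(self.discretization, self.b)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "z": self.z,
            "b": self.b,
            "nb_slots": self.nb_slots,
            "discretization": self.discretization,
            "canonical": self.canonical,
            "abundance_mode": self.abundance_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FimperaConfig":
        return cls(**d)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Surjective map f: abundance x in [1, inf) -> rank y in [0, 2**b - 1].

    identity: y = min(x, cap); log2: y = min(floor(log2 x), cap); log10
    analogous. ``decode`` returns the abundance interval [lo, hi] a rank
    stands for (hi = None for the open-ended top rank).
    """

    mode: str
    b: int

    @property
    def cap(self) -> int:
        return (1 << self.b) - 1

    def discretize(self, x: int) -> int:
        if x < 1:
            raise ValueError("abundance must be >= 1")
        if self.mode == "identity":
            return min(int(x), self.cap)
        base = 2 if self.mode == "log2" else 10
        return min(int(math.log(x, base) + 1e-12), self.cap)

    def discretize_array(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if np.any(x < 1):
            raise ValueError("abundance must be >= 1")
        if self.mode == "identity":
            return np.minimum(x, self.cap).astype(np.int64)
        base = 2.0 if self.mode == "log2" else 10.0
        ranks = np.floor(np.log(x.astype(np.float64)) / np.log(base) + 1e-12)
        return np.minimum(ranks.astype(np.int64), self.cap)

    def decode(self, rank: int) -> tuple[int, Optional[int]]:
        if not 0 <= rank <= self.cap:
            raise ValueError(f"rank {rank} outside [0, {self.cap}]")
        if self.mode == "identity":
            return (rank, rank if rank < self.cap else None)
        base = 2 if self.mode == "log2" else 10
        lo = base**rank
        hi = base ** (rank + 1) - 1 if rank < self.cap else None
        return (lo, hi)


@dataclass
class KmerAbundanceReport:
    """Per-sequence reported k-mer abundance ranks.

    ``ranks[p]`` is the response for the k-mer starting at offset p, in the
    shifted encoding: 0 = absent (or invalid window), v >= 1 = discretized
    rank v - 1. Length is ``max(0, len(seq) - k + 1)``.
    """

    id: str
    ranks: np.ndarray

    @property
    def mean_rank(self) -> Optional[float]:
        """Mean reported rank over the read (None for reads shorter than k).

        Computed on unshifted ranks, absent k-mers contributing 0 — under
        identity discretization with large b this is the mean abundance.
        """
        if self.ranks.size == 0:
            return None
        return float(np.maximum(self.ranks - 1, 0).mean())


def compute_sab(
    table: sio.CountedKmerTable, s: int, canonical: bool = False
) -> dict[str, int]:
    """Exact s-abundance map: s-mer -> max count over k-mers containing it.

    With ``canonical``, keys are canonical s-mers and every k-mer
    contributes through the canonical form of each of its s-mers.
    """
    if table.k is not None and s > table.k:
        raise ValueError(f"s={s} exceeds table k={table.k}")
    sab: dict[str, int] = {}
    for kmer, count in table:
        for i in range(len(kmer) - s + 1):
            smer = kmer[i : i + s]
            if canonical:
                smer = sio.canonical(smer)
            if count > sab.get(smer, 0):
                sab[smer] = count
    return sab


class FimperaIndex:
    """A built fimpera index: a counting filter plus its parameter bundle."""

    def __init__(self, config: FimperaConfig, filter: Optional[CountingFilter] = None):
        self.config = config
        self.filter = filter or CountingFilter(config.nb_slots, config.b)
        if self.filter.nb_slots != config.nb_slots or self.filter.b != config.b:
            raise ValueError("filter sizing disagrees with config")
        self._spec = config.spec()

    # -- construction ------------------------------------------------------
    @classmethod
    def build(cls, table: sio.CountedKmerTable, config: FimperaConfig) -> "FimperaIndex":
        """Index a counted k-mer table (sab mode) or s-mer table (raw mode).

        In sab mode each k-mer entry inserts all its z+1 s-mers with the
        k-mer's shifted discretized count; the filter's max-on-collision
        semantics then hold the discretized s-abundance (or more) per slot.
        In raw mode the table must contain s-mers and each is inserted with
        its own count.
        """
        index = cls(config)
        if table.k is not None:
            expected = config.k if config.abundance_mode == "sab" else config.s
            if table.k != expected:
                raise ValueError(
                    f"table word length {table.k} does not match {expected} "
                    f"required by abundance_mode={config.abundance_mode!r}"
                )
        index.insert_counted(table)
        return index

    def insert_counted(self, table: sio.CountedKmerTable) -> None:
        cfg = self.config
        spec = self._spec
        if len(table) == 0:
            return
        # one joined pass: concatenate entries with an N separator so a
        # single vectorized s-mer scan covers every word, with windows that
        # straddle two words automatically invalid
        words = [w for w, _ in table]
        counts = np.array([c for _, c in table], dtype=np.int64)
        shifted = np.minimum(spec.discretize_array(counts) + 1, self.filter.cap)
        joined = "N".join(words)
        codes, valid = sio.smer_codes(joined, cfg.s, cfg.canonical)
        word_len = len(words[0])
        per_word = word_len - cfg.s + 1  # z+1 in sab mode, 1 in raw mode
        stride = word_len + 1
        starts = np.arange(len(words)) * stride
        pos = (starts[:, None] + np.arange(per_word)[None, :]).reshape(-1)
        vals = np.repeat(shifted, per_word)
        ok = valid[pos]
        self.filter.insert_max_codes(codes[pos[ok]], cfg.s, vals[ok])
        logger.info(
            "indexed %d words (%d s-mer insertions), load factor %.4f",
            len(words),
            int(ok.sum()),
            self.filter.load_factor(),
        )

    # -- querying ----------------------------------------------------------
    def smer_responses(self, seq: str) -> np.ndarray:
        """Filter responses for every s-mer window of seq (0 for invalid)."""
        cfg = self.config
        codes, valid = sio.smer_codes(seq, cfg.s, cfg.canonical)
        responses = np.zeros(codes.size, dtype=np.int64)
        if codes.size:
            responses[valid] = self.filter.lookup_codes(codes[valid], cfg.s)
        return responses

    def query_sequence(self, seq: str, optimize: bool = True) -> np.ndarray:
        """Reported rank of every k-mer of seq (shifted encoding, 0=absent).

        Two steps: look up the s-mer response vector, then take the sliding
        minimum with window z+1. With ``optimize``, the rightmost s-mer of
        each window is probed first; an absent s-mer zeroes every k-mer
        spanning it and skips the intervening lookups. Output is
        bit-identical with and without the optimization.
        """
        cfg = self.config
        n_k = len(seq) - cfg.k + 1
        if n_k <= 0:
            return np.empty(0, dtype=np.int64)
        if not optimize:
            responses = self.smer_responses(seq)
            return sliding_window_min(responses, cfg.z + 1, in_place=True)
        return self._query_optimized(seq)

    def _query_optimized(self, seq: str) -> np.ndarray:
        cfg = self.config
        codes, valid = sio.smer_codes(seq, cfg.s, cfg.canonical)
        n_k = len(seq) - cfg.k + 1
        out = np.zeros(n_k, dtype=np.int64)
        resp = np.full(codes.size, -1, dtype=np.int64)  # -1 = not looked up

        def response(p: int) -> int:
            if resp[p] < 0:
                resp[p] = (
                    self.filter.lookup_code(int(codes[p]), cfg.s) if valid[p] else 0
                )
            return int(resp[p])

        q = 0
        while q < n_k:
            # probe the rightmost s-mer of the window first: if absent, all
            # z+1 k-mers containing it are absent and their other s-mers
            # need never be looked up
            right = response(q + cfg.z)
            if right == 0:
                q = q + cfg.z + 1
                continue
            m = right
            for p in range(q, q + cfg.z):
                r = response(p)
                if r < m:
                    m = r
                if m == 0:
                    break
            out[q] = m
            q += 1
        return out

    def query_kmers(self, kmers: Iterable[str]) -> np.ndarray:
        """Reported rank for each individual k-mer (vectorized batch path)."""
        cfg = self.config
        kmers = list(kmers)
        if not kmers:
            return np.empty(0, dtype=np.int64)
        joined = "N".join(kmers)
        codes, valid = sio.smer_codes(joined, cfg.s, cfg.canonical)
        stride = cfg.k + 1
        pos = (
            np.arange(len(kmers))[:, None] * stride + np.arange(cfg.z + 1)[None, :]
        ).reshape(-1)
        responses = np.zeros(pos.size, dtype=np.int64)
        ok = valid[pos]
        responses[ok] = self.filter.lookup_codes(codes[pos[ok]], cfg.s)
        return responses.reshape(len(kmers), cfg.z + 1).min(axis=1)

    def query_file(
        self,
        path: sio.PathLike,
        output_mode: str = "per_kmer",
        threshold: Optional[float] = None,
        optimize: bool = True,
    ) -> Iterator[tuple]:
        """Stream a FASTA/FASTQ file through the index.

        output_mode "per_kmer" yields ``(id, ranks)`` per record;
        "per_read_mean" yields ``(id, mean)`` (reads shorter than k are
        skipped and tallied); "threshold" yields only records whose mean
        exceeds ``threshold``.
        """
        if output_mode not in ("per_kmer", "per_read_mean", "threshold"):
            raise ValueError(f"unknown output mode {output_mode!r}")
        if output_mode == "threshold" and threshold is None:
            raise ValueError("threshold mode requires a threshold")
        skipped = 0
        for rec in sio.stream_sequences(path):
            ranks = self.query_sequence(rec.seq, optimize=optimize)
            report = KmerAbundanceReport(id=rec.id, ranks=ranks)
            if output_mode == "per_kmer":
                yield (rec.id, ranks)
                continue
            mean = report.mean_rank
            if mean is None:
                skipped += 1
                continue
            if output_mode == "per_read_mean":
                yield (rec.id, mean)
            elif mean > threshold:
                yield (rec.id, mean)
        if skipped:
            logger.info("skipped %d reads shorter than k=%d", skipped, self.config.k)

    # -- persistence -------------------------------------------------------
    def save(self, path: sio.PathLike) -> None:
        self.filter.save(path, config=self.config.to_dict())

    @classmethod
    def load(cls, path: sio.PathLike) -> "FimperaIndex":
        filt, cfg = CountingFilter.load(path)
        if cfg is None:
            raise ValueError(f"{path}: file carries no index configuration")
        return cls(FimperaConfig.from_dict(cfg), filt)
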