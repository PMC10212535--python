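"""Counting Approximate Membership Query structures.

The contract (:class:`CountingAMQ`) is an abundance sketch whose answers are
always correct or overestimated, never underestimated: ``insert_max(key, v)``
records v at the key's slot keeping the maximum over collisions, and
``lookup(key)`` returns the slot value (0 meaning "absent"). The shipped
backend is a single-hash counting Bloom filter with b-bit saturating
counters, bit-packed so the structure occupies nb_slots x b bits; b=1
degenerates to a plain Bloom filter (presence/absence).

The slot hash is a seed-free splitmix64 finalizer applied to the 2-bit
packing of the word (length folded in), reduced modulo the slot count —
deterministic across runs and platforms and recorded in the serialized
header so index files are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import struct
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .sequence_io import encode_word

PathLike = Union[str, Path]

_MAGIC = b"FIMPIDX1"
_VERSION = 1

_U = np.uint64
_GOLDEN = 0x9E3779B97F4A7C15
_MASK64 = 0xFFFFFFFFFFFFFFFF


class IndexFileError(IOError):
    """Corrupt, truncated or incompatible serialized filter."""


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer on uint64 (wrapping arithmetic)."""
    z = x + _U(_GOLDEN)
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


def hash_codes(codes: np.ndarray, length: int, nb_slots: int) -> np.ndarray:
    """Slot indices for an array of 2-bit-packed words of the given length."""
    mixed = splitmix64(codes.astype(np.uint64) ^ _U((length * _GOLDEN) & _MASK64))
    return (mixed % _U(nb_slots)).astype(np.int64)


def hash_smer(word: str, nb_slots: int) -> int:
    """Deterministic, seed-free slot index of an ACGT word in [0, nb_slots)."""
    code = encode_word(word)
    return int(hash_codes(np.array([code], dtype=np.uint64), len(word), nb_slots)[0])


def single_hash_fpr(n_distinct: int, nb_slots: int) -> float:
    """Closed-form false positive rate of a single-hash filter.

    The probability that a never-inserted key hashes to an occupied slot
    after n distinct insertions into m slots: ``1 - (1 - 1/m)**n``.
    """
    return float(-np.expm1(n_distinct * np.log1p(-1.0 / nb_slots)))


class CountingAMQ(ABC):
    """Pluggable counting-AMQ contract: never underestimates a stored value."""

    nb_slots: int
    b: int

    @abstractmethod
    def insert_max(self, word: str, value: int) -> None: ...

    @abstractmethod
    def lookup(self, word: str) -> int: ...


class CountingFilter(CountingAMQ):
    """Single-hash counting Bloom filter with b-bit saturating counters.

    Each word hashes to one slot; inserting stores the maximum of the
    colliding values, saturating at ``2**b - 1``. Lookups return the slot
    value, hence are never below the largest value ever inserted for that
    word. Counters are bit-packed: total payload is ``nb_slots * b`` bits.
    """

    def __init__(self, nb_slots: int, b: int = 5, hash_name: str = "splitmix64"):
        if nb_slots < 1:
            raise ValueError("nb_slots must be >= 1")
        if not 1 <= b <= 8:
            raise ValueError("b must be in 1..8")
        if hash_name != "splitmix64":
            raise ValueError(f"unknown hash scheme {hash_name!r}")
        self.nb_slots = int(nb_slots)
        self.b = int(b)
        self.hash_name = hash_name
        n_bytes = (self.nb_slots * self.b + 7) // 8
        self._payload = np.zeros(n_bytes, dtype=np.uint8)

    # -- sizing ------------------------------------------------------------
    @property
    def cap(self) -> int:
        """Largest storable counter value, 2**b - 1."""
        return (1 << self.b) - 1

    @property
    def bit_size(self) -> int:
        return self.nb_slots * self.b

    # -- packed counter access --------------------------------------------
    def _unpack(self) -> np.ndarray:
        """All counters as a uint8 array of length nb_slots."""
        bits = np.unpackbits(self._payload, bitorder="little")
        bits = bits[: self.nb_slots * self.b].reshape(self.nb_slots, self.b)
        weights = (1 << np.arange(self.b)).astype(np.uint16)
        return (bits.astype(np.uint16) @ weights).astype(np.uint8)

    def _pack(self, dense: np.ndarray) -> None:
        bits = ((dense[:, None].astype(np.uint16) >> np.arange(self.b)) & 1).astype(
            np.uint8
        )
        self._payload = np.packbits(bits.reshape(-1), bitorder="little")

    def value_at(self, slot: int) -> int:
        bitpos = slot * self.b
        byte, ofs = divmod(bitpos, 8)
        chunk = int.from_bytes(self._payload[byte : byte + 2].tobytes(), "little")
        return (chunk >> ofs) & self.cap

    def _set_at(self, slot: int, value: int) -> None:
        bitpos = slot * self.b
        byte, ofs = divmod(bitpos, 8)
        width = 2 if byte + 1 < self._payload.size else 1
        chunk = int.from_bytes(self._payload[byte : byte + width].tobytes(), "little")
        chunk = (chunk & ~(self.cap << ofs)) | ((value & self.cap) << ofs)
        self._payload[byte : byte + width] = np.frombuffer(
            chunk.to_bytes(width, "little"), dtype=np.uint8
        )

    # -- the cAMQ contract -------------------------------------------------
    def insert_max(self, word: str, value: int) -> None:
        if value < 0:
            raise ValueError("value must be >= 0")
        slot = hash_smer(word, self.nb_slots)
        self.insert_max_slot(slot, value)

    def insert_max_slot(self, slot: int, value: int) -> None:
        value = min(value, self.cap)
        if value > self.value_at(slot):
            self._set_at(slot, value)

    def lookup(self, word: str) -> int:
        return self.value_at(hash_smer(word, self.nb_slots))

    # -- vectorized bulk paths (2-bit codes) -------------------------------
    def insert_max_codes(self, codes: np.ndarray, length: int, values) -> None:
        """insert_max for many packed words at once (scatter-max)."""
        if codes.size == 0:
            return
        slots = hash_codes(codes, length, self.nb_slots)
        dense = self._unpack()
        vals = np.minimum(np.asarray(values, dtype=np.int64), self.cap).astype(np.uint8)
        np.maximum.at(dense, slots, np.broadcast_to(vals, slots.shape))
        self._pack(dense)

    def lookup_codes(self, codes: np.ndarray, length: int) -> np.ndarray:
        """Slot values for many packed words at once (int64 array)."""
        if codes.size == 0:
            return np.empty(0, dtype=np.int64)
        slots = hash_codes(codes, length, self.nb_slots)
        return self._unpack()[slots].astype(np.int64)

    def lookup_code(self, code: int, length: int) -> int:
        return self.value_at(
            int(hash_codes(np.array([code], dtype=np.uint64), length, self.nb_slots)[0])
        )

    # -- occupancy ---------------------------------------------------------
    def occupied_slots(self) -> int:
        return int(np.count_nonzero(self._unpack()))

    def load_factor(self) -> float:
        return self.occupied_slots() / self.nb_slots

    # -- serialization -----------------------------------------------------
    def save(self, path: PathLike, config: Optional[dict] = None) -> None:
        """Write magic, version, JSON header, packed payload, sha256 checksum.

        ``config`` (e.g. the owning index's parameter bundle) is embedded in
        the header so the file is self-describing.
        """
        header = {
            "version": _VERSION,
            "nb_slots": self.nb_slots,
            "b": self.b,
            "hash_name": self.hash_name,
            "config": config,
        }
        hdr = json.dumps(header, sort_keys=True).encode()
        payload = self._payload.tobytes()
        digest = hashlib.sha256(hdr + payload).digest()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(hdr)))
            fh.write(hdr)
            fh.write(struct.pack("<Q", len(payload)))
            fh.write(payload)
            fh.write(digest)

    @classmethod
    def load(cls, path: PathLike) -> tuple["CountingFilter", Optional[dict]]:
        """Bit-exact round trip of :meth:`save`; returns (filter, config)."""
        with open(path, "rb") as fh:
            blob = fh.read()
        if len(blob) < len(_MAGIC) + 4 or blob[: len(_MAGIC)] != _MAGIC:
            raise IndexFileError(f"{path}: not a fimpera index file")
        off = len(_MAGIC)
        (hdr_len,) = struct.unpack_from("<I", blob, off)
        off += 4
        if len(blob) < off + hdr_len + 8:
            raise IndexFileError(f"{path}: truncated header")
        hdr = blob[off : off + hdr_len]
        off += hdr_len
        header = json.loads(hdr)
        if header.get("version") != _VERSION:
            raise IndexFileError(
                f"{path}: unsupported format version {header.get('version')}"
            )
        (payload_len,) = struct.unpack_from("<Q", blob, off)
        off += 8
        if len(blob) < off + payload_len + 32:
            raise IndexFileError(f"{path}: truncated payload")
        payload = blob[off : off + payload_len]
        off += payload_len
        digest = blob[off : off + 32]
        if hashlib.sha256(hdr + payload).digest() != digest:
            raise IndexFileError(f"{path}: checksum mismatch")
        filt = cls(header["nb_slots"], header["b"], header["hash_name"])
        arr = np.frombuffer(payload, dtype=np.uint8)
        if arr.size != filt._payload.size:
            raise IndexFileError(f"{path}: payload size does not match header")
        filt._payload = arr.copy()
        return filt, header.get("config")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountingFilter):
            return NotImplemented
        return (
            self.nb_slots == other.nb_slots
            and self.b == other.b
            and self.hash_name == other.hash_name
            and np.array_equal(self._payload, other._payload)
        )
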