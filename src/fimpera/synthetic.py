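"""Synthetic genomes, reads and counted k-mer tables for testing and study.

Emulates the real-data workflow — one sample indexed as a counted k-mer
table, another queried as reads — with random uniform-base genomes, so
every experiment runs from a seed with no downloads. Generators draw from
a single per-scenario RNG stream split by fixed operation labels, so adding
an operation never perturbs earlier draws, and everything is
bit-reproducible from (seed, parameters).

The default abundance profile is geometric with mean 3 (counts >= 1): a
heavy-tailed, mostly-low-abundance profile typical of shotgun metagenomic
k-mer spectra. The experiment harness measures false positive and
abundance-error rates, which do not depend on the exact profile shape.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import sequence_io as sio
from .core import FimperaConfig, FimperaIndex
from .evalmetrics import GroundTruth, classify_calls, summarize

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rng_for(seed: int, label: str) -> np.random.Generator:
    """An independent generator for (seed, operation label)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class SyntheticScenario:
    """A fully seeded index/query experiment definition.

    ``fraction_absent_reads`` of the query reads are sampled from a second
    random genome verified to share no k-mer with the indexed one (the
    ground-truth-negative material); the rest come from the indexed genome.
    """

    seed: int = 0
    genome_length: int = 20_000
    k: int = 31
    z: int = 3
    b: int = 5
    nb_slots: int = 1 << 16
    read_count: int = 200
    read_length: int = 100
    fraction_absent_reads: float = 0.25
    abundance_mean: float = 3.0
    discretization: str = "log2"
    canonical: bool = False

    def config(self, z: Optional[int] = None) -> FimperaConfig:
        return FimperaConfig(
            k=self.k,
            z=self.z if z is None else z,
            b=self.b,
            nb_slots=self.nb_slots,
            discretization=self.discretization,
            canonical=self.canonical,
        )


def generate_genome(length: int, seed: int, label: str = "genome") -> str:
    """A uniform i.i.d. random DNA string."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = rng_for(seed, label)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def sample_reads(
    genome: str,
    n: int,
    read_length: int,
    revcomp_prob: float = 0.0,
    seed: int = 0,
    label: str = "reads",
    id_prefix: str = "read",
) -> list[sio.SequenceRecord]:
    """Reads as uniform-position substrings, reverse-complemented with
    probability ``revcomp_prob``."""
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = rng_for(seed, label)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n)
    flips = rng.random(n) < revcomp_prob
    records = []
    for i, (start, flip) in enumerate(zip(starts.tolist(), flips.tolist())):
        seq = genome[start : start + read_length]
        if flip:
            seq = sio.reverse_complement(seq)
        records.append(sio.SequenceRecord(id=f"{id_prefix}_{i}", seq=seq))
    return records


def geometric_abundance(mean: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Geometric profile on {1, 2, ...} with the given mean."""
    if mean < 1:
        raise ValueError("geometric mean must be >= 1")
    p = 1.0 / mean
    return lambda rng, n: rng.geometric(p, size=n)


def constant_abundance(c: int) -> Callable[[np.random.Generator, int], np.ndarray]:
    return lambda rng, n: np.full(n, c, dtype=np.int64)


def counted_kmers_from_genome(
    genome: str,
    k: int,
    abundance_profile: Optional[Callable] = None,
    canonical: bool = False,
    seed: int = 0,
    label: str = "counts",
) -> sio.CountedKmerTable:
    """Exact k-mer enumeration of a genome with profile-drawn counts.

    Every distinct (canonical) k-mer appears once, assigned a count >= 1
    drawn from the profile — a stand-in for a k-mer counter run on a
    sequenced sample.
    """
    if len(genome) < k:
        raise ValueError("genome shorter than k")
    seen: dict[str, None] = {}
    for i in range(len(genome) - k + 1):
        w = genome[i : i + k]
        if canonical:
            w = sio.canonical(w)
        seen.setdefault(w, None)
    kmers = list(seen)
    profile = abundance_profile or geometric_abundance(3.0)
    counts = profile(rng_for(seed, label), len(kmers))
    return sio.CountedKmerTable(
        entries=[(w, int(c)) for w, c in zip(kmers, counts)], k=k
    )


def generate_absent_kmers(
    truth: GroundTruth, n: int, seed: int = 0, label: str = "absent", max_tries: int = 50
) -> list[str]:
    """n random k-mers verified absent from the truth (rejection sampling)."""
    k = truth.config.k
    rng = rng_for(seed, label)
    out: list[str] = []
    for _ in range(max_tries):
        if len(out) >= n:
            break
        need = n - len(out)
        draws = _BASES[rng.integers(0, 4, size=(need, k))]
        for row in draws:
            w = row.tobytes().decode("ascii")
            if truth.count(w) == 0:
                out.append(w)
    if len(out) < n:
        raise RuntimeError(
            f"could not find {n} absent k-mers in {max_tries} rounds "
            "(truth pathologically saturated)"
        )
    return out


def disjoint_genome(
    indexed_genome: str, length: int, k: int, seed: int, label: str = "absent_genome"
) -> str:
    """A random genome sharing no k-mer with ``indexed_genome`` (verified;
    regenerated with a bumped label on violation)."""
    indexed = {
        indexed_genome[i : i + k] for i in range(len(indexed_genome) - k + 1)
    }
    indexed |= {sio.reverse_complement(w) for w in indexed}
    for attempt in range(50):
        g = generate_genome(length, seed, f"{label}_{attempt}")
        if all(g[i : i + k] not in indexed for i in range(len(g) - k + 1)):
            return g
    raise RuntimeError("could not generate a k-mer-disjoint genome")


def scenario_materials(scenario: SyntheticScenario):
    """(table, truth, query reads, absent probe genome) for a scenario."""
    g = generate_genome(scenario.genome_length, scenario.seed)
    table = counted_kmers_from_genome(
        g,
        scenario.k,
        geometric_abundance(scenario.abundance_mean),
        scenario.canonical,
        scenario.seed,
    )
    truth = GroundTruth.from_table(table, scenario.config())
    g_absent = disjoint_genome(
        g, scenario.genome_length, scenario.k, scenario.seed
    )
    n_absent = int(round(scenario.read_count * scenario.fraction_absent_reads))
    reads = sample_reads(
        g, scenario.read_count - n_absent, scenario.read_length,
        seed=scenario.seed, label="reads_present", id_prefix="present",
    ) + sample_reads(
        g_absent, n_absent, scenario.read_length,
        seed=scenario.seed, label="reads_absent", id_prefix="absent",
    )
    return table, truth, reads, g_absent


def smer_saturation_probability(s: int, n_chars: float) -> float:
    """Probability a random s-mer occurs by chance among n characters:
    ``1 - (1 - 1/4**s)**n``."""
    return float(-np.expm1(n_chars * np.log1p(-(0.25**s))))


def fpr_experiment(
    scenario: SyntheticScenario,
    z_values: Sequence[int],
    n_absent_probes: int = 20_000,
    n_present_probes: int = 5_000,
) -> pd.DataFrame:
    """Build one index per z at fixed filter size and measure error rates.

    Absent probes are i.i.d. uniform random k-mers verified absent (so the
    per-s-mer independence model applies); present probes are indexed
    k-mers. Each row reports the empirical FPR, the construction-FP share,
    the incorrect-abundance rate over true positives, and the analytic
    chance-saturation probability of an s-mer for the scenario's character
    count.
    """
    g = generate_genome(scenario.genome_length, scenario.seed)
    table = counted_kmers_from_genome(
        g,
        scenario.k,
        geometric_abundance(scenario.abundance_mean),
        scenario.canonical,
        scenario.seed,
    )
    rng = rng_for(scenario.seed, "probe_subset")
    kmers = [w for w, _ in table]
    present = [kmers[i] for i in rng.choice(len(kmers), min(n_present_probes, len(kmers)), replace=False)]
    rows = []
    for z in z_values:
        cfg = scenario.config(z=z)
        truth = GroundTruth.from_table(table, cfg)
        absent = generate_absent_kmers(
            truth, n_absent_probes, scenario.seed, label=f"absent_z{z}"
        )
        index = FimperaIndex.build(table, cfg)
        probes = absent + present
        responses = index.query_kmers(probes)
        cls = classify_calls(probes, responses, truth)
        summ = summarize(cls)
        rows.append(
            {
                "z": z,
                "s": cfg.s,
                "empirical_fpr": summ.fpr,
                "construction_fp_share": summ.construction_fp_share,
                "incorrect_abundance_rate": summ.incorrect_abundance_rate,
                "load_factor": index.filter.load_factor(),
                "analytic_smer_saturation": smer_saturation_probability(
                    cfg.s, len(g)
                ),
            }
        )
    return pd.DataFrame(rows)
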