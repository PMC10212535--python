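# fimpera

Indexing the *abundance* of k-mers at petabyte scale forces a trade-off:
counting approximate-membership-query structures such as counting Bloom
filters (cBF) store counts in fixed memory but pay a steep false positive
rate. This package implements **fimpera**, a wrapper that improves any such
counting structure: instead of indexing k-mers, it indexes their
constituent **s-mers** (s = k − z) together with their s-abundance
s_ab — the maximum abundance over the k-mers containing them — and answers
a k-mer query as the minimum of its z + 1 s-mer responses. A k-mer false
positive then requires z + 1 simultaneous s-mer false positives, so the
rate falls roughly as FPR^(z+1) at identical memory, while answers remain
*never underestimated*: an indexed k-mer is always reported with at least
its true (discretized) abundance. It is aimed at metagenomics and any
k-mer-abundance workload where the index must fit in a fixed memory budget.

The per-read query reduces to a sliding-window minimum, and the package
ships the standalone **fixed-window** algorithm for it: linear time, no
heap allocation, result written in place over the input (usable on its own
via `fimpera.sliding_window_min` / `sliding_window_max`).

Modules: `sequence_io` (counted k-mer TSV, FASTA/FASTQ with transparent
gzip, canonical k-mers, 2-bit encoding), `sliding_extrema`, `camq` (the
bit-packed single-hash counting Bloom filter behind a pluggable contract),
`core` (build/query), `evalmetrics` (exact-oracle call classification:
construction vs collision errors, FPR, overestimation score), `synthetic`
(seeded genomes, reads, counted tables, z-sweep harness), and a `fimpera`
CLI (`index`, `query`, `evaluate`, `synth`).

## Worked example

```python
from fimpera import (CountedKmerTable, FimperaConfig, FimperaIndex,
                     sliding_window_min)

# the sliding minimum the query step is built on (window 3):
print(sliding_window_min([5, 3, 7, 1, 4, 5, 3, 2, 2, 3], 3).tolist())
# [3, 1, 1, 1, 3, 2, 2, 2]

table = CountedKmerTable([("ACGTA", 5), ("CGTAC", 3)], k=5)
cfg = FimperaConfig(k=5, z=1, b=8, nb_slots=4096, discretization="identity")
idx = FimperaIndex.build(table, cfg)
idx.filter.lookup("CGTA")        # 6: s_ab(CGTA) = max(5, 3) = 5, stored as 5+1
idx.query_sequence("ACGTAC")     # array([6, 4]): responses 0 = absent,
                                 # v >= 1 = discretized rank v - 1
```

A seeded z sweep at fixed filter size (20 kb genome, 16 Ki slots, 20 000
absent probes) shows the false positive rate falling as z grows while the
z = 0 row reproduces the bare counting-filter rate:

```python
from fimpera import SyntheticScenario, fpr_experiment
df = fpr_experiment(SyntheticScenario(seed=1, genome_length=20_000,
                                      nb_slots=1 << 14),
                    [0, 1, 2, 3], n_absent_probes=20_000)
print(df[["z", "s", "empirical_fpr", "load_factor"]].to_string(index=False))
#  z  s  empirical_fpr  load_factor
#  0 31        0.70430     0.706543
#  1 30        0.49900     0.707275
#  2 29        0.35325     0.703674
#  3 28        0.24815     0.706421
```

At 70.6% filter load the z = 0 rate matches the single-hash closed form
1 − (1 − 1/m)^n = 0.7044, and z = 3 lands on its fourth power
(0.7043⁴ ≈ 0.2462 ≈ 0.248 measured): each extra s-mer per k-mer multiplies
the false positive rate by the per-s-mer rate.

From a shell, the same pipeline end to end:

```sh
fimpera synth --seed 5 --genome-length 3000 -k 21 --out-prefix demo
fimpera index --kmers demo.kmers.tsv -k 21 -z 3 -b 5 --nb-slots 16384 -o demo.idx
fimpera query --index demo.idx --query demo.query.fasta --output per-kmer
fimpera evaluate --index demo.idx --truth-kmers demo.truth.tsv \
                 --query demo.query.fasta --z-sweep 0,3
```

See `docs/methods.md` for the model, the in-place sliding-minimum
algorithm, the abundance encoding, and what the synthetic benchmarks do
and do not demonstrate.

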