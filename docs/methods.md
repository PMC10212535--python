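# Methods

## Problem and model

Counting approximate-membership-query (cAMQ) structures — here a counting
Bloom filter (cBF) with a single hash function and b-bit counters — answer
k-mer abundance queries with responses that are always correct or
overestimated, never underestimated: colliding insertions keep the maximum.
At the memory budgets practical for metagenomic-scale k-mer sets, a plain
cBF pays a substantial false positive rate (the single-hash closed form is
`FPR = 1 − (1 − 1/m)**n` for n distinct keys in m slots).

fimpera wraps any such structure. Instead of indexing k-mers directly, it
indexes their constituent s-mers, s = k − z. Each s-mer is stored with its
**s-abundance** `s_ab` — the maximum abundance over all indexed k-mers
containing it. At query time a k-mer is reported present only if all of its
z + 1 s-mers respond positively, and its reported abundance is the minimum
of their responses. Over a read of length L this is a sliding-window
minimum (window z + 1) over the L − s + 1 s-mer responses. A k-mer false
positive therefore needs z + 1 simultaneous s-mer false positives, so the
rate falls approximately as `FPR**(z+1)`; with z = 3 and a 25% per-s-mer
rate that is 0.25⁴ ≈ 0.39%. Because `s_ab ≥ abundance(d)` for every s-mer
of an indexed k-mer d, and the filter never underestimates, the end-to-end
answer never underestimates either: indexed k-mers are never missed.

The decomposition introduces two filter-independent error kinds, which the
evaluation module separates out using exact oracles:

* **construction false positives** — an absent k-mer all of whose s-mers
  truly occur in the indexed set;
* **construction overestimations** — a present k-mer whose every
  minimal-window s-mer is inflated by more abundant neighboring k-mers.

Both are decided against the exact `s_ab` map recomputed from the input
table, never against the filter, so the split is independent of filter
load. A mixed error (construction and collision both possible) counts as
construction, matching the filter-independent definition. Underestimation
is impossible by construction in s-abundance mode; the classifier raises if
it ever observes one rather than inventing a label for it.

## Sliding-window minimum ("fixed window" algorithm)

The query step needs the minimum of every length-W window of a response
vector, in linear time and without per-call heap allocation. The vector is
split into consecutive non-overlapping blocks of size W; within block j,
`minL` is the running block-prefix minimum and `minR` the block-suffix
minimum, and the sliding window starting at i spans the tail of one block
and the head of the next, so `r[i] = min(minL[i+W−1], minR[i])`.

Storage tricks: `minL` is a running scalar, never materialized; `minR` is
written over the input (safe because `r[i] ≤ minR[i] ≤ v[i]`); the result
itself overwrites the input prefix. One ordering subtlety matters: the
running `minL` must consume a block's *original* values, so the passes are
interleaved — for each block, first finish the results of the previous
block (reading the current block's untouched values), then overwrite the
current block with its suffix minima. Folding the minR pass over the whole
vector *before* the minL sweep would feed suffix minima into `minL` and
underestimate some windows (e.g. v = [5,5,5,0], W = 2 would yield
r[1] = 0 instead of 5).

A trailing block shorter than W is treated as a shorter final fixed window.
Ties need no special handling. The "no dynamic allocation" property is
exposed as a testable contract: auxiliary state is a constant number of
scalars, and an operation-count instrumentation (`OpCount`) verifies the
comparison count is O(|v|) with no W factor. The maximum variant is the
same algorithm with the comparison flipped.

## Counting filter backend

Single-hash cBF with b-bit saturating counters (b in 1..8, default 5),
bit-packed so the payload is exactly `nb_slots × b` bits; b = 1 degenerates
to a plain Bloom filter and is kept working intentionally. The slot index
is a splitmix64 finalizer applied to the 2-bit packing of the word (word
length folded in), reduced modulo the slot count — seed-free, deterministic
across platforms, uniform by chi-square test, and vectorizable over numpy
uint64 code arrays. 2-bit packing limits hashed words to 32 bases; only
s-mers are hashed, so k is unconstrained for z ≥ k − 32. The backend sits
behind a small abstract contract (`CountingAMQ`) so an alternative
structure (e.g. a counting quotient filter) could be plugged in; only the
cBF ships.

Index files are self-describing: magic bytes, format version, a JSON header
carrying the full parameter bundle and hash name, the packed payload, and a
SHA-256 checksum. Truncation, corruption and version mismatch are declared
errors, never garbage.

## Encoding of stored abundances

Abundances are discretized before storage by a surjective monotone map
`f: [1, ∞) → [0, 2**b − 1]`: `identity`, `floor(log2)` (default) or
`floor(log10)`, saturating at the counter cap. A rank of 0 (e.g. abundance
1 under log2) would collide with the filter's "absent" encoding, so ranks
are stored shifted by one (rank r → r + 1, saturating). Reports keep the
shifted encoding: 0 means absent or invalid window, v ≥ 1 means rank
v − 1. The shift survives the sliding minimum unchanged (it is monotone),
and all evaluation comparisons are made in the same encoding, so no
ambiguity remains anywhere in the pipeline. The cost is one rank of
headroom: the largest representable rank is 2**b − 2.

Per-read means are computed over unshifted ranks with absent k-mers
contributing 0; under identity discretization with b = 8 this reproduces
plain abundance averaging (counts capped at 254).

Canonicalization, when enabled, is applied at the s-mer level (each s-mer
replaced by the lexicographic minimum of itself and its reverse
complement, at build and at query). k-mer-level canonicalization would
break s-mer sharing across strand flips, which is what makes streamed
queries cheap. The flag is recorded in the index header.

## Query optimization

The naive query looks up every s-mer then takes the sliding minimum. The
optimized path probes the *rightmost* s-mer of each window first: if it is
absent, every k-mer spanning it is reported 0 and the query jumps past it,
skipping the intervening lookups entirely. Responses are cached so no
s-mer is looked up twice. The two paths are bit-identical by contract and
by test (including chimeric present/absent reads and reads with ambiguous
bases).

## Synthetic data

The generators emulate the real workflow — one sample indexed as a counted
k-mer table, a second sample queried as reads — with uniform i.i.d. random
genomes:

* genomes of configurable length (default scenario: 20 kb, desk scale);
* counted k-mer tables by exact enumeration, counts drawn from a geometric
  profile with mean 3 (counts ≥ 1) — a heavy-tailed, mostly-low-abundance
  profile in the spirit of shotgun metagenomic k-mer spectra; the measured
  quantities are rates, which do not depend on the profile's exact shape;
* reads as uniform-position substrings, optionally reverse-complemented;
* ground-truth-negative material from a second genome verified to share no
  k-mer with the first (regenerated on violation);
* absent k-mer probes by rejection sampling, i.i.d. uniform so that the
  per-s-mer independence model applies to the FPR measurements.

All draws come from one RNG stream per (seed, operation label), so adding
an operation never perturbs earlier draws and every scenario is
bit-reproducible.

What the generator does **not** emulate: sequencing errors and quality
scores, community abundance structure, GC bias, repeats beyond chance
k-mer sharing. Passing tests therefore demonstrate the algorithmic
contracts (no underestimation, FPR laws, z-monotonicity, optimization
equivalence) on idealized data, not performance on real metagenomes.

## Experiment harness and problem sizes

`fpr_experiment` builds one index per z at fixed filter size, probes
i.i.d. absent k-mers and indexed k-mers, classifies every call against the
exact oracles, and reports the empirical FPR, construction-FP share,
incorrect-abundance rate, filter load and the analytic chance-saturation
probability `1 − (1 − 1/4**s)**n` of an s-mer among n indexed characters.
Desk-scale defaults (20 kb genome, 2×10⁴ absent probes, 16 Ki–64 Ki slot
filters) were chosen so a full z sweep runs in seconds while keeping
binomial standard errors small relative to the effects measured; the
million-probe FPR-power-law check sizes its filter (10⁵ slots) so the
closed-form per-s-mer rate is exactly tunable to 25%.

## Numerical choices

* Discretization uses `floor(log(x)/log(base) + 1e-12)`: the epsilon
  absorbs float error at exact powers (verified against exact integer
  expectations for all powers up to 2³⁰).
* Closed-form probabilities use `expm1`/`log1p` to stay accurate at
  per-slot probabilities of 10⁻⁹ and below.
* Reads shorter than k yield an empty rank vector, are skipped by
  per-read-mean output and tallied in the log.
* Non-ACGT query windows respond 0 (absent) and count as ground-truth
  absent; empty denominators in summary rates are reported as undefined
  (None), never as 0.

## Known limitations

* Hashed words (s-mers) are limited to 32 bases by the single-chunk 2-bit
  packing.
* Raw s-mer-count mode (`abundance_mode="raw"`) is implemented but the
  no-underestimation guarantee only holds in s-abundance mode; the
  classifier assumes s-abundance truth.
* Single dataset per index; no online insertion after build; no
  multi-sample matrices.
* The optimized query path is scalar Python per read; the batch path
  (`query_kmers`) is vectorized and preferred for large probe campaigns.
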