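"""Linear-time sliding-window minimum and maximum with constant extra memory.

The "fixed window" algorithm: split the input vector into consecutive
non-overlapping blocks of the window size W. Within block j define

* ``minL[i]`` — the running minimum of the block from its start up to i;
* ``minR[i]`` — the suffix minimum of the block from i to its end.

The minimum of the *sliding* window starting at i is then
``r[i] = min(minL[i + W - 1], minR[i])``: the window spans the tail of one
block and the head of the next, and those two block-aligned partial minima
cover it exactly. ``minL`` never needs to be stored (it is a running scalar)
and ``minR`` can overwrite the input, since ``r[i] <= minR[i] <= v[i]`` at
every position; the result itself is also written over the input prefix.
The passes are interleaved block by block — each block's original values are
consumed for the running ``minL`` (finishing the previous block's results)
before being overwritten with that block's suffix minima — so the whole
computation is two linear sweeps with a constant number of scalars of
auxiliary state, no heap, no deque, and no dependence of the operation count
on W beyond the vector length itself.

A trailing block shorter than W is handled as a shorter final fixed window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class OpCount:
    """Instrumentation for the linearity contract: element reads/compares."""

    comparisons: int = 0
    reads: int = 0


def _sliding_extremum(
    v, W: int, better, in_place: bool, ops: Optional[OpCount]
) -> np.ndarray:
    n = len(v)
    if W < 1 or W > n:
        raise ValueError(f"window size {W} outside [1, {n}]")
    if in_place and isinstance(v, np.ndarray):
        a = v
    else:
        a = np.array(v)  # the caller keeps its input; we work on a copy
    n_out = n - W + 1

    # suffix extrema of block 0, in place
    for i in range(min(W, n) - 2, -1, -1):
        if better(a[i + 1], a[i]):
            a[i] = a[i + 1]
        if ops:
            ops.comparisons += 1
            ops.reads += 2

    block_start = W
    while block_start - W < n_out:
        block_end = min(block_start + W, n)
        # the block-aligned window starting at block_start - W is exactly the
        # previous block, whose suffix extremum already sits at that slot —
        # nothing to write for it. A running extremum over the current
        # block's original values closes the windows that start inside the
        # previous block.
        cur = None
        for p in range(block_start, block_end):
            i = p - W + 1
            if i > n_out - 1:
                break
            if cur is None or better(a[p], cur):
                cur = a[p]
            if ops:
                ops.comparisons += 1
                ops.reads += 1
            prev = a[i]  # this is minR[i] of the previous block
            a[i] = cur if better(cur, prev) else prev
            if ops:
                ops.comparisons += 1
                ops.reads += 1
        # overwrite the current block with its suffix extrema
        for p in range(block_end - 2, block_start - 1, -1):
            if better(a[p + 1], a[p]):
                a[p] = a[p + 1]
            if ops:
                ops.comparisons += 1
                ops.reads += 2
        block_start += W

    return a[:n_out] if in_place else a[:n_out].copy()


def sliding_window_min(
    v: Sequence, W: int, in_place: bool = False, ops: Optional[OpCount] = None
) -> np.ndarray:
    """Minimum of every length-W window of v.

    Returns ``r`` with ``r[i] = min(v[i], ..., v[i+W-1])`` for
    ``i in [0, len(v)-W]``. With ``in_place`` and a numpy input the result
    is written over the input's prefix and no buffer proportional to the
    input length is allocated; otherwise the input is left untouched.
    Pass an :class:`OpCount` to count element reads and comparisons.
    """
    return _sliding_extremum(v, W, lambda x, y: x < y, in_place, ops)


def sliding_window_max(
    v: Sequence, W: int, in_place: bool = False, ops: Optional[OpCount] = None
) -> np.ndarray:
    """Maximum of every length-W window of v (same contract as the minimum)."""
    return _sliding_extremum(v, W, lambda x, y: x > y, in_place, ops)


def fixed_window_tables(v: Sequence, W: int) -> tuple[np.ndarray, np.ndarray]:
    """The (minL, minR) block-prefix/suffix minima, materialized.

    Exposition and testing helper only — the production path never stores
    minL and keeps minR inside the queried vector. Satisfies
    ``r[i] = min(minL[i+W-1], minR[i])`` and ``r[i] <= minR[i] <= v[i]``.
    """
    a = np.array(v)
    n = a.size
    if W < 1 or W > n:
        raise ValueError(f"window size {W} outside [1, {n}]")
    minL = a.copy()
    minR = a.copy()
    for i in range(n):
        if i % W != 0 and minL[i - 1] < minL[i]:
            minL[i] = minL[i - 1]
    for i in range(n - 2, -1, -1):
        if (i + 1) % W != 0 and minR[i + 1] < minR[i]:
            minR[i] = minR[i + 1]
    return minL, minR
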