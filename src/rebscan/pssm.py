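"""Profile–sequence local alignment kernel.

Smith–Waterman (Gotoh affine-gap) DP of a position-specific scoring matrix
against an integer-encoded sequence.  No pre-installed library exposes
profile-vs-sequence local alignment, so this one kernel is implemented here
and JIT-compiled with numba.  Gap convention matches the pairwise aligner:
the first residue of a gap scores ``gap_open``, each further residue
``gap_extend`` (both negative).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG_INF = -1e30


@njit(cache=False)
def _sw_kernel(weights, seq, gap_open, gap_extend):  # pragma: no cover - jit
    n_cols = weights.shape[0]
    n = seq.shape[0]
    h_prev = np.zeros(n + 1)
    h_cur = np.zeros(n + 1)
    f = np.full(n + 1, _NEG_INF)
    best = 0.0
    for i in range(1, n_cols + 1):
        e = _NEG_INF
        h_cur[0] = 0.0
        for j in range(1, n + 1):
            f[j] = max(f[j] + gap_extend, h_prev[j] + gap_open)
            e = max(e + gap_extend, h_cur[j - 1] + gap_open)
            h = h_prev[j - 1] + weights[i - 1, seq[j - 1]]
            if f[j] > h:
                h = f[j]
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


def profile_local_score(
    weights: np.ndarray,
    encoded_seq: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best local alignment score of a profile against an encoded sequence."""
    if weights.ndim != 2:
        raise ValueError("weights must be 2-D (columns x alphabet)")
    return float(
        _sw_kernel(
            np.ascontiguousarray(weights, dtype=np.float64),
            np.ascontiguousarray(encoded_seq, dtype=np.int64),
            float(gap_open),
            float(gap_extend),
        )
    )
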