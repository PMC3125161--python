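"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the package's own dynamic-programming and scoring
paths: the block-alignment optimum is found by exhaustive enumeration and
the rigid baseline by plain iterated global superposition.
"""

from functools import lru_cache

import numpy as np

from flexalign.geometry import apply, kabsch


def brute_force_block_objective(S: np.ndarray, penalty: float, min_block: int = 6) -> float:
    """Exhaustive optimum of Σ S − penalty·(unmatched) over block alignments.

    Enumerates placements of diagonal blocks of length ≥ min_block with
    strictly increasing coordinates (adjacent blocks merge into longer runs,
    which the enumeration covers by allowing any block length ≥ min_block).
    """
    n1, n2 = S.shape
    G = S + 2.0 * penalty

    @lru_cache(maxsize=None)
    def best_gain(i0: int, j0: int) -> float:
        out = 0.0
        for i in range(i0, n1 - min_block + 1):
            for j in range(j0, n2 - min_block + 1):
                diag = 0.0
                for t in range(min_block):
                    diag += G[i + t, j + t]
                k = min_block
                while True:
                    cand = diag + best_gain(i + k, j + k)
                    if cand > out:
                        out = cand
                    if i + k >= n1 or j + k >= n2:
                        break
                    diag += G[i + k, j + k]
                    k += 1
        return out

    result = best_gain(0, 0) - penalty * (n1 + n2)
    best_gain.cache_clear()
    return result


def rigid_coverage(P: np.ndarray, Q: np.ndarray, cutoff: float = 5.0, rounds: int = 8) -> float:
    """Fraction of identity-corresponded sites within *cutoff* of the best
    single rigid superposition, refined by iteratively refitting on the
    currently covered subset (in the style of rigid-body aligners)."""
    n = P.shape[0]
    sel = np.arange(n)
    best = 0.0
    for _ in range(rounds):
        t = kabsch(P[sel], Q[sel])
        if t is None:
            break
        d = np.linalg.norm(apply(t, P) - Q, axis=1)
        cov = float((d <= cutoff).mean())
        best = max(best, cov)
        new_sel = np.flatnonzero(d <= cutoff)
        if new_sel.size < 3 or np.array_equal(new_sel, sel):
            break
        sel = new_sel
    return best
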