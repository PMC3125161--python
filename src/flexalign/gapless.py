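"""Sliding gapless alignments: the null model for prediction-quality scores.

The shorter domain is laid identity-wise onto windows of the longer domain,
starting at its N-terminus and sliding in leaps of 20 residues, with an extra
C-terminal window appended when the last leap does not land there.  Each
window is scored as a fixed (non-optimised) alignment.
"""

from __future__ import annotations

from flexalign.alignment_engine import EngineConfig, evaluate_alignment
from flexalign.structure_io import CAStructure

DEFAULT_LEAP = 20


def gapless_offsets(l_short: int, l_long: int, leap: int = DEFAULT_LEAP) -> list[int]:
    """Window start offsets in the longer structure: 0, leap, 2·leap, …, plus
    the C-terminal offset ``l_long − l_short`` if not already reached."""
    if l_short > l_long:
        raise ValueError("l_short must not exceed l_long; order the arguments")
    if leap < 1:
        raise ValueError("leap must be >= 1")
    last = l_long - l_short
    offsets = list(range(0, last + 1, leap))
    if offsets[-1] != last:
        offsets.append(last)
    return offsets


def score_gapless(
    a: CAStructure,
    b: CAStructure,
    leap: int = DEFAULT_LEAP,
    cfg: EngineConfig = EngineConfig(),
) -> list[tuple[int, float]]:
    """Score every gapless window between two labelled structures.

    Returns (offset, score) per window.  Fragments and neighbourhoods are
    computed on the shorter structure and on each window of the longer one
    (SSE labels are taken from the full chain; the decomposition is re-run on
    the window, which is the object being scored).
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    out: list[tuple[int, float]] = []
    n = len(short)
    for off in gapless_offsets(n, len(long_), leap):
        window = long_.slice(off, off + n)
        pairs = tuple((i, i) for i in range(n))
        score, _ = evaluate_alignment(short, window, pairs, cfg)
        out.append((off, score))
    return out
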