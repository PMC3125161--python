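"""Backbone fragmentation and fragment neighbourhoods.

The chain is partitioned into consecutive fragments that never mix
secondary-structure labels.  Within a maximal run of one label the cut rule
is: look at the next k = min(9, remaining) sites; if k = 9 emit a fragment of
6 (leaving at least 3 for the next one), otherwise emit all k.  Runs shorter
than 3 become (short) fragments as-is, so lengths are 3–9 except for those
rare short runs.

A fragment's neighbourhood is the set of the m sites of the whole chain
nearest to the fragment, where the site-to-fragment distance is the shortest
3D distance to any fragment site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flexalign.structure_io import CAStructure

#: look-ahead window within an SSE run
MAX_LOOK = 9
#: fragment size emitted when the window is full
TAKE = 6
#: default neighbourhood size (training-set value not published; tunable)
DEFAULT_M = 40


@dataclass(frozen=True)
class Fragment:
    """A contiguous, SSE-pure backbone segment ([start, end] inclusive)."""

    index: int
    start: int
    end: int
    sse_class: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def sites(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class Neighbourhood:
    fragment_index: int
    member_sites: frozenset[int]
    m: int


def decompose(
    sse_labels: str,
    max_look: int = MAX_LOOK,
    take: int = TAKE,
) -> list[Fragment]:
    """Partition a label string into fragments (tiling 0..n-1)."""
    if not sse_labels:
        raise ValueError("sse_labels must be nonempty")
    fragments: list[Fragment] = []
    n = len(sse_labels)
    pos = 0
    while pos < n:
        run_end = pos
        while run_end < n and sse_labels[run_end] == sse_labels[pos]:
            run_end += 1
        cursor = pos
        while cursor < run_end:
            k = min(max_look, run_end - cursor)
            size = take if k == max_look else k
            fragments.append(
                Fragment(
                    index=len(fragments),
                    start=cursor,
                    end=cursor + size - 1,
                    sse_class=sse_labels[pos],
                )
            )
            cursor += size
        pos = run_end
    return fragments


def fragments_for(s: CAStructure) -> list[Fragment]:
    """Decompose a labelled structure into fragments."""
    if s.sse is None:
        raise ValueError(f"structure {s.id} has no SSE labels; run assign_sse first")
    return decompose(s.sse)


def fragment_of_site(fragments: list[Fragment], n: int) -> np.ndarray:
    """Map each site index 0..n-1 to the index of its fragment."""
    out = np.empty(n, dtype=int)
    for f in fragments:
        out[f.start : f.end + 1] = f.index
    return out


def neighbourhood(s: CAStructure, f: Fragment, m: int = DEFAULT_M) -> Neighbourhood:
    """The min(m, n) sites nearest to fragment *f* (fragment sites included).

    Ties in the site-to-fragment distance are broken by smaller site index.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    coords = s.coords
    frag_coords = coords[f.start : f.end + 1]
    # shortest distance from every site to the fragment
    diff = coords[:, None, :] - frag_coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    k = min(m, len(s))
    # stable sort on distance => ties resolved by smaller index
    order = np.argsort(dist, kind="stable")[:k]
    return Neighbourhood(fragment_index=f.index, member_sites=frozenset(int(i) for i in order), m=m)


def neighbourhoods_for(
    s: CAStructure, fragments: list[Fragment], m: int = DEFAULT_M
) -> list[Neighbourhood]:
    return [neighbourhood(s, f, m) for f in fragments]
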