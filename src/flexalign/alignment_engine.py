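"""Iterated block-constrained alignment with fragment-local rigid transforms.

The aligner loop is: build an initial score matrix from secondary-structure
and distance-profile compatibility, find the best block alignment by dynamic
programming, fit one rigid transform per matched fragment pair on the
neighbourhood-restricted correspondence, rescore every cell from the
transformed distances, and repeat until the matching stabilises.

Scoring uses the similarity term ``sim(d²) = 1 / (1 + d²/d0)`` with
d0 = 11.5 Å².  Matrix entries are ``sim(d²) − κ`` with ``κ = 2·sim(81)`` and
the per-unmatched-site penalty is ``sim(81)/2``, so that matching a pair is
worth exactly ``sim(d²) − sim(81)`` over leaving both sites unmatched:
positive below 9 Å, negative above (a pair further apart than 9 Å is a poor
match).  The final score of a matching is the sum of per-pair similarity
terms normalised by 2/(L1+L2), which is symmetric, lies in [0, 1] and equals
1 on self-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from flexalign.fragmentation import (
    DEFAULT_M,
    Fragment,
    Neighbourhood,
    fragment_of_site,
    fragments_for,
    neighbourhoods_for,
)
from flexalign.geometry import RigidTransform, apply, kabsch
from flexalign.structure_io import CAStructure

#: distance-squared softening constant (Å²)
DEFAULT_D0 = 11.5
#: break-even pair distance (Å): beyond this a match is worth less than a gap
BREAK_EVEN_D = 9.0

ScoreMatrix = np.ndarray  # (L1, L2) array of finite reals


def simterm(d2: np.ndarray | float, d0: float = DEFAULT_D0) -> np.ndarray | float:
    """Similarity of a pair at squared distance d2: 1 / (1 + d2/d0)."""
    return 1.0 / (1.0 + d2 / d0)


def default_kappa(d0: float = DEFAULT_D0) -> float:
    return 2.0 * simterm(BREAK_EVEN_D**2, d0)


def default_penalty(d0: float = DEFAULT_D0) -> float:
    return simterm(BREAK_EVEN_D**2, d0) / 2.0


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the aligner (all echoed into outputs)."""

    m: int = DEFAULT_M
    d0: float = DEFAULT_D0
    penalty: float = field(default_factory=default_penalty)
    kappa: float = field(default_factory=default_kappa)
    min_block: int = 6
    max_steps: int = 30
    w_sse: float = 0.3
    w_prof: float = 0.7
    normalization: str = "sum"  # sum: 2/(L1+L2) | min: 1/min | geometric: 1/sqrt(L1*L2)

    def norm_factor(self, l1: int, l2: int) -> float:
        if self.normalization == "sum":
            return 2.0 / (l1 + l2)
        if self.normalization == "min":
            return 1.0 / min(l1, l2)
        if self.normalization == "geometric":
            return 1.0 / float(np.sqrt(l1 * l2))
        raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class Alignment:
    """An order-preserving partial one-to-one site correspondence."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = (-1, -1)
        for p in self.pairs:
            if not (p[0] > prev[0] and p[1] > prev[1]):
                raise ValueError("pairs must be strictly increasing in both coordinates")
            prev = p

    def __len__(self) -> int:
        return len(self.pairs)

    def runs(self) -> list[tuple[tuple[int, int], ...]]:
        """Maximal diagonal runs of consecutive pairs."""
        out: list[list[tuple[int, int]]] = []
        for p in self.pairs:
            if out and p[0] == out[-1][-1][0] + 1 and p[1] == out[-1][-1][1] + 1:
                out[-1].append(p)
            else:
                out.append([p])
        return [tuple(r) for r in out]

    def validate_blocks(self, min_block: int = 6) -> None:
        for r in self.runs():
            if len(r) < min_block:
                raise ValueError(f"run of length {len(r)} violates min_block={min_block}")

    def mirror(self) -> "Alignment":
        return Alignment(tuple((j, i) for i, j in self.pairs))


@dataclass(frozen=True)
class AlignmentResult:
    alignment: Alignment
    pd_score: float
    transforms: dict[tuple[int, int], RigidTransform | None]
    iterations: int
    converged: bool
    pair_distances: tuple[float, ...]
    swapped: bool = False


# ---------------------------------------------------------------------------
# initial score matrix
# ---------------------------------------------------------------------------

_PROFILE_OFFSETS = (-4, -3, -2, -1, 1, 2, 3, 4)


def _distance_profile(coords: np.ndarray) -> np.ndarray:
    """Per-site vector of |x_i - x_{i±k}| for k=1..4 (NaN where out of range)."""
    n = coords.shape[0]
    prof = np.full((n, len(_PROFILE_OFFSETS)), np.nan)
    for c, k in enumerate(_PROFILE_OFFSETS):
        if k < 0:
            idx = np.arange(-k, n)
            prof[idx, c] = np.linalg.norm(coords[idx] - coords[idx + k], axis=1)
        else:
            idx = np.arange(0, n - k)
            prof[idx, c] = np.linalg.norm(coords[idx] - coords[idx + k], axis=1)
    return prof


def init_score_matrix(a: CAStructure, b: CAStructure, cfg: EngineConfig = EngineConfig()) -> ScoreMatrix:
    """Environment-compatibility seed matrix from SSE match and distance profiles.

    Entry (i, j) is ``w_sse·[sse_i == sse_j] + w_prof·sim(msd) − κ`` where msd
    is the mean squared difference of the intra-chain distance profiles over
    offsets available in both chains; the entries span the same range as the
    transform-distance matrix produced by :func:`rescore`.
    """
    if a.sse is None or b.sse is None:
        raise ValueError("structures need SSE labels; run assign_sse first")
    pa = _distance_profile(a.coords)
    pb = _distance_profile(b.coords)
    n1, n2 = len(a), len(b)
    sq = np.zeros((n1, n2))
    cnt = np.zeros((n1, n2))
    for c in range(len(_PROFILE_OFFSETS)):
        va = pa[:, c][:, None]
        vb = pb[:, c][None, :]
        ok = ~np.isnan(va) & ~np.isnan(vb)
        diff = np.where(ok, va - vb, 0.0)
        sq += diff**2
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(cnt > 0, sq / np.maximum(cnt, 1), np.nan)
    prof_sim = np.where(cnt > 0, simterm(msd, cfg.d0), 0.5)
    sa = np.frombuffer(a.sse.encode(), dtype="S1")
    sb = np.frombuffer(b.sse.encode(), dtype="S1")
    sse_match = (sa[:, None] == sb[None, :]).astype(float)
    return cfg.w_sse * sse_match + cfg.w_prof * prof_sim - cfg.kappa


# ---------------------------------------------------------------------------
# block-constrained dynamic programming
# ---------------------------------------------------------------------------

def dp_align(S: ScoreMatrix, penalty: float, min_block: int = 6) -> Alignment:
    """Best order-preserving matching whose maximal diagonal runs are ≥ min_block.

    Maximises ``Σ S(i,j) − penalty·[(L1 − Na) + (L2 − Na)]``, which equals
    maximising the gain ``Σ (S(i,j) + 2·penalty)`` over matched pairs up to
    the constant ``−penalty·(L1 + L2)``.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    S = np.asarray(S, dtype=float)
    n1, n2 = S.shape
    b = min_block
    if min(n1, n2) < b:
        return Alignment(())

    G = S + 2.0 * penalty
    # W[i, j] = gain of the length-b diagonal window ending at (i, j)
    W = np.full((n1, n2), -np.inf)
    for i in range(b - 1, n1):
        for_col = np.arange(b - 1, n2)
        acc = np.zeros(n2 - b + 1)
        for t in range(b):
            acc += G[i - t, for_col - t]
        W[i, b - 1 :] = acc

    NEG = -np.inf
    B = np.full((n1, n2), NEG)  # best gain of an alignment ending with a run at (i, j)
    P = np.zeros((n1, n2))  # best gain over ends (p, q) with p<=i, q<=j (floor 0)
    for i in range(n1):
        row = np.full(n2, NEG)
        if i >= b - 1:
            new = W[i].copy()
            if i >= b:
                prefix = np.zeros(n2)
                prefix[b:] = P[i - b, :-b]
                new = np.where(np.isfinite(new), new + prefix, NEG)
            row = new
            if i >= b:
                ext = np.full(n2, NEG)
                prev = B[i - 1, :-1]
                valid = np.isfinite(prev)
                ext[1:][valid] = prev[valid] + G[i, 1:][valid]
                row = np.maximum(row, ext)
        B[i] = row
        cand = np.maximum(np.where(np.isfinite(row), row, 0.0), 0.0)
        if i > 0:
            cand = np.maximum(cand, P[i - 1])
        P[i] = np.maximum.accumulate(cand)

    best = P[n1 - 1, n2 - 1]
    if best <= 0:
        return Alignment(())

    # backtrack (deterministic: prefer ending a block here, then moving up,
    # then left; inside a block prefer extending the run over starting fresh)
    pairs: list[tuple[int, int]] = []
    i, j = n1 - 1, n2 - 1
    while True:
        # locate the cell where the current P value is realised by B
        while True:
            if np.isfinite(B[i, j]) and B[i, j] == P[i, j]:
                break
            if i > 0 and P[i - 1, j] == P[i, j]:
                i -= 1
                continue
            if j > 0 and P[i, j - 1] == P[i, j]:
                j -= 1
                continue
            # P must be 0 here with no contributing block
            pairs.reverse()
            return Alignment(tuple(pairs))
        # walk the block chain ending at (i, j)
        while True:
            ext_ok = (
                i >= b and j >= 1 and np.isfinite(B[i - 1, j - 1])
                and B[i - 1, j - 1] + G[i, j] == B[i, j]
            )
            if ext_ok:
                pairs.append((i, j))
                i, j = i - 1, j - 1
                continue
            # fresh window of length b ends here
            for t in range(b):
                pairs.append((i - t, j - t))
            i, j = i - b, j - b
            break
        if i < 0 or j < 0 or P[i, j] <= 0:
            pairs.reverse()
            return Alignment(tuple(pairs))


def alignment_objective(S: ScoreMatrix, alignment: Alignment, penalty: float) -> float:
    """Value of the matching objective: Σ S − penalty·(unmatched sites)."""
    n1, n2 = S.shape
    na = len(alignment)
    total = float(sum(S[i, j] for i, j in alignment.pairs))
    return total - penalty * ((n1 - na) + (n2 - na))


def alignment_gain(S: ScoreMatrix, alignment: Alignment, penalty: float) -> float:
    """Reformulated objective: Σ (S + 2·penalty) over matched pairs."""
    return float(sum(S[i, j] + 2.0 * penalty for i, j in alignment.pairs))


# ---------------------------------------------------------------------------
# local transforms, rescoring, final score
# ---------------------------------------------------------------------------

def compute_local_transforms(
    a: CAStructure,
    b: CAStructure,
    alignment: Alignment,
    frags_a: list[Fragment],
    frags_b: list[Fragment],
    nb_a: list[Neighbourhood],
    nb_b: list[Neighbourhood],
) -> dict[tuple[int, int], RigidTransform | None]:
    """One rigid transform per matched fragment pair.

    A fragment pair (F, G) is matched when some aligned pair (i, j) has
    i ∈ F and j ∈ G.  Its transform is fitted on the alignment restricted to
    the two neighbourhoods; with fewer than three such pairs it is undefined
    (``None``).
    """
    fa = fragment_of_site(frags_a, len(a))
    fb = fragment_of_site(frags_b, len(b))
    keys = sorted({(int(fa[i]), int(fb[j])) for i, j in alignment.pairs})
    out: dict[tuple[int, int], RigidTransform | None] = {}
    for kf, kg in keys:
        mem_a = nb_a[kf].member_sites
        mem_b = nb_b[kg].member_sites
        sel = [(i, j) for i, j in alignment.pairs if i in mem_a and j in mem_b]
        if len(sel) < 3:
            out[(kf, kg)] = None
            continue
        pi = np.array([p[0] for p in sel])
        pj = np.array([p[1] for p in sel])
        out[(kf, kg)] = kabsch(a.coords[pi], b.coords[pj])
    return out


def _global_transform(a: CAStructure, b: CAStructure, alignment: Alignment) -> RigidTransform | None:
    if len(alignment) < 3:
        return None
    pi = np.array([p[0] for p in alignment.pairs])
    pj = np.array([p[1] for p in alignment.pairs])
    return kabsch(a.coords[pi], b.coords[pj])


def rescore(
    a: CAStructure,
    b: CAStructure,
    alignment: Alignment,
    transforms: dict[tuple[int, int], RigidTransform | None],
    frags_a: list[Fragment],
    frags_b: list[Fragment],
    cfg: EngineConfig = EngineConfig(),
) -> ScoreMatrix:
    """Score matrix from transformed distances: sim(d²) − κ per cell.

    Cell (i, j) uses the transform of its fragment pair when defined, else
    the global transform fitted on the whole current alignment, else the
    floor value −κ.
    """
    glob = _global_transform(a, b, alignment)
    n1, n2 = len(a), len(b)
    if glob is not None:
        at = apply(glob, a.coords)
        d2 = cdist(at, b.coords, "sqeuclidean")
        S = simterm(d2, cfg.d0) - cfg.kappa
    else:
        S = np.full((n1, n2), -cfg.kappa)
    for (kf, kg), t in transforms.items():
        if t is None:
            continue
        F, G = frags_a[kf], frags_b[kg]
        at = apply(t, a.coords[F.start : F.end + 1])
        d2 = cdist(at, b.coords[G.start : G.end + 1], "sqeuclidean")
        S[F.start : F.end + 1, G.start : G.end + 1] = simterm(d2, cfg.d0) - cfg.kappa
    return S


def _pair_distances(
    a: CAStructure,
    b: CAStructure,
    alignment: Alignment,
    transforms: dict[tuple[int, int], RigidTransform | None],
    frags_a: list[Fragment],
    frags_b: list[Fragment],
) -> np.ndarray:
    """Per-pair distance after applying each pair's fragment-pair transform."""
    if not alignment.pairs:
        return np.zeros(0)
    fa = fragment_of_site(frags_a, len(a))
    fb = fragment_of_site(frags_b, len(b))
    glob = _global_transform(a, b, alignment)
    out = np.empty(len(alignment))
    for k, (i, j) in enumerate(alignment.pairs):
        t = transforms.get((int(fa[i]), int(fb[j])))
        if t is None:
            t = glob
        if t is None:
            out[k] = np.inf
            continue
        out[k] = float(np.linalg.norm(apply(t, a.coords[i]) - b.coords[j]))
    return out


def pd_score(
    a: CAStructure,
    b: CAStructure,
    alignment: Alignment,
    transforms: dict[tuple[int, int], RigidTransform | None],
    frags_a: list[Fragment] | None = None,
    frags_b: list[Fragment] | None = None,
    cfg: EngineConfig = EngineConfig(),
) -> float:
    """Length-normalised similarity of a matching in [0, 1].

    ``norm · Σ sim(d²)`` over matched pairs, with the default normalisation
    2/(L1+L2); distances come from each pair's fragment-pair transform (with
    global fallback).
    """
    frags_a = frags_a if frags_a is not None else fragments_for(a)
    frags_b = frags_b if frags_b is not None else fragments_for(b)
    d = _pair_distances(a, b, alignment, transforms, frags_a, frags_b)
    sims = np.where(np.isfinite(d), simterm(d**2, cfg.d0), 0.0)
    return float(cfg.norm_factor(len(a), len(b)) * sims.sum())


# ---------------------------------------------------------------------------
# the full iteration
# ---------------------------------------------------------------------------

def _align_canonical(a: CAStructure, b: CAStructure, cfg: EngineConfig) -> AlignmentResult:
    frags_a, frags_b = fragments_for(a), fragments_for(b)
    nb_a = neighbourhoods_for(a, frags_a, cfg.m)
    nb_b = neighbourhoods_for(b, frags_b, cfg.m)

    empty = AlignmentResult(Alignment(()), 0.0, {}, 0, True, ())
    if min(len(a), len(b)) < cfg.min_block:
        return empty

    S = init_score_matrix(a, b, cfg)
    seen: set[tuple[tuple[int, int], ...]] = set()
    best: AlignmentResult | None = None
    prev_pairs: tuple[tuple[int, int], ...] | None = None
    converged = False
    iterations = 0
    while iterations < cfg.max_steps:
        iterations += 1
        aln = dp_align(S, cfg.penalty, cfg.min_block)
        if aln.pairs == prev_pairs:
            converged = True
            break
        if aln.pairs in seen:  # cycle: keep the best matching seen so far
            break
        transforms = compute_local_transforms(a, b, aln, frags_a, frags_b, nb_a, nb_b)
        dists = _pair_distances(a, b, aln, transforms, frags_a, frags_b)
        score = pd_score(a, b, aln, transforms, frags_a, frags_b, cfg)
        cand = AlignmentResult(aln, score, transforms, iterations, False, tuple(float(x) for x in dists))
        if best is None or cand.pd_score > best.pd_score:
            best = cand
        seen.add(aln.pairs)
        S = rescore(a, b, aln, transforms, frags_a, frags_b, cfg)
        prev_pairs = aln.pairs
    if best is None:
        return empty
    return AlignmentResult(
        best.alignment, best.pd_score, best.transforms, iterations, converged, best.pair_distances
    )


def align(a: CAStructure, b: CAStructure, cfg: EngineConfig = EngineConfig()) -> AlignmentResult:
    """Run the full iterated alignment of two labelled structures.

    Arguments are ordered canonically (shorter first, ties by id) before
    aligning, so the result is exactly symmetric under argument swap; the
    returned pairs and transforms are expressed in the caller's (a, b) order.
    """
    if a.sse is None or b.sse is None:
        raise ValueError("structures need SSE labels; run assign_sse first")
    swapped = (len(b), b.id) < (len(a), a.id)
    first, second = (b, a) if swapped else (a, b)
    res = _align_canonical(first, second, cfg)
    if not swapped:
        return res
    mirrored = {
        (kg, kf): (t.inverse() if t is not None else None)
        for (kf, kg), t in res.transforms.items()
    }
    return AlignmentResult(
        res.alignment.mirror(),
        res.pd_score,
        mirrored,
        res.iterations,
        res.converged,
        res.pair_distances,
        swapped=True,
    )


def evaluate_alignment(
    a: CAStructure,
    b: CAStructure,
    given_pairs,
    cfg: EngineConfig = EngineConfig(),
) -> tuple[float, np.ndarray]:
    """Score a fixed externally supplied correspondence (no optimisation).

    The block-size constraint is not enforced here; pairs only need to be
    strictly increasing in both coordinates.  Fragment-pair transforms are
    fitted on the given pairs and the score of that matching is returned
    together with the per-pair distances.
    """
    aln = Alignment(tuple((int(i), int(j)) for i, j in given_pairs))
    frags_a, frags_b = fragments_for(a), fragments_for(b)
    nb_a = neighbourhoods_for(a, frags_a, cfg.m)
    nb_b = neighbourhoods_for(b, frags_b, cfg.m)
    transforms = compute_local_transforms(a, b, aln, frags_a, frags_b, nb_a, nb_b)
    dists = _pair_distances(a, b, aln, transforms, frags_a, frags_b)
    score = pd_score(a, b, aln, transforms, frags_a, frags_b, cfg)
    return score, dists
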