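"""Seeded generators for toy structures and simulated score samples.

Everything downstream is testable offline with these: ideal-geometry helices
and strands, multi-segment domains with randomised segment packing, hinge
pairs (one rigid sub-structure rotated about an internal site), and labelled
score samples drawn from stated distributions.

The helix constants (1.5 Å rise, 2.3 Å radius, 100° twist per residue) are
textbook Cα geometry; consecutive sites are ~3.8 Å apart in all generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from flexalign.structure_io import CAStructure

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0
CA_SPACING = 3.8
STRAND_STEP = 3.3  # along-axis advance; zig-zag amplitude keeps |Δ| = 3.8
MIN_CLEARANCE = 3.0
MAX_PLACEMENT_RETRIES = 200

_SEGMENT_SSE = {"helix": "H", "strand": "E", "loop": "C"}


@dataclass(frozen=True)
class DomainSpec:
    """Recipe for a toy domain: ordered (kind, length) segments."""

    segments: tuple[tuple[str, int], ...]
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        for kind, length in self.segments:
            if kind not in _SEGMENT_SSE:
                raise ValueError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValueError("segment lengths must be >= 1")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)


def make_helix(n: int) -> np.ndarray:
    """Ideal α-helix Cα trace along +z."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST_DEG) * t
    return np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * t]
    )


def make_strand(n: int) -> np.ndarray:
    """Extended zig-zag strand with exactly 3.8 Å consecutive spacing."""
    if n < 1:
        raise ValueError("n must be >= 1")
    half_amp = float(np.sqrt(CA_SPACING**2 - STRAND_STEP**2)) / 2.0
    t = np.arange(n)
    return np.column_stack(
        [STRAND_STEP * t, half_amp * np.where(t % 2 == 0, 1.0, -1.0), np.zeros(n)]
    )


def _make_loop(n: int, rng: np.random.Generator) -> np.ndarray:
    """Persistent random walk with 3.8 Å steps (coil geometry)."""
    pts = np.zeros((n, 3))
    direction = _unit(rng.normal(size=3))
    for i in range(1, n):
        direction = _unit(direction + 0.6 * rng.normal(size=3))
        pts[i] = pts[i - 1] + CA_SPACING * direction
    return pts


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])


def _has_clash(coords: np.ndarray) -> bool:
    if coords.shape[0] < 3:
        return False
    d = squareform(pdist(coords))
    n = coords.shape[0]
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    return bool((d[mask] < MIN_CLEARANCE).any())


def _segment_template(kind: str, length: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "helix":
        return make_helix(length)
    if kind == "strand":
        return make_strand(length)
    for _ in range(50):  # loops are stochastic; regenerate on self-clash
        tpl = _make_loop(length, rng)
        if not _has_clash(tpl):
            return tpl
    raise RuntimeError("could not generate a clash-free loop segment")


def _orient_outward(tpl: np.ndarray, outward: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random orientation biased so the segment grows along *outward*."""
    ee = tpl[-1] - tpl[0]
    if np.linalg.norm(ee) < 1e-9:
        return tpl @ Rotation.random(rng=rng).as_matrix().T
    target = _unit(outward + 0.8 * rng.normal(size=3))
    align, _ = Rotation.align_vectors(target[None, :], _unit(ee)[None, :])
    spin = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * target)
    return tpl @ (spin * align).as_matrix().T


def make_domain(spec: DomainSpec) -> CAStructure:
    """Assemble a toy domain from a spec (deterministic given the seed).

    Segments are attached end to end with seeded random orientations,
    biased outward from the growing body's centroid; any placement bringing
    two non-adjacent sites within 3 Å is retried.
    """
    rng = np.random.default_rng(spec.seed)
    sse = "".join(_SEGMENT_SSE[kind] * length for kind, length in spec.segments)
    pieces: list[np.ndarray] = [_segment_template(*spec.segments[0], rng) ]
    for kind, length in spec.segments[1:]:
        placed_ok = False
        for _ in range(MAX_PLACEMENT_RETRIES):
            tpl = _segment_template(kind, length, rng)
            tpl = tpl - tpl[0]
            existing = np.vstack(pieces)
            prev_end = pieces[-1][-1]
            outward = prev_end - existing.mean(axis=0)
            if np.linalg.norm(outward) < 1e-9:
                outward = rng.normal(size=3)
            oriented = _orient_outward(tpl, _unit(outward), rng)
            anchor = prev_end + CA_SPACING * _unit(_unit(outward) + 0.5 * rng.normal(size=3))
            cand = oriented - oriented[0] + anchor
            if not _has_clash(np.vstack([existing, cand])):
                pieces.append(cand)
                placed_ok = True
                break
        if not placed_ok:
            raise RuntimeError(
                f"could not place a {kind}({length}) segment without clashes "
                f"after {MAX_PLACEMENT_RETRIES} tries"
            )
    coords = np.vstack(pieces)
    if spec.jitter > 0:
        coords = coords + rng.normal(scale=spec.jitter, size=coords.shape)
    return CAStructure(
        id=f"synth{spec.seed}",
        coords=coords,
        residue_ids=tuple(str(i + 1) for i in range(coords.shape[0])),
        sse=sse,
    )


def make_hinge_pair(
    spec: DomainSpec,
    hinge_site: int,
    angle: float,
    axis_seed: int = 0,
) -> tuple[CAStructure, CAStructure]:
    """A domain and a copy with all sites ≥ hinge_site rigidly rotated.

    The rotation axis passes through the hinge Cα in a seeded random
    direction; residue correspondence between the two structures is the
    identity.
    """
    a = make_domain(spec)
    n = len(a)
    if not 0 < hinge_site < n:
        raise ValueError(f"hinge_site must be inside (0, {n})")
    rng = np.random.default_rng(axis_seed)
    axis = _unit(rng.normal(size=3))
    rot = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    pivot = a.coords[hinge_site]
    coords = a.coords.copy()
    coords[hinge_site:] = (coords[hinge_site:] - pivot) @ rot.T + pivot
    b = CAStructure(
        id=f"{a.id}_hinge",
        coords=coords,
        residue_ids=a.residue_ids,
        sse=a.sse,
    )
    return a, b


def sample_scores(
    n_same: int,
    n_diff: int,
    diff_model: tuple[float, float] = (0.058, 0.027),
    same_model: tuple[float, float] = (0.5, 0.1),
    seed: int = 0,
    context: str = "fold",
    length_range: tuple[int, int] = (50, 500),
) -> pd.DataFrame:
    """Labelled score sample: Gumbel 'diff' scores and truncated-normal 'same'
    scores, both restricted to [0, 1] by resampling; lengths drawn uniformly."""
    if n_same < 1 or n_diff < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    def _draw(sampler, n):
        out = np.empty(0)
        while out.size < n:
            x = sampler(2 * (n - out.size) + 16)
            out = np.concatenate([out, x[(x >= 0.0) & (x <= 1.0)]])
        return out[:n]

    mu_d, beta_d = diff_model
    mu_s, sd_s = same_model
    diff = _draw(lambda k: stats.gumbel_r.rvs(loc=mu_d, scale=beta_d, size=k, random_state=rng), n_diff)
    same = _draw(lambda k: rng.normal(loc=mu_s, scale=sd_s, size=k), n_same)

    n = n_same + n_diff
    lo, hi = length_range
    l1 = rng.integers(lo, hi + 1, size=n)
    l2 = rng.integers(lo, hi + 1, size=n)
    return pd.DataFrame(
        {
            "pair_id": [f"p{i:06d}" for i in range(n)],
            "L1": l1,
            "L2": l2,
            "score": np.concatenate([same, diff]),
            "label": ["same"] * n_same + ["diff"] * n_diff,
            "context": context,
        }
    )
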