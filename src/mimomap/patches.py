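"""Surface patches and compactness-regulated graphs.

The antigen surface is tiled into overlapping patches: one patch per surface
residue, containing every surface residue whose side-chain anchor lies within
a radius (default 15 Å) of the center's anchor.  Oversized patches
(> 50 residues, typically dense cores) are discarded.

Each patch becomes a graph whose vertices are the patch residues and whose
edges connect residue pairs with anchor distance at or below a distance
threshold.  Graph compactness is summarised by the compactness factor

    CF = e / (a * k)

with e the edge count, k the vertex count, and a an empirical constant
(default 4) so that a*k estimates the expected edge count of a
neighbour-limited residue graph.  Two threshold policies are offered:

* FDT — a fixed threshold (default 6.5 Å) for every patch;
* ADT — an adaptive threshold, started at 6.5 Å and stepped by 0.01 Å up
  (CF too low) or down (CF too high) until CF enters a target band
  (default 0.73 ± 0.06) or a threshold bound is hit.  Uniform compactness
  keeps the downstream path search cheap on dense regions and keeps sparse
  regions connected enough to carry paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import AntigenModel, ResidueKey
from .surface import AccessibilityResult

__all__ = [
    "Patch",
    "PatchGraph",
    "GraphParams",
    "generate_patches",
    "compute_cf",
    "build_graph_fdt",
    "build_graph_adt",
    "average_cf",
    "NoSurfaceResiduesError",
]

DEFAULT_PATCH_RADIUS = 15.0   # Å
DEFAULT_MAX_PATCH_SIZE = 50
DEFAULT_CF_TARGET = 0.73
DEFAULT_CF_TOL = 0.06
DEFAULT_START_THRESHOLD = 6.5  # Å
DEFAULT_STEP = 0.01            # Å
DEFAULT_THRESHOLD_BOUNDS = (3.0, 20.0)  # Å; guard against unreachable bands
DEFAULT_A_CONSTANT = 4


class NoSurfaceResiduesError(ValueError):
    """The accessibility result flags no surface residues."""


@dataclass
class Patch:
    center: ResidueKey
    members: list[ResidueKey]          # residue order of the parent model
    member_indices: np.ndarray         # indices into the model's residue list
    radius: float

    def __post_init__(self):
        if self.center not in self.members:
            raise ValueError("patch center must be a member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PatchGraph:
    """Graph over one patch: vertex i is the patch's i-th member residue."""

    patch: Patch
    vertices: list[ResidueKey]
    vertex_aa: list[str]                   # one-letter aa per vertex
    edges: set[tuple[int, int]]            # (i, j) with i < j
    threshold: float                       # Å, the threshold actually used
    a_constant: int = DEFAULT_A_CONSTANT
    band_reached: bool | None = None       # None for FDT graphs
    mode: str = "fdt"

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def cf(self) -> float:
        return compute_cf(self.n_edges, self.n_vertices, self.a_constant)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.vertices]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def to_edge_tsv(self, handle) -> None:
        def label(k: ResidueKey) -> str:
            return f"{k[0]}:{k[1]}{k[2]}"

        handle.write("vertex_a\tvertex_b\n")
        for i, j in sorted(self.edges):
            handle.write(f"{label(self.vertices[i])}\t{label(self.vertices[j])}\n")


@dataclass
class GraphParams:
    cf_target: float = DEFAULT_CF_TARGET
    cf_tol: float = DEFAULT_CF_TOL
    start_threshold: float = DEFAULT_START_THRESHOLD
    step: float = DEFAULT_STEP
    threshold_bounds: tuple[float, float] = DEFAULT_THRESHOLD_BOUNDS
    a_constant: int = DEFAULT_A_CONSTANT
    mode: str = "adt"   # "adt" or "fdt"
    fdt_threshold: float = DEFAULT_START_THRESHOLD

    def __post_init__(self):
        if self.cf_tol < 0:
            raise ValueError("cf_tol must be non-negative")
        if self.step <= 0:
            raise ValueError("step must be positive")
        lo, hi = self.threshold_bounds
        if lo > hi:
            raise ValueError("threshold bounds must be ordered")
        if self.mode not in ("adt", "fdt"):
            raise ValueError("mode must be 'adt' or 'fdt'")

    @property
    def band(self) -> tuple[float, float]:
        return (self.cf_target - self.cf_tol, self.cf_target + self.cf_tol)


def compute_cf(e: int, k: int, a: int = DEFAULT_A_CONSTANT) -> float:
    """Compactness factor e / (a*k)."""
    if k < 1 or a < 1 or e < 0:
        raise ValueError("require k >= 1, a >= 1, e >= 0")
    return e / (a * k)


def generate_patches(
    model: AntigenModel,
    accessibility: AccessibilityResult,
    radius: float = DEFAULT_PATCH_RADIUS,
    max_size: int = DEFAULT_MAX_PATCH_SIZE,
) -> list[Patch]:
    """One candidate patch per surface residue; oversized patches dropped.

    Membership uses anchor (Cβ) distance ≤ radius among surface residues only.
    Returns the retained patches in the order of their center residues.
    """
    surf_idx = accessibility.surface_indices
    if surf_idx.size == 0:
        raise NoSurfaceResiduesError("no surface residues above the RSA threshold")

    anchors = model.anchors()[surf_idx]
    keys = [model.residues[i].key for i in surf_idx]
    d = squareform(pdist(anchors))

    patches: list[Patch] = []
    n_discarded = 0
    for c in range(len(surf_idx)):
        within = np.flatnonzero(d[c] <= radius)
        if within.size > max_size:
            n_discarded += 1
            continue
        patches.append(
            Patch(
                center=keys[c],
                members=[keys[i] for i in within],
                member_indices=surf_idx[within],
                radius=radius,
            )
        )
    if n_discarded:
        import logging

        logging.getLogger(__name__).info(
            "discarded %d patch(es) larger than %d residues", n_discarded, max_size
        )
    return patches


def _patch_geometry(
    patch: Patch, model: AntigenModel
) -> tuple[list[ResidueKey], list[str], np.ndarray]:
    keys = patch.members
    aa = [model.residues[i].aa for i in patch.member_indices]
    anchors = model.anchors()[patch.member_indices]
    return keys, aa, anchors


def _edges_at(dist: np.ndarray, threshold: float) -> set[tuple[int, int]]:
    ii, jj = np.nonzero(np.triu(dist <= threshold, k=1))
    return set(zip(ii.tolist(), jj.tolist()))


def build_graph_fdt(
    patch: Patch,
    model: AntigenModel,
    threshold: float = DEFAULT_START_THRESHOLD,
    a_constant: int = DEFAULT_A_CONSTANT,
) -> PatchGraph:
    """Graph with a fixed distance threshold: edge iff anchor distance ≤ t."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keys, aa, anchors = _patch_geometry(patch, model)
    dist = squareform(pdist(anchors)) if len(keys) > 1 else np.zeros((1, 1))
    return PatchGraph(
        patch=patch,
        vertices=keys,
        vertex_aa=aa,
        edges=_edges_at(dist, threshold),
        threshold=threshold,
        a_constant=a_constant,
        band_reached=None,
        mode="fdt",
    )


def build_graph_adt(
    patch: Patch,
    model: AntigenModel,
    params: GraphParams | None = None,
) -> PatchGraph:
    """Graph with an adaptive threshold regulated by the compactness factor.

    Starting from ``params.start_threshold``, the threshold moves in 0.01 Å
    steps toward the CF band: up when CF is below the band, down when above,
    stopping when CF enters the band or a threshold bound is reached.  Because
    the edge count is monotone in the threshold, stepping can jump across a
    narrow band without landing inside it; in that case the side whose CF is
    closest to the target is kept.  An unreachable band (e.g. a 2-vertex patch
    whose CF can never exceed 1/8) returns the closest-CF graph with
    ``band_reached=False`` rather than raising.
    """
    params = params or GraphParams()
    lo_band, hi_band = params.band
    lo_t, hi_t = params.threshold_bounds
    keys, aa, anchors = _patch_geometry(patch, model)
    k = len(keys)
    dist = squareform(pdist(anchors)) if k > 1 else np.zeros((1, 1))
    pair_d = dist[np.triu_indices(k, 1)]

    def cf_at(t: float) -> float:
        return compute_cf(int(np.count_nonzero(pair_d <= t)), k, params.a_constant)

    t = float(np.clip(params.start_threshold, lo_t, hi_t))
    cf = cf_at(t)
    band_reached = lo_band <= cf <= hi_band
    if not band_reached:
        direction = 1.0 if cf < lo_band else -1.0
        prev_t, prev_cf = t, cf
        while True:
            nxt = round(t + direction * params.step, 10)
            if nxt < lo_t or nxt > hi_t:
                # bound hit: clamp; band unreachable from here
                t = float(np.clip(nxt, lo_t, hi_t))
                cf = cf_at(t)
                band_reached = lo_band <= cf <= hi_band
                break
            prev_t, prev_cf = t, cf
            t, cf = nxt, cf_at(nxt)
            if lo_band <= cf <= hi_band:
                band_reached = True
                break
            crossed = (direction > 0 and cf > hi_band) or (direction < 0 and cf < lo_band)
            if crossed:
                # jumped over the band in one step: keep the closer side
                if abs(prev_cf - params.cf_target) <= abs(cf - params.cf_target):
                    t, cf = prev_t, prev_cf
                band_reached = False
                break

    return PatchGraph(
        patch=patch,
        vertices=keys,
        vertex_aa=aa,
        edges=_edges_at(dist, t),
        threshold=t,
        a_constant=params.a_constant,
        band_reached=band_reached,
        mode="adt",
    )


def average_cf(graphs: list[PatchGraph], include_unreached: bool = True) -> float:
    """Arithmetic mean CF over graphs (optionally band-reached ADT ones only)."""
    if not graphs:
        raise ValueError("average_cf of an empty graph list")
    vals = [
        g.cf
        for g in graphs
        if include_unreached or g.band_reached is None or g.band_reached
    ]
    if not vals:
        raise ValueError("no graphs left after filtering unreached bands")
    return float(np.mean(vals))
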