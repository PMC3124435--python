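"""Synthetic protein-like structures and mimotope sets.

Small test antigens are built from ideal backbone geometry (NeRF chain
extension with standard bond lengths/angles): an α-helix (φ = −57°, ψ = −47°)
whose residues are almost all solvent-exposed, or a "coil" with jittered
torsions producing denser and sparser local packing.  Every residue carries a
pseudo-Cβ at the standard tetrahedral offset so side-chain anchoring works
uniformly.  A chosen epitope sequence can be planted onto a connected chain
of surface residues (consecutive anchors within the default 6.5 Å edge
threshold), and mimotope sets are sampled as noisy copies of the epitope with
NNK-distributed substitutions — emulating affinity-selected peptides that
share high sequence similarity with the native epitope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .align import Mimotope, nnk_frequencies
from .structure import (
    AMINO_ACIDS,
    AntigenModel,
    AtomRecord,
    ResidueKey,
    ResidueRecord,
    VDW_RADII,
    write_pdb,
)
from .surface import AccessibilityResult, compute_accessibility

__all__ = ["ToySpec", "make_toy_structure", "toy_pdb_text", "plant_epitope_path", "sample_mimotopes"]

# backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI, OMEGA = -57.0, -47.0, 180.0


@dataclass(frozen=True)
class ToySpec:
    n_residues: int
    geometry: str = "helix"          # "helix" or "coil"
    sequence: str | None = None      # None → random
    seed: int = 0
    chain_id: str = "A"

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.geometry not in ("helix", "coil"):
            raise ValueError("geometry must be 'helix' or 'coil'")
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length must equal n_residues")
            bad = set(self.sequence) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from three predecessors by internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(dihedral),
            length * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard tetrahedral Cβ reconstruction from backbone frame
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def make_toy_structure(spec: ToySpec) -> AntigenModel:
    """Ideal-geometry toy antigen; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.sequence is not None:
        seq = spec.sequence
    else:
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))

    if spec.geometry == "helix":
        phis = np.full(n, HELIX_PHI)
        psis = np.full(n, HELIX_PSI)
    else:
        # jittered torsions: alternating tight and open stretches
        phis = HELIX_PHI + rng.uniform(-45.0, 45.0, size=n)
        psis = HELIX_PSI + rng.uniform(-45.0, 75.0, size=n)

    # seed the first residue in a canonical frame
    coords_n = [np.zeros(3)]
    coords_ca = [np.array([B_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(180.0 - A_N_CA_C)
    coords_c = [coords_ca[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n):
        ni = _nerf(coords_n[-1], coords_ca[-1], coords_c[-1], B_C_N, A_CA_C_N, psis[i - 1])
        cai = _nerf(coords_ca[-1], coords_c[-1], ni, B_N_CA, A_C_N_CA, OMEGA)
        ci = _nerf(coords_c[-1], ni, cai, B_CA_C, A_N_CA_C, phis[i])
        coords_n.append(ni)
        coords_ca.append(cai)
        coords_c.append(ci)

    residues = []
    for i in range(n):
        ni, cai, ci = coords_n[i], coords_ca[i], coords_c[i]
        if i + 1 < n:
            oi = _nerf(coords_n[i], cai, ci, B_C_O, A_CA_C_O, psis[i] + 180.0)
        else:
            oi = _nerf(coords_n[i], cai, ci, B_C_O, A_CA_C_O, 0.0)
        cbi = _pseudo_cb(ni, cai, ci)
        mk = lambda name, elem, xyz: AtomRecord(
            name=name, element=elem, coord=np.round(xyz, 3), vdw_radius=VDW_RADII[elem]
        )
        residues.append(
            ResidueRecord(
                chain_id=spec.chain_id,
                seq_number=i + 1,
                insertion_code="",
                aa=seq[i],
                atoms=[
                    mk("N", "N", ni),
                    mk("CA", "C", cai),
                    mk("C", "C", ci),
                    mk("O", "O", oi),
                    mk("CB", "C", cbi),
                ],
            )
        )
    return AntigenModel(residues=residues, source_id=f"toy-{spec.geometry}-{spec.seed}",
                        chain_id=spec.chain_id)


def toy_pdb_text(spec: ToySpec) -> str:
    buf = io.StringIO()
    write_pdb(make_toy_structure(spec), buf)
    return buf.getvalue()


def plant_epitope_path(
    model: AntigenModel,
    epitope_seq: str,
    seed: int = 0,
    adjacency_threshold: float = 6.5,
    accessibility: AccessibilityResult | None = None,
) -> tuple[AntigenModel, list[ResidueKey]]:
    """Relabel a connected surface path to spell ``epitope_seq``.

    Picks (reproducibly, given ``seed``) a simple path of surface residues
    whose consecutive anchors lie within ``adjacency_threshold`` and rewrites
    their amino-acid identities.  Returns the modified model and the planted
    residue keys in path order (the ground truth for recovery tests).
    """
    bad = set(epitope_seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard letters in epitope: {sorted(bad)}")
    acc = accessibility if accessibility is not None else compute_accessibility(model)
    surf = acc.surface_indices
    L = len(epitope_seq)
    if L > surf.size:
        raise ValueError(
            f"epitope of length {L} cannot be planted on {surf.size} surface residues"
        )

    anchors = model.anchors()[surf]
    d = squareform(pdist(anchors)) if surf.size > 1 else np.zeros((1, 1))
    adj = [np.flatnonzero((d[i] <= adjacency_threshold) & (d[i] > 0)) for i in range(surf.size)]

    rng = np.random.default_rng(seed)
    order = rng.permutation(surf.size)

    def dfs(path: list[int], visited: set[int]) -> list[int] | None:
        if len(path) == L:
            return path
        nbrs = list(adj[path[-1]])
        rng.shuffle(nbrs)
        for j in nbrs:
            if j not in visited:
                found = dfs(path + [j], visited | {j})
                if found is not None:
                    return found
        return None

    found = None
    for start in order:
        found = dfs([int(start)], {int(start)})
        if found is not None:
            break
    if found is None:
        raise ValueError("no connected surface path long enough to plant the epitope")

    planted_model_residues = [
        ResidueRecord(r.chain_id, r.seq_number, r.insertion_code, r.aa, list(r.atoms))
        for r in model.residues
    ]
    keys: list[ResidueKey] = []
    for pos, si in enumerate(found):
        ri = int(surf[si])
        planted_model_residues[ri].aa = epitope_seq[pos]
        keys.append(planted_model_residues[ri].key)
    planted = AntigenModel(
        residues=planted_model_residues,
        source_id=model.source_id + "+epitope",
        chain_id=model.chain_id,
    )
    return planted, keys


def sample_mimotopes(
    epitope_seq: str,
    n: int,
    mutation_rate: float,
    seed: int = 0,
) -> list[Mimotope]:
    """Noisy copies of the epitope: per-position NNK substitution at ``mutation_rate``."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = nnk_frequencies()
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(n):
        chars = list(epitope_seq)
        mutate = rng.random(len(chars)) < mutation_rate
        draws = rng.choice(20, size=len(chars), p=freqs)
        for pos in np.flatnonzero(mutate):
            chars[pos] = letters[draws[pos]]
        out.append(Mimotope("".join(chars), label=f"mimotope_{i + 1}"))
    return out
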