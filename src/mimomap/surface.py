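"""Solvent accessibility and surface-residue detection.

Per-atom solvent-accessible surface area (ASA) is computed with the
Shrake-Rupley rolling-ball algorithm: each atom's expanded sphere
(van der Waals radius + probe radius, probe default 1.4 Å) is covered with a
deterministic golden-spiral point lattice, and the exposed fraction is the
fraction of points not buried inside any neighbouring expanded sphere.
Residue ASA is the sum over member atoms.  Relative solvent accessibility
(RSA) divides residue ASA by the maximum exposed area of that amino-acid type
in an extended tripeptide; residues with RSA above a threshold (default 0.05)
are flagged as surface residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import AntigenModel, ResidueKey

__all__ = [
    "MAX_AREA_TIEN_2013",
    "AccessibilityResult",
    "shrake_rupley_asa",
    "residue_asa",
    "surface_flags",
    "compute_accessibility",
    "sphere_points",
]

#: Theoretical maximum exposed areas (Å²) per amino acid, extended-tripeptide
#: normalisation of Tien et al. 2013.  Swappable: pass any 20-entry table.
MAX_AREA_TIEN_2013: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

DEFAULT_PROBE_RADIUS = 1.4  # Å
DEFAULT_N_POINTS = 960
DEFAULT_RSA_THRESHOLD = 0.05


class UnknownResidueTypeError(KeyError):
    """An amino-acid letter has no entry in the maximum-area table."""


@dataclass
class AccessibilityResult:
    """Per-residue accessibility, aligned with the model's residue order."""

    keys: list[ResidueKey]
    asa: np.ndarray          # Å² per residue
    rsa: np.ndarray          # dimensionless fraction
    is_surface: np.ndarray   # boolean
    rsa_threshold: float

    @property
    def surface_keys(self) -> list[ResidueKey]:
        return [k for k, s in zip(self.keys, self.is_surface) if s]

    @property
    def surface_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_surface)

    def to_tsv(self, handle) -> None:
        handle.write("chain\tresidue\tasa\trsa\tsurface\n")
        for (chain, num, icode), a, r, s in zip(
            self.keys, self.asa, self.rsa, self.is_surface
        ):
            handle.write(f"{chain}\t{num}{icode}\t{a:.3f}\t{r:.4f}\t{int(s)}\n")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_asa(
    model: AntigenModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (Å²), in the model's flat atom order.

    Each atom contributes ``exposed_fraction * 4π (r_vdw + probe)²`` where the
    exposed fraction is estimated on a fixed golden-spiral lattice of
    ``n_sphere_points`` test points, so results are reproducible without a
    random seed.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be at least 60")

    coords, radii, _ = model.atom_table()
    n_atoms = len(coords)
    expanded = radii + probe_radius
    unit = sphere_points(n_sphere_points)

    # neighbour candidates: atoms whose expanded spheres can overlap
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbours = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
            if j != i
            and np.dot(coords[j] - coords[i], coords[j] - coords[i])
            < (expanded[i] + expanded[j]) ** 2
        ]
        if neighbours:
            nb_coords = coords[neighbours]
            nb_r2 = expanded[neighbours] ** 2
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < nb_r2[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        areas[i] = exposed_frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def residue_asa(per_atom_areas: np.ndarray, model: AntigenModel) -> np.ndarray:
    """Sum per-atom areas into per-residue ASA (Å²)."""
    _, _, owner = model.atom_table()
    if len(per_atom_areas) != len(owner):
        raise ValueError("per-atom area vector does not match the model's atoms")
    out = np.zeros(len(model))
    np.add.at(out, owner, per_atom_areas)
    return out


def surface_flags(
    res_asa: np.ndarray,
    model: AntigenModel,
    max_table: dict[str, float] | None = None,
    rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
) -> AccessibilityResult:
    """Relative accessibility and surface flags (RSA > threshold)."""
    table = max_table if max_table is not None else MAX_AREA_TIEN_2013
    maxima = np.empty(len(model))
    for i, res in enumerate(model.residues):
        if res.aa not in table:
            raise UnknownResidueTypeError(
                f"no maximum-area entry for residue type {res.aa!r} ({res.label})"
            )
        maxima[i] = table[res.aa]
    rsa = np.asarray(res_asa, float) / maxima
    return AccessibilityResult(
        keys=model.keys,
        asa=np.asarray(res_asa, float),
        rsa=rsa,
        is_surface=rsa > rsa_threshold,
        rsa_threshold=rsa_threshold,
    )


def compute_accessibility(
    model: AntigenModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    max_table: dict[str, float] | None = None,
    rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
) -> AccessibilityResult:
    """ASA → residue ASA → RSA/surface flags in one call."""
    atom_areas = shrake_rupley_asa(model, probe_radius, n_sphere_points)
    res_areas = residue_asa(atom_areas, model)
    return surface_flags(res_areas, model, max_table, rsa_threshold)
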