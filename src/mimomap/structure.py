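"""Antigen structure handling.

Reads a single chain of a PDB file into a light-weight residue list carrying
everything the surface/patch stages need: per-atom coordinates with van der
Waals radii, and a per-residue side-chain anchor (the Cβ atom, falling back to
Cα for glycine and other Cβ-less residues).  Anchors drive both patch
membership and graph edges, on the rationale that antigen-antibody contacts
are made through side chains, so Cβ-Cβ distance is the better proxy for
spatial closeness of two residues than Cα-Cα distance.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.Data.PDBData import protein_letters_3to1_extended

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "AntigenModel",
    "load_antigen",
    "side_chain_anchor",
    "write_pdb",
    "VDW_RADII",
    "ChainNotFoundError",
    "StructureInputError",
]


class StructureInputError(ValueError):
    """Raised when a structure source cannot be parsed or is unusable."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent; carries the available ids."""

    def __init__(self, chain_id: str, available: Sequence[str]):
        self.chain_id = chain_id
        self.available = list(available)
        super().__init__(
            f"chain {chain_id!r} not found; available chains: "
            + ", ".join(repr(c) for c in self.available)
        )


#: Van der Waals radii (Å) keyed by element symbol.  Values for the organic
#: elements follow Bondi; anything unlisted falls back to 1.70 Å (carbon).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residue key: (chain id, PDB residue number, insertion code or "")
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float  # Å

    def __post_init__(self):
        if not np.all(np.isfinite(self.coord)):
            raise StructureInputError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise StructureInputError(f"non-positive radius for atom {self.name}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str  # "" when absent
    aa: str  # one-letter code, 'X' for unmapped
    atoms: list[AtomRecord]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def cb_coord(self) -> np.ndarray:
        return side_chain_anchor(self)


@dataclass
class AntigenModel:
    """A single antigen chain: ordered standard residues with coordinates."""

    residues: list[ResidueRecord]
    source_id: str = ""
    chain_id: str = ""

    def __post_init__(self):
        if not self.residues:
            raise StructureInputError("antigen model contains no usable residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureInputError("duplicate residue keys within chain")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def anchors(self) -> np.ndarray:
        """(n, 3) array of side-chain anchor coordinates, residue order."""
        return np.array([side_chain_anchor(r) for r in self.residues])

    def atom_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flat (coords, radii, residue_index) arrays over all atoms."""
        coords, radii, owner = [], [], []
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                coords.append(a.coord)
                radii.append(a.vdw_radius)
                owner.append(i)
        return np.asarray(coords, float), np.asarray(radii, float), np.asarray(owner, int)


def side_chain_anchor(residue: ResidueRecord) -> np.ndarray:
    """Cβ coordinate of a residue, or Cα for glycine / Cβ-less residues."""
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coord
    ca = residue.atom("CA")
    if ca is not None:
        return ca.coord
    raise StructureInputError(
        f"residue {residue.label} has neither CB nor CA; should have been dropped at load"
    )


def _one_letter(resname: str) -> str | None:
    resname = resname.strip().upper()
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname]
    # modified residues with a standard parent (MSE -> M etc.)
    letter = protein_letters_3to1_extended.get(resname)
    if letter in THREE_TO_ONE.values():
        return letter
    return None


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        # infer from the atom name: first alphabetic character
        for ch in bio_atom.get_name():
            if ch.isalpha():
                elem = ch.upper()
                break
    return elem


def load_antigen(
    pdb_source: Union[str, Path, io.TextIOBase],
    chain_id: str,
    model_index: int = 0,
    vdw_radii: dict[str, float] | None = None,
    include_hydrogens: bool = False,
) -> AntigenModel:
    """Load one chain of a PDB structure as an :class:`AntigenModel`.

    Only standard amino-acid residues (plus modified residues with a standard
    parent, e.g. MSE -> MET) are kept.  Waters, hetero ligands and alternate
    locations other than the first-listed one are dropped; residues missing
    both Cβ and Cα are dropped with a warning.

    Parameters
    ----------
    pdb_source
        Path to a PDB file or an open text handle.
    chain_id
        Chain identifier to extract.
    model_index
        Model to use for multi-model (NMR) files; default first model.
    vdw_radii
        Optional element -> radius (Å) table overriding the built-in one.
    """
    radii = dict(VDW_RADII)
    if vdw_radii:
        radii.update({k.upper(): v for k, v in vdw_radii.items()})

    parser = PDBParser(QUIET=True)
    name = getattr(pdb_source, "name", None) or str(pdb_source)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("antigen", pdb_source)
    except FileNotFoundError:
        raise StructureInputError(f"PDB file not found: {name}")
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureInputError(f"could not parse PDB input {name}: {exc}") from exc

    models = list(structure)
    if not models:
        raise StructureInputError(f"no models in PDB input {name}")
    if model_index >= len(models):
        raise StructureInputError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    chains = {c.id: c for c in model}
    if chain_id not in chains:
        raise ChainNotFoundError(chain_id, sorted(chains))
    chain = chains[chain_id]

    residues: list[ResidueRecord] = []
    n_dropped = 0
    for res in chain:
        hetflag, seq_number, icode = res.get_id()
        letter = _one_letter(res.get_resname())
        if letter is None:
            continue  # water, ligand, unmappable modified residue
        if hetflag != " " and not is_aa(res, standard=False):
            continue
        atoms = []
        for bio_atom in res:
            if bio_atom.is_disordered():
                # keep the first-listed altloc only
                bio_atom = sorted(
                    bio_atom.disordered_get_list(), key=lambda a: a.get_altloc()
                )[0]
            elem = _element_of(bio_atom)
            if elem == "H" and not include_hydrogens:
                continue
            atoms.append(
                AtomRecord(
                    name=bio_atom.get_name(),
                    element=elem,
                    coord=np.asarray(bio_atom.get_coord(), float),
                    vdw_radius=radii.get(elem, DEFAULT_VDW_RADIUS),
                )
            )
        record = ResidueRecord(
            chain_id=chain_id,
            seq_number=seq_number,
            insertion_code=icode.strip(),
            aa=letter,
            atoms=atoms,
        )
        if record.atom("CB") is None and record.atom("CA") is None:
            n_dropped += 1
            logger.warning("dropping residue %s: no CB or CA atom", record.label)
            continue
        residues.append(record)

    if n_dropped:
        logger.warning("dropped %d residue(s) without an anchor atom", n_dropped)
    if not residues:
        raise StructureInputError(
            f"chain {chain_id!r} of {name} contains no standard amino-acid residues"
        )
    return AntigenModel(residues=residues, source_id=name, chain_id=chain_id)


def write_pdb(model: AntigenModel, handle_or_path: Union[str, Path, io.TextIOBase]) -> None:
    """Write the retained residues back out as minimal PDB ATOM records."""
    own = isinstance(handle_or_path, (str, Path))
    handle = open(handle_or_path, "w") if own else handle_or_path
    try:
        serial = 1
        for res in model.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for a in res.atoms:
                x, y, z = a.coord
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                handle.write(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {res.chain_id}"
                    f"{res.seq_number:4d}{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
                serial += 1
        handle.write("TER\nEND\n")
    finally:
        if own:
            handle.close()
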