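"""Protein structure handling: PDB reading/writing and interface extraction.

The screening cascade starts from a receptor-peptide complex (a kinase
domain bound to a short activator fragment).  This module parses such a
complex from PDB text, lets callers name the anchor peptide (the short
partner-protein stretch whose contacts template the pharmacophore), and
extracts the receptor atoms lining the interface.

Parsing is delegated to :mod:`gemmi`; only the first MODEL is kept.
Residue numbering follows the input file verbatim (author numbering).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "ResidueSelection",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "select_residues",
    "interface_atoms",
]

#: Elements excluded from heavy-atom computations.
_HYDROGENS = frozenset({"H", "D"})


class StructureParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass(frozen=True, order=True)
class Atom:
    """A single atom record, in the file's own residue numbering."""

    chain_id: str
    residue_number: int
    name: str
    serial: int
    element: str
    residue_name: str
    x: float
    y: float
    z: float
    hetero: bool = False
    occupancy: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGENS


@dataclass
class Structure:
    """A parsed complex: a flat atom list plus chain bookkeeping.

    HETATM records (ions, cofactors, waters) are retained but carry
    ``hetero=True`` so callers can drop them; the screening protocol
    removes every ligand except the anchor peptide before building the
    pharmacophore.
    """

    atoms: list[Atom] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValueError(f"non-finite coordinates for atom {a}")
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str) -> list[int]:
        out: list[int] = []
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_number not in out:
                out.append(a.residue_number)
        return out

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def atom(self, chain_id: str, residue_number: int, name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == name
            ):
                return a
        raise KeyError((chain_id, residue_number, name))

    def without_hetero(self) -> "Structure":
        return Structure(
            atoms=[a for a in self.atoms if not a.hetero], name=self.name
        )

    def coordinates(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        if not src:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in src], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x' = R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            nx, ny, nz = rotation @ a.xyz + translation
            new_atoms.append(replace(a, x=float(nx), y=float(ny), z=float(nz)))
        return Structure(atoms=new_atoms, name=self.name)


@dataclass(frozen=True)
class ResidueSelection:
    """An ordered residue range on one chain, tagged by its role.

    ``role`` is ``"anchor"`` for the peptide stretch templating the
    pharmacophore (e.g. activator residues 7-11) or ``"receptor"``.
    """

    chain_id: str
    residue_numbers: tuple[int, ...]
    role: str = "anchor"

    def __post_init__(self) -> None:
        if not self.residue_numbers:
            raise ValueError("empty residue selection")
        if self.role not in ("anchor", "receptor"):
            raise ValueError(f"unknown selection role {self.role!r}")

    def atoms(self, structure: Structure, heavy_only: bool = False) -> list[Atom]:
        wanted = set(self.residue_numbers)
        out = [
            a
            for a in structure.atoms
            if a.chain_id == self.chain_id and a.residue_number in wanted
        ]
        if heavy_only:
            out = [a for a in out if not a.is_hydrogen]
        return out

    def validate(self, structure: Structure) -> None:
        present = set(structure.residues(self.chain_id))
        missing = [r for r in self.residue_numbers if r not in present]
        if missing:
            raise ValueError(
                f"selection residues {missing} absent from chain {self.chain_id!r}"
            )


def _check_coordinate_fields(pdb_text: str) -> None:
    # gemmi tolerates some malformed records silently; fail loudly with
    # the offending line instead.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise StructureParseError(
                        f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                    ) from None
        elif line.startswith(("ATOM", "HETATM")):
            raise StructureParseError(f"line {lineno}: truncated atom record")


def read_structure(pdb_text: str, name: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure` (first model only).

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties broken in favour of altloc ``A``).  Insertion codes are not
    supported and raise.
    """
    _check_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise StructureParseError(str(exc)) from exc
    if len(st) == 0:
        raise StructureParseError("no models in PDB text")
    model = st[0]

    best: dict[tuple[str, int, str], tuple[float, str, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    n_records = 0
    for chain in model:
        for residue in chain:
            if residue.seqid.icode not in ("", " "):
                raise StructureParseError(
                    f"insertion code {residue.seqid.icode!r} at "
                    f"{chain.name} {residue.seqid.num} is unsupported"
                )
            hetero = residue.het_flag == "H"
            for at in residue:
                n_records += 1
                atom = Atom(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    name=at.name,
                    serial=at.serial,
                    element=at.element.name,
                    residue_name=residue.name,
                    x=at.pos.x,
                    y=at.pos.y,
                    z=at.pos.z,
                    hetero=hetero,
                    occupancy=at.occ,
                )
                key = (atom.chain_id, atom.residue_number, atom.name)
                altloc = at.altloc if at.altloc else "A"
                if key not in best:
                    best[key] = (atom.occupancy, altloc, atom)
                    order.append(key)
                else:
                    occ0, alt0, _ = best[key]
                    if (atom.occupancy, _alt_rank(altloc)) > (occ0, _alt_rank(alt0)):
                        best[key] = (atom.occupancy, altloc, atom)
    if n_records == 0:
        raise StructureParseError("no ATOM/HETATM records found")
    return Structure(atoms=[best[k][2] for k in order], name=name or st.name)


def _alt_rank(altloc: str) -> int:
    # higher is preferred; 'A' wins ties over later letters
    return -ord(altloc[0]) if altloc else 0


def write_structure(structure: Structure) -> str:
    """Serialize to PDB text (fixed formatting, 3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = structure.name or "ppiscreen"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for a in structure.atoms:
        if a.chain_id not in chain_map:
            chain_map[a.chain_id] = gemmi.Chain(a.chain_id)
            model.add_chain(chain_map[a.chain_id])
        chain = model[a.chain_id]
        rkey = (a.chain_id, a.residue_number)
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.hetero else "A"
            chain.add_residue(res)
            res_map[rkey] = chain[len(chain) - 1]
        res = res_map[rkey]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(a.x, a.y, a.z)
        at.occ = a.occupancy
        at.serial = a.serial
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def select_residues(
    structure: Structure,
    chain_id: str,
    start: int,
    end: int,
    role: str = "anchor",
) -> ResidueSelection:
    """Build a validated contiguous selection ``chain:start-end`` (inclusive)."""
    present = [
        r for r in structure.residues(chain_id) if start <= r <= end
    ]
    if not present:
        raise ValueError(
            f"no residues in {start}-{end} on chain {chain_id!r}"
        )
    sel = ResidueSelection(chain_id=chain_id, residue_numbers=tuple(present), role=role)
    sel.validate(structure)
    return sel


def interface_atoms(
    structure: Structure,
    anchor: ResidueSelection,
    cutoff: float,
    include_hydrogens: bool = False,
) -> list[Atom]:
    """Receptor heavy atoms within ``cutoff`` angstrom of any anchor atom.

    The receptor is every non-hetero atom outside the anchor selection.
    Hydrogens are excluded on both sides by default.  Output order is
    deterministic: (chain, residue number, atom name).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    anchor.validate(structure)
    anchor_atoms = anchor.atoms(structure, heavy_only=not include_hydrogens)
    if not anchor_atoms:
        raise ValueError("anchor selection has no atoms")
    anchor_keys = {(a.chain_id, a.residue_number) for a in anchor_atoms}
    receptor = [
        a
        for a in structure.atoms
        if (a.chain_id, a.residue_number) not in anchor_keys
        and not a.hetero
        and (include_hydrogens or not a.is_hydrogen)
    ]
    if not receptor or cutoff == 0:
        return []
    tree = cKDTree(structure.coordinates(anchor_atoms))
    coords = structure.coordinates(receptor)
    dists, _ = tree.query(coords, k=1)
    hits = [a for a, d in zip(receptor, dists) if d <= cutoff]
    hits.sort(key=lambda a: (a.chain_id, a.residue_number, a.name))
    return hits
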