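"""Interface hot-spot scoring.

Hot spots are interface residues that contribute disproportionately to
binding free energy.  Two complementary read-outs are combined, mirroring
common practice for protein-protein interfaces:

* **evolutionary conservation** of each alignment column, normalised to
  the conventional 0-9 scale (0 = highly variable, 9 = invariant); and
* a **computational alanine-scan surrogate**: a ddG-like score for
  truncating each anchor side chain to alanine, proportional to the
  cross-interface heavy-atom contacts the truncation removes.

The conservation score averages two transparent column-scoring schemes
(Shannon entropy and mean pairwise BLOSUM62 similarity), each min-max
normalised over columns; web-server conservation pipelines that retrieve
their own homolog sets are deliberately not emulated.  The ddG surrogate
is a contact-count proxy on a kJ/mol-like scale: it is meant to rank
residues (buried aromatic anchors on top), not to reproduce force-field
energies.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .structure import Atom, ResidueSelection, Structure

__all__ = [
    "ConservationProfile",
    "AlaScanResult",
    "conservation_profile",
    "alanine_scan",
    "rank_hotspots",
]

#: kJ/mol per lost cross-interface heavy-atom contact.  Calibrated so a
#: fully buried tyrosine side chain (roughly 20-40 contacts at 4.5 A)
#: scores ~2-4 kJ/mol, the canonical key-residue window.
DDG_PER_CONTACT = 0.1

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ConservationProfile:
    """Per-column 0-9 conservation scores plus the raw scheme values."""

    scores: np.ndarray          # int, 0..9, one per column
    entropy_score: np.ndarray   # scheme A, raw (higher = conserved)
    similarity_score: np.ndarray  # scheme B, raw (higher = conserved)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.min(initial=9) < 0 or self.scores.max(initial=0) > 9:
            raise ValueError("conservation scores must lie in 0..9")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class AlaScanResult:
    """Surrogate ddG (kJ/mol-like scale) for one anchor residue.

    Positive values predict that replacing the side chain with alanine
    destabilises the complex.  ``ddg`` is ``None`` when side-chain atoms
    are missing from the model.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    ddg: float | None
    n_contacts: int = 0

    @property
    def missing(self) -> bool:
        return self.ddg is None


def _parse_alignment(msa) -> list[str]:
    if isinstance(msa, str):
        handle = io.StringIO(msa)
        aln = AlignIO.read(handle, "fasta")
        rows = [str(rec.seq).upper() for rec in aln]
    else:
        rows = [str(s).upper() for s in msa]
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    if len(rows[0]) == 0:
        raise ValueError("empty alignment")
    return rows


def column_entropy(column: str) -> float:
    """Shannon entropy (nats) of a column's residue distribution, gaps ignored."""
    residues = [c for c in column if c in _AMINO]
    if not residues:
        return math.log(len(_AMINO))
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    n = len(residues)
    return -sum((k / n) * math.log(k / n) for k in counts.values())


def conservation_profile(msa) -> ConservationProfile:
    """Score alignment columns 0 (variable) to 9 (invariant).

    Parameters
    ----------
    msa:
        Aligned FASTA text, or an iterable of equal-length aligned
        sequences.

    Scheme A is ``1 - H/H_max`` with ``H`` the column Shannon entropy;
    scheme B is the mean pairwise BLOSUM62 similarity of column residues,
    rescaled to [0, 1] by the matrix's own range.  Both schemes are
    min-max normalised over columns, averaged, and binned into ten
    equal-width bins on [0, 1].  Columns with a single residue type are
    pinned to 9 regardless of normalisation (the scale's definition of
    "invariant").
    """
    rows = _parse_alignment(msa)
    ncol = len(rows[0])
    blosum = substitution_matrices.load("BLOSUM62")
    bmin = min(blosum[a, b] for a in _AMINO for b in _AMINO)
    bmax = max(blosum[a, b] for a in _AMINO for b in _AMINO)

    ent = np.zeros(ncol)
    sim = np.zeros(ncol)
    invariant = np.zeros(ncol, dtype=bool)
    hmax = math.log(len(_AMINO))
    for j in range(ncol):
        col = "".join(r[j] for r in rows)
        residues = [c for c in col if c in _AMINO]
        ent[j] = 1.0 - column_entropy(col) / hmax
        if len(residues) >= 2:
            pairs = [
                (blosum[a, b] - bmin) / (bmax - bmin)
                for i, a in enumerate(residues)
                for b in residues[i + 1 :]
            ]
            sim[j] = float(np.mean(pairs))
        else:
            sim[j] = 1.0 if residues else 0.0
        invariant[j] = len(set(residues)) == 1 and len(residues) > 0

    combined = (_minmax(ent) + _minmax(sim)) / 2.0
    scores = np.minimum(9, np.floor(combined * 10 + 1e-9).astype(int))
    scores[invariant] = 9
    return ConservationProfile(
        scores=scores, entropy_score=ent, similarity_score=sim
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


# Side-chain atoms beyond C-beta are the part an alanine mutation removes.
_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT", "CB"})


def truncated_atoms(atoms: list[Atom]) -> list[Atom]:
    """Heavy side-chain atoms past C-beta (what Ala truncation deletes)."""
    return [
        a for a in atoms if not a.is_hydrogen and a.name not in _BACKBONE
    ]


def alanine_scan(
    structure: Structure,
    anchor: ResidueSelection,
    contact_cutoff: float = 4.5,
    k: float = DDG_PER_CONTACT,
) -> list[AlaScanResult]:
    """Surrogate alanine scan over the anchor residues.

    ``ddg = k * n``, where ``n`` counts receptor heavy atoms within
    ``contact_cutoff`` of any side-chain atom past C-beta (each
    atom-atom pair counts once).  Gly and Ala score exactly 0.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be > 0")
    anchor.validate(structure)
    anchor_keys = set(anchor.residue_numbers)
    receptor = [
        a
        for a in structure.atoms
        if not a.hetero
        and not a.is_hydrogen
        and not (a.chain_id == anchor.chain_id and a.residue_number in anchor_keys)
    ]
    rec_xyz = structure.coordinates(receptor)
    results: list[AlaScanResult] = []
    for resnum in anchor.residue_numbers:
        atoms = structure.residue_atoms(anchor.chain_id, resnum)
        resname = atoms[0].residue_name if atoms else "UNK"
        if resname in ("GLY", "ALA"):
            results.append(AlaScanResult(anchor.chain_id, resnum, resname, 0.0, 0))
            continue
        side = truncated_atoms(atoms)
        if not side:
            # model lacks the side chain: report missing, not zero
            results.append(AlaScanResult(anchor.chain_id, resnum, resname, None))
            continue
        n = 0
        if len(rec_xyz):
            side_xyz = structure.coordinates(side)
            d = np.linalg.norm(
                side_xyz[:, None, :] - rec_xyz[None, :, :], axis=-1
            )
            n = int((d <= contact_cutoff).sum())
        results.append(
            AlaScanResult(anchor.chain_id, resnum, resname, k * n, n)
        )
    return results


def rank_hotspots(
    profile: ConservationProfile,
    ddg_results: list[AlaScanResult],
    residue_columns: dict[int, int],
    cons_min: int = 7,
    ddg_window: tuple[float, float] = (2.0, 4.0),
) -> list[AlaScanResult]:
    """Residues passing both the conservation and the ddG criterion.

    A residue is a hot spot when its alignment column scores at least
    ``cons_min`` and its surrogate ddG lies inside ``ddg_window``
    (inclusive).  ``residue_columns`` maps residue numbers to 0-based
    alignment columns.  Output is sorted by ddG, highest first.
    """
    if len(profile) == 0 or not ddg_results:
        raise ValueError("empty conservation profile or ddG results")
    lo, hi = ddg_window
    picked = []
    for r in ddg_results:
        if r.residue_number not in residue_columns or r.missing:
            continue
        col = residue_columns[r.residue_number]
        if profile.scores[col] >= cons_min and lo <= r.ddg <= hi:
            picked.append(r)
    picked.sort(key=lambda r: (-r.ddg, r.residue_number))
    return picked
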