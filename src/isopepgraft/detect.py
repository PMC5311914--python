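"""Detection and validation of intramolecular Lys–Asn/Asp isopeptide bonds.

An intramolecular isopeptide bond is an amide formed autocatalytically
between the ε-amino nitrogen (NZ) of a lysine and the side-chain carbon
(CG) of an asparagine or aspartate, with loss of NH3.  In a crystal
structure it shows up as an NZ–CG distance at covalent range (ideal amide
C–N ≈ 1.33 Å).  Detection here is purely geometric:

1. every same-chain Lys NZ × Asn/Asp CG pair within ``max_bond_length``
   (default 2.0 Å, leaving slack for refinement error) is reported;
2. the amide dihedral CE–NZ–CG–CB classifies the bond cis / trans /
   distorted (|ω| ≤ 30° → cis, |ω| ≥ 150° → trans);
3. the catalytic Glu/Asp partner is the acidic residue whose carboxylate
   oxygens hydrogen-bond to the isopeptide N–H and C=O groups, evaluated
   per alternate conformer (the engineered catalytic Glu can adopt two).

Structures at typical resolution carry no hydrogens, so hydrogen bonds use
heavy-atom criteria: donor–acceptor distance ≤ 3.5 Å with the angle at the
donor ≥ 90°; for the carboxyl-to-carbonyl contact a plain O⋯O distance
≤ 3.5 Å is accepted (the acid may be protonated).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Residue, Structure, StructureError, angle, dihedral

logger = logging.getLogger("isopepgraft")

__all__ = [
    "HBond",
    "IsopeptideBond",
    "find_isopeptide_bonds",
    "classify_configuration",
    "find_catalytic_partner",
]

ACCEPTOR_NAMES = ("ASN", "ASP")
ACID_NAMES = ("GLU", "ASP")

#: carboxylate oxygen names per acidic residue type
_ACID_OXYGENS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


@dataclass
class HBond:
    """A heavy-atom hydrogen bond (or O⋯O carboxyl contact)."""

    donor_atom: str  # "resid/atom" reference, e.g. "A:13/NZ"
    acceptor_atom: str
    distance: float  # Å
    angle: float  # degrees at the donor heavy atom
    altloc: str = ""  # conformer of the acidic partner, "" if single


@dataclass
class IsopeptideBond:
    """A detected Lys NZ – Asn/Asp CG covalent link."""

    donor: str  # Lys residue id
    acceptor: str  # Asn/Asp residue id
    bond_length: float  # Å
    omega: float | None  # CE–NZ–CG–CB dihedral, degrees
    configuration: str  # "cis" | "trans" | "distorted" | "unknown"
    catalytic: str | None = None  # Glu/Asp residue id or None
    hbonds: list[HBond] = field(default_factory=list)


def classify_configuration(omega: float | None, cis_cutoff_deg: float = 30.0) -> str:
    """Classify the amide dihedral: cis, trans, or distorted in between.

    cis if \\|ω\\| ≤ cutoff, trans if \\|ω\\| ≥ 180 − cutoff.  Symmetric in
    the sign of ω.  ``None`` (dihedral atoms missing) gives "unknown".
    """
    if omega is None:
        return "unknown"
    a = abs(omega)
    if a <= cis_cutoff_deg:
        return "cis"
    if a >= 180.0 - cis_cutoff_deg:
        return "trans"
    return "distorted"


def _bond_omega(lys: Residue, acceptor: Residue) -> float | None:
    """Amide dihedral CE–NZ–CG–CB across the isopeptide, None if atoms missing."""
    atoms = (lys.atom("CE"), lys.atom("NZ"), acceptor.atom("CG"), acceptor.atom("CB"))
    if any(a is None for a in atoms):
        missing = [n for n, a in zip(("CE", "NZ", "CG", "CB"), atoms) if a is None]
        logger.warning(
            "cannot compute omega for %s-%s: missing %s", lys.id, acceptor.id, ",".join(missing)
        )
        return None
    return dihedral(*(a.position for a in atoms))


def _amide_carbonyl_oxygen(acceptor: Residue):
    """The isopeptide C=O oxygen on the acceptor residue (OD1, or OD2 fallback)."""
    return acceptor.atom("OD1") or acceptor.atom("OD2")


def find_catalytic_partner(
    lys: Residue,
    acceptor: Residue,
    structure: Structure,
    hb_dist: float = 3.5,
    hb_angle_deg: float = 90.0,
) -> tuple[str | None, list[HBond]]:
    """Identify the catalytic Glu/Asp hydrogen-bonded to the isopeptide amide.

    For every acidic residue (other than the acceptor itself) and every
    alternate conformer of its carboxylate, two interactions are scored:

    * carboxyl O as acceptor of the isopeptide N–H: NZ⋯O ≤ ``hb_dist`` and
      CE–NZ–O angle ≥ ``hb_angle_deg``;
    * carboxyl O(H) against the isopeptide C=O: O⋯O ≤ ``hb_dist``.

    The residue with the most hydrogen bonds (summed over conformers) wins;
    ties break on shortest mean distance.  Returns ``(None, [])`` when no
    carboxylate oxygen lies within range — a valid, bond-less outcome.
    """
    nz = lys.atom("NZ")
    ce = lys.atom("CE")
    carbonyl_o = _amide_carbonyl_oxygen(acceptor)
    if nz is None:
        return None, []

    best: tuple[int, float, str, list[HBond]] | None = None
    for res in structure.residues():
        if res.name not in ACID_NAMES or (res.chain_id, res.number, res.icode) == (
            acceptor.chain_id,
            acceptor.number,
            acceptor.icode,
        ):
            continue
        o_names = _ACID_OXYGENS[res.name]
        conformers = res.altlocs() or [""]
        hbonds: list[HBond] = []
        for alt in conformers:
            for o_name in o_names:
                o = res.atom(o_name, altloc=alt) if alt else res.atom(o_name)
                if o is None:
                    continue
                d_nz = float(np.linalg.norm(o.position - nz.position))
                if d_nz <= hb_dist:
                    ang = angle(ce.position, nz.position, o.position) if ce is not None else 180.0
                    if ang >= hb_angle_deg:
                        hbonds.append(
                            HBond(f"{lys.id}/NZ", f"{res.id}/{o_name}", d_nz, ang, alt)
                        )
                        continue
                if carbonyl_o is not None:
                    d_oo = float(np.linalg.norm(o.position - carbonyl_o.position))
                    if d_oo <= hb_dist:
                        hbonds.append(
                            HBond(
                                f"{res.id}/{o_name}",
                                f"{acceptor.id}/{carbonyl_o.name}",
                                d_oo,
                                180.0,
                                alt,
                            )
                        )
        if not hbonds:
            continue
        mean_d = sum(h.distance for h in hbonds) / len(hbonds)
        key = (-len(hbonds), mean_d)
        if best is None or key < (-best[0], best[1]):
            best = (len(hbonds), mean_d, res.id, hbonds)

    if best is None:
        return None, []
    return best[2], best[3]


def find_isopeptide_bonds(
    structure: Structure,
    max_bond_length: float = 2.0,
    cis_cutoff_deg: float = 30.0,
    hb_dist: float = 3.5,
    hb_angle_deg: float = 90.0,
    same_chain_only: bool = True,
) -> list[IsopeptideBond]:
    """Find every Lys NZ – Asn/Asp CG pair at covalent distance.

    Returns a fully populated :class:`IsopeptideBond` per hit (amide
    dihedral, cis/trans classification, catalytic partner with its
    hydrogen bonds), sorted by bond length.  Candidate residues missing
    their NZ/CG atoms are skipped with a logged warning; a structure with
    no Lys or no Asn/Asp yields an empty list.
    """
    if max_bond_length <= 0:
        raise StructureError("max_bond_length must be positive")
    lysines = [r for r in structure.residues() if r.name == "LYS"]
    acceptors = [r for r in structure.residues() if r.name in ACCEPTOR_NAMES]

    bonds: list[IsopeptideBond] = []
    for lys, acc in itertools.product(lysines, acceptors):
        if same_chain_only and lys.chain_id != acc.chain_id:
            continue
        nz, cg = lys.atom("NZ"), acc.atom("CG")
        if nz is None or cg is None:
            logger.warning(
                "skipping candidate %s-%s: missing %s",
                lys.id,
                acc.id,
                "NZ" if nz is None else "CG",
            )
            continue
        d = float(np.linalg.norm(nz.position - cg.position))
        if d > max_bond_length:
            continue
        omega = _bond_omega(lys, acc)
        catalytic, hbonds = find_catalytic_partner(lys, acc, structure, hb_dist, hb_angle_deg)
        bonds.append(
            IsopeptideBond(
                donor=lys.id,
                acceptor=acc.id,
                bond_length=d,
                omega=omega,
                configuration=classify_configuration(omega, cis_cutoff_deg),
                catalytic=catalytic,
                hbonds=hbonds,
            )
        )
    bonds.sort(key=lambda b: b.bond_length)
    return bonds
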