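"""Triad grafting: map an isopeptide-forming residue triad onto a target fold.

The design procedure mirrors how a crosslink is moved between two Ig-like
(CnaB-type) β-sandwich domains that share a fold but little sequence:

1. superpose the template onto the target over an explicit residue
   correspondence (Cα atoms);
2. locate the target positions structurally homologous to the template's
   reactive Lys, catalytic Glu/Asp and acceptor Asn — directly from the
   correspondence, or by nearest-Cα assignment after superposition;
3. emit the minimal mutations placing K / E / N at those positions
   (positions already holding the right residue need none);
4. audit the hydrophobic cage around the template lysine: wherever the
   template packs a large apolar side chain against the Lys aliphatic
   stem but the target offers a much smaller one, flag the position and
   suggest a steering mutation to the template's residue type (the
   Val→Phe class of mutation that restricts the lysine's conformational
   freedom so it can reach the acceptor).

Cavity flags compare standard mean side-chain volumes; the default 40 Å³
threshold separates a genuine cavity (Phe vs Val ≈ 50 Å³) from neutral
swaps (Leu vs Ile ≈ 0 Å³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import (
    Correspondence,
    Residue,
    SelectionError,
    Selector,
    Structure,
    StructureError,
    SuperpositionResult,
    _residue_by_id,
    ca_superpose,
    select_atoms,
)

logger = logging.getLogger("isopepgraft")

__all__ = [
    "TriadSpec",
    "Mutation",
    "MutationPlan",
    "ContactShell",
    "CavityFlag",
    "map_triad",
    "contact_shell",
    "hydrophobic_fraction",
    "cavity_audit",
    "stacking_distance",
    "SIDE_CHAIN_VOLUME",
    "HYDROPHOBIC_SET",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Mean amino-acid side-chain volumes (Å³): Zamyatnin's mean residue volumes
# (Prog. Biophys. Mol. Biol. 24, 107–123, 1972) minus the Gly value, so Gly
# itself is 0.  Used only for cavity deltas, where the differences matter.
_RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
SIDE_CHAIN_VOLUME = {aa: round(v - _RESIDUE_VOLUME["G"], 1) for aa, v in _RESIDUE_VOLUME.items()}

#: residues counted as hydrophobic in packing audits; Gly and Pro included
#: because both appear routinely in apolar contact shells.
HYDROPHOBIC_SET = frozenset("AVLIMFWPG")

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class TriadSpec:
    """The three template residues of an isopeptide triad (residue ids)."""

    lys_pos: str
    glu_pos: str
    asn_pos: str

    def validate(self, template: Structure) -> None:
        expected = {self.lys_pos: ("LYS",), self.glu_pos: ("GLU", "ASP"), self.asn_pos: ("ASN", "ASP")}
        if len({self.lys_pos, self.glu_pos, self.asn_pos}) != 3:
            raise StructureError("triad positions must be three distinct residues")
        for rid, allowed in expected.items():
            res = _residue_by_id(template, rid)
            if res is None:
                raise StructureError(f"triad residue {rid} not found in template")
            if res.name not in allowed:
                raise StructureError(
                    f"triad residue {rid} is {res.name}, expected one of {'/'.join(allowed)}"
                )


@dataclass
class Mutation:
    """A single point mutation in ``wt``-position-``new`` notation (1-based)."""

    wt_aa: str
    position: int
    new_aa: str
    role: str = "triad"  # "triad" | "steering"
    chain_id: str = "A"

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"


@dataclass
class MutationPlan:
    """Mutations mapping a template triad onto a target, plus the fit used."""

    target_id: str
    mutations: list[Mutation]
    superposition: SuperpositionResult
    triad_targets: dict[str, str] = field(default_factory=dict)  # role -> target residue id

    def notation(self) -> list[str]:
        return [str(m) for m in self.mutations]


@dataclass
class ContactShell:
    """Heavy atoms within ``radius`` of a named center-atom set."""

    center: str  # residue id
    atom_names: tuple[str, ...]
    radius: float
    contacts: list[tuple[str, str, str, float]]  # (residue id, resname, atom name, distance)


@dataclass
class CavityFlag:
    """A packing cavity at a target position relative to the template."""

    target_position: str  # residue id in the target
    template_residue: str  # 3-letter code
    target_residue: str  # 3-letter code
    volume_delta: float  # Å³, template minus target
    suggested: Mutation | None


# ---------------------------------------------------------------------------
# Triad mapping
# ---------------------------------------------------------------------------

_TRIAD_TARGET_AA = {"lys": "K", "glu": "E", "asn": "N"}
_TRIAD_ACCEPTED = {"lys": {"K"}, "glu": {"E", "D"}, "asn": {"N", "D"}}


def map_triad(
    template: Structure,
    triad: TriadSpec,
    target: Structure,
    correspondence: Correspondence,
    assign_cutoff: float = 3.5,
) -> MutationPlan:
    """Map the triad onto the target and emit the required mutations.

    Each triad position is resolved to a target residue via the
    correspondence; positions absent from it are assigned to the nearest
    target Cα within ``assign_cutoff`` Å after superposition.  A position
    already holding an acceptable residue type (Lys; Glu/Asp; Asn/Asp)
    contributes no mutation, so plans carry at most three.
    """
    sup = ca_superpose(template, target, correspondence)
    target_cas = [
        (res, res.atom("CA"))
        for res in target.residues()
        if res.atom("CA") is not None
    ]

    mutations: list[Mutation] = []
    triad_targets: dict[str, str] = {}
    for role, templ_id in (("lys", triad.lys_pos), ("glu", triad.glu_pos), ("asn", triad.asn_pos)):
        targ_id = correspondence.target_for(templ_id)
        if targ_id is None:
            targ_id = _nearest_ca_assignment(template, templ_id, target_cas, sup, assign_cutoff)
            if targ_id is None:
                raise StructureError(
                    f"triad position {templ_id} has no target CA within "
                    f"{assign_cutoff} Å; cannot map"
                )
        targ_res = _residue_by_id(target, targ_id)
        if targ_res is None:
            raise StructureError(f"correspondence names missing target residue {targ_id}")
        triad_targets[role] = targ_id
        wt = THREE_TO_ONE.get(targ_res.name, "X")
        if wt not in _TRIAD_ACCEPTED[role]:
            mutations.append(
                Mutation(
                    wt_aa=wt,
                    position=targ_res.number,
                    new_aa=_TRIAD_TARGET_AA[role],
                    role="triad",
                    chain_id=targ_res.chain_id,
                )
            )
    logger.info(
        "map_triad: %s -> %s (rmsd %.3f Å over %d Cα)",
        (triad.lys_pos, triad.glu_pos, triad.asn_pos),
        [str(m) for m in mutations] or "no mutations needed",
        sup.rmsd,
        sup.n_pairs,
    )
    return MutationPlan(
        target_id=target.id, mutations=mutations, superposition=sup, triad_targets=triad_targets
    )


def _nearest_ca_assignment(template, templ_id, target_cas, sup, cutoff):
    res = _residue_by_id(template, templ_id)
    if res is None or res.atom("CA") is None:
        raise StructureError(f"template residue {templ_id} missing or has no CA")
    moved = sup.apply(res.atom("CA").position[None, :])[0]
    best_id, best_d = None, cutoff
    for targ_res, ca in target_cas:
        d = float(np.linalg.norm(ca.position - moved))
        if d <= best_d:
            best_id, best_d = targ_res.id, d
    return best_id


# ---------------------------------------------------------------------------
# Contact shells and the hydrophobic cage
# ---------------------------------------------------------------------------

def contact_shell(
    structure: Structure,
    center: str,
    atom_names: set[str] | tuple[str, ...],
    radius: float = 4.5,
    exclude_center_residue: bool = True,
) -> ContactShell:
    """All heavy atoms within ``radius`` Å of the named center atoms.

    Center atoms are never their own contacts; by default the rest of the
    center residue (its backbone) is excluded too, so the shell reflects
    the packing environment rather than covalent neighbours.
    """
    center_res = _residue_by_id(structure, center)
    if center_res is None:
        raise SelectionError(f"center residue {center} not found")
    centers = [center_res.atom(n) for n in sorted(atom_names)]
    if any(a is None for a in centers):
        missing = [n for n, a in zip(sorted(atom_names), centers) if a is None]
        raise SelectionError(f"center residue {center} lacks atoms {','.join(missing)}")
    cpos = np.array([a.position for a in centers])

    contacts = []
    for res in structure.residues():
        same = res.id == center_res.id
        if same and exclude_center_residue:
            continue
        for atom in res.heavy_atoms():
            if same and atom.name in atom_names:
                continue
            d = float(np.linalg.norm(cpos - atom.position[None, :], axis=1).min())
            if d <= radius:
                contacts.append((res.id, res.name, atom.name, d))
    contacts.sort(key=lambda c: c[3])
    return ContactShell(
        center=center, atom_names=tuple(sorted(atom_names)), radius=radius, contacts=contacts
    )


def hydrophobic_fraction(
    shell: ContactShell, hydrophobic: frozenset[str] = HYDROPHOBIC_SET
) -> float:
    """Fraction of shell atoms that belong to hydrophobic residues.

    The isopeptide-forming reaction needs an apolar cage (it lowers the
    Lys ε-amine pKa); values near 1 indicate a template-like environment.
    """
    if not shell.contacts:
        raise StructureError(f"contact shell of {shell.center} is empty; fraction undefined")
    n_hydro = sum(
        1 for _, resname, _, _ in shell.contacts if THREE_TO_ONE.get(resname, "X") in hydrophobic
    )
    return n_hydro / len(shell.contacts)


LYS_SIDE_CHAIN = ("CB", "CG", "CD", "CE", "NZ")


def cavity_audit(
    template: Structure,
    target: Structure,
    correspondence: Correspondence,
    lys_pos_template: str,
    volume_threshold: float = 40.0,
    shell_radius: float = 4.5,
) -> list[CavityFlag]:
    """Compare the template lysine's packing cage with the target's.

    For every template residue whose side chain contacts the template Lys
    side chain (within ``shell_radius``), the standard side-chain volume of
    the template residue is compared with that of the corresponding target
    residue.  A volume deficit ≥ ``volume_threshold`` Å³ yields a flag with
    a suggested steering mutation to the template's residue type.  Contact
    residues with no correspondence entry are flagged as unmapped
    (``template_residue`` set, ``target_residue`` = "???", no suggestion).
    """
    lys_res = _residue_by_id(template, lys_pos_template)
    if lys_res is None:
        raise StructureError(f"template lysine {lys_pos_template} not found")
    present = [n for n in LYS_SIDE_CHAIN if lys_res.atom(n) is not None]
    if not present:
        raise StructureError(f"template lysine {lys_pos_template} has no side-chain atoms")
    shell = contact_shell(template, lys_pos_template, set(present), radius=shell_radius)

    flags: list[CavityFlag] = []
    seen: set[str] = set()
    for templ_rid, templ_resname, _, _ in shell.contacts:
        if templ_rid in seen:
            continue
        seen.add(templ_rid)
        templ_aa = THREE_TO_ONE.get(templ_resname, "X")
        targ_rid = correspondence.target_for(templ_rid)
        if targ_rid is None:
            logger.warning("cavity_audit: template contact %s has no correspondence", templ_rid)
            flags.append(CavityFlag(templ_rid, templ_resname, "???", float("nan"), None))
            continue
        targ_res = _residue_by_id(target, targ_rid)
        if targ_res is None:
            raise StructureError(f"correspondence names missing target residue {targ_rid}")
        targ_aa = THREE_TO_ONE.get(targ_res.name, "X")
        if templ_aa == "X" or targ_aa == "X":
            continue
        delta = SIDE_CHAIN_VOLUME[templ_aa] - SIDE_CHAIN_VOLUME[targ_aa]
        if delta >= volume_threshold:
            flags.append(
                CavityFlag(
                    target_position=targ_rid,
                    template_residue=templ_resname,
                    target_residue=targ_res.name,
                    volume_delta=delta,
                    suggested=Mutation(
                        wt_aa=targ_aa,
                        position=targ_res.number,
                        new_aa=templ_aa,
                        role="steering",
                        chain_id=targ_res.chain_id,
                    ),
                )
            )
    return flags


# ---------------------------------------------------------------------------
# Aromatic stacking
# ---------------------------------------------------------------------------

def stacking_distance(
    structure: Structure,
    plane_atoms: str | Selector,
    ring_residue: str,
) -> tuple[float, float]:
    """Distance between an amide plane and an aromatic ring.

    Returns ``(min_atom_distance, centroid_distance)``: the minimum over
    all plane-atom × ring-atom pairs, and the distance between the two
    centroids.  The ring residue must be Phe/Tyr/Trp/His with all ring
    atoms present.
    """
    res = _residue_by_id(structure, ring_residue)
    if res is None:
        raise SelectionError(f"ring residue {ring_residue} not found")
    if res.name not in RING_ATOMS:
        raise StructureError(f"{ring_residue} ({res.name}) is not an aromatic residue")
    ring = [res.atom(n) for n in RING_ATOMS[res.name]]
    if any(a is None for a in ring):
        missing = [n for n, a in zip(RING_ATOMS[res.name], ring) if a is None]
        raise StructureError(f"ring of {ring_residue} incomplete: missing {','.join(missing)}")
    ring_pos = np.array([a.position for a in ring])

    plane = select_atoms(structure, plane_atoms)
    plane_pos = np.array([a.position for _, a in plane])

    d = np.linalg.norm(plane_pos[:, None, :] - ring_pos[None, :, :], axis=-1)
    centroid_d = float(np.linalg.norm(plane_pos.mean(axis=0) - ring_pos.mean(axis=0)))
    return float(d.min()), centroid_d
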