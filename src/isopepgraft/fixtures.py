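"""Synthetic fixtures with known ground truth.

Every generator here builds an input whose correct answer is known by
construction, so the geometric and spectral operations can be tested
end-to-end without any deposited structure:

* :func:`make_isopeptide_fixture` — a ~20-residue two-strand chain with a
  Lys NZ–Asn CG link planted at an exact bond length and amide dihedral,
  optionally with a catalytic Glu whose carboxylate oxygens sit at
  hydrogen-bond geometry in two alternate conformations;
* :func:`make_decoy_fixture` — Lys and Asn present but far apart (NZ–CG
  > 6 Å), so detection must return nothing;
* :func:`make_graft_fixture_pair` — a template/target domain pair related
  by a random rigid transform, with the template carrying a K/E/N triad
  plus a Phe-lined lysine cage and the target carrying the residues that
  require the classic triad + steering mutations;
* :func:`make_spectrum_fixture` — a peak list containing every theoretical
  fragment of a branched peptide (± ppm jitter) plus uniform decoy peaks
  kept well away from any true ion.

Structures use ideal small-molecule bond lengths and angles (amide C–N
1.33 Å, C–C 1.52 Å); no energy minimisation is attempted and backbone
geometry away from the planted features is only loosely realistic.  All
randomness flows from the ``seed`` argument; identical parameters and seed
reproduce a fixture byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np

from .msverify import NH3_MONO, CrosslinkedPeptide, PeakList, theoretical_fragments
from .structure import Atom, Correspondence, Residue, Structure, StructureError

logger = logging.getLogger("isopepgraft")

__all__ = [
    "place_atom",
    "make_isopeptide_fixture",
    "make_decoy_fixture",
    "make_graft_fixture_pair",
    "make_spectrum_fixture",
    "write_sidecar",
]


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d given three reference atoms and internal coordinates.

    d is placed ``bond`` Å from c, with angle(b, c, d) = ``angle_deg`` and
    dihedral(a, b, c, d) = ``dihedral_deg`` (standard natural-extension
    reference-frame construction).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            -bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


def _residue(chain: str, number: int, name: str, atoms: dict[str, np.ndarray],
             altloc_atoms: dict[str, list[tuple[str, np.ndarray, float]]] | None = None) -> Residue:
    res = Residue(chain_id=chain, number=number, name=name)
    for atom_name, pos in atoms.items():
        res.atoms.append(Atom(name=atom_name, element=_element_of(atom_name), position=pos))
    for atom_name, variants in (altloc_atoms or {}).items():
        for alt, pos, occ in variants:
            res.atoms.append(
                Atom(name=atom_name, element=_element_of(atom_name), position=pos,
                     occupancy=occ, altloc=alt)
            )
    return res


def _filler_strand(chain: str, numbers: list[int], origin: np.ndarray,
                   direction: np.ndarray, rng: np.random.Generator) -> list[Residue]:
    """Glycine residues with rough backbones spaced 3.8 Å along a line."""
    direction = direction / np.linalg.norm(direction)
    out = []
    for k, num in enumerate(numbers):
        ca = origin + 3.8 * (k + 1) * direction + rng.normal(0, 0.05, 3)
        out.append(
            _residue(
                chain, num, "GLY",
                {
                    "N": ca + np.array([-1.2, 0.8, 0.0]),
                    "CA": ca,
                    "C": ca + np.array([1.2, 0.8, 0.0]),
                    "O": ca + np.array([1.3, 2.0, 0.0]),
                },
            )
        )
    return out


def make_isopeptide_fixture(
    bond_length: float = 1.33,
    omega_deg: float = 0.0,
    with_glu: bool = True,
    glu_conformers: int = 2,
    seed: int = 0,
) -> tuple[Structure, dict[str, Any]]:
    """Build a small structure with a planted Lys5 NZ–Asn15 CG isopeptide.

    The bond length and amide dihedral (CE–NZ–CG–CB) are exact by
    construction.  With ``with_glu`` a Glu-8 is added whose carboxylate
    oxygens hydrogen-bond to the isopeptide N–H and C=O in each of
    ``glu_conformers`` alternate conformations (mimicking a catalytic
    Glu with a rotated carboxyl).  Returns the structure and a ground-truth
    record of everything planted.
    """
    if bond_length <= 0:
        raise StructureError("bond_length must be positive")
    rng = np.random.default_rng(seed)

    # --- the isopeptide core, built in internal coordinates -----------------
    nz = np.zeros(3)
    cg_acc = np.array([bond_length, 0.0, 0.0])
    ce = 1.47 * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0.0])

    cb_acc = place_atom(ce, nz, cg_acc, 1.51, 116.0, omega_deg)
    od1 = place_atom(ce, nz, cg_acc, 1.23, 123.0, omega_deg + 180.0)

    # lysine side chain, extended conformation back from CE
    cd_l = place_atom(cg_acc, nz, ce, 1.52, 111.0, 180.0)
    cg_l = place_atom(nz, ce, cd_l, 1.52, 111.0, 180.0)
    cb_l = place_atom(ce, cd_l, cg_l, 1.52, 111.0, 180.0)
    ca_l = place_atom(cd_l, cg_l, cb_l, 1.53, 111.0, 180.0)
    n_l = place_atom(cg_l, cb_l, ca_l, 1.46, 110.0, 60.0)
    c_l = place_atom(cg_l, cb_l, ca_l, 1.53, 110.0, -60.0)
    o_l = place_atom(cb_l, ca_l, c_l, 1.23, 120.0, 0.0)

    # acceptor asparagine (ND2 left with the departed ammonia)
    ca_a = place_atom(nz, cg_acc, cb_acc, 1.53, 114.0, 120.0)
    n_a = place_atom(cg_acc, cb_acc, ca_a, 1.46, 110.0, 60.0)
    c_a = place_atom(cg_acc, cb_acc, ca_a, 1.53, 110.0, 180.0)
    o_a = place_atom(cb_acc, ca_a, c_a, 1.23, 120.0, 0.0)

    lys = _residue("A", 5, "LYS", {
        "N": n_l, "CA": ca_l, "C": c_l, "O": o_l,
        "CB": cb_l, "CG": cg_l, "CD": cd_l, "CE": ce, "NZ": nz,
    })
    asn = _residue("A", 15, "ASN", {
        "N": n_a, "CA": ca_a, "C": c_a, "O": o_a,
        "CB": cb_acc, "CG": cg_acc, "OD1": od1,
    })

    residues = [lys, asn]
    catalytic_truth = None

    if with_glu:
        # amide N-H direction: opposite the bisector of the two NZ substituents
        u_nh = -(_unit(ce - nz) + _unit(cg_acc - nz))
        u_nh = _unit(u_nh)
        v_co = _unit(od1 - cg_acc)  # C=O direction, prolonged

        variants_oe1: list[tuple[str, np.ndarray, float]] = []
        variants_oe2: list[tuple[str, np.ndarray, float]] = []
        n_conf = max(1, min(glu_conformers, 2))
        for conf, alt in zip(range(n_conf), "AB"):
            # conformer B: carboxyl rotated, oxygens swapped in role but
            # still at hydrogen-bond distance of both amide groups
            d_nh = 3.0 + 0.15 * conf
            d_co = 2.85 + 0.15 * conf
            oe1 = nz + d_nh * u_nh
            oe2 = od1 + d_co * v_co
            if conf == 1:
                oe1, oe2 = oe2, oe1
            occ = 1.0 / n_conf
            variants_oe1.append((alt if n_conf > 1 else "", oe1, occ))
            variants_oe2.append((alt if n_conf > 1 else "", oe2, occ))

        mid = 0.5 * (variants_oe1[0][1] + variants_oe2[0][1])
        away = _unit(mid - 0.5 * (nz + cg_acc))
        cd_g = mid + 0.8 * away
        cg_g = cd_g + 1.52 * away
        cb_g = cg_g + 1.52 * _unit(away + np.array([0.0, 0.0, 0.9]))
        ca_g = cb_g + 1.53 * _unit(away + np.array([0.0, 0.0, -0.9]))
        glu = _residue(
            "A", 8, "GLU",
            {"N": ca_g + np.array([-1.2, 0.8, 0.0]), "CA": ca_g, "C": ca_g + np.array([1.2, 0.8, 0.0]),
             "CB": cb_g, "CG": cg_g, "CD": cd_g},
            altloc_atoms={"OE1": variants_oe1, "OE2": variants_oe2},
        )
        residues.append(glu)
        catalytic_truth = "A:8"

    # --- filler strands so the file looks like a small two-strand domain ----
    strand_dir = _unit(np.cross(cg_acc - ca_l, np.array([0.0, 0.0, 1.0])))
    residues += _filler_strand("A", [1, 2, 3, 4], ca_l - 5 * 3.8 * strand_dir, strand_dir, rng)
    residues += _filler_strand("A", [6, 7], ca_l, strand_dir, rng)
    residues += _filler_strand("A", [11, 12, 13, 14], ca_a - 5 * 3.8 * strand_dir, strand_dir, rng)
    residues += _filler_strand("A", [16, 17, 18, 19, 20], ca_a, strand_dir, rng)
    residues.sort(key=lambda r: r.number)

    structure = Structure(id=f"isopep-fixture-{seed}", models=[{"A": residues}])
    truth = {
        "kind": "isopeptide_structure",
        "seed": seed,
        "donor": "A:5",
        "acceptor": "A:15",
        "bond_length": bond_length,
        "omega": omega_deg,
        "catalytic": catalytic_truth,
        "glu_conformers": glu_conformers if with_glu else 0,
    }
    return structure, truth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_decoy_fixture(seed: int = 0, min_separation: float = 6.0) -> tuple[Structure, dict]:
    """A structure with Lys and Asn present but no bond (NZ–CG well apart)."""
    rng = np.random.default_rng(seed)
    separation = float(min_separation + 2.0 + 4.0 * rng.random())
    structure, truth = make_isopeptide_fixture(
        bond_length=separation, omega_deg=float(rng.uniform(-180, 180)),
        with_glu=False, seed=seed,
    )
    structure.id = f"decoy-fixture-{seed}"
    truth.update(kind="decoy_structure", bonds_expected=0, nz_cg_distance=separation)
    return structure, truth


# ---------------------------------------------------------------------------
# Template/target pair for grafting
# ---------------------------------------------------------------------------

#: (template number, template residue) → (target number, target residue)
_GRAFT_MAP = [
    (34, "ALA", 11, "ALA"), (35, "ALA", 12, "ALA"), (36, "LYS", 13, "ASN"),
    (37, "ALA", 14, "ALA"), (38, "LEU", 15, "LEU"),
    (52, "PHE", 24, "PHE"), (53, "ALA", 25, "ALA"), (54, "PHE", 26, "VAL"),
    (55, "ALA", 27, "ALA"), (56, "ALA", 28, "ALA"),
    (115, "ALA", 65, "ALA"), (116, "ALA", 66, "ALA"), (117, "GLU", 67, "GLN"),
    (118, "ALA", 68, "ALA"), (119, "ALA", 69, "ALA"),
    (164, "ALA", 113, "ALA"), (165, "ALA", 114, "ALA"), (166, "PHE", 115, "PHE"),
    (167, "ALA", 116, "ALA"), (168, "ASN", 117, "PRO"),
]


def make_graft_fixture_pair(
    seed: int = 0,
) -> tuple[Structure, Structure, Correspondence, dict[str, Any]]:
    """A template/target domain pair for triad mapping and cavity auditing.

    The template carries an isopeptide triad (Lys-36, Glu-117, Asn-168)
    with the lysine's aliphatic stem sandwiched between two Phe side
    chains (54 and 166) at van der Waals distance.  The target is the same
    Cα scaffold under a random rigid transform, but with the wild-type
    residue complement: Asn-13, Gln-67, Pro-117 at the triad positions and
    the small Val-26 where the template packs Phe-54.  The correct design
    answer — mutations N13K, Q67E, P117N plus steering suggestion V26F —
    is recorded in the ground-truth dict.
    """
    rng = np.random.default_rng(seed)

    # template Lys-36 side chain along +y, cage around its CD
    lys_atoms = {
        "N": np.array([-1.3, -0.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.3, -0.8, 0.0]),
        "CB": np.array([0.0, 1.5, 0.0]),
        "CG": np.array([0.0, 3.0, 0.5]),
        "CD": np.array([0.0, 4.5, 0.0]),
        "CE": np.array([0.0, 6.0, 0.5]),
        "NZ": np.array([0.0, 7.5, 0.0]),
    }
    side_atoms: dict[int, dict[str, np.ndarray]] = {
        36: lys_atoms,
        54: {"CB": np.array([4.2, 4.5, 0.0]), "CG": np.array([4.9, 4.5, 1.2])},
        166: {"CB": np.array([-4.2, 4.5, 0.0]), "CG": np.array([-4.9, 4.5, 1.2])},
        38: {"CB": np.array([0.0, 4.5, 4.3])},
    }
    group_origin = {
        34: np.array([-7.6, 0.0, 0.0]),
        52: np.array([-7.6, 4.5, -6.0]),
        115: np.array([-7.6, 4.5, 6.0]),
        164: np.array([-7.6, 10.5, 2.0]),
    }

    template_res: list[Residue] = []
    target_res: list[Residue] = []
    pairs: list[tuple[str, str]] = []

    # random proper rigid transform for the target frame
    q = rng.normal(size=4)
    R = _quat_to_rot(q / np.linalg.norm(q))
    t = rng.uniform(-20, 20, 3)

    group_start = None
    for templ_num, templ_name, targ_num, targ_name in _GRAFT_MAP:
        if templ_num in group_origin:
            group_start, origin = templ_num, group_origin[templ_num]
        ca = origin + np.array([3.8 * (templ_num - group_start), 0.0, 0.0])
        atoms = {"N": ca + np.array([-1.2, 0.8, 0.0]), "CA": ca, "C": ca + np.array([1.2, 0.8, 0.0])}
        if templ_num == 36:
            atoms = dict(side_atoms[36])  # CA at origin by construction
        elif templ_num in side_atoms:
            atoms.update(side_atoms[templ_num])
        template_res.append(_residue("A", templ_num, templ_name, atoms))

        targ_atoms = {
            name: R @ pos + t for name, pos in atoms.items() if name in ("N", "CA", "C")
        }
        target_res.append(_residue("A", targ_num, targ_name, targ_atoms))
        pairs.append((f"A:{templ_num}", f"A:{targ_num}"))

    template = Structure(id=f"graft-template-{seed}", models=[{"A": template_res}])
    target = Structure(id=f"graft-target-{seed}", models=[{"A": target_res}])
    corr = Correspondence(pairs=pairs)
    truth = {
        "kind": "graft_pair",
        "seed": seed,
        "triad_template": {"lys": "A:36", "glu": "A:117", "asn": "A:168"},
        "expected_mutations": ["N13K", "Q67E", "P117N"],
        "expected_steering": "V26F",
        "cavity_position": "A:26",
    }
    return template, target, corr, truth


def _quat_to_rot(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def make_spectrum_fixture(
    xp: CrosslinkedPeptide,
    n_decoys: int = 20,
    noise_ppm: float = 0.0,
    seed: int = 0,
    charges: tuple[int, ...] = (1, 2),
) -> tuple[PeakList, dict[str, Any]]:
    """A peak list containing every theoretical fragment of ``xp`` plus decoys.

    Planted peaks are jittered uniformly within ±``noise_ppm``; decoy peaks
    are drawn uniformly over the observed m/z range but kept at least
    100 ppm away from every theoretical ion so the planted set remains the
    unique correct answer at any tolerance ≤ 50 ppm.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    ions = theoretical_fragments(xp, charges=charges)
    true_mz = np.array(sorted({i.mz for i in ions}))

    peaks: list[tuple[float, float]] = []
    planted = []
    for ion in ions:
        shift = rng.uniform(-noise_ppm, noise_ppm) * 1e-6
        mz = ion.mz * (1.0 + shift)
        peaks.append((mz, float(rng.uniform(50, 100))))
        planted.append({"label": ion.label, "mz_true": ion.mz, "mz_observed": mz})

    lo, hi = 100.0, float(true_mz.max() + 200.0)
    added = 0
    while added < n_decoys:
        mz = float(rng.uniform(lo, hi))
        if np.min(np.abs(true_mz - mz)) / mz > 100e-6:
            peaks.append((mz, float(rng.uniform(1, 50))))
            added += 1

    truth = {
        "kind": "spectrum",
        "seed": seed,
        "n_planted": len(ions),
        "n_decoys": n_decoys,
        "noise_ppm": noise_ppm,
        "planted": planted,
    }
    return PeakList(peaks=peaks), truth


def write_sidecar(truth: dict, path: str | Path) -> None:
    """Write a fixture's ground-truth record next to it as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
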