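"""Macromolecular coordinate model, superposition and distance primitives.

Coordinates are read through gemmi (PDB and mmCIF dialects) into a small
hierarchy of plain dataclasses — :class:`Structure` → chains → :class:`Residue`
→ :class:`Atom` — that preserves author chain IDs, author residue numbering,
insertion codes, alternate locations and occupancies exactly as deposited.
All geometric operations in the package (bond detection, contact shells,
triad grafting) are built on the primitives here:

* :func:`superpose` — closed-form least-squares rigid-body fit (Kabsch SVD,
  reflections rejected),
* :func:`ca_superpose` — Cα superposition over an explicit residue
  correspondence,
* :func:`min_distance` — minimum pairwise distance between two atom
  selections.

Residue positions everywhere use author numbering (``Lys-13`` means the
residue numbered 13 in the file); mutation strings are 1-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("isopepgraft")

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Correspondence",
    "SuperpositionResult",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_pdb",
    "superpose",
    "ca_superpose",
    "min_distance",
    "select_atoms",
    "parse_selector",
    "dihedral",
    "angle",
]


class StructureError(ValueError):
    """Raised for unreadable files, bad selections or degenerate geometry."""


class SelectionError(StructureError):
    """An atom selector matched nothing; the message names the selector."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom site.

    ``altloc`` is a single character, or ``""`` for an unambiguous site.
    ``position`` is a length-3 float array in Å.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue with author numbering and its ordered atoms."""

    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> str:
        """Residue identifier string, e.g. ``"A:13"`` or ``"A:52A"``."""
        return f"{self.chain_id}:{self.number}{self.icode}"

    def atom(self, name: str, altloc: str | None = None) -> Atom | None:
        """Return the named atom.

        With ``altloc=None`` the highest-occupancy conformer is returned
        (ties broken by altloc character); pass an explicit altloc to
        override, or ``""`` to require the unlabelled site.
        """
        candidates = [a for a in self.atoms if a.name == name]
        if altloc is not None:
            candidates = [a for a in candidates if a.altloc == altloc]
        if not candidates:
            return None
        return max(candidates, key=lambda a: (a.occupancy, -ord(a.altloc or "~")))

    def altlocs(self) -> list[str]:
        """Sorted distinct non-blank altloc characters present in the residue."""
        return sorted({a.altloc for a in self.atoms if a.altloc})

    def heavy_atoms(self, altloc: str | None = None) -> list[Atom]:
        """Non-hydrogen atoms, one site per atom name.

        Default altloc policy: highest occupancy per name; an explicit
        ``altloc`` keeps only that conformer plus unlabelled sites.
        """
        out: list[Atom] = []
        for name in dict.fromkeys(a.name for a in self.atoms):
            a = self.atom(name, None)
            if altloc is not None:
                specific = [x for x in self.atoms if x.name == name and x.altloc in ("", altloc)]
                a = max(specific, key=lambda x: x.occupancy) if specific else None
            if a is not None and not a.is_hydrogen:
                out.append(a)
        return out


@dataclass
class Structure:
    """A coordinate set: ordered models, each a list of chains of residues.

    ``models`` maps model name → {chain_id → [Residue, ...]}.  Most
    operations act on the first model.
    """

    id: str
    models: list[dict[str, list[Residue]]] = field(default_factory=list)

    @property
    def first_model(self) -> dict[str, list[Residue]]:
        if not self.models:
            raise StructureError(f"structure {self.id!r} has no models")
        return self.models[0]

    def chains(self) -> list[str]:
        return list(self.first_model)

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        for cid, residues in self.first_model.items():
            if chain_id is None or cid == chain_id:
                yield from residues

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for res in self.first_model.get(chain_id, []):
            if res.number == number and res.icode == icode:
                return res
        return None

    def n_atoms(self, heavy_only: bool = False) -> int:
        return sum(
            1
            for res in self.residues()
            for a in res.atoms
            if not (heavy_only and a.is_hydrogen)
        )


@dataclass
class Correspondence:
    """Ordered residue pairing between a template and a target structure.

    Each pair is ``(template_residue_id, target_residue_id)`` in the
    ``chain:number[icode]`` form.  No residue may appear twice on either side.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise StructureError("correspondence lists a residue twice")

    def target_for(self, template_id: str) -> str | None:
        for t, g in self.pairs:
            if t == template_id:
                return g
        return None

    @classmethod
    def identity(cls, structure: Structure, chain_id: str | None = None) -> "Correspondence":
        ids = [r.id for r in structure.residues(chain_id)]
        return cls(pairs=[(i, i) for i in ids])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Correspondence":
        """Read a two-column TSV of ``template_id<TAB>target_id`` pairs.

        Blank lines and ``#`` comments are skipped.
        """
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace("\t", " ").split()
            if len(fields) != 2:
                raise StructureError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
        return cls(pairs=pairs)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "# template_id\ttarget_id\n"
            + "".join(f"{t}\t{g}\n" for t, g in self.pairs)
        )


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference, plus fit rmsd."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_pairs: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Reading and writing coordinates
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM sites are kept, including waters and alternate
    locations; author chain IDs and residue numbers are preserved.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise StructureError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    structure = Structure(id=st.name or path.stem)
    for model in st:
        chains: dict[str, list[Residue]] = {}
        for chain in model:
            for res in chain:
                residue = Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                )
                for a in res:
                    residue.atoms.append(
                        Atom(
                            name=a.name,
                            element=a.element.name,
                            position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            occupancy=a.occ,
                            altloc=a.altloc.strip("\0") if a.altloc != "\0" else "",
                            b_factor=a.b_iso,
                        )
                    )
                chains.setdefault(chain.name, []).append(residue)
        if chains:
            structure.models.append(chains)
    if not structure.models:
        raise StructureError(f"{path}: no models with atoms")
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    for i, model in enumerate(structure.models, 1):
        gm = gemmi.Model(str(i))
        for chain_id, residues in model.items():
            gc = gemmi.Chain(chain_id)
            for res in residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
                gr.het_flag = "A"
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.position)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    ga.altloc = a.altloc or "\0"
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure in fixed-column PDB format (used for fixtures)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    st = _to_gemmi(structure)
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def superpose(mobile: Sequence, reference: Sequence) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Closed-form Kabsch solution via SVD of the covariance matrix; the
    rotation is forced proper (det +1), so reflections are never returned.
    Requires ≥3 non-collinear point pairs.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise StructureError(
            f"point sets must be equal-length Nx3 arrays, got {X.shape} and {Y.shape}"
        )
    n = X.shape[0]
    if n < 3:
        raise StructureError(f"need at least 3 point pairs, got {n}")

    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc

    # Collinearity check: rank of the centred mobile set must be >= 2.
    sv = np.linalg.svd(X0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise StructureError("degenerate (collinear) point set; superposition ill-conditioned")

    H = X0.T @ Y0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((X0 @ R.T - Y0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def ca_superpose(
    template: Structure, target: Structure, correspondence: Correspondence
) -> SuperpositionResult:
    """Superpose template Cα atoms onto target Cα atoms over a correspondence.

    The transform maps template coordinates into the target frame.  Any
    pair lacking a CA atom raises, naming the offending residue.
    """
    mobile, reference = [], []
    for templ_id, targ_id in correspondence.pairs:
        rt = _residue_by_id(template, templ_id)
        rg = _residue_by_id(target, targ_id)
        for res, sid, which in ((rt, templ_id, "template"), (rg, targ_id, "target")):
            if res is None:
                raise StructureError(f"{which} residue {sid} not found")
        ca_t, ca_g = rt.atom("CA"), rg.atom("CA")
        if ca_t is None:
            raise StructureError(f"template residue {templ_id} has no CA atom")
        if ca_g is None:
            raise StructureError(f"target residue {targ_id} has no CA atom")
        mobile.append(ca_t.position)
        reference.append(ca_g.position)
    return superpose(mobile, reference)


def _residue_by_id(structure: Structure, res_id: str) -> Residue | None:
    chain_id, _, rest = res_id.partition(":")
    num = ""
    icode = ""
    for ch in rest:
        if ch.isdigit() or (ch == "-" and not num):
            num += ch
        else:
            icode += ch
    if not num:
        raise StructureError(f"bad residue id {res_id!r}; expected chain:number[icode]")
    return structure.residue(chain_id, int(num), icode.strip())


# ---------------------------------------------------------------------------
# Selections and distances
# ---------------------------------------------------------------------------

Selector = Callable[[Residue, Atom], bool]


def parse_selector(spec: str) -> Selector:
    """Parse a ``chain:resnum[icode]:atomname`` selector string.

    The atom field may be ``*`` (all atoms), a single name, or a
    comma-separated list; omitting it selects the whole residue.  The chain
    field may be ``*`` for any chain.
    """
    parts = spec.split(":")
    if len(parts) not in (2, 3):
        raise SelectionError(f"bad selector {spec!r}; expected chain:resnum[:atomname]")
    chain, resfield = parts[0], parts[1]
    atom_field = parts[2] if len(parts) == 3 else "*"
    num = ""
    icode = ""
    for ch in resfield:
        if ch.isdigit() or (ch == "-" and not num):
            num += ch
        else:
            icode += ch
    if not num:
        raise SelectionError(f"bad residue number in selector {spec!r}")
    number = int(num)
    names = None if atom_field == "*" else {n.strip() for n in atom_field.split(",")}

    def pred(res: Residue, atom: Atom) -> bool:
        if chain != "*" and res.chain_id != chain:
            return False
        if res.number != number or res.icode != (icode.strip()):
            return False
        return names is None or atom.name in names

    return pred


def select_atoms(
    structure: Structure,
    selector: str | Selector,
    include_hydrogens: bool = False,
    altloc: str | None = None,
) -> list[tuple[Residue, Atom]]:
    """All (residue, atom) pairs matched by a selector.

    Alternate locations follow the highest-occupancy default unless an
    explicit ``altloc`` is given.  Hydrogens are excluded by default.
    """
    label = selector if isinstance(selector, str) else getattr(selector, "__name__", "<callable>")
    pred = parse_selector(selector) if isinstance(selector, str) else selector
    out = []
    for res in structure.residues():
        pool = res.heavy_atoms(altloc=altloc)
        if include_hydrogens:
            names = {a.name for a in pool}
            pool = pool + [a for a in res.atoms if a.is_hydrogen and a.name not in names]
        for atom in pool:
            if pred(res, atom):
                out.append((res, atom))
    if not out:
        raise SelectionError(f"selector {label!r} matched no atoms")
    return out


def min_distance(
    structure: Structure,
    atom_sel_a: str | Selector,
    atom_sel_b: str | Selector,
    include_hydrogens: bool = False,
    altloc: str | None = None,
) -> float:
    """Minimum pairwise Euclidean distance (Å) between two selections."""
    A = select_atoms(structure, atom_sel_a, include_hydrogens, altloc)
    B = select_atoms(structure, atom_sel_b, include_hydrogens, altloc)
    pa = np.array([a.position for _, a in A])
    pb = np.array([b.position for _, b in B])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------

def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang
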