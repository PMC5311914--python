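"""Mass-spectrometric verification of isopeptide bond formation.

Bond formation between a Lys ε-amine and an Asn carboxamide (or Asp
carboxylate) expels one ammonia, so the intact protein loses 17 Da
(monoisotopic 17.02655).  Verification therefore proceeds on two levels:

* **intact mass** — the bonded species is exactly one NH3 lighter than the
  unbonded calculated mass (:func:`isopeptide_mass_delta`);
* **bottom-up MS/MS** — a tryptic digest of the crosslinked protein yields
  a *branched* peptide: the Lys-site peptide and the Asn-site peptide
  joined through the side-chain amide.  :func:`crosslinked_candidates`
  enumerates these pairs (the bonded Lys is cleavage-blocked — its
  modified ε-amine no longer satisfies trypsin), and
  :func:`theoretical_fragments` generates b/y ions in which any fragment
  retaining the link site carries the intact partner chain (−NH3) as a
  fixed modification.  :func:`match_spectrum` then scores an observed
  peak list at ppm tolerance.

Residue and molecule masses come from pyteomics; monoisotopic masses are
used for fragment matching, average masses for intact-protein comparison
(ESI-TOF deconvolution of a ~14 kDa protein reports average-like masses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mass as _pmass

logger = logging.getLogger("isopepgraft")

__all__ = [
    "ProteinSequence",
    "Peptide",
    "CrosslinkedPeptide",
    "FragmentIon",
    "PeakList",
    "MatchResult",
    "SequenceError",
    "peptide_mass",
    "isopeptide_mass_delta",
    "digest",
    "crosslinked_candidates",
    "theoretical_fragments",
    "match_spectrum",
    "read_fasta",
    "read_peak_list",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

PROTON_MASS = 1.007276466879
WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
NH3_MONO = _pmass.calculate_mass(formula="NH3")
NH3_AVG = _pmass.calculate_mass(formula="NH3", average=True)


class SequenceError(ValueError):
    """Invalid sequence alphabet, link site or digestion parameter."""


@dataclass
class ProteinSequence:
    """A protein as a 1-letter string restricted to the 20 canonical residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        for i, aa in enumerate(self.residues, 1):
            if aa not in AMINO_ACIDS:
                raise SequenceError(f"{self.id}: invalid residue {aa!r} at position {i}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Peptide:
    """A proteolytic peptide: parent slice [start..end], 1-based inclusive."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def contains(self, parent_pos: int) -> bool:
        return self.start <= parent_pos <= self.end


@dataclass
class CrosslinkedPeptide:
    """Two tryptic peptides joined by the isopeptide (or one loop-linked).

    ``beta is None`` marks the loop-linked case where both link sites fall
    in a single tryptic peptide.  ``link_alpha_pos`` / ``link_beta_pos``
    are 1-based within each chain; for a loop link both index into alpha.
    """

    alpha: Peptide
    beta: Peptide | None
    link_alpha_pos: int
    link_beta_pos: int
    neutral_mass: float

    @property
    def is_loop(self) -> bool:
        return self.beta is None


@dataclass
class FragmentIon:
    chain: str  # "alpha" | "beta"
    series: str  # "b" | "y"
    index: int
    includes_link: bool
    charge: int
    mz: float

    @property
    def label(self) -> str:
        star = "*" if self.includes_link else ""
        return f"{self.chain[0]}.{self.series}{self.index}{star}({self.charge}+)"


@dataclass
class PeakList:
    """An m/z–intensity list, normalised to ascending m/z."""

    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz, _ in self.peaks):
            raise SequenceError("peak list contains non-positive m/z")
        if any(inten < 0 for _, inten in self.peaks):
            raise SequenceError("peak list contains negative intensity")
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class MatchResult:
    matched: list[tuple[FragmentIon, tuple[float, float], float]]  # (ion, peak, ppm error)
    n_theoretical: int
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        self.coverage = len(self.matched) / self.n_theoretical if self.n_theoretical else 0.0


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------

def peptide_mass(sequence: str, kind: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da: residue masses plus one water."""
    if not sequence:
        raise SequenceError("empty sequence has no mass")
    for i, aa in enumerate(sequence.upper(), 1):
        if aa not in AMINO_ACIDS:
            raise SequenceError(f"invalid residue {aa!r} at position {i}")
    if kind not in ("monoisotopic", "average"):
        raise SequenceError(f"kind must be monoisotopic or average, got {kind!r}")
    return float(_pmass.calculate_mass(sequence=sequence.upper(), average=(kind == "average")))


def isopeptide_mass_delta(kind: str = "monoisotopic") -> float:
    """Mass change on isopeptide bond formation: −NH3 (≈ −17 Da)."""
    if kind == "monoisotopic":
        return -NH3_MONO
    if kind == "average":
        return -NH3_AVG
    raise SequenceError(f"kind must be monoisotopic or average, got {kind!r}")


def _residue_mass(aa: str) -> float:
    return float(_pmass.std_aa_mass[aa])


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------

def digest(
    sequence: ProteinSequence | str,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    blocked_sites: set[int] | frozenset[int] = frozenset(),
) -> list[Peptide]:
    """Tryptic in-silico digest with blockable cleavage sites.

    Classic trypsin rule: cleave after K or R except when the next residue
    is P.  ``blocked_sites`` are 1-based positions of K/R residues whose
    C-terminal bond must never be cut — an isopeptide-bonded lysine, with
    its derivatised ε-amine, is not a trypsin substrate.  Peptides with
    0..``max_missed`` missed cleavages are emitted in order of start
    position; the 0-missed set tiles the sequence exactly.
    """
    if isinstance(sequence, ProteinSequence):
        seq = sequence.residues
    else:
        seq = ProteinSequence("<anon>", sequence).residues
    if enzyme != "trypsin":
        raise SequenceError(f"unsupported enzyme {enzyme!r}")
    if max_missed < 0:
        raise SequenceError("max_missed must be >= 0")
    for pos in blocked_sites:
        if not 1 <= pos <= len(seq) or seq[pos - 1] not in "KR":
            raise SequenceError(f"blocked site {pos} is not a K/R position")

    # cleavage sites: cut between pos and pos+1 (1-based pos)
    sites = [
        pos
        for pos in range(1, len(seq))
        if seq[pos - 1] in "KR" and seq[pos] != "P" and pos not in blocked_sites
    ]
    bounds = [0] + sites + [len(seq)]  # segment boundaries, 0-based exclusive cuts

    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            peptides.append(
                Peptide(
                    sequence=seq[start - 1 : end],
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


# ---------------------------------------------------------------------------
# Crosslinked (branched) peptides
# ---------------------------------------------------------------------------

def crosslinked_candidates(
    sequence: ProteinSequence | str,
    lys_pos: int,
    asn_pos: int,
    max_missed: int = 2,
    kind: str = "monoisotopic",
) -> list[CrosslinkedPeptide]:
    """Enumerate branched tryptic peptides for a Lys↔Asn/Asp crosslink.

    The digest treats ``lys_pos`` as cleavage-blocked.  Every
    (alpha ∋ Lys, beta ∋ Asn) pair of non-overlapping peptides becomes a
    candidate with neutral mass m(alpha) + m(beta) − NH3; a peptide
    containing both sites becomes a loop-linked candidate with mass
    m(peptide) − NH3.
    """
    if isinstance(sequence, str):
        sequence = ProteinSequence("<anon>", sequence)
    seq = sequence.residues
    if not 1 <= lys_pos <= len(seq) or seq[lys_pos - 1] != "K":
        raise SequenceError(f"position {lys_pos} is not K")
    if not 1 <= asn_pos <= len(seq) or seq[asn_pos - 1] not in "ND":
        raise SequenceError(f"position {asn_pos} is not N or D")

    delta = isopeptide_mass_delta(kind)
    peptides = digest(sequence, max_missed=max_missed, blocked_sites={lys_pos})
    alphas = [p for p in peptides if p.contains(lys_pos)]
    betas = [p for p in peptides if p.contains(asn_pos)]

    out: list[CrosslinkedPeptide] = []
    seen: set[tuple] = set()
    for a in alphas:
        if a.contains(asn_pos):
            key = (a.start, a.end, None)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CrosslinkedPeptide(
                    alpha=a,
                    beta=None,
                    link_alpha_pos=lys_pos - a.start + 1,
                    link_beta_pos=asn_pos - a.start + 1,
                    neutral_mass=peptide_mass(a.sequence, kind) + delta,
                )
            )
            continue
        for b in betas:
            if b.contains(lys_pos) or not (a.end < b.start or b.end < a.start):
                continue  # overlapping pair: impossible digestion product
            key = (a.start, a.end, b.start, b.end)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CrosslinkedPeptide(
                    alpha=a,
                    beta=b,
                    link_alpha_pos=lys_pos - a.start + 1,
                    link_beta_pos=asn_pos - b.start + 1,
                    neutral_mass=peptide_mass(a.sequence, kind)
                    + peptide_mass(b.sequence, kind)
                    + delta,
                )
            )
    out.sort(key=lambda x: (x.alpha.start, x.alpha.end, x.beta.start if x.beta else -1))
    return out


# ---------------------------------------------------------------------------
# Theoretical fragment ions
# ---------------------------------------------------------------------------

def theoretical_fragments(
    xp: CrosslinkedPeptide,
    series: tuple[str, ...] = ("b", "y"),
    charges: tuple[int, ...] = (1, 2),
) -> list[FragmentIon]:
    """b/y fragment ions of a branched peptide.

    The isopeptide bond itself is assumed not to fragment under CID, so a
    fragment retaining the link residue carries the whole partner chain
    (−NH3) as a fixed modification; for a loop-linked peptide, backbone
    cleavages between the two linked residues yield no separable fragments
    and are skipped.  Neutral masses: b = Σresidues, y = Σresidues + H2O;
    m/z = (neutral + z·m_proton)/z.
    """
    bad = set(series) - {"b", "y"}
    if bad:
        raise SequenceError(f"unsupported ion series {sorted(bad)}")
    if any(z < 1 for z in charges):
        raise SequenceError("charges must be >= 1")

    ions: list[FragmentIon] = []
    if xp.is_loop:
        lo, hi = sorted((xp.link_alpha_pos, xp.link_beta_pos))
        ring_extra = -NH3_MONO  # the ring closure still lost one ammonia
        ions.extend(
            _chain_fragments(
                xp.alpha.sequence, "alpha", (lo, hi), ring_extra, series, charges,
                skip_between=(lo, hi),
            )
        )
        return ions

    alpha_mass = peptide_mass(xp.alpha.sequence)
    beta_mass = peptide_mass(xp.beta.sequence)
    ions.extend(
        _chain_fragments(
            xp.alpha.sequence, "alpha", (xp.link_alpha_pos,), beta_mass - NH3_MONO, series, charges
        )
    )
    ions.extend(
        _chain_fragments(
            xp.beta.sequence, "beta", (xp.link_beta_pos,), alpha_mass - NH3_MONO, series, charges
        )
    )
    return ions


def _chain_fragments(
    seq: str,
    chain: str,
    link_positions: tuple[int, ...],
    partner_mass: float,
    series: tuple[str, ...],
    charges: tuple[int, ...],
    skip_between: tuple[int, int] | None = None,
) -> list[FragmentIon]:
    n = len(seq)
    prefix = [0.0]
    for aa in seq:
        prefix.append(prefix[-1] + _residue_mass(aa))
    total = prefix[-1]

    ions = []
    for i in range(1, n):  # cleavage between residue i and i+1
        if skip_between is not None and skip_between[0] <= i < skip_between[1]:
            continue
        for s in series:
            if s == "b":
                neutral = prefix[i]
                covered = range(1, i + 1)
                idx = i
            else:
                neutral = total - prefix[i] + WATER_MONO
                covered = range(i + 1, n + 1)
                idx = n - i
            includes_link = all(p in covered for p in link_positions)
            if includes_link:
                neutral += partner_mass
            for z in charges:
                ions.append(
                    FragmentIon(
                        chain=chain,
                        series=s,
                        index=idx,
                        includes_link=includes_link,
                        charge=z,
                        mz=(neutral + z * PROTON_MASS) / z,
                    )
                )
    return ions


# ---------------------------------------------------------------------------
# Spectrum matching
# ---------------------------------------------------------------------------

def match_spectrum(
    ions: list[FragmentIon], peaks: PeakList, tol_ppm: float = 20.0
) -> MatchResult:
    """Greedy nearest-peak assignment of theoretical ions at ppm tolerance.

    Ions are processed in ascending m/z; each matches the nearest unused
    peak within ``tol_ppm``.  Coverage is matched / theoretical.  An empty
    peak list is a valid input (coverage 0).
    """
    if tol_ppm <= 0:
        raise SequenceError("tol_ppm must be positive")
    used: set[int] = set()
    matched = []
    for ion in sorted(ions, key=lambda i: i.mz):
        tol = ion.mz * tol_ppm * 1e-6
        best_j, best_err = None, tol
        for j, (mz, _) in enumerate(peaks.peaks):
            if j in used:
                continue
            err = abs(mz - ion.mz)
            if err <= best_err:
                best_j, best_err = j, err
            if mz - ion.mz > tol:
                break
        if best_j is not None:
            used.add(best_j)
            peak = peaks.peaks[best_j]
            matched.append((ion, peak, (peak[0] - ion.mz) / ion.mz * 1e6))
    return MatchResult(matched=matched, n_theoretical=len(ions))


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def read_peak_list(path: str | Path) -> PeakList:
    """Read a peak list: two-column text (m/z, intensity) or mzML.

    mzML files (by extension) are read through pyteomics and the peaks of
    all spectra are pooled; anything else is parsed as whitespace- or
    comma-delimited text, one peak per line, '#' comments allowed.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        try:
            from pyteomics import mzml
        except ImportError as exc:  # pragma: no cover
            raise SequenceError("mzML input requires the pyteomics mzML reader") from exc
        peaks = []
        with mzml.read(str(path)) as reader:
            for spectrum in reader:
                peaks.extend(zip(spectrum["m/z array"], spectrum["intensity array"]))
        return PeakList(peaks=[(float(mz), float(i)) for mz, i in peaks])

    peaks = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace(",", " ").split()
        if len(fields) < 1:
            continue
        try:
            mz = float(fields[0])
            inten = float(fields[1]) if len(fields) > 1 else 1.0
        except ValueError as exc:
            raise SequenceError(f"{path}:{lineno}: cannot parse peak line {line!r}") from exc
        peaks.append((mz, inten))
    return PeakList(peaks=peaks)
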