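# Methods

This note documents the models, conventions and numerical choices behind
`isopepgraft`, and what its synthetic fixtures do and do not emulate.

## Coordinate model and superposition

Coordinates are parsed with gemmi and held in a small dataclass hierarchy.
Residue identity is **author numbering exactly as deposited** (`chain:number[icode]`);
nothing is renumbered, because the literature on these crosslinks names
residues by author numbers (Lys-13, Glu-67, …). Mutation strings are 1-based
`wt-position-new` one-letter notation (N13K).

Alternate locations: the default policy takes the highest-occupancy conformer
per atom name (ties broken by altloc character); every geometric operation
accepts an explicit altloc override. This matters for catalytic Glu residues,
which can adopt two discrete carboxyl conformations. Hydrogens, when present,
are excluded from distance and contact calculations by default (typical
2 Å crystal structures have none); a flag re-includes them.

Rigid-body superposition is the closed-form least-squares fit (Kabsch, via
SVD of the 3×3 covariance matrix). Reflections are rejected by forcing
det(R) = +1. Inputs need ≥ 3 point pairs and are checked for collinearity
(second singular value of the centred set ≥ 1e−8 of the first). The test
suite cross-checks this implementation against an algebraically independent
oracle (Horn's quaternion eigen-method) to 1e−9 Å.

## Isopeptide bond detection

A bond is any same-chain Lys NZ – Asn/Asp CG pair within
`max_bond_length = 2.0 Å`. The ideal amide C–N bond is ≈ 1.33 Å; the extra
slack absorbs refinement error in real structures. Detection is
threshold-monotone by construction.

Configuration uses the amide dihedral **CE–NZ–CG–CB** (the literature states
cis/trans without fixing a convention; this is the natural choice of the
four heavy atoms flanking the new amide): |ω| ≤ 30° → *cis*,
|ω| ≥ 150° → *trans*, otherwise *distorted*. The classification is symmetric
in the sign of ω.

Catalytic partner: for every Glu/Asp (each alternate conformer scored
separately), two hydrogen-free criteria are applied —

* carboxyl O as acceptor of the isopeptide N–H: NZ⋯O ≤ 3.5 Å **and**
  CE–NZ–O angle ≥ 90°;
* carboxyl O(H) against the isopeptide C=O: plain O⋯O ≤ 3.5 Å (the acid may
  be the donor, so no angle condition is imposed at the carbonyl).

The acidic residue with the most such bonds wins; ties break on shortest
mean distance; "no partner" is a valid result, not an error. Candidate
residues missing NZ/CG are skipped with a logged warning rather than
aborting a whole-structure scan.

## Triad grafting and the hydrophobic cage

The mapping from template to target requires an **explicit residue
correspondence** (TSV). Whole-fold structure alignment is deliberately out
of scope: baking in one alignment heuristic would hide the main scientific
judgement call. Triad positions absent from the correspondence are assigned
to the nearest target Cα within 3.5 Å after superposition — a convenience
fallback, not an alignment algorithm.

Mutations are emitted only where needed: a target position already holding
Lys (for the lysine slot), Glu/Asp (catalytic slot) or Asn/Asp (acceptor
slot) contributes none, so a plan carries at most three triad mutations.

The cavity audit reflects the empirical requirement that the flexible lysine
side chain be *steered* into the acceptor by tight apolar packing (which
also lowers the ε-amine pKa). Every template residue contacting the template
lysine side chain (shell radius 4.5 Å, heavy atoms) is compared with its
target counterpart by **standard mean side-chain volume** (Zamyatnin's mean
residue volumes minus Gly, embedded as constants). A deficit ≥ 40 Å³ flags
the position and suggests mutating the target to the template's residue
type. The threshold is chosen so Phe-vs-Val (≈ 50 Å³) flags while
Leu-vs-Ile (≈ 0 Å³) does not. The hydrophobic residue set for shell
statistics is {A,V,L,I,M,F,W,P,G} — Gly and Pro included because both occur
routinely in apolar contact shells; configurable.

No rotamer modelling, repacking or ΔΔG estimation is attempted; a flag is a
pointer for the designer, not an energy claim.

## Mass-spectrometric verification

Residue and molecule masses come from pyteomics. Monoisotopic masses drive
MS/MS matching; average masses serve intact-protein comparisons (ESI-TOF
deconvolution of a ~14 kDa protein reports average-like masses). Bond
formation loses one NH₃: −17.02655 Da monoisotopic, ≈ −17.031 average —
the "17 Da lighter than calculated" intact-mass signature.

Digestion is classic trypsin (cleave after K/R, never before P), missed
cleavages ≤ 2 by default. The isopeptide-bonded lysine is treated as
**cleavage-blocked**: its derivatised ε-amine no longer presents the side
chain trypsin recognises. Candidate branched peptides are all
non-overlapping (Lys-peptide, Asn-peptide) pairs, plus the loop-linked case
when both sites fall in one peptide (mass = single peptide − NH₃; one water
lighter than the corresponding two-chain form).

Fragmentation model: the isopeptide bond is assumed not to break under CID,
so any b/y fragment retaining the link residue carries the intact partner
chain (−NH₃) as a fixed modification; in loop-linked peptides, backbone
cleavages between the two linked residues produce no separable fragments and
are skipped. m/z = (neutral + z·1.007276)/z for z ∈ {1, 2}.

Peak matching is greedy nearest-match in ascending m/z at a ppm tolerance
(default 20 ppm), each peak used at most once; coverage = matched /
theoretical. Input peak lists are two-column text; mzML is read through
pyteomics when present.

## Melt fitting

The two-state sigmoid S(T) = L + (U−L)/(1+exp((T_m−T)/k)) is fit by
nonlinear least squares (scipy `curve_fit`) with a deterministic
initialisation: L and U from the first/last signal deciles, T_m from the
extremum of the numerical derivative, k = 2 °C; T_m is bounded to the
observed range and k to (0, 100] °C. Falling transitions (CD at 215 nm)
fit with U < L; k stays positive. DSF post-transition aggregation decay is
truncated at the signal extremum before fitting when the tail drops by more
than 5 % of the amplitude (`truncate_max=False` disables this).

Experimental melting temperatures of real wild-type/engineered protein
pairs are wet-lab measurements and are **not** computable from sequence or
structure; the package treats them purely as simulator parameters. The
simulator's default grid (25–95 °C, 1 °C steps) mirrors a standard DSF ramp.
Recovery guarantees demonstrated by the tests: noiseless curves anywhere in
40–90 °C to 0.01 °C; mean over 100 replicates at 2 % amplitude noise within
0.2 °C; a simulated 71/81 °C pair returns ΔT_m = 10.0 °C.

## Synthetic fixtures: what they show and what they don't

Fixture structures are built from ideal internal coordinates (amide C–N
1.33 Å, C–C ≈ 1.52 Å, tetrahedral/planar angles) with the planted features
exact and the surrounding backbone only loosely realistic; no energy
minimisation is performed and packing far from the planted site can be
unphysical. They are reproducible byte-for-byte from (kind, parameters,
seed), and each generator returns a ground-truth record (also written as a
JSON sidecar by the CLI).

Passing on fixtures therefore demonstrates that the *geometric and
arithmetic machinery* is correct — detection thresholds, dihedral
conventions, hydrogen-bond criteria, mass identities, matching logic — under
exactly known ground truth. It does not demonstrate robustness to
crystallographic noise, disorder, missing atoms or sequence errors in real
deposited structures; those paths (altloc handling, skip-with-warning on
missing atoms, configurable cutoffs) exist and are unit-tested, but their
tolerances were chosen from standard stereochemistry, not calibrated on a
corpus. Deposited coordinate files remain optional extras: the CLI consumes
them exactly as it consumes fixtures.

## Problem sizes

The test and acceptance runs use desk-scale inputs chosen to exercise every
code path: ~20-residue fixture structures (≈ 90 atoms), 20-residue
template/target pairs, 14-residue parents for branched-peptide enumeration
(≈ 50 fragment ions per candidate), 71-point melt curves, 100-replicate
Monte-Carlo recovery, 50-decoy detection batches, and 25-instance oracle
comparisons.
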