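# isopepgraft

Tools for engineering **spontaneous intramolecular isopeptide bonds** into
Ig-like protein domains, and for verifying that they formed.

Certain Gram-positive bacterial surface proteins (pilins, adhesins) carry an
autocatalytic crosslink between the ε-amino group of a lysine and the
side-chain carboxamide of an asparagine (or the carboxylate of an aspartate),
with an adjacent Glu/Asp acting as the proton shuttle. The bond forms during
folding with loss of one ammonia (−17 Da), ties the first and last β-strands
of the CnaB-type β-sandwich together, and adds striking thermal and
mechanical stability. Grafting this Lys/Glu/Asn triad into a domain that
lacks it is an attractive alternative to engineered disulfides because the
crosslink is redox-insensitive.

`isopepgraft` covers the complete design-and-verification loop for this kind
of engineering project:

| stage | module | what it does |
|---|---|---|
| design | `isopepgraft.graft` | map a template's triad onto a target via Cα superposition over a residue correspondence; audit the lysine's hydrophobic cage for cavities and suggest steering mutations (the Val→Phe class) |
| structure | `isopepgraft.structure` | PDB/mmCIF I/O (author numbering, altlocs, occupancies), closed-form Kabsch superposition, atom-selection distances |
| validation | `isopepgraft.detect` | geometric detection of Lys NZ–Asn/Asp CG bonds in crystal structures: covalent distance, cis/trans amide dihedral, catalytic Glu/Asp via hydrogen-bond geometry (per alternate conformer) |
| mass spec | `isopepgraft.msverify` | the −17.02655 Da NH₃ signature; crosslink-aware tryptic digestion (the bonded Lys is cleavage-blocked); theoretical b/y ions of branched peptides; ppm-tolerance peak matching |
| stability | `isopepgraft.meltfit` | Boltzmann sigmoid fits of DSF/CD melts, S(T) = L + (U−L)/(1+exp((T_m−T)/k)), for T_m and ΔT_m |
| testing | `isopepgraft.fixtures` | synthetic structures, spectra and melt curves with planted ground truth |

## Worked example

Generate a structure with a planted cis isopeptide and detect it:

```bash
$ isopepgraft --seed 3 fixtures isopeptide_structure --out fix.pdb
$ isopepgraft detect fix.pdb
donor	acceptor	length	omega	configuration	catalytic	n_hbonds
A:5	A:15	1.33	0.0	cis	A:8	4
```

The one detected bond joins Lys-5 NZ to Asn-15 CG at 1.33 Å (the ideal amide
C–N length), the amide dihedral ω = 0° classifies it *cis*, and the
catalytic partner is Glu-8, whose two carboxylate conformers each make two
hydrogen bonds to the isopeptide N–H and C=O (4 in total).

Map a triad from a template domain onto a wild-type target and audit the
lysine cage (fixture pair shown; any PDB/mmCIF pair plus a correspondence
TSV works the same way):

```bash
$ isopepgraft graft --template template.pdb --target target.pdb \
      --corr corr.tsv --triad A:36,A:117,A:168
{
  ...
  "mutations": ["N13K", "Q67E", "P117N"],
  "cavity_flags": [{"target_position": "A:26", "template_residue": "PHE",
                    "target_residue": "VAL", "volume_delta": 49.9,
                    "suggested": "V26F"}],
  "all_mutations": ["N13K", "Q67E", "P117N", "V26F"]
}
```

Three mutations place the reactive Lys, catalytic Glu and acceptor Asn; the
audit finds that where the template packs a Phe against the lysine stem the
target offers only Val (a ~50 Å³ cavity) and suggests the steering mutation
V26F — four mutations in all.

Fit a wild-type / engineered melt pair:

```bash
$ isopepgraft fixtures melt_curve --out wt.csv  --tm 71
$ isopepgraft fixtures melt_curve --out iso.csv --tm 81
$ isopepgraft meltfit wt.csv iso.csv
{ "fits": [{"curve": "wt.csv", "tm": 71.0, ...},
           {"curve": "iso.csv", "tm": 81.0, ...}],
  "delta_tm": 10.0 }
```

A ΔT_m of +10 °C is the stabilisation expected from a successfully formed
crosslink of this type.

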