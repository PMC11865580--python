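# concavekit

Toolkit for analysing and engineering **concave helical binder scaffolds**
against convex protein surfaces — the geometry problem posed by
immunoglobulin-fold immune receptors (TGFβRII, CTLA-4, PD-L1, PD-1, TIGIT,
LAG3), whose binding sites bulge outward and are hard to grip with small
globular miniproteins.

It is aimed at protein designers and structural bioinformaticians who need
to (1) quantify how concave or convex a protein–protein interface is,
(2) screen five-helix scaffolds for a concave binding face, (3) analyse
site-saturation mutagenesis (SSM) deep-sequencing data, and (4) design
degenerate-codon combinatorial libraries for affinity maturation.

## The core computation

**Signed interface convexity.** For a complex with partners *A* and *B*,
per-atom solvent-accessible surface area (Shrake–Rupley, probe 1.4 Å,
deterministic golden-spiral sampling) is computed for each partner in
isolation (*apo*) and in the complex (*holo*). Heavy atoms with
dSASA = SASA_apo − SASA_holo ≥ 0.5 Å² are the interfacial atoms. A sphere
is fitted to their coordinates by RANSAC (minimal samples of 4 points,
exact-sphere solve, inlier threshold 1 Å, up to 10⁵ iterations, final
least-squares refit on the consensus set). The convexity of the patch is

> c = s / r,  with  s = sign[(g_p − g_i) · (c_s − g_i)]

where *r* is the fitted radius, *g_p* the centroid of the partner's heavy
atoms, *g_i* the centroid of the interfacial atoms and *c_s* the fitted
sphere center: **negative = concave** (pocket-like, sphere center on the
solvent side), **positive = convex**. Scaffold screening admits five-helix
bundles under 120 residues whose face helices (H1/H3/H5) span 18–22
residues each and form a concave face.

Around that core: per-position Shannon entropy H = −Σ p·log₂ p and log₂
enrichment matrices from SSM count tables; exhaustive degenerate-codon
search over all 15³ IUPAC triplets with DNA/protein diversity accounting
against a ~10⁷ transformation capacity; Kabsch Cα superposition and
sequence identity for model-vs-crystal comparison; metric-table filtering
(ddG ≤ −40, contact molecular surface ≥ 400, pAE ≤ 10, optional mean
plDDT ≥ 80).

## Worked example

Generate a synthetic ball-in-socket complex (a convex pseudo-atom ball
docked into a concave shell) and profile its interface:

```sh
concavekit --seed 1 make-fixture --kind ball-socket --out bs.pdb
concavekit --seed 1 profile-interface --structure bs.pdb \
    --partner-a A --partner-b B --ransac-iters 20000 --out prof.tsv
```

prints

```
partner_a: convexity +0.1666 1/A (sign +1, radius 6.00 A)
partner_b: convexity -0.0908 1/A (sign -1, radius 11.01 A)
buried polar/apolar: 0.0 / 625.1 A^2
```

The ball (chain A, built on a 6 Å sphere) is recovered as convex with
radius 6.00 Å; the socket (chain B, an 11 Å shell) as concave with radius
11.01 Å — the signs and reciprocal radii a designer would read off before
deciding which partner presents the pocket. Buried area is all apolar
because the fixture uses carbon-like pseudo-atoms.

Screening a generated five-helix bundle:

```sh
concavekit make-fixture --curvature -0.05 --out pdbs/toy.pdb
concavekit screen-scaffolds --pdb-dir pdbs --out screen.tsv
```

```
toy.pdb  5  107  19+19+19+19+19  -0.0643  True  n_helices=True,total_length=True,helix_lengths=True,concave_face=True
```

five helices of 19 residues, 107 total, fitted face convexity −0.064 1/Å,
all admission rules pass.

Other subcommands: `ssm-enrich`, `ssm-entropy` (count tables → enrichment
matrix / conservation profile), `design-codons` (e.g. desired {N,D} →
`RAC`), `filter-designs`, `superpose`, `seqid`. Every run writes a
provenance JSON (inputs, parameters, seed, version).

## Layout

- `structure_io` — PDB/mmCIF parsing (gemmi), atom annotation (Chothia/
  NACCESS vdW radii, element-level polarity), selection, PDB writing
- `surface` — Shrake–Rupley SASA, interfacial-atom definition, buried-area
  splits
- `convexity` — least-squares and RANSAC sphere fits, concave/convex sign,
  interface profiles
- `scaffold` — dihedral-based helix assignment, admission rules, parametric
  bundle and ball-in-socket generators
- `ssm` — enrichment matrices, entropy profiles, conservation classes,
  sorting simulation, B-factor mapping, heatmaps
- `library_design` — degenerate-codon expansion/search, library diversity,
  design-metric filters
- `compare` — Kabsch superposition, Cα RMSD, sequence identity
- `cli` — `concavekit` console entry point

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
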