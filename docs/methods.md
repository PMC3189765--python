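# Methods

## Scope and model

The package implements ligand-based 3D-QSAR for a congeneric series:
all compounds share one rigid scaffold, are superposed through it, and
differ only by substituents.  Activity (pIC50 = −log10 of the molar
IC50) is modelled as a linear function of molecular interaction fields
sampled on a shared lattice; the many, strongly collinear lattice
columns are handled by partial least squares.  A complementary
common-feature pharmacophore search abstracts the same series into
typed interaction points.  The two assays a series may carry
(binding-type endpoint I, functional endpoint II) are treated as
separate responses with the same pipeline.

## Alignment

The scaffold is specified as a SMARTS query that must match the
template exactly once (up to automorphism).  For each molecule, every
substructure match is scored by the closed-form least-squares rigid
superposition (SVD/Kabsch with the determinant correction, so the
fitted transform is always a proper rotation) and the minimum-RMSD
match wins, ties broken by lexicographic atom order.  Collinear
scaffolds are rejected (second singular value below 1e-8 of the
first): the rotation would be undetermined.  Substituent torsions are
left as provided — no flexible alignment.

## Fields

*Lattice.*  Axis-aligned bounding box of all aligned molecules, padded
by a 4 Å margin, sampled at 2 Å spacing (both configurable); points
are ordered z-fastest, matching Gaussian-cube convention.

*CoMFA.*  sp³-carbon probe (r* = 1.70 Å, ε = 0.107 kcal/mol, charge
+1 e).  Combination rules: r*ᵢₚ = r_vdW,i + r*_probe, εᵢₚ = √(εᵢ ε_p),
so the pair minimum is exactly −εᵢₚ at r*.  Electrostatics use
k = 332.17 kcal·Å/(mol·e²) and a distance-dependent dielectric
D(r) = r (a constant-dielectric mode exists behind the probe spec).
Both fields are truncated to ±30 kcal/mol.  Points whose untruncated
steric energy reaches the cutoff are flagged as clashes; electrostatic
values there are later replaced by the training-column mean, since a
probe inside an atom measures nothing.  Element parameters (Bondi
radii, OPLS/AMBER-magnitude well depths) ship in a fixed table for
{H, C, N, O, F, S, Cl, Br, I}; any other element is a hard error.

*CoMSIA.*  Gaussian similarity indices A_k(q) = Σᵢ ω_probe,k ω_ik
exp(−α r²ᵢq) with α = 0.3 and probe value +1 for every property.
Atomic property values ω: steric r³_vdW, electrostatic partial charge,
hydrophobic Crippen atomic logP contribution, donor/acceptor indicator
flags.  The positive sign convention is used throughout; a global sign
flip would be absorbed by the PLS coefficients.

*Charges and flags.*  Iterative Gasteiger charges (RDKit), explicit
hydrogens required.  Donor: N/O bearing ≥ 1 H.  Acceptor: N/O with
non-positive formal charge.  ClogP is the sum of Crippen atomic
contributions and enters the model as one extra descriptor column.

## Descriptor processing and PLS

Columns are processed in an order that is refitted inside every
cross-validation fold (no leakage):

1. clash mean-fill (CoMFA electrostatic columns only),
2. minimum-sigma filter: lattice columns with std below ``sigma_min``
   dropped; extra descriptors exempt.  The threshold is in the field's
   own units — the 1.0 default suits the kcal/mol CoMFA energies,
   while dimensionless CoMSIA similarity indices (indicator fields
   especially) call for a smaller value (≈ 0.05) in the study config,
3. block scaling ("CoMFA-std"): each field block divided by its pooled
   standard deviation √(mean column variance), so a block's total
   variance equals its column count and no field dominates by units;
   extras are scaled to unit variance (constant extras kept unscaled).

PLS is fitted by NIPALS on centered data; coefficients are
back-transformed to the input column space.  Degenerate cases: a
constant response and c ≥ n are errors; if the residual is exhausted
before c components, extraction stops early.

Validation follows the classical conventions: LOO Q² = 1 − PRESS/SS
with SS about the full training-set mean, SEP = √(PRESS/(n−c−1)),
OPN = argmax Q² (ties to fewer components), SEE = √(RSS/(n−c−1)),
F = [R²/(1−R²)]·(n−c−1)/c — the degrees-of-freedom convention that
reproduces the published F values of the activity II reference models
to ≤ 0.1% from their rounded (R², n, OPN).  External prediction uses
the training-set preprocessing frozen and applied to test rows;
r²pred = 1 − PRESS/SD with SD about the training mean.  Field
contribution fractions are Σ|coeff_j|·std_j per block, normalized;
they are invariant to the block scaling because std and coefficient
scale inversely.

The train/test split is activity-stratified: compounds sorted by
activity, cut into n_test bins, one seeded draw per bin — emulating
the usual "test set spans the activity range" practice at the 4:1
ratio.

## Contour maps

For one field, each retained column contributes std_j·coeff_j at its
lattice point (filtered columns contribute zero).  The favored and
disfavored iso-levels are the 0.80 and 0.20 linear-interpolation
quantiles of the *nonzero* grid values — zeros are bookkeeping for
filtered columns, not model output, and are excluded from both the
quantiles and the point sets.  The commercial "contribution level"
display convention is unpublished; the quantile interpretation is this
package's documented stand-in.  Grids are exported as Gaussian cube or
OpenDX (values in Å units, levels recorded in the header comment).

## Pharmacophore search

Feature inventory: HD (donor heavy atom), HA (acceptor heavy atom),
DS (site 2.9 Å from the donor along each D–H bond), AS (site 2.9 Å
opposite the single heavy-atom bond of a *terminal* acceptor — for
ether- or ring-type acceptors with several heavy neighbours a
lone-pair axis is ill-defined and no site is placed), AR (aromatic
ring centroid via a minimum cycle basis of the aromatic subgraph), HP
(centroid of a connected group of ≥ 3 C/halogen atoms with |q| < 0.2),
PN (positively charged, or protonatable aliphatic amine — aromatic,
aniline-type and amide nitrogens excluded).  The 2.9 Å projection is
an idealized hydrogen-bond length.

Conformers: rigid molecules keep their input geometry; flexible ones
get up to 50 seeded distance-geometry embeddings, sorted by MMFF
energy, pruned by a Tanimoto-style similarity (Σmin/Σmax of sorted
heavy-atom distance profiles, threshold 0.6) and capped at 7.

Search: for a reference conformer and each other molecule's conformer,
a correspondence graph pairs same-kind features; an edge joins two
pairs when |d_ref − d_mol| ≤ 2·tolerance (tolerance 0.25 Å).  Maximal
cliques (networkx `find_cliques`, pivoting Bron–Kerbosch, deterministic
node order; > 10⁴ nodes is an explicit "search too large" error) give
the matchable reference-feature sets per molecule; intersecting these
across molecules (any subset of a clique is itself consistent) yields
the candidate common models, filtered to the 4–16 feature window.
Reported metrics: SIZE; HITS = molecules with a full match; DMEAN =
mean of the upper-triangle inter-feature distances; SCORE =
SIZE·(1 − mean_deviation/tolerance), where mean_deviation averages the
matched pairwise-distance discrepancies over molecules — an explicit,
documented replacement for the proprietary DISCO score (zero deviation
gives SCORE = SIZE; scores may go negative for sloppy models).  Only
internal distances enter, so results are invariant under rigid motion
of any input.

## Synthetic benchmark generator

The generator emulates the study conditions a series of this kind
presents, with known ground truth:

* **Structures** — a rigid carbazole-like fused tricycle with three
  substituent positions, 1–3 substituents per compound drawn from a
  10-group library (halogens, Me, OH, OMe, CF₃, CN, NH₂, ethynyl).
  Each compound is embedded by seeded distance geometry, superposed on
  the bare-scaffold template, and its scaffold atoms snapped exactly
  onto the template coordinates — the series is pre-aligned by
  construction (scaffold coordinates identical to 1e-12).
* **Activities** — endpoint I pIC50 = affine(Σ planted-cell weight ×
  CoMFA field value) + N(0, noise_sd²), rescaled to mean 7, sd 1
  (typical potency scale for such series).  Default noise_sd 0.2
  (≈ assay replicate error in log units).  Planted cells form two
  spatially coherent regions per field — a top-variance seed cell plus
  its 26-neighbourhood, one uniform(0.5–1.5) random-sign weight per
  region — restricted to cells with std ≥ 2 kcal/mol and at most half
  the series on the truncation plateau.  The coherence mirrors how a
  binding-pocket preference extends over neighbouring lattice cells;
  planting on isolated truncation-saturated cells would reduce the
  "field" to a clash indicator and make the linear model ill-posed.
  An explicit cell→weight mapping can be supplied instead.
* **Endpoint coupling** — endpoint II = I + s·η with
  s = sd(I)·√(1/r² − 1), which gives expected squared correlation r²
  (default 0.39, the coupling observed between binding and functional
  assays for this antagonist class); the realized value is checked,
  never forced.
* **Split** — stratified 4:1 (15 test of 75 at the default size).
* **Pharmacophore fixture** — a hand-built rigid dummy molecule
  (synthetic, not real chemistry: charges and donor/acceptor flags
  assigned directly) carrying exactly six features: an aromatic
  six-ring (AR and one HP at the same centroid — coincident ring
  features are a known trait of such models), a bridging ether oxygen
  (HA; non-terminal, so no AS), a three-carbon cluster (second HP) and
  an N–H donor (HD + DS).  Copies are reposed by seeded random rigid
  transforms; optionally one feature group in the last copy is shifted
  radially by 1 Å to test feature expulsion.

What passing the synthetic benchmarks does *not* show: recovery of any
particular published model (the original structure files of such
studies are rarely machine-readable, and conformer/charge details of
commercial software differ), robustness to alignment noise (the series
is aligned by construction), tautomer/protonation effects, or
performance on flexible scaffolds.

## Default parameters

| parameter | default | unit | why |
|---|---|---|---|
| lattice spacing | 2.0 | Å | standard CoMFA/CoMSIA sampling |
| lattice margin | 4.0 | Å | covers the probe interaction range |
| truncation | 30 | kcal/mol | conventional energy cap |
| attenuation α | 0.3 | Å⁻² | standard CoMSIA default |
| minimum sigma | 1.0 | kcal/mol | conventional column filter |
| c_max (LOO scan) | 8 | components | above the usual OPN range |
| pharmacophore tolerance | 0.25 | Å | strict common-feature matching |
| min/max features | 4 / 16 | — | conventional search window |
| conformers (pool/kept) | 50 / 7 | — | conventional stochastic search budget |
| Tanimoto prune | 0.6 | — | near-duplicate conformer cutoff |
| noise_sd (generator) | 0.2 | pIC50 | assay-replicate-scale noise |
| endpoint r² (generator) | 0.39 | — | observed binding/functional coupling |

## Numerical choices and degenerate inputs

Quantiles use linear interpolation (`numpy.quantile` default).  Column
standard deviations are population (ddof 0).  Ties in OPN go to fewer
components; ties in substructure matching to lexicographic order.
Zero-variance field blocks are an error under block scaling; constant
extras are kept unscaled.  A perfect fit reports F = +inf.  Probe-atom
coincidence in the Coulomb sum is treated as a clash, never a division
by zero.  Empty molecule sets, unparameterized elements, constant
responses, and c ≥ n are explicit errors.  Problem sizes in tests
(75-compound series, ~750-point lattices, 50 LOO oracle instances)
keep the full suite around ten seconds and the acceptance script a few
seconds on one CPU.

## Known limitations

No energy minimization (input geometries are trusted; a minimizer hook
is deliberately absent so field values are reproducible from the input
file alone), no flexible or field-based alignment, no region focusing
or SAMPLS, no excluded-volume pharmacophore features, no virtual
screening.  The Gasteiger charges are σ-only (no Hückel π component),
and the LJ/logP parameter tables are open-literature approximations of
the proprietary originals, so absolute field values differ from
commercial implementations even where the statistics agree.
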