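# Methods

This note records the models, criteria and numerical choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the underlying conventions were open.

## Fragment library and hydropathy

Peptide sequences are cut by a sliding window (step 1) into every k-mer
with k in [k_min, k_max], default 4–10. Fragments are 0-based, half-open
slices of their parent and retain provenance (parent id, offset, length);
duplicate sequences are kept by default because each window is a distinct
docking query, with an optional deduplication mode that keeps the
first-seen window per distinct sequence.

Hydropathy uses the Kyte–Doolittle (1982) scale, stored as a versioned
constant. GRAVY is the unweighted mean of per-residue values, bounded by
the scale extrema [−4.5, 4.5]. The hydrophobic class is *strictly* positive
GRAVY; a score of exactly 0 classes as hydrophilic. Composition statistics
count {R, K, H, D, E} as charged and {H, F, Y, W} as aromatic — histidine
deliberately appears in both sets. Non-standard letters (B, Z, X, U, \*)
are rejected at parse with the offending position, never silently mapped.

## Screening statistics

Binding-site p-values are adjusted with the Benjamini–Hochberg step-up
rule (delegated to `statsmodels.stats.multitest`; a hand-written step-up
implementation serves as the test oracle). The retention rule is
p_adj ≤ cutoff, default 0.25 — a deliberately permissive threshold for an
exploratory screen whose hits are triaged downstream.

Pocket consistency, used to ask whether different peptides predicted on
one structure share a binding site, clusters pocket residue sets greedily
against first-seen representatives at Jaccard similarity ≥ 0.5
(configurable). The criterion is symmetric, order-stable and conservative:
a pocket that shares fewer than half its residues with the consensus
counts as a different site. The largest cluster defines "same pocket".

## Structure model

PDB parsing and writing go through gemmi. Only model 1 is read (docked
poses are single-conformer; MD snapshots arrive as separate files). For
alternate locations the highest-occupancy conformer is kept, ties broken
by alphabetical altLoc. Waters and common monoatomic ions are always
dropped; other heteroatom groups are kept only on request, for
ligand-site work. Residue numbering and insertion codes are taken verbatim
from the file, since site annotations use author numbering.

Backbone atoms are {N, CA, C, O, OXT} plus the amide/N-terminal hydrogens
and HA; everything else is side chain. Because docked models may or may
not carry explicit hydrogens, atom-class tallies are always reported both
all-atom and heavy-only.

## Peptide builder

Backbones are grown by internal-coordinate (NeRF) placement with ideal
geometry: bonds N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å;
angles N-CA-C 111.0°, CA-C-N 117.2°, C-N-CA 121.7°; ω fixed at 180°
(trans). Conformers: α-helical φ/ψ = −57°/−47°, extended −139°/−135°,
polyproline −78°/149°. The carbonyl O is placed anti to the following
amide nitrogen (torsion N-CA-C-O = ψ + 180°). Side chains are represented
by a single Cβ at ideal tetrahedral geometry in the L-configuration
(improper N-C-CA-CB ≈ −122.8°); full side chains are intentionally not
built, as docking engines rebuild them, and a Cβ-only model keeps the
builder exactly verifiable.

Dihedral measurement uses gemmi's torsion primitive, so construction and
validation run on independent code paths; the round trip recovers every
internal φ/ψ within 0.5°. Near-collinear atom quadruples yield an
undefined-dihedral marker rather than a number.

The helix rise diagnostic estimates the helix axis from Cα second
differences (successive radial vectors; their cross products all point
along the axis) rather than from the principal component of Cα positions,
because the principal-component axis is end-biased for helices shorter
than about four turns and overestimates the rise of a decapeptide by
~3 %. With the ideal angles above the α-conformer rises 1.56 Å per
residue (canonical value ≈ 1.5 Å).

## Interaction profiler

All "within X Å" gates are inclusive (≤ X). Defaults:

| criterion | default | status |
|---|---|---|
| close contact (any receptor–peptide atom pair) | ≤ 4.0 Å | standard criterion |
| hydrophobic contact (C–C pairs) | ≤ 4.0 Å | standard criterion |
| H-bond donor–acceptor distance | ≤ 4.0 Å | standard criterion |
| H-bond deviation of D–H···A from 180° | ≤ 40° | standard criterion |
| H-bond distance-only fallback (donor lacks H) | ≤ 3.5 Å | package assumption |
| salt bridge, minimal inter-group atom distance | ≤ 4.0 Å | package assumption |
| π–π centroid distance | ≤ 5.5 Å | package assumption |
| π–π inter-plane angle (parallel stacking only) | ≤ 30° | package assumption |

Hydrogen-bond chemistry uses per-residue donor/acceptor tables (backbone N
donates except proline; backbone O/OXT always accepts). The fallback for
donors without explicit hydrogens is applied *per donor atom*, not per
structure, so mixed-protonation models behave sensibly; such bonds are
flagged geometry-incomplete. Charged groups are Arg {NE, NH1, NH2},
Lys {NZ}, His {ND1, NE2} (histidine treated as charged, consistent with
the composition statistics), Asp {OD1, OD2}, Glu {OE1, OE2}, plus the
N-terminal amine and C-terminal carboxylate of every chain. Aromatic rings
(His, Phe, Tyr, both Trp rings) need at least five resolved atoms; ring
normals come from the least-squares plane (SVD), and the inter-plane angle
is folded to [0°, 90°]. T-shaped stacking is deliberately out of scope.

Contact search uses a k-d tree (`scipy.spatial.cKDTree`) and is held to
exact set equality with the all-pairs rule in tests. The per-complex
profile reports, for the peptide, the fraction of side-chain and backbone
atoms in at least one close contact, contacts per interacting atom, and
the unique and overall side-chain:backbone ratios — the comparison that
reveals whether the peptide binds mainly through its backbone.

## Interface and site overlap

Interface residues between two receptor chains are those with any Cα–Cα
pair strictly below 6.0 Å — strict, unlike the inclusive 4.0 Å contact
rule, following the "less than" wording of the interface criterion. Only
Cα atoms are compared; residues lacking one are skipped with a warning.
Pocket overlap with an interface or an annotated site is declared at ≥ 1
shared residue by default (configurable `min_shared`), with the shared
residues reported for manual triage. Empty ligand codes are accepted only
for catalytic-site annotations.

## Energy decomposition

Each Gibbs term is G = E_bnd + E_el + E_vdw + G_pol + G_np − TS, with the
entropy term absent in the default workflow (it is rarely computed in
end-point MM/GBSA and cancels in relative comparisons). The binding energy
is the arithmetic mean of per-snapshot
ΔG = G_complex − G_protein − G_peptide with sample SD (n − 1); a
single-snapshot input reports SD 0 with a warning. Missing roles fail
loudly, naming the snapshot.

The prominence rule takes M = max |ΔG_contrib| per system and selects all
residues with |ΔG_contrib| ≥ 0.4·M. Both the absolute-value reading of
"largest contribution, stabilizing or destabilizing" and the inclusive
comparison are this package's documented interpretation; the rule is
scale-invariant by construction. Peptide residues additionally carry a
position class (index 1 → N-terminal, index L → C-terminal, else
internal), and summaries report appearance counts and mean contributions
per (chain role, amino-acid type) and per (type, position class).

## Report aggregation

Cohort summaries use the sample SD (n − 1) throughout; "±" denotes SD, not
SE. The salt-bridge/π–π partition has four exclusive categories
(bridge-only, stack-only, both, neither) whose fractions always sum to 1;
bridge and stack count means are conditional on the system possessing the
interaction. Percentages are rounded only at presentation.

## Synthetic data: what it emulates and what it does not

`make_complex` plants each requested interaction analytically — partner
atoms placed on the exact sphere/cone the target geometry requires, ring
pairs as rotated hexagons (radius 1.39 Å), the H-bond hydrogen positioned
by a one-dimensional root solve so the planted deviation is exact — with
sites spaced 25 Å apart and far-away terminal cap residues so chain
termini exist without touching anything. Atom chemistry is chosen so each
site triggers exactly its own detector (e.g. proline backbone N for
plain close contacts, since it is neither donor, acceptor nor carbon).
Ground-truth close/hydrophobic contact sets are computed by a brute-force
all-pairs scan inside the generator. These fixtures are geometric
scaffolds, not foldable proteins: passing tests demonstrate detector
correctness and bookkeeping, not performance on real docked poses, where
protonation states, clashes and near-threshold geometry are messier.

Screening tables draw null p-values from Uniform(0, 1) and signal p-values
from Beta(0.1, 10); the pocket-shuffle generator reuses a structure's
consensus pocket with a set probability. Decomposition tables split fixed
role energies into the five Gibbs terms and absorb ΔG* plus Normal(0, σ)
snapshot noise into the complex electrostatic term, with per-residue
contributions required to sum to ΔG* exactly.

Cohort draws use the characterized study conditions as defaults: close
contacts ~ Normal(167, 49) truncated at 0, hydrophobic contacts
~ Normal(24, 8), H-bonds ~ Normal(4.5, 2), protein-side donor probability
0.51, category probabilities (52, 7.7, 5.8, 34.6) % (normalized from the
printed, rounding-inflated 100.1 %), conditional bridge/stack counts
Normal(1.72, 1)/Normal(1.63, 0.7) floored at 1, and participation
fractions centred at 23.8 %/38.7 %. Binding energies are drawn from
Normal(−35, 18.5) kcal/mol, chosen once so that the favourable-binder
fraction matches the observed ~97 % (101/104) of systems; only the
negative fraction, not the distribution's moments, is a published
condition. Counts are integer-rounded, which adds at most ~0.3 to a
recovered SD; recovery tests budget for it explicitly.

## Problem sizes and tolerances

Oracle-equivalence checks run 100 random fixtures per geometric search and
1000 random p-value vectors; statistical recovery uses 200 replicates of
100-snapshot systems for ΔG and a 400-system cohort, with 3·SE acceptance
bands derived from the generator parameters. The acceptance script reports
a 104-system cohort and 2000-structure pocket-shuffle. Dihedral round
trips are asserted at 0.5°, planted geometry at 10⁻⁶–10⁻⁹ of the target,
and fraction partitions at 10⁻¹².

## Known limitations

* No cation–π, halogen-bond or water-mediated interaction classes, and no
  T-shaped stacking.
* No mmCIF input, assembly generation or protonation-state prediction.
* Pocket identity (Jaccard ≥ 0.5), salt-bridge and π–π cutoffs, and the
  ≥ 1-shared-residue overlap rule are documented assumptions where the
  field has no single convention; all are configurable.
* The composition statistics of the real published peptide catalogue can
  be recomputed only after transcribing its sequences (website/PDF
  supplements) to `data/sip_catalogue.fasta`; the corresponding check
  fails with instructions until then.
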