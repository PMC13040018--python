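# Methods

This note documents the models, parameter choices and numerical policies
behind `epifab`, what the synthetic fixtures do and do not establish, and
the package's known limitations.

## Coordinate model and I/O policies

Structures are chains → residues → atoms keyed by *author* numbering
(chain id, residue number, insertion code), because every range the
analysis consumes — the EGFR 287–302 epitope loop, the 293–302 hairpin
anchor, receptor domain boundaries, CDR windows — is conventionally stated
in author coordinates.  Parsing (PDB and mmCIF) and PDB writing go through
gemmi; this package adds only policy:

- **Single conformer.**  Alternate locations are reduced at read time to
  the highest-occupancy conformer, ties broken by first altloc
  alphabetically.  All downstream distances assume one position per atom.
- **Heavy atoms, no waters.**  Hydrogens and waters are excluded by
  default (togglable); a mid-2-Å X-ray structure resolves neither, and the
  contact rules are heavy-atom rules.
- **Chain roles are configuration.**  Which deposited chain is the
  peptide, heavy chain, light chain or receptor is supplied via config
  (`RunConfig.chain_roles`, `data/structures/roles.yaml` for the
  accession tests), never inferred.

## Superposition

Kabsch's closed-form solution: SVD of the covariance of centered paired
coordinates, with the reflection branch corrected by the sign of
det(V·Uᵀ) so the returned rotation always has determinant +1, even for
mirror-symmetric point sets.  Point sets whose second singular value is
≤ 1e-10 of the first are rejected as (near-)collinear rather than
returning an arbitrary member of the solution family.

Pairing is explicit and separate from solving.  `by-seqnum` matches
residues sharing (number, insertion code); `by-sequence-alignment` runs a
global pairwise alignment (identity scoring, match +1, mismatch 0, gap
open −1, extend −0.5) and pairs aligned residues.  Within a residue pair,
only atoms of the requested set present in *both* structures are used —
missing atoms are dropped pairwise, never imputed, so partially resolved
loops simply contribute fewer pairs.  Hairpin alignments default to
backbone (N, CA, C, O) atoms over residues 293–302, the well-ordered
strand pair of the epitope; CA-only is exposed alongside because published
RMSDs rarely state their atom selection.  No outlier rejection or
iterative trimming is performed: reported RMSDs are plain.

## Solvent-accessible surface area

Shrake–Rupley with a probe radius of 1.4 Å (water) and a deterministic
golden-section sphere lattice of 960 points per atom — no random number
generator, so results are bit-reproducible and convergence can be checked
by doubling the point count (the suite requires < 1 % change on the
fixtures).  The default van der Waals radii are a Bondi-style table
(C 1.70, N 1.55, O 1.52, S 1.80 Å); a NACCESS-flavoured alternative is
selectable, and unknown elements raise unless a fallback radius is
configured.  Accuracy against closed forms at 960 points: isolated-sphere
area exact to < 1 %, two-sphere spherical-cap burial to < 2 %.

Buried surface is definitional: for components that *partition* the
complex, ΔSASA(c) = SASA(c isolated) − SASA(c in complex) summed over the
component's atoms, and the total is the sum of the components — additivity
is structural, not numerical.  Non-partitions (overlapping or incomplete
component definitions) are rejected because their "decomposition" would
decompose nothing.  Published interface areas for this system come from
unstated software and radii; agreement within ±5 % is the appropriate
expectation, with additivity the exactly testable claim.

## Contact typing

Heavy-atom distance criteria only — no donor–H–acceptor angles, since the
structures carry no hydrogens and published interaction tables report
plain distances:

| type | atoms | default cutoff |
|---|---|---|
| salt bridge (ionic) | Asp OD1/OD2, Glu OE1/OE2 vs Lys NZ, Arg NE/NH1/NH2, His ND1/NE2 | 4.0 Å |
| cation-π | cationic N vs Phe/Tyr/Trp/His ring atom | 4.5 Å |
| hydrogen bond | any N/O/S vs any N/O/S | 3.5 Å |

A pair satisfying a stronger rule is reported once with the stronger type
(ionic > cation-π > H-bond).  The cutoffs were chosen to admit the longest
distances conventionally reported for each class (≈3.1 Å H-bonds, ≈3.4 Å
salt bridges, ≈3.7 Å cation-π) with headroom; all are configurable, and
raising a cutoff can only add records of that type (tested).  Van der
Waals contacts are deliberately not enumerated.  CDR labels come from
configured per-chain residue windows; no antibody numbering scheme is
implemented, because scheme choice (Kabat/Chothia/IMGT) would silently
move boundaries.

## Graft-and-clash accessibility

To ask whether a Fab that binds the isolated epitope peptide can reach the
same epitope inside a receptor conformation: superpose the bound hairpin
(293–302 backbone) onto the receptor's copy, apply the transform to the
whole Fab, drop the peptide, and count inter-structure heavy-atom pairs
with d < r₁ + r₂ − 0.4 Å, excluding the receptor's own epitope residues
(the Fab is supposed to hug those).  The 0.4 Å tolerance is the
conventional severe-clash margin.  Counts are aggregated per receptor
domain (default EGFR ectodomain layout: I 1–164, II 165–310, III 311–480,
IV 481–618; residues outside any range land in an explicit "unmapped"
bucket) and per chain.  Neighbour search uses a KD-tree but the contract
equals the all-pairs definition exactly (tested on 2,000-atom scenes).
Alignment RMSDs above 3.0 Å trigger a warning — the graft is returned but
the pose is unreliable.

The accessible / partial / inaccessible call is a pure threshold function
of the clash count, defaulting to ≤ 10 → accessible and ≥ 200 →
inaccessible.  These defaults were fixed from severe-clash conventions
(a handful of marginal overlaps is relievable by side-chain relaxation;
hundreds are not); the scientifically meaningful claim — and the one the
tests assert — is the *ordering* of conformations, not absolute counts.
The EGFRvIII-style receptor model is built by truncating the ectodomain
chain after residue 273, which removes domain I and part of domain II and
leaves the epitope loop on a solvent-exposed remainder of domain II.

## 1:1 Langmuir kinetics

The binding model is the pseudo-first-order 1:1 interaction at constant
analyte concentration C:

- association: R(t) = Rmax·kaC/(kaC + kd)·(1 − e^{−(kaC+kd)t})
- dissociation: R(t) = R(t_assoc)·e^{−kd(t − t_assoc)}

Simulation uses this closed form directly — no ODE solver, hence no solver
tolerance to document — with optional seeded Gaussian noise.  No
mass-transport or bivalent-analyte terms are modelled.

Fitting is global nonlinear least squares over all concentrations
simultaneously with shared (ka, kd, Rmax), parameterized in log space to
enforce positivity, Levenberg–Marquardt with multi-start initialization
(heuristic start: kd from the log-linear dissociation tail, Rmax from the
peak response, KD guessed at the working concentration; remaining starts
jittered).  Standard errors come from the Gauss–Newton covariance
σ²(JᵀJ)⁻¹ mapped back to the linear scale by the delta method.
Non-convergence is reported as a flag with best-so-far parameters, never a
silent exception; dissociation-only or single-concentration inputs are
accepted but flagged as leaving ka under-identified.  KD = kd/ka, reported
in nM (×1e9).  Recomputed KD values are compared with printed tables at
±0.02 nM, the slack implied by 3-significant-figure rounding of the rates.

Default simulated-study conditions: association 600 s, dissociation 900 s,
5 s sampling, Rmax 100 RU, five analyte concentrations spanning 0.1–10×KD,
noise 2 % of Rmax — typical of a modern SPR titration series.  Under these
conditions the 100-replicate recovery experiment yields a median |KD|
error well under 10 % (≈0.6 %).

## Synthetic fixtures: what they do and do not show

The generators produce standard PDB-writable structures plus machine-
readable truth, so the tested code path is identical to the real-data
path:

- **Hairpin**: idealized antiparallel β geometry (3.3 Å rise, 0.95 Å
  pleat → ~3.8 Å consecutive Cα, 4.8 Å inter-strand), terminal-cysteine
  SG pair at ~2.05 Å, stylized side chains carrying only the functional
  atoms contact detection keys on.
- **Groove complex**: two rigid slabs flanking the hairpin at a set gap,
  with one planted salt bridge, cation-π and H-bond at known distances in
  CDR-window residue numbers; gaps > 6 Å are emitted as open
  (non-contacting) scenes.
- **Clash scene**: background atoms rejection-sampled clash-free plus
  exactly n planted overlapping pairs, verified by an all-pairs scan
  before emission.
- **Occluded receptor**: the bound peptide copied to a receptor chain at a
  known random rigid transform, plus k blocker atoms placed at transformed
  Fab atom positions — grafting must recover the planted transform and
  each blocker must register as a clash, dialing scenes from open through
  partially to heavily occluded.
- **Sensorgram sets**: closed-form traces with known (ka, kd, Rmax) and
  seeded noise.

These establish correctness of the *operations* (exact counts, exact
transforms, tolerance-bounded areas and rates).  They are geometric, not
energetic: no rotamers, no realistic packing density, no crystallographic
disorder, no instrument drift or bulk-shift artifacts.  Passing them shows
the algorithms implement their definitions; it does not certify agreement
with any particular deposited structure, which is why the
accession-dependent checks exist separately and require the fetched
coordinate files plus a human-reviewed chain-role map.

## Problem sizes

The suite and the acceptance script run on desk-scale inputs chosen to
exercise every code path with exact oracles: ≤ 500-atom contact scenes
(where brute force is feasible), 2,000-atom clash scenes, 240–960-point
SASA lattices on ~250-atom complexes, and 100 kinetic-recovery replicates
of five 301-point traces.

## Known limitations

- Contact typing has no π-π stacking, halogen bonds or water bridges, and
  no angle terms; borderline H-bonds at unfavourable geometry are counted.
- SASA radii conventions differ between published tools by a few percent;
  cross-tool comparisons should quote the radii set and probe.
- The graft is rigid: no induced fit, side-chain relaxation or energy
  model, so clash counts upper-bound the true steric conflict.
- The kinetics module fits only the 1:1 model; heterogeneous-ligand or
  mass-transport-limited data will show structured residuals rather than a
  model-selection warning.
- `pair_atoms` pairs chains positionally (first with first); reorder
  selections, or select single chains, when comparing structures whose
  chain order differs.
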