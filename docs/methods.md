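# Methods

## Scope and model

`cysdimer` models covalent homodimers of single-cysteine protein mutants
under one structural assumption: the only rigid constraint joining the two
protomers is the interchain disulfide bridge, so any experimentally
observed interchain cystine geometry is a legitimate template for the
dimer. The pipeline is purely geometric — no force field, no minimization,
no dynamics. Models are judged afterwards against solution measurements
(hydrodynamic size, Trp-quenching contacts, disulfide chirality), not by
energy.

## Structure I/O (structio)

A minimal fixed-width PDB ATOM reader/writer:

- Only ATOM records are parsed; HETATM is ignored except oxidized/modified
  cysteine variants (CSO, CSS, OCS, CME, CSD, CSX, CYX), which are mapped
  to CYS so mined bridges are not lost.
- Hydrogens are dropped on read — every downstream criterion is
  heavy-atom based.
- Altlocs resolve to the highest occupancy (ties → 'A', then
  alphabetical); discarded copies are logged.
- Insertion codes join the author residue number as a composite key;
  numbering is author numbering throughout.
- Coordinates round-trip at the format's 3-decimal precision; serial
  numbers are reassigned on write and wrap at 99 999 so any structure
  stays re-readable.

The parser is deliberately in-package (≈60 lines) because the module's
contract — line-numbered format errors, the altloc/HETATM policy above,
and a lossless round-trip — is itself under test; a test cross-checks
coordinates against biotite's PDB reader as an independent oracle.

## Rotamer mining (rotamer_library)

Interchain disulfides are all CYS pairs on different chains with
SG–SG ≤ 2.3 Å (covalent S–S ≈ 2.05 Å plus coordinate error; the cutoff is
exposed). Each pair is lifted to a ten-atom rotamer with
χ³ = dihedral(CBᴬ, SGᴬ, SGᴮ, CBᴮ) and per-chain χ¹ = dihedral(N, CA, CB,
SG). Torsions follow the IUPAC sign convention (verified against
Biopython), with range (−180°, 180°]; torsions are reversal-symmetric and
rigid-motion invariant, both asserted as properties. Rotamer ids follow
`<pos_a><chain_a>_<pos_b><chain_b>_<source>` so every dimer model is
traceable to the structure its bridge came from. Libraries serialize to a
headered TSV (full-precision coordinates via `repr`) for diffability.

Corpus choice matters: the library's composition is a snapshot of
whatever multi-chain structures are supplied, so mined χ³ statistics are
corpus statistics. The package ships no corpus; the synthetic generator
provides one with known truth.

## Dimer construction (dimer_builder)

- `mutate_to_cys` keeps the backbone + CB and places SG at 1.81 Å,
  CA–CB–SG = 114°, torsion equal to the parent's χ¹ (gamma-atom direction)
  when one exists, else −60° (the most common χ¹ rotamer).
- Each monomer copy is fitted on its half-cystine over {N, CA, C, CB}.
  Four atoms over-determine the rigid placement and fix both position and
  side-chain take-off direction; the fit RMSD is recorded per chain.
- After the whole-copy rigid motion, the cysteine's N, CA, C, CB, SG are
  overwritten with the rotamer's coordinates (so the bridge geometry is
  exactly the template's) and the carbonyl O is rebuilt in the rotamer
  backbone's local frame to keep the peptide plane consistent.
- Superposition is Kabsch via `scipy.spatial.transform.Rotation
  .align_vectors`, restricted to proper rotations; a brute-force rotation
  search serves as the independent oracle in tests only.
- Clash filter: interchain heavy-atom pairs closer than 0.6 × (r₁ + r₂)
  with Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80 Å); the bridging
  cysteines' SG/CB are exempt (they are covalently bonded across the
  interface by construction); the inequality is strict. 0.6 is a common
  steric-overlap heuristic; it is a parameter, not a fitted value.

## Ensemble analysis (ensemble_analysis)

- Pairwise distance = Cα RMSD after optimal superposition, minimized over
  the two chain pairings of a homodimer (A→A/B→B vs A→B/B→A).
- Clustering: scipy agglomerative linkage (average by default; single and
  complete are exposed) cut at 8.0 Å. Models are sorted by id before the
  matrix is built and clusters relabelled by first appearance, so labels
  are invariant to input order. Each cluster reports its medoid (minimum
  summed distance) as the representative.
- Maximum diameter is the largest heavy-atom pairwise distance; Rg is
  mass-weighted; both reported in nm (internal math in Å) to match
  hydrodynamic measurements.
- SASA is Shrake–Rupley with a golden-spiral lattice, 960 points/atom and
  a 1.4 Å probe (freesasa is not a dependency; the in-package sampler is
  cross-checked against the analytic sphere and against biotite).
  Interface area = (SASA_A + SASA_B − SASA_AB)/2; interface residues bury
  more than 0.1 Å².
- Hydrogen bonds use a heavy-atom donor–acceptor distance criterion
  (≤ 3.5 Å) with a per-residue donor/acceptor typing table and no angle
  term — the models carry no hydrogens, so an angular criterion would be
  fiction. `hbond_persistence` reports bonds present in ≥ 30 % of an
  ensemble's models, the static analog of trajectory persistence.
- Trp-quencher contacts measure the indole benzene-ring centroid against
  partner aromatic-ring centroids (or SG for Cys) at ≤ 7 Å, the π–π
  stacking range; the quencher set is {Cys, His, Tyr, Phe}.
- Selection = conjunction of (i) diameter in the configured window,
  (ii) an interface Trp with a quencher contact from the partner chain,
  (iii) zero clashes.

## Chirality and CD consistency (spectro_consistency)

χ³ ∈ (0°, 180°) ⇒ P (right-handed screw), (−180°, 0°) ⇒ M; exactly 0° or
180° are the cis/trans boundaries, flagged achiral. The empirical rule
mapping the near-UV CD difference band to candidate χ³ values is *not*
implemented: both an na-σ* and an nb-σ* band of either sign can occur for
a given handedness, so the sign→angle mapping is ambiguous from first
principles. Candidates are therefore configuration (default {85°, −95°},
tolerance 10°), and the module records the measured band sign and the
candidate set independently, never deriving one from the other. Distances
on the torsion circle are circular (min(|a−b|, 360−|a−b|)), so 179° and
−179° are 2° apart.

## Measurement formulas (biophysics)

All fitters achieve exact recovery on noiseless synthetic data and are
deterministic (closed-form linear algebra, or least squares from
data-driven starts with 10 seeded jittered restarts taken only if needed).

- Extinction: least-squares line of (corrected) A₂₈₀ vs concentration,
  free intercept reported; the slope is ε.
- Hemolysis % is not clamped; values above 100 % are flagged, not hidden.
- Half-time: first crossing of A₀/2 with linear interpolation —
  first-crossing semantics are robust to post-lysis noise.
- Rate law v(c) = V_max(1 − e^(−c/c₀)): chosen because lysis rates
  saturate; a Michaelis-like alternative would differ only in curvature.
- Hill fit y = plateau·cʰ/(kʰ + cʰ) with k₀ at the dose nearest 50 %,
  h₀ = 1, plateau₀ = max response; HC₅₀ = k.
- Tm: the denaturation fraction (S₂₀ − S)/(S₂₀ − S₉₀)·100 is
  differentiated with a Savitzky–Golay first-derivative filter (window 9
  grid points, cubic) and the maximum refined by quadratic interpolation;
  the window is comparable to the transition width, which is what a
  derivative estimator needs to be unbiased yet noise-stable. The 50 %
  crossing is computed as a cross-check and a >2 °C discrepancy warns.
- Stern–Volmer slope with the intercept fixed at 1 (the [Q] = 0 point
  defines F₀); the free-intercept line is a diagnostic for static
  quenching.
- MALDI: per-peak M = z·(m/z) − z·m_H (proton 1.007276 Da, overridable;
  the printed consensus reproduces to ±0.1 Da under either 1.0 or
  1.007276). Dimer mass bookkeeping offers `paper` (exactly 2 × monomer)
  and `chemical` (2 × monomer − 2.016 Da for the two hydrogens lost on
  disulfide formation) conventions; `paper` is the default because the
  reference tabulation uses it.
- SEC: log₁₀(MW) linear in elution volume; queries outside the calibrated
  range warn about extrapolation.
- Trp/Tyr decomposition scales the 295 nm-excited (pure Trp) spectrum to
  match the 275 nm-excited total at 380 nm, where Tyr no longer emits;
  Tyr = total − scaled Trp, reported raw and clipped at zero, with
  trapezoid areas.

## Synthetic data: what it emulates and what it does not

Generators are deterministic per (parameters, seed) and echo all
parameters into truth sidecars; recovery tests read truth only from
sidecars.

- The protomer is an idealized α-helix (rise 1.5 Å, 100°/residue, CA
  radius 2.3 Å, consecutive CA–CA ≈ 3.8 Å) of poly-Ala with one Cys and
  optional schematic aromatic rings. It is *not* an actinoporin
  β-sandwich: the geometric pipeline is fold-agnostic, and a real
  template PDB remains an ordinary external input. Passing tests
  therefore demonstrate the correctness of the geometry, clustering and
  selection machinery, not the biological realism of any particular
  dimer model.
- The dimer constructor imposes SG–SG = 2.05 Å, CB–S–S = 104° and an
  exact χ³ analytically; the two torsions the bridge does not constrain
  (the χ²-like rotations about each CB–SG bond) are scanned on a seeded
  deterministic grid until the placement is clash-free. Rotating copy B
  about its own CB–SG bond leaves all four torsion-defining atoms fixed,
  which is why the search cannot disturb χ³.
- Curves are generated from the same functional families the fitters
  assume, with multiplicative Gaussian noise (default 2 % relative) for
  optical signals and additive jitter for m/z — a deliberate
  "well-specified model" regime that measures estimator quality, not
  model misspecification. Default parameters are the measured reference
  values of the W111C system (HC₅₀ 0.31/62.4 nM; V_max 1.05/0.69 min⁻¹;
  Tm 57.2/64.9 °C by CD and 69.9/74 °C by fluorescence; K_SV
  4.56/3.03 M⁻¹; ε 1.78 mL mg⁻¹ cm⁻¹; dimer consensus mass 38 618.35 Da;
  DLS diameters 4.2/5.9 nm).
- The hemolysis generator produces logistic turbidity decays whose rate
  follows the saturating law, whose lag shortens monotonically with
  concentration, and whose endpoint follows the Hill sigmoid; the
  noiseless half-time has a closed form that tests use as the oracle.

## Problem sizes

The default study conditions are a 20-structure synthetic corpus of
12-residue protomers, recovery suites of 20 noise seeds per parameter,
71-point melting grids (20–90 °C at 1 °C), 8–10-point dose/rate ladders
and 7-point quench series — sizes chosen to match the corresponding
experimental designs while keeping the full suite fast.

## Known limitations

- No energetics: models are filtered, never relaxed; clash-free is the
  only quality notion. Interface areas on unrelaxed grafts are lower
  bounds on what a refined model would bury.
- Ensemble-scale counts depend entirely on the supplied corpus; the
  package reproduces the procedure, not any particular published
  library's census (83 rotamers / 67 clash-free / 9 clusters at 8 Å are
  snapshot-dependent figures of the original survey and are not asserted
  anywhere).
- The CD "quadrant rule" is consumed only through its output candidates;
  the package cannot infer χ³ candidates from a spectrum.
- H-bond detection without hydrogens or angles over-counts relative to
  donor-geometry-aware criteria; it is used comparatively, across models
  analyzed identically.
- The parent-toxin sequence utility (`sequences`) validates and applies
  point mutations but ships no sequence data; checks that need the real
  StI sequence require the user to supply a FASTA (e.g. UniProt P81662).
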