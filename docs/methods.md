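# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the limitations a user should know before applying the pipeline to
deposited coordinates.

## Structure model

Coordinates are held in a typed chain → residue → atom hierarchy with
author residue numbering preserved verbatim; every residue reference in the
analyses (lobe ranges, hinge, swapped segment, named salt-bridge partners)
is expressed in that frame, so no renumbering ever happens.  Parsing and
serialisation are delegated to gemmi.  Policy decisions, all motivated by
single-conformer crystallographic analysis: only the first MODEL is kept;
alternate locations other than blank/'A' are dropped; hydrogens are
discarded (the target structures are at 1.47–2.49 Å, where riding hydrogens
carry no independent information) and all geometry uses heavy atoms;
waters are excluded from area and contact computations by default.
Chain labels of the two copies in an asymmetric unit are not assumed to be
A/B — the pipeline config carries an explicit chain mapping.

## Superposition and closure

Kabsch superposition is the standard SVD solution with the
reflection-corrected determinant, requiring ≥ 3 non-collinear paired atoms.
Pairing across structures is by author residue number and atom name;
unmatched residues (e.g. unmodelled C-terminal residues in one form) are
dropped with a logged count.

The inter-lobe ("Venus fly-trap") closure between two conformers is a
deterministic two-stage fit: (1) superpose conformer B onto A over the
*fixed* lobe; (2) fit B's *moving* lobe, as transformed by stage 1, onto
A's moving lobe.  The stage-2 rotation is the closure.  Angles are reported
in [0°, 180°] with a right-handed unit axis; the angle is extracted as
atan2(‖skew(R)‖, tr(R) − 1), which stays fully conditioned near 0° and
180° where the acos form loses half the floating-point digits.  Domain
ranges are supplied explicitly rather than detected automatically
(published lobe definitions exist for the systems of interest); this keeps
the statistic deterministic and testable.  Both diagnostic RMSDs (fixed
lobe after stage 1, moving lobe before stage 2) are reported so a poor
fixed-lobe fit cannot masquerade as a large closure.

## Solvent accessibility and buried interfaces

Shrake–Rupley with a deterministic golden-spiral (Fibonacci) point set:
for each atom, n points are placed on the sphere of radius r_vdw + probe;
a point is exposed iff it lies outside every neighbour's expanded sphere;
the atom's area is the exposed fraction × 4π(r+w)².  Defaults: probe
1.4 Å, n = 960 points, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å with a
1.70 Å fallback, all config-overridable.  Accuracy at the defaults: exact
single-sphere area to ~1e-13 relative (the spiral's equal-weight points
integrate a constant exactly), two-sphere overlap within 0.2% of the
closed-form spherical-cap value, and within 2% of an independent
latitude–longitude quadrature on multi-atom toys.

Buried interface area of a two-sided complex is
`SASA(side1) + SASA(side2) − SASA(complex)` — the *total* area lost by both
sides, not halved; because databases differ, the halved one-face value is
emitted alongside.  Waters and hetero ligands are excluded from interface
areas by default: a ligand sitting in an intra-monomer cleft must not leak
into a dimer-interface number.  When comparing against areas produced by
other programs, a ±5% band is appropriate — radii sets and point schemes
differ legitimately between implementations.

## Contact censuses and swap-interface classification

Geometric criteria, deliberately conventional and config-exposed:

- salt bridge: basic side-chain N (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) to
  acidic side-chain O (Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å.  His is counted
  but flagged, since its protonation is unknown from coordinates.
- hydrogen bond: N/O–N/O heavy-atom pairs ≤ 3.5 Å with
  antecedent–donor–acceptor angle ≥ 120°, the antecedent being any heavy
  atom bonded to the donor (bonds inferred at < 1.8 Å, plus the preceding
  carbonyl C for backbone N).  Pairs whose angle cannot be computed are
  kept on distance alone and flagged.  Pairs closer than 2.2 Å are treated
  as covalent/clash artefacts, not bonds.
- hydrophobic contact: side-chain carbon pairs of apolar residues
  (A,V,L,I,M,F,W,P,Y) ≤ 4.5 Å.

Every census stores one contact per residue pair per kind (minimum-distance
atom pair), canonically ordered, so counts are symmetric and monotone in
the cutoff.

For a two-chain swapped dimer, inter-chain contacts are partitioned by the
Eisenberg nomenclature: a contact is **C-interface** iff one partner lies in
the swapped segment and the other in the opposite chain's main body (the
interface a hypothetical closed monomer would also have); *all* other
inter-chain contacts — hinge-mediated, body–body, tail–tail — are
**O-interface** (present only in the swapped assembly).  Unclassifiable
combinations therefore default to O rather than being dropped, preserving
|C| + |O| = number of inter-chain contacts.  An isolated monomer yields an
empty report rather than an error.

The thermostability salt-bridge count is reported per chain at the
configured cutoff rather than as a single number, because published counts
of this kind rarely state chain or cutoff conventions.

## Backbone stereochemistry

φ(i), ψ(i) as usual; ω(i) = τ(Cα_i, C_i, N_{i+1}, Cα_{i+1}) is assigned to
the *preceding* residue (the peptide i → i+1), and Δω(i) = wrap(ω − 180°)
with wrap into (−180°, 180°], so ω = −179° gives Δω = +1°.  Carbonyl
pyramidalization is the improper-torsion deviation
ϑc(i) = wrap(τ(O_i, C_i, N_{i+1}, Cα_i) − 180°); the sign follows that
torsion's right-hand rule and a config switch flips it, since both sign
conventions circulate.  ψ-window statistics (default windows 75–105° and
135–165°) pair residue i's ψ with peptide i's Δω and ϑc — the
psi-dependence of these quantities, and of the N–Cα–C bond angle, is a
known signature of well-refined structures, and aggregating them by window
is how that signature is checked.  Chains are split logically at breaks
(consecutive Cα–Cα > 4.5 Å); residues missing a needed backbone atom get
missing values, never fabricated ones.

Secondary structure is a lightweight hydrogen-bond-pattern assignment, not
a DSSP energy model: helices from runs of O(i)···N(i+4) ≤ 3.5 Å turns;
strands from cross-strand backbone N–O ladders with at least two rungs
within two residues (antiparallel ladders alternate, so rungs sit two
apart).  It exists only to aggregate geometry statistics by class; users
needing publication-grade assignments should substitute DSSP output.

## Sequence metrics

Charged = {K,R,E,D}, polar = {N,S,Q,T}, His in neither class; percentages
to one decimal.  Theoretical mass is the average (not monoisotopic)
Expasy residue-mass table plus one water — the convention under which a
"theoretical monomer mass" printed next to light-scattering data is
computed.  Stoichiometry divides a measured weight-average molar mass by
the monomer mass and flags ratios further than 0.15 from an integer.  The
composition frame (full-length vs expressed construct) is the caller's
choice via `first_number`; the hinge-motif check extracts the subsequence
by author numbering verbatim and reports Pro presence, taking no position
on off-by-one ambiguities in published hinge annotations.

## One-site ITC model

Forward model: the Wiseman one-set-of-sites bound fraction
Θ = (a − sqrt(a² − 4X/(nM)))/2 with a = 1 + X/(nM) + 1/(nK_a M).
Default cell bookkeeping is mole-conserving ("linear"): after cumulative
injected volume dV, M_t = M₀V₀/(V₀+dV), X_t = X_syr·dV/(V₀+dV), and the
heat content Q = nΘM_t·ΔH·(V₀+dV), so cumulative heat equals
n·M₀·V₀·ΔH·Θ_final + offsets *exactly* and the cumulative molar ratio
equals the injected-moles ratio.  The MicroCal-style exponential perfusion
convention (with the displaced-volume heat correction) is available via
`dilution="exponential"`; the two differ by a few percent at a typical
36 µL total into a 280 µL cell.

Fitting: bounded nonlinear least squares over (n, log₁₀K_d, ΔH, offset),
K_d in log space with bounds [1e-12, 1e-2] M because the cost surface in
K_d is poorly conditioned at high c; a three-point multistart over
log₁₀K_d ∈ {−9, −7, −5} guards against the multimodality of noisy,
nearly-rectangular isotherms.  Standard errors come from the Jacobian at
the optimum.  A fit whose structured signal (model minus offset) does not
exceed three times the residual RMS is flagged `no_binding` — a null
(non-binding ligand) titration must come back flagged, not as a spurious
tight binder.

Identifiability: at the default design (18 × 2 µL of 1.25 mM ligand into
0.280 mL of 0.05 mM protein), a nanomolar binder sits at Wiseman
c = n·M₀/K_d ≈ 38,000 — far above the c ≲ 1000 window in which K_d is
measurable.  Measured over 100 simulated titrations at 2% noise, the
fitted K_d spans more than four decades (16–84 percentile) while the
stoichiometry n stays within ~1%.  This is a property of the experiment,
not the fitter: the same fitter at truth K_d = 1e-7 M (c = 500) recovers
the median K_d within ~7%.  The package therefore validates quantitative
K_d recovery in the c = 500 regime and validates the nanomolar regime for
what it actually determines — a sharp n, an accurate ΔH, and an
order-of-magnitude K_d.

## Synthetic generators

All fixtures are poly-alanine chains built by a NeRF (natural extension
reference frame) internal-coordinate builder with Engh–Huber-style ideal
bond lengths (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å).  Because
every φ/ψ/ω/N–Cα–C/ϑc is prescribed exactly (the carbonyl O is placed via
the same improper torsion the analysis measures), the stereochemistry
oracles are exact to machine precision rather than approximate.

The bilobed monomer is two helical lobes joined by an extended linker,
with a C-terminal tail whose first residues are extended (the swap hinge)
and whose remainder is helical (the swapped segment).  The swapped dimer
is built by placing chain B as the exact 180° image of chain A about an
axis perpendicular to the body→tail direction; the axis position is found
by a deterministic grid-plus-bisection search such that the tail's
side-chain carbons pack against the opposite body at a set distance
(default 4.0 Å, inside the hydrophobic cutoff) while every other region
pair stays ≥ 6 Å clear of contact range.  That clearance is the
construction guarantee behind the classification tests: all inter-chain
contacts are tail-vs-body by design.  The assembly is exactly two-fold
symmetric (chains superpose at RMSD ~1e-14 Å).

What the toys do *not* emulate: real packing density (the toy interface
buries ~200 Å², an order of magnitude less residue-dense than a real
dimer interface), side chains beyond Cβ, sequence diversity, or
crystallographic noise (coordinate uncertainty is available separately as
isotropic Gaussian perturbation).  Passing tests therefore demonstrate the
*correctness of the measurements* on geometry with known ground truth —
not that real structures will reproduce any particular published value.
Runs on deposited coordinate files use exactly the same code paths via the
pipeline config.

## Pipeline

`run_analysis` executes load → RMSD table → closure analyses → interface
areas → censuses/classification → ligand pocket → sequence metrics →
stereochemistry → optional ITC fit.  Stage failures are recorded by stage
name and independent stages continue.  Configs reject unknown keys
(fail-fast against typos); reports carry a schema version, package
version, and a config digest so re-runs are comparable.  With no input
files the pipeline runs on the synthetic open/closed swapped-dimer pair,
where every measured quantity has a constructed ground truth.

## Problem sizes

The default toy monomer is 75 residues (two 30-residue lobes, 5-residue
linker, 10-residue tail), chosen as the smallest chain on which lobes are
unambiguous, interfaces form, and the full pipeline runs in seconds;
Monte-Carlo studies use 100 replicates, and SASA oracles use 960–4000
sphere points.
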