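# Methods

This note documents the models implemented in vsdkit, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the design decisions taken where the underlying procedures
left room for choice.

## Coordinate frame and units

All structural analyses work in a membrane frame: a unit normal vector
(default the z axis, since the simulated bilayer is planar and normal to z),
a reference level along the normal (by convention the Cα of the
charge-transfer-center phenylalanine, so displacements read as Å above or
below the constriction that S4 charges cross), and slab bounds marking the
membrane. Units are fixed at the I/O boundaries: coordinates in Å,
potentials in mV, energies in kcal/mol, charges in elementary charges e0,
with kB = 0.0019872041 kcal/(mol·K) and a default temperature of 300 K.

Van der Waals radii come from a single bundled Bondi table; unknown elements
fall back to 1.70 Å (carbon). Multi-model PDB is the trajectory interchange
format — text-only, readable everywhere — and OpenDX scalar grids carry the
potential maps. The bundled DX writer and reader use the standard OpenDX
node-centered convention (the origin is the first grid node); trilinear
interpolation between nodes is exactly consistent with how the synthetic
capacitor writes its ramp when the slab edges sit on nodes, which the default
grid geometry guarantees.

## Gating charge from coupling functions

The coupling function f(r) is the dimensionless fraction of the applied
voltage felt at r, estimated per atom from potential maps at several applied
voltages: the finite-difference slope for two maps, the least-squares slope
of φ(r) versus V_m for more. Per-residue contributions are
Q_j = Σ_i q_ij [f_a − f_r] with f_a evaluated at activated-state positions
and f_r at resting-state positions: the atom positions are state properties,
and evaluating each state's field at its own coordinates is what makes a
moving charge (and only physics, not bookkeeping) the source of Q. For
sensitivity checks both states' grids can be evaluated on one frame before
calling the decomposition. The estimator is gauge-invariant: adding any
voltage-independent field to all maps cancels in the slope. Aggregation over
conformations (five per state in the intended workflow, any number accepted)
reports the mean per-residue Q, the standard error across conformations, the
cumulative curve in sequence order, and the per-channel total assuming four
identical independent sensors.

Partial charges are an external per-atom input (CSV in the CLI); force-field
parsing is out of scope. Coupling is computed and applied per atom, not
averaged per residue first.

## Helix geometry

Per-residue helicity h = (1+cos(φ−φα))(1+cos(ψ−ψα))/4 with φα = −57°,
ψα = −47° by default (configurable). It is 1 exactly at the reference
torsions, 0 at the antipodal pair, and needs no secondary-structure
assignment — appropriate for tracking a helix that partially unwinds.
Torsions use the IUPAC sign convention; chain termini and residues with
missing backbone atoms yield NaN records rather than being dropped, so
per-frame lists stay positionally aligned.

Helix axes are the dominant principal component of the Cα cloud (robust down
to 4-residue sub-helices, and matching the "principal axis" convention for
the whole sensor domain). The eigenvector sign is fixed toward the membrane
normal by default; for sub-helix bend angles the axis is oriented along the
chain direction instead, so bends beyond 90° — the regime where the lower S4
sub-helix approaches the membrane plane — are reported as such instead of
folding back. The axis of a short discrete helix wobbles with the fractional
number of turns; measured on the bundled generators this limits bend-angle
recovery to about ±3° for ~20-residue segments, which is the tolerance the
tests assert.

A degenerate covariance (no dominant direction, e.g. an isotropic cloud)
raises rather than returning an arbitrary axis; the threshold is a relative
eigenvalue gap of 1e-6.

Hydration profiles count water oxygens per bin along the normal (default
bin width 3 Å), optionally restricted to a counting volume — a cylinder
around the sensor is the intended use, since no universal counting volume
exists — and summarise across frames as 10/25/50/75/90 percentiles. RMSD
uses Kabsch superposition (scipy's rotation alignment) on an atom
correspondence keyed by (chain, residue, atom name). Contact persistence
calls two residues in contact when any heavy-atom pair is within 4.5 Å
(default) and reports the fraction of frames in contact; 0.5 is a reasonable
persistence cut for "maintained" contacts. Both cutoffs are conventions, not
measured constants, and are exposed as parameters.

## Probe accessibility

Shrake–Rupley SASA with test points on a golden-spiral sphere: deterministic,
so results are bit-stable for a given point count (default 960, within 1% of
the closed form for a lone atom). The probe radius defaults to 2.9 Å, the
effective MTSET head-group size, making "accessible" mean reachable by the
modifying reagent rather than by water. Occluder atoms (e.g. a membrane
slab) can be added without being reported. Accessibility calls compare up-
and down-state per-residue SASA against a threshold (default 5 Å²; there is
no canonical numeric cut, so sweep it when it matters) and classify residues
as gain/loss/unchanged. Whole-residue area is reported by default with a
sidechain-only option. Note the fixed point lattice makes rotation
invariance approximate at the ~0.2% (total area) level for 960 points.

A true "reachable from the intracellular side" criterion would need crevice
connectivity, not just exposed area; that is a known limitation.

## Free energies

BAR solves the self-consistent acceptance balance between forward and
reverse work samples by bracketed root finding (tolerance 1e-8 kcal/mol on
the root) and reports the standard asymptotic variance. The imbalance
function is monotone in ΔG, so the bracket always closes. Two overlap
diagnostics set a warning flag: a large asymptotic variance, and a mean
Fermi acceptance weight below 1e-6 in either direction — the latter is
needed because near-zero-width, mutually inconsistent work distributions can
fool the variance formula. Windows chain additively with errors combined in
quadrature (independent-window assumption; samples are treated as
independent — decorrelation of time series is the caller's responsibility).
The thermodynamic cycle takes independent per-conformation legs for each
state, reports ΔΔG per sensor as the difference of leg means with the two
standard errors propagated (a single-leg state contributes zero spread), and
scales by the subunit count (default 4) for the per-channel value.

The synthetic work generator draws the unique Gaussian pair consistent with
the Crooks fluctuation theorem for a stated ΔG and width σ: forward work
N(ΔG + βσ²/2, σ), reverse work N(−ΔG + βσ²/2, σ). Real alchemical work
distributions are only approximately Gaussian and time-correlated; passing
the recovery tests therefore validates the estimator, not any simulation
protocol.

## Electrophysiology

The relative-Po model is a sum of two Boltzmann components. The symmetric
form (amplitude A1 − O1 in the first component) is the default; the
asymmetric variant with A1 − O2, which some legacy fits used, is available
behind a flag. The model as parameterised has a one-dimensional gauge
freedom — a constant can be shuttled between O1 and the amplitude/offset
pairs without changing the curve — so only the combinations V½ and k per
component, the transition amplitudes A−O, and the asymptotic levels A1+O2
and O1+A2 are identifiable; tests and downstream quantities (polarity index,
predictions) use only identifiable quantities. Fitting is nonlinear least
squares from a documented multi-start grid (quantile-spaced half-points,
both slope-sign combinations, plus a flat start so constant and
single-component data converge); the best residual sum of squares wins, and
components are reported in canonical order V1 ≤ V2 (component 1 = the
hyperpolarization limb). Curves can be normalised to max |Po| = 1 before
fitting, mirroring the relative-Po convention.

The gating polarity index is Po(−150 mV)/Po(+50 mV), evaluated from the
fitted model or by interpolation of measured points (provenance recorded);
a zero denominator is flagged infinite. Correlations against residue
property scales are Pearson on log10(index) by default — the index spans
orders of magnitude — with infinite entries excluded with a warning.
Bundled scales: Kyte–Doolittle hydropathy (1982), Pace–Scholtz helix
propensity (1998), Chou–Fasman turn propensity (1978), each with citation
metadata; any user mapping (e.g. a membrane-derived helical-propensity
scale) can be passed instead.

Modification kinetics fit I(t) = I∞ + (I0 − I∞)e^(−t/τ) in cumulative
exposure time, for potentiating or inhibiting modification, and report
k = 1/(τ·[MTSET]) with delta-method standard errors. If the fitted
amplitude is within twice the residual noise the result is flagged
no-change and k should be read as an upper bound.

## Sequence logos

Column frequencies are over the 20 amino acids with gaps excluded from the
normalisation (configurable); entropy is Shannon H in bits, at most
log2 20 ≈ 4.32. The default stack height is the information content
log2 20 − H, the standard logo convention; a literal inverse-entropy mode
(height ∝ 1/(H+ε), ε = 0.1 bit) is provided because plain inverse
proportionality is undefined for perfectly conserved columns. Consensus
ties break alphabetically and carry a flag. No small-sample entropy
correction is applied.

## Synthetic data: what it emulates, what it does not

Generators are deterministic given a seed (numpy Generator streams; one
master seed can fan out to child seeds). Helices are built from ideal
backbone geometry by natural-extension placement, so the requested (φ, ψ)
are reproduced to machine precision; a requested rise is honoured exactly by
a uniform scale along the axis, which perturbs torsions by well under 1° near
the ideal geometry. The twist per residue follows from the torsions and is
deliberately not an independent parameter. Hinged helices rotate the lower
segment rigidly about an in-membrane-plane axis through the hinge Cα, giving
a known ground-truth bend. The capacitor grid is the textbook planar-
capacitor potential (0 below the slab, V_m above, linear inside) with
optional additive Gaussian noise; its coupling function is analytic, which
is what makes the gating-charge oracle exact. Noise models are additive
Gaussian on grids, potentials and Po values, and multiplicative (2% default)
on peak currents — measurement noise is not characterised in detail
anywhere, so these are conventional choices.

None of the generators produce physically realistic simulation snapshots:
no lipids, no sidechains beyond the backbone, no correlated dynamics, no
non-Gaussian work tails. Passing the closed-loop tests demonstrates that
each analysis recovers known ground truth under its stated model, not that
the model captures every feature of real trajectories or recordings.

## Problem sizes and defaults used in the checks

The shipped checks run at desk scale: 20–40-residue helices, 21×21×61
capacitor grids, 5000 work samples per direction at σ = 1 kcal/mol and
300 K, 20-point modification courses at 2% noise summarised over 5
replicates, 21-point Po–V curves, and alignments of tens of sequences.
These sizes keep the full suite in seconds while leaving estimator noise
well inside the asserted tolerances.
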