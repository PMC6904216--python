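# vsdkit

Analysis toolkit for voltage-sensor gating studies of hyperpolarization-
activated (HCN-type) channels — for computational biophysicists and
electrophysiologists who need the downstream analysis of such a study as
tested, reusable code rather than one-off scripts.

## What it computes

**Gating charge by the coupling-function method.** The coupling function
f(r) = ∂φ(r)/∂V_m is the fraction of the applied transmembrane voltage felt
at point r, estimated from electrostatic-potential maps (OpenDX grids) at two
or more applied voltages. The gating-charge contribution of residue *j*
between the resting (r) and activated (a) states is

    Q_j = Σ_i q_ij [ f_a(r_ij) − f_r(r_ij) ],      Q = Σ_j Q_j

summed over the residue's partial charges, with f evaluated at each state's
atom positions. Charges contribute whether they move through a static field
or sit still in a rearranging field.

**Helix geometry.** Per-residue helicity from backbone torsions,
h = (1+cos(φ−φ_α))(1+cos(ψ−ψ_α))/4; principal axes and sub-helix bend angles
(the S4 helix of these channels breaks into two sub-helices on activation);
crevice hydration profiles along the membrane normal; Kabsch-superposed RMSD
to reference conformations; residue-contact persistence across trajectories.

**Probe accessibility.** Shrake–Rupley solvent-accessible surface area with a
2.9 Å probe (the MTSET head group) and up/down-state accessibility calls.

**Free-energy cycles.** Bennett acceptance ratio (BAR) from forward/reverse
alchemical work samples, chained over λ windows, combined into the mutation
thermodynamic cycle ΔΔG = ΔG_a(wt→mut) − ΔG_r(wt→mut), per voltage sensor
and per (four-subunit) channel.

**Electrophysiology fits.** Sum-of-two-Boltzmann fits of relative Po–V
curves, the gating polarity index Po(−150 mV)/Po(+50 mV), its correlation
with residue property scales (Kyte–Doolittle hydropathy, helix propensity,
turn propensity bundled), and mono-exponential MTSET modification kinetics
with the apparent second-order rate k = 1/(τ·[MTSET]).

**Sequence logos.** Column frequencies, Shannon entropy and stack heights for
aligned S4 sequences, plus consensus calling.

**Synthetic data.** Generators with known ground truth for every input class
(ideal/hinged helices, planar-capacitor grids, water boxes, Crooks-consistent
work samples, Po–V curves, modification time courses, alignments), so every
analysis closes a generate → analyze → recover loop in the tests.

## Worked example

Fit a simulated MTSET modification time course recorded at 1 mM probe and
recover the apparent second-order modification rate:

```python
from vsdkit.synthetic import make_modification_course
from vsdkit.ephys import fit_modification_rate

t, current = make_modification_course(440.0, concentration=1e-3,
                                      timepoints=20, noise_frac=0.02, seed=0)
fit = fit_modification_rate(t, current, concentration=1e-3)
print(f"tau = {fit.tau:.3f} s, k = {fit.k2nd:.1f} M^-1 s^-1")
```

```
tau = 2.232 s, k = 448.0 M^-1 s^-1
```

The generator's true rate was 440 M⁻¹s⁻¹ (an activated-state charge-transfer-
center cysteine); the fit recovers it within the 2% current noise. The same
loop from the shell:

```sh
vsdkit synth modification_course --seed 0 -o course.csv
vsdkit ephys mtset-rate --csv course.csv --concentration 0.001
```

And a free-energy cycle from synthetic work samples:

```python
from vsdkit.synthetic import make_work_samples
from vsdkit.fep import bar_estimate, thermodynamic_cycle

leg_a = bar_estimate(make_work_samples(1.2, sigma=1.0, n=5000, seed=71)).dg
leg_r = bar_estimate(make_work_samples(0.5, sigma=1.0, n=5000, seed=72)).dg
print(thermodynamic_cycle([leg_a], [leg_r], subunits=4).summary())
```

```
Thermodynamic cycle (wt -> mutant)
  dG activated  :    1.194 kcal/mol (1 leg(s))
  dG resting    :    0.477 kcal/mol (1 leg(s))
  ddG per VSD   :    0.718 +/- 0.000 kcal/mol
  ddG per channel (4 subunits):    2.870 kcal/mol
```

A positive ΔΔG means the mutation disfavors the activated (bent-S4) state.

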