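"""Synthetic-data generators with known ground truth for every input class
the analyses consume: ideal and hinged α-helices, planar-capacitor potential
grids, water boxes, Crooks-consistent alchemical work samples, two-component
Boltzmann Po–V curves, mono-exponential probe-modification time courses, and
alignments with controlled column conservation.

Each generator's ground truth is recoverable by the corresponding analysis
operation, which closes the generator/analyzer loop the test suite relies on.
All randomness flows through numpy Generators; the same seed reproduces the
same output byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import ConformationFrame, PotentialGrid, vdw_radius
from .ephys import BoltzmannFit, PoVCurve
from .fep import DEFAULT_TEMPERATURE, KB_KCAL_PER_MOL_K, WorkSamples

AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

# ideal backbone geometry (Engh-Huber): bond lengths in Å, angles in degrees
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8}
_OMEGA = 180.0


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension placement of atom D from A-B-C internal coordinates."""
    theta = math.radians(angle_deg)
    chi = -math.radians(torsion_deg)  # IUPAC sign convention
    w = c - b
    w = w / np.linalg.norm(w)
    u = b - a
    n = np.cross(u, w)
    n = n / np.linalg.norm(n)
    m = np.cross(n, w)
    d = bond * (-math.cos(theta) * w
                + math.sin(theta) * (math.cos(chi) * m + math.sin(chi) * n))
    return c + d


def _build_backbone(n_residues, phi, psi):
    """Backbone N, CA, C, O coordinates from uniform (φ, ψ), ω = 180°."""
    coords = {}
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[(0, "N")], coords[(0, "CA")], coords[(0, "C")] = n0, ca0, c0
    for i in range(n_residues):
        n_i = coords[(i, "N")]
        ca_i = coords[(i, "CA")]
        c_i = coords[(i, "C")]
        if i + 1 < n_residues:
            n_next = _place_atom(n_i, ca_i, c_i, _BOND["C-N"],
                                 _ANGLE["CA-C-N"], psi)
            ca_next = _place_atom(ca_i, c_i, n_next, _BOND["N-CA"],
                                  _ANGLE["C-N-CA"], _OMEGA)
            c_next = _place_atom(c_i, n_next, ca_next, _BOND["CA-C"],
                                 _ANGLE["N-CA-C"], phi)
            coords[(i + 1, "N")] = n_next
            coords[(i + 1, "CA")] = ca_next
            coords[(i + 1, "C")] = c_next
        # carbonyl O anti to the next amide N (torsion ψ + 180 about N-CA-C)
        coords[(i, "O")] = _place_atom(n_i, ca_i, c_i, _BOND["C-O"],
                                       _ANGLE["CA-C-O"], psi + 180.0)
    return coords


def _frame_from_backbone(coords, n_residues, chain_id="A", resname="ALA",
                         state_label="") -> ConformationFrame:
    order = ("N", "CA", "C", "O")
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    names, els, resids, xyz = [], [], [], []
    for i in range(n_residues):
        for atom in order:
            names.append(atom)
            els.append(elements[atom])
            resids.append(i + 1)
            xyz.append(coords[(i, atom)])
    els = np.array(els)
    return ConformationFrame(
        atom_ids=np.arange(1, len(names) + 1),
        coordinates=np.array(xyz),
        element=els,
        vdw_radius=np.array([vdw_radius(e) for e in els]),
        residue_index=np.array(resids),
        residue_name=np.array([resname] * len(names)),
        chain_id=np.array([chain_id] * len(names)),
        atom_name=np.array(names),
        state_label=state_label,
    )


def _align_axis_to_z(frame: ConformationFrame) -> ConformationFrame:
    ca = frame.coordinates[frame.atom_name == "CA"]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # point the axis from the first toward the last residue, then up
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    out = frame.translated(-frame.coordinates.mean(axis=0))
    out.coordinates = rot.apply(out.coordinates)
    return out


def make_helix(n_residues: int, rise: float = None, phi: float = -57.0,
               psi: float = -47.0, chain_id: str = "A",
               state_label: str = "") -> ConformationFrame:
    """Ideal helix backbone (N, CA, C, O) with the stated internal torsions.

    The helix axis is aligned with +z and centered at the origin. The twist
    per residue follows from (φ, ψ) and is not an independent parameter. If
    ``rise`` is given, coordinates are scaled uniformly along z so the mean
    Cα rise per residue matches it exactly — a small affine distortion of the
    torsions; leave it None to preserve (φ, ψ) to machine precision.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    for name, val in (("phi", phi), ("psi", psi)):
        if not -180.0 < val <= 180.0:
            raise ValueError(f"{name} must lie in (-180, 180]")
    frame = _frame_from_backbone(_build_backbone(n_residues, phi, psi),
                                 n_residues, chain_id=chain_id,
                                 state_label=state_label)
    frame = _align_axis_to_z(frame)
    if rise is not None:
        if rise <= 0:
            raise ValueError("rise must be positive")
        ca_z = frame.coordinates[frame.atom_name == "CA"][:, 2]
        current = (ca_z.max() - ca_z.min()) / (n_residues - 1)
        frame.coordinates[:, 2] *= rise / current
    return frame


def make_hinged_helix(n_residues: int, hinge_residue: int, bend: float,
                      phi: float = -57.0, psi: float = -47.0,
                      chain_id: str = "A", state_label: str = ""
                      ) -> ConformationFrame:
    """Helix with its lower segment bent by ``bend`` degrees at a hinge Cα.

    Residues below the hinge (1-based index) are rotated rigidly about an
    axis through the hinge Cα lying in the membrane plane (x), so the angle
    between the two segments' principal axes equals the requested bend.
    """
    if not 1 < hinge_residue < n_residues:
        raise ValueError("hinge must be strictly inside the helix")
    if not 0.0 <= bend <= 180.0:
        raise ValueError("bend must be within [0, 180] degrees")
    frame = make_helix(n_residues, phi=phi, psi=psi, chain_id=chain_id,
                       state_label=state_label)
    if bend == 0.0:
        return frame
    hinge_mask = frame.atom_mask(residue_indices=[hinge_residue],
                                 atom_names=["CA"])
    pivot = frame.coordinates[hinge_mask][0]
    # lower segment = residues below the hinge along z (smaller residue index
    # sits at lower z after axis alignment)
    lower = frame.residue_index < hinge_residue
    rot = Rotation.from_rotvec(np.radians(bend) * np.array([1.0, 0.0, 0.0]))
    coords = frame.coordinates.copy()
    coords[lower] = rot.apply(coords[lower] - pivot) + pivot
    frame.coordinates = coords
    return frame


def make_capacitor_grid(box=(40.0, 40.0, 60.0), shape=(21, 21, 61),
                        slab=(15.0, 45.0), voltage: float = 100.0,
                        noise_sd: float = 0.0, seed=0,
                        origin=(0.0, 0.0, 0.0)) -> PotentialGrid:
    """Planar-capacitor potential: 0 below the slab, Vm above, linear inside.

    Emulates the potential map of a membrane slab of thickness z1−z0 under an
    applied transmembrane voltage (mV). Optional additive Gaussian noise.
    Trilinear interpolation reproduces the ramp exactly only when z0 and z1
    fall on grid nodes, as they do for the default geometry.
    """
    z0, z1 = slab
    lo = np.asarray(origin, dtype=float)
    if not (lo[2] <= z0 < z1 <= lo[2] + box[2]):
        raise ValueError("slab must lie inside the box with z0 < z1")
    shape = tuple(int(s) for s in shape)
    spacing = np.array([box[d] / (shape[d] - 1) for d in range(3)])
    z = lo[2] + spacing[2] * np.arange(shape[2])
    ramp = np.clip((z - z0) / (z1 - z0), 0.0, 1.0) * voltage
    values = np.broadcast_to(ramp, shape).copy()
    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, size=shape)
    return PotentialGrid(origin=lo, spacing=spacing, values=values,
                         applied_voltage=float(voltage))


def make_water_box(lo, hi, n_waters: int, seed=0) -> ConformationFrame:
    """Water oxygens placed uniformly in an axis-aligned box."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("box corners must satisfy lo < hi")
    if n_waters < 1:
        raise ValueError("need at least one water")
    coords = _rng(seed).uniform(lo, hi, size=(n_waters, 3))
    n = n_waters
    return ConformationFrame(
        atom_ids=np.arange(1, n + 1),
        coordinates=coords,
        element=np.array(["O"] * n),
        vdw_radius=np.full(n, vdw_radius("O")),
        residue_index=np.arange(1, n + 1),
        residue_name=np.array(["HOH"] * n),
        chain_id=np.array(["W"] * n),
        atom_name=np.array(["O"] * n),
    )


def make_pov_curve(truth: BoltzmannFit, voltages=None, noise_sd: float = 0.0,
                   seed=0, label: str = "synthetic") -> PoVCurve:
    """Relative Po–V curve from known two-Boltzmann parameters plus noise."""
    if voltages is None:
        voltages = np.arange(-150.0, 60.0, 10.0)
    voltages = np.asarray(voltages, dtype=float)
    y = truth.predict(voltages)
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, size=y.shape)
    return PoVCurve(voltages, y, construct_label=label)


def make_work_samples(dg_true: float, sigma: float, n: int,
                      temperature: float = DEFAULT_TEMPERATURE, seed=0,
                      window_index: int = 0) -> WorkSamples:
    """Crooks-consistent Gaussian work samples with known true ΔG (kcal/mol).

    Forward work ~ N(ΔG + βσ²/2, σ) and reverse work ~ N(−ΔG + βσ²/2, σ),
    the unique Gaussian pair satisfying the Crooks fluctuation theorem for
    the given ΔG and width.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    beta = 1.0 / (KB_KCAL_PER_MOL_K * temperature)
    dissipation = beta * sigma ** 2 / 2.0
    wf = rng.normal(dg_true + dissipation, sigma, size=n)
    wr = rng.normal(-dg_true + dissipation, sigma, size=n)
    return WorkSamples(wf, wr, temperature=temperature,
                       window_index=window_index)


def make_modification_course(k2nd_true: float, concentration: float,
                             timepoints=20, noise_frac: float = 0.02, seed=0,
                             i0: float = 1.0, iinf: float = 3.0):
    """Mono-exponential modification time course with known true rate.

    ``k2nd_true`` in M⁻¹s⁻¹ and ``concentration`` in mol/L set
    τ = 1/(k·C). ``timepoints`` is either a count (points span ~4τ) or an
    explicit array of cumulative exposure times (s). Noise is multiplicative
    Gaussian on the peak current. Returns (t, current).
    """
    if k2nd_true <= 0 or concentration <= 0:
        raise ValueError("rate and concentration must be positive")
    tau = 1.0 / (k2nd_true * concentration)
    if np.isscalar(timepoints):
        t = np.linspace(0.0, 4.0 * tau, int(timepoints))
    else:
        t = np.asarray(timepoints, dtype=float)
    current = iinf + (i0 - iinf) * np.exp(-t / tau)
    if noise_frac > 0:
        current = current * (1.0 + _rng(seed).normal(0.0, noise_frac,
                                                     size=current.shape))
    return t, current


def make_msa(consensus: str, conservation, n_sequences: int, seed=0):
    """Alignment of ``n_sequences`` around a consensus with controlled
    per-column conservation (probability of the consensus residue; other
    residues drawn uniformly). Returns [(id, sequence), ...].
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    consensus = consensus.upper()
    cons = np.broadcast_to(np.asarray(conservation, dtype=float),
                           (len(consensus),))
    if np.any((cons < 0) | (cons > 1)):
        raise ValueError("conservation must lie in [0, 1]")
    rng = _rng(seed)
    seqs = []
    for s in range(n_sequences):
        chars = []
        for pos, aa in enumerate(consensus):
            if rng.random() < cons[pos]:
                chars.append(aa)
            else:
                alternatives = [x for x in AA20 if x != aa]
                chars.append(alternatives[rng.integers(len(alternatives))])
        seqs.append((f"seq{s + 1}", "".join(chars)))
    return seqs


def write_fasta(msa, path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa:
            fh.write(f">{name}\n{seq}\n")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic dataset (for the CLI)."""

    seed: int
    kind: str
    parameters: dict

    _KINDS = ("helix", "hinged_helix", "capacitor_grid", "water_box",
              "pov_curve", "work_samples", "modification_course", "msa")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind '{self.kind}'")

    @classmethod
    def from_json(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=int(d["seed"]), kind=d["kind"],
                   parameters=d.get("parameters", {}))


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to its generator, seeding from the spec."""
    p = dict(spec.parameters)
    defaults = {
        "helix": {"n_residues": 30},
        "hinged_helix": {"n_residues": 30, "hinge_residue": 15, "bend": 80.0},
        "capacitor_grid": {},
        "water_box": {"lo": (0.0, 0.0, 0.0), "hi": (30.0, 30.0, 30.0),
                      "n_waters": 300},
        "pov_curve": {"truth": {"a1": 1.0, "o1": 0.0, "v1": -90.0, "k1": 0.08,
                                "a2": 0.3, "o2": 0.0, "v2": 0.0, "k2": -0.08}},
        "work_samples": {"dg_true": 1.0, "sigma": 1.0, "n": 5000},
        "modification_course": {"k2nd_true": 440.0, "concentration": 1e-3},
        "msa": {"consensus": "ILRLWRVGRVFRIL", "conservation": 0.8,
                "n_sequences": 50},
    }
    table = {
        "helix": make_helix,
        "hinged_helix": make_hinged_helix,
        "capacitor_grid": make_capacitor_grid,
        "water_box": make_water_box,
        "pov_curve": lambda **kw: make_pov_curve(
            BoltzmannFit(**kw.pop("truth")), **kw),
        "work_samples": make_work_samples,
        "modification_course": make_modification_course,
        "msa": make_msa,
    }
    p = {**defaults[spec.kind], **p}
    fn = table[spec.kind]
    if spec.kind not in ("helix", "hinged_helix"):
        p.setdefault("seed", spec.seed)
    return fn(**p)
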