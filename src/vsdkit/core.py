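"""Domain containers and file I/O shared by every analysis stage.

The membrane coordinate frame used throughout the package puts the bilayer
normal along a unit vector (z by default) and measures positions along that
normal relative to a named reference atom — conventionally the Cα of the
charge-transfer-center phenylalanine, so that gating-charge displacements read
directly as "Å above/below the charge transfer center".

Unit policy, applied at I/O boundaries: coordinates in Å, electrostatic
potentials in mV, energies in kcal/mol, charge in elementary charges e0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

# Bondi (1964) van der Waals radii, Å. Elements outside this table get
# DEFAULT_VDW_RADIUS; the choice matters only for SASA, where unknown heavy
# atoms are rare in protein inputs.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "K": 2.75, "NA": 2.27, "MG": 1.73, "ZN": 1.39,
    "CA": 2.31, "FE": 2.00,
}
DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for an element symbol (Å)."""
    return BONDI_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)


@dataclass
class ConformationFrame:
    """One structural snapshot: atom coordinates plus residue/chain metadata.

    Arrays are parallel over atoms. ``state_label`` is a free tag such as
    "resting" or "activated" used to keep track of which conformational state
    a frame represents.
    """

    atom_ids: np.ndarray
    coordinates: np.ndarray          # (n_atoms, 3), Å
    element: np.ndarray
    vdw_radius: np.ndarray           # Å
    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    atom_name: np.ndarray
    state_label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        if np.any(self.vdw_radius <= 0):
            raise ValueError("vdw_radius must be positive")
        for name in ("atom_ids", "element", "residue_index", "residue_name",
                     "chain_id", "atom_name"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.n_atoms:
                raise ValueError(f"{name} length does not match coordinates")
            setattr(self, name, arr)
        self.residue_index = self.residue_index.astype(int)
        # residue indices must be non-decreasing within a chain
        for ch in np.unique(self.chain_id):
            resids = self.residue_index[self.chain_id == ch]
            if np.any(np.diff(resids) < 0):
                raise ValueError(f"residue indices not ordered in chain {ch}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def atom_mask(self, chain_id=None, residue_indices=None, atom_names=None,
                  elements=None) -> np.ndarray:
        """Boolean mask over atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_id == chain_id
        if residue_indices is not None:
            mask &= np.isin(self.residue_index, list(residue_indices))
        if atom_names is not None:
            mask &= np.isin(self.atom_name, list(atom_names))
        if elements is not None:
            mask &= np.isin(self.element, list(elements))
        return mask

    def subset(self, mask: np.ndarray) -> "ConformationFrame":
        return ConformationFrame(
            atom_ids=self.atom_ids[mask],
            coordinates=self.coordinates[mask],
            element=self.element[mask],
            vdw_radius=self.vdw_radius[mask],
            residue_index=self.residue_index[mask],
            residue_name=self.residue_name[mask],
            chain_id=self.chain_id[mask],
            atom_name=self.atom_name[mask],
            state_label=self.state_label,
        )

    def translated(self, shift) -> "ConformationFrame":
        out = replace(self)
        out.coordinates = self.coordinates + np.asarray(shift, dtype=float)
        return out

    def residues(self):
        """Iterate (chain_id, residue_index, residue_name, atom index array)."""
        keys = list(zip(self.chain_id.tolist(), self.residue_index.tolist()))
        seen = {}
        for i, key in enumerate(keys):
            seen.setdefault(key, []).append(i)
        for (ch, ri), idx in seen.items():
            idx = np.asarray(idx)
            yield ch, ri, str(self.residue_name[idx[0]]), idx


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: normal direction, reference level, slab."""

    normal: tuple = (0.0, 0.0, 1.0)
    reference_z: float = 0.0
    slab_bounds: tuple = (-15.0, 15.0)

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector")
        if not self.slab_bounds[0] < self.slab_bounds[1]:
            raise ValueError("slab_bounds must be ordered (inner, outer)")

    @classmethod
    def from_reference_atom(cls, frame: ConformationFrame, chain_id, residue_index,
                            atom_name="CA", normal=(0.0, 0.0, 1.0),
                            slab_bounds=(-15.0, 15.0)) -> "MembraneFrame":
        """Anchor reference_z at a named atom, e.g. the charge-transfer-center Cα."""
        mask = frame.atom_mask(chain_id=chain_id, residue_indices=[residue_index],
                               atom_names=[atom_name])
        if not mask.any():
            raise ValueError(
                f"reference atom {atom_name} of residue {residue_index} not found")
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        z = float(frame.coordinates[mask][0] @ n)
        return cls(normal=tuple(n), reference_z=z, slab_bounds=tuple(slab_bounds))


@dataclass(frozen=True)
class ResidueSelection:
    """A named set of residues on one chain, e.g. the S4 helix or its charges."""

    chain_id: str
    residue_indices: tuple
    role: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residue_indices",
                           tuple(sorted(set(int(i) for i in self.residue_indices))))
        if len(self.residue_indices) == 0:
            raise ValueError("selection must contain at least one residue")

    def mask(self, frame: ConformationFrame, atom_names=None) -> np.ndarray:
        m = frame.atom_mask(chain_id=self.chain_id,
                            residue_indices=self.residue_indices,
                            atom_names=atom_names)
        present = set(frame.residue_index[frame.chain_id == self.chain_id].tolist())
        missing = [i for i in self.residue_indices if i not in present]
        if missing:
            raise ValueError(f"residues not present in frame: {missing}")
        return m


@dataclass
class PotentialGrid:
    """Regular scalar grid of electrostatic potential φ(r), in mV.

    ``origin`` is the coordinate of the first grid node (standard OpenDX
    convention); node i,j,k sits at origin + (i,j,k)*spacing.
    ``applied_voltage`` is the transmembrane potential Vm (mV) under which the
    potential map was computed.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray            # (nx, ny, nz), mV
    applied_voltage: float        # mV

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive on all axes")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    def axes(self):
        return tuple(self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
                     for d in range(3))

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of φ at Cartesian points (Å) -> mV."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        interp = RegularGridInterpolator(self.axes(), self.values,
                                         method="linear", bounds_error=True)
        try:
            return interp(points)
        except ValueError:
            lo = self.origin
            hi = self.origin + self.spacing * (np.array(self.values.shape) - 1)
            bad = np.where(np.any((points < lo) | (points > hi), axis=1))[0]
            raise ValueError(f"atoms outside grid bounds: indices {bad.tolist()}")


# --------------------------------------------------------------------------
# PDB I/O (biotite behind the scenes)
# --------------------------------------------------------------------------

def _frame_from_atom_array(atoms, state_label="") -> ConformationFrame:
    elements = np.array([e if e else "C" for e in atoms.element])
    return ConformationFrame(
        atom_ids=np.arange(1, atoms.array_length() + 1),
        coordinates=np.asarray(atoms.coord, dtype=float),
        element=elements,
        vdw_radius=np.array([vdw_radius(e) for e in elements]),
        residue_index=np.asarray(atoms.res_id, dtype=int),
        residue_name=np.asarray(atoms.res_name),
        chain_id=np.asarray(atoms.chain_id),
        atom_name=np.asarray(atoms.atom_name),
        state_label=state_label,
    )


def read_structure(path, model_index: int = 0, state_label="") -> ConformationFrame:
    """Read one model of a (possibly multi-model) PDB file.

    ``model_index`` is zero-based; multi-model PDB files serve as the
    trajectory interchange format of this package.
    """
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if not 0 <= model_index < n_models:
        raise IndexError(
            f"model not found: index {model_index}, file has {n_models} model(s)")
    try:
        atoms = pdb.get_structure(model=model_index + 1)
    except Exception as exc:
        raise ValueError(f"unparsable ATOM records in {path}: {exc}") from exc
    return _frame_from_atom_array(atoms, state_label=state_label)


def read_trajectory(path, state_label="") -> list:
    """Read every model of a multi-model PDB as a list of frames."""
    pdb = PDBFile.read(str(path))
    return [
        _frame_from_atom_array(pdb.get_structure(model=m + 1), state_label)
        for m in range(pdb.get_model_count())
    ]


def _atom_array_from_frame(frame: ConformationFrame):
    atoms = struc.AtomArray(frame.n_atoms)
    atoms.coord = frame.coordinates.astype(np.float32)
    atoms.chain_id = frame.chain_id.astype("U4")
    atoms.res_id = frame.residue_index
    atoms.res_name = frame.residue_name.astype("U5")
    atoms.atom_name = frame.atom_name.astype("U6")
    atoms.element = frame.element.astype("U2")
    atoms.hetero = np.isin(frame.residue_name, ["HOH", "WAT", "TIP3"])
    return atoms


def write_structure(frames, path) -> None:
    """Write one frame or a sequence of frames as a (multi-model) PDB file."""
    if isinstance(frames, ConformationFrame):
        frames = [frames]
    arrays = [_atom_array_from_frame(f) for f in frames]
    if len(arrays) == 1:
        payload = arrays[0]
    else:
        payload = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(payload)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# OpenDX scalar grid I/O
# --------------------------------------------------------------------------

def read_potential_grid(path, applied_voltage: float) -> PotentialGrid:
    """Read an OpenDX scalar grid and tag it with its applied voltage (mV)."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    counts = origin = None
    deltas = []
    data_start = None
    for i, ln in enumerate(lines):
        tok = ln.split()
        if ln.startswith("object 1"):
            if "counts" not in tok:
                raise ValueError("malformed DX header: missing grid counts")
            j = tok.index("counts")
            counts = [int(x) for x in tok[j + 1:j + 4]]
        elif ln.startswith("origin"):
            origin = [float(x) for x in tok[1:4]]
        elif ln.startswith("delta"):
            deltas.append([float(x) for x in tok[1:4]])
        elif "data follows" in ln:
            data_start = i + 1
            break
    if counts is None or origin is None or len(deltas) != 3 or data_start is None:
        raise ValueError(f"malformed DX header in {path}")
    delta = np.asarray(deltas)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise ValueError("only axis-aligned DX grids are supported")
    spacing = np.diag(delta)
    flat = np.array(
        [float(x) for ln in lines[data_start:] for x in ln.split()
         if not ln.startswith("object") and not ln.startswith("attribute")])
    n = int(np.prod(counts))
    if flat.size < n:
        raise ValueError(f"DX data truncated: expected {n} values, got {flat.size}")
    values = flat[:n].reshape(counts)  # DX order: z varies fastest
    if np.any(np.isnan(values)):
        raise ValueError("DX grid contains NaN values")
    return PotentialGrid(origin=origin, spacing=spacing, values=values,
                         applied_voltage=float(applied_voltage))


def write_potential_grid(grid: PotentialGrid, path) -> None:
    """Write a grid in OpenDX scalar format (node-centered, z fastest)."""
    nx, ny, nz = grid.values.shape
    buf = io.StringIO()
    buf.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    buf.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
    buf.write(f"delta {grid.spacing[0]:.6f} 0.0 0.0\n")
    buf.write(f"delta 0.0 {grid.spacing[1]:.6f} 0.0\n")
    buf.write(f"delta 0.0 0.0 {grid.spacing[2]:.6f}\n")
    buf.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    buf.write(f"object 3 class array type double rank 0 items {nx * ny * nz} "
              "data follows\n")
    flat = grid.values.ravel()
    for i in range(0, flat.size, 3):
        buf.write(" ".join(f"{v:.8e}" for v in flat[i:i + 3]) + "\n")
    buf.write('attribute "dep" string "positions"\n')
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# --------------------------------------------------------------------------
# Membrane-normal projection
# --------------------------------------------------------------------------

def project_onto_normal(frame: ConformationFrame, selection: ResidueSelection,
                        mframe: MembraneFrame, atom_name: str = "CA") -> dict:
    """Displacement of a named atom of each selected residue along the
    membrane normal, relative to the frame's reference level (Å).

    Returns {residue_index: z_displacement}. Raises if any selected residue
    lacks the named atom.
    """
    n = np.asarray(mframe.normal)
    out = {}
    for resid in selection.residue_indices:
        mask = frame.atom_mask(chain_id=selection.chain_id,
                               residue_indices=[resid], atom_names=[atom_name])
        if not mask.any():
            raise ValueError(f"atom {atom_name} missing in residue {resid} "
                             f"(chain {selection.chain_id})")
        out[resid] = float(frame.coordinates[mask][0] @ n - mframe.reference_z)
    return out
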