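"""Helix geometry analyses: backbone torsions and per-residue helicity,
principal axes and bend angles, crevice hydration profiles, RMSD to reference
conformations, and contact persistence across a trajectory.

The helicity metric scores each residue by how close its (φ, ψ) pair lies to
the torsions of a perfect α-helix:

    h = (1 + cos(φ − φα)) (1 + cos(ψ − ψα)) / 4

which is 1 exactly at (φα, ψα) and falls smoothly to 0 at the antipodal
torsion pair. It requires no secondary-structure assignment and behaves
gracefully for partially unwound helices, which is why it is used here to
track the S4 helix breaking into two sub-helices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import ConformationFrame, MembraneFrame, ResidueSelection


@dataclass(frozen=True)
class TorsionRecord:
    residue_index: int
    phi: float   # degrees, NaN if undefined
    psi: float   # degrees, NaN if undefined

    @property
    def defined(self) -> bool:
        return math.isfinite(self.phi) and math.isfinite(self.psi)


@dataclass(frozen=True)
class HelicityParams:
    """Reference torsions of a perfect α-helix (degrees)."""
    phi_alpha: float = -57.0
    psi_alpha: float = -47.0


@dataclass
class HydrationProfile:
    bin_edges: np.ndarray        # Å along the membrane normal
    counts: np.ndarray           # (n_frames, n_bins) water counts
    percentiles: pd.DataFrame    # columns p10..p90, one row per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple     # (chain, resid)
    residue_b: tuple
    persistence: float   # fraction of frames in contact, [0, 1]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return math.degrees(math.atan2(y, x))


def _backbone_atom(frame, chain, resid, name):
    mask = frame.atom_mask(chain_id=chain, residue_indices=[resid],
                           atom_names=[name])
    if not mask.any():
        return None
    return frame.coordinates[mask][0]


def compute_torsions(frames, selection: ResidueSelection):
    """Backbone φ/ψ per selected residue for each frame.

    Chain termini (and residues with missing backbone atoms) yield records
    with NaN angles rather than being dropped, so callers can align torsion
    lists across frames positionally.
    """
    if isinstance(frames, ConformationFrame):
        frames = [frames]
    results = []
    for frame in frames:
        records = []
        for resid in selection.residue_indices:
            ch = selection.chain_id
            n = _backbone_atom(frame, ch, resid, "N")
            ca = _backbone_atom(frame, ch, resid, "CA")
            c = _backbone_atom(frame, ch, resid, "C")
            c_prev = _backbone_atom(frame, ch, resid - 1, "C")
            n_next = _backbone_atom(frame, ch, resid + 1, "N")
            phi = psi = float("nan")
            if all(p is not None for p in (c_prev, n, ca, c)):
                phi = dihedral(c_prev, n, ca, c)
            if all(p is not None for p in (n, ca, c, n_next)):
                psi = dihedral(n, ca, c, n_next)
            records.append(TorsionRecord(resid, phi, psi))
        results.append(records)
    return results


def helicity(torsion, params: HelicityParams = HelicityParams()) -> float:
    """Per-residue helicity h ∈ [0, 1] from a TorsionRecord (NaN if undefined)."""
    if not torsion.defined:
        return float("nan")
    dphi = math.radians(torsion.phi - params.phi_alpha)
    dpsi = math.radians(torsion.psi - params.psi_alpha)
    return (1.0 + math.cos(dphi)) * (1.0 + math.cos(dpsi)) / 4.0


def helicity_profile(frames, selection: ResidueSelection,
                     params: HelicityParams = HelicityParams()) -> pd.DataFrame:
    """Helicity per residue summarised over frames.

    Returns a DataFrame (residue, hp, median, p25, p75) where hp is the mean;
    residues with undefined torsions in every frame carry NaN.
    """
    per_frame = compute_torsions(frames, selection)
    h = np.array([[helicity(t, params) for t in recs] for recs in per_frame])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN termini
        df = pd.DataFrame({
            "residue": list(selection.residue_indices),
            "hp": np.nanmean(h, axis=0),
            "median": np.nanmedian(h, axis=0),
            "p25": np.nanpercentile(h, 25, axis=0),
            "p75": np.nanpercentile(h, 75, axis=0),
        })
    return df


def principal_axis(frame: ConformationFrame, selection: ResidueSelection,
                   normal=(0.0, 0.0, 1.0), anisotropy_tol: float = 1e-6,
                   orient: str = "normal") -> np.ndarray:
    """Dominant principal axis of the selection's Cα cloud (unit vector).

    The eigenvector sign is fixed either toward the positive membrane normal
    (``orient="normal"``, the default) or along the chain direction from the
    first to the last selected residue (``orient="sequence"``, needed when
    segments may tilt past 90° from the normal). Raises if the covariance is
    degenerate (no dominant direction).
    """
    mask = selection.mask(frame, atom_names=["CA"])
    coords = frame.coordinates[mask]
    if coords.shape[0] < 3:
        raise ValueError("principal axis needs at least 3 Cα atoms")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] <= 0 or (evals[2] - evals[1]) / evals[2] < anisotropy_tol:
        raise ValueError("degenerate point cloud: no dominant principal axis")
    axis = evecs[:, 2]
    if orient == "sequence":
        reference = coords[-1] - coords[0]
    elif orient == "normal":
        reference = np.asarray(normal, dtype=float)
    else:
        raise ValueError("orient must be 'normal' or 'sequence'")
    if axis @ reference < 0:
        axis = -axis
    return axis


def bend_angle(frame: ConformationFrame, sub_helix: ResidueSelection,
               reference_axis, normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, [0, 180]) between a sub-helix principal axis and a
    reference axis, e.g. the principal axis of the whole voltage sensor.

    The sub-helix axis is oriented along its chain direction so bends past
    90° are reported as such rather than folding back.
    """
    if len(sub_helix.residue_indices) < 4:
        raise ValueError("sub-helix needs at least 4 residues")
    axis = principal_axis(frame, sub_helix, normal=normal, orient="sequence")
    ref = np.asarray(reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    cosang = float(np.clip(axis @ ref, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


class CylinderRegion:
    """Counting volume: a cylinder along the membrane normal (z by default)."""

    def __init__(self, center_xy, radius, normal=(0.0, 0.0, 1.0)):
        self.center_xy = np.asarray(center_xy, dtype=float)
        self.radius = float(radius)
        self.normal = np.asarray(normal, dtype=float)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        n = self.normal
        along = coords @ n
        radial = coords - np.outer(along, n)
        ref = self.center_xy - (self.center_xy @ n) * n
        d = np.linalg.norm(radial - ref, axis=1)
        return d <= self.radius


class BoxRegion:
    """Counting volume: an axis-aligned box given by (lo, hi) corners."""

    def __init__(self, lo, hi):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        return np.all((coords >= self.lo) & (coords <= self.hi), axis=1)


def hydration_profile(frames, water_selection: ResidueSelection,
                      mframe: MembraneFrame, bin_width: float = 3.0,
                      region=None, z_range=None) -> HydrationProfile:
    """Water count along the membrane normal, summarised across frames.

    Counts water oxygens of the selected water residues, optionally restricted
    to a counting region (cylinder around the voltage sensor by default usage).
    Percentiles 10/25/50/75/90 are taken across frames per bin, matching the
    shaded-band presentation of crevice hydration.
    """
    if isinstance(frames, ConformationFrame):
        frames = [frames]
    if len(frames) == 0:
        raise ValueError("hydration_profile requires at least one frame")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = np.asarray(mframe.normal)

    all_z = []
    for frame in frames:
        mask = water_selection.mask(frame) & (frame.element == "O")
        coords = frame.coordinates[mask]
        if region is not None:
            coords = coords[region.contains(coords)]
        all_z.append(coords @ n - mframe.reference_z)
    if z_range is None:
        zmin = min(z.min() for z in all_z if z.size)
        zmax = max(z.max() for z in all_z if z.size)
    else:
        zmin, zmax = z_range
    nbins = max(1, int(math.ceil((zmax - zmin) / bin_width)))
    edges = zmin + bin_width * np.arange(nbins + 1)

    counts = np.array([np.histogram(z, bins=edges)[0] for z in all_z])
    pct = np.percentile(counts, [10, 25, 50, 75, 90], axis=0)
    table = pd.DataFrame(pct.T, columns=["p10", "p25", "p50", "p75", "p90"])
    table.insert(0, "z_center", 0.5 * (edges[:-1] + edges[1:]))
    return HydrationProfile(bin_edges=edges, counts=counts, percentiles=table)


def _matched_coordinates(frame, reference, selection):
    def keyed(f):
        mask = selection.mask(f)
        keys = list(zip(f.chain_id[mask], f.residue_index[mask], f.atom_name[mask]))
        return dict(zip(keys, f.coordinates[mask]))

    a, b = keyed(frame), keyed(reference)
    unmatched = set(a) ^ set(b)
    if unmatched:
        residues = sorted({(k[0], int(k[1])) for k in unmatched})
        raise ValueError(f"atom correspondence mismatch in residues {residues}")
    keys = sorted(a)
    return (np.array([a[k] for k in keys]), np.array([b[k] for k in keys]))


def rmsd_to_reference(frame: ConformationFrame, reference: ConformationFrame,
                      selection: ResidueSelection, superpose: bool = True) -> float:
    """RMSD (Å) over the selection, with optional Kabsch superposition."""
    x, y = _matched_coordinates(frame, reference, selection)
    if superpose:
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot, _ = Rotation.align_vectors(yc, xc)
        xc = rot.apply(xc)
        return float(np.sqrt(np.mean(np.sum((xc - yc) ** 2, axis=1))))
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def contact_persistence(frames, group_a: ResidueSelection, group_b: ResidueSelection,
                        cutoff: float = 4.5, include_absent: bool = False):
    """Residue-pair contact persistence across frames.

    A pair is in contact in a frame if any heavy-atom pair is within
    ``cutoff`` Å. Persistence is the fraction of frames in contact; pairs
    never in contact are omitted unless ``include_absent``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(frames, ConformationFrame):
        frames = [frames]
    counts: dict = {}
    pairs_universe = set()
    for frame in frames:
        mask_a = group_a.mask(frame) & (frame.element != "H")
        mask_b = group_b.mask(frame) & (frame.element != "H")
        if not mask_a.any() or not mask_b.any():
            raise ValueError("empty heavy-atom selection for contact analysis")
        ids_a = list(zip(frame.chain_id[mask_a], frame.residue_index[mask_a]))
        ids_b = list(zip(frame.chain_id[mask_b], frame.residue_index[mask_b]))
        pairs_universe.update(
            frozenset({ra, rb}) for ra in set(ids_a) for rb in set(ids_b)
            if ra != rb)
        tree_b = cKDTree(frame.coordinates[mask_b])
        hits = tree_b.query_ball_point(frame.coordinates[mask_a], r=cutoff)
        frame_pairs = set()
        for i, lst in enumerate(hits):
            for j in lst:
                if ids_a[i] != ids_b[j]:
                    frame_pairs.add(frozenset({ids_a[i], ids_b[j]}))
        for p in frame_pairs:
            counts[p] = counts.get(p, 0) + 1
    nf = len(frames)
    records = []
    universe = pairs_universe if include_absent else counts.keys()
    for p in universe:
        a, b = sorted(p)
        records.append(ContactRecord(tuple(a), tuple(b), counts.get(p, 0) / nf))
    records.sort(key=lambda r: (r.residue_a, r.residue_b))
    return records
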