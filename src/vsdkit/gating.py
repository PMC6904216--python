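"""Gating-charge decomposition via the coupling-function method.

The coupling function f(r) is the dimensionless fraction of the applied
transmembrane voltage Vm felt at point r. It is estimated as the rate of
change of the local electrostatic potential with the applied voltage,

    f(r) = ∂φ(r)/∂Vm ≈ [φ(r, Vm1) − φ(r, Vm2)] / (Vm1 − Vm2),

or, given potential maps at more than two voltages, as the least-squares
slope of φ(r) against Vm. The gating-charge contribution of residue j is
then the sum over its partial charges q_ij of the change in coupling between
the resting and activated states,

    Q_j = Σ_i q_ij [f_a(r_ij) − f_r(r_ij)],

with f_a evaluated at the activated-state atom positions and f_r at the
resting-state positions. A charge contributes either because it moves through
the field or because the field rearranges around it — both enter through the
same expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConformationFrame, PotentialGrid


@dataclass
class CouplingProfile:
    """Per-atom coupling f for one conformation, with provenance tags."""

    f: np.ndarray                 # dimensionless, one value per atom
    state_label: str = ""
    conformation_id: str = ""
    voltages: tuple = ()          # mV, the applied voltages used

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if not np.all(np.isfinite(self.f)):
            raise ValueError("coupling function contains non-finite values")


@dataclass
class GatingChargeTable:
    """Per-residue gating-charge contributions Q_j (e0) for one conformation pair."""

    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    q_j: np.ndarray               # e0 per residue
    net_per_vsd: float            # e0
    cumulative: np.ndarray        # running sum in sequence order

    def __post_init__(self):
        if abs(self.q_j.sum() - self.net_per_vsd) > 1e-9:
            raise ValueError("net_per_vsd inconsistent with per-residue sum")
        if abs(self.cumulative[-1] - self.net_per_vsd) > 1e-9:
            raise ValueError("cumulative must end at the net charge")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": self.chain_id,
            "residue": self.residue_index,
            "name": self.residue_name,
            "Q": self.q_j,
            "cumulative": self.cumulative,
        })


def coupling_function(frame: ConformationFrame, grids,
                      conformation_id: str = "") -> CouplingProfile:
    """Coupling f per atom from potential grids at ≥ 2 distinct voltages.

    Two grids give the finite-difference slope; more give the least-squares
    slope of φ(r) vs Vm. Atoms must lie inside every grid.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("need at least two grids at distinct voltages")
    volts = np.array([g.applied_voltage for g in grids], dtype=float)
    if len(np.unique(volts)) < 2:
        raise ValueError("applied voltages must be distinct")
    phi = np.stack([g.interpolate(frame.coordinates) for g in grids])
    if len(grids) == 2:
        f = (phi[0] - phi[1]) / (volts[0] - volts[1])
    else:
        # slope of phi vs voltage, per atom
        vc = volts - volts.mean()
        f = (vc @ (phi - phi.mean(axis=0))) / (vc @ vc)
    return CouplingProfile(f=f, state_label=frame.state_label,
                           conformation_id=conformation_id,
                           voltages=tuple(volts))


def _residue_keys(frame):
    keys = []
    seen = set()
    for ch, ri in zip(frame.chain_id, frame.residue_index):
        if (ch, ri) not in seen:
            seen.add((ch, ri))
            keys.append((ch, int(ri)))
    return keys


def per_residue_charge(frame_r: ConformationFrame, frame_a: ConformationFrame,
                       profile_r: CouplingProfile, profile_a: CouplingProfile,
                       charges: np.ndarray) -> GatingChargeTable:
    """Per-residue gating charge Q_j = Σ_i q_ij [f_a − f_r] (e0).

    ``charges`` is the per-atom partial charge array (e0) aligned with the
    frames' atom order; the two frames must share residue topology. f_a is
    evaluated at activated positions and f_r at resting positions (build the
    profiles from the matching frames). For a shared-coordinates sensitivity
    check, evaluate both states' grids on the same frame before calling, e.g.
    ``coupling_function(frame_r, grids_a)``.
    """
    keys_r = _residue_keys(frame_r)
    keys_a = _residue_keys(frame_a)
    if keys_r != keys_a:
        raise ValueError("residue topology differs between states")
    charges = np.asarray(charges, dtype=float)
    if charges.shape[0] != frame_r.n_atoms:
        raise ValueError("charge array length does not match atom count")
    if not np.all(np.isfinite(charges)):
        raise ValueError("charges must be finite")

    contrib = charges * (profile_a.f - profile_r.f)

    resids, names, chains, qj = [], [], [], []
    for ch, ri, rname, idx in frame_r.residues():
        resids.append(ri)
        names.append(rname)
        chains.append(ch)
        qj.append(contrib[idx].sum())
    qj = np.asarray(qj)
    return GatingChargeTable(
        residue_index=np.asarray(resids),
        residue_name=np.asarray(names),
        chain_id=np.asarray(chains),
        q_j=qj,
        net_per_vsd=float(qj.sum()),
        cumulative=np.cumsum(qj),
    )


def aggregate_charge(tables, subunits: int = 4) -> dict:
    """Aggregate per-conformation charge tables into the reported summary.

    Returns mean per-residue Q with the standard error across conformations,
    the mean cumulative curve with its standard error, the mean net charge
    per voltage sensor, and the per-channel total (subunits × per-VSD mean).
    Standard errors for a single conformation are reported as NaN.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one charge table")
    if subunits < 1:
        raise ValueError("subunits must be >= 1")
    ref = tables[0]
    for t in tables[1:]:
        if not (np.array_equal(t.residue_index, ref.residue_index)
                and np.array_equal(t.chain_id, ref.chain_id)):
            raise ValueError("inconsistent residue sets across tables")
    q = np.stack([t.q_j for t in tables])
    cum = np.stack([t.cumulative for t in tables])
    n = len(tables)
    sem = (q.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.full(q.shape[1], np.nan)
    cum_sem = (cum.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
        else np.full(cum.shape[1], np.nan)
    nets = np.array([t.net_per_vsd for t in tables])
    summary = pd.DataFrame({
        "chain": ref.chain_id,
        "residue": ref.residue_index,
        "name": ref.residue_name,
        "mean_Q": q.mean(axis=0),
        "stderr": sem,
        "cumulative": cum.mean(axis=0),
        "cumulative_stderr": cum_sem,
    })
    return {
        "table": summary,
        "net_per_vsd": float(nets.mean()),
        "net_stderr": float(nets.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "per_channel": float(subunits * nets.mean()),
        "n_conformations": n,
    }
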