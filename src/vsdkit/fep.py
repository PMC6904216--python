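"""Bennett-acceptance-ratio free energies and the mutation thermodynamic cycle.

BAR estimates the free-energy difference between two states from forward and
reverse work samples by solving the self-consistency condition

    Σ_i fermi(β(M + W_f,i − ΔG)) = Σ_j fermi(β(−M + W_r,j + ΔG)),

where fermi(x) = 1/(1+e^x), M = ln(n_f/n_r)/β, W_f is work measured along the
forward switch (0→1) and W_r along the reverse (1→0). Among all two-state
estimators built from work samples this choice minimises the asymptotic
variance. λ windows chain additively; the activation free-energy shift of a
point mutation follows from the thermodynamic cycle

    ΔΔG = ΔG_a(wt→mut) − ΔG_r(wt→mut),

the difference between the alchemical transformation free energies in the
activated and resting conformations, scaled by the number of voltage sensors
per channel when a per-channel figure is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol·K)
DEFAULT_TEMPERATURE = 300.0       # K


def kbt_to_kcal(x_kbt: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in units of kB·T to kcal/mol."""
    return x_kbt * KB_KCAL_PER_MOL_K * temperature


@dataclass
class WorkSamples:
    """Forward/reverse work samples (kcal/mol) for one λ window."""

    forward_work: np.ndarray     # work for the i -> i+1 switch
    reverse_work: np.ndarray     # work for the i+1 -> i switch
    temperature: float = DEFAULT_TEMPERATURE
    window_index: int = 0

    def __post_init__(self):
        self.forward_work = np.asarray(self.forward_work, dtype=float)
        self.reverse_work = np.asarray(self.reverse_work, dtype=float)
        if self.forward_work.size == 0 or self.reverse_work.size == 0:
            raise ValueError("both work directions must be non-empty")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def swapped(self) -> "WorkSamples":
        return WorkSamples(self.reverse_work, self.forward_work,
                           self.temperature, self.window_index)


@dataclass
class BARResult:
    dg: float                    # kcal/mol
    stderr: float                # kcal/mol
    overlap_warning: bool = False

    def __iter__(self):
        return iter((self.dg, self.stderr))


@dataclass
class CycleResult:
    """Activation free-energy shift of a mutation from the alchemical cycle."""

    dg_activated: float          # kcal/mol, mean over activated-state legs
    dg_resting: float            # kcal/mol, mean over resting-state legs
    ddg_per_vsd: float
    ddg_per_channel: float
    stderr: float
    subunits: int = 4
    n_legs: tuple = (0, 0)

    def summary(self) -> str:
        lines = [
            "Thermodynamic cycle (wt -> mutant)",
            f"  dG activated  : {self.dg_activated:8.3f} kcal/mol "
            f"({self.n_legs[0]} leg(s))",
            f"  dG resting    : {self.dg_resting:8.3f} kcal/mol "
            f"({self.n_legs[1]} leg(s))",
            f"  ddG per VSD   : {self.ddg_per_vsd:8.3f} +/- {self.stderr:.3f} kcal/mol",
            f"  ddG per channel ({self.subunits} subunits): "
            f"{self.ddg_per_channel:8.3f} kcal/mol",
        ]
        return "\n".join(lines)


def bar_estimate(samples: WorkSamples, min_samples: int = 10,
                 tol: float = 1e-8) -> BARResult:
    """BAR free-energy estimate for one window (kcal/mol).

    Solves the self-consistent acceptance balance by bracketed root finding,
    then evaluates the standard asymptotic variance. When the forward and
    reverse work distributions barely overlap, the variance estimate diverges
    and the result carries ``overlap_warning=True``.
    """
    wf, wr = samples.forward_work, samples.reverse_work
    if wf.size < min_samples or wr.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples in each direction")
    beta = 1.0 / (KB_KCAL_PER_MOL_K * samples.temperature)
    nf, nr = wf.size, wr.size
    m = math.log(nf / nr) / beta

    def imbalance(dg):
        lhs = expit(-beta * (m + wf - dg)).sum()
        rhs = expit(-beta * (-m + wr + dg)).sum()
        return lhs - rhs

    lo = min(wf.min(), -wr.max()) - 1.0
    hi = max(wf.max(), -wr.min()) + 1.0
    # imbalance is monotone increasing in dg; expand bracket if needed
    while imbalance(lo) > 0:
        lo -= 10.0
    while imbalance(hi) < 0:
        hi += 10.0
    dg = brentq(imbalance, lo, hi, xtol=tol)

    ff = expit(-beta * (m + wf - dg))
    fr = expit(-beta * (-m + wr + dg))
    overlap = False
    var = 0.0
    for f, n in ((ff, nf), (fr, nr)):
        mean_f = f.mean()
        mean_f2 = (f ** 2).mean()
        if mean_f <= 1e-6:
            # vanishing mean acceptance: the two work distributions do not
            # overlap and the asymptotic variance is meaningless
            overlap = True
        if mean_f <= 0:
            var = float("inf")
            break
        var += (mean_f2 / mean_f ** 2 - 1.0) / n
    stderr = math.sqrt(var) / beta if math.isfinite(var) else float("inf")
    if not math.isfinite(stderr) or (math.isfinite(var) and var > 1e4):
        overlap = True
    return BARResult(dg=float(dg), stderr=float(stderr), overlap_warning=overlap)


class BAREstimator:
    """Model-style wrapper: construct from work samples, ``fit()`` for the result."""

    def __init__(self, forward_work, reverse_work,
                 temperature: float = DEFAULT_TEMPERATURE):
        self.samples = WorkSamples(forward_work, reverse_work, temperature)

    def fit(self, **kwargs) -> BARResult:
        return bar_estimate(self.samples, **kwargs)


def chain_windows(per_window) -> tuple:
    """Total ΔG over consecutive λ windows and its propagated standard error.

    ``per_window`` is a sequence of (dG, stderr) pairs (or BARResults);
    windows are treated as statistically independent.
    """
    per_window = list(per_window)
    if not per_window:
        raise ValueError("no windows given")
    pairs = [(w.dg, w.stderr) if isinstance(w, BARResult) else (w[0], w[1])
             for w in per_window]
    return (sum(p[0] for p in pairs),
            math.sqrt(sum(p[1] ** 2 for p in pairs)))


def _leg_stats(legs):
    legs = np.asarray(list(legs), dtype=float)
    if legs.size == 0:
        raise ValueError("each cycle leg needs at least one estimate")
    mean = float(legs.mean())
    sem = float(legs.std(ddof=1) / np.sqrt(legs.size)) if legs.size > 1 else 0.0
    return mean, sem, legs.size


def thermodynamic_cycle(legs_activated, legs_resting, subunits: int = 4
                        ) -> CycleResult:
    """ΔΔG of a mutation from independent activated- and resting-state legs.

    Each leg is one independent alchemical ΔG(wt→mut) estimate (kcal/mol).
    ΔΔG per voltage sensor is mean(activated) − mean(resting), with the
    standard error propagated from the two leg means; the per-channel value
    assumes ``subunits`` independent identical sensors.
    """
    mean_a, sem_a, n_a = _leg_stats(legs_activated)
    mean_r, sem_r, n_r = _leg_stats(legs_resting)
    ddg = mean_a - mean_r
    stderr = math.sqrt(sem_a ** 2 + sem_r ** 2)
    return CycleResult(
        dg_activated=mean_a, dg_resting=mean_r,
        ddg_per_vsd=ddg, ddg_per_channel=subunits * ddg,
        stderr=stderr, subunits=subunits, n_legs=(n_a, n_r))
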