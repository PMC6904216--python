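"""Electrophysiology fitting: sum-of-two-Boltzmann open-probability curves,
the gating polarity index and its correlation with residue property scales,
and MTSET modification kinetics.

Relative open probability of a bipolar (hyperpolarization- and
depolarization-activated) channel is described by the sum of two independent
Boltzmann components,

    I(V) = O1 + (A1 − O1)/(1 + exp(k1 (V − V1)))
         + O2 + (A2 − O2)/(1 + exp(k2 (V − V2))),

with amplitudes A, offsets O, half-activation voltages V½ and slope factors k
per component. By convention component 1 is the hyperpolarization-activated
limb (more negative V½). The gating polarity index Po(−150 mV)/Po(+50 mV)
summarises each curve as the relative strength of the two pathways; it is
compared against residue property scales on a log10 axis.

Cysteine-modification time courses follow a mono-exponential in cumulative
probe exposure, I(t) = I∞ + (I0 − I∞) e^(−t/τ); the apparent second-order
modification rate is k = 1/(τ·[MTSET]).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .scales import get_scale


@dataclass
class PoVCurve:
    voltages: np.ndarray       # mV, strictly monotone
    relative_po: np.ndarray
    construct_label: str = ""

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.relative_po = np.asarray(self.relative_po, dtype=float)
        d = np.diff(self.voltages)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("voltages must be strictly monotone")
        if not np.all(np.isfinite(self.relative_po)):
            raise ValueError("relative_po must be finite")

    def normalized(self) -> "PoVCurve":
        """Scale so the largest |Po| is 1 (relative-Po convention)."""
        peak = np.abs(self.relative_po).max()
        if peak == 0:
            return self
        return PoVCurve(self.voltages, self.relative_po / peak,
                        self.construct_label)


@dataclass
class BoltzmannFit:
    """Parameters of the sum-of-two-Boltzmann model (component 1: more
    negative V½, the hyperpolarization limb)."""

    a1: float
    o1: float
    v1: float      # mV
    k1: float      # 1/mV
    a2: float
    o2: float
    v2: float      # mV
    k2: float      # 1/mV
    rss: float = float("nan")
    as_printed: bool = False

    def params(self) -> np.ndarray:
        return np.array([self.a1, self.o1, self.v1, self.k1,
                         self.a2, self.o2, self.v2, self.k2])

    def predict(self, voltages) -> np.ndarray:
        return double_boltzmann(np.asarray(voltages, dtype=float), *self.params(),
                                as_printed=self.as_printed)

    def ordered(self) -> "BoltzmannFit":
        """Canonical component order: V1 <= V2."""
        if self.v1 <= self.v2:
            return self
        return BoltzmannFit(self.a2, self.o2, self.v2, self.k2,
                            self.a1, self.o1, self.v1, self.k1,
                            rss=self.rss, as_printed=self.as_printed)


@dataclass(frozen=True)
class PolarityIndex:
    po_neg: float            # Po at −150 mV
    po_pos: float            # Po at +50 mV
    index: float             # po_neg / po_pos
    infinite: bool = False
    source: str = "fit"      # "fit" or "data"


@dataclass
class ModificationFit:
    tau: float               # s
    concentration: float     # mol/L
    k2nd: float              # 1/(M s)
    i0: float
    iinf: float
    tau_stderr: float = float("nan")
    k2nd_stderr: float = float("nan")
    no_change: bool = False  # amplitude below noise: k2nd is an upper bound

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.iinf + (self.i0 - self.iinf) * np.exp(-t / self.tau)


def double_boltzmann(v, a1, o1, v1, k1, a2, o2, v2, k2, as_printed=False):
    """Sum-of-two-Boltzmann model of relative Po vs voltage (mV).

    The symmetric form uses (A1 − O1) in the first component; ``as_printed``
    switches to the asymmetric (A1 − O2) variant for strict compatibility
    with legacy fits.
    """
    first_amp = (a1 - o2) if as_printed else (a1 - o1)
    with np.errstate(over="ignore"):
        return (o1 + first_amp / (1.0 + np.exp(k1 * (v - v1)))
                + o2 + (a2 - o2) / (1.0 + np.exp(k2 * (v - v2))))


def _start_grid(v, y):
    """Initialization grid for the multi-start double-Boltzmann fit."""
    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-6)
    vlo, vhi = float(v.min()), float(v.max())
    q = np.quantile(v, [0.25, 0.5, 0.75])
    starts = []
    for v1, v2 in itertools.product(q[:2], q[1:]):
        for k1, k2 in ((0.05, -0.05), (0.1, -0.1), (-0.05, 0.05)):
            starts.append([ymin + span, ymin, v1, k1,
                           ymin + span, ymin, v2, k2])
    # flat start: handles constant curves and single-component data
    mean = float(y.mean())
    starts.append([mean / 2, mean / 2, vlo + (vhi - vlo) / 3, 0.01,
                   mean / 2, mean / 2, vhi - (vhi - vlo) / 3, -0.01])
    starts.append([ymax, ymin, vlo + (vhi - vlo) / 4, 0.05,
                   ymin, ymin, vhi - (vhi - vlo) / 4, 0.05])
    return starts


class DoubleBoltzmannModel:
    """Sum-of-two-Boltzmann model of a relative Po–V curve.

    statsmodels-style: construct from data, ``fit()`` returns a
    ``DoubleBoltzmannResults`` with parameters, residuals and a summary table.
    """

    def __init__(self, curve: PoVCurve, as_printed: bool = False,
                 normalize: bool = False):
        if isinstance(curve, tuple):
            curve = PoVCurve(*curve)
        if curve.voltages.size < 8:
            raise ValueError("need at least 8 voltage points spanning both limbs")
        self.curve = curve.normalized() if normalize else curve
        self.as_printed = as_printed

    def fit(self, start: BoltzmannFit = None, maxfev: int = 20000
            ) -> "DoubleBoltzmannResults":
        v, y = self.curve.voltages, self.curve.relative_po
        starts = ([list(start.params())] if start is not None
                  else _start_grid(v, y))

        def model(vv, *p):
            return double_boltzmann(vv, *p, as_printed=self.as_printed)

        best = None
        best_cov = None
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = curve_fit(model, v, y, p0=p0, maxfev=maxfev)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((model(v, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
                best_cov = pcov
        if best is None:
            raise RuntimeError("double-Boltzmann fit failed to converge from "
                               "every start")
        popt, rss = best
        fit = BoltzmannFit(*popt, rss=rss, as_printed=self.as_printed).ordered()
        return DoubleBoltzmannResults(self, fit, best_cov)


@dataclass
class DoubleBoltzmannResults:
    model: DoubleBoltzmannModel
    fit: BoltzmannFit
    cov: np.ndarray = None

    @property
    def rss(self) -> float:
        return self.fit.rss

    def predict(self, voltages=None) -> np.ndarray:
        if voltages is None:
            voltages = self.model.curve.voltages
        return self.fit.predict(voltages)

    def summary(self) -> str:
        f = self.fit
        rows = [("component 1 (hyperpol.)", f.a1, f.o1, f.v1, f.k1),
                ("component 2 (depol.)", f.a2, f.o2, f.v2, f.k2)]
        lines = ["Double-Boltzmann fit of relative Po(V)",
                 f"{'':26s}{'A':>10s}{'O':>10s}{'V1/2 (mV)':>12s}{'k (1/mV)':>12s}"]
        for name, a, o, vh, k in rows:
            lines.append(f"{name:26s}{a:10.4f}{o:10.4f}{vh:12.2f}{k:12.4f}")
        lines.append(f"RSS: {f.rss:.6g}   n: {self.model.curve.voltages.size}")
        return "\n".join(lines)


def fit_double_boltzmann(curve, start=None, as_printed=False,
                         normalize=False) -> BoltzmannFit:
    """Functional wrapper around :class:`DoubleBoltzmannModel`."""
    res = DoubleBoltzmannModel(curve, as_printed=as_printed,
                               normalize=normalize).fit(start=start)
    return res.fit


def polarity_index(source, v_neg: float = -150.0, v_pos: float = 50.0
                   ) -> PolarityIndex:
    """Gating polarity index Po(v_neg)/Po(v_pos).

    ``source`` may be a BoltzmannFit / DoubleBoltzmannResults (evaluated from
    the fitted model) or a PoVCurve (linear interpolation between measured
    points; extrapolation clamps to the nearest point).
    """
    if isinstance(source, DoubleBoltzmannResults):
        source = source.fit
    if isinstance(source, BoltzmannFit):
        po_neg = float(source.predict([v_neg])[0])
        po_pos = float(source.predict([v_pos])[0])
        origin = "fit"
    elif isinstance(source, PoVCurve):
        v, y = source.voltages, source.relative_po
        order = np.argsort(v)
        po_neg = float(np.interp(v_neg, v[order], y[order]))
        po_pos = float(np.interp(v_pos, v[order], y[order]))
        origin = "data"
    else:
        raise TypeError("expected a BoltzmannFit, results object or PoVCurve")
    if po_pos == 0:
        return PolarityIndex(po_neg, po_pos, float("inf"), infinite=True,
                             source=origin)
    return PolarityIndex(po_neg, po_pos, po_neg / po_pos, source=origin)


def propensity_correlation(indices: dict, scale, transform: str = "log10"
                           ) -> dict:
    """Correlate gating polarity indices with a residue property scale.

    ``indices`` maps one-letter residue codes of the substituted amino acid to
    PolarityIndex objects (or plain index values). The correlation is Pearson
    on the transformed index ('log10' default, 'linear' available) vs the
    scale value. Residues with infinite index are excluded with a warning.

    Returns {'r', 'slope', 'intercept', 'pvalue', 'n', 'excluded'}.
    """
    sc = get_scale(scale)
    xs, ys, excluded = [], [], []
    for aa, idx in indices.items():
        value = idx.index if isinstance(idx, PolarityIndex) else float(idx)
        if not math.isfinite(value) or (transform == "log10" and value <= 0):
            excluded.append(aa)
            continue
        xs.append(sc[aa])
        ys.append(math.log10(value) if transform == "log10" else value)
    if excluded:
        warnings.warn(f"excluded non-finite polarity indices: {excluded}")
    if len(xs) < 3:
        raise ValueError("need at least 3 finite substitutions to correlate")
    if np.std(ys) == 0 or np.std(xs) == 0:
        return {"r": float("nan"), "slope": 0.0,
                "intercept": float(np.mean(ys)), "pvalue": float("nan"),
                "n": len(xs), "excluded": excluded}
    res = linregress(xs, ys)
    return {"r": float(res.rvalue), "slope": float(res.slope),
            "intercept": float(res.intercept), "pvalue": float(res.pvalue),
            "n": len(xs), "excluded": excluded}


class ModificationKineticsModel:
    """Mono-exponential fit of peak current vs cumulative probe exposure.

    Construct from the time course and the MTSET concentration (mol/L);
    ``fit()`` returns a ModificationFit with the apparent second-order rate
    k = 1/(τ·C) and delta-method standard errors.
    """

    def __init__(self, exposure_s, current, concentration: float):
        self.t = np.asarray(exposure_s, dtype=float)
        self.i = np.asarray(current, dtype=float)
        if self.t.size < 5:
            raise ValueError("need at least 5 exposure points")
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        self.concentration = float(concentration)

    def fit(self) -> ModificationFit:
        t, y = self.t, self.i
        i0_guess, iinf_guess = float(y[0]), float(y[-1])
        tau_guess = max(float(t.max()) / 3.0, 1e-6)

        def model(tt, i0, iinf, tau):
            return iinf + (i0 - iinf) * np.exp(-tt / tau)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, t, y, p0=[i0_guess, iinf_guess or i0_guess + 1e-3,
                                     tau_guess],
                    bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                    maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"modification fit failed: {exc}") from exc
        i0, iinf, tau = popt
        resid = y - model(t, *popt)
        noise = float(np.std(resid, ddof=1)) if t.size > 3 else 0.0
        no_change = abs(iinf - i0) <= 2.0 * noise or abs(iinf - i0) < 1e-12
        tau_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) \
            else float("nan")
        k = 1.0 / (tau * self.concentration)
        k_se = k * tau_se / tau if math.isfinite(tau_se) else float("nan")
        return ModificationFit(tau=float(tau), concentration=self.concentration,
                               k2nd=float(k), i0=float(i0), iinf=float(iinf),
                               tau_stderr=tau_se, k2nd_stderr=float(k_se),
                               no_change=bool(no_change))


def fit_modification_rate(exposure_s, current, concentration: float
                          ) -> ModificationFit:
    """Functional wrapper around :class:`ModificationKineticsModel`."""
    return ModificationKineticsModel(exposure_s, current, concentration).fit()
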