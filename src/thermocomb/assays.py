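"""Thermostability and kinetics curve fits.

Model classes (statsmodels-style ``Model.fit() -> Results``):

* :class:`BoltzmannMelt` — sigmoid melts (DSF fluorescence, CD unfolding
  fraction, T50^15 residual-activity-vs-temperature):
  ``y(T) = y_lo + (y_hi - y_lo) / (1 + exp((Tm - T)/a))``, Tm at the inflection.
* :class:`DscTwoState` — two-state van 't Hoff excess heat capacity with a
  linear baseline; reports both the van 't Hoff and the calorimetric
  (peak-integral) unfolding enthalpy.
* :class:`FirstOrderDecay` — thermal inactivation, ``k*t = ln(Ar/A0)``,
  half-life ``t1/2 = -ln(2)/k`` (k < 0 for a decaying enzyme).
* :class:`MichaelisMenten` — ``v = Vmax*S/(Km + S)``; kcat = Vmax/[E].

All fitters are deterministic given the data and the documented
initialization rules; convergence failures are reported, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

R_KJ = 8.314462618e-3  # gas constant, kJ mol^-1 K^-1
C_TO_K = 273.15


class FitError(RuntimeError):
    pass


@dataclass
class MeltCurve:
    """A thermal transition curve: temperature (degC) vs signal."""

    temperature: np.ndarray
    signal: np.ndarray
    modality: str = "dsf"  # dsf | cd | t50 | generic

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if self.temperature.size < 8:
            raise ValueError("need at least 8 points to fit a melt curve")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(self.temperature)) and np.all(np.isfinite(self.signal))):
            raise ValueError("non-finite values in curve")


def _boltzmann(T, y_lo, y_hi, tm, a):
    return y_lo + (y_hi - y_lo) / (1.0 + np.exp((tm - T) / a))


@dataclass
class MeltFitResults:
    tm: float
    slope: float          # transition width parameter a (degC), > 0
    y_lo: float           # low-temperature plateau
    y_hi: float           # high-temperature plateau
    residual_sd: float
    converged: bool
    n_points: int
    modality: str = "generic"

    def predict(self, T):
        return _boltzmann(np.asarray(T, dtype=float),
                          self.y_lo, self.y_hi, self.tm, self.slope)

    def summary(self) -> str:
        return (
            f"Boltzmann melt fit ({self.modality}, n={self.n_points})\n"
            f"  Tm        = {self.tm:.2f} degC\n"
            f"  slope a   = {self.slope:.3f} degC\n"
            f"  plateaus  = {self.y_lo:.4g} (low T) / {self.y_hi:.4g} (high T)\n"
            f"  resid SD  = {self.residual_sd:.4g}\n"
            f"  converged = {self.converged}"
        )

    def plot(self, ax=None):  # pragma: no cover - thin matplotlib wrapper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T = np.linspace(self.tm - 8 * self.slope, self.tm + 8 * self.slope, 200)
        ax.plot(T, self.predict(T), label=f"fit (Tm={self.tm:.2f} degC)")
        ax.axvline(self.tm, ls="--", color="grey")
        ax.set_xlabel("temperature (degC)")
        ax.legend()
        return ax


class BoltzmannMelt:
    """Least-squares Boltzmann sigmoid fit of a melt curve.

    Initialization: Tm at the maximum |dy/dT| (finite differences),
    a = 2 degC, plateaus from the first/last signal deciles.  For DSF curves
    that decline past the unfolding peak (dye dissociation), the fit uses
    only points up to the global signal maximum (``truncate_at_max``,
    default on for ``modality="dsf"``).
    """

    def __init__(self, curve: MeltCurve, truncate_at_max: bool | None = None):
        self.curve = curve
        if truncate_at_max is None:
            truncate_at_max = curve.modality == "dsf"
        self.truncate_at_max = truncate_at_max

    def _prepare(self):
        T, y = self.curve.temperature, self.curve.signal
        if self.truncate_at_max:
            imax = int(np.argmax(y))
            if imax >= 7:  # keep at least 8 points
                T, y = T[: imax + 1], y[: imax + 1]
        return T, y

    def fit(self) -> MeltFitResults:
        T, y = self._prepare()
        noise = np.std(np.diff(y)) / np.sqrt(2.0)
        span = float(y.max() - y.min())
        if span == 0 or (noise > 0 and span < 5 * noise):
            raise FitError(
                f"no transition detected: signal span {span:.3g} "
                f"vs point noise {noise:.3g}"
            )
        dy = np.gradient(y, T)
        tm0 = float(T[np.argmax(np.abs(dy))])
        k = max(1, len(y) // 10)
        y_lo0 = float(np.mean(y[:k]))
        y_hi0 = float(np.mean(y[-k:]))
        p0 = [y_lo0, y_hi0, tm0, 2.0]
        try:
            popt, _ = curve_fit(
                _boltzmann, T, y, p0=p0,
                bounds=([-np.inf, -np.inf, T.min() - 5, 1e-6],
                        [np.inf, np.inf, T.max() + 5, (T.max() - T.min())]),
                maxfev=20000,
            )
            converged = True
        except RuntimeError:
            popt, converged = p0, False
        y_lo, y_hi, tm, a = (float(p) for p in popt)
        resid = y - _boltzmann(T, *popt)
        in_range = T.min() <= tm <= T.max()
        return MeltFitResults(
            tm=tm, slope=a, y_lo=y_lo, y_hi=y_hi,
            residual_sd=float(np.std(resid)),
            converged=bool(converged and in_range),
            n_points=len(y), modality=self.curve.modality,
        )


def fit_boltzmann_sigmoid(temperature, signal, modality="generic",
                          truncate_at_max=None) -> MeltFitResults:
    """Convenience wrapper: arrays in, :class:`MeltFitResults` out."""
    curve = MeltCurve(np.asarray(temperature), np.asarray(signal), modality)
    return BoltzmannMelt(curve, truncate_at_max=truncate_at_max).fit()


def unfolding_fraction(curve: MeltCurve) -> np.ndarray:
    """CD unfolding fraction fu(T) = (CD_T - CD_min)/(CD_max - CD_min) x 100%."""
    y = curve.signal
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise FitError("constant CD signal: unfolding fraction undefined")
    return (y - lo) / (hi - lo) * 100.0


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------


@dataclass
class Thermogram:
    """Excess heat capacity (kJ mol^-1 K^-1) vs temperature (degC)."""

    temperature: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature.shape != self.cp.shape:
            raise ValueError("temperature and Cp lengths differ")
        if self.temperature.size < 8:
            raise ValueError("need at least 8 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def _dsc_two_state(T_c, tm_c, dh, b0, b1):
    """Two-state van 't Hoff excess Cp plus linear baseline (T in degC)."""
    T = T_c + C_TO_K
    tm = tm_c + C_TO_K
    K = np.exp(-(dh / R_KJ) * (1.0 / T - 1.0 / tm))
    return dh**2 / (R_KJ * T**2) * K / (1.0 + K) ** 2 + b0 + b1 * T_c


@dataclass
class DscFitResults:
    tm: float                 # degC, fitted two-state Tm
    dh_vant_hoff: float       # kJ/mol, from the peak shape
    dh_calorimetric: float    # kJ/mol, baseline-subtracted peak integral
    baseline: tuple[float, float]
    residual_sd: float
    converged: bool
    multi_peak_warning: bool = False

    def summary(self) -> str:
        return (
            "DSC two-state fit\n"
            f"  Tm              = {self.tm:.2f} degC\n"
            f"  dH (van 't Hoff)   = {self.dh_vant_hoff:.1f} kJ/mol\n"
            f"  dH (calorimetric)  = {self.dh_calorimetric:.1f} kJ/mol\n"
            f"  baseline        = {self.baseline[0]:.3g} + {self.baseline[1]:.3g}*T\n"
            f"  resid SD        = {self.residual_sd:.4g}\n"
            f"  converged       = {self.converged}"
            + ("\n  warning: multiple peaks detected" if self.multi_peak_warning else "")
        )


class DscTwoState:
    """Two-state van 't Hoff fit of a DSC thermogram (single endothermic peak)."""

    def __init__(self, thermogram: Thermogram):
        self.tg = thermogram

    def _detect_multi_peak(self, y) -> bool:
        # peaks above half the global max, separated by a dip below 25% of max
        span = y - y.min()
        if span.max() <= 0:
            return False
        norm = span / span.max()
        above = norm > 0.5
        # count contiguous blocks above the half-max line
        blocks = int(np.sum(np.diff(above.astype(int)) == 1)) + int(above[0])
        return blocks > 1

    def fit(self) -> DscFitResults:
        T, y = self.tg.temperature, self.tg.cp
        if float(y.max() - y.min()) == 0.0:
            raise FitError("zero-amplitude thermogram")
        multi = self._detect_multi_peak(y)
        tm0 = float(T[np.argmax(y)])
        peak0 = float(y.max() - np.median(y))
        if peak0 <= 0:
            raise FitError("no endothermic peak above the baseline")
        # invert peak height = dH^2 / (4 R Tm^2) for the dH initial value
        dh0 = float(np.sqrt(max(peak0, 1e-9) * 4 * R_KJ * (tm0 + C_TO_K) ** 2))
        p0 = [tm0, dh0, float(np.percentile(y, 5)), 0.0]
        try:
            popt, _ = curve_fit(
                _dsc_two_state, T, y, p0=p0,
                bounds=([T.min(), 1.0, -np.inf, -np.inf],
                        [T.max(), 1e5, np.inf, np.inf]),
                maxfev=40000,
            )
            converged = True
        except RuntimeError:
            popt, converged = p0, False
        tm, dh, b0, b1 = (float(p) for p in popt)
        baseline = b0 + b1 * T
        dh_cal = float(np.trapezoid(y - baseline, T))
        resid = y - _dsc_two_state(T, *popt)
        return DscFitResults(
            tm=tm, dh_vant_hoff=dh, dh_calorimetric=dh_cal,
            baseline=(b0, b1), residual_sd=float(np.std(resid)),
            converged=converged, multi_peak_warning=multi,
        )


def fit_dsc_two_state(temperature, cp) -> DscFitResults:
    return DscTwoState(Thermogram(np.asarray(temperature), np.asarray(cp))).fit()


# ---------------------------------------------------------------------------
# first-order thermal inactivation
# ---------------------------------------------------------------------------


@dataclass
class DecaySeries:
    """Residual activity over incubation time at a fixed temperature."""

    time: np.ndarray          # min, strictly increasing, >= 0
    activity: np.ndarray      # same units as a0
    a0: float                 # initial activity
    incubation_celsius: float | None = None  # metadata only

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.a0 <= 0:
            raise ValueError("initial activity must be > 0")
        if np.any(self.time < 0) or np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if self.time.shape != self.activity.shape:
            raise ValueError("time and activity lengths differ")


@dataclass
class DecayFitResults:
    k: float                  # min^-1, negative for a decaying enzyme
    t_half: float | None      # min; None when the fit is invalid
    residual_sd: float
    valid: bool
    n_used: int
    n_dropped: int
    incubation_celsius: float | None = None

    def summary(self) -> str:
        th = f"{self.t_half:.2f} min" if self.t_half is not None else "undefined"
        return (
            "First-order inactivation fit\n"
            f"  k       = {self.k:.6g} min^-1\n"
            f"  t1/2    = {th}\n"
            f"  points  = {self.n_used} used, {self.n_dropped} dropped (Ar <= 0)\n"
            f"  resid SD (log scale) = {self.residual_sd:.4g}\n"
            f"  valid   = {self.valid}"
        )


class FirstOrderDecay:
    """k from the through-origin regression of ln(Ar/A0) on t; t1/2 = -ln2/k."""

    def __init__(self, series: DecaySeries):
        self.series = series

    def fit(self) -> DecayFitResults:
        s = self.series
        keep = s.activity > 0
        n_dropped = int(np.sum(~keep))
        if n_dropped:
            import warnings
            warnings.warn(
                f"dropping {n_dropped} non-positive activities before log transform",
                stacklevel=2,
            )
        t, ar = s.time[keep], s.activity[keep]
        if t.size < 2:
            raise FitError("fewer than 2 usable points for the decay fit")
        logy = np.log(ar / s.a0)
        k = float(np.sum(t * logy) / np.sum(t * t))  # least squares through origin
        resid = logy - k * t
        valid = k < 0
        t_half = float(-np.log(2.0) / k) if valid else None
        return DecayFitResults(
            k=k, t_half=t_half, residual_sd=float(np.std(resid)),
            valid=valid, n_used=int(t.size), n_dropped=n_dropped,
            incubation_celsius=s.incubation_celsius,
        )


def fit_first_order_decay(time, activity, a0, incubation_celsius=None) -> DecayFitResults:
    return FirstOrderDecay(DecaySeries(
        np.asarray(time), np.asarray(activity), a0, incubation_celsius
    )).fit()


def half_life_fold_change(t_half_variant: float, t_half_reference: float) -> float:
    """Fold improvement in half-life of a variant over a reference enzyme."""
    if t_half_reference <= 0 or t_half_variant <= 0:
        raise ValueError("half-lives must be positive")
    return t_half_variant / t_half_reference


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


def _mm(S, vmax, km):
    return vmax * S / (km + S)


@dataclass
class KineticsResults:
    km: float                 # mM
    vmax: float               # rate units of the input
    kcat: float | None        # s^-1; None without an enzyme concentration
    residual_sd: float
    converged: bool
    extrapolated: bool        # Km beyond 10x the largest substrate level

    def summary(self) -> str:
        kcat = f"{self.kcat:.3g} s^-1" if self.kcat is not None else "n/a"
        return (
            "Michaelis-Menten fit\n"
            f"  Km    = {self.km:.3f} mM\n"
            f"  Vmax  = {self.vmax:.4g}\n"
            f"  kcat  = {kcat}\n"
            f"  resid SD = {self.residual_sd:.4g}\n"
            f"  converged = {self.converged}"
            + ("\n  warning: Km beyond the sampled substrate range" if self.extrapolated else "")
        )


class MichaelisMenten:
    """Nonlinear least squares of v = Vmax*S/(Km+S); kcat = Vmax/[E]."""

    def __init__(self, substrate_mM: Sequence[float], rate: Sequence[float],
                 enzyme_conc: float | None = None):
        self.S = np.asarray(substrate_mM, dtype=float)
        self.v = np.asarray(rate, dtype=float)
        self.enzyme_conc = enzyme_conc
        if self.S.size < 5:
            raise ValueError("need at least 5 substrate levels")
        if np.any(self.v < 0):
            raise ValueError("rates must be non-negative")

    def fit(self) -> KineticsResults:
        vmax0 = float(self.v.max()) or 1.0
        # substrate level nearest half-maximal rate seeds Km
        km0 = float(self.S[np.argmin(np.abs(self.v - vmax0 / 2))]) or 1.0
        try:
            popt, _ = curve_fit(
                _mm, self.S, self.v, p0=[vmax0, km0],
                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000,
            )
            converged = True
        except RuntimeError:
            popt, converged = [vmax0, km0], False
        vmax, km = (float(p) for p in popt)
        resid = self.v - _mm(self.S, vmax, km)
        kcat = vmax / self.enzyme_conc if self.enzyme_conc else None
        return KineticsResults(
            km=km, vmax=vmax, kcat=kcat,
            residual_sd=float(np.std(resid)), converged=converged,
            extrapolated=bool(km > 10 * self.S.max()),
        )


def fit_michaelis_menten(substrate_mM, rate, enzyme_conc=None) -> KineticsResults:
    return MichaelisMenten(substrate_mM, rate, enzyme_conc).fit()
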