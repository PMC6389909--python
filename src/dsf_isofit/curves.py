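"""Melt-curve containers and per-curve unfolding models.

A DSF/ThermoFluor experiment yields, per well, a fluorescence trace Y(T).
Two models are offered for fitting a single trace:

* the empirical **Boltzmann sigmoid**, parameterised by the midpoint Tm and
  a steepness ``a`` (both in Celsius) — used for midpoint location and
  baseline normalisation only;
* the two-state **thermodynamic model**, in which the fraction unfolded
  follows K_U(T)/(1 + K_U(T)) with K_U from the integrated Gibbs-Helmholtz
  relation (dH_U free, dCp_U held fixed).

Raw traces additionally carry linear dye baselines for the folded and
unfolded states; the observed signal is modelled as

    Y(T) = (1 - f_u(T)) * (m_F*T + b_F) + f_u(T) * (m_U*T + b_U)

with T in Celsius on the baseline terms (the instrument axis) and the
fraction term evaluated in kelvin for the thermodynamic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .constants import c_to_k, k_to_c
from .thermo import ku_unfolding

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "ThermoFit",
    "CurveFitError",
    "fit_boltzmann",
    "fit_thermodynamic",
    "fit_global",
    "fraction_unfolded_at",
    "normalize_curve",
]

# Least-squares settings: trust-region reflective, tight tolerances.
_LSQ_KW = dict(method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)

#: fraction of points at each end of the trace used to seed baselines
_BASELINE_FRACTION = 0.15


class CurveFitError(RuntimeError):
    """A melt curve could not be fit (no transition, non-convergence,
    degenerate baselines, ...).  Carries a human-readable diagnosis."""


@dataclass(frozen=True)
class MeltCurve:
    """One well's fluorescence-versus-temperature trace.

    Parameters
    ----------
    temperature : array-like
        Strictly increasing temperatures, Celsius.
    signal : array-like
        Fluorescence, arbitrary units (or fraction unfolded if normalized).
    ligand_conc_total : float
        Total ligand concentration in the well, molar.
    replicate_id : str
        Replicate-group label (wells sharing a condition share this).
    well : str
        Well label from the plate export.
    normalized : bool
        True when signal is on the 0..1 fraction-unfolded scale.
    """

    temperature: np.ndarray
    signal: np.ndarray
    ligand_conc_total: float = 0.0
    replicate_id: str = ""
    well: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("temperature and signal must be 1-D and equal length")
        if t.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in melt curve")
        if self.ligand_conc_total < 0:
            raise ValueError("ligand_conc_total must be >= 0")
        if self.normalized and (y.min() < -0.5 or y.max() > 1.5):
            raise ValueError(
                "normalized signal outside the plausible [0, 1] band "
                f"(range {y.min():.3g}..{y.max():.3g})"
            )
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)

    def __len__(self) -> int:
        return self.temperature.size

    def truncated_after_max(self) -> "MeltCurve":
        """Drop points after the signal maximum (post-transition aggregation
        decay in dye-based data); returns self if the max is near the end."""
        imax = int(np.argmax(self.signal))
        if imax >= len(self) - 1:
            return self
        if imax + 1 < 10:
            raise ValueError("truncation would leave fewer than 10 points")
        return replace(
            self,
            temperature=self.temperature[: imax + 1],
            signal=self.signal[: imax + 1],
        )


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann-sigmoid fit of one melt curve.

    ``tm`` and ``a`` are in Celsius; baseline parameters are None when the
    fit was performed on an already-normalized curve.
    """

    tm: float
    a: float
    m_f: Optional[float] = None
    b_f: Optional[float] = None
    m_u: Optional[float] = None
    b_u: Optional[float] = None
    residual_norm: float = 0.0
    converged: bool = True
    t_range: tuple = (float("-inf"), float("inf"))

    @property
    def has_baselines(self) -> bool:
        return self.m_f is not None

    def fraction_unfolded(self, t_celsius):
        """f_u(T) = 1 / (1 + exp((Tm - T) / a)), clipped to [0, 1]."""
        t = np.asarray(t_celsius, dtype=float)
        return np.clip(1.0 / (1.0 + np.exp((self.tm - t) / self.a)), 0.0, 1.0)


@dataclass(frozen=True)
class ThermoFit:
    """Two-state thermodynamic fit of one melt curve.

    ``tm`` is in kelvin; ``dh_u`` (free) and ``dcp_u`` (held fixed during
    fitting) in kcal/mol and kcal/mol/K.  K_U(tm) = 1 by construction.
    """

    tm: float
    dh_u: float
    dcp_u: float
    m_f: Optional[float] = None
    b_f: Optional[float] = None
    m_u: Optional[float] = None
    b_u: Optional[float] = None
    residual_norm: float = 0.0
    converged: bool = True
    t_range: tuple = (float("-inf"), float("inf"))

    @property
    def has_baselines(self) -> bool:
        return self.m_f is not None

    @property
    def tm_celsius(self) -> float:
        return k_to_c(self.tm)

    def ku(self, t_celsius):
        """Unfolding constant K_U at the given temperature(s), Celsius in."""
        return ku_unfolding(c_to_k(np.asarray(t_celsius, dtype=float)),
                            self.tm, self.dh_u, self.dcp_u)

    def fraction_unfolded(self, t_celsius):
        """f_u(T) = K_U / (1 + K_U), clipped to [0, 1]; exactly 0.5 at Tm."""
        ku = self.ku(t_celsius)
        return np.clip(ku / (1.0 + ku), 0.0, 1.0)


CurveFit = Union[BoltzmannFit, ThermoFit]


def _seed_tm(curve: MeltCurve) -> float:
    """Midpoint seed: temperature of the steepest signal increase
    (centred finite difference of Y against T)."""
    t, y = curve.temperature, curve.signal
    dy = np.gradient(y, t)
    return float(t[int(np.argmax(dy))])


def _seed_baselines(curve: MeltCurve):
    """Linear-regression seeds for the folded (early) and unfolded (late)
    dye baselines, using the outer 15% of points on each side."""
    n = max(2, int(round(_BASELINE_FRACTION * len(curve))))
    t, y = curve.temperature, curve.signal
    m_f, b_f = np.polyfit(t[:n], y[:n], 1)
    m_u, b_u = np.polyfit(t[-n:], y[-n:], 1)
    return float(m_f), float(b_f), float(m_u), float(b_u)


def _check_transition(curve: MeltCurve, min_amplitude: float) -> None:
    span = float(curve.signal.max() - curve.signal.min())
    if span <= min_amplitude:
        raise CurveFitError(
            f"no unfolding transition detected: signal span {span:.4g} "
            f"<= noise floor {min_amplitude:.4g}"
        )


def _resolve_amplitude_floor(curve: MeltCurve, min_amplitude: Optional[float]) -> float:
    if min_amplitude is not None:
        return min_amplitude
    if curve.normalized:
        return 0.1
    # raw data: require the span to exceed 5x the robust point-to-point noise
    noise = 1.4826 * np.median(np.abs(np.diff(curve.signal))) / np.sqrt(2.0)
    return float(max(5.0 * noise, 1e-12))


def _boltzmann_signal(t, tm, a, m_f, b_f, m_u, b_u):
    f = 1.0 / (1.0 + np.exp((tm - t) / a))
    return (1.0 - f) * (m_f * t + b_f) + f * (m_u * t + b_u)


def _thermo_signal(t_c, tm_k, dh, dcp, m_f, b_f, m_u, b_u):
    ku = ku_unfolding(c_to_k(t_c), tm_k, dh, dcp)
    f = ku / (1.0 + ku)
    return (1.0 - f) * (m_f * t_c + b_f) + f * (m_u * t_c + b_u)


def fit_boltzmann(
    curve: MeltCurve,
    *,
    fit_baselines: Optional[bool] = None,
    min_amplitude: Optional[float] = None,
) -> BoltzmannFit:
    """Fit the Boltzmann sigmoid to one melt curve.

    For normalized curves only (Tm, a) are free; for raw curves the four
    linear-baseline parameters are fit as well.  Raises
    :class:`CurveFitError` when no transition is present, the optimiser
    fails, or the fitted midpoint escapes the observed temperature range.
    """
    floor = _resolve_amplitude_floor(curve, min_amplitude)
    _check_transition(curve, floor)
    if fit_baselines is None:
        fit_baselines = not curve.normalized

    t, y = curve.temperature, curve.signal
    tm0 = _seed_tm(curve)
    lo_t, hi_t = t[0] - 5.0, t[-1] + 5.0

    if fit_baselines:
        m_f0, b_f0, m_u0, b_u0 = _seed_baselines(curve)
        x0 = [tm0, 1.0, m_f0, b_f0, m_u0, b_u0]
        lo = [lo_t, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [hi_t, 50.0, np.inf, np.inf, np.inf, np.inf]

        def resid(x):
            return _boltzmann_signal(t, *x) - y

    else:
        x0 = [tm0, 1.0]
        lo, hi = [lo_t, 1e-3], [hi_t, 50.0]

        def resid(x):
            return _boltzmann_signal(t, x[0], x[1], 0.0, 0.0, 0.0, 1.0) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), **_LSQ_KW)
    if not sol.success:
        raise CurveFitError(f"Boltzmann fit did not converge: {sol.message}")
    tm, a = float(sol.x[0]), float(sol.x[1])
    if not (t[0] <= tm <= t[-1]):
        raise CurveFitError(
            f"fitted Tm {tm:.2f} C outside observed range "
            f"[{t[0]:.2f}, {t[-1]:.2f}] C — no usable transition"
        )
    base = (None,) * 4 if not fit_baselines else tuple(float(v) for v in sol.x[2:])
    return BoltzmannFit(
        tm=tm, a=a, m_f=base[0], b_f=base[1], m_u=base[2], b_u=base[3],
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=True, t_range=(float(t[0]), float(t[-1])),
    )


def fit_thermodynamic(
    curve: MeltCurve,
    dcp_u: float,
    *,
    fit_baselines: Optional[bool] = None,
    min_amplitude: Optional[float] = None,
) -> ThermoFit:
    """Fit the two-state thermodynamic model to one melt curve.

    ``dcp_u`` (kcal/mol/K) is held fixed; Tm and dH_U are free, plus the
    four baseline parameters on raw data.  The enthalpy is constrained
    positive; failures raise :class:`CurveFitError`.
    """
    floor = _resolve_amplitude_floor(curve, min_amplitude)
    _check_transition(curve, floor)
    if fit_baselines is None:
        fit_baselines = not curve.normalized

    t, y = curve.temperature, curve.signal
    tm0_k = c_to_k(_seed_tm(curve))
    lo_t, hi_t = c_to_k(t[0] - 5.0), c_to_k(t[-1] + 5.0)

    if fit_baselines:
        m_f0, b_f0, m_u0, b_u0 = _seed_baselines(curve)
        x0 = [tm0_k, 100.0, m_f0, b_f0, m_u0, b_u0]
        lo = [lo_t, 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [hi_t, 2000.0, np.inf, np.inf, np.inf, np.inf]

        def resid(x):
            return _thermo_signal(t, x[0], x[1], dcp_u, *x[2:]) - y

    else:
        x0 = [tm0_k, 100.0]
        lo, hi = [lo_t, 1.0], [hi_t, 2000.0]

        def resid(x):
            return _thermo_signal(t, x[0], x[1], dcp_u, 0.0, 0.0, 0.0, 1.0) - y

    sol = least_squares(resid, x0, bounds=(lo, hi), **_LSQ_KW)
    if not sol.success:
        raise CurveFitError(f"thermodynamic fit did not converge: {sol.message}")
    tm_k, dh = float(sol.x[0]), float(sol.x[1])
    if dh <= 0:
        raise CurveFitError(f"fitted dH_U {dh:.3g} kcal/mol is non-positive")
    if not (c_to_k(t[0]) <= tm_k <= c_to_k(t[-1])):
        raise CurveFitError(
            f"fitted Tm {k_to_c(tm_k):.2f} C outside observed range "
            f"[{t[0]:.2f}, {t[-1]:.2f}] C — no usable transition"
        )
    base = (None,) * 4 if not fit_baselines else tuple(float(v) for v in sol.x[2:])
    return ThermoFit(
        tm=tm_k, dh_u=dh, dcp_u=dcp_u,
        m_f=base[0], b_f=base[1], m_u=base[2], b_u=base[3],
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=True, t_range=(float(t[0]), float(t[-1])),
    )


def fit_global(
    curves: Sequence[MeltCurve],
    *,
    model: str = "thermodynamic",
    dcp_u: Optional[float] = None,
    min_amplitude: Optional[float] = None,
):
    """Jointly fit several raw curves with shared baseline slopes.

    The dye's temperature dependence does not change with ligand, so the
    folded/unfolded baseline slopes m_F and m_U are shared across curves
    while the transition parameters (Tm and dH_U or a) and the intercepts
    b_F, b_U stay per-curve.

    Returns ``(fits, failures)``: ``fits`` is a list parallel to
    ``curves`` with ``None`` for members that could not be fit, and
    ``failures`` maps curve index to the error message.  A single curve,
    or a set of already-normalized curves (no baselines to share), falls
    back to independent fits.
    """
    if model not in ("thermodynamic", "boltzmann"):
        raise ValueError("model must be 'thermodynamic' or 'boltzmann'")
    if model == "thermodynamic" and dcp_u is None:
        raise ValueError("dcp_u is required for the thermodynamic model")

    def fit_one(c):
        if model == "thermodynamic":
            return fit_thermodynamic(c, dcp_u, min_amplitude=min_amplitude)
        return fit_boltzmann(c, min_amplitude=min_amplitude)

    fits: list = [None] * len(curves)
    failures: dict = {}

    # independent prefits: seeds for the joint problem, and the fallback
    pre = [None] * len(curves)
    for i, c in enumerate(curves):
        try:
            pre[i] = fit_one(c)
        except CurveFitError as exc:
            failures[i] = str(exc)
    good = [i for i in range(len(curves)) if pre[i] is not None]

    share = (
        len(good) >= 2
        and all(not curves[i].normalized for i in good)
        and all(pre[i].has_baselines for i in good)
    )
    if not share:
        for i in good:
            fits[i] = pre[i]
        return fits, failures

    # parameter vector: [m_F, m_U] + per curve [tm, dh|a, b_F, b_U]
    m_f0 = float(np.mean([pre[i].m_f for i in good]))
    m_u0 = float(np.mean([pre[i].m_u for i in good]))
    x0, lo, hi = [m_f0, m_u0], [-np.inf, -np.inf], [np.inf, np.inf]
    for i in good:
        p = pre[i]
        if model == "thermodynamic":
            x0 += [p.tm, p.dh_u, p.b_f, p.b_u]
            lo += [c_to_k(curves[i].temperature[0] - 5.0), 1.0, -np.inf, -np.inf]
            hi += [c_to_k(curves[i].temperature[-1] + 5.0), 2000.0, np.inf, np.inf]
        else:
            x0 += [p.tm, p.a, p.b_f, p.b_u]
            lo += [curves[i].temperature[0] - 5.0, 1e-3, -np.inf, -np.inf]
            hi += [curves[i].temperature[-1] + 5.0, 50.0, np.inf, np.inf]

    def resid(x):
        m_f, m_u = x[0], x[1]
        out = []
        for k, i in enumerate(good):
            tm, shape, b_f, b_u = x[2 + 4 * k: 6 + 4 * k]
            t, y = curves[i].temperature, curves[i].signal
            if model == "thermodynamic":
                out.append(_thermo_signal(t, tm, shape, dcp_u, m_f, b_f, m_u, b_u) - y)
            else:
                out.append(_boltzmann_signal(t, tm, shape, m_f, b_f, m_u, b_u) - y)
        return np.concatenate(out)

    sol = least_squares(resid, x0, bounds=(lo, hi), **_LSQ_KW)
    if not sol.success:
        raise CurveFitError(f"global fit did not converge: {sol.message}")

    m_f, m_u = float(sol.x[0]), float(sol.x[1])
    for k, i in enumerate(good):
        tm, shape, b_f, b_u = (float(v) for v in sol.x[2 + 4 * k: 6 + 4 * k])
        t = curves[i].temperature
        if model == "thermodynamic":
            ku = ku_unfolding(c_to_k(t), tm, shape, dcp_u)
            f = ku / (1.0 + ku)
            yhat = (1.0 - f) * (m_f * t + b_f) + f * (m_u * t + b_u)
            fits[i] = ThermoFit(
                tm=tm, dh_u=shape, dcp_u=dcp_u,
                m_f=m_f, b_f=b_f, m_u=m_u, b_u=b_u,
                residual_norm=float(np.linalg.norm(yhat - curves[i].signal)),
                converged=True, t_range=(float(t[0]), float(t[-1])),
            )
        else:
            yhat = _boltzmann_signal(t, tm, shape, m_f, b_f, m_u, b_u)
            fits[i] = BoltzmannFit(
                tm=tm, a=shape, m_f=m_f, b_f=b_f, m_u=m_u, b_u=b_u,
                residual_norm=float(np.linalg.norm(yhat - curves[i].signal)),
                converged=True, t_range=(float(t[0]), float(t[-1])),
            )
    return fits, failures


def fraction_unfolded_at(fit: CurveFit, t_celsius, *, extrapolation_margin: float = 5.0):
    """Fraction of protein unfolded at temperature(s) ``t_celsius``.

    Evaluates the fitted model's f_u, clipped to [0, 1].  A warning is
    issued when T lies more than ``extrapolation_margin`` Celsius outside
    the fitted data range.
    """
    t = np.asarray(t_celsius, dtype=float)
    lo, hi = fit.t_range
    if np.any(t < lo - extrapolation_margin) or np.any(t > hi + extrapolation_margin):
        warnings.warn(
            f"evaluating fraction unfolded {extrapolation_margin:g} C or more "
            f"outside the fitted range [{lo:.2f}, {hi:.2f}] C",
            stacklevel=2,
        )
    out = fit.fraction_unfolded(t)
    return float(out) if np.isscalar(t_celsius) else out


def _transition_window(fit: CurveFit):
    """Temperature interval where the fitted f_u lies in [0.25, 0.75]
    (the central half of the transition)."""
    if isinstance(fit, BoltzmannFit):
        w = fit.a * np.log(3.0)
        return fit.tm - w, fit.tm + w
    # thermodynamic: bracket numerically on a fine grid around Tm
    tc = fit.tm_celsius
    grid = np.linspace(tc - 20.0, tc + 20.0, 801)
    f = fit.fraction_unfolded(grid)
    inside = grid[(f >= 0.25) & (f <= 0.75)]
    if inside.size == 0:
        return tc, tc
    return float(inside[0]), float(inside[-1])


def normalize_curve(curve: MeltCurve, fit: CurveFit) -> MeltCurve:
    """Rescale a raw trace to the fraction-unfolded scale using the fitted
    dye baselines: (Y - folded) / (unfolded - folded), pointwise.

    The result keeps over/undershoot (no clipping) so residual structure
    survives.  Raises :class:`CurveFitError` when the fit carries no
    baselines or the baselines are inverted/degenerate across the central
    half of the transition.
    """
    if not fit.has_baselines:
        raise CurveFitError("fit has no baselines; was it obtained from raw data?")
    t = curve.temperature
    folded = fit.m_f * t + fit.b_f
    unfolded = fit.m_u * t + fit.b_u
    lo, hi = _transition_window(fit)
    mask = (t >= lo) & (t <= hi)
    check = mask if mask.any() else slice(None)
    if np.any((unfolded - folded)[check] <= 0):
        raise CurveFitError(
            "inverted or degenerate baselines across the transition region; "
            "curve cannot be normalized"
        )
    y = (curve.signal - folded) / (unfolded - folded)
    return replace(curve, signal=y, normalized=True)
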