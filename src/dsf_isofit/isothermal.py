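"""Coupled folding/binding equilibrium at a single temperature.

At a fixed temperature the system

    U + L  <=K_U=>  F + L  <=K_d=>  FL

is governed by two constants only: K_U = [U]/[F] (unfolding of the unbound
protein) and K_d = [F][L]/[FL] (dissociation).  Mass balance gives a
quadratic for the free ligand concentration [L], and the fraction of
unfolded protein follows

    f_u = 1 / (1 + (1/K_U) * (1 + [L]/K_d))

Fitting f_u against the total ligand concentration across a dilution
series ("a vertical slice" of the melt-curve family) therefore yields K_d
and K_U directly, with no thermodynamic parameters involved.

A closed-form corollary links the midpoint of that titration to K_d:

    EC50 = K_d / (1 - f_u0) + [P]_T / 2
    K_d  = (1 - f_u0) * (EC50 - [P]_T / 2)

where f_u0 = K_U/(1 + K_U) is the ligand-free fraction unfolded and EC50
is the total ligand concentration at which f_u has dropped to f_u0/2.
When EC50 approaches [P]_T/2 binding is stoichiometric and K_d can only
be bounded from above, not estimated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit, least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "IsothermalDataset",
    "BindingFit",
    "StoichiometricRegimeError",
    "FlatDataError",
    "free_ligand",
    "species_concentrations",
    "fraction_unfolded_model",
    "fit_isothermal",
    "ec50_hill",
    "kd_from_ec50",
    "ec50_from_kd",
]


class StoichiometricRegimeError(ValueError):
    """EC50 <= [P]_T/2: the titration midpoint is set by stoichiometry,
    not affinity, and K_d is not identifiable."""


class FlatDataError(RuntimeError):
    """The fraction unfolded does not respond to ligand at this
    temperature — nothing to fit."""


def free_ligand(L_total: float, P_total: float, K_d: float, K_U: float) -> float:
    """Free ligand concentration [L] at equilibrium, molar.

    Solves the mass-balance quadratic

        [L]^2 + ([P]_T - [L]_T + K_d(1+K_U)) [L] - [L]_T K_d(1+K_U) = 0

    and returns its unique non-negative root (the other root is
    unphysical).  Uses the subtraction-free form of the quadratic formula
    for numerical stability when K_d(1+K_U) >> [L]_T.
    """
    if L_total < 0 or P_total < 0 or K_U < 0:
        raise ValueError("concentrations and K_U must be non-negative")
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if L_total == 0.0:
        return 0.0
    if P_total == 0.0:
        return float(L_total)
    q = K_d * (1.0 + K_U)
    b = P_total - L_total + q          # [L]^2 + b[L] - L_T*q = 0
    disc = math.sqrt(b * b + 4.0 * L_total * q)
    if b >= 0:
        L = 2.0 * L_total * q / (disc + b)
    else:
        L = 0.5 * (disc - b)
    return float(min(max(L, 0.0), L_total))


def species_concentrations(L_total: float, P_total: float, K_d: float, K_U: float):
    """Equilibrium concentrations ([F], [U], [FL], [L]), molar.

    [FL] is computed from its own mass-balance quadratic in the
    subtraction-free (Morrison) form,

        [FL] = 2 [P]_T [L]_T / (B + sqrt(B^2 - 4 [P]_T [L]_T)),
        B = [P]_T + [L]_T + K_d (1 + K_U),

    which avoids the catastrophic cancellation of [L]_T - [L] when the
    ligand is nearly all free; [F] and [U] then follow from the protein
    balance, so [F] + [U] + [FL] = [P]_T holds to machine rounding.
    """
    if L_total < 0 or P_total < 0 or K_U < 0:
        raise ValueError("concentrations and K_U must be non-negative")
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if L_total == 0.0 or P_total == 0.0:
        FL = 0.0
    else:
        B = P_total + L_total + K_d * (1.0 + K_U)
        FL = 2.0 * P_total * L_total / (
            B + math.sqrt(B * B - 4.0 * P_total * L_total)
        )
    F = (P_total - FL) / (1.0 + K_U)
    U = K_U * F
    L = free_ligand(L_total, P_total, K_d, K_U)
    return F, U, FL, L


def fraction_unfolded_model(
    L_total, P_total: float, K_d: float, K_U: float
):
    """Fraction of protein unfolded at total ligand concentration [L]_T.

    Evaluates f_u = 1 / (1 + (1/K_U)(1 + [L]/K_d)) at the equilibrium free
    ligand concentration.  Accepts a scalar or array of [L]_T.
    """
    if K_U <= 0:
        raise ValueError("K_U must be positive")
    Lt = np.asarray(L_total, dtype=float)
    L = np.array([free_ligand(v, P_total, K_d, K_U) for v in np.atleast_1d(Lt)])
    f = 1.0 / (1.0 + (1.0 / K_U) * (1.0 + L / K_d))
    return float(f[0]) if Lt.ndim == 0 else f


def ec50_from_kd(K_d: float, P_total: float, f_u0: float) -> float:
    """Closed-form titration midpoint: EC50 = K_d/(1-f_u0) + [P]_T/2."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    if not 0.0 <= f_u0 < 1.0:
        raise ValueError("f_u0 must lie in [0, 1); f_u0 = 1 means fully "
                         "unfolded protein and no binding signal")
    return K_d / (1.0 - f_u0) + P_total / 2.0


def kd_from_ec50(EC50: float, P_total: float, f_u0: float) -> float:
    """Closed-form inverse: K_d = (1 - f_u0) * (EC50 - [P]_T/2).

    Raises :class:`StoichiometricRegimeError` when EC50 <= [P]_T/2, where
    the midpoint reflects stoichiometry rather than affinity.
    """
    if not 0.0 <= f_u0 < 1.0:
        raise ValueError("f_u0 must lie in [0, 1)")
    if EC50 <= P_total / 2.0:
        raise StoichiometricRegimeError(
            f"EC50 ({EC50:.3g} M) <= [P]_T/2 ({P_total / 2:.3g} M): "
            "binding is stoichiometric and K_d is not identifiable"
        )
    return (1.0 - f_u0) * (EC50 - P_total / 2.0)


@dataclass(frozen=True)
class IsothermalDataset:
    """(ligand concentration, fraction unfolded) points at one temperature.

    Parameters
    ----------
    temperature : float
        The slice temperature, Celsius (metadata; the fit itself is
        temperature-free).
    L_total : ndarray
        Total ligand concentrations, molar.
    f_u : ndarray
        Fraction unfolded at each concentration.
    P_total : float
        Total protein concentration, molar.
    sem : ndarray, optional
        Standard error of the mean of each f_u (used as fit weights).
    n_replicates : ndarray, optional
        Replicate count behind each point.
    """

    temperature: float
    L_total: np.ndarray
    f_u: np.ndarray
    P_total: float
    sem: Optional[np.ndarray] = None
    n_replicates: Optional[np.ndarray] = None

    def __post_init__(self):
        L = np.asarray(self.L_total, dtype=float)
        f = np.asarray(self.f_u, dtype=float)
        if L.shape != f.shape or L.ndim != 1:
            raise ValueError("L_total and f_u must be 1-D and equal length")
        if np.any(L < 0):
            raise ValueError("ligand concentrations must be >= 0")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fraction unfolded must lie in [0, 1]")
        if self.P_total <= 0:
            raise ValueError("P_total must be positive")
        order = np.argsort(L)
        object.__setattr__(self, "L_total", L[order])
        object.__setattr__(self, "f_u", f[order])
        for name in ("sem", "n_replicates"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != L.shape:
                    raise ValueError(f"{name} must match L_total in length")
                object.__setattr__(self, name, v[order])

    @property
    def has_zero_point(self) -> bool:
        return bool(np.any(self.L_total == 0.0))

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.L_total).size)


@dataclass(frozen=True)
class BindingFit:
    """Result of the isothermal coupled-equilibrium fit.

    ``kd_upper_bound`` is populated (and ``stoichiometric_regime`` set)
    when the fitted EC50 falls at or below the protein concentration, in
    which case ``K_d`` should be read as "smaller than the bound", not as
    a point estimate.
    """

    K_d: float
    K_U: float
    EC50: float
    K_d_se: Optional[float] = None
    K_U_se: Optional[float] = None
    EC50_se: Optional[float] = None
    stoichiometric_regime: bool = False
    kd_upper_bound: Optional[float] = None
    K_U_fixed: bool = False
    temperature: float = float("nan")
    P_total: float = float("nan")
    residual_norm: float = 0.0
    converged: bool = True

    @property
    def f_u0(self) -> float:
        """Ligand-free fraction unfolded, K_U/(1 + K_U)."""
        return self.K_U / (1.0 + self.K_U)

    def summary(self) -> str:
        kd_uM = self.K_d * 1e6
        ec50_uM = self.EC50 * 1e6
        if self.stoichiometric_regime:
            kd_txt = f"K_d < {self.kd_upper_bound * 1e6:.2g} uM (stoichiometric regime)"
        else:
            kd_txt = f"K_d = {kd_uM:.3g} uM"
        return (f"{kd_txt}; K_U = {self.K_U:.3g} "
                f"(f_u0 = {self.f_u0:.3g}); EC50 = {ec50_uM:.3g} uM")


def _hill_4pl(x, top, bottom, logmid, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - logmid)))


def ec50_hill(data: IsothermalDataset, *, pseudo_decades: float = 2.0) -> float:
    """Quick EC50 estimate from a 4-parameter logistic in log10 [L]_T.

    The zero-ligand point is placed at a pseudo-concentration
    ``pseudo_decades`` below the smallest non-zero dose.  The returned
    EC50 is the concentration at which the fitted curve crosses half the
    zero-ligand plateau (top/2) — the midpoint definition used throughout,
    *not* the logistic's own inflection parameter.  Intended only for
    initial guesses and rapid triage; the coupled-equilibrium fit is the
    quantitative route.
    """
    L, f = data.L_total, data.f_u
    nz = L[L > 0]
    if nz.size < 3:
        raise FlatDataError("need at least 3 non-zero ligand concentrations")
    floor = nz.min() * 10.0 ** (-pseudo_decades)
    x = np.log10(np.where(L > 0, L, floor))
    if f[np.argmax(L)] >= f[np.argmin(L)]:
        raise FlatDataError("fraction unfolded does not decrease with ligand")

    top0, bot0 = float(f.max()), float(max(f.min(), 0.0))
    mid0 = float(np.median(x))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _hill_4pl, x, f,
                p0=[top0, bot0, mid0, 1.0],
                bounds=([0.0, 0.0, x.min() - 3, 0.05],
                        [1.5, 1.0, x.max() + 3, 10.0]),
                maxfev=10000,
            )
    except RuntimeError as exc:
        raise FlatDataError(f"logistic midpoint fit failed: {exc}") from exc
    top, bottom, logmid, hill = popt
    half = top / 2.0
    if half <= bottom:
        raise FlatDataError("fitted plateau never drops to half its "
                            "zero-ligand value within the logistic model")
    ratio = (top - bottom) / (half - bottom) - 1.0
    x50 = logmid + np.log10(ratio) / hill
    ec50 = float(10.0 ** x50)
    if not (nz.min() <= ec50 <= nz.max()):
        warnings.warn(
            f"Hill-estimated EC50 {ec50:.3g} M lies outside the tested "
            f"ladder [{nz.min():.3g}, {nz.max():.3g}] M", stacklevel=2,
        )
    return ec50


def _initial_guesses(data: IsothermalDataset, fix_K_U: Optional[float]):
    if fix_K_U is not None:
        ku0 = fix_K_U
    elif data.has_zero_point:
        f0 = float(np.mean(data.f_u[data.L_total == 0.0]))
        f0 = min(max(f0, 1e-4), 1.0 - 1e-4)
        ku0 = f0 / (1.0 - f0)
    else:
        f0 = min(max(float(data.f_u.max()), 1e-4), 1.0 - 1e-4)
        ku0 = f0 / (1.0 - f0)
    ku0 = float(np.clip(ku0, 1e-4, 1e4))
    fu0 = ku0 / (1.0 + ku0)
    try:
        ec50 = ec50_hill(data)
        kd0 = kd_from_ec50(ec50, data.P_total, fu0)
    except (FlatDataError, StoichiometricRegimeError, ValueError):
        nz = data.L_total[data.L_total > 0]
        kd0 = float(np.median(nz)) if nz.size else 1e-6
    return float(np.clip(kd0, 1e-15, 1.0)), ku0


def fit_isothermal(
    data: IsothermalDataset,
    fix_K_U: Optional[float] = None,
    *,
    min_span: float = 0.05,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> BindingFit:
    """Fit (K_d, K_U) to fraction-unfolded-versus-ligand data.

    Weighted least squares (1/sem^2 when per-point standard errors are
    available and positive, unweighted otherwise) on the coupled
    folding/binding model, optimised in log10 parameter space to enforce
    positivity.  With ``fix_K_U`` only K_d is free; otherwise K_U must be
    anchored by a zero-ligand point in the data.

    The reported EC50 follows from the closed-form relation
    EC50 = K_d/(1-f_u0) + [P]_T/2; when it falls at or below [P]_T the
    stoichiometric-regime flag is set and K_d is reported as an upper
    bound (1-f_u0)([P]_T/2).

    ``bootstrap > 0`` adds residual-bootstrap standard errors (seeded) on
    top of the Jacobian-based ones.
    """
    if fix_K_U is None and not data.has_zero_point:
        raise ValueError(
            "K_U is unidentifiable: provide a zero-ligand point or fix_K_U"
        )
    if fix_K_U is None and data.n_distinct < 4:
        raise ValueError("need >= 4 distinct ligand concentrations for the "
                         "two-parameter fit")
    if data.n_distinct < 2:
        raise ValueError("need >= 2 distinct ligand concentrations")
    span = float(data.f_u.max() - data.f_u.min())
    if span < min_span:
        raise FlatDataError(
            f"fraction unfolded spans only {span:.3g} (< {min_span:g}); the "
            "ligand does not measurably stabilize the protein at this "
            "temperature"
        )

    if data.sem is not None and np.all(data.sem > 0):
        w = 1.0 / data.sem
    else:
        w = np.ones_like(data.f_u)

    kd0, ku0 = _initial_guesses(data, fix_K_U)
    L, f, P = data.L_total, data.f_u, data.P_total

    if fix_K_U is None:
        def resid(x):
            kd, ku = 10.0 ** x[0], 10.0 ** x[1]
            return w * (fraction_unfolded_model(L, P, kd, ku) - f)
        x0 = [np.log10(kd0), np.log10(ku0)]
    else:
        def resid(x):
            kd = 10.0 ** x[0]
            return w * (fraction_unfolded_model(L, P, kd, fix_K_U) - f)
        x0 = [np.log10(kd0)]

    sol = least_squares(resid, x0, method="lm" if len(x0) < len(f) else "trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
    if not sol.success:
        raise FlatDataError(f"isothermal fit did not converge: {sol.message}")

    kd = float(10.0 ** sol.x[0])
    ku = float(fix_K_U if fix_K_U is not None else 10.0 ** sol.x[1])
    fu0 = ku / (1.0 + ku)
    ec50 = ec50_from_kd(kd, P, fu0)

    # covariance of log10-parameters from the Jacobian; delta method to
    # the linear scale
    kd_se = ku_se = ec50_se = None
    dof = len(f) - len(x0)
    if dof > 0:
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
            ln10 = math.log(10.0)
            kd_se = kd * ln10 * math.sqrt(max(cov[0, 0], 0.0))
            if fix_K_U is None:
                ku_se = ku * ln10 * math.sqrt(max(cov[1, 1], 0.0))
                # EC50 = kd/(1-fu0) + P/2 ; gradient wrt (log10 kd, log10 ku)
                d_ec50_dkd = 1.0 / (1.0 - fu0)
                dfu0_dku = 1.0 / (1.0 + ku) ** 2
                d_ec50_dku = kd / (1.0 - fu0) ** 2 * dfu0_dku
                g = np.array([d_ec50_dkd * kd * ln10, d_ec50_dku * ku * ln10])
                ec50_se = math.sqrt(max(g @ cov @ g, 0.0))
            else:
                ec50_se = kd_se / (1.0 - fu0)
        except np.linalg.LinAlgError:
            pass

    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        model_f = fraction_unfolded_model(L, P, kd, ku)
        res = f - model_f
        draws = []
        for _ in range(bootstrap):
            f_star = np.clip(model_f + rng.choice(res, size=res.size), 0.0, 1.0)
            try:
                b = fit_isothermal(
                    IsothermalDataset(data.temperature, L, f_star, P,
                                      sem=data.sem),
                    fix_K_U=fix_K_U, min_span=0.0, bootstrap=0,
                )
                draws.append((b.K_d, b.K_U))
            except (FlatDataError, ValueError):
                continue
        if len(draws) >= 10:
            arr = np.array(draws)
            kd_se = float(np.std(arr[:, 0], ddof=1))
            if fix_K_U is None:
                ku_se = float(np.std(arr[:, 1], ddof=1))

    stoich = ec50 <= P
    bound = (1.0 - fu0) * (P / 2.0) if stoich else None
    if stoich:
        logger.info(
            "EC50 %.3g M <= [P]_T %.3g M: stoichiometric regime, reporting "
            "K_d < %.3g M", ec50, P, bound,
        )
    return BindingFit(
        K_d=kd, K_U=ku, EC50=ec50,
        K_d_se=kd_se, K_U_se=ku_se, EC50_se=ec50_se,
        stoichiometric_regime=bool(stoich), kd_upper_bound=bound,
        K_U_fixed=fix_K_U is not None,
        temperature=data.temperature, P_total=P,
        residual_norm=float(np.linalg.norm(sol.fun)), converged=True,
    )
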