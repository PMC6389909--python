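"""Temperature dependence of the unfolding and binding equilibria.

Two-state protein unfolding is described by the integrated Gibbs-Helmholtz
relation with a temperature-independent heat-capacity change, anchored at
the melting temperature Tm (where dG_U = 0 by definition):

    dG_U(T) = dH_U * (1 - T/Tm) - dCp_U * (Tm - T + T * ln(T/Tm))
    K_U(T)  = exp(-dG_U(T) / (R*T))

Ligand unbinding (FL <=> F + L, dissociation constant K_d) uses the same
integrated form with constant dCp_b, anchored by K_d at Tm:

    dG_b(Tm) = R * Tm * ln(Kd_Tm)          (binding free energy, < 0)
    dS_b(T)  = (dH_b - dG_b(Tm)) / Tm + dCp_b * ln(T/Tm)
    dG_b(T)  = dH_b + dCp_b * (T - Tm) - T * dS_b(T)
    K_d(T)   = exp(dG_b(T) / (R*T))

With dCp_b = 0 this reduces to the van't Hoff relation.  All temperatures
in kelvin, energies in kcal/mol.
"""

from __future__ import annotations

import numpy as np

from .constants import R_KCAL

__all__ = ["delta_g_unfolding", "ku_unfolding", "kd_binding"]


def delta_g_unfolding(t_kelvin, tm_kelvin: float, dh_u: float, dcp_u: float):
    """Unfolding free energy dG_U(T) in kcal/mol.

    Parameters
    ----------
    t_kelvin : float or ndarray
        Temperature(s), K.
    tm_kelvin : float
        Melting temperature, K (dG_U(Tm) = 0).
    dh_u : float
        Unfolding enthalpy at Tm, kcal/mol.
    dcp_u : float
        Unfolding heat-capacity change, kcal/mol/K (assumed constant).
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0) or tm_kelvin <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    return dh_u * (1.0 - t / tm_kelvin) - dcp_u * (
        tm_kelvin - t + t * np.log(t / tm_kelvin)
    )


def ku_unfolding(t_kelvin, tm_kelvin: float, dh_u: float, dcp_u: float):
    """Unfolding equilibrium constant K_U(T) = exp(-dG_U / RT).

    Equals 1 exactly at T = Tm.
    """
    t = np.asarray(t_kelvin, dtype=float)
    dg = delta_g_unfolding(t, tm_kelvin, dh_u, dcp_u)
    return np.exp(-dg / (R_KCAL * t))


def kd_binding(t_kelvin, tm_kelvin: float, kd_tm: float, dh_b: float, dcp_b: float):
    """Dissociation constant K_d(T), molar, anchored at K_d(Tm) = kd_tm.

    ``dh_b`` and ``dcp_b`` are the enthalpy and heat-capacity change of
    *binding* at Tm (kcal/mol, kcal/mol/K); exothermic binding has
    dh_b < 0 and weakens (K_d rises) as T increases above Tm.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0) or tm_kelvin <= 0:
        raise ValueError("temperatures must be positive (kelvin)")
    if kd_tm <= 0:
        raise ValueError("kd_tm must be positive")
    dg_b_tm = R_KCAL * tm_kelvin * np.log(kd_tm)
    ds_b = (dh_b - dg_b_tm) / tm_kelvin + dcp_b * np.log(t / tm_kelvin)
    dg_b = dh_b + dcp_b * (t - tm_kelvin) - t * ds_b
    return np.exp(dg_b / (R_KCAL * t))
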