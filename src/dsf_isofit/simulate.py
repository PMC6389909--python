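"""Thermodynamic simulator for DSF melt-curve families.

Generates fraction-unfolded traces over a temperature grid for a ladder of
ligand concentrations, from a full thermodynamic parameterisation of both
equilibria: unfolding (Tm, dH_U, dCp_U) and binding (Kd at Tm, dH_b,
dCp_b).  At every (T, [L]_T) point the simulator evaluates K_U(T) and
K_d(T) (see :mod:`dsf_isofit.thermo`) and then calls the *same*
coupled-equilibrium solver the isothermal fitter uses
(:func:`dsf_isofit.isothermal.fraction_unfolded_model`), so the simulator
and the fitter share one equilibrium oracle.

Optional i.i.d. Gaussian noise is added on the normalized (0..1) scale;
optional linear dye baselines turn the traces into raw-style signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import c_to_k, k_to_c
from .curves import MeltCurve
from .isothermal import fraction_unfolded_model
from .thermo import kd_binding, ku_unfolding

__all__ = [
    "SimSpec",
    "default_ligand_ladder",
    "mbp_like_spec",
    "ku_at_temperature",
    "kd_at_temperature",
    "simulate_fraction_unfolded",
    "generate_dataset",
]


def default_ligand_ladder(top: float = 500e-6, n_dilutions: int = 11) -> np.ndarray:
    """Zero plus a two-fold dilution series: 12 concentrations by default,
    500 uM down to ~0.49 uM, matching a typical dose-response plate row."""
    series = top / 2.0 ** np.arange(n_dilutions)
    return np.concatenate([[0.0], series[::-1]])


@dataclass(frozen=True)
class SimSpec:
    """Thermodynamic parameter set for simulated unfolding data.

    Parameters
    ----------
    tm : float
        Ligand-free melting temperature, kelvin.
    dh_u : float
        Unfolding enthalpy at Tm, kcal/mol (> 0).
    dcp_u : float
        Unfolding heat-capacity change, kcal/mol/K.
    dh_b : float
        Binding enthalpy at Tm, kcal/mol (exothermic < 0).
    dcp_b : float
        Binding heat-capacity change, kcal/mol/K.
    kd_tm : float
        Dissociation constant at Tm, molar.
    p_total : float
        Total protein concentration, molar.
    ligand_ladder : ndarray
        Total ligand concentrations, molar.
    temp_grid : ndarray or None
        Temperatures in Celsius; default Tm +/- 15 C in 0.25 C steps.
    noise_sigma : float
        Standard deviation of Gaussian noise added on the 0..1 scale.
    seed : int
        Seed for the noise stream (ignored when noise_sigma == 0).
    baselines : tuple (m_F, b_F, m_U, b_U) or None
        When given, emit raw-style signal with linear dye baselines
        instead of normalized fraction unfolded.
    """

    tm: float = 323.15
    dh_u: float = 120.0
    dcp_u: float = 4.0
    dh_b: float = -10.0
    dcp_b: float = -0.5
    kd_tm: float = 1e-6
    p_total: float = 2e-6
    ligand_ladder: np.ndarray = field(default_factory=default_ligand_ladder)
    temp_grid: Optional[np.ndarray] = None
    noise_sigma: float = 0.0
    seed: int = 0
    baselines: Optional[Tuple[float, float, float, float]] = None

    def __post_init__(self):
        if self.dh_u <= 0:
            raise ValueError("dh_u must be positive")
        if self.kd_tm <= 0 or self.p_total <= 0:
            raise ValueError("kd_tm and p_total must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        ladder = np.asarray(self.ligand_ladder, dtype=float)
        if np.any(ladder < 0):
            raise ValueError("ligand concentrations must be >= 0")
        object.__setattr__(self, "ligand_ladder", ladder)
        grid = self.temp_grid
        if grid is None:
            tc = k_to_c(self.tm)
            grid = np.arange(tc - 15.0, tc + 15.0 + 1e-9, 0.25)
        else:
            grid = np.asarray(grid, dtype=float)
            if not np.all(np.diff(grid) > 0):
                raise ValueError("temp_grid must be strictly increasing")
        object.__setattr__(self, "temp_grid", grid)

    @property
    def tm_celsius(self) -> float:
        return k_to_c(self.tm)

    def to_dict(self) -> dict:
        return {
            "tm_K": self.tm, "dh_u_kcal_mol": self.dh_u,
            "dcp_u_kcal_mol_K": self.dcp_u, "dh_b_kcal_mol": self.dh_b,
            "dcp_b_kcal_mol_K": self.dcp_b, "kd_tm_M": self.kd_tm,
            "p_total_M": self.p_total,
            "ligand_ladder_M": self.ligand_ladder.tolist(),
            "noise_sigma": self.noise_sigma, "seed": self.seed,
            "baselines": list(self.baselines) if self.baselines else None,
        }


def mbp_like_spec(**overrides) -> SimSpec:
    """A maltose-binding-protein-like parameter set: Tm = 50 C,
    K_d(Tm) = 1 uM, dH_U = 120 kcal/mol, dH_b = -10 kcal/mol,
    dCp_U = 4 and dCp_b = -0.5 kcal/mol/K, 2 uM protein."""
    return SimSpec(**overrides)


def ku_at_temperature(spec: SimSpec, t_kelvin) -> float:
    """Unfolding constant K_U(T); equals 1 at T = spec.tm."""
    return ku_unfolding(t_kelvin, spec.tm, spec.dh_u, spec.dcp_u)


def kd_at_temperature(spec: SimSpec, t_kelvin) -> float:
    """Dissociation constant K_d(T), molar; equals spec.kd_tm at T = spec.tm."""
    return kd_binding(t_kelvin, spec.tm, spec.kd_tm, spec.dh_b, spec.dcp_b)


def simulate_fraction_unfolded(spec: SimSpec, t_kelvin: float, L_total: float) -> float:
    """Noise-free fraction unfolded at one (temperature, ligand) point,
    via the shared coupled-equilibrium solver."""
    kd = float(kd_at_temperature(spec, t_kelvin))
    ku = float(ku_at_temperature(spec, t_kelvin))
    return fraction_unfolded_model(L_total, spec.p_total, kd, ku)


def generate_dataset(spec: SimSpec) -> list[MeltCurve]:
    """One melt curve per ladder entry over the temperature grid.

    Noise (when noise_sigma > 0) is drawn per curve from deterministic
    substreams of ``spec.seed``, added on the normalized scale; curves
    are bit-identical across runs when noise_sigma == 0.  With baselines
    configured, the (noisy) fraction unfolded is wrapped in the linear
    dye-baseline signal model to emit raw-style traces.
    """
    grid_c = spec.temp_grid
    grid_k = c_to_k(grid_c)
    kd_t = kd_at_temperature(spec, grid_k)
    ku_t = ku_at_temperature(spec, grid_k)

    children = np.random.SeedSequence(spec.seed).spawn(len(spec.ligand_ladder))
    curves = []
    for i, L in enumerate(spec.ligand_ladder):
        f = np.array([
            fraction_unfolded_model(L, spec.p_total, kd_t[j], ku_t[j])
            for j in range(grid_k.size)
        ])
        if spec.noise_sigma > 0:
            rng = np.random.default_rng(children[i])
            f = f + rng.normal(0.0, spec.noise_sigma, size=f.size)
        well = f"L{i + 1:02d}"
        if spec.baselines is not None:
            m_f, b_f, m_u, b_u = spec.baselines
            y = (1.0 - f) * (m_f * grid_c + b_f) + f * (m_u * grid_c + b_u)
            curves.append(MeltCurve(grid_c, y, ligand_conc_total=float(L),
                                    replicate_id=well, well=well,
                                    normalized=False))
        else:
            # guard the container's sanity band against extreme noise draws
            f = np.clip(f, -0.499, 1.499)
            curves.append(MeltCurve(grid_c, f, ligand_conc_total=float(L),
                                    replicate_id=well, well=well,
                                    normalized=True))
    return curves
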