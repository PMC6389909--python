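"""End-to-end orchestration: fit curves, slice, fit binding, report.

The pipeline mirrors how an analyst works through a plate: every melt
curve is fit (with globally shared baseline slopes on raw data), the
fraction unfolded is read off each fit at one or more slice temperatures,
replicates are aggregated (mean +/- standard error), and the coupled
folding/binding model is fit per slice temperature.  A conventional
dTm-versus-ligand table is included for continuity with T_m-shift
reporting, but plays no part in the K_d determination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import (
    BoltzmannFit,
    CurveFitError,
    MeltCurve,
    ThermoFit,
    fit_global,
    fraction_unfolded_at,
)
from .isothermal import (
    BindingFit,
    FlatDataError,
    IsothermalDataset,
    fit_isothermal,
)

logger = logging.getLogger(__name__)

__all__ = ["AssayConfig", "PipelineReport", "run_pipeline",
           "slice_at_temperature", "write_report"]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class AssayConfig:
    """Assay constants and pipeline choices.

    ``dcp_u`` is the fixed unfolding heat-capacity change (kcal/mol/K)
    required by the thermodynamic curve model; it typically comes from
    calorimetry or a buried-surface-area estimate.
    """

    protein_conc_total: float
    slice_temperatures: Sequence[float] = ()
    model: str = "thermodynamic"
    dcp_u: Optional[float] = None
    fix_ku: Optional[float] = None
    truncate_after_max: bool = False
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.protein_conc_total <= 0:
            raise ValueError("protein_conc_total must be positive")
        if self.model not in ("thermodynamic", "boltzmann"):
            raise ValueError("model must be 'thermodynamic' or 'boltzmann'")
        if self.model == "thermodynamic" and self.dcp_u is None:
            raise ValueError("dcp_u is required for the thermodynamic model")


@dataclass
class PipelineReport:
    config: AssayConfig
    fits: list                      # per-curve fit or None
    curve_failures: dict            # curve index -> message
    curve_table: pd.DataFrame
    delta_tm_table: pd.DataFrame
    binding_fits: dict              # slice T (C) -> BindingFit
    binding_failures: dict          # slice T (C) -> message
    datasets: dict = field(default_factory=dict)  # slice T -> IsothermalDataset

    def to_dict(self) -> dict:
        def bf_dict(b: BindingFit) -> dict:
            return {
                "temperature_C": b.temperature,
                "K_d_M": b.K_d, "K_d_se_M": b.K_d_se,
                "K_U": b.K_U, "K_U_se": b.K_U_se, "K_U_fixed": b.K_U_fixed,
                "f_u0": b.f_u0,
                "EC50_M": b.EC50, "EC50_se_M": b.EC50_se,
                "stoichiometric_regime": b.stoichiometric_regime,
                "K_d_upper_bound_M": b.kd_upper_bound,
                "residual_norm": b.residual_norm,
            }

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": {
                "protein_conc_total_M": self.config.protein_conc_total,
                "model": self.config.model,
                "dcp_u_kcal_mol_K": self.config.dcp_u,
                "fix_ku": self.config.fix_ku,
                "slice_temperatures_C": list(self.config.slice_temperatures),
            },
            "curve_fits": self.curve_table.to_dict(orient="records"),
            "curve_failures": {str(k): v for k, v in self.curve_failures.items()},
            "delta_tm": self.delta_tm_table.to_dict(orient="records"),
            "isothermal": {f"{t:g}": bf_dict(b)
                           for t, b in self.binding_fits.items()},
            "isothermal_failures": {f"{t:g}": m
                                    for t, m in self.binding_failures.items()},
        }


def _tm_celsius(fit) -> float:
    return fit.tm_celsius if isinstance(fit, ThermoFit) else fit.tm


def _curve_table(curves, fits, failures) -> pd.DataFrame:
    rows = []
    for i, (c, f) in enumerate(zip(curves, fits)):
        row = {
            "well": c.well or f"W{i + 1:02d}",
            "replicate_group": c.replicate_id,
            "ligand_conc_molar": c.ligand_conc_total,
        }
        if f is None:
            row.update(model=None, converged=False,
                       error=failures.get(i, "unfit"))
        elif isinstance(f, ThermoFit):
            row.update(model="thermodynamic", tm_C=f.tm_celsius,
                       dh_u_kcal_mol=f.dh_u, dcp_u_kcal_mol_K=f.dcp_u,
                       m_f=f.m_f, b_f=f.b_f, m_u=f.m_u, b_u=f.b_u,
                       residual_norm=f.residual_norm, converged=f.converged)
        else:
            row.update(model="boltzmann", tm_C=f.tm, a_C=f.a,
                       m_f=f.m_f, b_f=f.b_f, m_u=f.m_u, b_u=f.b_u,
                       residual_norm=f.residual_norm, converged=f.converged)
        rows.append(row)
    return pd.DataFrame(rows)


def _delta_tm_table(curves, fits) -> pd.DataFrame:
    """Mean fitted Tm per ligand concentration, shifted against the
    zero-ligand mean. Reported for continuity with conventional
    T_m-shift analysis; never used for K_d."""
    recs: dict[float, list[float]] = {}
    for c, f in zip(curves, fits):
        if f is None:
            continue
        recs.setdefault(c.ligand_conc_total, []).append(_tm_celsius(f))
    if not recs:
        return pd.DataFrame(columns=["ligand_conc_molar", "tm_C", "delta_tm_C"])
    concs = sorted(recs)
    tm_mean = {L: float(np.mean(v)) for L, v in recs.items()}
    tm0 = tm_mean.get(0.0, tm_mean[concs[0]])
    return pd.DataFrame([
        {"ligand_conc_molar": L, "tm_C": tm_mean[L],
         "delta_tm_C": tm_mean[L] - tm0, "n_curves": len(recs[L])}
        for L in concs
    ])


def slice_at_temperature(
    curves: Sequence[MeltCurve],
    fits: Sequence,
    slice_temp_c: float,
    p_total: float,
) -> IsothermalDataset:
    """Build the isothermal dataset at one temperature.

    Fraction unfolded is evaluated from each successful fit; curves
    sharing (replicate group, ligand concentration) are aggregated as
    mean +/- standard error of the mean.
    """
    groups: dict[tuple, list[float]] = {}
    for c, f in zip(curves, fits):
        if f is None:
            continue
        # replicates of a condition are wells with the same ligand
        # concentration; group on concentration
        groups.setdefault(c.ligand_conc_total, []).append(
            float(fraction_unfolded_at(f, slice_temp_c))
        )
    if not groups:
        raise FlatDataError("no successfully fitted curves to slice")
    L = np.array(sorted(groups))
    f_u = np.array([np.mean(groups[v]) for v in L])
    n = np.array([len(groups[v]) for v in L], dtype=float)
    sem = np.array([
        np.std(groups[v], ddof=1) / np.sqrt(len(groups[v]))
        if len(groups[v]) > 1 else np.nan
        for v in L
    ])
    if np.any(np.isnan(sem)):
        sem_arr = None
    else:
        sem_arr = sem
    return IsothermalDataset(
        temperature=slice_temp_c, L_total=L, f_u=np.clip(f_u, 0.0, 1.0),
        P_total=p_total, sem=sem_arr, n_replicates=n,
    )


def run_pipeline(config: AssayConfig, curves: Sequence[MeltCurve]) -> PipelineReport:
    """Fit curves -> slice -> fit binding, isolating partial failures.

    Returns a :class:`PipelineReport`; individual curve or slice failures
    are recorded and the rest of the analysis completes.
    """
    if config.truncate_after_max:
        curves = [c.truncated_after_max() for c in curves]

    logger.info(
        "pipeline: %d curves, model=%s, dCp_U=%s kcal/mol/K (fixed), "
        "[P]_T=%.3g M, fix_K_U=%s",
        len(curves), config.model, config.dcp_u,
        config.protein_conc_total, config.fix_ku,
    )
    fits, failures = fit_global(curves, model=config.model, dcp_u=config.dcp_u)
    for i, msg in failures.items():
        logger.warning("curve %d (%s) flagged: %s", i, curves[i].well, msg)

    binding: dict[float, BindingFit] = {}
    bind_fail: dict[float, str] = {}
    datasets: dict[float, IsothermalDataset] = {}
    for t in config.slice_temperatures:
        try:
            ds = slice_at_temperature(curves, fits, t, config.protein_conc_total)
            datasets[t] = ds
            b = fit_isothermal(ds, fix_K_U=config.fix_ku)
            binding[t] = b
            logger.info("slice %.2f C: %s", t, b.summary())
        except (FlatDataError, ValueError, CurveFitError) as exc:
            bind_fail[t] = str(exc)
            logger.warning("slice %.2f C failed: %s", t, exc)

    return PipelineReport(
        config=config, fits=list(fits), curve_failures=failures,
        curve_table=_curve_table(curves, fits, failures),
        delta_tm_table=_delta_tm_table(curves, fits),
        binding_fits=binding, binding_failures=bind_fail,
        datasets=datasets,
    )


def write_report(report: PipelineReport, out_dir) -> dict:
    """Write report.json plus curve_fits.csv / delta_tm.csv /
    isothermal.csv under ``out_dir``; returns the JSON payload."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    report.curve_table.to_csv(out / "curve_fits.csv", index=False)
    report.delta_tm_table.to_csv(out / "delta_tm.csv", index=False)
    pd.DataFrame(list(payload["isothermal"].values())).to_csv(
        out / "isothermal.csv", index=False
    )
    return payload


def plot_isothermal(dataset: IsothermalDataset, fit: BindingFit, path) -> None:
    """QC figure: f_u against log10 ligand concentration with the fitted
    coupled-equilibrium curve.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .isothermal import fraction_unfolded_model

    nz = dataset.L_total[dataset.L_total > 0]
    floor = nz.min() / 100.0 if nz.size else 1e-9
    x = np.where(dataset.L_total > 0, dataset.L_total, floor)
    grid = np.geomspace(floor, x.max() * 2, 200)
    model = fraction_unfolded_model(grid, dataset.P_total, fit.K_d, fit.K_U)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if dataset.sem is not None:
        ax.errorbar(x, dataset.f_u, yerr=dataset.sem, fmt="o", ms=4, capsize=2)
    else:
        ax.plot(x, dataset.f_u, "o", ms=4)
    ax.plot(grid, model, "-", lw=1.5)
    ax.set_xscale("log")
    ax.set_xlabel("total ligand (M)")
    ax.set_ylabel("fraction unfolded")
    ax.set_title(f"{dataset.temperature:g} C: {fit.summary()}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
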