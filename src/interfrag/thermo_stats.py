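"""End-point binding-enthalpy thermodynamics and scaling regression.

The binding reaction is treated end-point: with the convention that no
waters stay bound to the free target or ligand (T = L = 0) and s >= 0
waters join the complex from bulk, the reaction heat is

    drH = dfH(complex[H2O]_s) - dfH(target) - dfH(ligand) - s * dfH(H2O)

in kcal/mol, from semi-empirical QM heats of formation.  Calculated
reaction heats are related to experimental binding enthalpies by simple
linear regression

    dHb_exp_i = alpha * drH_i + beta + eps_i        (optionally beta = 0)

whose statistics follow fixed conventions: with an intercept R^2 is
centred and the error degrees of freedom are N - 2; without an intercept
R^2 is uncentred (SStot = sum y^2) and the dof are N - 1.  RMSE is
sqrt(SSres / dof), F = (SStot - SSres) / (SSres / dof), and for a
one-predictor model t_alpha = sqrt(F).  Leave-one-out cross-validation
refits excluding each system in turn and reports
R^2_cv = 1 - PRESS / SStot with SStot in the model's convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CAL_PER_JOULE",
    "HessInput",
    "SystemRecord",
    "RegressionResult",
    "StatsBundle",
    "reaction_heat",
    "fit_scaling",
    "stats_from_residuals",
    "loo_cv_r2",
    "predict_binding_enthalpy",
    "convert_enthalpy_units",
    "read_energy_table",
]

#: thermochemical calorie: 1 cal = 4.184 J exactly
CAL_PER_JOULE = 4.184


@dataclass
class HessInput:
    """Heats of formation (kcal/mol) entering the end-point reaction.

    ``s`` is the number of water molecules taken from bulk into the
    complex interface; the free target and ligand are modelled without
    bound waters (T = L = 0).
    """

    dfH_complex: float
    dfH_target: float
    dfH_ligand: float
    dfH_water: float = 0.0
    s: int = 0
    T: int = 0
    L: int = 0

    def __post_init__(self) -> None:
        if self.T != 0 or self.L != 0:
            raise ValueError("the protocol convention fixes T = L = 0")
        if self.s < 0:
            raise ValueError("s must be non-negative (waters come from bulk)")


def reaction_heat(h: HessInput) -> float:
    """Hess's-law reaction heat of binding, kcal/mol."""
    values = (h.dfH_complex, h.dfH_target, h.dfH_ligand, h.dfH_water)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("heats of formation must be finite")
    return h.dfH_complex - h.dfH_target - h.dfH_ligand - h.s * h.dfH_water


@dataclass
class SystemRecord:
    """One target-ligand system under one solvent model."""

    system_id: str
    drH: float
    dHb_exp: float
    ligand_mw: Optional[float] = None
    solvent_model: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.dHb_exp):
            raise ValueError(f"{self.system_id}: dHb_exp must be finite")


class StatsBundle(NamedTuple):
    r2: float
    F: float
    t_alpha: float
    rmse: float


@dataclass
class RegressionResult:
    """Fitted scaling model with the full statistics block."""

    alpha: float
    beta: Optional[float]  # None for the no-intercept model
    residuals: np.ndarray
    r2: float
    r2_cv: float
    F: float
    t_alpha: float
    t_beta: Optional[float]
    rmse: float
    N: int
    p: int

    def predict(self, drH) -> np.ndarray:
        return predict_binding_enthalpy(drH, self.alpha, self.beta)


def _xy(records: Sequence[SystemRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([r.drH for r in records], dtype=float)
    y = np.array([r.dHb_exp for r in records], dtype=float)
    return x, y


def _ols(
    x: np.ndarray, y: np.ndarray, with_intercept: bool
) -> tuple[float, Optional[float]]:
    if with_intercept:
        X = np.column_stack([x, np.ones_like(x)])
        (alpha, beta), *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(alpha), float(beta)
    alpha = float(np.dot(x, y) / np.dot(x, x))
    return alpha, None


def fit_scaling(
    records: Sequence[SystemRecord], with_intercept: bool = True
) -> RegressionResult:
    """Ordinary least squares of experimental dHb on calculated drH."""
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 systems, got {n}")
    x, y = _xy(records)
    if np.ptp(x) == 0:
        raise ValueError("drH values are all identical; regression degenerate")

    alpha, beta = _ols(x, y, with_intercept)
    pred = alpha * x + (beta or 0.0)
    residuals = y - pred
    p = 2 if with_intercept else 1
    r2, F, t_alpha, rmse = stats_from_residuals(residuals, y, p)

    t_beta = None
    if with_intercept:
        ssres = float(np.sum(residuals**2))
        sigma2 = ssres / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_beta = math.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))
        t_beta = beta / se_beta if se_beta > 0 else math.inf

    r2_cv = loo_cv_r2(records, with_intercept) if n >= 4 else math.nan
    return RegressionResult(
        alpha=alpha,
        beta=beta,
        residuals=residuals,
        r2=r2,
        r2_cv=r2_cv,
        F=F,
        t_alpha=t_alpha,
        t_beta=t_beta,
        rmse=rmse,
        N=n,
        p=p,
    )


def stats_from_residuals(
    residuals: Sequence[float], y: Sequence[float], p: int
) -> StatsBundle:
    """R^2, F, t_alpha and RMSE from residual magnitudes alone.

    Only squared residuals enter, so absolute values (as printed in
    benchmark tables) work as well as signed ones.  ``p`` = 2 selects
    the centred (intercept) conventions, ``p`` = 1 the uncentred
    (no-intercept) ones.
    """
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    eps = np.asarray(residuals, dtype=float)
    yv = np.asarray(y, dtype=float)
    if eps.shape != yv.shape:
        raise ValueError("residuals and y must have equal length")
    n = len(yv)
    ssres = float(np.sum(eps**2))
    sstot = float(np.sum((yv - yv.mean()) ** 2)) if p == 2 else float(
        np.sum(yv**2)
    )
    if ssres == 0:
        return StatsBundle(r2=1.0, F=math.inf, t_alpha=math.inf, rmse=0.0)
    r2 = 1.0 - ssres / sstot if sstot > 0 else -math.inf
    dof = n - p
    F = (sstot - ssres) / (ssres / dof)
    rmse = math.sqrt(ssres / dof)
    t_alpha = math.sqrt(max(F, 0.0))
    return StatsBundle(r2=r2, F=F, t_alpha=t_alpha, rmse=rmse)


def loo_cv_r2(
    records: Sequence[SystemRecord], with_intercept: bool = True
) -> float:
    """Leave-one-out cross-validated R^2 of the scaling regression.

    PRESS = sum of squared prediction errors with each system predicted
    by a model fitted to the other N-1; SStot uses the full-sample mean
    (centred for the intercept model, uncentred otherwise).
    """
    n = len(records)
    if n < 4:
        raise ValueError(f"leave-one-out needs at least 4 systems, got {n}")
    x, y = _xy(records)
    if np.ptp(x) == 0:
        raise ValueError("drH values are all identical; regression degenerate")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        alpha, beta = _ols(x[mask], y[mask], with_intercept)
        press += (y[i] - (alpha * x[i] + (beta or 0.0))) ** 2
    sstot = (
        float(np.sum((y - y.mean()) ** 2))
        if with_intercept
        else float(np.sum(y**2))
    )
    if sstot == 0:
        return 1.0 if press == 0 else -math.inf
    return 1.0 - press / sstot


def predict_binding_enthalpy(
    drH, alpha: float, beta: Optional[float] = None
) -> np.ndarray:
    """dHb_calc = alpha * drH (+ beta), kcal/mol."""
    return np.asarray(drH, dtype=float) * alpha + (beta or 0.0)


def convert_enthalpy_units(value_kj_per_mol: float) -> float:
    """kJ/mol -> kcal/mol with the thermochemical calorie (4.184 J/cal)."""
    return value_kj_per_mol / CAL_PER_JOULE


def read_energy_table(path) -> list[SystemRecord]:
    """Read a per-system heats-of-formation TSV into records with drH.

    Required columns: system_id, solvent_model, dfH_complex, dfH_target,
    dfH_ligand, dfH_water, s, dHb_exp (all energies kcal/mol).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = [
        "system_id",
        "solvent_model",
        "dfH_complex",
        "dfH_target",
        "dfH_ligand",
        "dfH_water",
        "s",
        "dHb_exp",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    records = []
    for row in df.itertuples():
        drh = reaction_heat(
            HessInput(
                dfH_complex=float(row.dfH_complex),
                dfH_target=float(row.dfH_target),
                dfH_ligand=float(row.dfH_ligand),
                dfH_water=float(row.dfH_water),
                s=int(row.s),
            )
        )
        records.append(
            SystemRecord(
                system_id=str(row.system_id),
                drH=drh,
                dHb_exp=float(row.dHb_exp),
                solvent_model=str(row.solvent_model),
            )
        )
    return records
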