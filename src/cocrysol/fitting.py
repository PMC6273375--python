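"""Parameter estimation from saturation data and the ARD error metric.

Binary interaction parameters k_ij(T) = k_slope·T + k_intercept are fitted
to saturation mole fractions of one solute in one solvent by least squares
on ln x (solubilities span orders of magnitude and accuracy is judged on
relative deviations, so a log loss is the natural choice).  The cocrystal
solubility product is calibrated from a single two-solute saturation record
using model activity coefficients.

Model accuracy is reported as the average relative deviation

    ARD[%] = 100 · (1/n) Σ |x_calc − x_exp| / x_exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import ParameterDB
from .pcsaft import get_model
from .sle import DEFAULT_PRESSURE, normalize_solvent_composition, solve_solubility, solvent_mole_split
from .cocrystal import ks_from_point

logger = logging.getLogger(__name__)

#: columns of the in-memory saturation record table
DATASET_COLUMNS = ["solute", "cosolute", "solvents", "T_K", "x_solute", "x_cosolute", "sd", "branch"]


@dataclass(frozen=True)
class SolubilityDataset:
    """Saturation records, experimental or synthetic.

    ``records`` is a DataFrame with columns ``solute``, ``cosolute`` (empty
    string if absent), ``solvents`` (a mapping of solute-free solvent mass
    fractions), ``T_K``, ``x_solute``, ``x_cosolute`` (NaN if absent),
    ``sd`` and ``branch``.
    """

    records: pd.DataFrame
    provenance: str = "experimental"
    seed: Optional[int] = None

    def __post_init__(self):
        df = self.records
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if len(df) == 0:
            raise ValueError("dataset must contain at least one record")
        x = df["x_solute"].to_numpy(float)
        if np.any((x <= 0.0) | (x >= 1.0)):
            raise ValueError("x_solute values must lie in (0, 1)")
        if np.any(df["T_K"].to_numpy(float) <= 0.0):
            raise ValueError("temperatures must be positive")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, solute: str, solvent: Optional[str] = None) -> "SolubilityDataset":
        """Records of one solute, optionally restricted to one pure solvent."""
        df = self.records
        mask = df["solute"] == solute
        if solvent is not None:
            mask &= df["solvents"].map(
                lambda s: set(normalize_solvent_composition(s)) == {solvent}
            )
        sub = df[mask].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"no records for solute {solute!r} in solvent {solvent!r}")
        return SolubilityDataset(records=sub, provenance=self.provenance, seed=self.seed)


@dataclass(frozen=True)
class FitResult:
    """Optimized parameters together with fit diagnostics.

    ``stderr`` holds linearized standard errors from the residual Jacobian
    at the optimum (NaN when the degrees of freedom vanish).
    """

    parameters: Mapping[str, float]
    objective: float
    ard_percent: float
    n_records: int
    converged: bool
    message: str = ""
    stderr: Mapping[str, float] = field(default_factory=dict)


def ard(x_calc: Sequence[float], x_exp: Sequence[float]) -> float:
    """Average relative deviation in percent, 100·mean(|x_calc − x_exp|/x_exp)."""
    calc = np.asarray(x_calc, float)
    exp_ = np.asarray(x_exp, float)
    if calc.shape != exp_.shape or calc.ndim != 1 or calc.size == 0:
        raise ValueError("x_calc and x_exp must be equal-length 1-D vectors")
    if np.any(exp_ == 0.0):
        raise ValueError("experimental values must be nonzero")
    return float(100.0 * np.mean(np.abs(calc - exp_) / np.abs(exp_)))


def _model_solubilities(
    dataset: SolubilityDataset, db: ParameterDB, pressure: float
) -> np.ndarray:
    out = np.empty(len(dataset))
    for i, rec in dataset.records.iterrows():
        cos = {}
        if rec["cosolute"] and not pd.isna(rec.get("x_cosolute", np.nan)):
            cos = {rec["cosolute"]: float(rec["x_cosolute"])}
        pt = solve_solubility(
            rec["solute"], rec["solvents"], float(rec["T_K"]), db,
            cosolute_amounts=cos, pressure=pressure,
        )
        out[i] = pt.x_solute
    return out


def dataset_ard(dataset: SolubilityDataset, db: ParameterDB, pressure: float = DEFAULT_PRESSURE) -> float:
    """ARD of the model against every record of a dataset."""
    calc = _model_solubilities(dataset, db, pressure)
    return ard(calc, dataset.records["x_solute"].to_numpy(float))


def fit_kij(
    dataset: SolubilityDataset,
    solute_id: str,
    solvent_id: str,
    db: ParameterDB,
    pressure: float = DEFAULT_PRESSURE,
) -> FitResult:
    """Fit (k_slope, k_intercept) of one solute/solvent pair to saturation data.

    Minimizes Σ(ln x_calc − ln x_exp)².  Internally the pair is
    reparameterized as (k at the mean data temperature, slope), which breaks
    the near-collinearity of slope and intercept over a narrow temperature
    window; the returned parameters are on the slope/intercept scale.
    Datasets at a single temperature fit the intercept only (slope fixed 0).
    """
    sub = dataset.subset(solute_id, solvent_id)
    T = sub.records["T_K"].to_numpy(float)
    x_exp = sub.records["x_solute"].to_numpy(float)
    ln_x_exp = np.log(x_exp)
    T_mid = float(T.mean())
    fit_slope = np.unique(T).size >= 2
    comp = {solvent_id: 1.0}

    def residuals(theta: np.ndarray) -> np.ndarray:
        k_mid, slope = (theta[0], theta[1]) if fit_slope else (theta[0], 0.0)
        intercept = k_mid - slope * T_mid
        trial = db.with_binary(solute_id, solvent_id, slope, intercept)
        res = np.empty(T.size)
        for i, Ti in enumerate(T):
            pt = solve_solubility(solute_id, comp, Ti, trial, pressure=pressure)
            res[i] = np.log(pt.x_solute) - ln_x_exp[i]
        return res

    start = db.binary(solute_id, solvent_id)
    theta0 = np.array(
        [start.k_slope * T_mid + start.k_intercept, start.k_slope][: 2 if fit_slope else 1]
    )
    scale = np.array([1e-2, 1e-4][: theta0.size])
    sol = least_squares(
        residuals, theta0, x_scale=scale, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        diff_step=1e-6,
    )
    k_mid, slope = (sol.x[0], sol.x[1]) if fit_slope else (sol.x[0], 0.0)
    intercept = k_mid - slope * T_mid
    fitted = db.with_binary(solute_id, solvent_id, slope, intercept)
    x_calc = np.array(
        [solve_solubility(solute_id, comp, Ti, fitted, pressure=pressure).x_solute for Ti in T]
    )
    objective = float(np.sum((np.log(x_calc) - ln_x_exp) ** 2))
    # linearized covariance, transformed from (k_mid, slope) to (slope, int)
    stderr = {"k_slope": float("nan"), "k_intercept": float("nan")}
    dof = T.size - sol.x.size
    if dof > 0:
        try:
            cov_internal = objective / dof * np.linalg.pinv(sol.jac.T @ sol.jac)
            if fit_slope:
                A = np.array([[0.0, 1.0], [1.0, -T_mid]])  # (k_mid, slope) -> (slope, int)
            else:
                A = np.array([[0.0], [1.0]])
            cov = A @ cov_internal @ A.T
            stderr = {
                "k_slope": float(np.sqrt(max(cov[0, 0], 0.0))),
                "k_intercept": float(np.sqrt(max(cov[1, 1], 0.0))),
            }
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        parameters={"k_slope": float(slope), "k_intercept": float(intercept)},
        objective=objective,
        ard_percent=ard(x_calc, x_exp),
        n_records=int(T.size),
        converged=bool(sol.success),
        message=str(sol.message),
        stderr=stderr,
    )


def fit_ks(
    record: Mapping,
    cc_stoichiometry: tuple[int, int],
    db: ParameterDB,
    api_id: str = "NA",
    cf_id: str = "SA",
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
) -> float:
    """Solubility product from one two-solute saturation record.

    ``record`` needs keys ``x_api``, ``x_cf``, ``T_K`` and ``solvents`` (a
    mapping of solute-free solvent mass fractions).  Activity coefficients
    are evaluated with PC-SAFT at the record's full liquid composition;
    ``ideal=True`` reduces the result to the ideal solubility product.
    """
    nu_api, nu_cf = cc_stoichiometry
    x_api = float(record["x_api"])
    x_cf = float(record["x_cf"])
    if ideal:
        gamma_api = gamma_cf = 1.0
    else:
        split = solvent_mole_split(db, record["solvents"])
        ids = (api_id, cf_id, *split.keys())
        x_solv = 1.0 - x_api - x_cf
        x = np.array([x_api, x_cf, *(x_solv * f for f in split.values())])
        model = get_model(db, ids)
        gamma, _ = model.activity_coefficients(float(record["T_K"]), pressure, x)
        gamma_api, gamma_cf = float(gamma[0]), float(gamma[1])
    return ks_from_point(x_api, x_cf, gamma_api, gamma_cf, nu_api, nu_cf)
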