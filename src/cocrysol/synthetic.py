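"""Pseudo-experimental saturation datasets with known generating truth.

The generator emulates the structure of gravimetric/photometric saturation
measurements: model solubilities on a temperature × solvent-ratio design,
perturbed by multiplicative lognormal noise

    x_obs = x_model · exp(ε),   ε ~ N(0, noise_rel_sd²), independent,

which matches analyses judged on relative deviations of quantities spanning
decades.  The default relative noise of 2% mimics the scatter of triplicate
saturation analyses.  A single integer seed fixes the full output stream:
records are generated in design order (temperature-major, then solvent
ratio, then replicate) and the noise draws follow that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .params import CocrystalDefinition, ParameterDB
from .cocrystal import cc_solubility_line, ks_at_temperature
from .fitting import DATASET_COLUMNS, SolubilityDataset
from .sle import DEFAULT_PRESSURE, SolubilityError, solve_solubility

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticDesign:
    """Measurement design for one solute (or an API+CF pair) in a solvent pair."""

    solute_id: str
    solvent_pair: tuple[str, str]
    mass_ratio_grid: tuple[float, ...]  # mass fraction of the first solvent
    temperature_grid: tuple[float, ...]  # K
    cosolute_id: Optional[str] = None
    solute_ratio_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)  # x_API/x_CF nodes
    noise_rel_sd: float = 0.02
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_rel_sd < 0:
            raise ValueError("noise_rel_sd must be >= 0")
        if not self.mass_ratio_grid or not self.temperature_grid:
            raise ValueError("design grids must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def solvent_composition(self, ratio: float) -> dict[str, float]:
        a, b = self.solvent_pair
        if ratio >= 1.0:
            return {a: 1.0}
        if ratio <= 0.0:
            return {b: 1.0}
        return {a: ratio, b: 1.0 - ratio}


def generate_binary_solubility(
    design: SyntheticDesign,
    true_params: Optional[Mapping[str, tuple[float, float]]] = None,
    db: Optional[ParameterDB] = None,
    pressure: float = DEFAULT_PRESSURE,
) -> SolubilityDataset:
    """Noisy single-solute saturation records over the design grid.

    ``true_params`` maps solvent id → (k_slope, k_intercept) overrides for
    the solute/solvent binary interaction; absent entries keep the packaged
    values.  With ``noise_rel_sd = 0`` the records reproduce the generating
    model exactly.
    """
    if db is None:
        raise ValueError("a parameter database is required")
    if true_params:
        for solvent, (slope, intercept) in true_params.items():
            db = db.with_binary(design.solute_id, solvent, slope, intercept)
    rng = np.random.default_rng(design.seed)
    rows = []
    for T in design.temperature_grid:
        for ratio in design.mass_ratio_grid:
            comp = design.solvent_composition(ratio)
            try:
                pt = solve_solubility(design.solute_id, comp, T, db, pressure=pressure)
            except SolubilityError as exc:
                logger.warning("design node T=%.2f ratio=%.3f skipped: %s", T, ratio, exc)
                continue
            for _ in range(design.n_replicates):
                eps = rng.normal(0.0, design.noise_rel_sd) if design.noise_rel_sd > 0 else 0.0
                rows.append(
                    {
                        "solute": design.solute_id,
                        "cosolute": "",
                        "solvents": comp,
                        "T_K": T,
                        "x_solute": pt.x_solute * np.exp(eps),
                        "x_cosolute": np.nan,
                        "sd": design.noise_rel_sd,
                        "branch": design.solute_id,
                    }
                )
    if not rows:
        raise SolubilityError("no design node produced a saturation record")
    return SolubilityDataset(
        records=pd.DataFrame(rows, columns=DATASET_COLUMNS),
        provenance="synthetic",
        seed=design.seed,
    )


def generate_cc_dataset(
    design: SyntheticDesign,
    cc: CocrystalDefinition,
    db: ParameterDB,
    ks: Optional[float] = None,
    pressure: float = DEFAULT_PRESSURE,
) -> SolubilityDataset:
    """Noisy cocrystal saturation records (both solute mole fractions).

    Points are sampled along the model cocrystal line at the design's
    API/CF ratio nodes for each temperature × solvent-ratio cell; both mole
    fractions are perturbed independently.  ``ks`` overrides the
    Gibbs-Helmholtz value derived from the cocrystal definition.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for T in design.temperature_grid:
        ks_T = ks if ks is not None else ks_at_temperature(cc, T, db.universal_gas_constant)
        for ratio in design.mass_ratio_grid:
            comp = design.solvent_composition(ratio)
            line = cc_solubility_line(
                cc, comp, T, ratio_grid=design.solute_ratio_grid, db=db,
                ks=ks_T, pressure=pressure,
            )
            for (x_api, x_cf, _, _) in line.points:
                for _ in range(design.n_replicates):
                    eps_a = rng.normal(0.0, design.noise_rel_sd) if design.noise_rel_sd > 0 else 0.0
                    eps_c = rng.normal(0.0, design.noise_rel_sd) if design.noise_rel_sd > 0 else 0.0
                    rows.append(
                        {
                            "solute": cc.api_id,
                            "cosolute": cc.cf_id,
                            "solvents": comp,
                            "T_K": T,
                            "x_solute": x_api * np.exp(eps_a),
                            "x_cosolute": x_cf * np.exp(eps_c),
                            "sd": design.noise_rel_sd,
                            "branch": "CC",
                        }
                    )
    if not rows:
        raise SolubilityError("no design cell produced cocrystal records")
    return SolubilityDataset(
        records=pd.DataFrame(rows, columns=DATASET_COLUMNS),
        provenance="synthetic",
        seed=design.seed,
    )
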