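"""Solid-liquid-equilibrium solubility of a single crystalline solute.

The saturation mole fraction of a solute i in any liquid (solvent,
solvent/anti-solvent mixture, optionally with a second dissolved solute)
follows from equality of the solid and liquid chemical potentials:

    x_i = (1/γ_i) exp[ −Δh_i/(R T) (1 − T/T0_i)
                       − Δcp_i/R (T0_i/T − 1 − ln(T0_i/T)) ]

with T0_i the melting temperature, Δh_i the (temperature-independent) fusion
enthalpy, Δcp_i the heat-capacity difference at the melting point and γ_i
the activity coefficient of the solute in the saturated liquid, computed
with PC-SAFT at the full liquid composition.  Because γ_i itself depends on
x_i the equation is solved by damped fixed-point iteration started from the
ideal (γ = 1) solubility.

Solvent/anti-solvent compositions are specified on a solute-free mass basis
throughout, as is conventional for crystallization screening; conversion to
mole fractions uses the database molar masses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .params import MeltingProperties, ParameterDB
from .pcsaft import get_model

logger = logging.getLogger(__name__)

#: All liquid-phase activity coefficients are evaluated at atmospheric
#: pressure; liquid-phase γ are insensitive to pressure.
DEFAULT_PRESSURE = 101325.0


class SolubilityError(RuntimeError):
    """The saturation fixed point did not converge."""


class FullyMiscibleError(SolubilityError):
    """The solubility iteration diverged toward x = 1: no solid phase is
    stable at this temperature (the solute is fully miscible)."""


@dataclass(frozen=True)
class SolubilityPoint:
    """One converged saturation state."""

    solute_id: str
    solvent_composition: Mapping[str, float]  # solute-free mass fractions
    temperature: float  # K
    x_solute: float
    gamma_solute: float
    cosolute_amounts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.x_solute < 1.0:
            raise ValueError(f"x_solute must lie in (0, 1), got {self.x_solute}")
        if self.gamma_solute <= 0.0:
            raise ValueError("gamma_solute must be positive")
        tot = sum(self.solvent_composition.values())
        if abs(tot - 1.0) > 1e-12:
            raise ValueError(f"solvent mass fractions sum to {tot}, not 1")


def normalize_solvent_composition(solvent_composition: Mapping[str, float]) -> dict[str, float]:
    """Normalize solvent mass fractions to sum exactly to one."""
    items = {k: float(v) for k, v in solvent_composition.items() if float(v) > 0.0}
    if not items:
        raise ValueError("solvent composition is empty")
    tot = sum(items.values())
    return {k: v / tot for k, v in items.items()}


def solvent_mole_split(db: ParameterDB, solvent_composition: Mapping[str, float]) -> dict[str, float]:
    """Solute-free solvent mole fractions from solute-free mass fractions."""
    comp = normalize_solvent_composition(solvent_composition)
    moles = {k: w / db.component(k).molar_mass for k, w in comp.items()}
    tot = sum(moles.values())
    return {k: n / tot for k, n in moles.items()}


def liquid_composition(
    db: ParameterDB,
    solute_id: str,
    x_solute: float,
    solvent_composition: Mapping[str, float],
    cosolute_amounts: Optional[Mapping[str, float]] = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Full liquid composition vector for a saturation calculation.

    The solute and any cosolutes enter as mole fractions of the total
    liquid; the remaining amount is split over the solvents in their stated
    solute-free mass ratio.
    """
    cosolutes = dict(cosolute_amounts or {})
    x_cos = sum(cosolutes.values())
    if x_solute + x_cos >= 1.0:
        raise ValueError("solute and cosolute mole fractions leave no room for solvent")
    split = solvent_mole_split(db, solvent_composition)
    ids = (solute_id, *cosolutes.keys(), *split.keys())
    x_solv = 1.0 - x_solute - x_cos
    x = np.array([x_solute, *cosolutes.values(), *(x_solv * f for f in split.values())])
    return ids, x


def ideal_solubility(melting: MeltingProperties, T: float, R: float = 8.314) -> float:
    """Ideal (γ = 1) saturation mole fraction at temperature ``T``.

    Equals 1 at the melting temperature; values that would exceed 1 are
    reported clipped at 1.  ``T`` above the melting temperature is a domain
    error (the solid phase does not exist there).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    T0 = melting.melting_temperature
    if T > T0:
        raise ValueError(
            f"T = {T} K exceeds the melting temperature {T0} K of "
            f"{melting.component_id}: no solid phase"
        )
    dh = melting.fusion_enthalpy * 1000.0  # kJ/mol -> J/mol, the one conversion site
    arg = -dh / (R * T) * (1.0 - T / T0) - melting.delta_cp / R * (
        T0 / T - 1.0 - np.log(T0 / T)
    )
    return min(float(np.exp(arg)), 1.0)


def solve_solubility(
    solute_id: str,
    solvent_composition: Mapping[str, float],
    T: float,
    db: ParameterDB,
    cosolute_amounts: Optional[Mapping[str, float]] = None,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
    rtol: float = 1e-9,
    max_iter: int = 400,
) -> SolubilityPoint:
    """Saturation mole fraction of ``solute_id`` in the given liquid.

    Damped fixed-point iteration x ← x_ideal/γ(x), damping 0.5, started at
    the ideal solubility; converged when successive iterates agree to
    ``rtol`` relative.  ``ideal=True`` forces γ ≡ 1 (the solver then reduces
    exactly to :func:`ideal_solubility`).
    """
    solvent_composition = normalize_solvent_composition(solvent_composition)
    x_id = ideal_solubility(db.melting_of(solute_id), T, db.universal_gas_constant)
    if ideal:
        return SolubilityPoint(
            solute_id=solute_id,
            solvent_composition=solvent_composition,
            temperature=T,
            x_solute=x_id,
            gamma_solute=1.0,
            cosolute_amounts=dict(cosolute_amounts or {}),
        )
    cos = dict(cosolute_amounts or {})
    x_cos = sum(cos.values())
    x_cap = 1.0 - x_cos - 1e-9
    x = min(x_id, 0.5 * x_cap)
    ids, _ = liquid_composition(db, solute_id, x, solvent_composition, cos)
    model = get_model(db, ids)
    eta_guess = None
    ln_id = np.log(x_id)
    ln_cap = np.log(x_cap)

    def step(ln_x: float) -> float:
        """Fixed-point residual F(ln x) = ln(x_ideal/γ(x)) − ln x."""
        nonlocal eta_guess
        _, xvec = liquid_composition(db, solute_id, np.exp(ln_x), solvent_composition, cos)
        gamma, eta_guess = model.activity_coefficients(T, pressure, xvec, eta_guess=eta_guess)
        return ln_id - np.log(float(gamma[0])) - ln_x

    # one damped substitution seeds the secant iteration
    t0 = float(np.log(x))
    f0 = step(t0)
    t1 = min(t0 + 0.5 * f0, ln_cap)
    converged = abs(f0) < rtol
    it = 1
    if not converged:
        f1 = step(t1)
        for it in range(2, max_iter):
            if abs(f1) < rtol:
                converged = True
                break
            if f1 == f0:
                raise SolubilityError("saturation iteration stalled")
            t2 = t1 - f1 * (t1 - t0) / (f1 - f0)
            # safeguard: fall back to a damped substitution step if the
            # secant extrapolates wildly
            if not np.isfinite(t2) or abs(t2 - t1) > 2.0:
                t2 = t1 + 0.5 * f1
            if t2 >= ln_cap:
                raise FullyMiscibleError(
                    f"{solute_id} appears fully miscible at {T} K in {solvent_composition}"
                )
            t0, f0 = t1, f1
            t1 = t2
            f1 = step(t1)
        else:
            raise SolubilityError(
                f"saturation fixed point for {solute_id} not converged after {max_iter} iterations"
            )
    x = float(np.exp(t1))
    logger.debug(
        "solve_solubility(%s) converged in %d evaluations: x=%.6e", solute_id, it + 1, x
    )
    # report the self-consistent gamma at the converged composition
    _, xvec = liquid_composition(db, solute_id, x, solvent_composition, cos)
    gamma, _ = model.activity_coefficients(T, pressure, xvec, eta_guess=eta_guess)
    return SolubilityPoint(
        solute_id=solute_id,
        solvent_composition=solvent_composition,
        temperature=T,
        x_solute=x,
        gamma_solute=float(gamma[0]),
        cosolute_amounts=cos,
    )


def solubility_line_vs_solvent_ratio(
    solute_id: str,
    solvent_pair: Sequence[str],
    ratio_grid: Sequence[float],
    T: float,
    db: ParameterDB,
    **kwargs,
) -> list[Optional[SolubilityPoint]]:
    """Saturation points over a solute-free mass-ratio grid of a solvent pair.

    ``ratio_grid`` holds the mass fraction of the *first* solvent of the
    pair.  Nodes whose saturation solve fails are returned as ``None`` (the
    gap is logged); the endpoints reproduce the pure-solvent solubilities.
    """
    a, b = solvent_pair
    line: list[Optional[SolubilityPoint]] = []
    for r in ratio_grid:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"mass ratio {r} outside [0, 1]")
        comp = {a: r, b: 1.0 - r}
        try:
            line.append(solve_solubility(solute_id, comp, T, db, **kwargs))
        except SolubilityError as exc:
            logger.warning("solubility node %s failed: %s", comp, exc)
            line.append(None)
    return line
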