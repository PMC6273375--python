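"""Cocrystal solubility product, solubility lines and ternary phase diagrams.

A cocrystal dissociates completely on dissolution, so its solid cannot be
treated with the single-solute solid-liquid equilibrium.  Instead its
saturation states satisfy the solubility product

    Ks = (x_API γ_API)^ν_API (x_CF γ_CF)^ν_CF,

which depends on temperature only — not on the solvent, the solvent/anti-
solvent ratio or the concentration.  One saturation point in any solvent
therefore fixes Ks, and with PC-SAFT activity coefficients the cocrystal
solubility line can be predicted in every other solvent system.  The
temperature dependence of Ks follows a Gibbs-Helmholtz (van 't Hoff) form,

    ln Ks(T) = ln Ks_ref + Δh_ref/R (1/T_ref − 1/T),

with a reference dissolution enthalpy Δh_ref assumed constant over the
temperature window of interest.

The ternary phase diagram of API/CF/solvent(s) is assembled from three
saturation branches — API solid with dissolved CF, CF solid with dissolved
API, and the cocrystal line — which intersect pairwise at the two eutectic
(invariant) points bounding the cocrystal stability region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root

from .params import CocrystalDefinition, ParameterDB
from .pcsaft import get_model
from .sle import (
    DEFAULT_PRESSURE,
    SolubilityError,
    SolubilityPoint,
    ideal_solubility,
    normalize_solvent_composition,
    solve_solubility,
    solvent_mole_split,
)

logger = logging.getLogger(__name__)


class PhaseDiagramError(RuntimeError):
    """A required line or point of the diagram could not be constructed."""


# ---------------------------------------------------------------------------
# solubility product


def ks_from_point(
    x_api: float,
    x_cf: float,
    gamma_api: float,
    gamma_cf: float,
    nu_api: int,
    nu_cf: int,
) -> float:
    """Solubility product from one saturation point: Π (x_i γ_i)^ν_i.

    The result is independent of the solvent and of the API/CF ratio of the
    point used, which is what makes single-point calibration possible.
    """
    if min(x_api, x_cf, gamma_api, gamma_cf) <= 0:
        raise ValueError("mole fractions and activity coefficients must be positive")
    return (x_api * gamma_api) ** nu_api * (x_cf * gamma_cf) ** nu_cf


def ks_ideal_from_point(x_api: float, x_cf: float, nu_api: int, nu_cf: int) -> float:
    """Ideal solubility product Π x_i^ν_i (activity coefficients neglected).

    Unlike :func:`ks_from_point` this quantity is *not* transferable between
    solvents; it is provided for comparison with ideal-solution treatments.
    """
    if min(x_api, x_cf) <= 0:
        raise ValueError("mole fractions must be positive")
    return x_api**nu_api * x_cf**nu_cf


def ks_at_temperature(cc: CocrystalDefinition, T: float, R: float = 8.314) -> float:
    """Gibbs-Helmholtz extrapolation of Ks from the reference temperature."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    dh = cc.dh_ref * 1000.0  # kJ/mol -> J/mol
    return math.exp(math.log(cc.ks_ref) + dh / R * (1.0 / cc.t_ref - 1.0 / T))


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class CocrystalLine:
    """Saturation line of the cocrystal solid in one solvent system."""

    cocrystal: CocrystalDefinition
    solvent_composition: Mapping[str, float]
    temperature: float
    points: tuple[tuple[float, float, float, float], ...]  # (x_API, x_CF, γ_API, γ_CF)
    ks_used: float

    def x_api(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    def x_cf(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


class SoluteBranch(Sequence):
    """Saturation branch of one solute solid with the other solute dissolved.

    Behaves as a sequence of :class:`SolubilityPoint` and carries the
    metadata the eutectic solver needs.
    """

    def __init__(
        self,
        solute_id: str,
        cosolute_id: str,
        points: Sequence[SolubilityPoint],
        solvent_composition: Mapping[str, float],
        temperature: float,
    ):
        self.solute_id = solute_id
        self.cosolute_id = cosolute_id
        self.points = tuple(points)
        self.solvent_composition = dict(solvent_composition)
        self.temperature = temperature

    def __len__(self):
        return len(self.points)

    def __getitem__(self, i):
        return self.points[i]


@dataclass(frozen=True)
class EutecticPoint:
    """Liquid composition in simultaneous equilibrium with two solids."""

    x_api: float
    x_cf: float
    residuals: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class TernaryPhaseDiagram:
    """Assembled isothermal phase diagram of API/CF/solvent(s).

    The three lines are clipped to their stable segments: the cocrystal line
    between the two eutectics, the API and CF branches outside.
    """

    api_line: tuple[SolubilityPoint, ...]
    cf_line: tuple[SolubilityPoint, ...]
    cc_line: CocrystalLine
    eutectic_api_cc: Optional[EutecticPoint]
    eutectic_cf_cc: Optional[EutecticPoint]
    solvent_composition: Mapping[str, float]
    temperature: float


# ---------------------------------------------------------------------------
# activity-coefficient plumbing shared by the line builders


class _GammaEvaluator:
    """γ_API, γ_CF at arbitrary (x_API, x_CF) in a fixed solvent system."""

    def __init__(self, db, api_id, cf_id, solvent_composition, T, pressure, ideal=False):
        self.split = solvent_mole_split(db, solvent_composition)
        self.ids = (api_id, cf_id, *self.split.keys())
        self.model = get_model(db, self.ids)
        self.T = T
        self.p = pressure
        self.ideal = ideal
        self._eta = None

    def __call__(self, x_api: float, x_cf: float) -> tuple[float, float]:
        if self.ideal:
            return 1.0, 1.0
        x_solv = 1.0 - x_api - x_cf
        if x_solv <= 0.0:
            raise ValueError("solute mole fractions leave no room for solvent")
        x = np.array([x_api, x_cf, *(x_solv * f for f in self.split.values())])
        gamma, self._eta = self.model.activity_coefficients(
            self.T, self.p, x, eta_guess=self._eta
        )
        return float(gamma[0]), float(gamma[1])


# ---------------------------------------------------------------------------
# lines


def cc_solubility_line(
    cc: CocrystalDefinition,
    solvent_composition: Mapping[str, float],
    T: float,
    ratio_grid: Optional[Sequence[float]] = None,
    db: Optional[ParameterDB] = None,
    ks: Optional[float] = None,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
) -> CocrystalLine:
    """Cocrystal saturation line traced over solute-ratio nodes.

    Each node fixes the ratio r = x_API/x_CF and solves for the scale s with
    x_API = r·s, x_CF = s such that the activity product equals Ks, by
    bracketed one-dimensional root finding in ln s.  ``ks`` defaults to the
    Gibbs-Helmholtz value at ``T`` from the cocrystal's reference data.
    Nodes that fail to converge are skipped (and logged); an empty line is
    an error.
    """
    if db is None:
        raise ValueError("a parameter database is required")
    solvent_composition = normalize_solvent_composition(solvent_composition)
    if ks is None:
        ks = ks_at_temperature(cc, T, db.universal_gas_constant)
    if ratio_grid is None:
        ratio_grid = np.geomspace(0.01, 100.0, 60)
    gamma_at = _GammaEvaluator(db, cc.api_id, cc.cf_id, solvent_composition, T, pressure, ideal)
    nu_a, nu_c = cc.nu_api, cc.nu_cf
    ln_ks = math.log(ks)
    points = []
    prev_ln_s = None
    for r in ratio_grid:
        def f(ln_s: float) -> float:
            s = math.exp(ln_s)
            ga, gc = gamma_at(r * s, s)
            return nu_a * math.log(r * s * ga) + nu_c * math.log(s * gc) - ln_ks

        # ideal-solution center of the bracket: (r s)^νa s^νc = Ks
        ln_s0 = (ln_ks - nu_a * math.log(r)) / (nu_a + nu_c)
        if prev_ln_s is not None:
            ln_s0 = prev_ln_s
        # s must keep x_api + x_cf < 1
        ln_s_cap = math.log(1.0 / (1.0 + r)) - 1e-9
        try:
            lo = min(ln_s0 - 1.0, ln_s_cap - 2.0)
            hi = min(ln_s0 + 1.0, ln_s_cap)
            flo, fhi = f(lo), f(hi)
            for _ in range(60):
                if flo < 0.0 < fhi:
                    break
                if flo > 0.0:
                    lo -= 1.0
                    flo = f(lo)
                if fhi < 0.0 and hi < ln_s_cap:
                    hi = min(hi + 1.0, ln_s_cap)
                    fhi = f(hi)
                elif fhi < 0.0:
                    raise SolubilityError("activity product below Ks up to the composition cap")
            else:
                raise SolubilityError("no bracket for the cocrystal scale")
            ln_s = brentq(f, lo, hi, xtol=1e-12)
        except (SolubilityError, ValueError, RuntimeError) as exc:
            logger.warning("cocrystal line node r=%.4g failed: %s", r, exc)
            continue
        prev_ln_s = ln_s
        s = math.exp(ln_s)
        ga, gc = gamma_at(r * s, s)
        points.append((r * s, s, ga, gc))
    if not points:
        raise PhaseDiagramError(
            f"cocrystal line empty in {solvent_composition} at {T} K"
        )
    return CocrystalLine(
        cocrystal=cc,
        solvent_composition=solvent_composition,
        temperature=T,
        points=tuple(points),
        ks_used=ks,
    )


def cc_x_api_at_x_cf(
    cc: CocrystalDefinition,
    solvent_composition: Mapping[str, float],
    T: float,
    x_cf: float,
    db: ParameterDB,
    ks: Optional[float] = None,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
) -> float:
    """API mole fraction on the cocrystal line at a given CF mole fraction.

    This is the deviation convention for comparing predicted cocrystal lines
    with two-solute saturation measurements: the line is evaluated at the
    experimental CF loading and the deviation is attributed to the API.
    """
    solvent_composition = normalize_solvent_composition(solvent_composition)
    if ks is None:
        ks = ks_at_temperature(cc, T, db.universal_gas_constant)
    gamma_at = _GammaEvaluator(db, cc.api_id, cc.cf_id, solvent_composition, T, pressure, ideal)
    ln_ks = math.log(ks)

    def f(ln_xa: float) -> float:
        xa = math.exp(ln_xa)
        ga, gc = gamma_at(xa, x_cf)
        return cc.nu_api * math.log(xa * ga) + cc.nu_cf * math.log(x_cf * gc) - ln_ks

    # ideal-solution seed: x_api^nu_api * x_cf^nu_cf = Ks
    ln0 = (ln_ks - cc.nu_cf * math.log(x_cf)) / cc.nu_api
    cap = math.log(1.0 - x_cf) - 1e-9
    lo, hi = min(ln0 - 1.0, cap - 2.0), min(ln0 + 1.0, cap)
    flo, fhi = f(lo), f(hi)
    for _ in range(60):
        if flo < 0.0 < fhi:
            break
        if flo > 0.0:
            lo -= 1.0
            flo = f(lo)
        if fhi < 0.0:
            if hi >= cap:
                raise PhaseDiagramError("activity product below Ks up to the composition cap")
            hi = min(hi + 1.0, cap)
            fhi = f(hi)
    else:
        raise PhaseDiagramError("no bracket for the API mole fraction")
    return math.exp(brentq(f, lo, hi, xtol=1e-12))


def api_or_cf_line_with_cosolute(
    solute_id: str,
    cosolute_id: str,
    cosolute_grid: Sequence[float],
    solvent_composition: Mapping[str, float],
    T: float,
    db: ParameterDB,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
) -> SoluteBranch:
    """Saturation branch of one solute solid at increasing cosolute loadings.

    The first grid node (zero cosolute) reproduces the single-solute
    solubility; only the named solute's solid is treated as the equilibrium
    phase.
    """
    solvent_composition = normalize_solvent_composition(solvent_composition)
    points = []
    for x_cos in cosolute_grid:
        cos = {} if x_cos == 0.0 else {cosolute_id: float(x_cos)}
        try:
            pt = solve_solubility(
                solute_id, solvent_composition, T, db,
                cosolute_amounts=cos, pressure=pressure, ideal=ideal,
            )
        except SolubilityError as exc:
            logger.warning("cosolute branch node x_cos=%.4g failed: %s", x_cos, exc)
            continue
        if ideal and cos:
            # the ideal branch is flat; record the cosolute loading explicitly
            pt = SolubilityPoint(
                solute_id=pt.solute_id,
                solvent_composition=pt.solvent_composition,
                temperature=pt.temperature,
                x_solute=pt.x_solute,
                gamma_solute=pt.gamma_solute,
                cosolute_amounts=cos,
            )
        points.append(pt)
    if not points:
        raise PhaseDiagramError(f"{solute_id} branch empty in {solvent_composition} at {T} K")
    return SoluteBranch(solute_id, cosolute_id, points, solvent_composition, T)


# ---------------------------------------------------------------------------
# eutectics and diagram assembly


def _branch_coords(branch, api_id: str) -> np.ndarray:
    """(x_API, x_CF) coordinates of a branch, in diagram orientation."""
    if isinstance(branch, CocrystalLine):
        return np.column_stack([branch.x_api(), branch.x_cf()])
    pts = []
    for p in branch.points:
        x_cos = p.cosolute_amounts.get(branch.cosolute_id, 0.0)
        if p.solute_id == api_id:
            pts.append((p.x_solute, x_cos))
        else:
            pts.append((x_cos, p.x_solute))
    return np.array(pts)


def _branch_residual_fn(branch, db: ParameterDB, api_id: str, cf_id: str, pressure, ideal):
    """Equilibrium residual of a branch as a function of (x_API, x_CF)."""
    T = branch.temperature
    gamma_at = _GammaEvaluator(db, api_id, cf_id, branch.solvent_composition, T, pressure, ideal)
    if isinstance(branch, CocrystalLine):
        cc = branch.cocrystal
        ln_ks = math.log(branch.ks_used)

        def resid(x_api: float, x_cf: float) -> float:
            ga, gc = gamma_at(x_api, x_cf)
            return (
                cc.nu_api * math.log(x_api * ga)
                + cc.nu_cf * math.log(x_cf * gc)
                - ln_ks
            )

        return resid

    x_id = ideal_solubility(db.melting_of(branch.solute_id), T, db.universal_gas_constant)
    is_api = branch.solute_id == api_id

    def resid(x_api: float, x_cf: float) -> float:
        ga, gc = gamma_at(x_api, x_cf)
        xs, gs = (x_api, ga) if is_api else (x_cf, gc)
        return math.log(xs * gs) - math.log(x_id)

    return resid


def locate_eutectic(
    line_a,
    line_b,
    db: ParameterDB,
    api_id: Optional[str] = None,
    cf_id: Optional[str] = None,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
    tol: float = 1e-6,
) -> Optional[EutecticPoint]:
    """Composition where two saturation lines cross, refined by 2-D rootfinding.

    The discrete crossing of the sampled lines seeds a simultaneous solve of
    both equilibrium conditions in (x_API, x_CF).  Returns ``None`` when the
    sampled lines do not cross (a legitimate outcome: the two solids have no
    common saturation point in the sampled region).
    """
    for line in (line_a, line_b):
        if isinstance(line, CocrystalLine):
            api_id = api_id or line.cocrystal.api_id
            cf_id = cf_id or line.cocrystal.cf_id
    if api_id is None or cf_id is None:
        raise ValueError("api_id and cf_id could not be inferred; pass them explicitly")

    ra = _branch_residual_fn(line_a, db, api_id, cf_id, pressure, ideal)
    rb = _branch_residual_fn(line_b, db, api_id, cf_id, pressure, ideal)
    coords_a = _branch_coords(line_a, api_id)

    # sign change of line_b's residual along line_a marks the crossing
    seed = None
    vals = []
    for xa, xc in coords_a:
        try:
            vals.append(rb(xa, xc))
        except (ValueError, SolubilityError, RuntimeError):
            vals.append(np.nan)
    for i in range(len(vals) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if np.isnan(v0) or np.isnan(v1):
            continue
        if v0 == 0.0 or v0 * v1 < 0.0:
            w = abs(v0) / (abs(v0) + abs(v1)) if v0 != v1 else 0.5
            seed = (1 - w) * coords_a[i] + w * coords_a[i + 1]
            break
    if seed is None:
        return None

    def system(z):
        xa, xc = math.exp(z[0]), math.exp(z[1])
        return [ra(xa, xc), rb(xa, xc)]

    sol = root(system, np.log(seed), method="hybr", tol=1e-12)
    xa, xc = math.exp(sol.x[0]), math.exp(sol.x[1])
    res = system(sol.x)
    if max(abs(res[0]), abs(res[1])) > tol:
        logger.warning("eutectic refinement residuals %s exceed tol %g", res, tol)
        return None
    return EutecticPoint(x_api=xa, x_cf=xc, residuals=(res[0], res[1]))


def build_phase_diagram(
    cc: CocrystalDefinition,
    solvent_composition: Mapping[str, float],
    T: float,
    db: ParameterDB,
    n_branch: int = 10,
    ratio_grid: Optional[Sequence[float]] = None,
    pressure: float = DEFAULT_PRESSURE,
    ideal: bool = False,
) -> TernaryPhaseDiagram:
    """Assemble the isothermal ternary phase diagram of an API/CF/solvent system.

    Branches are clipped at the eutectics: the cocrystal line keeps its
    segment between the two eutectic points, the API (CF) solid branch keeps
    the segment at cosolute loadings below its eutectic.
    """
    solvent_composition = normalize_solvent_composition(solvent_composition)
    api, cf = cc.api_id, cc.cf_id
    sat_api = solve_solubility(api, solvent_composition, T, db, pressure=pressure, ideal=ideal)
    sat_cf = solve_solubility(cf, solvent_composition, T, db, pressure=pressure, ideal=ideal)

    api_branch = api_or_cf_line_with_cosolute(
        api, cf, np.linspace(0.0, 0.95 * sat_cf.x_solute, n_branch),
        solvent_composition, T, db, pressure=pressure, ideal=ideal,
    )
    cf_branch = api_or_cf_line_with_cosolute(
        cf, api, np.linspace(0.0, 0.95 * sat_api.x_solute, n_branch),
        solvent_composition, T, db, pressure=pressure, ideal=ideal,
    )
    if ratio_grid is None:
        # span the diagram region around the congruent ratio
        r0 = sat_api.x_solute / sat_cf.x_solute
        ratio_grid = np.geomspace(r0 / 30.0, r0 * 30.0, 31)
    line_cc = cc_solubility_line(
        cc, solvent_composition, T, ratio_grid=ratio_grid, db=db,
        pressure=pressure, ideal=ideal,
    )

    eut_api = locate_eutectic(api_branch, line_cc, db, pressure=pressure, ideal=ideal)
    eut_cf = locate_eutectic(cf_branch, line_cc, db, pressure=pressure, ideal=ideal)

    api_pts = tuple(
        p for p in api_branch.points
        if eut_api is None or p.cosolute_amounts.get(cf, 0.0) <= eut_api.x_cf
    )
    cf_pts = tuple(
        p for p in cf_branch.points
        if eut_cf is None or p.cosolute_amounts.get(api, 0.0) <= eut_cf.x_api
    )
    cc_pts = tuple(
        p for p in line_cc.points
        if (eut_api is None or p[1] >= eut_api.x_cf * (1 - 1e-9))
        and (eut_cf is None or p[0] >= eut_cf.x_api * (1 - 1e-9))
    )
    cc_clipped = CocrystalLine(
        cocrystal=cc,
        solvent_composition=solvent_composition,
        temperature=T,
        points=cc_pts if cc_pts else line_cc.points,
        ks_used=line_cc.ks_used,
    )
    return TernaryPhaseDiagram(
        api_line=api_pts,
        cf_line=cf_pts,
        cc_line=cc_clipped,
        eutectic_api_cc=eut_api,
        eutectic_cf_cc=eut_cf,
        solvent_composition=solvent_composition,
        temperature=T,
    )
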