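"""Perturbed-chain SAFT equation of state for associating liquid mixtures.

The residual Helmholtz energy is the sum of three contributions,

    a_res = a_hard-chain + a_dispersion + a_association,

evaluated per mole of molecules and reduced by RT.  The hard-chain and
dispersion terms follow the standard perturbed-chain formulation with the
universal model constants of the original correlation; the association term
is the Wertheim first-order perturbation with donor/acceptor site
inventories per component and the bonding strength

    Δ^AiBj = σ_ij³ g_ij^hs κ^AiBj [exp(ε^AiBj / k_B T) − 1].

Cross parameters use Berthelot–Lorentz rules for σ_ij and u_ij (with a
temperature-linear binary correction k_ij) and Wolbach–Sandler rules for the
association energy and volume.  Polar but non-self-associating solvents
(acetonitrile, ethyl acetate) carry an induced-association site pair with
zero association energy and κ = 0.01: alone they do not bond (Δ_ii = 0
because exp(0) − 1 = 0), but in mixtures with a self-associating partner the
cross energy ½(0 + ε_jj) switches bonding on.

Derivatives of a_res (compressibility factor, residual chemical potentials)
are obtained by complex-step differentiation, which is exact to machine
precision; every routine below therefore accepts complex density and mole
fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import ParameterDB, PureComponentParams

KB = 1.380649e-23  # Boltzmann constant, J/K
NAV = 6.02214076e23  # Avogadro constant, 1/mol
_CSTEP = 1e-20  # complex-step size
ETA_MAX = 0.7404  # close-packing bound on the packing fraction

# Universal model constants of the dispersion power series I1, I2,
# transcribed from the original perturbed-chain correlation
# (Gross & Sadowski, Ind. Eng. Chem. Res. 40 (2001) 1244, Table 1).
_A = np.array([
    [0.9105631445, -0.3084016918, -0.0906148351],
    [0.6361281449, 0.1860531159, 0.4527842806],
    [2.6861347891, -2.5030047259, 0.5962700728],
    [-26.547362491, 21.419793629, -1.7241829131],
    [97.759208784, -65.255885330, -4.1302112531],
    [-159.59154087, 83.318680481, 13.776631870],
    [91.297774084, -33.746922930, -8.6728470368],
])
_B = np.array([
    [0.7240946941, -0.5755498075, 0.0976883116],
    [2.2382791861, 0.6995095521, -0.2557574982],
    [-4.0025849485, 3.8925673390, -9.1558561530],
    [-21.003576815, -17.215471648, 20.642075974],
    [26.855641363, 192.67226447, -38.804430052],
    [206.55133841, -161.82646165, 93.626774077],
    [-355.60235612, -165.20769346, -29.666905585],
])


class DensitySolverError(RuntimeError):
    """No density root with the requested character could be bracketed."""


class AssociationError(RuntimeError):
    """The Wertheim site-fraction fixed point failed to converge."""


# ---------------------------------------------------------------------------
# combining rules


def combine_sigma(sigma_i: float, sigma_j: float) -> float:
    """Arithmetic-mean cross segment diameter σ_ij, Å."""
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("segment diameters must be positive")
    return 0.5 * (sigma_i + sigma_j)


def combine_u(u_i: float, u_j: float, kij: float = 0.0) -> float:
    """Geometric-mean cross dispersion energy (1 − k_ij)·√(u_i u_j), K."""
    if u_i < 0 or u_j < 0:
        raise ValueError("dispersion energies must be non-negative")
    if not -1.0 < kij <= 1.0:
        raise ValueError("kij must lie in (-1, 1]")
    return (1.0 - kij) * math.sqrt(u_i * u_j)


def combine_association(
    i: PureComponentParams, j: PureComponentParams, T: float = 298.15
) -> tuple[float, float]:
    """Wolbach–Sandler cross association energy (K) and volume (−).

    ε^AiBj = ½(ε^AiBi + ε^AjBj);
    κ^AiBj = √(κ^AiBi κ^AjBj)·(√(σ_i σ_j) / ½(σ_i + σ_j))³,
    with the segment diameters evaluated at ``T`` (relevant only for water).
    """
    if not (i.has_sites or j.has_sites):
        raise ValueError("at least one component must carry association sites")
    si, sj = i.sigma_at(T), j.sigma_at(T)
    eps = 0.5 * (i.assoc_energy + j.assoc_energy)
    kappa = math.sqrt(i.assoc_volume * j.assoc_volume) * (
        math.sqrt(si * sj) / (0.5 * (si + sj))
    ) ** 3
    return eps, kappa


# ---------------------------------------------------------------------------
# states


@dataclass(frozen=True)
class MixtureState:
    """Temperature, pressure and composition of a liquid mixture."""

    temperature: float  # K
    pressure: float  # Pa
    component_ids: tuple[str, ...]
    mole_fractions: tuple[float, ...]

    def __post_init__(self):
        x = np.asarray(self.mole_fractions, float)
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be positive")
        if len(self.component_ids) != x.size:
            raise ValueError("component_ids and mole_fractions length mismatch")
        if np.any(x < -1e-15):
            raise ValueError("mole fractions must be non-negative")
        if abs(float(x.sum()) - 1.0) > 1e-12:
            raise ValueError(f"mole fractions sum to {x.sum()}, not 1")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.mole_fractions, float)


@dataclass(frozen=True)
class CrossParameters:
    """Cross interaction parameters of one (i, j) pair."""

    sigma_ij: float
    u_ij: float
    eps_AiBj: float
    kappa_AiBj: float


@dataclass(frozen=True)
class EosState:
    """A converged equation-of-state evaluation."""

    mixture: MixtureState
    packing_fraction: float
    molar_density: float  # mol/m^3
    association_fractions: Mapping[str, float]  # "<id>:donor" / "<id>:acceptor"
    helmholtz_contributions: Mapping[str, float]

    @property
    def residual_helmholtz(self) -> float:
        c = self.helmholtz_contributions
        return c["hard_chain"] + c["dispersion"] + c["association"]


@dataclass
class _Ares:
    hard_chain: complex
    dispersion: complex
    association: complex
    XD: np.ndarray
    XA: np.ndarray
    eta: complex

    @property
    def total(self) -> complex:
        return self.hard_chain + self.dispersion + self.association


# ---------------------------------------------------------------------------
# the bound model


class PcSaft:
    """Equation-of-state model bound to a parameter database and a fixed,
    ordered component list."""

    def __init__(self, db: ParameterDB, component_ids: Sequence[str]):
        comps = [db.component(c) for c in component_ids]
        self.db = db
        self.ids = tuple(component_ids)
        self.n = len(comps)
        self.comps = comps
        self.m = np.array([c.segment_number for c in comps])
        self.Mw = np.array([c.molar_mass for c in comps])
        self.u = np.array([c.dispersion_energy for c in comps])
        self.eps = np.array([c.assoc_energy for c in comps])
        self.kappa = np.array([c.assoc_volume for c in comps])
        self.nD = np.array([float(c.n_donor_sites) for c in comps])
        self.nA = np.array([float(c.n_acceptor_sites) for c in comps])
        self._has_sites = np.array([c.has_sites for c in comps])
        self._tcache: dict[float, dict] = {}
        self._pure_cache: dict[tuple[int, float, float], tuple[float, float]] = {}
        self._X_warm: tuple[np.ndarray, np.ndarray] | None = None

    # -- temperature-dependent parameter block --------------------------

    def _tdata(self, T: float) -> dict:
        td = self._tcache.get(T)
        if td is not None:
            return td
        sigma = np.array([c.sigma_at(T) for c in self.comps])
        d = sigma * (1.0 - 0.12 * np.exp(-3.0 * self.u / T))
        kij = np.zeros((self.n, self.n))
        for i in range(self.n):
            for j in range(i + 1, self.n):
                kij[i, j] = kij[j, i] = self.db.kij(self.ids[i], self.ids[j], T)
        sigma_ij = 0.5 * (sigma[:, None] + sigma[None, :])
        u_ij = (1.0 - kij) * np.sqrt(np.outer(self.u, self.u))
        eps_ij = 0.5 * (self.eps[:, None] + self.eps[None, :])
        kappa_ij = np.sqrt(np.outer(self.kappa, self.kappa)) * (
            np.sqrt(np.outer(sigma, sigma)) / sigma_ij
        ) ** 3
        # bonding strength prefactor: Δ_ij = pref_ij * g_ij(η)
        pref = sigma_ij**3 * kappa_ij * np.expm1(eps_ij / T)
        site_mask = np.outer(self._has_sites, self._has_sites)
        pref = np.where(site_mask, pref, 0.0)
        td = {
            "sigma": sigma,
            "d": d,
            "d3": d**3,
            "u_ij_T": u_ij / T,
            "sigma_ij3": sigma_ij**3,
            "pref": pref,
            "assoc": bool(np.any(pref > 0.0)),
        }
        if len(self._tcache) > 64:
            self._tcache.clear()
        self._tcache[T] = td
        return td

    def cross_parameters(self, i: int, j: int, T: float) -> CrossParameters:
        td = self._tdata(T)
        sigma = td["sigma"]
        eps, kap = 0.5 * (self.eps[i] + self.eps[j]), 0.0
        if self._has_sites[i] or self._has_sites[j]:
            eps, kap = combine_association(self.comps[i], self.comps[j], T)
        return CrossParameters(
            sigma_ij=combine_sigma(sigma[i], sigma[j]),
            u_ij=td["u_ij_T"][i, j] * T,
            eps_AiBj=eps,
            kappa_AiBj=kap,
        )

    # -- residual Helmholtz energy ---------------------------------------

    def a_res(self, T: float, rho, x) -> _Ares:
        """Reduced residual Helmholtz energy a_res = A_res/(N k_B T).

        ``rho`` is the total number density in Å⁻³; ``rho`` and ``x`` may be
        complex (complex-step differentiation).
        """
        td = self._tdata(T)
        d = td["d"]
        x = np.asarray(x)
        pi6rho = (np.pi / 6.0) * rho
        z0 = pi6rho * np.sum(x * self.m)
        z1 = pi6rho * np.sum(x * self.m * d)
        z2 = pi6rho * np.sum(x * self.m * d**2)
        z3 = pi6rho * np.sum(x * self.m * td["d3"])
        eta = z3
        one = 1.0 - z3
        m_bar = np.sum(x * self.m)

        a_hs = (1.0 / z0) * (
            3.0 * z1 * z2 / one
            + z2**3 / (z3 * one**2)
            + (z2**3 / z3**2 - z0) * np.log(one)
        )
        dij = np.outer(d, d) / (d[:, None] + d[None, :])
        g = 1.0 / one + dij * 3.0 * z2 / one**2 + dij**2 * 2.0 * z2**2 / one**3
        a_hc = m_bar * a_hs - np.sum(x * (self.m - 1.0) * np.log(np.diag(g)))

        mf1 = (m_bar - 1.0) / m_bar
        mf2 = mf1 * (m_bar - 2.0) / m_bar
        acoef = _A[:, 0] + mf1 * _A[:, 1] + mf2 * _A[:, 2]
        bcoef = _B[:, 0] + mf1 * _B[:, 1] + mf2 * _B[:, 2]
        eta_pow = eta ** np.arange(7)
        I1 = np.sum(acoef * eta_pow)
        I2 = np.sum(bcoef * eta_pow)
        C1 = 1.0 / (
            1.0
            + m_bar * (8.0 * eta - 2.0 * eta**2) / one**4
            + (1.0 - m_bar)
            * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
            / (one * (2.0 - eta)) ** 2
        )
        xm = x * self.m
        m2es3 = np.sum(np.outer(xm, xm) * td["u_ij_T"] * td["sigma_ij3"])
        m2e2s3 = np.sum(np.outer(xm, xm) * td["u_ij_T"] ** 2 * td["sigma_ij3"])
        a_disp = -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * m_bar * C1 * I2 * m2e2s3

        if td["assoc"]:
            delta = td["pref"] * g
            XD, XA = self._solve_X(rho, x, delta)
            a_assoc = np.sum(
                x
                * (
                    self.nD * (np.log(XD) - 0.5 * XD + 0.5)
                    + self.nA * (np.log(XA) - 0.5 * XA + 0.5)
                )
            )
        else:
            XD = np.ones(self.n)
            XA = np.ones(self.n)
            a_assoc = 0.0 * eta

        return _Ares(a_hc, a_disp, a_assoc, XD, XA, eta)

    def _solve_X(self, rho, x, delta, tol: float = 1e-14, maxit: int = 3000):
        """Damped successive substitution for the Wertheim site fractions.

        X_D,i = 1 / (1 + ρ Σ_j x_j N_A,j X_A,j Δ_ij)  and symmetrically for
        acceptors; donor–donor and acceptor–acceptor bonding is excluded by
        construction.
        """
        is_complex = np.iscomplexobj(x) or isinstance(rho, complex)
        if self._X_warm is not None:
            XD = self._X_warm[0].astype(complex if is_complex else float).copy()
            XA = self._X_warm[1].astype(complex if is_complex else float).copy()
        else:
            XD = np.ones(self.n, complex if is_complex else float)
            XA = np.ones(self.n, complex if is_complex else float)
        # a few damped substitutions to enter the Newton basin
        lam = 0.5
        for _ in range(8):
            newD = 1.0 / (1.0 + rho * (delta @ (x * self.nA * XA)))
            newA = 1.0 / (1.0 + rho * (delta @ (x * self.nD * XD)))
            XD = (1.0 - lam) * XD + lam * newD
            XA = (1.0 - lam) * XA + lam * newA
        # Newton on the residual R = X − 1/(1 + ρ Δ (x N X)); the linear solve
        # also propagates the complex-step derivative channel exactly
        n = self.n
        eye = np.eye(n)
        err = np.inf
        for it in range(100):
            denD = 1.0 + rho * (delta @ (x * self.nA * XA))
            denA = 1.0 + rho * (delta @ (x * self.nD * XD))
            fD, fA = 1.0 / denD, 1.0 / denA
            RD, RA = XD - fD, XA - fA
            err = max(np.max(np.abs(RD)), np.max(np.abs(RA)))
            if err < tol and it > 0:
                break
            B = rho * (x * self.nA)[None, :] * delta * (fD**2)[:, None]
            C = rho * (x * self.nD)[None, :] * delta * (fA**2)[:, None]
            J = np.block([[eye.astype(B.dtype), B], [C, eye.astype(C.dtype)]])
            dz = np.linalg.solve(J, -np.concatenate([RD, RA]))
            XD = XD + dz[:n]
            XA = XA + dz[n:]
            # keep the real parts physical; full steps can overshoot (0, 1]
            if not is_complex:
                XD = np.clip(XD, 1e-12, 1.0)
                XA = np.clip(XA, 1e-12, 1.0)
            else:
                XD = np.clip(XD.real, 1e-12, 1.0) + 1j * XD.imag
                XA = np.clip(XA.real, 1e-12, 1.0) + 1j * XA.imag
        else:
            raise AssociationError(
                f"association solver not converged: residual {err:.3e} "
                f"after damped substitution + 100 Newton steps"
            )
        self._X_warm = (np.real(XD).copy(), np.real(XA).copy())
        return XD, XA

    # -- pressure and density -------------------------------------------

    def compressibility(self, T: float, rho: float, x) -> float:
        """Z = 1 + η ∂a_res/∂η at constant T, x (complex step in ρ)."""
        a = self.a_res(T, rho * (1.0 + 1j * _CSTEP), np.asarray(x, float))
        return 1.0 + a.total.imag / _CSTEP

    def pressure(self, T: float, rho: float, x) -> float:
        """EoS pressure in Pa at number density ``rho`` (Å⁻³)."""
        return self.compressibility(T, rho, x) * rho * 1e30 * KB * T

    def _eta_to_rho(self, T: float, eta, x):
        td = self._tdata(T)
        return 6.0 * eta / (np.pi * np.sum(np.asarray(x) * self.m * td["d3"]))

    def _rho_to_eta(self, T: float, rho, x):
        td = self._tdata(T)
        return (np.pi / 6.0) * rho * np.sum(np.asarray(x) * self.m * td["d3"])

    def solve_density(
        self,
        T: float,
        p: float,
        x,
        phase: str = "liquid",
        eta_guess: float | None = None,
    ) -> float:
        """Packing fraction η at which the EoS pressure equals ``p``.

        The liquid hint selects the largest-η root (mechanically stable by
        construction of the directional bracket search); the vapor hint the
        smallest.  Relative pressure consistency at the root is better than
        1e-9.
        """
        x = np.asarray(x, float)

        def f(eta):
            rho = self._eta_to_rho(T, eta, x)
            return self.pressure(T, rho, x) - p

        lo_lim, hi_lim = 1e-10, ETA_MAX
        bracket = None
        if eta_guess is not None and lo_lim < eta_guess < hi_lim:
            a = max(lo_lim, eta_guess * 0.98)
            b = min(hi_lim, eta_guess * 1.02)
            fa, fb = f(a), f(b)
            if fa < 0.0 < fb:
                bracket = (a, b, fa, fb)
        if bracket is None:
            if phase == "liquid":
                b = hi_lim
                fb = f(b)
                if fb < 0:
                    raise DensitySolverError(
                        "pressure below specification even at close packing"
                    )
                step = 0.02
                a = b - step
                while a > lo_lim:
                    fa = f(a)
                    if fa < 0.0:
                        bracket = (a, b, fa, fb)
                        break
                    b, fb = a, fa
                    a -= step
                else:
                    raise DensitySolverError(
                        f"no liquid density root in ({lo_lim}, {hi_lim}) at "
                        f"T={T} K, p={p} Pa"
                    )
            else:
                a = lo_lim
                fa = f(a)
                if fa > 0:
                    raise DensitySolverError("pressure above specification at zero density")
                b = 2e-10
                while b < hi_lim:
                    fb = f(b)
                    if fb > 0.0:
                        bracket = (a, b, fa, fb)
                        break
                    a, fa = b, fb
                    b *= 2.0
                else:
                    raise DensitySolverError(
                        f"no vapor density root in ({lo_lim}, {hi_lim}) at "
                        f"T={T} K, p={p} Pa"
                    )
        a, b, _, _ = bracket
        eta = brentq(f, a, b, xtol=1e-15, rtol=8.9e-16)
        return float(eta)

    # -- fugacity and activity coefficients ------------------------------

    def ln_phi_at_eta(self, T: float, eta: float, x) -> np.ndarray:
        """ln φ_i from the residual chemical potentials at packing η."""
        x = np.asarray(x, float)
        rho = self._eta_to_rho(T, eta, x)
        ar = self.a_res(T, rho * (1.0 + 1j * _CSTEP), x)
        a = ar.total.real
        Z = 1.0 + ar.total.imag / _CSTEP
        # composition derivatives at constant T and total number density
        dadx = np.empty(self.n)
        for i in range(self.n):
            xc = x.astype(complex)
            xc[i] = xc[i] + 1j * _CSTEP
            dadx[i] = self.a_res(T, rho, xc).total.imag / _CSTEP
        mu = a + (Z - 1.0) + dadx - np.sum(x * dadx)
        return mu - np.log(Z)

    def ln_phi(
        self, T: float, p: float, x, phase: str = "liquid", eta_guess: float | None = None
    ) -> tuple[np.ndarray, float]:
        eta = self.solve_density(T, p, x, phase=phase, eta_guess=eta_guess)
        return self.ln_phi_at_eta(T, eta, x), eta

    def ln_phi_pure(self, i: int, T: float, p: float) -> float:
        """Pure-liquid fugacity coefficient of component ``i`` at (T, p)."""
        key = (i, T, p)
        cached = self._pure_cache.get(key)
        if cached is not None:
            return cached
        x = np.zeros(self.n)
        x[i] = 1.0
        warm = self._X_warm
        self._X_warm = None  # pure state: do not inherit mixture site fractions
        try:
            eta = self.solve_density(T, p, x, phase="liquid")
            rho = self._eta_to_rho(T, eta, x)
            a = self.a_res(T, rho, x).total.real
            Z = self.compressibility(T, rho, x)
        finally:
            self._X_warm = warm
        val = a + (Z - 1.0) - math.log(Z)
        self._pure_cache[key] = val
        return val

    def activity_coefficients(
        self, T: float, p: float, x, eta_guess: float | None = None
    ) -> tuple[np.ndarray, float]:
        """Symmetric-convention activity coefficients γ_i and the liquid η.

        γ_i = φ_i(T, p, x) / φ_i^pure-liquid(T, p); γ_i → 1 as x_i → 1.
        """
        lnphi, eta = self.ln_phi(T, p, x, phase="liquid", eta_guess=eta_guess)
        lnphi0 = np.array([self.ln_phi_pure(i, T, p) for i in range(self.n)])
        return np.exp(lnphi - lnphi0), eta

    # -- reporting -------------------------------------------------------

    def eos_state(self, state: MixtureState, eta: float) -> EosState:
        rho = self._eta_to_rho(state.temperature, eta, state.x)
        a = self.a_res(state.temperature, rho, state.x)
        assoc = {}
        for i, cid in enumerate(self.ids):
            if self._has_sites[i]:
                assoc[f"{cid}:donor"] = float(np.real(a.XD[i]))
                assoc[f"{cid}:acceptor"] = float(np.real(a.XA[i]))
        return EosState(
            mixture=state,
            packing_fraction=float(np.real(a.eta)),
            molar_density=float(rho * 1e30 / NAV),
            association_fractions=assoc,
            helmholtz_contributions={
                "hard_chain": float(np.real(a.hard_chain)),
                "dispersion": float(np.real(a.dispersion)),
                "association": float(np.real(a.association)),
            },
        )


# ---------------------------------------------------------------------------
# model cache and module-level surface

_MODEL_CACHE: dict[tuple[int, tuple[str, ...]], PcSaft] = {}


def get_model(db: ParameterDB, component_ids: Sequence[str]) -> PcSaft:
    """Memoized :class:`PcSaft` model for (db, ordered component list)."""
    key = (id(db), tuple(component_ids))
    model = _MODEL_CACHE.get(key)
    if model is None:
        if len(_MODEL_CACHE) > 256:
            _MODEL_CACHE.clear()
        model = PcSaft(db, component_ids)
        _MODEL_CACHE[key] = model
    return model


def residual_helmholtz(db: ParameterDB, state: MixtureState, packing_fraction: float) -> EosState:
    """Evaluate the three Helmholtz contributions at a given packing fraction."""
    if not 0.0 < packing_fraction < ETA_MAX:
        raise ValueError("packing fraction must lie in (0, 0.74)")
    model = get_model(db, state.component_ids)
    return model.eos_state(state, packing_fraction)


def solve_association_fractions(
    db: ParameterDB, state: MixtureState, packing_fraction: float
) -> dict[str, float]:
    """Unbonded site fractions X at a given state and packing fraction."""
    return dict(residual_helmholtz(db, state, packing_fraction).association_fractions)


def solve_density(db: ParameterDB, state: MixtureState, phase_hint: str = "liquid") -> EosState:
    """Density root of the EoS at the state's (T, p); see :meth:`PcSaft.solve_density`."""
    model = get_model(db, state.component_ids)
    eta = model.solve_density(
        state.temperature, state.pressure, state.x, phase=phase_hint
    )
    return model.eos_state(state, eta)


def activity_coefficients(db: ParameterDB, state: MixtureState) -> np.ndarray:
    """Symmetric activity coefficients γ_i for a liquid mixture state."""
    model = get_model(db, state.component_ids)
    gamma, _ = model.activity_coefficients(state.temperature, state.pressure, state.x)
    return gamma
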