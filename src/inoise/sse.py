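"""System-size expansion of the chemical master equation.

For a well-mixed mass-action network the master equation is expanded in
powers of Omega^(-1/2) about the macroscopic trajectory.  Collecting
orders gives, in increasing accuracy:

* rate equations (REs) for the mean concentrations,
* the linear noise approximation (LNA): Gaussian fluctuations whose
  covariance sigma solves the Lyapunov equation  J sigma + sigma J^T + D = 0,
* the effective mesoscopic rate equation (EMRE): the order Omega^(-1)
  correction [eps_i]_1 to the means,
* the IOS ("inverse omega squared") correction: third moments
  [eps_i eps_k eps_l]_1 and the order Omega^(-2) covariance correction
  [eps_i eps_j]_2 centred on the EMRE means.

The EMRE/IOS moment equations used here are obtained by substituting the
ansatz n/Omega = X + Omega^(-1/2) eps into the master equation, expanding
the step operators and the mass-action propensities, collecting orders
Omega^(-1/2) and Omega^(-1), taking moments and closing the fourth moments
with the Gaussian (Wick) factorisation that is exact at leading order.
For networks of at most bimolecular reactions the macroscopic rates are at
most quadratic, so all third derivatives vanish and the resulting systems
are (given the rate-equation solution) linear:

    d[eps]_1/dt   = J [eps]_1 + h,
        h_i       = 1/2 J2_{i,mn} sigma_mn + J1_i
    dT_ikl/dt     = (J T)_sym + (D (x) eps1)_sym + (h (x) sigma)_sym
                    + (J2 sigma sigma)_sym + (D21 sigma)_sym + D3_ikl
    ds2_ik/dt     = J s2 + s2 J^T + 1/2 (J2 : T)_sym + (J1 (x) eps1)_sym
                    + D21 : eps1 + (J1g sigma)_sym + 1/2 D22 : sigma + D1

with the stoichiometry/derivative tensors defined in :class:`SSETensors`.
The assembled forms are validated in the test suite against brute-force
stationary solutions of the master equation and against exactness on
first-order networks.

All expansion blocks are computed for the conservation-reduced set of
independent species (the Jacobian is singular otherwise); moments of
eliminated species are recovered exactly through the affine reduction map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eigvals, solve_continuous_lyapunov

from . import _packing as pk
from .netmodel import (NetworkError, ReactionNetwork, Reduction,
                       conservation_analysis)

__all__ = [
    "SSEConfig", "SSETensors", "SSEState", "SteadyState", "SSESystem",
    "MonostabilityError", "macroscopic_rates", "re_rhs", "solve_re",
    "solve_steady_state", "lna_covariance", "emre_correction",
    "ios_correction", "equation_count", "moments",
    "sse_steady_state", "sse_timecourse", "ORDERS",
]

ORDERS = ("re", "lna", "emre", "ios")


class MonostabilityError(NetworkError):
    """The rate equations have no stable unique fixed point at hand."""


@dataclass
class SSEConfig:
    """Numerical tolerances for the expansion solvers.

    rtol/atol: ODE integrator tolerances.
    ss_tol: relative residual accepted for the rate-equation fixed point.
    lyap_rtol: accepted Lyapunov residual relative to ||D||.
    t_relax: initial relaxation horizon for the steady-state seed
        (doubled until the RE right-hand side is small).
    """

    rtol: float = 1e-8
    atol: float = 1e-12
    ss_tol: float = 1e-10
    lyap_rtol: float = 1e-10
    t_relax: float = 100.0
    max_relax_doublings: int = 40


@dataclass
class SSETensors:
    """Rate functions and stoichiometry/derivative tensors at one point.

    All arrays live in the reduced (independent-species) space of size N.
    `nu` is the reduced net stoichiometry (N x R).

    J        = sum_j nu_ij d_k f0_j                 (N x N Jacobian)
    D        = sum_j nu_ij nu_kj f0_j               (diffusion matrix)
    D3       = sum_j nu_ij nu_kj nu_lj f0_j
    J2_{i,kl}  = sum_j nu_ij d_k d_l f0_j
    D21_{ik,l} = sum_j nu_ij nu_kj d_l f0_j
    J1       = sum_j nu_ij f1_j
    J1g_{i,k}  = sum_j nu_ij d_k f1_j
    D1       = sum_j nu_ij nu_kj f1_j
    D22_{ik,lm} = sum_j nu_ij nu_kj d_l d_m f0_j

    f1 is the order Omega^(-1) part of the mass-action propensity
    (the n(n-1) combinatorial correction; nonzero only for homodimeric
    reactions 2A -> ...).
    """

    y: np.ndarray
    x_full: np.ndarray
    nu: np.ndarray
    f0: np.ndarray
    f1: np.ndarray
    grad_f0: np.ndarray
    hess_f0: np.ndarray
    grad_f1: np.ndarray
    J: np.ndarray
    D: np.ndarray
    D3: np.ndarray
    J2: np.ndarray
    D21: np.ndarray
    J1: np.ndarray
    J1g: np.ndarray
    D1: np.ndarray
    D22: np.ndarray

    @property
    def emre_drive(self) -> np.ndarray:
        """h_i = 1/2 J2 : sigma + J1 requires sigma; see emre_correction."""
        raise AttributeError("use emre_correction(tensors, sigma)")


# ---------------------------------------------------------------------------
# macroscopic rates (full species space)
# ---------------------------------------------------------------------------

def _check_mass_action(network: ReactionNetwork):
    if network.has_custom_propensities():
        raise NetworkError(
            "network has custom (non-mass-action) propensities; the system "
            "size expansion supports mass action only (the SSA accepts them)")


def macroscopic_rates(network: ReactionNetwork, X) -> tuple[np.ndarray, np.ndarray]:
    """Macroscopic rate f0_j and its Omega^(-1) correction f1_j at X.

    f0_j = k_j prod_i X_i^{s_ij}; f1_j carries the combinatorial correction
    from n(n-1)-type propensities: for a reaction consuming 2A,
    f1_j = -k_j X_A (zero for all reactions of order <= 1 and for
    bimolecular reactions of distinct species).
    """
    _check_mass_action(network)
    X = np.asarray(X, dtype=float)
    if np.any(X < -1e-300):
        raise NetworkError("negative concentration")
    R = network.n_reactions
    f0 = np.zeros(R)
    f1 = np.zeros(R)
    for j, r in enumerate(network.reactions):
        val = r.rate_constant
        for sid, s in r.reactant_stoich.items():
            val *= X[network.species_index(sid)] ** s
        f0[j] = val
        for sid, s in r.reactant_stoich.items():
            if s == 2:
                f1[j] = -r.rate_constant * X[network.species_index(sid)]
    return f0, f1


def re_rhs(network: ReactionNetwork, X) -> np.ndarray:
    """dX/dt = S f0(X) in the full species space."""
    f0, _ = macroscopic_rates(network, X)
    return network.stoichiometric_matrix() @ f0


def solve_re(network: ReactionNetwork, X0, t_grid, config: SSEConfig | None = None):
    """Integrate the rate equations; returns X(t) with shape (len(t), N)."""
    cfg = config or SSEConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    S = network.stoichiometric_matrix().astype(float)

    def rhs(t, x):
        f0, _ = macroscopic_rates(network, np.maximum(x, 0.0))
        return S @ f0

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), np.asarray(X0, dtype=float),
                    t_eval=t_grid, method="LSODA", rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        raise NetworkError(f"rate-equation integration failed at t={sol.t[-1]:g}: "
                           f"{sol.message}")
    return sol.y.T


# ---------------------------------------------------------------------------
# the reduced expansion system
# ---------------------------------------------------------------------------

class SSESystem:
    """Conservation-reduced network with cached expansion tensors.

    Wraps a :class:`ReactionNetwork` together with its :class:`Reduction`;
    the expansion state lives in the space of independent species.
    """

    def __init__(self, network: ReactionNetwork, reduction: Reduction | None = None,
                 config: SSEConfig | None = None):
        _check_mass_action(network)
        self.network = network
        self.reduction = reduction if reduction is not None else conservation_analysis(network)
        self.config = config or SSEConfig()
        red = self.reduction
        self.A = red.A                          # N_full x N
        self.c = red.c
        self.n = red.n_independent
        S = network.stoichiometric_matrix().astype(float)
        self.nu = S[red.independent_idx, :]     # N x R
        self.k = np.array([r.rate_constant for r in network.reactions])
        # reactant index/stoich lists per reaction (full-species indices)
        self._reactants = [
            [(network.species_index(sid), s) for sid, s in r.reactant_stoich.items()]
            for r in network.reactions
        ]
        # constant pieces: full-space Hessians and grad f1, projected once
        Nf, R = network.n_species, network.n_reactions
        H = np.zeros((R, Nf, Nf))
        G1 = np.zeros((R, Nf))
        for j, terms in enumerate(self._reactants):
            kj = self.k[j]
            if len(terms) == 1 and terms[0][1] == 2:
                a = terms[0][0]
                H[j, a, a] = 2.0 * kj
                G1[j, a] = -kj
            elif len(terms) == 2:
                (a, _), (b, _) = terms
                H[j, a, b] += kj
                H[j, b, a] += kj
        self._hess_red = np.einsum("jab,ap,bq->jpq", H, self.A, self.A)
        self._gradf1_red = G1 @ self.A
        # packing metadata
        self.i2 = pk.sym2_indices(self.n)
        self.i3 = pk.sym3_indices(self.n)

    # -- evaluation ------------------------------------------------------
    def rates(self, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(f0, f1, grad_f0 reduced) at independent concentrations y."""
        x = self.A @ np.asarray(y, dtype=float) + self.c
        R = self.network.n_reactions
        Nf = self.network.n_species
        f0 = np.zeros(R)
        f1 = np.zeros(R)
        gfull = np.zeros((R, Nf))
        for j, terms in enumerate(self._reactants):
            val = self.k[j]
            for idx, s in terms:
                val *= x[idx] ** s
            f0[j] = val
            if len(terms) == 0:
                continue
            if len(terms) == 1:
                idx, s = terms[0]
                gfull[j, idx] = self.k[j] * s * x[idx] ** (s - 1)
                if s == 2:
                    f1[j] = -self.k[j] * x[idx]
            else:
                (a, _), (b, _) = terms
                gfull[j, a] = self.k[j] * x[b]
                gfull[j, b] = self.k[j] * x[a]
        return f0, f1, gfull @ self.A

    def tensors(self, y) -> SSETensors:
        f0, f1, g = self.rates(y)
        nu = self.nu
        x = self.A @ np.asarray(y, dtype=float) + self.c
        J = nu @ g
        D = np.einsum("ij,kj,j->ik", nu, nu, f0)
        D3 = np.einsum("ij,kj,lj,j->ikl", nu, nu, nu, f0)
        J2 = np.einsum("ij,jkl->ikl", nu, self._hess_red)
        D21 = np.einsum("ij,kj,jl->ikl", nu, nu, g)
        J1 = nu @ f1
        J1g = nu @ self._gradf1_red
        D1 = np.einsum("ij,kj,j->ik", nu, nu, f1)
        D22 = np.einsum("ij,kj,jlm->iklm", nu, nu, self._hess_red)
        return SSETensors(y=np.asarray(y, dtype=float), x_full=x, nu=nu, f0=f0,
                          f1=f1, grad_f0=g, hess_f0=self._hess_red,
                          grad_f1=self._gradf1_red, J=J, D=D, D3=D3, J2=J2,
                          D21=D21, J1=J1, J1g=J1g, D1=D1, D22=D22)

    def re_rhs_reduced(self, y) -> np.ndarray:
        f0, _, _ = self.rates(y)
        return self.nu @ f0

    def re_jacobian(self, y) -> np.ndarray:
        _, _, g = self.rates(y)
        return self.nu @ g


# ---------------------------------------------------------------------------
# steady state of the rate equations
# ---------------------------------------------------------------------------

@dataclass
class SteadyState:
    """Stable fixed point of the (reduced) rate equations."""

    system: SSESystem
    y_star: np.ndarray                  # independent-species concentrations
    jacobian_eigenvalues: np.ndarray
    stable: bool
    residual_norm: float

    @property
    def X_star(self) -> np.ndarray:
        """Full-species steady-state concentrations."""
        return self.system.A @ self.y_star + self.system.c


def solve_steady_state(network_or_system, config: SSEConfig | None = None,
                       y0=None) -> SteadyState:
    """Find the stable fixed point of the reduced rate equations.

    Strategy: relax the REs from the initial condition until the right-hand
    side is small, then polish with damped Newton.  Raises
    :class:`MonostabilityError` if Newton does not converge or the fixed
    point is unstable (the expansion is then invalid).
    """
    sys_ = (network_or_system if isinstance(network_or_system, SSESystem)
            else SSESystem(network_or_system, config=config))
    cfg = config or sys_.config
    y = np.array(sys_.reduction.reduced_initial() if y0 is None else y0, dtype=float)
    scale = max(np.max(np.abs(y)), 1.0)

    # relaxation seed
    t_end = cfg.t_relax
    for _ in range(cfg.max_relax_doublings):
        rhs = sys_.re_rhs_reduced(y)
        if np.linalg.norm(rhs) <= 1e-6 * scale:
            break
        try:
            sol = solve_ivp(lambda t, z: sys_.re_rhs_reduced(z), (0.0, t_end), y,
                            method="LSODA", rtol=cfg.rtol, atol=cfg.atol,
                            jac=lambda t, z: sys_.re_jacobian(z))
        except (ValueError, FloatingPointError) as exc:
            raise MonostabilityError(
                f"relaxation integration diverged: {exc}") from None
        if not sol.success:
            raise MonostabilityError(f"relaxation integration failed: {sol.message}")
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            raise MonostabilityError(
                "rate equations diverge from this initial condition; no "
                "finite fixed point reached")
        t_end *= 2.0

    # damped Newton polish
    converged = False
    for _ in range(100):
        rhs = sys_.re_rhs_reduced(y)
        res = np.linalg.norm(rhs)
        scale = max(np.max(np.abs(y)), 1e-30)
        if res <= cfg.ss_tol * max(scale, 1.0):
            converged = True
            break
        J = sys_.re_jacobian(y)
        try:
            step = np.linalg.solve(J, -rhs)
        except np.linalg.LinAlgError:
            raise MonostabilityError("singular Jacobian at the candidate fixed point")
        lam = 1.0
        for _ in range(30):
            y_new = y + lam * step
            if np.linalg.norm(sys_.re_rhs_reduced(y_new)) < res:
                break
            lam *= 0.5
        y = y + lam * step
    rhs = sys_.re_rhs_reduced(y)
    res = np.linalg.norm(rhs)
    if not converged:
        raise MonostabilityError(
            f"Newton iteration did not reach the fixed-point tolerance "
            f"(residual {res:.3e})")

    eig = eigvals(sys_.re_jacobian(y))
    max_re = float(np.max(eig.real))
    stable = max_re < 0.0
    if not stable:
        worst = eig[np.argmax(eig.real)]
        raise MonostabilityError(
            f"fixed point is not stable: Jacobian eigenvalue {worst:.6g} has "
            f"nonnegative real part; the system size expansion requires a "
            f"monostable regime")
    return SteadyState(system=sys_, y_star=y, jacobian_eigenvalues=eig,
                       stable=stable, residual_norm=res)


# ---------------------------------------------------------------------------
# expansion blocks at steady state
# ---------------------------------------------------------------------------

def lna_covariance(J, D, lyap_rtol: float = 1e-10) -> np.ndarray:
    """Solve J sigma + sigma J^T + D = 0 for the LNA covariance.

    J must be stable (all eigenvalues with negative real part).
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.max(eigvals(J).real) >= 0:
        raise MonostabilityError("Lyapunov solve requires a stable Jacobian")
    sigma = solve_continuous_lyapunov(J, -D)
    sigma = 0.5 * (sigma + sigma.T)
    dnorm = np.linalg.norm(D)
    # iterative refinement: badly scaled rate constants can leave the
    # Bartels-Stewart solution several digits short of the target residual
    for _ in range(10):
        R = J @ sigma + sigma @ J.T + D
        resid = np.linalg.norm(R)
        if dnorm == 0 or resid <= lyap_rtol * dnorm:
            break
        delta = solve_continuous_lyapunov(J, -R)
        sigma = sigma + 0.5 * (delta + delta.T)
    else:
        resid = np.linalg.norm(J @ sigma + sigma @ J.T + D)
        if resid > lyap_rtol * dnorm:
            raise NetworkError(f"Lyapunov residual {resid:.3e} exceeds tolerance")
    return sigma


def emre_correction(tensors: SSETensors, sigma: np.ndarray) -> np.ndarray:
    """Steady-state EMRE mean correction [eps]_1.

    Solves J eps1 + h = 0 with h_i = 1/2 J2_{i,mn} sigma_mn + J1_i.
    """
    h = 0.5 * np.einsum("imn,mn->i", tensors.J2, sigma) + tensors.J1
    try:
        return np.linalg.solve(tensors.J, -h)
    except np.linalg.LinAlgError:
        raise MonostabilityError("singular Jacobian in EMRE solve") from None


def _third_moment_drive(t: SSETensors, sigma, eps1):
    """Inhomogeneity of the third-moment equations (everything but J T)."""
    h = 0.5 * np.einsum("imn,mn->i", t.J2, sigma) + t.J1
    B = np.multiply.outer(t.D, eps1)              # D_ik eps_l
    drive = B + B.transpose(0, 2, 1) + B.transpose(2, 0, 1)
    C = np.multiply.outer(h, sigma)               # h_i sigma_kl
    drive += C + C.transpose(1, 0, 2) + C.transpose(1, 2, 0)
    E = np.einsum("imn,mk,nl->ikl", t.J2, sigma, sigma)
    drive += E + E.transpose(1, 0, 2) + E.transpose(1, 2, 0)
    F = np.einsum("ikm,ml->ikl", t.D21, sigma)
    drive += F + F.transpose(0, 2, 1) + F.transpose(2, 0, 1)
    drive += t.D3
    return drive


def _sigma2_drive(t: SSETensors, sigma, eps1, T):
    """Inhomogeneity of the [eps eps]_2 equations (everything but J s2 + s2 J^T)."""
    M = 0.5 * np.einsum("imn,kmn->ik", t.J2, T)
    M = M + M.T
    M += np.multiply.outer(t.J1, eps1) + np.multiply.outer(eps1, t.J1)
    M += np.einsum("ikm,m->ik", t.D21, eps1)
    G = np.einsum("im,mk->ik", t.J1g, sigma)
    M += G + G.T
    M += 0.5 * np.einsum("iklm,lm->ik", t.D22, sigma)
    M += t.D1
    return 0.5 * (M + M.T)


def ios_correction(tensors: SSETensors, sigma: np.ndarray,
                   eps1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state third moments [eps eps eps]_1 and covariance correction
    [eps eps]_2.

    The third moments solve the linear system (J (+) J (+) J) T = -drive
    (Kronecker-sum structure); the covariance correction solves a Lyapunov
    equation driven by eps1, T and the mixed tensors.
    """
    n = tensors.J.shape[0]
    J = tensors.J
    drive = _third_moment_drive(tensors, sigma, eps1)
    I = np.eye(n)
    K = (np.kron(np.kron(J, I), I) + np.kron(np.kron(I, J), I)
         + np.kron(np.kron(I, I), J))
    T = np.linalg.solve(K, -drive.reshape(-1)).reshape(n, n, n)
    # symmetrise against round-off
    T = (T + T.transpose(0, 2, 1) + T.transpose(1, 0, 2) + T.transpose(1, 2, 0)
         + T.transpose(2, 0, 1) + T.transpose(2, 1, 0)) / 6.0
    B = _sigma2_drive(tensors, sigma, eps1, T)
    sigma2 = solve_continuous_lyapunov(J, -B)
    sigma2 = 0.5 * (sigma2 + sigma2.T)
    bnorm = np.linalg.norm(B)
    for _ in range(10):
        R = J @ sigma2 + sigma2 @ J.T + B
        if bnorm == 0 or np.linalg.norm(R) <= 1e-12 * bnorm:
            break
        delta = solve_continuous_lyapunov(J, -R)
        sigma2 = sigma2 + 0.5 * (delta + delta.T)
    return T, sigma2


# ---------------------------------------------------------------------------
# state container, counts, moments
# ---------------------------------------------------------------------------

def equation_count(N: int) -> tuple[int, int, int]:
    """(total, nonlinear, linear) expansion equations for N independent species.

    total = 2N + N(N+1) + N(N+1)(N+2)/6: the N rate equations, N(N+1)/2
    packed LNA covariances, N EMRE corrections, N(N+1)(N+2)/6 packed third
    moments and N(N+1)/2 packed covariance corrections.  Only the N rate
    equations are nonlinear; at steady state the rest is a linear solve.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    total = 2 * N + N * (N + 1) + N * (N + 1) * (N + 2) // 6
    return total, N, total - N


@dataclass
class SSEState:
    """Expansion state: packed blocks in the independent-species space.

    X: rate-equation concentrations (N)
    sigma: packed LNA covariances [eps_i eps_j]_0 (N(N+1)/2)
    eps1: EMRE mean corrections [eps_i]_1 (N)
    T: packed third moments [eps_i eps_k eps_l]_1 (N(N+1)(N+2)/6)
    sigma2: packed IOS covariance corrections [eps_i eps_j]_2 (N(N+1)/2)
    """

    system: SSESystem
    order: str
    X: np.ndarray
    sigma: np.ndarray | None = None
    eps1: np.ndarray | None = None
    T: np.ndarray | None = None
    sigma2: np.ndarray | None = None
    time: float | None = None

    @property
    def n(self) -> int:
        return self.system.n

    def sigma_matrix(self) -> np.ndarray:
        return pk.unpack_sym2(self.sigma, self.n)

    def T_tensor(self) -> np.ndarray:
        return pk.unpack_sym3(self.T, self.n)

    def sigma2_matrix(self) -> np.ndarray:
        return pk.unpack_sym2(self.sigma2, self.n)

    def pack(self) -> np.ndarray:
        blocks = [self.X]
        if self.order in ("lna", "emre", "ios"):
            blocks.append(self.sigma)
        if self.order in ("emre", "ios"):
            blocks.append(self.eps1)
        if self.order == "ios":
            blocks += [self.T, self.sigma2]
        return np.concatenate(blocks)

    @classmethod
    def unpack(cls, system: SSESystem, order: str, v: np.ndarray,
               time: float | None = None) -> "SSEState":
        n = system.n
        m2, m3 = pk.sym2_size(n), pk.sym3_size(n)
        pos = 0

        def take(sz):
            nonlocal pos
            out = v[pos:pos + sz]
            pos += sz
            return np.array(out)

        X = take(n)
        sigma = take(m2) if order in ("lna", "emre", "ios") else None
        eps1 = take(n) if order in ("emre", "ios") else None
        T = take(m3) if order == "ios" else None
        sigma2 = take(m2) if order == "ios" else None
        return cls(system=system, order=order, X=X, sigma=sigma, eps1=eps1,
                   T=T, sigma2=sigma2, time=time)

    def to_dataframe(self):
        """Columnar snapshot of every packed entry with its index labels."""
        import pandas as pd
        ids = self.system.reduction.independent_ids
        rows = [("X", ids[i], "", "", v) for i, v in enumerate(self.X)]
        if self.sigma is not None:
            rows += [("sigma", ids[i], ids[j], "", v)
                     for (i, j), v in zip(self.system.i2, self.sigma)]
        if self.eps1 is not None:
            rows += [("eps1", ids[i], "", "", v) for i, v in enumerate(self.eps1)]
        if self.T is not None:
            rows += [("T", ids[i], ids[k], ids[l], v)
                     for (i, k, l), v in zip(self.system.i3, self.T)]
        if self.sigma2 is not None:
            rows += [("sigma2", ids[i], ids[j], "", v)
                     for (i, j), v in zip(self.system.i2, self.sigma2)]
        return pd.DataFrame(rows, columns=["block", "i", "k", "l", "value"])


def moments(sse_state: SSEState, omega: float | None = None,
            order: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Full-species mean concentrations and concentration covariance matrix.

    mean = X (+ eps1/Omega at EMRE/IOS order);
    Sigma = sigma/Omega (+ (s2 - eps1 eps1^T)/Omega^2 at IOS order).
    Multiply by Omega and Omega^2 respectively for molecule-number units.
    """
    st = sse_state
    order = st.order if order is None else order
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    avail = ORDERS.index(st.order)
    if ORDERS.index(order) > avail:
        raise ValueError(f"state holds {st.order!r} blocks; cannot report {order!r}")
    om = st.system.network.omega if omega is None else omega
    n = st.n
    mean_y = st.X.copy()
    cov_y = np.zeros((n, n))
    if order in ("lna", "emre", "ios"):
        cov_y += st.sigma_matrix() / om
    if order in ("emre", "ios"):
        mean_y += st.eps1 / om
    if order == "ios":
        cov_y += (st.sigma2_matrix() - np.outer(st.eps1, st.eps1)) / om ** 2
    A, c = st.system.A, st.system.c
    return A @ mean_y + c, A @ cov_y @ A.T


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def sse_steady_state(network_or_system, order: str = "ios",
                     config: SSEConfig | None = None, y0=None) -> SSEState:
    """Full steady-state expansion solve at the requested order.

    Solves the nonlinear reduced REs by relaxation + Newton, then the
    remaining blocks by direct linear algebra (Lyapunov and Kronecker-sum
    solves) — never by pseudo-time integration.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    ss = solve_steady_state(network_or_system, config=config, y0=y0)
    sys_ = ss.system
    st = SSEState(system=sys_, order=order, X=ss.y_star)
    if order == "re":
        return st
    t = sys_.tensors(ss.y_star)
    sigma = lna_covariance(t.J, t.D, sys_.config.lyap_rtol)
    st.sigma = pk.pack_sym2(sigma)
    if order == "lna":
        return st
    eps1 = emre_correction(t, sigma)
    st.eps1 = eps1
    if order == "emre":
        return st
    T, sigma2 = ios_correction(t, sigma, eps1)
    st.T = pk.pack_sym3(T)
    st.sigma2 = pk.pack_sym2(sigma2)
    _warn_negative_ios(st)
    return st


def _warn_negative_ios(st: SSEState):
    om = st.system.network.omega
    for i in range(st.n):
        var = (st.sigma_matrix()[i, i] / om
               + (st.sigma2_matrix()[i, i] - st.eps1[i] ** 2) / om ** 2)
        if var < 0:
            warnings.warn(
                f"IOS variance of species "
                f"{st.system.reduction.independent_ids[i]!r} is negative at "
                f"Omega={om:g}; the expansion is outside its validity regime",
                RuntimeWarning, stacklevel=3)


@dataclass
class SSETimecourse:
    system: SSESystem
    order: str
    t: np.ndarray
    Y: np.ndarray  # (len(t), n_equations)

    @property
    def n_equations(self) -> int:
        return self.Y.shape[1]

    def state(self, idx: int) -> SSEState:
        return SSEState.unpack(self.system, self.order, self.Y[idx],
                               time=float(self.t[idx]))

    def final(self) -> SSEState:
        return self.state(len(self.t) - 1)


def sse_timecourse(network_or_system, t_grid, order: str = "ios", X0=None,
                   config: SSEConfig | None = None) -> SSETimecourse:
    """Integrate the time-dependent expansion equations on t_grid.

    Deterministic initial conditions: all fluctuation blocks start at zero.
    The packed state length equals ``equation_count(N)[0]`` at IOS order.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    sys_ = (network_or_system if isinstance(network_or_system, SSESystem)
            else SSESystem(network_or_system, config=config))
    cfg = config or sys_.config
    n = sys_.n
    m2, m3 = pk.sym2_size(n), pk.sym3_size(n)
    y0 = np.array(sys_.reduction.reduced_initial() if X0 is None else X0, dtype=float)
    sizes = {"re": n, "lna": n + m2, "emre": 2 * n + m2,
             "ios": 2 * n + 2 * m2 + m3}
    v0 = np.zeros(sizes[order])
    v0[:n] = y0

    i2, i3 = sys_.i2, sys_.i3

    def rhs(t_, v):
        st = SSEState.unpack(sys_, order, v)
        tns = sys_.tensors(st.X)
        out = [sys_.nu @ tns.f0]
        if order != "re":
            sig = st.sigma_matrix()
            dsig = tns.J @ sig + sig @ tns.J.T + tns.D
            out.append(np.array([dsig[i, j] for i, j in i2]))
        if order in ("emre", "ios"):
            h = 0.5 * np.einsum("imn,mn->i", tns.J2, sig) + tns.J1
            out.append(tns.J @ st.eps1 + h)
        if order == "ios":
            T = st.T_tensor()
            JT = np.einsum("im,mkl->ikl", tns.J, T)
            dT = (JT + JT.transpose(1, 0, 2) + JT.transpose(1, 2, 0)
                  + _third_moment_drive(tns, sig, st.eps1))
            out.append(np.array([dT[i, k, l] for i, k, l in i3]))
            s2 = st.sigma2_matrix()
            ds2 = (tns.J @ s2 + s2 @ tns.J.T
                   + _sigma2_drive(tns, sig, st.eps1, T))
            out.append(np.array([ds2[i, j] for i, j in i2]))
        return np.concatenate(out)

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), v0, t_eval=t_grid,
                    method="LSODA", rtol=cfg.rtol, atol=cfg.atol)
    if not sol.success:
        raise NetworkError(f"expansion time course failed at t={sol.t[-1]:g}: "
                           f"{sol.message}")
    return SSETimecourse(system=sys_, order=order, t=sol.t, Y=sol.y.T)
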