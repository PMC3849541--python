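"""Exact stochastic simulation (Gillespie direct method) and a brute-force
master-equation oracle for small systems.

Sample paths are statistically exact realisations of the master equation
for the statistical law of mass action.  Stationary statistics are
event-weighted time averages (piecewise-constant integration between
reaction events), which avoids the discretisation bias of grid sampling;
grid-sampled views exist only for spectral estimation.  Standard errors
come from batch means over equal sub-windows of the averaging interval.

Reproducibility: every trajectory is driven by one named seed; ensemble
runs derive independent per-run seeds from a ``numpy.random.SeedSequence``
spawned from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .netmodel import NetworkError, ReactionNetwork, propensities

__all__ = [
    "Trajectory", "StationaryStats", "EnsembleStats", "CMEDistribution",
    "ssa_run", "time_average_stats", "stationary_stats", "ensemble_stats",
    "grid_sample", "cme_oracle",
]


# ---------------------------------------------------------------------------
# kernel preparation
# ---------------------------------------------------------------------------

def _kernel_arrays(network: ReactionNetwork, omega: float):
    """(S, r1, r2, c) arrays for the mass-action direct-method kernels."""
    if network.has_custom_propensities():
        raise NetworkError(
            "custom-propensity reactions are not supported by the compiled "
            "SSA kernels")
    N, R = network.n_species, network.n_reactions
    S = np.ascontiguousarray(network.stoichiometric_matrix().T)  # (R, N)
    r1 = np.full(R, -1, dtype=np.int64)
    r2 = np.full(R, -1, dtype=np.int64)
    c = np.zeros(R)
    for j, rxn in enumerate(network.reactions):
        c[j] = rxn.rate_constant * omega ** (1 - rxn.order)
        slots = []
        for sid, s in rxn.reactant_stoich.items():
            slots += [network.species_index(sid)] * s
        if len(slots) >= 1:
            r1[j] = slots[0]
        if len(slots) == 2:
            r2[j] = slots[1]
    return S, r1, r2, c


@njit(cache=True)
def _props(n, r1, r2, c, a):
    R = c.shape[0]
    a0 = 0.0
    for j in range(R):
        aj = c[j]
        if r1[j] >= 0:
            aj *= n[r1[j]]
            if r2[j] >= 0:
                if r2[j] == r1[j]:
                    aj *= max(n[r2[j]] - 1, 0)
                else:
                    aj *= n[r2[j]]
        if aj < 0.0:
            aj = 0.0
        a[j] = aj
        a0 += aj
    return a0


@njit(cache=True)
def _kernel_path(S, r1, r2, c, n0, t_end, max_events, seed):
    np.random.seed(seed)
    R, N = S.shape
    n = n0.copy()
    times = np.zeros(max_events + 1)
    states = np.zeros((max_events + 1, N), dtype=np.int64)
    states[0] = n
    a = np.zeros(R)
    t = 0.0
    m = 0
    absorbed = False
    while m < max_events:
        a0 = _props(n, r1, r2, c, a)
        if a0 <= 0.0:
            absorbed = True
            break
        t += -math.log(np.random.random()) / a0
        if t > t_end:
            t = t_end
            break
        u = np.random.random() * a0
        acc = 0.0
        j = R - 1
        for jj in range(R):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for i in range(N):
            n[i] += S[j, i]
        m += 1
        times[m] = t
        states[m] = n
    return m, times[: m + 1], states[: m + 1], absorbed, t


@njit(cache=True)
def _kernel_stats(S, r1, r2, c, n0, t_end, burn_in, n_batches, checkpoints, seed):
    """Streaming event-weighted means/variances over [burn_in, t_end].

    Returns (w, s1, s2, batch_w, batch_s1, ck_mean, ck_var, n_events,
    final_state, absorbed).  Checkpoint rows hold the running mean and
    variance estimate at each checkpoint time.
    """
    np.random.seed(seed)
    R, N = S.shape
    K = checkpoints.shape[0]
    n = n0.copy()
    a = np.zeros(R)
    s1 = np.zeros(N)
    s2 = np.zeros(N)
    w = 0.0
    batch_w = np.zeros(n_batches)
    batch_s1 = np.zeros((n_batches, N))
    ck_mean = np.zeros((K, N))
    ck_var = np.zeros((K, N))
    ck_i = 0
    t = 0.0
    n_events = 0
    absorbed = False
    batch_len = (t_end - burn_in) / n_batches
    while True:
        a0 = _props(n, r1, r2, c, a)
        if a0 <= 0.0:
            absorbed = True
            tau = t_end - t
        else:
            tau = -math.log(np.random.random()) / a0
        t_next = t + tau
        if t_next > t_end:
            t_next = t_end
        # accumulate the piece of [t, t_next) inside [burn_in, t_end]
        lo = t if t > burn_in else burn_in
        if t_next > lo:
            dt = t_next - lo
            w += dt
            for i in range(N):
                s1[i] += n[i] * dt
                s2[i] += float(n[i]) * n[i] * dt
            # batch means
            b0 = int((lo - burn_in) / batch_len)
            b1 = int((t_next - burn_in) / batch_len)
            if b1 >= n_batches:
                b1 = n_batches - 1
            if b0 >= n_batches:
                b0 = n_batches - 1
            if b0 == b1:
                batch_w[b0] += dt
                for i in range(N):
                    batch_s1[b0, i] += n[i] * dt
            else:
                for b in range(b0, b1 + 1):
                    seg_lo = burn_in + b * batch_len
                    seg_hi = seg_lo + batch_len
                    piece_lo = lo if lo > seg_lo else seg_lo
                    piece_hi = t_next if t_next < seg_hi else seg_hi
                    if piece_hi > piece_lo:
                        dd = piece_hi - piece_lo
                        batch_w[b] += dd
                        for i in range(N):
                            batch_s1[b, i] += n[i] * dd
        # checkpoints
        while ck_i < K and t_next >= checkpoints[ck_i]:
            if w > 0.0:
                for i in range(N):
                    mu = s1[i] / w
                    ck_mean[ck_i, i] = mu
                    ck_var[ck_i, i] = s2[i] / w - mu * mu
            ck_i += 1
        if absorbed or t_next >= t_end:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        j = R - 1
        for jj in range(R):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for i in range(N):
            n[i] += S[j, i]
        n_events += 1
    return w, s1, s2, batch_w, batch_s1, ck_mean, ck_var, n_events, n, absorbed


@njit(cache=True)
def _kernel_grid(S, r1, r2, c, n0, t_grid, seed):
    np.random.seed(seed)
    R, N = S.shape
    M = t_grid.shape[0]
    n = n0.copy()
    a = np.zeros(R)
    out = np.zeros((M, N), dtype=np.int64)
    t = 0.0
    gi = 0
    while gi < M:
        a0 = _props(n, r1, r2, c, a)
        if a0 <= 0.0:
            t_next = t_grid[M - 1] + 1.0
        else:
            t_next = t + (-math.log(np.random.random()) / a0)
        while gi < M and t_grid[gi] < t_next:
            out[gi] = n
            gi += 1
        if gi >= M:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        j = R - 1
        for jj in range(R):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for i in range(N):
            n[i] += S[j, i]
    return out


def _seed32(x) -> int:
    return int(np.uint32(x))


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n).astype(np.int64)


# ---------------------------------------------------------------------------
# trajectories and statistics
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """SSA sample path: event times and integer copy-number states."""

    network: ReactionNetwork
    omega: float
    seed: int
    event_times: np.ndarray       # (M+1,), strictly increasing, starts at 0
    states: np.ndarray            # (M+1, N) int copy numbers
    t_end: float
    absorbed: bool = False

    @property
    def n_events(self) -> int:
        return len(self.event_times) - 1

    def grid_view(self, t_grid) -> np.ndarray:
        """Piecewise-constant (sample-and-hold) states at grid times."""
        t_grid = np.asarray(t_grid, dtype=float)
        idx = np.searchsorted(self.event_times, t_grid, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.event_times) - 1)]

    def to_csv(self) -> str:
        import io
        buf = io.StringIO()
        buf.write(f"# seed={self.seed} omega={self.omega:.17g} "
                  f"model={self.network.name}\n")
        buf.write("time," + ",".join(self.network.species_ids()) + "\n")
        for t, row in zip(self.event_times, self.states):
            buf.write(f"{t:.17g}," + ",".join(str(int(v)) for v in row) + "\n")
        return buf.getvalue()


def ssa_run(network: ReactionNetwork, omega: float | None = None,
            t_end: float = 100.0, seed: int = 0, n0=None,
            max_events: int = 10_000_000) -> Trajectory:
    """One exact sample path up to ``t_end`` (or the event cap).

    The initial state defaults to the rounded copy numbers
    ``round(Omega * initial_concentrations)``.  Identical arguments give an
    identical event sequence.  If every propensity vanishes the path is
    returned truncated with ``absorbed=True``.
    """
    om = network.omega if omega is None else omega
    S, r1, r2, c = _kernel_arrays(network, om)
    n0 = (network.initial_copy_numbers(om) if n0 is None
          else np.asarray(n0, dtype=np.int64))
    if np.any(n0 < 0):
        raise NetworkError("negative initial copy number")
    m, times, states, absorbed, t_last = _kernel_path(
        S, r1, r2, c, n0, float(t_end), max_events, _seed32(seed))
    return Trajectory(network=network, omega=om, seed=seed,
                      event_times=times, states=states, t_end=float(t_end),
                      absorbed=absorbed)


@dataclass
class StationaryStats:
    """Event-weighted stationary moments of one long sample path."""

    species: list[str]
    omega: float
    seed: int
    burn_in: float
    averaging_time: float
    mean: np.ndarray
    variance: np.ndarray
    se_mean: np.ndarray           # batch-means standard error
    n_events: int
    converged: bool
    convergence: np.ndarray       # (K, N, 2): running mean/var at checkpoints
    checkpoint_times: np.ndarray

    def cv(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(self.variance) / self.mean

    def fano(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.variance / self.mean

    def get(self, sid: str, measure: str) -> float:
        i = self.species.index(sid)
        return float({"mean": self.mean, "variance": self.variance,
                      "cv": self.cv(), "fano": self.fano(),
                      "se_mean": self.se_mean}[measure][i])


def _convergence_ok(ck_mean, ck_var, rel_tol=0.01):
    """Relative change of mean and Fano below tolerance between the two
    final doubling checkpoints, per species with nonzero mean."""
    if ck_mean.shape[0] < 2:
        return False
    m1, m0 = ck_mean[-1], ck_mean[-2]
    f1 = np.where(ck_mean[-1] > 0, ck_var[-1] / np.maximum(ck_mean[-1], 1e-300), 0.0)
    f0 = np.where(ck_mean[-2] > 0, ck_var[-2] / np.maximum(ck_mean[-2], 1e-300), 0.0)
    ok = True
    for a, b in ((m0, m1), (f0, f1)):
        scale = np.maximum(np.abs(b), 1e-300)
        mask = np.abs(b) > 1e-12
        if np.any(np.abs(a - b)[mask] / scale[mask] > rel_tol):
            ok = False
    return ok


def stationary_stats(network: ReactionNetwork, omega: float | None = None,
                     t_end: float = 1000.0, burn_in: float = 100.0,
                     seed: int = 0, n0=None, n_batches: int = 16,
                     min_window: float = 0.0) -> StationaryStats:
    """Streaming time-averaged moments over [burn_in, t_end].

    Convergence is monitored at doubling checkpoints of the averaging
    window; the run is flagged converged when mean and Fano change by less
    than 1% between the last two checkpoints.
    """
    om = network.omega if omega is None else omega
    if t_end <= burn_in:
        raise NetworkError("averaging window is empty: t_end <= burn_in")
    if (t_end - burn_in) < min_window:
        raise NetworkError(
            f"averaging window {t_end - burn_in:g} shorter than required "
            f"minimum {min_window:g}")
    S, r1, r2, c = _kernel_arrays(network, om)
    n0 = (network.initial_copy_numbers(om) if n0 is None
          else np.asarray(n0, dtype=np.int64))
    window = t_end - burn_in
    K = 8
    checkpoints = burn_in + window / (2.0 ** np.arange(K - 1, -1, -1.0))
    w, s1, s2, bw, bs1, ck_mean, ck_var, n_events, nf, absorbed = _kernel_stats(
        S, r1, r2, c, n0, float(t_end), float(burn_in), n_batches,
        checkpoints, _seed32(seed))
    mean = s1 / w
    var = s2 / w - mean ** 2
    good = bw > 0
    bmeans = np.where(good[:, None], bs1 / np.maximum(bw[:, None], 1e-300), 0.0)
    nb = int(np.sum(good))
    se = (np.std(bmeans[good], axis=0, ddof=1) / math.sqrt(nb)
          if nb > 1 else np.full(network.n_species, np.nan))
    conv = np.stack([ck_mean, ck_var], axis=-1)
    return StationaryStats(
        species=network.species_ids(), omega=om, seed=seed, burn_in=burn_in,
        averaging_time=w, mean=mean, variance=var, se_mean=se,
        n_events=n_events, converged=_convergence_ok(ck_mean, ck_var),
        convergence=conv, checkpoint_times=checkpoints)


def time_average_stats(trajectory: Trajectory, burn_in: float,
                       min_window: float = 0.0) -> StationaryStats:
    """Event-weighted time averages of a stored path over [burn_in, t_end]."""
    tr = trajectory
    t_end = tr.t_end
    if t_end <= burn_in:
        raise NetworkError("averaging window is empty: t_end <= burn_in")
    if (t_end - burn_in) < min_window:
        raise NetworkError(
            f"averaging window {t_end - burn_in:g} shorter than required "
            f"minimum {min_window:g}")
    times = np.append(tr.event_times, t_end)
    lo = np.clip(times[:-1], burn_in, t_end)
    hi = np.clip(times[1:], burn_in, t_end)
    wts = hi - lo
    w = wts.sum()
    states = tr.states.astype(float)
    mean = (states * wts[:, None]).sum(axis=0) / w
    var = (states ** 2 * wts[:, None]).sum(axis=0) / w - mean ** 2
    # doubling checkpoints for the convergence record
    K = 8
    window = t_end - burn_in
    cps = burn_in + window / (2.0 ** np.arange(K - 1, -1, -1.0))
    ck_mean = np.zeros((K, tr.states.shape[1]))
    ck_var = np.zeros((K, tr.states.shape[1]))
    for kk, cp in enumerate(cps):
        hi_k = np.clip(times[1:], burn_in, cp)
        w_k = np.maximum(hi_k - lo, 0.0)
        tot = w_k.sum()
        if tot > 0:
            mu = (states * w_k[:, None]).sum(axis=0) / tot
            ck_mean[kk] = mu
            ck_var[kk] = (states ** 2 * w_k[:, None]).sum(axis=0) / tot - mu ** 2
    # batch means over 16 equal sub-windows
    nb = 16
    edges = np.linspace(burn_in, t_end, nb + 1)
    bmeans = np.zeros((nb, tr.states.shape[1]))
    ok = np.zeros(nb, dtype=bool)
    for b in range(nb):
        blo = np.clip(times[:-1], edges[b], edges[b + 1])
        bhi = np.clip(times[1:], edges[b], edges[b + 1])
        bw = bhi - blo
        tot = bw.sum()
        if tot > 0:
            bmeans[b] = (states * bw[:, None]).sum(axis=0) / tot
            ok[b] = True
    se = (np.std(bmeans[ok], axis=0, ddof=1) / math.sqrt(ok.sum())
          if ok.sum() > 1 else np.full(tr.states.shape[1], np.nan))
    return StationaryStats(
        species=tr.network.species_ids(), omega=tr.omega, seed=tr.seed,
        burn_in=burn_in, averaging_time=w, mean=mean, variance=var,
        se_mean=se, n_events=tr.n_events,
        converged=_convergence_ok(ck_mean, ck_var),
        convergence=np.stack([ck_mean, ck_var], axis=-1),
        checkpoint_times=cps)


@dataclass
class EnsembleStats:
    """Across-realisation moments at fixed time points."""

    species: list[str]
    t: np.ndarray
    n_runs: int
    mean: np.ndarray        # (T, N)
    variance: np.ndarray    # (T, N), unbiased across runs
    se_mean: np.ndarray     # (T, N)
    seed: int


def ensemble_stats(network: ReactionNetwork, omega: float | None = None,
                   n_runs: int = 100, t_points=None, seed: int = 0,
                   n0=None) -> EnsembleStats:
    """Unbiased ensemble mean/variance estimates over independent runs."""
    if n_runs < 2:
        raise NetworkError("ensemble statistics need n_runs >= 2")
    om = network.omega if omega is None else omega
    t_points = np.asarray(
        t_points if t_points is not None else np.linspace(0, 10, 11), dtype=float)
    S, r1, r2, c = _kernel_arrays(network, om)
    n0 = (network.initial_copy_numbers(om) if n0 is None
          else np.asarray(n0, dtype=np.int64))
    seeds = _spawn_seeds(seed, n_runs)
    acc = np.zeros((len(t_points), network.n_species))
    acc2 = np.zeros_like(acc)
    for s in seeds:
        x = _kernel_grid(S, r1, r2, c, n0, t_points, _seed32(s)).astype(float)
        acc += x
        acc2 += x ** 2
    mean = acc / n_runs
    var = (acc2 - n_runs * mean ** 2) / (n_runs - 1)
    se = np.sqrt(np.maximum(var, 0.0) / n_runs)
    return EnsembleStats(species=network.species_ids(), t=t_points,
                         n_runs=n_runs, mean=mean, variance=var, se_mean=se,
                         seed=seed)


def grid_sample(network: ReactionNetwork, t_grid, omega: float | None = None,
                seed: int = 0, n0=None) -> np.ndarray:
    """Grid-sampled copy numbers of a single run (for spectra)."""
    om = network.omega if omega is None else omega
    S, r1, r2, c = _kernel_arrays(network, om)
    n0 = (network.initial_copy_numbers(om) if n0 is None
          else np.asarray(n0, dtype=np.int64))
    return _kernel_grid(S, r1, r2, c, n0,
                        np.asarray(t_grid, dtype=float), _seed32(seed))


# ---------------------------------------------------------------------------
# brute-force master-equation oracle
# ---------------------------------------------------------------------------

@dataclass
class CMEDistribution:
    """Stationary distribution of the master equation on a truncated lattice.

    States are enumerated by breadth-first reachability from the initial
    state inside the user-supplied copy-number bounds; transitions that
    would leave the box are dropped, and the stationary probability mass on
    states with a dropped transition is reported as the truncation deficit.
    """

    network: ReactionNetwork
    omega: float
    states: np.ndarray      # (M, N) int
    p: np.ndarray           # (M,)
    deficit: float

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact mean vector and covariance matrix of the copy numbers."""
        x = self.states.astype(float)
        mean = self.p @ x
        cov = (x - mean).T @ ((x - mean) * self.p[:, None])
        return mean, cov

    def marginal(self, sid: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.network.species_index(sid)
        vals = np.unique(self.states[:, i])
        probs = np.array([self.p[self.states[:, i] == v].sum() for v in vals])
        return vals, probs

    def state_probabilities(self) -> dict[tuple, float]:
        return {tuple(int(v) for v in s): float(q)
                for s, q in zip(self.states, self.p)}


def cme_oracle(network: ReactionNetwork, omega: float | None = None,
               bounds: dict[str, int] | int = 200, n0=None,
               deficit_bound: float = 1e-8,
               max_states: int = 200_000) -> CMEDistribution:
    """Stationary solve of the truncated master equation (small models only).

    ``bounds`` is a per-species copy-number cap (int applies to all
    species).  Raises if the enumeration exceeds ``max_states`` or the
    truncation deficit exceeds ``deficit_bound`` (enlarge the bounds).
    """
    om = network.omega if omega is None else omega
    N = network.n_species
    S = network.stoichiometric_matrix().T  # (R, N)
    n0 = (network.initial_copy_numbers(om) if n0 is None
          else np.asarray(n0, dtype=np.int64))
    if isinstance(bounds, int):
        cap = np.full(N, bounds, dtype=np.int64)
    else:
        cap = np.full(N, np.iinfo(np.int64).max // 4, dtype=np.int64)
        for sid, b in bounds.items():
            cap[network.species_index(sid)] = b
    if np.any(n0 > cap):
        raise NetworkError("initial state outside the truncation bounds")

    index: dict[tuple, int] = {tuple(n0): 0}
    order = [np.array(n0)]
    frontier = [np.array(n0)]
    rows, cols, vals = [], [], []
    diag: dict[int, float] = {}
    boundary = set()
    while frontier:
        new_frontier = []
        for n in frontier:
            i = index[tuple(n)]
            a = propensities(network, n, om)
            for j in range(network.n_reactions):
                if a[j] <= 0:
                    continue
                n2 = n + S[j]
                if np.any(n2 < 0) or np.any(n2 > cap):
                    boundary.add(i)
                    continue
                key = tuple(n2)
                if key not in index:
                    if len(index) >= max_states:
                        raise NetworkError(
                            f"state enumeration exceeded {max_states} states; "
                            "tighten the bounds or shrink Omega")
                    index[key] = len(index)
                    order.append(n2)
                    new_frontier.append(n2)
                k = index[key]
                rows.append(k)
                cols.append(i)
                vals.append(a[j])
                diag[i] = diag.get(i, 0.0) - a[j]
        frontier = new_frontier

    M = len(index)
    for i, d in diag.items():
        rows.append(i)
        cols.append(i)
        vals.append(d)
    Q = csr_matrix((vals, (rows, cols)), shape=(M, M))
    # stationary: Q p = 0 with sum(p) = 1 (replace one balance equation)
    A = Q.tolil()
    A[0, :] = 1.0
    b = np.zeros(M)
    b[0] = 1.0
    p = spsolve(csr_matrix(A), b)
    p = np.maximum(p, 0.0)
    p /= p.sum()
    deficit = float(sum(p[i] for i in boundary))
    if deficit > deficit_bound:
        raise NetworkError(
            f"truncation deficit {deficit:.3e} exceeds bound "
            f"{deficit_bound:g}; enlarge the bounds")
    return CMEDistribution(network=network, omega=om,
                           states=np.array(order, dtype=np.int64), p=p,
                           deficit=deficit)
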