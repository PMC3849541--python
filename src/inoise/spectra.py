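"""Power spectra of stationary copy-number fluctuations.

Noise-induced (quasi-)oscillations show up as an interior peak of the
stationary power spectrum even when the deterministic rate equations only
have damped oscillations.  Two estimators are provided:

* the analytic LNA spectrum
      S(w) = (Omega/2pi) diag[ (J + i w I)^-1 D (J^T - i w I)^-1 ],
  the spectrum of the Ornstein-Uhlenbeck fluctuations about the stable
  fixed point, and
* an averaged, Hann-windowed periodogram of mean-removed grid-sampled SSA
  realisations (Bartlett averaging).

Both use angular frequency and the two-sided normalisation
``integral of S_i over the real line = Var(n_i)`` (molecule-number
variance); :meth:`SpectrumResult.variance_integral` evaluates
``2 * trapezoid(S, w)`` over the stored w >= 0 grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netmodel import NetworkError, ReactionNetwork
from .sse import SSEConfig, solve_steady_state
from . import ssa as _ssa

__all__ = ["SpectrumResult", "PeakStats", "lna_spectrum",
           "lna_spectrum_ss", "ssa_spectrum", "periodogram", "peak_stats"]


@dataclass
class SpectrumResult:
    """Per-species power spectrum on a nonnegative angular-frequency grid."""

    freq: np.ndarray            # (M,) angular frequencies, >= 0
    power: np.ndarray           # (M, K) two-sided spectral density
    species: list[str]
    method: str                 # "LNA" or "SSA"
    n_realizations: int = 1
    metadata: dict = field(default_factory=dict)

    def series(self, sid: str) -> np.ndarray:
        return self.power[:, self.species.index(sid)]

    def variance_integral(self, sid: str | None = None) -> np.ndarray | float:
        """2 * integral over the stored grid: the implied variance(s)."""
        out = 2.0 * np.trapezoid(self.power, self.freq, axis=0)
        return out if sid is None else float(out[self.species.index(sid)])

    def to_csv(self) -> str:
        import io
        buf = io.StringIO()
        meta = " ".join(f"{k}={v}" for k, v in self.metadata.items())
        buf.write(f"# method={self.method} n_realizations={self.n_realizations} {meta}\n")
        buf.write("omega," + ",".join(self.species) + "\n")
        for i, w in enumerate(self.freq):
            buf.write(f"{w:.17g}," + ",".join(f"{v:.17g}" for v in self.power[i]) + "\n")
        return buf.getvalue()


@dataclass
class PeakStats:
    """Location and size of an interior spectral maximum."""

    peak_present: bool
    peak_frequency: float = float("nan")
    period: float = float("nan")
    amplitude: float = float("nan")     # sqrt(peak power)
    peak_power: float = float("nan")

    def to_dict(self) -> dict:
        return {"peak_present": self.peak_present,
                "peak_frequency": self.peak_frequency, "period": self.period,
                "amplitude": self.amplitude, "peak_power": self.peak_power}


def lna_spectrum(J, D, omega_grid, scale: float = 1.0,
                 species: list[str] | None = None) -> SpectrumResult:
    """Analytic LNA spectrum from a stable Jacobian and diffusion matrix.

    ``scale`` multiplies the concentration-fluctuation density; pass the
    system size Omega to obtain molecule-number spectra (the default 1
    integrates to the Lyapunov covariance sigma_ii).
    """
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.max(np.linalg.eigvals(J).real) >= 0:
        raise NetworkError("LNA spectrum requires a stable Jacobian")
    n = J.shape[0]
    w = np.asarray(omega_grid, dtype=float)
    power = np.empty((len(w), n))
    I = np.eye(n)
    for m, wm in enumerate(w):
        Sm = np.linalg.solve(J + 1j * wm * I, D) @ np.linalg.inv(J.T - 1j * wm * I)
        power[m] = scale / (2.0 * math.pi) * np.real(np.diag(Sm))
    ids = species if species is not None else [f"s{i}" for i in range(n)]
    return SpectrumResult(freq=w, power=power, species=ids, method="LNA")


def lna_spectrum_ss(network: ReactionNetwork, omega_grid,
                    config: SSEConfig | None = None) -> SpectrumResult:
    """LNA spectrum of every species at the network's stable steady state.

    Reported in molecule-number units, so the variance integral equals
    Omega * sigma_ii.  Species eliminated by conservation are mapped back
    through the (linear) reduction, which fluctuations obey exactly.
    """
    ss = solve_steady_state(network, config=config)
    t = ss.system.tensors(ss.y_star)
    red = lna_spectrum(t.J, t.D, omega_grid, scale=network.omega)
    A = ss.system.A
    w = red.freq
    # full-species diagonal: diag(A S A^T) needs the full matrix per w
    n = ss.system.n
    I = np.eye(n)
    power = np.empty((len(w), network.n_species))
    for m, wm in enumerate(w):
        Sm = np.linalg.solve(t.J + 1j * wm * I, t.D) @ np.linalg.inv(t.J.T - 1j * wm * I)
        Sm = network.omega / (2.0 * math.pi) * np.real(Sm)
        power[m] = np.diag(A @ Sm @ A.T)
    return SpectrumResult(freq=w, power=power, species=network.species_ids(),
                          method="LNA", metadata={"omega": network.omega})


def periodogram(x: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, mean-removed periodogram of one realisation.

    ``x`` has shape (m,) or (m, k); returns (angular frequencies, two-sided
    density) normalised so that 2 * integral over w >= 0 estimates the
    signal variance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    m = x.shape[0]
    window = np.hanning(m)
    wsum2 = float(np.sum(window ** 2))
    xw = (x - x.mean(axis=0)) * window[:, None]
    X = np.fft.rfft(xw, axis=0)
    dens = (np.abs(X) ** 2) * dt / (2.0 * math.pi * wsum2)
    freq = 2.0 * math.pi * np.fft.rfftfreq(m, d=dt)
    return freq, dens


def ssa_spectrum(network: ReactionNetwork, omega: float | None = None,
                 n_runs: int = 16, t_end: float = 100.0, dt: float = 0.1,
                 seed: int = 0, burn_in: float = 0.0,
                 nyquist_guard: float = 2.0) -> SpectrumResult:
    """Averaged periodogram of mean-removed, Hann-windowed SSA samples.

    Each realisation is grid-sampled on [burn_in, t_end] with spacing dt,
    mean-removed, windowed and Fourier transformed; periodograms are
    averaged across realisations.  If the LNA spectrum has an interior
    peak at w*, dt must satisfy pi/dt >= nyquist_guard * w* (otherwise the
    expected peak is unresolvable and an error names the required dt).
    """
    om = network.omega if omega is None else omega
    net = network if om == network.omega else network.with_omega(om)
    # Nyquist check against the analytic peak location, when available
    wny = math.pi / dt
    try:
        probe = lna_spectrum_ss(net, np.linspace(0, wny * 4, 600))
    except Exception:
        probe = None  # no stable LNA reference (e.g. custom propensities)
    if probe is not None:
        for sid in net.species_ids():
            pk = peak_stats(probe, sid)
            if pk.peak_present and wny < nyquist_guard * pk.peak_frequency:
                need = math.pi / (nyquist_guard * pk.peak_frequency)
                raise NetworkError(
                    f"dt={dt:g} violates the Nyquist condition for the "
                    f"expected spectral peak of {sid!r} at w={pk.peak_frequency:g}; "
                    f"use dt <= {need:g}")

    m = int(round((t_end - burn_in) / dt))
    if m < 8:
        raise NetworkError("fewer than 8 samples per realisation")
    t_grid = burn_in + dt * np.arange(m)
    seeds = _ssa._spawn_seeds(seed, n_runs)
    acc = None
    for s in seeds:
        x = _ssa.grid_sample(net, t_grid, seed=int(s)).astype(float)
        freq, pxx = periodogram(x, dt)
        acc = pxx if acc is None else acc + pxx
    acc /= n_runs
    return SpectrumResult(
        freq=freq, power=acc, species=net.species_ids(), method="SSA",
        n_realizations=n_runs,
        metadata={"dt": dt, "t_end": t_end, "burn_in": burn_in,
                  "window": "hann", "seed": seed, "omega": om})


def peak_stats(spectrum: SpectrumResult, species: str | None = None) -> PeakStats:
    """Interior spectral maximum with local quadratic refinement.

    A peak is present only if some interior grid point is a local maximum
    whose power exceeds S(0) (monotone decay reports no peak).
    """
    S = spectrum.power[:, 0] if species is None else spectrum.series(species)
    w = spectrum.freq
    if len(w) < 3:
        return PeakStats(peak_present=False)
    start = 1 if w[0] == 0 else 0
    interior = slice(max(start, 1), len(w) - 1)
    idx = np.arange(len(w))[interior]
    is_max = (S[interior] >= S[interior.start - 1:interior.stop - 1]) & \
             (S[interior] >= S[interior.start + 1:interior.stop + 1])
    cands = idx[is_max & (S[interior] > S[0])]
    if len(cands) == 0:
        return PeakStats(peak_present=False)
    i = int(cands[np.argmax(S[cands])])
    # quadratic refinement through (w_{i-1}, w_i, w_{i+1})
    x0, x1, x2 = w[i - 1], w[i], w[i + 1]
    y0, y1, y2 = S[i - 1], S[i], S[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom != 0:
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
        if a < 0:
            wstar = -b / (2 * a)
            if x0 <= wstar <= x2:
                c = (y0 - a * x0 ** 2 - b * x0)
                pstar = a * wstar ** 2 + b * wstar + c
                return PeakStats(True, wstar, 2.0 * math.pi / wstar,
                                 math.sqrt(max(pstar, 0.0)), pstar)
    return PeakStats(True, w[i], 2.0 * math.pi / w[i],
                     math.sqrt(max(S[i], 0.0)), float(S[i]))
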