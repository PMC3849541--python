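"""Coefficients of variation and Fano factors at LNA and IOS order.

Both measures are reported for molecule numbers n_i = Omega x_i:
CV = sqrt(Var(n))/E(n) and F = Var(n)/E(n); CV scales as Omega^(-1/2) and
the Fano factor as Omega^0.  The IOS-order measures carry the relative
correction factors

    CV_ios = CV_lna (1 + c_i / Omega),
    F_ios  = F_lna  (1 + f_i / Omega),

with c_i = ([eps_i eps_i]_2 - [eps_i]_1^2)/(2 sigma_ii) - [eps_i]_1/(2 [X_i])
and f_i the same with both halves doubled.  The correction factors split
into a variance part and a mean part and are proportional to the
bimolecular rate constants: for networks of zeroth/first order reactions
they vanish identically and LNA = IOS.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _packing as pk
from .netmodel import NetworkError
from .sse import SSEState, moments

__all__ = ["NoiseSummary", "cv", "fano", "lna_measures", "ios_measures"]

#: species whose rate-equation mean falls below this floor are excluded
#: from measure tables instead of producing infinities
MEAN_FLOOR = 1e-12


class UndefinedMeasureError(NetworkError):
    """CV/Fano requested for a species with nonpositive mean."""


def cv(mean: float, variance: float) -> float:
    """Coefficient of variation sqrt(variance)/mean (molecule numbers)."""
    if mean <= 0:
        raise UndefinedMeasureError(f"CV undefined for mean {mean:g} <= 0")
    return math.sqrt(variance) / mean


def fano(mean: float, variance: float) -> float:
    """Fano factor variance/mean; 1 for a Poisson distribution."""
    if mean <= 0:
        raise UndefinedMeasureError(f"Fano factor undefined for mean {mean:g} <= 0")
    return variance / mean


@dataclass
class NoiseSummary:
    """Per-species noise table at one or two expansion orders.

    Means/variances are in molecule numbers; ``correction_c`` and
    ``correction_f`` are the relative LNA->IOS correction factors (only
    populated when IOS blocks are available).  Species skipped because of a
    near-zero mean are listed in ``skipped``.
    """

    species: list[str]
    omega: float
    mean_molecules: np.ndarray
    variance_molecules: np.ndarray
    cv_lna: np.ndarray
    fano_lna: np.ndarray
    cv_ios: np.ndarray | None = None
    fano_ios: np.ndarray | None = None
    correction_c: np.ndarray | None = None
    correction_f: np.ndarray | None = None
    skipped: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per (species, order, measure)."""
        rows = []
        for i, sid in enumerate(self.species):
            rows.append((sid, "lna", "mean", self.mean_molecules[i]))
            rows.append((sid, "lna", "variance", self.variance_molecules[i]))
            rows.append((sid, "lna", "cv", self.cv_lna[i]))
            rows.append((sid, "lna", "fano", self.fano_lna[i]))
            if self.cv_ios is not None:
                rows.append((sid, "ios", "cv", self.cv_ios[i]))
                rows.append((sid, "ios", "fano", self.fano_ios[i]))
                rows.append((sid, "ios", "correction_c", self.correction_c[i]))
                rows.append((sid, "ios", "correction_f", self.correction_f[i]))
        return pd.DataFrame(rows, columns=["species", "order", "measure", "value"])

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, index=False)
        return buf.getvalue()

    def get(self, species_id: str, measure: str, order: str = "lna") -> float:
        df = self.to_dataframe()
        sel = df[(df.species == species_id) & (df.order == order) & (df.measure == measure)]
        if sel.empty:
            raise KeyError(f"{measure}[{order}] for {species_id!r} not available")
        return float(sel.value.iloc[0])


def lna_measures(state_or_Xstar, sigma=None, omega=None, species=None,
                 mean_floor: float = MEAN_FLOOR) -> NoiseSummary:
    """LNA noise measures at steady state.

    Accepts either an :class:`SSEState` (at LNA order or higher), or the
    triple ``(X_star, sigma, omega)`` of full-species steady-state
    concentrations, concentration covariance matrix sigma (the Lyapunov
    solution), and system size.

    CV_lna,i = Omega^(-1/2) sqrt(sigma_ii)/X_i, F_lna,i = sigma_ii/X_i.
    """
    if isinstance(state_or_Xstar, SSEState):
        st = state_or_Xstar
        om = st.system.network.omega if omega is None else omega
        X, cov = moments(st, omega=om, order="lna")
        sig = cov * om  # back to Omega-free sigma
        ids = st.system.network.species_ids()
    else:
        X = np.asarray(state_or_Xstar, dtype=float)
        sig = np.asarray(sigma, dtype=float)
        om = float(omega)
        ids = list(species) if species is not None else [f"s{i}" for i in range(len(X))]

    keep = X > mean_floor
    skipped = [sid for sid, k in zip(ids, keep) if not k]
    idx = np.where(keep)[0]
    Xk = X[idx]
    var_conc = np.array([sig[i, i] for i in idx])
    return NoiseSummary(
        species=[ids[i] for i in idx],
        omega=om,
        mean_molecules=om * Xk,
        variance_molecules=om * var_conc,
        cv_lna=np.sqrt(np.maximum(var_conc, 0.0)) / Xk / math.sqrt(om),
        fano_lna=var_conc / Xk,
        skipped=skipped,
    )


def ios_measures(sse_state: SSEState, omega: float | None = None,
                 mean_floor: float = MEAN_FLOOR) -> NoiseSummary:
    """IOS noise measures with the relative correction factors.

    Applies the expansions CV_ios = CV_lna (1 + c/Omega) and
    F_ios = F_lna (1 + f/Omega) species-wise; requires the full IOS state.
    Species with sigma_ii = 0 get flagged (correction undefined).
    """
    st = sse_state
    if st.order != "ios":
        raise NetworkError(f"IOS measures need an IOS-order state, got {st.order!r}")
    om = st.system.network.omega if omega is None else omega
    A, c_aff = st.system.A, st.system.c
    X = A @ st.X + c_aff
    sig = A @ st.sigma_matrix() @ A.T
    s2 = A @ st.sigma2_matrix() @ A.T
    eps1 = A @ st.eps1  # linear fluctuation map: eliminated species follow exactly
    ids = st.system.network.species_ids()

    base = lna_measures(X, sig, om, species=ids, mean_floor=mean_floor)
    kept = [ids.index(sid) for sid in base.species]
    c_fac = np.full(len(kept), np.nan)
    f_fac = np.full(len(kept), np.nan)
    for out_i, i in enumerate(kept):
        if sig[i, i] <= 0:
            base.skipped.append(ids[i] + " (zero LNA variance)")
            continue
        var_part = (s2[i, i] - eps1[i] ** 2) / sig[i, i]
        mean_part = eps1[i] / X[i]
        c_fac[out_i] = 0.5 * var_part - 0.5 * mean_part
        f_fac[out_i] = var_part - mean_part
    base.correction_c = c_fac
    base.correction_f = f_fac
    base.cv_ios = base.cv_lna * (1.0 + c_fac / om)
    base.fano_ios = base.fano_lna * (1.0 + f_fac / om)
    # EMRE-order molecule-number means for reference
    mean_emre, cov_ios = moments(st, omega=om, order="ios")
    base.mean_molecules = om * np.array([mean_emre[i] for i in kept])
    base.variance_molecules = om ** 2 * np.array([cov_ios[i, i] for i in kept])
    return base
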