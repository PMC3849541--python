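"""Steady-state parameter scans of noise measures.

A scan evaluates the expansion (and optionally time-averaged SSA
statistics) over a list of parameter values — e.g. the sRNA/mRNA
transcription ratio alpha, the transcription rate k0, the protein-DNA
association rate k3, the gene copy number or the system size — and
returns one tidy table row per (parameter value, species, order).

The expansion solve at each point is seeded from the previous point's
fixed point (simple continuation), which is faster and keeps the scan on
one deterministic branch.  Points where the reduced rate equations are
not monostable are flagged and skipped, not dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .netmodel import NetworkError, ReactionNetwork
from .noise import MEAN_FLOOR, ios_measures, lna_measures
from .sse import MonostabilityError, SSEConfig, SSESystem, moments, sse_steady_state
from .ssa import stationary_stats, _spawn_seeds

__all__ = ["ScanSpec", "steady_state_scan", "ssa_scan", "repressed_fraction"]


@dataclass
class ScanSpec:
    """Declarative description of a 1-D steady-state scan.

    ``builder`` maps one parameter value to a ReactionNetwork;
    ``parameter`` is the scanned name (recorded in the output);
    ``orders`` selects expansion orders from {"re","lna","emre","ios"} and
    may include "ssa".  Per-point SSA settings apply when "ssa" is listed.
    """

    builder: Callable[[float], ReactionNetwork]
    parameter: str
    values: list[float]
    orders: tuple[str, ...] = ("lna", "ios")
    t_end: float = 1000.0
    burn_in: float = 100.0
    seed: int = 0
    covariates: Callable[[ReactionNetwork, np.ndarray], dict] | None = None

    def __post_init__(self):
        vals = list(self.values)
        if not vals:
            raise NetworkError("scan needs a nonempty value list")
        if not all(np.isfinite(vals)):
            raise NetworkError("scan values must be finite")
        self.values = vals


def steady_state_scan(spec: ScanSpec, config: SSEConfig | None = None) -> pd.DataFrame:
    """Expansion-based scan; columns:
    value, species, order, mean, variance, cv, fano, flag [+ covariates].
    """
    sse_orders = [o for o in spec.orders if o != "ssa"]
    need = "ios" if "ios" in sse_orders or "emre" in sse_orders else (
        "lna" if "lna" in sse_orders else "re")
    rows = []
    y_prev = None
    for val in spec.values:
        try:
            net = spec.builder(val)
        except Exception as exc:
            raise NetworkError(f"model builder failed at {spec.parameter}={val!r}: {exc}")
        try:
            st = sse_steady_state(net, order=need, config=config, y0=y_prev)
            y_prev = st.X
        except MonostabilityError as exc:
            y_prev = None
            for order in sse_orders:
                rows.append({"value": val, "species": None, "order": order,
                             "mean": np.nan, "variance": np.nan, "cv": np.nan,
                             "fano": np.nan, "flag": f"monostability: {exc}"})
            continue
        om = net.omega
        X_full, _ = moments(st, order="re")
        cov = dict(spec.covariates(net, X_full)) if spec.covariates else {}
        summaries = {}
        if need in ("lna", "ios"):
            summaries["lna"] = lna_measures(st)
        if need == "ios":
            summaries["ios"] = ios_measures(st)
        mean_by_order = {}
        for order in sse_orders:
            mean_c, cov_c = moments(st, order=order)
            mean_by_order[order] = (mean_c, cov_c)
        for order in sse_orders:
            mean_c, cov_c = mean_by_order[order]
            for i, sid in enumerate(net.species_ids()):
                if mean_c[i] <= MEAN_FLOOR:
                    continue
                mean_n = om * mean_c[i]
                var_n = om ** 2 * cov_c[i, i]
                if order in ("lna", "ios") and order in summaries:
                    summ = summaries[order]
                    if sid in summ.species:
                        cvv = summ.get(sid, "cv", order)
                        fan = summ.get(sid, "fano", order)
                    else:
                        cvv = fan = np.nan
                else:
                    cvv = np.sqrt(max(var_n, 0.0)) / mean_n if var_n > 0 else 0.0
                    fan = var_n / mean_n
                rows.append({"value": val, "species": sid, "order": order,
                             "mean": mean_n, "variance": var_n, "cv": cvv,
                             "fano": fan, "flag": "", **cov})
    return pd.DataFrame(rows)


def ssa_scan(spec: ScanSpec, config: SSEConfig | None = None) -> pd.DataFrame:
    """Time-averaged SSA scan with reproducible per-point seeds."""
    seeds = _spawn_seeds(spec.seed, len(spec.values))
    rows = []
    for val, sd in zip(spec.values, seeds):
        net = spec.builder(val)
        stats = stationary_stats(net, t_end=spec.t_end, burn_in=spec.burn_in,
                                 seed=int(sd))
        om = net.omega
        X_full, _ = (None, None)
        cov = {}
        if spec.covariates:
            try:
                st = sse_steady_state(net, order="re", config=config)
                X_full, _ = moments(st, order="re")
                cov = dict(spec.covariates(net, X_full))
            except MonostabilityError:
                cov = {}
        flag = "" if stats.converged else "not converged"
        for i, sid in enumerate(net.species_ids()):
            if stats.mean[i] <= 0:
                continue
            rows.append({"value": val, "species": sid, "order": "ssa",
                         "mean": stats.mean[i], "variance": stats.variance[i],
                         "cv": float(stats.cv()[i]), "fano": float(stats.fano()[i]),
                         "se_mean": stats.se_mean[i], "flag": flag, **cov})
    return pd.DataFrame(rows)


def repressed_fraction(network: ReactionNetwork, X_star,
                       promoter_ids=("G", "GPs", "GPs2")) -> float:
    """Average fraction of protein-bound (repressed) promoter states.

    ([GPs] + [GPs2]) / ([G] + [GPs] + [GPs2]) evaluated at the supplied
    mean concentrations (any expansion order's means may be passed).
    """
    X_star = np.asarray(X_star, dtype=float)
    try:
        idx = [network.species_index(sid) for sid in promoter_ids]
    except NetworkError:
        raise NetworkError(
            f"model does not expose promoter species {promoter_ids}") from None
    free, bound = X_star[idx[0]], X_star[idx[1]] + X_star[idx[2]]
    return float(bound / (free + bound))
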