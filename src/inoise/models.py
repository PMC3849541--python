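"""Benchmark and validation reaction networks.

Two gene-regulation case studies with literature parameter values:

* :func:`srna_model` — gene expression with enzymatic (nonlinear) protein
  degradation, post-transcriptionally regulated by a small RNA that binds
  its target mRNA and commits both to degradation.  The transcription-rate
  ratio ``alpha`` (sRNA over mRNA) plays the role of a stress level: the
  crossover ``alpha = 1`` has equal sRNA and mRNA transcription.
* :func:`autoreg_model` — transcription/translation with negative
  autoregulation through a phosphorylation cycle: the phosphorylated
  protein represses its own promoter at two operator sites, and both
  protein forms are degraded enzymatically (14 species, 20 irreversible
  reactions; 5 conservation laws leave 9 independent species).

Plus small validation models with closed-form or brute-force-checkable
answers: birth-death, the linear two-stage gene expression model,
an enzymatic degradation cycle parameterised by the free-enzyme fraction
delta, and a dimerisation model (the smallest network with a nonlinear
propensity).

Quantities not fixed by the published tables (compartment volumes, the
enzyme/kinase/phosphatase/protease pool totals and the catalytic rates of
the phosphorylation cycle) are explicit keyword arguments; the defaults
are documented and were chosen so the models sit in the regimes the noise
analysis targets (see docs/methods.md).  Tests that depend on them assert
qualitative shape, not specific coordinates.
"""

from __future__ import annotations

from .netmodel import ReactionNetwork, Species, build_network

__all__ = [
    "srna_model", "autoreg_model", "validation_model", "birth_death",
    "linear_gene", "enzyme_cycle", "dimerization",
    "SRNA_PARAMS", "AUTOREG_PARAMS", "AUTOREG_OSC_OVERRIDES",
]

# Published rate constants for the sRNA model (concentrations in uM,
# time in min).  k0G is the transcription flux k0*[G] with the constant
# gene pool folded in.
SRNA_PARAMS = {
    "i": {"k0G": 0.024, "kdM": 0.2, "ks": 1.5, "km1": 2.0, "k2": 2.0,
          "k1": 400.0, "kdS": 0.2, "kR": 100.0},
    "ii": {"k0G": 0.0024, "kdM": 0.2, "ks": 1.5, "km1": 2.0, "k2": 2.0,
           "k1": 4000.0, "kdS": 0.2, "kR": 1000.0},
}

#: default enzyme totals (uM) per parameter set: sized so the enzymatic
#: degradation capacity exceeds the translation flux with a free-enzyme
#: reserve of ~10%, which puts the unregulated protein level near 60
#: copies for set (i) and near 6 for set (ii) at the default volume
SRNA_ENZYME_TOTAL = {"i": 0.1, "ii": 0.01}

#: default system size for the sRNA model, molecules per uM
#: (a bacterial-scale compartment of ~1.1 fl)
SRNA_OMEGA = 667.0


def srna_model(set_tag: str = "i", alpha: float = 1.0,
               omega: float = SRNA_OMEGA,
               enzyme_total: float | None = None) -> ReactionNetwork:
    """Gene expression with enzymatic degradation and sRNA control.

    Species: M (mRNA), P (protein), E (free degradation enzyme),
    C (enzyme-protein complex), S (sRNA).  The gene pools are constant and
    folded into the zeroth-order transcription rates k0*[G] and
    alpha*k0*[G].
    """
    if set_tag not in SRNA_PARAMS:
        raise ValueError(f"unknown parameter set {set_tag!r}; use 'i' or 'ii'")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = SRNA_PARAMS[set_tag]
    et = SRNA_ENZYME_TOTAL[set_tag] if enzyme_total is None else enzyme_total
    if et <= 0:
        raise ValueError("enzyme_total must be > 0")
    params = dict(p, alpha=alpha, k0S=alpha * p["k0G"], enzyme_total=et)
    species = [
        Species("M", "mRNA", 0.0),
        Species("P", "protein", 0.0),
        Species("E", "degradation enzyme", et),
        Species("C", "enzyme-protein complex", 0.0),
        Species("S", "small RNA", 0.0),
    ]
    rxns = [
        ({}, {"M": 1}, p["k0G"], "transcription"),
        ({"M": 1}, {}, p["kdM"], "mrna_decay"),
        ({"M": 1}, {"M": 1, "P": 1}, p["ks"], "translation"),
        ({"P": 1, "E": 1}, {"C": 1}, p["k1"], "enzyme_binding"),
        ({"C": 1}, {"P": 1, "E": 1}, p["km1"], "enzyme_binding_rev"),
        ({"C": 1}, {"E": 1}, p["k2"], "protein_degradation"),
        ({}, {"S": 1}, alpha * p["k0G"], "srna_transcription"),
        ({"S": 1}, {}, p["kdS"], "srna_decay"),
        ({"S": 1, "M": 1}, {}, p["kR"], "srna_mrna_removal"),
    ]
    return build_network(species, rxns, omega=omega, parameters=params,
                         name=f"srna_set_{set_tag}",
                         concentration_unit="uM", time_unit="min")


# Published rate constants for the negative-autoregulation model
# (concentrations in nM, time in h).  k0 and k3 are recorded as products
# with the system size factor: k0 = flux0 * omega_tilde / n_genes (so the
# free-gene transcription flux is flux0 for a single gene at concentration
# 1/omega_tilde) and k3 = 0.5 * omega_tilde.
AUTOREG_PARAMS = {
    "flux0": 50.0,        # nM/h transcription flux scale ("k0 = 50 Omega~ (nM)")
    "ks": 50.0, "kdM": 5.0, "kdp": 0.5,
    "k1": 0.5, "km1": 1.0,            # kinase binding, (nM h)^-1 / h^-1
    "k2": 0.5, "km2": 1.0,            # phosphatase binding
    "k3_factor": 0.5,                 # "k3 = 0.5 Omega~" -> k3 = 0.5*omega_tilde
    "km3": 450.0,
    "k4_over_k3": 50.0, "km4": 450.0,
    "k5": 0.25, "km5": 0.5, "kp5": 0.5,
    "k6": 5.0, "km6": 5.0, "kp6": 10.0,
    "omega_tilde": 450.0,             # molecules per nM
}

#: oscillatory variant: a 50 fl compartment (omega_tilde = 30 /nM) and a
#: 60-fold larger transcription flux scale (3e3 nM/h per gene, shared
#: across the gene pool) -- the regime showing noise-induced oscillations
AUTOREG_OSC_OVERRIDES = {"omega_tilde": 30.0, "flux0": 3000.0}

#: default pool totals in nM per variant (unpublished; see
#: docs/methods.md): kinase/phosphatase pools of tens of nM and protease
#: pools sized so the enzymatic degradation capacity comfortably exceeds
#: the translation flux.  The oscillatory variant carries 60x the flux and
#: proportionally larger pools, with extra protease headroom so the
#: degradation machinery never saturates for epochs long compared to the
#: oscillation period.
AUTOREG_POOLS = {
    "reference": {"K": 10.0, "R": 10.0, "E": 100.0, "D": 10.0},
    "oscillatory": {"K": 600.0, "R": 600.0, "E": 12000.0, "D": 600.0},
}

#: catalytic rates of the phosphorylation cycle (unpublished), h^-1
AUTOREG_KCAT = {"kp1": 10.0, "kp2": 10.0}


def autoreg_model(n_genes: int = 1, variant: str = "reference",
                  pool_totals: dict | None = None, k3: float | None = None,
                  flux0: float | None = None,
                  kp1: float | None = None, kp2: float | None = None) -> ReactionNetwork:
    """Negative autoregulation through a phosphorylation cycle.

    ``variant`` is "reference" (omega_tilde = 450 /nM, a ~0.75 fl
    bacterial-scale compartment) or "oscillatory" (omega_tilde = 30 /nM,
    i.e. a 50 fl yeast-scale volume, with the larger transcription flux).
    The transcription rate is scaled by 1/n_genes so the deterministic
    steady state is independent of the gene copy number.
    ``k3`` overrides the protein-DNA association rate (the feedback
    strength dial); ``flux0`` overrides the transcription flux scale in
    nM/h (the k0 dial).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if variant not in ("reference", "oscillatory"):
        raise ValueError(
            f"unknown variant {variant!r}; use 'reference' or 'oscillatory'")
    p = dict(AUTOREG_PARAMS)
    if variant == "oscillatory":
        p.update(AUTOREG_OSC_OVERRIDES)
    if flux0 is not None:
        p["flux0"] = flux0
    om = p["omega_tilde"]
    pools = dict(AUTOREG_POOLS[variant])
    pools.update(pool_totals or {})
    k0 = p["flux0"] * om / n_genes          # h^-1
    k3v = p["k3_factor"] * om if k3 is None else k3
    k4v = p["k4_over_k3"] * k3v
    kp1v = AUTOREG_KCAT["kp1"] if kp1 is None else kp1
    kp2v = AUTOREG_KCAT["kp2"] if kp2 is None else kp2
    gene_conc = n_genes / om

    species = [
        Species("G", "free gene", gene_conc),
        Species("GPs", "singly repressed gene", 0.0),
        Species("GPs2", "doubly repressed gene", 0.0),
        Species("M", "mRNA", 0.0),
        Species("P", "protein", 0.0),
        Species("Ps", "phosphorylated protein", 0.0),
        Species("K", "kinase", pools["K"]),
        Species("KP", "kinase-protein complex", 0.0),
        Species("R", "phosphatase", pools["R"]),
        Species("RPs", "phosphatase complex", 0.0),
        Species("E", "protease (P)", pools["E"]),
        Species("EP", "protease-P complex", 0.0),
        Species("D", "protease (Ps)", pools["D"]),
        Species("DPs", "protease-Ps complex", 0.0),
    ]
    rxns = [
        ({"G": 1}, {"G": 1, "M": 1}, k0, "transcription"),
        ({"M": 1}, {}, p["kdM"], "mrna_decay"),
        ({"M": 1}, {"M": 1, "P": 1}, p["ks"], "translation"),
        ({"P": 1}, {}, p["kdp"], "protein_dilution"),
        ({"K": 1, "P": 1}, {"KP": 1}, p["k1"], "kinase_binding"),
        ({"KP": 1}, {"K": 1, "P": 1}, p["km1"], "kinase_binding_rev"),
        ({"KP": 1}, {"K": 1, "Ps": 1}, kp1v, "phosphorylation"),
        ({"R": 1, "Ps": 1}, {"RPs": 1}, p["k2"], "phosphatase_binding"),
        ({"RPs": 1}, {"R": 1, "Ps": 1}, p["km2"], "phosphatase_binding_rev"),
        ({"RPs": 1}, {"R": 1, "P": 1}, kp2v, "dephosphorylation"),
        ({"Ps": 1, "G": 1}, {"GPs": 1}, k3v, "operator1_binding"),
        ({"GPs": 1}, {"Ps": 1, "G": 1}, p["km3"], "operator1_binding_rev"),
        ({"Ps": 1, "GPs": 1}, {"GPs2": 1}, k4v, "operator2_binding"),
        ({"GPs2": 1}, {"Ps": 1, "GPs": 1}, p["km4"], "operator2_binding_rev"),
        ({"P": 1, "E": 1}, {"EP": 1}, p["k5"], "proteaseE_binding"),
        ({"EP": 1}, {"P": 1, "E": 1}, p["km5"], "proteaseE_binding_rev"),
        ({"EP": 1}, {"E": 1}, p["kp5"], "P_degradation"),
        ({"Ps": 1, "D": 1}, {"DPs": 1}, p["k6"], "proteaseD_binding"),
        ({"DPs": 1}, {"Ps": 1, "D": 1}, p["km6"], "proteaseD_binding_rev"),
        ({"DPs": 1}, {"D": 1}, p["kp6"], "Ps_degradation"),
    ]
    params = dict(p, k0=k0, k3=k3v, k4=k4v, kp1=kp1v, kp2=kp2v,
                  n_genes=n_genes, **{f"{k}_total": v for k, v in pools.items()})
    return build_network(species, rxns, omega=om, parameters=params,
                         name=f"autoreg_{variant}_{n_genes}gene",
                         concentration_unit="nM", time_unit="h")


# ---------------------------------------------------------------------------
# validation models
# ---------------------------------------------------------------------------

def birth_death(k_in: float = 1.0, k_out: float = 1.0,
                omega: float = 1.0, x0: float = 0.0) -> ReactionNetwork:
    """Open birth-death process 0 -> X -> 0; stationary law is Poisson."""
    return build_network(
        [("X", x0)],
        [({}, {"X": 1}, k_in, "birth"), ({"X": 1}, {}, k_out, "death")],
        omega=omega, name="birth_death",
        parameters={"k_in": k_in, "k_out": k_out})


def linear_gene(k0: float = 1.0, ks: float = 5.0, kdM: float = 1.0,
                kdp: float = 0.2, omega: float = 1.0) -> ReactionNetwork:
    """Two-stage gene expression, all reactions first order.

    The expansion is exact here; the stationary protein Fano factor has the
    closed form 1 + ks/(kdM + kdp).
    """
    return build_network(
        [("M", 0.0), ("P", 0.0)],
        [({}, {"M": 1}, k0, "transcription"),
         ({"M": 1}, {}, kdM, "mrna_decay"),
         ({"M": 1}, {"M": 1, "P": 1}, ks, "translation"),
         ({"P": 1}, {}, kdp, "protein_decay")],
        omega=omega, name="linear_gene",
        parameters={"k0": k0, "ks": ks, "kdM": kdM, "kdp": kdp})


def enzyme_cycle(delta: float = 0.5, E_total: float = 1.0, k1: float = 10.0,
                 km1: float = 1.0, k2: float = 1.0,
                 omega: float = 50.0) -> ReactionNetwork:
    """Enzymatic degradation cycle 0 -> S, S + E <-> C -> E.

    ``delta`` is the stationary free-enzyme fraction [E]*/E_total: the
    substrate influx is set to k2 * E_total * (1 - delta), so delta -> 1 is
    the substrate-poor and delta -> 0 the saturated regime.  Initial
    concentrations sit at the deterministic fixed point.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    k_in = k2 * E_total * (1.0 - delta)
    S_star = (km1 + k2) * (1.0 - delta) / (k1 * delta)
    return build_network(
        [("S", S_star), ("E", delta * E_total), ("C", (1.0 - delta) * E_total)],
        [({}, {"S": 1}, k_in, "influx"),
         ({"S": 1, "E": 1}, {"C": 1}, k1, "binding"),
         ({"C": 1}, {"S": 1, "E": 1}, km1, "binding_rev"),
         ({"C": 1}, {"E": 1}, k2, "catalysis")],
        omega=omega, name="enzyme_cycle",
        parameters={"delta": delta, "E_total": E_total, "k1": k1,
                    "km1": km1, "k2": k2, "k_in": k_in})


def dimerization(k_in: float = 1.0, k_dim: float = 1.0,
                 omega: float = 10.0, x0: float = 0.0) -> ReactionNetwork:
    """Influx plus pair annihilation, 0 -> A, 2A -> 0.

    The smallest network with a combinatorial n(n-1) propensity; its
    brute-force stationary solution validates the finite-size corrections.
    """
    return build_network(
        [("A", x0)],
        [({}, {"A": 1}, k_in, "influx"), ({"A": 2}, {}, k_dim, "dimerization")],
        omega=omega, name="dimerization",
        parameters={"k_in": k_in, "k_dim": k_dim})


_FAMILIES = {
    "birth_death": birth_death,
    "linear_gene": linear_gene,
    "enzyme_cycle": enzyme_cycle,
    "dimerization": dimerization,
}


def validation_model(family: str, **params) -> ReactionNetwork:
    """Build a validation model by family name."""
    try:
        builder = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}") from None
    return builder(**params)
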