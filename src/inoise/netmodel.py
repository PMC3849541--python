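"""Reaction-network data model.

A :class:`ReactionNetwork` holds species, mass-action reactions and the
system size Omega (molecules per unit concentration), and is the object
every analysis method in this package consumes.  The module also provides

* statistical mass-action propensities (the combinatorial law of mass
  action on copy numbers),
* conservation analysis: an exact integer basis of the left null space of
  the stoichiometric matrix, and the affine reduction that eliminates the
  dependent species, and
* reading/writing a small SBML-shorthand style text dialect
  (see :func:`parse_sbmlsh`).

Copy numbers and concentrations are related by ``n = Omega * x`` with no
hidden Avogadro factors: Omega already carries the volume and the unit
conversion (e.g. a 50 fl compartment with concentrations in nM has
Omega close to 30 molecules/nM).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "Reduction",
    "NetworkError",
    "UnsupportedOrderError",
    "SbmlShSyntaxError",
    "build_network",
    "propensity",
    "propensities",
    "conservation_analysis",
    "parse_sbmlsh",
    "write_sbmlsh",
    "read_sbmlsh",
]


class NetworkError(ValueError):
    """Invalid network construction or use."""


class UnsupportedOrderError(NetworkError):
    """Reaction order above 2 — outside the scope of the expansion machinery."""


class SbmlShSyntaxError(NetworkError):
    """Malformed SBML-shorthand document; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Species:
    id: str
    name: str = ""
    initial_value: float = 0.0  # concentration in model units
    is_constant: bool = False

    def __post_init__(self):
        if not re.fullmatch(r"[A-Za-z_]\w*", self.id):
            raise NetworkError(f"species id {self.id!r} is not a valid symbol")
        if self.initial_value < 0:
            raise NetworkError(f"species {self.id}: initial value must be >= 0")


@dataclass
class Reaction:
    """A single irreversible mass-action reaction.

    ``reactant_stoich`` / ``product_stoich`` map species ids to nonnegative
    integer coefficients.  ``rate_constant`` has units
    concentration^(1-order) / time where order = sum of reactant
    coefficients.  A reversible reaction is stored as two Reaction objects.
    """

    reactant_stoich: dict[str, int]
    product_stoich: dict[str, int]
    rate_constant: float
    label: str = ""
    rate_param: str | None = None  # name of the parameter the constant came from
    propensity_expr: str | None = None  # custom (non-mass-action) propensity, SSA only

    def __post_init__(self):
        for d in (self.reactant_stoich, self.product_stoich):
            for sid, coef in list(d.items()):
                if int(coef) != coef or coef < 0:
                    raise NetworkError(
                        f"reaction {self.label!r}: stoichiometry of {sid} must be a "
                        f"nonnegative integer, got {coef}"
                    )
                if coef == 0:
                    del d[sid]
                else:
                    d[sid] = int(coef)
        if self.rate_constant < 0:
            raise NetworkError(f"reaction {self.label!r}: rate constant must be >= 0")
        if self.order > 2:
            raise UnsupportedOrderError(
                f"reaction {self.label!r} has order {self.order}; only orders 0-2 "
                "(at most bimolecular) are supported"
            )

    @property
    def order(self) -> int:
        return sum(self.reactant_stoich.values())

    def is_noop(self) -> bool:
        """Pure catalytic no-op: products identical to reactants."""
        return self.reactant_stoich == self.product_stoich


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    omega: float = 1.0  # molecules per unit concentration
    parameters: dict[str, float] = field(default_factory=dict)
    name: str = "model"
    concentration_unit: str = ""
    time_unit: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.species]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise NetworkError(f"duplicate species id(s): {sorted(dup)}")
        if self.omega <= 0:
            raise NetworkError("system size Omega must be > 0")
        self._index = {sid: i for i, sid in enumerate(ids)}
        for r in self.reactions:
            for sid in (*r.reactant_stoich, *r.product_stoich):
                if sid not in self._index:
                    raise NetworkError(
                        f"reaction {r.label!r} references unknown species {sid!r}"
                    )

    # -- basic views ----------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        try:
            return self._index[sid]
        except KeyError:
            raise NetworkError(f"unknown species {sid!r}") from None

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.species], dtype=float)

    def initial_copy_numbers(self, omega: float | None = None) -> np.ndarray:
        om = self.omega if omega is None else omega
        return np.rint(om * self.initial_concentrations()).astype(np.int64)

    def reactant_matrix(self) -> np.ndarray:
        """N x R integer matrix of reactant stoichiometries s_ij."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for sid, c in r.reactant_stoich.items():
                S[self._index[sid], j] = c
        return S

    def product_matrix(self) -> np.ndarray:
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for sid, c in r.product_stoich.items():
                S[self._index[sid], j] = c
        return S

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix S = products - reactants (N x R).

        Rows of constant species are zeroed: their copy number never changes.
        """
        S = self.product_matrix() - self.reactant_matrix()
        for i, s in enumerate(self.species):
            if s.is_constant:
                S[i, :] = 0
        return S

    def reaction_orders(self) -> np.ndarray:
        return np.array([r.order for r in self.reactions], dtype=np.int64)

    def has_custom_propensities(self) -> bool:
        return any(r.propensity_expr is not None for r in self.reactions)

    def with_omega(self, omega: float) -> "ReactionNetwork":
        return ReactionNetwork(
            species=[Species(s.id, s.name, s.initial_value, s.is_constant) for s in self.species],
            reactions=list(self.reactions),
            omega=omega,
            parameters=dict(self.parameters),
            name=self.name,
            concentration_unit=self.concentration_unit,
            time_unit=self.time_unit,
        )

    # -- export ---------------------------------------------------------
    def stoichiometry_csv(self) -> str:
        """CSV of the net stoichiometric matrix (species rows, reaction cols)."""
        S = self.stoichiometric_matrix()
        labels = [r.label or f"r{j}" for j, r in enumerate(self.reactions)]
        buf = io.StringIO()
        buf.write("species," + ",".join(labels) + "\n")
        for i, s in enumerate(self.species):
            buf.write(s.id + "," + ",".join(str(v) for v in S[i]) + "\n")
        return buf.getvalue()


def build_network(species_specs, reaction_specs, omega=1.0, parameters=None,
                  name="model", **units) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork`.

    ``species_specs``: iterable of Species, or tuples ``(id, initial_value)`` /
    ``(id, initial_value, is_constant)``.
    ``reaction_specs``: iterable of Reaction, or tuples
    ``(reactants, products, rate_constant[, label])`` where reactants and
    products are dicts of stoichiometries.
    """
    spec_list = []
    for s in species_specs:
        if isinstance(s, Species):
            spec_list.append(s)
        else:
            sid, x0, *rest = s
            spec_list.append(Species(sid, initial_value=x0, is_constant=bool(rest and rest[0])))
    rxn_list = []
    for r in reaction_specs:
        if isinstance(r, Reaction):
            rxn_list.append(r)
        else:
            reac, prod, k, *rest = r
            rxn_list.append(Reaction(dict(reac), dict(prod), k, label=rest[0] if rest else ""))
    return ReactionNetwork(spec_list, rxn_list, omega=omega,
                           parameters=dict(parameters or {}), name=name, **units)


# ---------------------------------------------------------------------------
# propensities
# ---------------------------------------------------------------------------

def propensity(network: ReactionNetwork, j: int, n, omega: float | None = None) -> float:
    """Statistical mass-action propensity a_j(n), events per unit time.

    a_j(n) = k_j * Omega * prod_i n_i (n_i - 1) ... (n_i - s_ij + 1) / Omega^{s_ij};
    zero whenever any reactant count is insufficient.
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise NetworkError("negative copy number")
    om = network.omega if omega is None else omega
    r = network.reactions[j]
    if r.propensity_expr is not None:
        return _eval_custom_propensity(network, r, n, om)
    a = r.rate_constant * om
    for sid, s in r.reactant_stoich.items():
        ni = float(n[network.species_index(sid)])
        if ni < s:
            return 0.0
        for m in range(s):
            a *= (ni - m)
        a /= om ** s
    return a


def propensities(network: ReactionNetwork, n, omega: float | None = None) -> np.ndarray:
    return np.array([propensity(network, j, n, omega) for j in range(network.n_reactions)])


def _eval_custom_propensity(network, reaction, n, omega):
    # custom expressions are written in terms of species concentrations and
    # parameter names; evaluated here at x = n / Omega and scaled by Omega
    subs = {sid: n[network.species_index(sid)] / omega for sid in network.species_ids()}
    subs.update(network.parameters)
    expr = sp.sympify(reaction.propensity_expr)
    return float(omega * expr.evalf(subs=subs))


# ---------------------------------------------------------------------------
# conservation analysis
# ---------------------------------------------------------------------------

@dataclass
class Reduction:
    """Exact affine elimination of conserved species.

    ``gamma`` is an L x N integer matrix of conservation laws with
    ``gamma @ S == 0`` exactly; ``totals`` are the conserved quantities
    evaluated from the initial concentrations.  ``independent_idx`` indexes
    the N - L retained dynamic species; each eliminated species is an affine
    function of the retained ones: x_full = A @ y + c.

    Constant species are treated like eliminated species with a fixed value.
    """

    network: ReactionNetwork
    gamma: np.ndarray           # L x N (all species), exact integers
    totals: np.ndarray          # L, concentration units
    independent_idx: np.ndarray  # indices into network.species
    dependent_idx: np.ndarray    # indices of species eliminated by a law
    A: np.ndarray               # N x (N-L-n_const) float: linear part of recovery
    c: np.ndarray               # N float: affine part of recovery

    @property
    def n_laws(self) -> int:
        return self.gamma.shape[0]

    @property
    def independent_ids(self) -> list[str]:
        return [self.network.species[i].id for i in self.independent_idx]

    @property
    def dependent_ids(self) -> list[str]:
        return [self.network.species[i].id for i in self.dependent_idx]

    @property
    def n_independent(self) -> int:
        return len(self.independent_idx)

    def recover(self, y: np.ndarray) -> np.ndarray:
        """Full concentration vector from independent concentrations y."""
        y = np.asarray(y, dtype=float)
        return self.A @ y + self.c if y.ndim == 1 else (self.A @ y.T).T + self.c

    def reduced_initial(self) -> np.ndarray:
        return self.network.initial_concentrations()[self.independent_idx]

    def with_totals(self, totals_by_law) -> "Reduction":
        """Copy with different conserved totals (array of length L)."""
        totals = np.asarray(totals_by_law, dtype=float)
        A, c = _recovery_map(self.network, self.gamma, totals,
                             self.independent_idx, self.dependent_idx)
        return Reduction(self.network, self.gamma, totals,
                         self.independent_idx, self.dependent_idx, A, c)

    def laws_csv(self) -> str:
        buf = io.StringIO()
        ids = self.network.species_ids()
        buf.write("law," + ",".join(ids) + ",total\n")
        for ell in range(self.n_laws):
            buf.write(f"L{ell}," + ",".join(str(int(v)) for v in self.gamma[ell])
                      + f",{self.totals[ell]:.17g}\n")
        return buf.getvalue()


def conservation_analysis(network: ReactionNetwork) -> Reduction:
    """Integer basis of the left null space of S and the induced reduction.

    The basis is computed exactly over the rationals and scaled to primitive
    integer vectors.  The species eliminated by each law is the last-indexed
    species appearing in it (ties resolved by reduced row echelon form with
    columns scanned from the last species to the first), which makes the
    reduction deterministic.
    """
    S = network.stoichiometric_matrix()
    N = network.n_species
    const_idx = [i for i, s in enumerate(network.species) if s.is_constant]
    dyn_idx = [i for i in range(N) if i not in const_idx]

    M = sp.Matrix(S[dyn_idx, :].tolist())
    null = M.T.nullspace()  # vectors v with v^T S_dyn = 0
    if null:
        G = sp.Matrix([list(v.T) for v in null])  # L0 x N_dyn
        # RREF with columns reversed so pivots fall on the last-indexed species
        Grev = G[:, ::-1]
        R, piv = Grev.rref()
        L = len(piv)
        rows = []
        dep_local = []
        for r_i in range(L):
            row = list(R.row(r_i))[::-1]  # back to original column order
            denom = sp.ilcm(*[sp.fraction(sp.nsimplify(v))[1] for v in row if v != 0])
            ints = [sp.Integer(v * denom) for v in row]
            g = sp.igcd(*[abs(v) for v in ints if v != 0])
            ints = [int(v // g) for v in ints]
            pivot_col = len(row) - 1 - piv[r_i]
            if ints[pivot_col] < 0:
                ints = [-v for v in ints]
            rows.append(ints)
            dep_local.append(pivot_col)
        gamma_dyn = np.array(rows, dtype=np.int64)
    else:
        gamma_dyn = np.zeros((0, len(dyn_idx)), dtype=np.int64)
        dep_local = []

    gamma = np.zeros((gamma_dyn.shape[0], N), dtype=np.int64)
    gamma[:, dyn_idx] = gamma_dyn
    assert np.all(gamma @ S == 0), "conservation basis failed exact check"

    dependent_idx = np.array([dyn_idx[i] for i in dep_local], dtype=np.int64)
    independent_idx = np.array(
        [i for i in dyn_idx if i not in set(dependent_idx)], dtype=np.int64)
    x0 = network.initial_concentrations()
    totals = gamma @ x0
    A, c = _recovery_map(network, gamma, totals, independent_idx, dependent_idx)
    return Reduction(network, gamma, totals, independent_idx, dependent_idx, A, c)


def _recovery_map(network, gamma, totals, independent_idx, dependent_idx):
    """Affine map x_full = A y + c recovering all species from independents."""
    N = network.n_species
    Nr = len(independent_idx)
    A = np.zeros((N, Nr))
    c = np.zeros(N)
    for col, i in enumerate(independent_idx):
        A[i, col] = 1.0
    for i, s in enumerate(network.species):
        if s.is_constant:
            c[i] = s.initial_value
    for ell, i_dep in enumerate(dependent_idx):
        d = gamma[ell, i_dep]
        c[i_dep] = totals[ell] / d
        for col, i in enumerate(independent_idx):
            if gamma[ell, i]:
                A[i_dep, col] = -gamma[ell, i] / d
        # laws are in RREF over the dependent columns, so no dependent
        # species appears in another law's row
    return A, c


# ---------------------------------------------------------------------------
# SBML-shorthand style dialect
# ---------------------------------------------------------------------------
#
# @model = name
#   concentration_unit = nM
#   time_unit = h
#   omega = 450
# @compartments
#   cell = 1
# @species
#   M = 0.5 "mRNA"
#   G = 0.1 constant
# @parameters
#   k0 = 22500
# @reactions
# @r = transcription "free-gene transcription"
#   G -> G + M
#   k0
# @r = binding
#   P + E <-> C
#   k1, kminus1
#
# A reversible equation line ("<->") requires two rate constants and expands
# to two irreversible reactions labelled <label> and <label>_rev.

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def parse_sbmlsh(text: str) -> ReactionNetwork:
    """Parse the SBML-shorthand dialect into a :class:`ReactionNetwork`."""
    name = "model"
    conc_unit = time_unit = ""
    omega = 1.0
    species: list[Species] = []
    parameters: dict[str, float] = {}
    reactions: list[Reaction] = []
    section = None
    have_reactions_section = False

    # reaction block under construction
    rlabel = None
    rname = ""
    requation = None
    rline = 0

    def flush_reaction(lineno):
        nonlocal rlabel, requation
        if rlabel is None:
            return
        if requation is None:
            raise SbmlShSyntaxError(f"reaction {rlabel!r} has no chemical equation", rline)
        reac, prod, rev, consts = requation
        for sid in (*reac, *prod):
            if sid not in {s.id for s in species}:
                raise SbmlShSyntaxError(
                    f"reaction {rlabel!r} uses undeclared species {sid!r}", rline)
        if rev and len(consts) != 2:
            raise SbmlShSyntaxError(
                f"reversible reaction {rlabel!r} needs two rate constants", rline)
        if not rev and len(consts) != 1:
            raise SbmlShSyntaxError(
                f"reaction {rlabel!r} needs exactly one rate constant", rline)
        vals = []
        for cname in consts:
            if re.fullmatch(_NUM, cname):
                vals.append((float(cname), None))
            elif cname in parameters:
                vals.append((parameters[cname], cname))
            else:
                raise SbmlShSyntaxError(
                    f"reaction {rlabel!r}: unknown rate parameter {cname!r}", rline)
        reactions.append(Reaction(dict(reac), dict(prod), vals[0][0],
                                  label=rlabel, rate_param=vals[0][1]))
        if rev:
            reactions.append(Reaction(dict(prod), dict(reac), vals[1][0],
                                      label=rlabel + "_rev", rate_param=vals[1][1]))
        rlabel = None
        requation = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            m = re.match(r"@(\w+)\s*(?:=\s*(\S+)\s*(?:\"([^\"]*)\")?)?$", line)
            if not m:
                raise SbmlShSyntaxError(f"malformed section header {line!r}", lineno)
            tag, val, title = m.groups()
            if tag == "model":
                section = "model"
                if val:
                    name = val
            elif tag in ("compartments", "species", "parameters", "reactions"):
                flush_reaction(lineno)
                section = tag
                if tag == "reactions":
                    have_reactions_section = True
            elif tag == "r":
                if section != "reactions":
                    raise SbmlShSyntaxError("@r block outside @reactions", lineno)
                flush_reaction(lineno)
                if not val:
                    raise SbmlShSyntaxError("reaction block needs a label (@r = label)", lineno)
                rlabel, rname, rline = val, title or "", lineno
            else:
                raise SbmlShSyntaxError(f"unknown section @{tag}", lineno)
            continue

        if section == "model":
            m = re.match(r"(\w+)\s*=\s*(\S+)$", line)
            if not m:
                raise SbmlShSyntaxError(f"malformed model attribute {line!r}", lineno)
            key, val = m.groups()
            if key == "concentration_unit":
                conc_unit = val
            elif key == "time_unit":
                time_unit = val
            elif key == "omega":
                omega = float(val)
            else:
                raise SbmlShSyntaxError(f"unknown model attribute {key!r}", lineno)
        elif section == "compartments":
            pass  # single well-mixed compartment; volume is carried by omega
        elif section == "species":
            m = re.match(rf"(\w+)\s*=\s*({_NUM})\s*(constant)?\s*(?:\"([^\"]*)\")?$", line)
            if not m:
                raise SbmlShSyntaxError(f"malformed species line {line!r}", lineno)
            sid, x0, const, sname = m.groups()
            species.append(Species(sid, name=sname or "", initial_value=float(x0),
                                   is_constant=bool(const)))
        elif section == "parameters":
            m = re.match(rf"(\w+)\s*=\s*({_NUM})$", line)
            if not m:
                raise SbmlShSyntaxError(f"malformed parameter line {line!r}", lineno)
            parameters[m.group(1)] = float(m.group(2))
        elif section == "reactions":
            if rlabel is None:
                raise SbmlShSyntaxError("reaction content outside an @r block", lineno)
            if requation is None:
                requation = _parse_equation(line, lineno)
            else:
                reac, prod, rev, consts = requation
                if consts:
                    raise SbmlShSyntaxError(
                        f"unexpected extra line in reaction {rlabel!r}", lineno)
                consts = [c.strip() for c in line.split(",")]
                requation = (reac, prod, rev, consts)
        else:
            raise SbmlShSyntaxError(f"content before any section: {line!r}", lineno)

    flush_reaction(-1)
    if not have_reactions_section:
        raise SbmlShSyntaxError("document has no @reactions section")
    return ReactionNetwork(species, reactions, omega=omega, parameters=parameters,
                           name=name, concentration_unit=conc_unit, time_unit=time_unit)


def _parse_equation(line: str, lineno: int):
    rev = "<->" in line
    arrow = "<->" if rev else "->"
    if arrow not in line:
        raise SbmlShSyntaxError(f"expected a chemical equation, got {line!r}", lineno)
    lhs, rhs = line.split(arrow)

    def side(expr):
        stoich: dict[str, int] = {}
        expr = expr.strip()
        if not expr:
            return stoich
        for term in expr.split("+"):
            term = term.strip()
            m = re.fullmatch(r"(?:(\d+)\s*\*?\s*)?([A-Za-z_]\w*)", term)
            if not m:
                raise SbmlShSyntaxError(f"malformed species term {term!r}", lineno)
            coef = int(m.group(1) or 1)
            stoich[m.group(2)] = stoich.get(m.group(2), 0) + coef
        return stoich

    return side(lhs), side(rhs), rev, []


def write_sbmlsh(network: ReactionNetwork) -> str:
    """Serialize a network to the SBML-shorthand dialect.

    ``parse_sbmlsh(write_sbmlsh(net))`` reproduces ``net`` field by field.
    Pairs of reactions labelled ``x`` / ``x_rev`` with mirrored equations are
    recombined into a single reversible block.
    """
    out = io.StringIO()
    out.write(f"@model = {network.name}\n")
    if network.concentration_unit:
        out.write(f"  concentration_unit = {network.concentration_unit}\n")
    if network.time_unit:
        out.write(f"  time_unit = {network.time_unit}\n")
    out.write(f"  omega = {network.omega:.17g}\n")
    out.write("@compartments\n  cell = 1\n")
    out.write("@species\n")
    for s in network.species:
        line = f"  {s.id} = {s.initial_value:.17g}"
        if s.is_constant:
            line += " constant"
        if s.name:
            line += f' "{s.name}"'
        out.write(line + "\n")
    if network.parameters:
        out.write("@parameters\n")
        for k, v in network.parameters.items():
            out.write(f"  {k} = {v:.17g}\n")
    out.write("@reactions\n")

    def eqside(stoich):
        return " + ".join((f"{c} " if c > 1 else "") + sid for sid, c in stoich.items())

    def rate(r):
        return r.rate_param if r.rate_param is not None else f"{r.rate_constant:.17g}"

    skip = set()
    rxns = network.reactions
    for j, r in enumerate(rxns):
        if j in skip:
            continue
        partner = None
        for jj in range(j + 1, len(rxns)):
            rr = rxns[jj]
            if (rr.label == r.label + "_rev" and rr.reactant_stoich == r.product_stoich
                    and rr.product_stoich == r.reactant_stoich and jj not in skip):
                partner = jj
                break
        out.write(f"@r = {r.label or f'r{j}'}\n")
        if partner is not None:
            skip.add(partner)
            out.write(f"  {eqside(r.reactant_stoich)} <-> {eqside(r.product_stoich)}\n")
            out.write(f"  {rate(r)}, {rate(rxns[partner])}\n")
        else:
            out.write(f"  {eqside(r.reactant_stoich)} -> {eqside(r.product_stoich)}\n")
            out.write(f"  {rate(r)}\n")
    return out.getvalue()


def read_sbmlsh(path) -> ReactionNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_sbmlsh(fh.read())
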