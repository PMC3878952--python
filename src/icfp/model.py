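"""The carbon-flux-path mixed-integer model.

A carbon flux path from a source metabolite alpha to a target beta is a
simple directed path over carbon-exchange arcs that the whole network
can sustain at steady state.  The MILP has three blocks of variables:

* ``u_ij``  (binary)      - arc (i -> j) is on the path.  Variables are
  created only for ordered metabolite pairs covered by at least one
  carbon-exchange arc; the arc-support constraint forces all others to
  zero anyway, so pruning them shrinks the model with no semantic
  change.  Self-pairs (i = j) are excluded.
* ``z_r``   (binary)      - reaction r is active (carries flux).
* ``v_r``   (continuous)  - flux of r, with 0 or 1 <= v_r <= N.

Constraint families (tags used in the registry, LP export and the
independent checker):

=========  ==========================================================
``deg_src``    one arc leaves alpha and one enters beta; none enter
               alpha or leave beta (the latter via variable bounds)
``deg_bal``    arcs entering k equal arcs leaving k (k != alpha, beta)
``visit``      each metabolite entered at most once (simple path)
``mass``       steady state for every internal metabolite
``export``     external non-medium metabolites: net production >= 0
``link``       z_r <= v_r <= N z_r  (semicontinuous flux)
``rev``        a reaction and its reverse are never both active
``arc_sup``    a used arc is witnessed by an active reaction with a
               matching carbon-exchange triple
=========  ==========================================================

Medium metabolites carry no balance constraint at all (they may be
freely consumed and produced).  Source and target receive their usual
class-based constraint; they get no special exemption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

# big-M models amplify solver feasibility slack into visible flux drift;
# run HiGHS tighter than its defaults so solutions re-verify at 1e-6
_HIGHS_TOLERANCES = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
    "mip_feasibility_tolerance": 1e-9,
}

from .expression import ReactionClassification
from .network import MetabolicNetwork

__all__ = [
    "PathQuery",
    "CfpModel",
    "PathSolution",
    "NoPathError",
    "SolverError",
    "build_cfp_model",
    "check_solution",
]

_EQ_TAGS = {
    "deg_src": "eq1-2",
    "deg_bal": "eq3",
    "visit": "eq4",
    "mass": "eq5",
    "export": "eq6",
    "link": "eq7",
    "rev": "eq8",
    "arc_sup": "eq9",
}


class NoPathError(RuntimeError):
    """No carbon flux path exists for the query."""


class SolverError(RuntimeError):
    """The MILP solver failed to prove optimality."""


@dataclass
class PathQuery:
    """A source -> target enumeration request.

    ``big_m`` is the flux upper bound N linking flux to activity; the
    minimum non-zero flux is fixed at 1.  ``stage_tolerance`` is the
    relative slack used when carrying a stage optimum into the next
    stage.
    """

    source: str
    target: str
    k: int = 1
    big_m: float = 1000.0
    flux_floor: float = 1.0
    stage_tolerance: float = 1e-6
    time_limit: float | None = None
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")
        if self.k < 1:
            raise ValueError("number of paths K must be >= 1")
        if not self.big_m > self.flux_floor > 0:
            raise ValueError("need big_m > flux_floor > 0")


@dataclass
class PathSolution:
    """One enumerated carbon flux path with its balancing flux scenario."""

    rank: int
    nodes: list[str]
    arcs: list[tuple[str, str]]
    active_reactions: set[str]
    fluxes: dict[str, float]
    staged_objective: tuple[float, float, int]  # (V1, V2, length)

    @property
    def v1(self) -> float:
        return self.staged_objective[0]

    @property
    def v2(self) -> float:
        return self.staged_objective[1]

    @property
    def length(self) -> int:
        return self.staged_objective[2]


@dataclass
class CfpModel:
    """Solver-ready MILP over (u, z, v) with a tagged constraint registry."""

    net: MetabolicNetwork
    query: PathQuery
    classification: ReactionClassification
    u_pairs: list[tuple[str, str]]
    rxn_ids: list[str]
    rows: list[tuple[str, dict[int, float], float, float]] = field(
        default_factory=list
    )  # (tag, {col: coeff}, lb, ub)
    extra_rows: list[tuple[str, dict[int, float], float, float]] = field(
        default_factory=list
    )  # stage-fixing and elimination cuts, accumulated across solves

    def __post_init__(self) -> None:
        self.n_u = len(self.u_pairs)
        self.n_r = len(self.rxn_ids)
        self.u_index = {p: i for i, p in enumerate(self.u_pairs)}
        self.z_index = {r: self.n_u + i for i, r in enumerate(self.rxn_ids)}
        self.v_index = {r: self.n_u + self.n_r + i for i, r in enumerate(self.rxn_ids)}
        self.n_var = self.n_u + 2 * self.n_r

    # -- variable bounds ---------------------------------------------------
    def bounds(self) -> Bounds:
        lb = np.zeros(self.n_var)
        ub = np.concatenate(
            [np.ones(self.n_u + self.n_r), np.full(self.n_r, self.query.big_m)]
        )
        # no arc may enter the source or leave the target
        for (i, j), col in self.u_index.items():
            if j == self.query.source or i == self.query.target:
                ub[col] = 0.0
        return Bounds(lb, ub)

    def integrality(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(self.n_u + self.n_r), np.zeros(self.n_r)]
        )

    # -- objectives --------------------------------------------------------
    def flux_objective(self, reactions: Sequence[str]) -> np.ndarray:
        c = np.zeros(self.n_var)
        for r in reactions:
            c[self.v_index[r]] = 1.0
        return c

    def length_objective(self) -> np.ndarray:
        c = np.zeros(self.n_var)
        c[: self.n_u] = 1.0
        return c

    def reactions_in(self, state: str) -> list[str]:
        return [r for r in self.rxn_ids if self.classification[r] == state]

    # -- solving -----------------------------------------------------------
    def _constraint_matrix(self) -> LinearConstraint:
        rows = self.rows + self.extra_rows
        data, ri, ci = [], [], []
        lb = np.empty(len(rows))
        ub = np.empty(len(rows))
        for k, (_tag, coeffs, lo, hi) in enumerate(rows):
            lb[k], ub[k] = lo, hi
            for col, val in coeffs.items():
                ri.append(k)
                ci.append(col)
                data.append(val)
        mat = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(rows), self.n_var)
        )
        return LinearConstraint(mat, lb, ub)

    def solve(self, c: np.ndarray):
        """Minimize c.x over the model; returns the scipy result."""
        options: dict = {"mip_rel_gap": self.query.mip_gap, **_HIGHS_TOLERANCES}
        if self.query.time_limit is not None:
            options["time_limit"] = self.query.time_limit
        with warnings.catch_warnings():
            # the tolerance options are not in scipy's whitelist but are
            # forwarded to HiGHS verbatim
            warnings.simplefilter("ignore", RuntimeWarning)
            return milp(
                c=c,
                constraints=[self._constraint_matrix()],
                integrality=self.integrality(),
                bounds=self.bounds(),
                options=options,
            )

    def add_extra_row(
        self, tag: str, coeffs: dict[int, float], lb: float, ub: float
    ) -> None:
        self.extra_rows.append((tag, coeffs, lb, ub))

    def pop_extra_rows(self, tag_prefix: str) -> None:
        self.extra_rows = [
            row for row in self.extra_rows if not row[0].startswith(tag_prefix)
        ]

    # -- debugging ---------------------------------------------------------
    def export_lp(self, path) -> None:
        """Write the model in LP-format text with tagged constraint names."""
        names = (
            [f"u__{i}__{j}" for i, j in self.u_pairs]
            + [f"z__{r}" for r in self.rxn_ids]
            + [f"v__{r}" for r in self.rxn_ids]
        )
        lines = ["Minimize", " obj: 0", "Subject To"]
        counters: dict[str, int] = {}
        for tag, coeffs, lo, hi in self.rows + self.extra_rows:
            base = _EQ_TAGS.get(tag, tag)
            counters[base] = counters.get(base, 0) + 1
            cname = f"{base}_{counters[base]}"
            expr = " + ".join(
                f"{val:g} {names[col]}" for col, val in sorted(coeffs.items())
            ).replace("+ -", "- ")
            if lo == hi:
                lines.append(f" {cname}: {expr} = {lo:g}")
            else:
                if lo != -np.inf:
                    lines.append(f" {cname}_lb: {expr} >= {lo:g}")
                if hi != np.inf:
                    lines.append(f" {cname}_ub: {expr} <= {hi:g}")
        bounds = self.bounds()
        lines.append("Bounds")
        for idx, name in enumerate(names):
            lines.append(f" {bounds.lb[idx]:g} <= {name} <= {bounds.ub[idx]:g}")
        lines.append("Binary")
        lines.extend(f" {n}" for n in names[: self.n_u + self.n_r])
        lines.append("End")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def build_cfp_model(
    net: MetabolicNetwork,
    query: PathQuery,
    classification: ReactionClassification,
) -> CfpModel:
    """Assemble the carbon-flux-path MILP for a split network.

    Raises :class:`NoPathError` early when the target is not reachable
    from the source in the carbon-arc graph (no MILP can then be
    feasible), and :class:`ValueError` for unknown endpoints or a
    classification not covering every reaction.
    """
    if not net.is_split:
        raise ValueError("network must be split to irreversible form first")
    for end in (query.source, query.target):
        if not net.has_metabolite(end):
            raise ValueError(f"query endpoint {end!r} not in network")
    missing = [r.id for r in net.reactions if r.id not in classification]
    if missing:
        raise ValueError(f"classification missing reactions: {missing[:5]}...")

    pairs = sorted(p for p in net.carbon_arcs.pairs() if p[0] != p[1])
    graph = nx.DiGraph(pairs)
    if (
        query.source not in graph
        or query.target not in graph
        or not nx.has_path(graph, query.source, query.target)
    ):
        raise NoPathError(
            f"{query.target!r} is not carbon-reachable from {query.source!r}"
        )

    rxn_ids = [r.id for r in net.reactions]
    model = CfpModel(
        net=net,
        query=query,
        classification=classification,
        u_pairs=pairs,
        rxn_ids=rxn_ids,
    )
    rows = model.rows
    uix, zix, vix = model.u_index, model.z_index, model.v_index

    out_pairs: dict[str, list[int]] = {}
    in_pairs: dict[str, list[int]] = {}
    for (i, j), col in uix.items():
        out_pairs.setdefault(i, []).append(col)
        in_pairs.setdefault(j, []).append(col)

    # one arc leaves the source, one arc enters the target
    rows.append(
        ("deg_src", {c: 1.0 for c in out_pairs.get(query.source, [])}, 1.0, 1.0)
    )
    rows.append(
        ("deg_src", {c: 1.0 for c in in_pairs.get(query.target, [])}, 1.0, 1.0)
    )
    # (arcs into the source / out of the target are fixed to 0 via bounds)

    # degree balance at intermediates, and the single-visit bound everywhere
    met_ids = [m.id for m in net.metabolites]
    for k in met_ids:
        if k not in (query.source, query.target):
            coeffs: dict[int, float] = {}
            for c in in_pairs.get(k, []):
                coeffs[c] = coeffs.get(c, 0.0) + 1.0
            for c in out_pairs.get(k, []):
                coeffs[c] = coeffs.get(c, 0.0) - 1.0
            if coeffs:
                rows.append(("deg_bal", coeffs, 0.0, 0.0))
        if in_pairs.get(k):
            rows.append(("visit", {c: 1.0 for c in in_pairs[k]}, -np.inf, 1.0))

    # steady state / net-production constraints on fluxes
    medium = net.medium_ids
    for m in net.metabolites:
        coeffs = {}
        for r in net.reactions:
            coeff = r.stoich.get(m.id)
            if coeff:
                coeffs[vix[r.id]] = coeffs.get(vix[r.id], 0.0) + coeff
        if not coeffs:
            continue
        if m.is_internal:
            rows.append(("mass", coeffs, 0.0, 0.0))
        elif m.id not in medium:
            rows.append(("export", coeffs, 0.0, np.inf))
        # medium metabolites: unconstrained

    # semicontinuous flux linking: floor <= v - floor*z + floor <= ... i.e.
    # v - floor*z >= 0 and v - N*z <= 0
    floor = query.flux_floor
    for r in rxn_ids:
        rows.append(("link", {vix[r]: 1.0, zix[r]: -floor}, 0.0, np.inf))
        rows.append(("link", {vix[r]: 1.0, zix[r]: -query.big_m}, -np.inf, 0.0))

    # a reaction and its reverse never both active
    for lam, mu in net.reverse_pairs:
        rows.append(("rev", {zix[lam]: 1.0, zix[mu]: 1.0}, -np.inf, 1.0))

    # every used arc is witnessed by an active carbon-exchanging reaction
    for (i, j), col in uix.items():
        witnesses = net.carbon_arcs.reactions_for_pair(i, j)
        coeffs = {zix[r]: 1.0 for r in witnesses}
        coeffs[col] = coeffs.get(col, 0.0) - 1.0
        rows.append(("arc_sup", coeffs, 0.0, np.inf))

    return model


# ---------------------------------------------------------------------------
# Independent verification
# ---------------------------------------------------------------------------

def check_solution(
    net: MetabolicNetwork,
    query: PathQuery,
    classification: ReactionClassification,
    sol: PathSolution,
    tol: float = 1e-6,
) -> list[str]:
    """Re-verify a path solution against every constraint family.

    Works purely from the solution's arcs and fluxes (activity is
    reconstructed from the fluxes), without touching the MILP.  Returns
    a list of violation messages, each tagged with the constraint
    family; an empty list means the solution is valid.
    """
    violations: list[str] = []
    arcs = list(sol.arcs)
    arc_set = set(arcs)
    if len(arc_set) != len(arcs):
        violations.append("Eq4: duplicate arcs in path")

    out_deg: dict[str, int] = {}
    in_deg: dict[str, int] = {}
    for i, j in arc_set:
        out_deg[i] = out_deg.get(i, 0) + 1
        in_deg[j] = in_deg.get(j, 0) + 1

    if out_deg.get(query.source, 0) != 1 or in_deg.get(query.target, 0) != 1:
        violations.append("Eq1: source/target degree not exactly one")
    if in_deg.get(query.source, 0) or out_deg.get(query.target, 0):
        violations.append("Eq2: arc enters the source or leaves the target")
    for k in set(out_deg) | set(in_deg):
        if k in (query.source, query.target):
            continue
        if in_deg.get(k, 0) != out_deg.get(k, 0):
            violations.append(f"Eq3: degree imbalance at {k}")
    for k, d in in_deg.items():
        if d > 1:
            violations.append(f"Eq4: metabolite {k} revisited")

    # walk from the source: the arcs must form one simple path to the target
    succ = {i: j for i, j in arc_set}
    walk = [query.source]
    seen = {query.source}
    node = query.source
    while node in succ:
        node = succ[node]
        if node in seen:
            violations.append("Eq4: cycle reachable from the source")
            break
        walk.append(node)
        seen.add(node)
    if walk[-1] != query.target:
        violations.append("Eq1: walking the arcs from the source misses the target")
    elif len(walk) - 1 != len(arc_set):
        violations.append("Eq3: arcs disconnected from the source path")
    if sol.nodes and walk != sol.nodes and walk[-1] == query.target:
        violations.append("path: recorded node sequence disagrees with the arcs")

    fluxes = {r.id: float(sol.fluxes.get(r.id, 0.0)) for r in net.reactions}
    active = set()
    for r, v in fluxes.items():
        if v < -tol:
            violations.append(f"Eq7: negative flux on {r}")
        elif v > tol:
            active.add(r)
            if v < query.flux_floor - tol:
                violations.append(f"Eq7: flux of {r} below the active floor ({v:g})")
            if v > query.big_m + tol:
                violations.append(f"Eq7: flux of {r} exceeds N ({v:g})")
    if active != sol.active_reactions:
        violations.append(
            "Eq7: recorded active set disagrees with fluxes "
            f"(recorded {sorted(sol.active_reactions)}, fluxes {sorted(active)})"
        )

    medium = net.medium_ids
    for m in net.metabolites:
        net_prod = sum(
            r.stoich.get(m.id, 0.0) * fluxes[r.id] for r in net.reactions
        )
        if m.is_internal:
            if abs(net_prod) > tol:
                violations.append(f"Eq5: internal {m.id} off balance ({net_prod:g})")
        elif m.id not in medium and net_prod < -tol:
            violations.append(f"Eq6: external {m.id} net consumed ({net_prod:g})")

    for lam, mu in net.reverse_pairs:
        if lam in active and mu in active:
            violations.append(f"Eq8: reverse pair ({lam}, {mu}) both active")

    for i, j in arc_set:
        witnesses = net.carbon_arcs.reactions_for_pair(i, j)
        if not witnesses & active:
            violations.append(f"Eq9: arc ({i}, {j}) has no active carbon witness")

    v1 = sum(fluxes[r] for r in fluxes if classification.get(r) == "L")
    v2 = sum(fluxes[r] for r in fluxes if classification.get(r) == "M")
    rv1, rv2, rlen = sol.staged_objective
    all_m = all(classification.get(r.id) == "M" for r in net.reactions)
    if abs(v1 - rv1) > 1e-4:
        violations.append(f"objective: V1 recomputes to {v1:g}, recorded {rv1:g}")
    if not all_m and abs(v2 - rv2) > 1e-4:
        # with M = R the flux stage is skipped and V2 is 0 by convention
        violations.append(f"objective: V2 recomputes to {v2:g}, recorded {rv2:g}")
    if rlen != len(arc_set):
        violations.append(
            f"objective: length recomputes to {len(arc_set)}, recorded {rlen}"
        )
    return violations
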