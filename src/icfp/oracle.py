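"""Brute-force reference implementation of ranked carbon flux paths.

Independent of the main solver in structure: instead of one MILP over
arc variables with elimination cuts, every simple source->target path
in the carbon-arc graph is enumerated explicitly (guarded to small
networks), and for each candidate path a small subproblem over
(reaction activity, flux) only decides whether the path can be balanced
and at what lowly/medium flux cost.  Survivors are sorted
lexicographically by (V1, V2, length).

The per-path subproblem is itself a tiny mixed-integer program rather
than a plain LP: the flux-activity link makes fluxes semicontinuous
(v in {0} union [1, N]), and a continuous relaxation could under-report
the balancing cost by running support reactions below the unit floor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .expression import ReactionClassification
from .model import _HIGHS_TOLERANCES
from .network import MetabolicNetwork

__all__ = ["OraclePath", "brute_force_icfp", "GUARD_MAX_METABOLITES"]

GUARD_MAX_METABOLITES = 12


@dataclass(frozen=True)
class OraclePath:
    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]
    v1: float
    v2: float
    length: int

    @property
    def staged_objective(self) -> tuple[float, float, int]:
        return (self.v1, self.v2, self.length)


def _path_subproblem(
    net: MetabolicNetwork,
    arcs: list[tuple[str, str]],
    classification: ReactionClassification,
    big_m: float,
    flux_floor: float,
    tol: float = 1e-6,
) -> tuple[float, float] | None:
    """Min L-flux then min M-flux with the path's arcs forced.

    Variables are one activity binary and one flux per reaction; all
    off-path reactions may carry flux freely subject to steady state,
    net production of non-medium externals, the flux-activity link and
    reverse-pair exclusion; each path arc needs an active witnessing
    reaction.  Returns (V1, V2) or None when the path cannot balance.
    """
    rxn_ids = [r.id for r in net.reactions]
    n = len(rxn_ids)
    zix = {r: i for i, r in enumerate(rxn_ids)}
    vix = {r: n + i for i, r in enumerate(rxn_ids)}

    rows_data: list[tuple[dict[int, float], float, float]] = []
    medium = net.medium_ids
    for m in net.metabolites:
        coeffs: dict[int, float] = {}
        for r in net.reactions:
            c = r.stoich.get(m.id)
            if c:
                coeffs[vix[r.id]] = coeffs.get(vix[r.id], 0.0) + c
        if not coeffs:
            continue
        if m.is_internal:
            rows_data.append((coeffs, 0.0, 0.0))
        elif m.id not in medium:
            rows_data.append((coeffs, 0.0, np.inf))
    for r in rxn_ids:
        rows_data.append(({vix[r]: 1.0, zix[r]: -flux_floor}, 0.0, np.inf))
        rows_data.append(({vix[r]: 1.0, zix[r]: -big_m}, -np.inf, 0.0))
    for lam, mu in net.reverse_pairs:
        rows_data.append(({zix[lam]: 1.0, zix[mu]: 1.0}, -np.inf, 1.0))
    for i, j in arcs:
        witnesses = net.carbon_arcs.reactions_for_pair(i, j)
        if not witnesses:
            return None
        rows_data.append(({zix[r]: 1.0 for r in witnesses}, 1.0, np.inf))

    def matrix(extra: list[tuple[dict[int, float], float, float]]):
        all_rows = rows_data + extra
        data, ri, ci = [], [], []
        lb = np.empty(len(all_rows))
        ub = np.empty(len(all_rows))
        for k, (coeffs, lo, hi) in enumerate(all_rows):
            lb[k], ub[k] = lo, hi
            for col, val in coeffs.items():
                ri.append(k)
                ci.append(col)
                data.append(val)
        return LinearConstraint(
            sparse.csr_matrix((data, (ri, ci)), shape=(len(all_rows), 2 * n)), lb, ub
        )

    bounds = Bounds(
        np.zeros(2 * n), np.concatenate([np.ones(n), np.full(n, big_m)])
    )
    integrality = np.concatenate([np.ones(n), np.zeros(n)])

    def solve(objective_rxns: list[str], extra):
        c = np.zeros(2 * n)
        for r in objective_rxns:
            c[vix[r]] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return milp(
                c=c,
                constraints=[matrix(extra)],
                integrality=integrality,
                bounds=bounds,
                options={"mip_rel_gap": 0.0, **_HIGHS_TOLERANCES},
            )

    low = [r for r in rxn_ids if classification[r] == "L"]
    medium_set = [r for r in rxn_ids if classification[r] == "M"]

    res1 = solve(low, [])
    if res1.status == 2:
        return None
    if res1.status != 0:
        raise RuntimeError(f"oracle stage-1 subproblem failed: {res1.message}")
    v1 = float(res1.fun)

    if not medium_set or len(medium_set) == n:
        # no discriminating expression information: flux stage skipped
        return v1, 0.0
    fix = []
    if low:
        fix.append(({vix[r]: 1.0 for r in low}, 0.0, v1 * (1 + tol) + tol))
    res2 = solve(medium_set, fix)
    if res2.status == 2:
        return None
    if res2.status != 0:
        raise RuntimeError(f"oracle stage-2 subproblem failed: {res2.message}")
    return v1, float(res2.fun)


def brute_force_icfp(
    net: MetabolicNetwork,
    classification: ReactionClassification,
    source: str,
    target: str,
    top_n: int = 3,
    big_m: float = 1000.0,
    flux_floor: float = 1.0,
) -> list[OraclePath]:
    """Enumerate and rank every balanceable simple carbon path.

    Refuses networks above :data:`GUARD_MAX_METABOLITES` metabolites
    (the enumeration is exponential).  Returns the *top_n* feasible
    paths sorted by (V1, V2, length), ties broken by node sequence for
    reproducibility; an empty list when no path balances.
    """
    if len(net.metabolites) > GUARD_MAX_METABOLITES:
        raise ValueError(
            f"network too large for exhaustive enumeration "
            f"({len(net.metabolites)} > {GUARD_MAX_METABOLITES} metabolites)"
        )
    if not net.is_split:
        raise ValueError("network must be split to irreversible form first")
    pairs = sorted(p for p in net.carbon_arcs.pairs() if p[0] != p[1])
    graph = nx.DiGraph(pairs)
    if source not in graph or target not in graph:
        return []
    results: list[OraclePath] = []
    for nodes in nx.all_simple_paths(graph, source, target):
        arcs = list(itertools.pairwise(nodes))
        staged = _path_subproblem(
            net, arcs, classification, big_m=big_m, flux_floor=flux_floor
        )
        if staged is None:
            continue
        v1, v2 = staged
        results.append(
            OraclePath(
                nodes=tuple(nodes),
                arcs=tuple(arcs),
                v1=round(v1, 9),
                v2=round(v2, 9),
                length=len(arcs),
            )
        )
    results.sort(key=lambda p: (p.v1, p.v2, p.length, p.nodes))
    return results[:top_n]
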