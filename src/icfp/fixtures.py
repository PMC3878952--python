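"""Synthetic inputs: the illustrative toy network, random stoichiometric
networks with a planted balanceable path, and synthetic expression
series with planted differential features.

Everything here is generated programmatically and reproducible by seed;
no external data is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionSeries, ReactionClassification
from .model import PathQuery
from .network import (
    CarbonArcTable,
    Metabolite,
    MetabolicNetwork,
    Reaction,
)
from .gpr import parse_gpr

__all__ = [
    "PlantedTruth",
    "illustrative_fixture",
    "random_network",
    "random_classification",
    "synthetic_expression",
]


@dataclass
class PlantedTruth:
    """Ground truth written down by a generator at generation time."""

    feature_states: dict[str, str] = field(default_factory=dict)
    planted_path: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# The 10-metabolite / 12-reaction illustrative network
# ---------------------------------------------------------------------------

def illustrative_fixture() -> tuple[MetabolicNetwork, ReactionClassification, PathQuery]:
    """A small network contrasting expression-blind and expression-aware
    path finding.

    Ten metabolites, twelve reactions, query A -> E, classification
    L = {9, 10, 11}, M = {1, 6, 7, 12}, H = {2, 3, 4, 5, 8}.  The
    stoichiometry is a reconstruction built to reproduce the published
    narrative (no canonical coefficients exist for it):

    * The length-minimal route A->B->C->E rides reactions 3, 5 and 8
      (all H), but reaction 5 throws off a byproduct X whose only
      disposal is the two lowly expressed steps 10 (X->Y) and 11 (Y->F),
      so balancing that backbone forces flux through L.
    * The alternative route A->B->C->D->E is carried by reactions 2
      (A + C -> B + D + Q, arcs A->B and C->D) and 4
      (B + D + P -> C + E, arcs B->C and D->E); its cofactor by-product
      Q and co-substrate P are regenerated by the medium-expressed pair
      6 (Q->F) and 7 (F->P) alone, so the whole scenario avoids L.

    A is the sole medium (carbon-input) metabolite; E and F are external
    products; 1 (F sink) and 12 (E sink) are decorative medium-expressed
    exchanges.  Both structural claims are asserted by the test suite
    with the brute-force oracle.
    """
    internal = ["B", "C", "D", "P", "Q", "X", "Y"]
    mets = (
        [Metabolite("A", "source", is_internal=False, in_medium=True)]
        + [Metabolite(m, m) for m in internal]
        + [
            Metabolite("E", "target", is_internal=False),
            Metabolite("F", "byproduct sink", is_internal=False),
        ]
    )
    reactions = [
        Reaction("R1", {"F": -1.0}),
        Reaction("R2", {"A": -1.0, "C": -1.0, "B": 1.0, "D": 1.0, "Q": 1.0}),
        Reaction("R3", {"A": -1.0, "B": 1.0}),
        Reaction("R4", {"B": -1.0, "D": -1.0, "P": -1.0, "C": 1.0, "E": 1.0}),
        Reaction("R5", {"B": -1.0, "C": 1.0, "X": 1.0}),
        Reaction("R6", {"Q": -1.0, "F": 1.0}),
        Reaction("R7", {"F": -1.0, "P": 1.0}),
        Reaction("R8", {"C": -1.0, "E": 1.0}),
        Reaction("R9", {"C": -1.0, "D": 1.0}),
        Reaction("R10", {"X": -1.0, "Y": 1.0}),
        Reaction("R11", {"Y": -1.0, "F": 1.0}),
        Reaction("R12", {"E": -1.0}),
    ]
    arcs = CarbonArcTable()
    for rxn, i, j in [
        ("R2", "A", "B"),
        ("R2", "C", "D"),
        ("R3", "A", "B"),
        ("R4", "B", "C"),
        ("R4", "D", "E"),
        ("R5", "B", "C"),
        ("R6", "Q", "F"),
        ("R7", "F", "P"),
        ("R8", "C", "E"),
        ("R9", "C", "D"),
        ("R10", "X", "Y"),
        ("R11", "Y", "F"),
    ]:
        arcs.add(i, j, rxn)
    net = MetabolicNetwork(metabolites=mets, reactions=reactions, carbon_arcs=arcs)
    classification = {
        "R1": "M",
        "R2": "H",
        "R3": "H",
        "R4": "H",
        "R5": "H",
        "R6": "M",
        "R7": "M",
        "R8": "H",
        "R9": "L",
        "R10": "L",
        "R11": "L",
        "R12": "M",
    }
    query = PathQuery(source="A", target="E", k=2)
    return net, classification, query


# ---------------------------------------------------------------------------
# Random networks with a planted balanceable path
# ---------------------------------------------------------------------------

_GENE_POOL = [f"g{i}" for i in range(1, 9)]


def random_network(
    n_mets: int = 8,
    n_rxns: int = 12,
    seed: int = 0,
    density: float = 0.5,
    reversible_fraction: float = 0.2,
) -> MetabolicNetwork:
    """A connected random stoichiometric network with a planted path.

    The first metabolite is the external medium source, the last the
    external target; a unimolecular chain source -> ... -> target with
    unit coefficients is always planted, so at least one balanceable
    carbon flux path exists by construction.  Remaining reactions draw
    1-2 substrates and 1-2 products with coefficients in {1, 2}; each
    substrate-product pair becomes a carbon arc with probability
    *density* (sign-consistent by construction); a *reversible_fraction*
    of the extra reactions is reversible; GPRs are random small Boolean
    rules over an eight-gene pool.  Fully reproducible by seed.
    """
    if n_mets < 3:
        raise ValueError("need at least 3 metabolites")
    rng = np.random.default_rng(seed)
    met_ids = [f"m{i}" for i in range(n_mets)]
    source, target = met_ids[0], met_ids[-1]
    mets = [Metabolite(source, is_internal=False, in_medium=True)]
    mets += [Metabolite(m) for m in met_ids[1:-1]]
    mets.append(Metabolite(target, is_internal=False))

    arcs = CarbonArcTable()
    reactions: list[Reaction] = []

    chain_len = min(3, n_mets - 1)
    chain = [source] + list(
        rng.choice(met_ids[1:-1], size=chain_len - 1, replace=False)
    ) + [target]
    for a, b in zip(chain, chain[1:]):
        rid = f"p{len(reactions)}"
        reactions.append(Reaction(rid, {a: -1.0, b: 1.0}, gpr=_random_gpr(rng)))
        arcs.add(a, b, rid)

    n_extra = max(0, n_rxns - len(reactions))
    for k in range(n_extra):
        while True:
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            chosen = rng.choice(met_ids, size=n_sub + n_prod, replace=False)
            subs, prods = list(chosen[:n_sub]), list(chosen[n_sub:])
            stoich = {m: -float(rng.integers(1, 3)) for m in subs}
            stoich.update({m: float(rng.integers(1, 3)) for m in prods})
            break
        rid = f"r{k}"
        reversible = bool(rng.random() < reversible_fraction)
        reactions.append(
            Reaction(rid, stoich, reversible=reversible, gpr=_random_gpr(rng))
        )
        for s in subs:
            for p in prods:
                if rng.random() < density:
                    arcs.add(s, p, rid)
    return MetabolicNetwork(metabolites=mets, reactions=reactions, carbon_arcs=arcs)


def _random_gpr(rng: np.random.Generator):
    form = rng.random()
    g = rng.choice(_GENE_POOL, size=2, replace=False)
    if form < 0.25:
        return None
    if form < 0.55:
        return parse_gpr(g[0])
    if form < 0.8:
        return parse_gpr(f"{g[0]} and {g[1]}")
    return parse_gpr(f"{g[0]} or {g[1]}")


def random_classification(
    net: MetabolicNetwork, seed: int = 0, p_h: float = 0.3, p_l: float = 0.3
) -> ReactionClassification:
    """Random H/M/L assignment; both members of a reverse pair share it."""
    rng = np.random.default_rng(seed)
    classification: ReactionClassification = {}
    for r in net.reactions:
        if r.id in classification:
            continue
        u = rng.random()
        state = "H" if u < p_h else ("L" if u < p_h + p_l else "M")
        classification[r.id] = state
        if r.reverse_partner is not None:
            classification[r.reverse_partner] = state
    return classification


# ---------------------------------------------------------------------------
# Synthetic expression series
# ---------------------------------------------------------------------------

def synthetic_expression(
    n_features: int = 500,
    conditions: np.ndarray | None = None,
    frac_up: float = 0.1,
    frac_down: float = 0.1,
    effect_log2: float = 2 * np.log2(1.5),
    noise_sd: float = 0.25,
    seed: int = 0,
    protein_fraction: float = 0.3,
) -> tuple[list[ExpressionSeries], PlantedTruth]:
    """Per-feature log2 series across conditions with planted trends.

    Emulates growth-rate-resolved expression profiling: differential
    features follow a linear log2 trend whose total change across the
    condition range is +-*effect_log2*; invariant features have slope
    zero; all values carry iid Gaussian noise.  A random
    *protein_fraction* of features additionally gets an independent
    protein-level series with the same planted trend, exercising the
    protein-over-gene merging rule.  Defaults mirror the study setup:
    eight growth-rate conditions (0.10-0.45 1/h), a planted change of
    twice the 1.5-fold test threshold, and 20% differential features.
    """
    if frac_up + frac_down > 1:
        raise ValueError("frac_up + frac_down must be <= 1")
    if conditions is None:
        conditions = np.linspace(0.10, 0.45, 8)
    conditions = np.asarray(conditions, dtype=float)
    rng = np.random.default_rng(seed)
    n_up = int(round(frac_up * n_features))
    n_down = int(round(frac_down * n_features))
    states = ["up"] * n_up + ["down"] * n_down
    states += ["invariant"] * (n_features - len(states))
    cond_range = float(conditions.max() - conditions.min())
    series: list[ExpressionSeries] = []
    truth = PlantedTruth()
    for idx, state in enumerate(states):
        fid = f"f{idx:04d}"
        truth.feature_states[fid] = state
        direction = {"up": 1.0, "down": -1.0, "invariant": 0.0}[state]
        slope = direction * effect_log2 / cond_range
        mean = slope * conditions
        series.append(
            ExpressionSeries(
                feature_id=fid,
                kind="gene",
                conditions=conditions,
                values=mean + rng.normal(0.0, noise_sd, size=len(conditions)),
            )
        )
        if rng.random() < protein_fraction:
            series.append(
                ExpressionSeries(
                    feature_id=fid,
                    kind="protein",
                    conditions=conditions,
                    values=mean + rng.normal(0.0, noise_sd, size=len(conditions)),
                )
            )
    return series, truth
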