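# icfp — expression-guided carbon flux paths

`icfp` finds ranked **carbon flux paths** in metabolic networks: simple
source → target routes over carbon-exchange arcs that the *whole*
network can sustain at steady state, with gene and protein expression
data steering the ranking. It is aimed at systems biologists who want
pathway hypotheses for a phenotype (e.g. overflow metabolism) that are
both stoichiometrically consistent and supported by expression data —
something classical graph path finding cannot deliver, because it
ignores the off-path reactions needed to balance a route.

## The model

A network has metabolites C (internal set I, external set E, medium
subset E_m), irreversible reactions R (reversible reactions are split
into forward/backward pairs B) with stoichiometry S_cr and GPR Boolean
rules, and carbon-exchange arcs d_ijr = 1 when reaction r actually
transfers carbon from substrate i to product j.

A path is encoded by binaries u_ij (arc on the path), z_r (reaction
active) and fluxes v_r ≥ 0 subject to:

* degree constraints making the u-arcs one simple path α → β;
* steady state Σ_r S_cr v_r = 0 for every c ∈ I, and Σ_r S_cr v_r ≥ 0
  for external metabolites outside the medium (producible, not
  consumable);
* semicontinuous flux z_r ≤ v_r ≤ N·z_r (minimum active flux 1, big-M
  N, default 1000);
* mutual exclusion z_λ + z_μ ≤ 1 for reverse pairs;
* arc support: every used arc needs an active reaction with a matching
  carbon-exchange triple.

Expression data partitions R into **H** (highly/over expressed), **L**
(lowly/down expressed) and **M** (the rest) via a TREAT-style
threshold test per feature (OLS of log2 expression on the condition
value; null hypothesis: the fitted change across the condition range
stays within a 1.5-fold threshold), protein-over-gene merging, FDR
control at 0.2, and ternary GPR evaluation (AND = min, OR = max over
up/invariant/down). A one-shot log2 fold-change route (cutoff 0.5850)
is also provided.

The objective is lexicographic, solved as three sequential MILPs:
minimize Σ_{r∈L} v_r (optimum V1), then Σ_{r∈M} v_r holding V1
(optimum V2), then path length Σ u_ij. Ranked enumeration adds, after
each solution, a cut forbidding its complete arc set and re-solves, so
staged tuples (V1, V2, length) are non-decreasing. Expression thus
*influences* the flux scenario without hard-constraining it.

MILPs are solved with HiGHS through `scipy.optimize.milp`. A
brute-force oracle (exhaustive simple-path enumeration plus per-path
subproblems) provides an independent cross-check on small networks.

## Worked example

The bundled 10-metabolite / 12-reaction toy network (query A → E,
L = {9,10,11}, M = {1,6,7,12}, H = {2,3,4,5,8}):

```python
from icfp import illustrative_fixture, find_paths
net, classification, query = illustrative_fixture()
solutions, report = find_paths(net, query, classification)
for p in report["paths"]:
    print(p["rank"], "->".join(p["nodes"]),
          f"V1={p['V1']:g} V2={p['V2']:g} len={p['length']}",
          {r: f"{i['state']}:{i['flux']:g}" for r, i in p["active"].items()})
```

prints

```
1 A->B->C->D->E V1=0 V2=2 len=4 {'R2': 'H:1', 'R4': 'H:1', 'R6': 'M:1', 'R7': 'M:1'}
2 A->B->C->E V1=2 V2=0 len=3 {'R10': 'L:1', 'R11': 'L:1', 'R3': 'H:1', 'R5': 'H:1', 'R8': 'H:1'}
```

The top-ranked path takes the *longer* backbone (4 arcs through the
highly expressed reactions 2 and 4) because it balances using only
medium-expressed reactions (6, 7): V1 = 0 means no flux through lowly
expressed reactions anywhere in the scenario. The graph-shortest route
(3 arcs, reactions 3/5/8, all H) is ranked second: balancing it forces
two units of flux through the lowly expressed reactions 10 and 11
(V1 = 2). An expression-blind run (`ignore_expression=True`) returns
exactly that shorter route — the difference is the point of the method.

The same pipeline is scriptable from the shell:

```bash
icfp simulate --kind toy --out toy
icfp pathfind --network toy --classification toy/classification.tsv \
    -a A -b E -k 2 --out run1        # writes paths.tsv / paths.json
icfp classify --network net/ --expression expression.tsv --out cls/
icfp oracle  --network toy --classification toy/classification.tsv -a A -b E
```

Network input is a three-file TSV dialect (`metabolites.tsv`,
`reactions.tsv`, `carbon_arcs.tsv`); SBML L3/fbc is accepted for the
network proper, with carbon arcs always supplied as the TSV side table.

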