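"""Metabolic network container and I/O.

The in-memory model mirrors what carbon-flux-path finding needs and
nothing more: metabolites partitioned into internal (mass balanced) and
external species, with external species optionally belonging to the
growth medium (freely exchangeable); reactions with signed stoichiometry
and GPR rules; and a side table of carbon-exchange arcs, the ordered
substrate->product pairs of a reaction between which carbon atoms are
actually transferred.  Compartments are not modelled separately - a
compartmentalised species is simply a distinct metabolite id
(e.g. ``acald_c``).

The authoritative on-disk format is a three-file tab-separated dialect
(``metabolites.tsv``, ``reactions.tsv``, ``carbon_arcs.tsv``); SBML
Level 3 / fbc import is provided as a convenience mapping (carbon arcs
have no SBML representation and always come from the TSV side file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .gpr import GprNode, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "CarbonArc",
    "CarbonArcTable",
    "MetabolicNetwork",
    "NetworkValidationError",
    "NetworkFormatError",
    "load_network",
    "write_network",
    "load_carbon_arcs",
    "split_reversible",
    "apply_medium",
]

REVERSE_SUFFIX = "__rev"


class NetworkValidationError(ValueError):
    """A structurally invalid network, arc table, or medium definition."""


class NetworkFormatError(ValueError):
    """A file that does not parse in the expected dialect."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_internal: bool = True
    in_medium: bool = False

    def __post_init__(self) -> None:
        if self.in_medium and self.is_internal:
            raise NetworkValidationError(
                f"medium metabolite {self.id!r} must be external"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: dict[str, float]
    reversible: bool = False
    gpr: GprNode | None = None
    reverse_partner: str | None = None

    def __post_init__(self) -> None:
        if not self.stoich:
            raise NetworkValidationError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoich.items() if c > 0]


@dataclass(frozen=True, order=True)
class CarbonArc:
    """One (substrate i, product j, reaction r) carbon-exchange triple."""

    substrate: str
    product: str
    reaction: str


@dataclass
class CarbonArcTable:
    entries: set[CarbonArc] = field(default_factory=set)

    def add(self, substrate: str, product: str, reaction: str) -> None:
        self.entries.add(CarbonArc(substrate, product, reaction))

    def pairs(self) -> set[tuple[str, str]]:
        """Ordered metabolite pairs covered by at least one arc."""
        return {(a.substrate, a.product) for a in self.entries}

    def reactions_for_pair(self, i: str, j: str) -> set[str]:
        return {a.reaction for a in self.entries if a.substrate == i and a.product == j}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(sorted(self.entries))


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    carbon_arcs: CarbonArcTable = field(default_factory=CarbonArcTable)

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        self.validate()

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_internal]

    @property
    def external_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_internal]

    @property
    def medium_ids(self) -> set[str]:
        return {m.id for m in self.metabolites if m.in_medium}

    @property
    def reverse_pairs(self) -> list[tuple[str, str]]:
        """Unordered (lambda, mu) reverse-of-each-other reaction pairs."""
        pairs = []
        for r in self.reactions:
            if r.reverse_partner is not None and r.id < r.reverse_partner:
                pairs.append((r.id, r.reverse_partner))
        return pairs

    @property
    def is_split(self) -> bool:
        return all(not r.reversible for r in self.reactions)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            seen: set[str] = set()
            dups = [m.id for m in self.metabolites if m.id in seen or seen.add(m.id)]
            raise NetworkValidationError(f"duplicate metabolite ids: {dups}")
        if len(self._rxn_index) != len(self.reactions):
            seen = set()
            dups = [r.id for r in self.reactions if r.id in seen or seen.add(r.id)]
            raise NetworkValidationError(f"duplicate reaction ids: {dups}")
        if not self.reactions:
            raise NetworkValidationError("network has no reactions")
        dangling = sorted(
            {
                m
                for r in self.reactions
                for m in r.stoich
                if m not in self._met_index
            }
        )
        if dangling:
            raise NetworkValidationError(
                f"reactions reference unknown metabolites: {dangling}"
            )
        validate_carbon_arcs(self.carbon_arcs, self)
        for lam, mu in self.reverse_pairs:
            a, b = self.reaction(lam), self.reaction(mu)
            if b.reverse_partner != a.id:
                raise NetworkValidationError(
                    f"reverse partner link {lam}<->{mu} is not mutual"
                )
            for met, coeff in a.stoich.items():
                if not math.isclose(b.stoich.get(met, 0.0), -coeff, abs_tol=1e-9):
                    raise NetworkValidationError(
                        f"stoichiometries of reverse pair ({lam}, {mu}) "
                        f"are not negations of each other at {met!r}"
                    )


def validate_carbon_arcs(table: CarbonArcTable, net: MetabolicNetwork) -> None:
    """Check every triple against the stoichiometric sign convention."""
    bad: list[str] = []
    for arc in table.entries:
        if arc.reaction not in net._rxn_index:
            bad.append(f"{arc}: unknown reaction")
            continue
        if arc.substrate == arc.product:
            bad.append(f"{arc}: substrate equals product")
            continue
        stoich = net._rxn_index[arc.reaction].stoich
        if arc.substrate not in net._met_index or arc.product not in net._met_index:
            bad.append(f"{arc}: unknown metabolite")
            continue
        if not stoich.get(arc.substrate, 0.0) < 0:
            bad.append(f"{arc}: substrate {arc.substrate!r} is not consumed")
        elif not stoich.get(arc.product, 0.0) > 0:
            bad.append(f"{arc}: product {arc.product!r} is not produced")
    if bad:
        raise NetworkValidationError(
            "invalid carbon-exchange arcs:\n  " + "\n  ".join(sorted(bad))
        )


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_MET_HEADER = ["id", "name", "internal", "in_medium"]
_RXN_HEADER = ["id", "reversible", "gpr", "stoichiometry"]
_ARC_HEADER = ["reaction", "substrate", "product"]


def _read_tsv(path: Path, header: list[str]) -> list[list[str]]:
    if not path.exists():
        raise NetworkFormatError(f"missing file: {path}")
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1:
                if [f.strip() for f in fields] != header:
                    raise NetworkFormatError(
                        f"{path}:1: expected header {header}, got {fields}"
                    )
                continue
            if len(fields) != len(header):
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            rows.append([f.strip() for f in fields])
    return rows


def _parse_flag(value: str, where: str) -> bool:
    if value not in ("0", "1"):
        raise NetworkFormatError(f"{where}: flag must be 0 or 1, got {value!r}")
    return value == "1"


def _parse_stoich(token_str: str, where: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for token in token_str.split(";"):
        token = token.strip()
        if not token:
            continue
        met, sep, coeff = token.rpartition(":")
        if not sep or not met:
            raise NetworkFormatError(f"{where}: malformed stoichiometry token {token!r}")
        try:
            value = float(coeff)
        except ValueError as exc:
            raise NetworkFormatError(
                f"{where}: non-numeric coefficient in {token!r}"
            ) from exc
        if value == 0:
            raise NetworkFormatError(f"{where}: zero coefficient for {met!r}")
        stoich[met] = stoich.get(met, 0.0) + value
    return stoich


def load_network(path: str | Path, format: str = "tabular") -> MetabolicNetwork:
    """Load a network in raw (possibly reversible) form.

    ``tabular``: *path* is a directory containing ``metabolites.tsv`` and
    ``reactions.tsv`` (and, optionally, ``carbon_arcs.tsv``).
    ``sbml``: *path* is an SBML L3/fbc file (read through cobrapy); carbon
    arcs must be supplied separately via :func:`load_carbon_arcs`.
    """
    path = Path(path)
    if format == "tabular":
        return _load_tabular(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def _load_tabular(directory: Path) -> MetabolicNetwork:
    mets = []
    for row in _read_tsv(directory / "metabolites.tsv", _MET_HEADER):
        mets.append(
            Metabolite(
                id=row[0],
                name=row[1],
                is_internal=_parse_flag(row[2], f"metabolite {row[0]}"),
                in_medium=_parse_flag(row[3], f"metabolite {row[0]}"),
            )
        )
    rxns = []
    for row in _read_tsv(directory / "reactions.tsv", _RXN_HEADER):
        rxns.append(
            Reaction(
                id=row[0],
                reversible=_parse_flag(row[1], f"reaction {row[0]}"),
                gpr=parse_gpr(row[2]),
                stoich=_parse_stoich(row[3], f"reaction {row[0]}"),
            )
        )
    table = CarbonArcTable()
    arc_path = directory / "carbon_arcs.tsv"
    if arc_path.exists():
        for row in _read_tsv(arc_path, _ARC_HEADER):
            table.add(reaction=row[0], substrate=row[1], product=row[2])
    return MetabolicNetwork(metabolites=mets, reactions=rxns, carbon_arcs=table)


def write_network(net: MetabolicNetwork, directory: str | Path) -> None:
    """Write *net* in the tabular dialect (round-trips with load_network)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metabolites.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MET_HEADER) + "\n")
        for m in net.metabolites:
            fh.write(
                f"{m.id}\t{m.name}\t{int(m.is_internal)}\t{int(m.in_medium)}\n"
            )
    with open(directory / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RXN_HEADER) + "\n")
        for r in net.reactions:
            stoich = ";".join(
                f"{met}:{coeff:.12g}" for met, coeff in sorted(r.stoich.items())
            )
            gpr = str(r.gpr) if r.gpr is not None else ""
            fh.write(f"{r.id}\t{int(r.reversible)}\t{gpr}\t{stoich}\n")
    with open(directory / "carbon_arcs.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ARC_HEADER) + "\n")
        for arc in net.carbon_arcs:
            fh.write(f"{arc.reaction}\t{arc.substrate}\t{arc.product}\n")


def load_carbon_arcs(path: str | Path, net: MetabolicNetwork) -> CarbonArcTable:
    """Load and validate a (reaction, substrate, product) arc table."""
    table = CarbonArcTable()
    for row in _read_tsv(Path(path), _ARC_HEADER):
        table.add(reaction=row[0], substrate=row[1], product=row[2])
    validate_carbon_arcs(table, net)
    return table


def _load_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - cobra is an extra
        raise NetworkFormatError(
            "SBML import requires the 'cobra' package (pip install icfp[sbml])"
        ) from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            # extracellular species are taken as the external set E
            is_internal=(m.compartment or "").lower() not in ("e", "extracellular"),
        )
        for m in model.metabolites
    ]
    rxns = []
    for r in model.reactions:
        if not r.metabolites:
            continue
        rxns.append(
            Reaction(
                id=r.id,
                stoich={m.id: float(c) for m, c in r.metabolites.items()},
                reversible=r.lower_bound < 0,
                gpr=parse_gpr(r.gene_reaction_rule),
            )
        )
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Replace each reversible reaction by a forward/backward pair.

    The backward copy negates the stoichiometry and mirrors the carbon
    arcs with (i, j) swapped; the two copies point at each other via
    ``reverse_partner`` so that the mutual-exclusion constraint can
    forbid both running at once.  Irreversible reactions and networks
    that are already split pass through unchanged (idempotent).
    """
    if net.is_split:
        return net
    reactions: list[Reaction] = []
    table = CarbonArcTable()
    for r in net.reactions:
        arcs = [a for a in net.carbon_arcs.entries if a.reaction == r.id]
        if not r.reversible:
            reactions.append(r)
            for a in arcs:
                table.add(a.substrate, a.product, r.id)
            continue
        rev_id = r.id + REVERSE_SUFFIX
        reactions.append(
            replace(r, reversible=False, reverse_partner=rev_id)
        )
        reactions.append(
            Reaction(
                id=rev_id,
                stoich={m: -c for m, c in r.stoich.items()},
                reversible=False,
                gpr=r.gpr,
                reverse_partner=r.id,
            )
        )
        for a in arcs:
            table.add(a.substrate, a.product, r.id)
            table.add(a.product, a.substrate, rev_id)
    return MetabolicNetwork(
        metabolites=list(net.metabolites), reactions=reactions, carbon_arcs=table
    )


def apply_medium(net: MetabolicNetwork, medium_ids: set[str]) -> MetabolicNetwork:
    """Return a copy of *net* with the growth-medium membership set.

    Medium metabolites are left entirely unconstrained by the model
    builder; external metabolites outside the medium may only be net
    produced.  Naming an internal or unknown metabolite is an error.
    """
    unknown = sorted(m for m in medium_ids if not net.has_metabolite(m))
    if unknown:
        raise NetworkValidationError(f"medium names unknown metabolites: {unknown}")
    internal = sorted(
        m for m in medium_ids if net.metabolite(m).is_internal
    )
    if internal:
        raise NetworkValidationError(
            f"medium metabolites must be external, got internal: {internal}"
        )
    mets = [
        replace(m, in_medium=(m.id in medium_ids)) if not m.is_internal else m
        for m in net.metabolites
    ]
    return MetabolicNetwork(
        metabolites=mets,
        reactions=list(net.reactions),
        carbon_arcs=CarbonArcTable(set(net.carbon_arcs.entries)),
    )
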