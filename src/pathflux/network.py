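"""Layered knowledge-network model: genes, species, reactions, pathways.

The network is the static substrate of the flux analysis.  It has four
layers connected top-down:

1. genes — identifiers matching the rows of an expression matrix;
2. (implicitly) transcripts and their products, folded into
3. species — RNAs, proteins, complexes and compounds, each tied to the
   set of genes whose expression determines its concentration
   (compounds such as H2O/O2 may instead be declared constant); and
4. pathways — named sets of reactions classified as signaling
   transduction or energy metabolism, optionally linked to other
   pathways by crosstalk edges.

Reactions connect species via typed participant roles: ``e`` enzyme,
``g`` gene, ``s`` substrate, ``tr_a`` transcriptional activator
(activating roles), and ``i`` inhibitor, ``tr_r`` transcriptional
repressor (inhibitory roles).  Regulatory feedback from pathways back
to genes is expressed through ``tr_a``/``tr_r`` participants of
ordinary reactions; there is no separate edge type.

Networks are serialized as a single JSON object (see
:func:`load_network` / :func:`write_network`); writing is canonical so
that identical networks produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

ACTIVATING_ROLES = frozenset({"e", "g", "s", "tr_a"})
INHIBITORY_ROLES = frozenset({"i", "tr_r"})
ROLES = ACTIVATING_ROLES | INHIBITORY_ROLES

PATHWAY_CLASSES = ("signaling_transduction", "energy_metabolism")


class NetworkFormatError(ValueError):
    """The file is not parseable as the network JSON dialect."""


class NetworkValidationError(ValueError):
    """A structurally parsed network violates a model invariant.

    ``messages`` collects every violation found, so a single load
    attempt reports all dangling references at once.
    """

    def __init__(self, messages: Iterable[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class Gene:
    id: str
    name: str = ""


@dataclass(frozen=True)
class Species:
    """A molecular species whose concentration drives reaction fluxes.

    ``constituents`` are the genes whose expression values multiply to
    give the species concentration (a complex of two proteins has both
    coding genes as constituents).  A constant species (e.g. water or
    oxygen, assumed invariant over the analysis) carries a fixed
    ``constant_value`` and no constituents.
    """

    id: str
    kind: str  # rna | protein | complex | compound
    constituents: frozenset[str] = frozenset()
    is_constant: bool = False
    constant_value: float | None = None


@dataclass(frozen=True)
class Participant:
    species_id: str  # resolves to a Species or, for role "g", often a Gene
    role: str


@dataclass(frozen=True)
class Reaction:
    id: str
    participants: tuple[Participant, ...]
    products: tuple[str, ...] = ()
    rate_constant: float = 1.0


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    klass: str
    reaction_ids: frozenset[str]
    crosstalk_ids: frozenset[str] = frozenset()


@dataclass
class KnowledgeNetwork:
    """A validated four-layer network; collections preserve file order."""

    genes: dict[str, Gene] = field(default_factory=dict)
    species: dict[str, Species] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def validate(self) -> None:
        """Check every model invariant; raise listing all violations."""
        errors: list[str] = []
        seen: dict[str, str] = {}
        for layer, ids in (
            ("gene", self.genes),
            ("species", self.species),
            ("reaction", self.reactions),
            ("pathway", self.pathways),
        ):
            for i in ids:
                if not i:
                    errors.append(f"empty {layer} id")
                elif i in seen:
                    errors.append(
                        f"id {i!r} used by both {seen[i]} and {layer} layers"
                    )
                else:
                    seen[i] = layer

        for sp in self.species.values():
            if sp.kind not in ("rna", "protein", "complex", "compound"):
                errors.append(f"species {sp.id!r}: unknown kind {sp.kind!r}")
            for g in sorted(sp.constituents):
                if g not in self.genes:
                    errors.append(
                        f"species {sp.id!r}: unresolved constituent gene {g!r}"
                    )
            if sp.is_constant:
                if sp.constituents:
                    errors.append(
                        f"constant species {sp.id!r} must have no constituents"
                    )
                if sp.constant_value is None:
                    errors.append(
                        f"constant species {sp.id!r} missing constant_value"
                    )
                elif sp.constant_value < 0:
                    errors.append(
                        f"constant species {sp.id!r}: constant_value < 0"
                    )
            elif sp.constant_value is not None:
                errors.append(
                    f"species {sp.id!r}: constant_value given but "
                    "is_constant is false"
                )

        for rxn in self.reactions.values():
            if not rxn.participants:
                errors.append(f"reaction {rxn.id!r} has no participants")
            if not rxn.rate_constant > 0:
                errors.append(
                    f"reaction {rxn.id!r}: rate_constant must be positive"
                )
            activating = False
            for p in rxn.participants:
                if p.role not in ROLES:
                    errors.append(
                        f"reaction {rxn.id!r}: unknown role {p.role!r}"
                    )
                elif p.role in ACTIVATING_ROLES:
                    activating = True
                if p.species_id not in self.species and p.species_id not in self.genes:
                    errors.append(
                        f"reaction {rxn.id!r}: unresolved participant "
                        f"{p.species_id!r}"
                    )
            if rxn.participants and not activating:
                errors.append(
                    f"reaction {rxn.id!r} has no activating participant "
                    "(role e, g, s, or tr_a)"
                )
            for prod in rxn.products:
                if prod not in self.species and prod not in self.genes:
                    errors.append(
                        f"reaction {rxn.id!r}: unresolved product {prod!r}"
                    )

        if not self.pathways:
            errors.append("network defines no pathways")
        for pw in self.pathways.values():
            if pw.klass not in PATHWAY_CLASSES:
                errors.append(f"pathway {pw.id!r}: unknown klass {pw.klass!r}")
            if not pw.reaction_ids:
                errors.append(f"pathway {pw.id!r} has no reactions")
            for r in sorted(pw.reaction_ids):
                if r not in self.reactions:
                    errors.append(
                        f"pathway {pw.id!r}: unresolved reaction {r!r}"
                    )
            for c in sorted(pw.crosstalk_ids):
                if c == pw.id:
                    errors.append(f"pathway {pw.id!r} lists itself as crosstalk")
                elif c not in self.pathways:
                    errors.append(
                        f"pathway {pw.id!r}: unresolved crosstalk pathway {c!r}"
                    )

        if errors:
            raise NetworkValidationError(errors)


def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise NetworkFormatError(f"{where}: missing required key {key!r}")
    return obj[key]


def network_from_dict(doc: Mapping) -> KnowledgeNetwork:
    """Build and validate a network from a parsed JSON object."""
    if not isinstance(doc, Mapping):
        raise NetworkFormatError("top level must be a JSON object")
    net = KnowledgeNetwork()
    for i, g in enumerate(doc.get("genes", [])):
        where = f"genes[{i}]"
        net.genes[str(_require(g, "id", where))] = Gene(
            id=str(_require(g, "id", where)), name=str(g.get("name", ""))
        )
    for i, s in enumerate(doc.get("species", [])):
        where = f"species[{i}]"
        sid = str(_require(s, "id", where))
        cv = s.get("constant_value")
        net.species[sid] = Species(
            id=sid,
            kind=str(_require(s, "kind", where)),
            constituents=frozenset(str(c) for c in s.get("constituents", [])),
            is_constant=bool(s.get("is_constant", False)),
            constant_value=None if cv is None else float(cv),
        )
    for i, r in enumerate(doc.get("reactions", [])):
        where = f"reactions[{i}]"
        rid = str(_require(r, "id", where))
        parts = tuple(
            Participant(
                species_id=str(_require(p, "species_id", f"{where}.participants[{j}]")),
                role=str(_require(p, "role", f"{where}.participants[{j}]")),
            )
            for j, p in enumerate(_require(r, "participants", where))
        )
        net.reactions[rid] = Reaction(
            id=rid,
            participants=parts,
            products=tuple(str(x) for x in r.get("products", [])),
            rate_constant=float(r.get("rate_constant", 1.0)),
        )
    for i, p in enumerate(doc.get("pathways", [])):
        where = f"pathways[{i}]"
        pid = str(_require(p, "id", where))
        net.pathways[pid] = Pathway(
            id=pid,
            name=str(p.get("name", pid)),
            klass=str(_require(p, "klass", where)),
            reaction_ids=frozenset(str(x) for x in _require(p, "reaction_ids", where)),
            crosstalk_ids=frozenset(str(x) for x in p.get("crosstalk_ids", [])),
        )
    net.validate()
    return net


def network_to_dict(net: KnowledgeNetwork) -> dict:
    """Canonical plain-dict form: entity order preserved, sets sorted."""
    return {
        "genes": [{"id": g.id, "name": g.name} for g in net.genes.values()],
        "species": [
            {
                "id": s.id,
                "kind": s.kind,
                "constituents": sorted(s.constituents),
                "is_constant": s.is_constant,
                **(
                    {"constant_value": s.constant_value}
                    if s.is_constant
                    else {}
                ),
            }
            for s in net.species.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "participants": [
                    {"species_id": p.species_id, "role": p.role}
                    for p in r.participants
                ],
                "products": list(r.products),
                "rate_constant": r.rate_constant,
            }
            for r in net.reactions.values()
        ],
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "klass": p.klass,
                "reaction_ids": sorted(p.reaction_ids),
                "crosstalk_ids": sorted(p.crosstalk_ids),
            }
            for p in net.pathways.values()
        ],
    }


def load_network(path: str | Path) -> KnowledgeNetwork:
    """Read and fully validate a network JSON file.

    Raises :class:`NetworkFormatError` on malformed JSON or missing
    required keys (naming the offending location) and
    :class:`NetworkValidationError` listing every invariant violation,
    including all unresolved references.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise NetworkFormatError(f"cannot read {path}: {exc}") from exc
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise NetworkFormatError(
            f"{path}: invalid JSON at line {exc.lineno} column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    return network_from_dict(doc)


def write_network(net: KnowledgeNetwork, path: str | Path) -> None:
    """Write the canonical JSON form; byte-identical on repeated calls."""
    net.validate()
    path = Path(path)
    payload = json.dumps(network_to_dict(net), indent=1, sort_keys=True)
    path.write_text(payload + "\n", encoding="utf-8")


def network_summary(net: KnowledgeNetwork) -> dict:
    """Per-layer counts, per-klass pathway counts, and a role histogram."""
    roles: dict[str, int] = {r: 0 for r in sorted(ROLES)}
    for rxn in net.reactions.values():
        for p in rxn.participants:
            roles[p.role] += 1
    klass_counts = {k: 0 for k in PATHWAY_CLASSES}
    for pw in net.pathways.values():
        klass_counts[pw.klass] += 1
    return {
        "n_genes": len(net.genes),
        "n_species": len(net.species),
        "n_reactions": len(net.reactions),
        "n_pathways": len(net.pathways),
        "pathways_by_klass": klass_counts,
        "role_histogram": roles,
        "n_constant_species": sum(
            s.is_constant for s in net.species.values()
        ),
        "n_crosstalk_links": sum(
            len(p.crosstalk_ids) for p in net.pathways.values()
        ),
    }
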