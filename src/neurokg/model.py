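"""Domain model: anatomical entities, neuron populations, and validation.

A neuron population is one region-to-region connectivity statement,
"population *N* at *A* projects to *B* via *C*": *A* holds the somata, *B*
the axon (or sensory) terminals, and *C* the axon-course structures in
between, nerves included.  Populations carry locational phenotypes per
neuron-part role, autonomic/circuit/functional phenotypes, species and sex
assertions, an ordered partial-order tree of the axonal course, forward
connections to post-synaptic partner populations, and provenance.

Species assertions are open-world: an empty taxon set means "observed in at
least one mammal, species unspecified" — never "in no species".  Sex
assertions are closed-world: a sex-specific population carries an explicit
negation of the opposite sex when serialized.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Union

from .vocab import (
    AXON_COURSE_ROLES,
    DESTINATION_ROLES,
    AnsPhenotype,
    CircuitRole,
    Curie,
    FunctionalRole,
    LocationRole,
    ROLE_ORDER,
    Sex,
)

if TYPE_CHECKING:  # pragma: no cover
    from .store import KnowledgeGraph

BLANK = "blank"


class TreeError(ValueError):
    """Raised for structurally malformed partial-order trees."""


@dataclass(frozen=True)
class PartialOrderTree:
    """Rooted ordered tree of anatomical CURIEs encoding an axonal course.

    The distinguished root marker ``"blank"`` appears only at the root; the
    root's children begin at soma locations and every leaf is a terminal
    location of the owning population.
    """

    node: Union[Curie, str]
    children: tuple["PartialOrderTree", ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.node, str) and self.node != BLANK:
            raise TreeError(f"string node must be the {BLANK!r} marker, got {self.node!r}")
        if not isinstance(self.children, tuple):
            object.__setattr__(self, "children", tuple(self.children))
        for child in self.children:
            if not isinstance(child, PartialOrderTree):
                raise TreeError(f"child is not a subtree: {child!r}")
            if child.node == BLANK:
                raise TreeError(f"{BLANK!r} marker may only appear at the root")

    @classmethod
    def root(cls, children: Iterable["PartialOrderTree"]) -> "PartialOrderTree":
        return cls(BLANK, tuple(children))

    @classmethod
    def chain(cls, nodes: Iterable[Curie]) -> "PartialOrderTree":
        """A blank-rooted linear chain through ``nodes`` in order."""
        seq = list(nodes)
        tree: tuple[PartialOrderTree, ...] = ()
        for node in reversed(seq):
            tree = (cls(node, tree),)
        return cls(BLANK, tree)

    @property
    def is_root(self) -> bool:
        return self.node == BLANK


def tree_nodes(path: PartialOrderTree) -> frozenset[Curie]:
    """All CURIEs appearing in the tree, excluding the blank root marker."""
    if not isinstance(path, PartialOrderTree):
        raise TreeError(f"not a partial-order tree: {path!r}")
    out: set[Curie] = set()
    stack = [path]
    while stack:
        t = stack.pop()
        if isinstance(t.node, Curie):
            out.add(t.node)
        stack.extend(t.children)
    return frozenset(out)


@dataclass(frozen=True)
class AnatomicalEntity:
    """A CURIE-identified anatomical structure with its raw relation edges."""

    curie: Curie
    label: str
    synonyms: frozenset[str] = frozenset()
    part_of: frozenset[Curie] = frozenset()
    subclass_of: frozenset[Curie] = frozenset()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"entity {self.curie} has an empty label")
        if not self.curie.is_anatomical:
            raise ValueError(
                f"anatomical entities must use UBERON or ILX identifiers, got {self.curie}"
            )
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))
        object.__setattr__(self, "part_of", frozenset(self.part_of))
        object.__setattr__(self, "subclass_of", frozenset(self.subclass_of))


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """At most one value per phenotypic dimension."""

    ans: Optional[AnsPhenotype] = None
    circuit_role: Optional[CircuitRole] = None
    functional_role: Optional[FunctionalRole] = None


@dataclass(frozen=True)
class SpeciesAssertion:
    """Open-world species observation set (empty = mammalian, unspecified)."""

    taxa: frozenset[Curie] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))


@dataclass(frozen=True)
class SexAssertion:
    """Optional sex specificity; a set sex implies negation of the other."""

    sex: Optional[Sex] = None


class CitationKind(enum.Enum):
    DOI = "DOI"
    PMID = "PMID"
    ISBN = "ISBN"
    ORCID = "ORCID"


class SourceKind(enum.Enum):
    """Knowledge source: expert-contributed circuit model or literature."""

    EXPERT_MODEL = "expert_model"
    LITERATURE = "literature"


@dataclass(frozen=True, order=True)
class Citation:
    kind: CitationKind
    value: str

    def render(self) -> str:
        return f"{self.kind.value}:{self.value}"

    @classmethod
    def parse(cls, text: str) -> "Citation":
        kind, sep, value = text.partition(":")
        if not sep:
            raise ValueError(f"citation must be KIND:value, got {text!r}")
        return cls(CitationKind(kind), value)


@dataclass(frozen=True)
class Provenance:
    citations: frozenset[Citation] = frozenset()
    alert_notes: tuple[str, ...] = ()
    source_kind: SourceKind = SourceKind.LITERATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "citations", frozenset(self.citations))
        object.__setattr__(self, "alert_notes", tuple(self.alert_notes))


@dataclass(frozen=True)
class NeuronPopulation:
    """One connectivity statement with all its phenotypic annotations."""

    id: Curie
    label: str
    pref_label: str = ""
    locations: Mapping[LocationRole, frozenset[Curie]] = field(default_factory=dict)
    path: Optional[PartialOrderTree] = None
    phenotypes: PhenotypeAnnotation = PhenotypeAnnotation()
    species: SpeciesAssertion = SpeciesAssertion()
    sex: SexAssertion = SexAssertion()
    forward_connections: frozenset[Curie] = frozenset()
    provenance: Provenance = Provenance()

    def __post_init__(self) -> None:
        norm = {
            role: frozenset(locs)
            for role, locs in self.locations.items()
            if locs
        }
        object.__setattr__(self, "locations", norm)
        object.__setattr__(self, "forward_connections", frozenset(self.forward_connections))

    def locs(self, role: LocationRole) -> frozenset[Curie]:
        return self.locations.get(role, frozenset())

    @property
    def origins(self) -> frozenset[Curie]:
        return self.locs(LocationRole.SOMA)

    @property
    def destinations(self) -> frozenset[Curie]:
        return self.locs(LocationRole.AXON_TERMINAL) | self.locs(LocationRole.SENSORY_TERMINAL)

    @property
    def axon_course(self) -> frozenset[Curie]:
        out: frozenset[Curie] = frozenset()
        for role in AXON_COURSE_ROLES:
            out |= self.locs(role)
        return out

    @property
    def all_locations(self) -> frozenset[Curie]:
        """Union over every role — the connected locations of the population."""
        out: frozenset[Curie] = frozenset()
        for locs in self.locations.values():
            out |= locs
        return out

    def roles_of(self, location: Curie) -> tuple[LocationRole, ...]:
        return tuple(r for r in ROLE_ORDER if location in self.locs(r))


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    code: str
    message: str


ValidationReport = list  # list[ValidationIssue]


def validate_population(
    pop: NeuronPopulation, graph: Optional["KnowledgeGraph"] = None
) -> list[ValidationIssue]:
    """Check a population's invariants.

    Hard errors (``Severity.ERROR``) are violations of the model contract: a
    population must have at least one origin (soma location) and one
    destination (axon or sensory terminal), and may not forward-connect to
    itself.  Softer consistency issues — partial-order nodes missing from
    the location sets, CURIEs or forward-connection targets unknown to a
    supplied knowledge graph — are warnings: the pathway encoding and the
    location sets are parallel encodings without a hard consistency rule,
    so callers decide whether warnings block.

    The check is side-effect free and idempotent: it never mutates the
    population or the graph.
    """
    issues: list[ValidationIssue] = []
    if not pop.origins:
        issues.append(
            ValidationIssue(
                Severity.ERROR,
                "MISSING_ORIGIN",
                f"{pop.id}: population has no soma location (at least one origin required)",
            )
        )
    if not pop.destinations:
        issues.append(
            ValidationIssue(
                Severity.ERROR,
                "MISSING_DESTINATION",
                f"{pop.id}: population has no axon-terminal or sensory-terminal location",
            )
        )
    if pop.id in pop.forward_connections:
        issues.append(
            ValidationIssue(
                Severity.ERROR,
                "SELF_FORWARD_CONNECTION",
                f"{pop.id}: population forward-connects to itself",
            )
        )
    for role, locs in pop.locations.items():
        for loc in locs:
            if not loc.is_anatomical:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR,
                        "NON_ANATOMICAL_LOCATION",
                        f"{pop.id}: {role.name.lower()} location {loc} is not a UBERON/ILX term",
                    )
                )
    if pop.path is not None:
        known = pop.all_locations
        for node in sorted(tree_nodes(pop.path)):
            if node not in known:
                issues.append(
                    ValidationIssue(
                        Severity.WARNING,
                        "PATH_LOCATION_MISMATCH",
                        f"{pop.id}: partial-order node {node} is in no locational phenotype set",
                    )
                )
    if graph is not None:
        for loc in sorted(pop.all_locations):
            if not graph.knows(loc):
                issues.append(
                    ValidationIssue(
                        Severity.WARNING,
                        "UNKNOWN_CURIE",
                        f"{pop.id}: location {loc} does not resolve in the knowledge graph",
                    )
                )
        for target in sorted(pop.forward_connections):
            if not graph.knows_population(target):
                issues.append(
                    ValidationIssue(
                        Severity.WARNING,
                        "UNKNOWN_FORWARD_TARGET",
                        f"{pop.id}: forward-connection target {target} is absent from the graph",
                    )
                )
    return issues


def hard_errors(report: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in report if i.severity is Severity.ERROR]
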