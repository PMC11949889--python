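"""Namespaces, CURIE handling and the predicate vocabulary.

The connectivity dialects handled by this package live almost entirely in a
single readable-predicate namespace (``ilxtr``), with anatomical terms drawn
from UBERON and InterLex (ILX).  This module owns the prefix registry, the
:class:`Curie` value type, and the mapping tables between neuron-part roles
and their OWL-dialect / simple-dialect predicate names.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

ILXTR = "http://uri.interlex.org/tgbugs/uris/readable/"
PARTOF_IRI = "http://purl.obolibrary.org/obo/BFO_0000050"

#: Default prefix expansions.  Population namespaces (``prostate``,
#: ``femrep``, ...) are registered on top of these by fixtures, generators or
#: user configuration.
DEFAULT_PREFIXES: dict[str, str] = {
    "ilxtr": ILXTR,
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "ILX": "http://uri.interlex.org/base/ilx_",
    "NCBITaxon": "http://purl.obolibrary.org/obo/NCBITaxon_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "partOf": PARTOF_IRI,
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
}

#: Anatomical entities must be identified in one of these namespaces.
ANATOMICAL_PREFIXES = frozenset({"UBERON", "ILX"})


class CurieError(ValueError):
    """Raised for malformed or unregistered compact URIs."""


@dataclass(frozen=True, order=True)
class Curie:
    """A compact URI ``prefix:local_id``.

    Ordering is lexicographic on the rendered form, which gives the
    deterministic tie-breaking used throughout serialization and query
    result ordering.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not self.local_id:
            raise CurieError(f"empty prefix or local id in {self.prefix!r}:{self.local_id!r}")
        if ":" in self.prefix:
            raise CurieError(f"prefix may not contain ':': {self.prefix!r}")

    @classmethod
    def parse(cls, text: str) -> "Curie":
        prefix, sep, local = text.partition(":")
        if not sep:
            raise CurieError(f"not a CURIE (missing ':'): {text!r}")
        return cls(prefix, local)

    def render(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def is_anatomical(self) -> bool:
        return self.prefix in ANATOMICAL_PREFIXES


class PrefixRegistry:
    """Bidirectional prefix <-> IRI-base registry.

    Population namespaces are unrestricted but must be declared here before
    their CURIEs can be expanded to IRIs (and recognized when reading).
    """

    def __init__(self, extra: Optional[dict[str, str]] = None) -> None:
        self._by_prefix: dict[str, str] = dict(DEFAULT_PREFIXES)
        if extra:
            for prefix, base in extra.items():
                self.register(prefix, base)

    def register(self, prefix: str, base_iri: str) -> None:
        existing = self._by_prefix.get(prefix)
        if existing is not None and existing != base_iri:
            raise CurieError(f"prefix {prefix!r} already bound to {existing}")
        self._by_prefix[prefix] = base_iri

    def __contains__(self, prefix: str) -> bool:
        return prefix in self._by_prefix

    def items(self) -> Iterable[tuple[str, str]]:
        return sorted(self._by_prefix.items())

    def expand(self, curie: Curie) -> str:
        try:
            return self._by_prefix[curie.prefix] + curie.local_id
        except KeyError:
            raise CurieError(f"unregistered prefix: {curie.prefix!r}") from None

    def compact(self, iri: str) -> Optional[Curie]:
        """Longest-match compaction of an IRI back to a CURIE."""
        best: Optional[tuple[str, str]] = None
        for prefix, base in self._by_prefix.items():
            if iri.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            return None
        return Curie(best[0], iri[len(best[1]):])


class LocationRole(enum.Enum):
    """The neuron part placed at an anatomical location.

    Each role maps to exactly one OWL-dialect property and one
    simple-dialect shortcut predicate (both in the ``ilxtr`` namespace).
    The axon-to-sensory-terminal role marks the axonal course of a
    pseudo-monopolar sensory process; for routing queries it is treated as
    an axon-course location alongside the plain axon role.
    """

    SOMA = ("hasSomaLocatedIn", "hasSomaLocation")
    DENDRITE = ("hasDendriteLocatedIn", "hasDendriteLocation")
    AXON = ("hasAxonLocatedIn", "hasAxonLocation")
    AXON_TO_SENSORY_TERMINAL = ("hasAxonToSensoryTerminalIn", "hasAxonToSensoryTerminal")
    AXON_TERMINAL = ("hasAxonPresynapticElementIn", "hasAxonTerminalLocation")
    SENSORY_TERMINAL = ("hasAxonSensorySubcellularElementIn", "hasAxonSensoryLocation")

    def __init__(self, owl_property: str, simple_predicate: str) -> None:
        self.owl_property = owl_property
        self.simple_predicate = simple_predicate


#: Canonical emission / reporting order of the roles.
ROLE_ORDER: tuple[LocationRole, ...] = (
    LocationRole.SOMA,
    LocationRole.DENDRITE,
    LocationRole.AXON,
    LocationRole.AXON_TO_SENSORY_TERMINAL,
    LocationRole.AXON_TERMINAL,
    LocationRole.SENSORY_TERMINAL,
)

ORIGIN_ROLES = frozenset({LocationRole.SOMA})
DESTINATION_ROLES = frozenset({LocationRole.AXON_TERMINAL, LocationRole.SENSORY_TERMINAL})
AXON_COURSE_ROLES = frozenset({LocationRole.AXON, LocationRole.AXON_TO_SENSORY_TERMINAL})

OWL_PROPERTY_TO_ROLE = {r.owl_property: r for r in LocationRole}
SIMPLE_PREDICATE_TO_ROLE = {r.simple_predicate: r for r in LocationRole}

# Non-locational predicates.
P_TAXON = "hasInstanceInTaxon"
P_SEX = "hasBiologicalSex"
P_EXCLUDED_SEX = "hasExcludedBiologicalSex"  # simple dialect only; see docs
P_ANS_OWL = "hasAnatomicalSystemPhenotype"
P_ANS_SIMPLE = "hasNeuronalPhenotype"
P_CIRCUIT_ROLE = "hasCircuitRolePhenotype"
P_FUNCTIONAL_ROLE = "hasFunctionalCircuitRolePhenotype"
P_FORWARD_OWL = "hasForwardConnectionPhenotype"
P_FORWARD_SIMPLE = "hasForwardConnection"
P_CONNECTED = "hasConnectedLocation"
P_PARTIAL_ORDER = "neuronPartialOrder"
P_IS_PART_OF = "isPartOf"
P_SUPPLIES_TO = "suppliesTo"
P_ALERT_NOTE = "alertNote"
P_CITATION = "literatureCitation"
# Reified adjacency-edge vocabulary (plain-RDF rendering of the
# hasNextNode-annotated-by-isConnectedBy pattern).
C_PATH_EDGE = "NextNodeEdge"
P_EDGE_FROM = "edgeFrom"
P_EDGE_TO = "edgeTo"
P_CONNECTED_BY = "isConnectedBy"

#: Base class markers distinguishing knowledge provenance kinds.
MARKER_LITERATURE = Curie("ilxtr", "NeuronSparcNlp")
MARKER_EXPERT = Curie("ilxtr", "NeuronApinatSimple")


class Sex(enum.Enum):
    MALE = ("PATO:0000384", "male")
    FEMALE = ("PATO:0000383", "female")

    def __init__(self, curie: str, label: str) -> None:
        self.curie = Curie.parse(curie)
        self.label = label

    @property
    def opposite(self) -> "Sex":
        return Sex.FEMALE if self is Sex.MALE else Sex.MALE


SEX_BY_CURIE = {s.curie: s for s in Sex}


class AnsDivision(enum.Enum):
    SYMPATHETIC = "Sympathetic"
    PARASYMPATHETIC = "Parasympathetic"
    ENTERIC = "Enteric"


class GanglionicOrder(enum.Enum):
    PRE_GANGLIONIC = "Pre-Ganglionic"
    POST_GANGLIONIC = "Post-Ganglionic"
    UNSPECIFIED = ""


@dataclass(frozen=True, order=True)
class AnsPhenotype:
    """An autonomic subdivision phenotype, e.g. sympathetic pre-ganglionic."""

    division: AnsDivision
    order: GanglionicOrder = GanglionicOrder.UNSPECIFIED

    @property
    def label(self) -> str:
        if self.order is GanglionicOrder.UNSPECIFIED:
            return f"{self.division.value} phenotype"
        return f"{self.division.value} {self.order.value} phenotype"

    @property
    def curie(self) -> Curie:
        local = self.division.value + (
            self.order.value.replace("-", "") if self.order is not GanglionicOrder.UNSPECIFIED else ""
        )
        return Curie("ilxtr", f"neuron-phenotype-{local}")


ANS_PHENOTYPES: tuple[AnsPhenotype, ...] = tuple(
    AnsPhenotype(d, o) for d in AnsDivision for o in GanglionicOrder
)
ANS_BY_CURIE = {p.curie: p for p in ANS_PHENOTYPES}
ANS_BY_LABEL = {p.label.lower(): p for p in ANS_PHENOTYPES}


class CircuitRole(enum.Enum):
    INTRINSIC = "Intrinsic"
    MOTOR = "Motor"
    SENSORY = "Sensory"
    PROJECTION = "Projection"

    @property
    def label(self) -> str:
        return f"{self.value} phenotype"

    @property
    def curie(self) -> Curie:
        return Curie("ilxtr", f"neuron-circuit-role-{self.value}")


class FunctionalRole(enum.Enum):
    EXCITATORY = "Excitatory"
    INHIBITORY = "Inhibitory"

    @property
    def label(self) -> str:
        return f"{self.value} phenotype"

    @property
    def curie(self) -> Curie:
        return Curie("ilxtr", f"neuron-functional-role-{self.value}")


CIRCUIT_BY_CURIE = {c.curie: c for c in CircuitRole}
FUNCTIONAL_BY_CURIE = {f.curie: f for f in FunctionalRole}

#: Labels of the class roots that make a structure count as a routing
#: conduit ("via") in the competency queries.
NERVE_LIKE_LABELS = frozenset({"nerve", "nerve plexus", "nerve fiber"})

#: Well-known taxa used for species assertions (labels for reporting).
COMMON_TAXA: dict[str, str] = {
    "NCBITaxon:9685": "Felis catus",
    "NCBITaxon:9615": "Canis familiaris",
    "NCBITaxon:10141": "Cavia porcellus",
    "NCBITaxon:9606": "Homo sapiens",
    "NCBITaxon:10090": "Mus musculus",
    "NCBITaxon:9823": "Sus scrofa",
    "NCBITaxon:10116": "Rattus norvegicus",
}
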