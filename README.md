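# neurokg

Connectivity knowledge graphs for the peripheral and autonomic nervous
system, modeled at the neuron-population level.

Bioelectronic medicine and neuromodulation research need machine-readable
answers to questions like "which neural connections terminate in the
bladder, and through which nerves?" or "what might be affected if an
electrode perturbs the inferior mesenteric ganglion?".  `neurokg` is a
library + CLI for building, serializing and querying the knowledge
representation behind such answers.

## The model

Connectivity is represented as neuron populations rather than regions or
single cells.  A population *N* is one connectivity statement

> population *N* at *A* projects to *B* via *C*

where *A* is the non-empty set of anatomical regions holding the somata,
*B* the non-empty set holding the axon (or sensory) terminals, and *C* the
regions — typically nerves — containing the axon segments in between.
Each population additionally carries:

* **locational phenotypes** per neuron-part role (soma, dendrite, axon,
  axon terminal, axon sensory terminal, and the axon course of a
  pseudo-monopolar sensory process),
* a **partial-order tree** encoding the ordered, possibly branching axonal
  course from origins to destinations,
* **autonomic phenotypes** (sympathetic / parasympathetic / enteric ×
  pre- / post-ganglionic), circuit role and functional role,
* **species** assertions (open world: an empty set means "observed in some
  mammal, species unspecified", never "in no species") and **sex**
  assertions (closed world: a sex-specific population carries an explicit
  negation of the opposite sex),
* **forward connections** to post-synaptic partner populations.  When a
  pre-ganglionic population forward-connects to a post-ganglionic one, the
  synapse locations are the shared structures where the former terminates
  and the latter originates.

Anatomical structures are identified by UBERON or InterLex (ILX) CURIEs
and carry labels, synonyms, part-of and subclass edges; queries scope
organs and nerve branches through reflexive-transitive closures over these
relations (SPARQL `*`-path semantics).

Two interchangeable Turtle dialects are supported: a full **OWL axiom
dialect** (equivalent-class intersections of `someValuesFrom` restrictions,
every location wrapped in a `'part of' some ...` restriction, paths as
nested RDF collections under `ilxtr:neuronPartialOrder`) and a flat
**shortcut dialect** (`ilxtr:hasSomaLocation`, `ilxtr:hasAxonLocation`,
`ilxtr:hasAxonTerminalLocation`, `ilxtr:hasConnectedLocation`, reified
path-adjacency edges, ...) materialized from it for easy querying.

## Worked example

The bundled `femrep` fixture encodes a sympathetic innervation circuit of
the ovary in female rats: a pre-ganglionic population (`femrep:36`) from
the T9–T10 spinal segments to three paravertebral-chain locations via the
white communicating rami, synapsing onto two post-ganglionic populations
(`femrep:37`, `femrep:40-1`) that travel the ovarian nerve plexus to the
left and right ovary.

```python
>>> import neurokg as nk
>>> kg = nk.load_fixture("femrep")
>>> rows = nk.innervation_circuit(kg, "ovary", "Sympathetic Post-Ganglionic phenotype")
>>> sorted({r.population.render() for r in rows})
['femrep:36', 'femrep:37', 'femrep:40-1']
>>> sorted(r.v2.label for r in rows if r.is_synapse)
['L1 paravertebral sympathetic chain ganglion', 'T12 paravertebral sympathetic chain ganglion', 'T13 paravertebral sympathetic chain ganglion']
```

The circuit query returns one pre- and two post-ganglionic populations,
and flags exactly the three chain ganglia as synapse locations — the
structures that are simultaneously terminals of `femrep:36` and somata of
the post-ganglionic populations.

The same works from the shell:

```
neurokg fixture femrep -o femrep.ttl
neurokg query cq4 femrep.ttl --organ ovary
neurokg export dot femrep.ttl --organ ovary -o circuit.dot
neurokg query cq3 femrep.ttl --structure "ovarian nerve plexus"
neurokg report summary femrep.ttl
```

`query cq1` (organ termination), `cq2` (nerve routing, branches included),
`cq3` (perturbation footprint) and `cq4` (innervation circuit) emit CSV or
JSON; `transform` materializes the shortcut dialect from an axiom-dialect
file; `export dot` renders a circuit as a Graphviz digraph with synapse
nodes highlighted.

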