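# ontoppi

Ontological integration of heterogeneous protein–protein interaction (PPI)
datasets.

## The problem

Primary PPI databases (BioGRID, IntAct, MINT, DIP, HPRD) overlap only
partially and record interactions at different levels of genetic reference:
BioGRID keys interactors by Entrez gene, IntAct/MINT/DIP by UniProt entry,
HPRD by mRNA accession. Meta-databases usually integrate them by *a priori*
normalization — convert everything to one level, then merge — which is
irreversible: once a gene-level record has been expanded to protein pairs,
you can no longer tell which protein pairs are experimental facts and which
are artifacts of the expansion.

`ontoppi` takes the opposite route. It first builds a **genetic-information
ontology graph** over a fixed reference proteome: protein (UniProt) nodes,
gene nodes (GenBank/Entrez and Ensembl sub-classes) and mRNA nodes (RefSeq
and EMBL sub-classes), linked by cross-references following the gene → mRNA
→ protein information flow. Primary records are then superimposed on this
graph **in their original representation**, producing a heterogeneous
"hybrid" network that can be *reversibly* normalized to the protein or the
gene level, with every normalized interaction keeping back-links to the
primary associations that produced it.

## The method

Each source line becomes one **evidence set** (interaction type, detection
method, throughput/expansion label, publication keys) graded into ordinal
quality classes by precedence:

1. protein–gene/RNA association → class **5** (kept outside the PPI network,
   used only for cross-checking);
2. curator-declared direct interaction type → class **1**, regardless of any
   other attribute;
3. detection method capable of demonstrating a direct contact (e.g. yeast
   two-hybrid, X-ray crystallography) → class **1**;
4. high-throughput or spoke-expanded record → class **3**;
5. anything else → class **2**.

(There is no class 4; the numbering jumps from the third to the "quinary"
class.) An interaction's confidence score is the minimum class over its
evidence. Three nested filtering modes follow: **unfiltered** (score ≤ 3),
**standard** (score ≤ 2) and the **cross-checked default** (cross-checked
score ≤ 2), where cross-checking downgrades a class-2 evidence to class 3
whenever another source contributes, for the same publication, a class-3 or
class-5 evidence on the same (or a fan-out-interrelated) interaction. The
same bookkeeping flags interactions that exist purely through a fan-out
which finer-grained evidence from another source contradicts — *potential
normalization artifacts*.

## Worked example

A gene-level record links the GNAS complex locus (Entrez 2778, encoding the
four UniProt entries O95467, P63092, P84996, Q5JWF2) to FSCN1 (Entrez 6624
→ Q16658) as a high-throughput affinity-capture-MS physical association;
a second source reports the specific protein pair P63092–Q16658 by anti-bait
coimmunoprecipitation. Both cite PubMed 17353931.

```python
import tempfile
from ontoppi import run_pipeline, FilterMode
from ontoppi.fixtures import worked_example_fixture

d = tempfile.mkdtemp()
worked_example_fixture(d)
res = run_pipeline(d)
for a in res.hybrid.all_associations():
    print(a.id, [(e.standard_class, e.crosschecked_class) for e in a.evidence_sets])
for mode in FilterMode:
    print("protein", mode.value, len(res.filtered("protein", mode)))
```

prints

```
biogrid:1 [(3, 3)]
intact:1 [(2, 3)]
protein unfiltered 4
protein standard 1
protein default 0
```

The gene-level record grades to class 3 (high throughput) and explodes into
4 protein-level interactions; the protein-specific record grades to class 2,
so only its pair survives the standard filter; cross-checking then notices
both evidences come from the same publication, downgrades the class-2
evidence to 3, and the pair drops out of the default network as well. The
three fan-out-only pairs are flagged as potential normalization artifacts.

The same run is available from the shell:

```sh
ontoppi fixtures worked-example --out /tmp/we
ontoppi integrate --bundle /tmp/we --mode unfiltered --out /tmp/nets
ontoppi query --bundle /tmp/we --mode unfiltered --level protein Q16658
```

## Package layout

| module | role |
| --- | --- |
| `ontoppi.ontology` | build/query the ontology graph, identifier maintenance |
| `ontoppi.ingest` | PSI-MITAB and HPRD-dialect parsers, human filter, record classification |
| `ontoppi.grading` | evidence classes, declarative grading ruleset |
| `ontoppi.hybrid` | superimposition onto the ontology; side store; rejection log |
| `ontoppi.normalize` | reversible protein/gene-level normalization |
| `ontoppi.crosscheck` | per-publication cross-source downgrades, artifact flags |
| `ontoppi.network` | scoring, filtering modes, queries, summaries, export |
| `ontoppi.fixtures` | synthetic bundle generator with independent truth tables |
| `ontoppi.cli` | `ontoppi` command-line entry point |

See `docs/methods.md` for the modelling decisions and their rationale.
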