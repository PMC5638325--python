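# Methods

## The ontology graph

The graph has five node namespaces — `uniprot`, `gene_genbank` (Entrez),
`gene_ensembl`, `mrna_refseq`, `mrna_embl` — and eight permitted link
kinds: the six explicit cross-references (protein↔each gene/mRNA
sub-class, Entrez gene↔RefSeq mRNA, Ensembl gene↔EMBL mRNA) plus two
*bridges* (Ensembl gene→Entrez gene, EMBL mRNA→Ensembl gene) that make
indirect Entrez links traversable for proteins annotated only against
Ensembl. Construction is bottom-up: the protein partition is exactly the
supplied reference proteome; gene and mRNA nodes are admitted only when a
cross-reference row connects them, directly or transitively, to a
reference protein. Rows outside that closure are dropped and counted in
the build report. No extra transitivity is invented: a protein linked to a
gene only through an mRNA is reachable gene-wise only because the
gene↔mRNA link kind exists, not through any synthesized protein–gene edge.

Identifier maintenance follows database practice: a deprecated accession
becomes a searchable alias of its active entry (edges of a lingering
deprecated node are folded into the active one first), an obsolete
accession is removed together with its edges. Accessions match
case-sensitively with trailing numeric versions stripped (the original
versioned form is kept as an attribute); symbols and other stored
attributes match case-insensitively — accession standards are
case-stable, gene symbols are not.

One EMBL mRNA may bridge to multiple Ensembl genes; the behaviour of such
fan-out is not standardized, so the graph permits it and the build report
makes it visible rather than silently collapsing it.

## Normalization

`normalize_node` is a breadth-first traversal over the typed links with
two stopping rules: never expand beyond a node already at the target
level, and never pass *through* a protein node (genetic information flows
gene → mRNA → protein; proteins are sinks — passing through one would
leak between unrelated genes via shared interactors). The gene level
collects Entrez gene nodes only; Ensembl genes and mRNAs are way-points.
An interaction is the Cartesian product of its endpoints' correspondent
sets, merged across associations by unordered pair (endpoints keyed in
lexicographic accession order). Self-pairs arising when both endpoints
normalize to one node are kept and flagged — dropping them would lose
primary links and break reversibility. Associations with an endpoint
lacking any correspondent at the requested level go to an orphan log (an
mRNA-level association can therefore appear at the gene level yet be
orphaned at the protein level, or vice versa).

Reversibility is the design invariant: every normalized interaction keeps
the identifiers of the primary associations that produced it, the
evidence view is the union over those back-links, and re-normalizing the
denormalized associations reproduces the network exactly. The test suite
asserts this round trip on every fixture.

## Evidence grading

Grading is a pure function of (evidence, ruleset, association kind) with
the precedence listed in the README. Classes are restricted to
{1, 2, 3, 5}; class 4 is reserved/unused and rejected by validation — the
numbering gap is preserved, not interpreted. The shipped default ruleset
(`src/ontoppi/data/default_ruleset.yaml`) lists the direct interaction
types, direct-capable detection methods, low-confidence labels
(high-throughput for BioGRID/DIP, spoke expansion for IntAct/MINT — one
axis, since both demote for the same reason) and the protein–gene/RNA and
genetic-interference vocabularies. Unknown terms fall through to class 2.
HPRD's non-PSI-MI experiment labels are converted to PSI-MI equivalents
through a config table before grading; unmapped labels pass through
unchanged rather than failing.

## Cross-checking

Evidences are reconciled per publication key. A standard class-2 evidence
is downgraded to cross-checked class 3 exactly when another source
contributes, for the same publication, a class-3 or class-5 evidence
whose normalized footprint shares at least one interaction with it —
"interrelated" means sharing a normalized counterpart directly or through
fan-out, not merely citing the same paper anywhere in the corpus.
Class-1 evidences always retain their classification; class-5 side-store
evidence can trigger downgrades but is never itself re-graded or
exported; publication-less evidences never form overlaps. The procedure
is idempotent because it reads only standard classes. Cross-checked
classes are level-specific judgements: the pipeline recomputes them per
normalization level and captures the resulting scores level by level.

Artifact designation uses the minimal rule consistent with the intended
behaviour: when one source's evidence fans out to a set S of normalized
interactions and another source supports, for the same publication, a
non-empty strict subset of S, the interactions in the complement whose
entire evidence derives from fan-out are flagged. The flag is an
annotation only — membership in the filtered networks is always decided
by the confidence scores. This rule is deliberately a heuristic and is
labelled as such in the export format.

## Scoring, filtering, queries

Interaction scores are minima over the evidence view, once per class
variant; 5-only interactions are excluded from all three PPI networks.
The filtering modes nest by construction (cross-checking only demotes).
Query scopes are first-neighbors, neighbors-plus-interconnections and
among-queried; results always display a queried entity first (rows
connecting two non-queried neighbors under the interconnection scope have
none to display) and sort by cross-checked score ascending, standard
score ascending, distinct publication count descending, then
lexicographically by partner accession — publication count is over
*distinct* keys to avoid double-counting one paper curated by several
sources, and descending order follows the usual relevance convention;
both choices are isolated in one comparator.

## Synthetic data

The fixture generator emulates the study conditions at desk scale: a
50-protein reference proteome; genes encoding 1–4 proteins with
probabilities (0.70, 0.15, 0.10, 0.05), echoing that multi-gene/protein
loci are a small minority of a real proteome while still exercising
fan-out; 10% of proteins with no gene correspondent (the real proteome
contains entries never mapped to an Entrez gene); 10% of loci reachable
only through the Ensembl→Entrez bridge; RefSeq mRNAs on half the loci;
five sources contributing records at their native levels (30/20/10/10/10
per source by default) with a class mix of 20% direct-type, 35% moderate,
30% high-throughput/spoke, 10% protein–gene/RNA and 5% genetic
interference; and a 30% chance that a record cites a publication from a
small shared pool, which is what creates cross-source curation overlaps.
Optional corruption knobs (malformed-line rate, non-human rate) exist for
robustness tests and default to zero.

Truth tables are computed inside the generator by direct enumeration over
its own bookkeeping (it knows which gene it assigned to each protein),
never by calling the pipeline modules — they are independent oracles.
What the generator does **not** emulate: realistic degree distributions,
isoform-level annotation, per-source curation idiosyncrasies beyond the
identifier level and the CV terms listed in the default ruleset, or the
scale of real releases. Passing tests therefore demonstrate the
correctness of the integration logic, not release-level statistics of any
real snapshot.

The acceptance script runs the worked example (2 records, 7 ontology
nodes) and one random bundle of ~200 records / ~160 merged associations —
sizes chosen so a full run takes seconds while every code path
(fan-out, bridges, side store, cross-checking, orphans) is exercised.

## Known limitations

- Protein-isoform-level normalization is out of scope.
- CV term lists are explicit; there is no ontology-aware expansion of
  PSI-MI terms to their descendants.
- An interactor resolving ambiguously (one accession, several active
  nodes in one namespace) rejects the record with a distinct reason code
  instead of fanning out; fan-out is a normalization-time concept.
- The artifact-designation subset rule is a stated heuristic; it cannot
  distinguish a genuine multi-protein complex from a normalization
  artifact when no finer-grained source exists.
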