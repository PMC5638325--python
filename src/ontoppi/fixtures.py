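"""Generate synthetic ontologies and primary datasets at toy scale.

The generator emits file bundles in the exact dialects the ingest module
consumes — a reference-proteome list, 4-column cross-reference TSVs,
per-source PSI-MITAB files, an HPRD-style flat-file pair — together with
machine-readable truth tables.  Crucially, the truth tables are computed
by straightforward enumeration from the generator's own bookkeeping (it
knows which gene it gave each protein), never by calling the pipeline
modules, so they serve as independent oracles.

``worked_example_fixture`` reproduces the published two-record scenario of
a gene-level record (one gene encoding four proteins) colliding with a
protein-specific record from another source on the same publication.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .entities import ConfigurationError

MITAB_COLUMNS = 16

#: MI term numbers are cosmetic; grading matches on the term names.
_DETECTION = {
    "direct_capable": ("MI:0018", "two hybrid"),
    "moderate": ("MI:0006", "anti bait coimmunoprecipitation"),
    "low": ("MI:0004", "affinity capture-ms"),
    "gene_rna": ("MI:1017", "affinity capture-rna"),
}
_TYPES = {
    "direct": ("MI:0407", "direct interaction"),
    "physical": ("MI:0915", "physical association"),
    "interference": ("MI:0208", "genetic interaction"),
}


def _mi(term: tuple[str, str]) -> str:
    return f'psi-mi:"{term[0]}"({term[1]})'


def mitab_line(
    id_a: str,
    id_b: str,
    *,
    detection: str,
    publication: str | list[str],
    taxid_a: int = 9606,
    taxid_b: int = 9606,
    interaction_type: str,
    source_db: str,
    label: str = "-",
) -> str:
    """Compose one 16-column PSI-MITAB line in the fixture dialect."""
    pubs = publication if isinstance(publication, list) else [publication]
    cols = [
        id_a,
        id_b,
        "-",
        "-",
        "-",
        "-",
        detection,
        "-",
        "|".join(f"pubmed:{p}" for p in pubs),
        f"taxid:{taxid_a}(species)",
        f"taxid:{taxid_b}(species)",
        interaction_type,
        f'psi-mi:"MI:0000"({source_db})',
        "-",
        "-",
        label,
    ]
    assert len(cols) == MITAB_COLUMNS
    return "\t".join(cols)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study scenario.

    The defaults describe a small but structurally complete scenario: a
    50-protein proteome in which most genes encode a single protein, a few
    fan out to up to four (mirroring multi-protein loci such as the GNAS
    complex locus), a minority of proteins lack any gene correspondent,
    and five sources contribute records at their native levels with a
    realistic mixture of evidence quality and cross-source publication
    overlap.
    """

    n_proteins: int = 50
    #: P(gene encodes k proteins) for k = 1..len(list)
    gene_fanout_probs: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05)
    #: probability a gene gets a RefSeq mRNA node linked to gene + protein
    mrna_density: float = 0.5
    #: fraction of proteins with no gene correspondent at all
    orphan_protein_rate: float = 0.1
    #: fraction of gene-having proteins linked only via an Ensembl gene
    #: that bridges to an Entrez gene
    ensembl_only_rate: float = 0.1
    per_source_counts: dict[str, int] = field(
        default_factory=lambda: {
            "biogrid": 30,
            "intact": 20,
            "mint": 10,
            "dip": 10,
            "hprd": 10,
        }
    )
    #: P(intended class) over 1 / 2 / 3 / 5 / genetic interference
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"1": 0.2, "2": 0.35, "3": 0.3, "5": 0.1, "interference": 0.05}
    )
    #: probability a record draws its publication from the shared pool
    shared_publication_rate: float = 0.3
    nonhuman_rate: float = 0.0
    malformed_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if abs(sum(self.gene_fanout_probs) - 1.0) > 1e-9:
            raise ConfigurationError("gene_fanout_probs must sum to 1")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if sum(self.per_source_counts.values()) > 0 and self.n_proteins < 2:
            raise ConfigurationError("records need at least two proteins")


@dataclass
class FixtureBundle:
    """Paths of one generated bundle."""

    directory: Path
    proteome: Path
    crossref: Path
    gene_bridge: Path
    mrna_bridge: Path
    mitab: dict[str, Path]
    hprd_binary: Path
    hprd_mapping: Path
    truth_records: Path
    truth_pairs: dict[str, Path]


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Emit a parseable file bundle plus enumeration-derived truth tables."""
    spec.validate()
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- ontology structure, tracked in plain dicts -----------------------
    proteins = [f"Q{10000 + i}" for i in range(spec.n_proteins)]
    protein_gene: dict[str, str | None] = {}
    gene_proteins: dict[str, list[str]] = {}
    ensembl_of_gene: dict[str, str] = {}  # genes reached only via bridge
    protein_mrna: dict[str, str] = {}
    mrna_gene: dict[str, str] = {}
    gene_counter = 0

    idx = 0
    while idx < len(proteins):
        p = proteins[idx]
        if rng.random() < spec.orphan_protein_rate:
            protein_gene[p] = None
            idx += 1
            continue
        gene_counter += 1
        gene = str(1000 + gene_counter)
        k = rng.choices(
            range(1, len(spec.gene_fanout_probs) + 1),
            weights=spec.gene_fanout_probs,
        )[0]
        members = proteins[idx : idx + k]
        gene_proteins[gene] = list(members)
        for member in members:
            protein_gene[member] = gene
        if rng.random() < spec.ensembl_only_rate:
            ensembl_of_gene[gene] = f"ENSG{900000 + gene_counter}"
        if rng.random() < spec.mrna_density:
            mrna = f"NM_{100000 + gene_counter}"
            mrna_gene[mrna] = gene
            protein_mrna[members[0]] = mrna
        idx += k

    (out / "proteome.txt").write_text("\n".join(proteins) + "\n")

    crossref_rows: list[tuple[str, str, str, str]] = []
    gene_bridge_rows: list[tuple[str, str]] = []
    for gene, members in sorted(gene_proteins.items()):
        ensembl = ensembl_of_gene.get(gene)
        for p in members:
            if ensembl is None:
                crossref_rows.append(("uniprot", p, "gene_genbank", gene))
            else:
                crossref_rows.append(("uniprot", p, "gene_ensembl", ensembl))
        if ensembl is not None:
            gene_bridge_rows.append((ensembl, gene))
    for mrna, gene in sorted(mrna_gene.items()):
        crossref_rows.append(("gene_genbank", gene, "mrna_refseq", mrna))
        if ensembl_of_gene.get(gene):
            # keep the mRNA in the closure even though its gene enters by bridge
            pass
    for p, mrna in sorted(protein_mrna.items()):
        crossref_rows.append(("uniprot", p, "mrna_refseq", mrna))

    with open(out / "crossref.tsv", "w") as fh:
        fh.write("namespace_from\taccession_from\tnamespace_to\taccession_to\n")
        for row in crossref_rows:
            fh.write("\t".join(row) + "\n")
    with open(out / "gene_bridge.tsv", "w") as fh:
        for row in gene_bridge_rows:
            fh.write("\t".join(row) + "\n")
    (out / "mrna_bridge.tsv").write_text("")

    # effective gene of each protein after bridges (for truth enumeration)
    def gene_of(p: str) -> str | None:
        return protein_gene[p]

    def proteins_of_gene(g: str | None) -> list[str]:
        return gene_proteins.get(g, []) if g else []

    # ---- primary records --------------------------------------------------
    shared_pubs = [str(20000000 + i) for i in range(5)]
    next_pub = [30000000]

    def draw_pub() -> str:
        if rng.random() < spec.shared_publication_rate:
            return rng.choice(shared_pubs)
        next_pub[0] += 1
        return str(next_pub[0])

    hprd_eligible = sorted(protein_mrna)
    truth_rows: list[dict] = []

    mitab_paths: dict[str, Path] = {}
    hprd_binary = out / "hprd_binary.tsv"
    hprd_mapping = out / "hprd_mapping.tsv"
    hprd_lines: list[str] = []
    hprd_map_lines = [
        f"{i + 1:05d}\t{protein_mrna[p]}" for i, p in enumerate(hprd_eligible)
    ]
    hprd_id_of = {p: f"{i + 1:05d}" for i, p in enumerate(hprd_eligible)}

    class_names = sorted(spec.class_mix)
    class_weights = [spec.class_mix[c] for c in class_names]

    for source in sorted(spec.per_source_counts):
        count = spec.per_source_counts[source]
        lines: list[str] = []
        for _ in range(count):
            pool = hprd_eligible if source == "hprd" else proteins
            if source == "biogrid":
                pool = [p for p in proteins if gene_of(p)]
            if len(pool) < 2:
                raise ConfigurationError(f"too few eligible proteins for {source}")
            p_a, p_b = rng.sample(pool, 2)
            intended = rng.choices(class_names, weights=class_weights)[0]
            pub = draw_pub()
            malformed = rng.random() < spec.malformed_rate
            # HPRD is human by construction; taxa only exist in MITAB dialects
            nonhuman = (
                source != "hprd"
                and not malformed
                and rng.random() < spec.nonhuman_rate
            )

            if source == "hprd":
                expt = "y2h" if intended == "1" else "in vivo"
                if malformed:
                    lines.append(f"{hprd_id_of[p_a]}\t{hprd_id_of[p_b]}")
                else:
                    lines.append(
                        f"{hprd_id_of[p_a]}\t{hprd_id_of[p_b]}\t{expt}\t{pub}"
                    )
                acc_a, acc_b = protein_mrna[p_a], protein_mrna[p_b]
                # HPRD carries no class-3/5/interference machinery in this
                # dialect; realized class is 1 (Y2H) or 2
                realized = intended if intended == "1" else "2"
            else:
                if source == "biogrid":
                    acc_a, acc_b = gene_of(p_a), gene_of(p_b)
                    id_a = f"entrez gene/locuslink:{acc_a}"
                    id_b = f"entrez gene/locuslink:{acc_b}"
                else:
                    acc_a, acc_b = p_a, p_b
                    id_a, id_b = f"uniprotkb:{acc_a}", f"uniprotkb:{acc_b}"
                itype = _mi(_TYPES["physical"])
                detection = _mi(_DETECTION["moderate"])
                label = "-"
                if intended == "1":
                    itype = _mi(_TYPES["direct"])
                elif intended == "3":
                    detection = _mi(_DETECTION["low"])
                    label = (
                        "high throughput"
                        if source in ("biogrid", "dip")
                        else _mi(("MI:1060", "spoke expansion"))
                    )
                elif intended == "5":
                    detection = _mi(_DETECTION["gene_rna"])
                elif intended == "interference":
                    itype = _mi(_TYPES["interference"])
                line = mitab_line(
                    id_a,
                    id_b,
                    detection=detection,
                    publication=pub,
                    taxid_b=10090 if nonhuman else 9606,
                    interaction_type=itype,
                    source_db=source,
                    label=label,
                )
                if malformed:
                    line = "\t".join(line.split("\t")[:5])
                lines.append(line)
                realized = intended

            truth_rows.append(
                {
                    "source": source,
                    "line_number": len(lines),
                    "intended_class": realized,
                    "human": not nonhuman,
                    "malformed": malformed,
                    "protein_a": p_a,
                    "protein_b": p_b,
                    "accession_a": acc_a,
                    "accession_b": acc_b,
                    "publication": pub,
                }
            )
        if source == "hprd":
            hprd_lines = lines
        else:
            path = out / f"{source}.mitab"
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
            mitab_paths[source] = path

    hprd_binary.write_text("\n".join(hprd_lines) + ("\n" if hprd_lines else ""))
    hprd_mapping.write_text("\n".join(hprd_map_lines) + ("\n" if hprd_map_lines else ""))

    truth_records = out / "truth_records.tsv"
    with open(truth_records, "w") as fh:
        fh.write(
            "source\tline_number\tintended_class\thuman\tmalformed\t"
            "protein_a\tprotein_b\taccession_a\taccession_b\tpublication\n"
        )
        for row in truth_rows:
            fh.write(
                "\t".join(
                    str(row[k])
                    for k in (
                        "source", "line_number", "intended_class", "human",
                        "malformed", "protein_a", "protein_b",
                        "accession_a", "accession_b", "publication",
                    )
                )
                + "\n"
            )

    # ---- truth networks by independent enumeration ------------------------
    def protein_level_pairs(row: dict) -> set[tuple[str, str]]:
        if row["source"] == "biogrid":
            set_a = proteins_of_gene(row["accession_a"])
            set_b = proteins_of_gene(row["accession_b"])
        elif row["source"] == "hprd":
            # an mRNA's correspondents: its protein plus its gene's proteins
            def mrna_proteins(p: str) -> list[str]:
                g = gene_of(p)
                return sorted(set(proteins_of_gene(g)) | {p})

            set_a = mrna_proteins(row["protein_a"])
            set_b = mrna_proteins(row["protein_b"])
        else:
            set_a, set_b = [row["protein_a"]], [row["protein_b"]]
        return {tuple(sorted((a, b))) for a in set_a for b in set_b}

    def gene_level_pairs(row: dict) -> set[tuple[str, str]]:
        g_a = gene_of(row["protein_a"])
        g_b = gene_of(row["protein_b"])
        if not g_a or not g_b:
            return set()
        return {tuple(sorted((g_a, g_b)))}

    truth_pairs: dict[str, Path] = {}
    for level, expand in (("protein", protein_level_pairs), ("gene", gene_level_pairs)):
        pairs: set[tuple[str, str]] = set()
        for row in truth_rows:
            if row["malformed"] or not row["human"]:
                continue
            if row["intended_class"] in ("5", "interference"):
                continue
            pairs |= expand(row)
        path = out / f"truth_{level}_pairs.tsv"
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")
        truth_pairs[level] = path

    return FixtureBundle(
        directory=out,
        proteome=out / "proteome.txt",
        crossref=out / "crossref.tsv",
        gene_bridge=out / "gene_bridge.tsv",
        mrna_bridge=out / "mrna_bridge.tsv",
        mitab=mitab_paths,
        hprd_binary=hprd_binary,
        hprd_mapping=hprd_mapping,
        truth_records=truth_records,
        truth_pairs=truth_pairs,
    )


GNAS_PROTEINS = ("O95467", "P63092", "P84996", "Q5JWF2")
FSCN1_PROTEIN = "Q16658"
GNAS_GENE = "2778"
FSCN1_GENE = "6624"
SHARED_PUBMED = "17353931"


def worked_example_fixture(out_dir: str | Path) -> FixtureBundle:
    """The published two-source scenario around a four-protein gene locus.

    One gene-level record (gene 2778 x gene 6624; physical association by
    high-throughput affinity capture-MS) and one protein-level record
    (P63092 x Q16658; non-spoke physical association by anti bait
    coimmunoprecipitation), both citing PubMed 17353931.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteome = list(GNAS_PROTEINS) + [FSCN1_PROTEIN]
    (out / "proteome.txt").write_text("\n".join(proteome) + "\n")
    with open(out / "crossref.tsv", "w") as fh:
        fh.write("namespace_from\taccession_from\tnamespace_to\taccession_to\n")
        for p in GNAS_PROTEINS:
            fh.write(f"uniprot\t{p}\tgene_genbank\t{GNAS_GENE}\n")
        fh.write(f"uniprot\t{FSCN1_PROTEIN}\tgene_genbank\t{FSCN1_GENE}\n")
    (out / "gene_bridge.tsv").write_text("")
    (out / "mrna_bridge.tsv").write_text("")

    biogrid = mitab_line(
        f"entrez gene/locuslink:{GNAS_GENE}",
        f"entrez gene/locuslink:{FSCN1_GENE}",
        detection=_mi(_DETECTION["low"]),
        publication=SHARED_PUBMED,
        interaction_type=_mi(_TYPES["physical"]),
        source_db="biogrid",
        label="high throughput",
    )
    intact = mitab_line(
        "uniprotkb:P63092",
        f"uniprotkb:{FSCN1_PROTEIN}",
        detection=_mi(_DETECTION["moderate"]),
        publication=SHARED_PUBMED,
        interaction_type=_mi(_TYPES["physical"]),
        source_db="intact",
        label="-",
    )
    (out / "biogrid.mitab").write_text(biogrid + "\n")
    (out / "intact.mitab").write_text(intact + "\n")
    (out / "hprd_binary.tsv").write_text("")
    (out / "hprd_mapping.tsv").write_text("")

    truth_records = out / "truth_records.tsv"
    with open(truth_records, "w") as fh:
        fh.write(
            "source\tline_number\tintended_class\thuman\tmalformed\t"
            "protein_a\tprotein_b\taccession_a\taccession_b\tpublication\n"
        )
        fh.write(
            f"biogrid\t1\t3\tTrue\tFalse\t\t\t{GNAS_GENE}\t{FSCN1_GENE}\t{SHARED_PUBMED}\n"
        )
        fh.write(
            f"intact\t1\t2\tTrue\tFalse\tP63092\t{FSCN1_PROTEIN}\tP63092\t"
            f"{FSCN1_PROTEIN}\t{SHARED_PUBMED}\n"
        )
    truth_pairs: dict[str, Path] = {}
    with open(out / "truth_protein_pairs.tsv", "w") as fh:
        fh.write("node_a\tnode_b\n")
        for p in sorted(GNAS_PROTEINS):
            a, b = sorted((p, FSCN1_PROTEIN))
            fh.write(f"{a}\t{b}\n")
    truth_pairs["protein"] = out / "truth_protein_pairs.tsv"
    with open(out / "truth_gene_pairs.tsv", "w") as fh:
        fh.write("node_a\tnode_b\n")
        a, b = sorted((GNAS_GENE, FSCN1_GENE))
        fh.write(f"{a}\t{b}\n")
    truth_pairs["gene"] = out / "truth_gene_pairs.tsv"

    return FixtureBundle(
        directory=out,
        proteome=out / "proteome.txt",
        crossref=out / "crossref.tsv",
        gene_bridge=out / "gene_bridge.tsv",
        mrna_bridge=out / "mrna_bridge.tsv",
        mitab={"biogrid": out / "biogrid.mitab", "intact": out / "intact.mitab"},
        hprd_binary=out / "hprd_binary.tsv",
        hprd_mapping=out / "hprd_mapping.tsv",
        truth_records=truth_records,
        truth_pairs=truth_pairs,
    )
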