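"""Grade interaction evidence into ordinal quality classes.

Each source line yields one evidence set, graded 1 (strongly suggests a
direct interaction), 2 (may be direct), 3 (low probability of being
direct — high-throughput or spoke-expanded data) or 5 (protein–gene/RNA
association, kept only for cross-checking).  There is no class 4: the
numbering goes straight from the third to the "quinary" class, and the
gap is preserved, not interpreted.

Grading precedence, highest first:

1. protein–gene/RNA association            -> class 5
2. interaction type declared direct        -> class 1 (curator designation
   trusted regardless of every other attribute)
3. detection method capable of showing a
   direct interaction (e.g. yeast two-hybrid) -> class 1
4. high-throughput / spoke-expanded        -> class 3
5. everything else                         -> class 2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .entities import ConfigurationError
from .ingest import AssociationKind

VALID_CLASSES = (1, 2, 3, 5)


@dataclass
class EvidenceSet:
    """The graded attributes of one source line supporting an interaction."""

    source_db: str
    interaction_type_term: str = ""
    detection_method_term: str = ""
    throughput_or_expansion: str = ""
    publication_keys: frozenset[str] = frozenset()
    standard_class: int | None = None
    crosschecked_class: int | None = None
    origin_record_id: str = ""

    def identity(self) -> tuple:
        """Deduplication identity: two identical source lines are one evidence."""
        return (
            self.source_db,
            self.interaction_type_term,
            self.detection_method_term,
            self.throughput_or_expansion,
            self.publication_keys,
        )

    def validate(self) -> None:
        for value in (self.standard_class, self.crosschecked_class):
            if value is not None and value not in VALID_CLASSES:
                raise ValueError(f"invalid evidence class {value}; allowed {VALID_CLASSES}")
        if (
            self.standard_class is not None
            and self.crosschecked_class is not None
            and self.crosschecked_class < self.standard_class
        ):
            raise ValueError("cross-checking can only downgrade (raise the class number)")


def _fold(terms: Iterable[str]) -> frozenset[str]:
    return frozenset(t.casefold() for t in terms)


@dataclass
class GradingRuleset:
    """Declarative term lists driving the grading precedence.

    ``direct_capable_methods`` and ``low_confidence_labels`` may vary per
    source database; the ``default`` entry applies to sources without their
    own list.
    """

    direct_interaction_types: frozenset[str] = frozenset()
    direct_capable_methods: dict[str, frozenset[str]] = field(default_factory=dict)
    low_confidence_labels: dict[str, frozenset[str]] = field(default_factory=dict)
    protein_gene_rna_terms: frozenset[str] = frozenset()
    genetic_interference_terms: frozenset[str] = frozenset()
    hprd_term_conversion: dict[str, str] = field(default_factory=dict)

    def _per_source(self, table: dict[str, frozenset[str]], source_db: str) -> frozenset[str]:
        return table.get(source_db, table.get("default", frozenset()))

    def is_direct_type(self, term: str) -> bool:
        return term.casefold() in self.direct_interaction_types

    def is_direct_capable(self, source_db: str, term: str) -> bool:
        return term.casefold() in self._per_source(self.direct_capable_methods, source_db)

    def is_low_confidence(self, source_db: str, label: str) -> bool:
        return label.casefold() in self._per_source(self.low_confidence_labels, source_db)

    def cv_config(self) -> dict[str, frozenset[str]]:
        """Term lists consumed by association-kind classification."""
        return {
            "genetic_interference_terms": self.genetic_interference_terms,
            "protein_gene_rna_terms": self.protein_gene_rna_terms,
        }


def grade_evidence(
    evidence: EvidenceSet, ruleset: GradingRuleset, kind: AssociationKind
) -> int:
    """Assign the standard quality class of one evidence set.

    Pure function of (evidence, ruleset, kind); unknown terms fall through
    to class 2.  See the module docstring for the precedence.
    """
    if kind == AssociationKind.PROTEIN_GENE_OR_RNA:
        return 5
    if ruleset.is_direct_type(evidence.interaction_type_term):
        return 1
    if ruleset.is_direct_capable(evidence.source_db, evidence.detection_method_term):
        return 1
    if ruleset.is_low_confidence(evidence.source_db, evidence.throughput_or_expansion):
        return 3
    return 2


def _load_per_source(section) -> dict[str, frozenset[str]]:
    if section is None:
        return {}
    if isinstance(section, list):
        return {"default": _fold(section)}
    if isinstance(section, dict):
        return {str(k): _fold(v or ()) for k, v in section.items()}
    raise ConfigurationError("per-source term section must be a list or mapping")


def ruleset_from_mapping(cfg: Mapping) -> GradingRuleset:
    known = {
        "direct_interaction_types",
        "direct_capable_methods",
        "low_confidence_labels",
        "protein_gene_rna_terms",
        "genetic_interference_terms",
        "hprd_term_conversion",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ConfigurationError(f"unknown ruleset sections: {sorted(unknown)}")
    return GradingRuleset(
        direct_interaction_types=_fold(cfg.get("direct_interaction_types") or ()),
        direct_capable_methods=_load_per_source(cfg.get("direct_capable_methods")),
        low_confidence_labels=_load_per_source(cfg.get("low_confidence_labels")),
        protein_gene_rna_terms=_fold(cfg.get("protein_gene_rna_terms") or ()),
        genetic_interference_terms=_fold(cfg.get("genetic_interference_terms") or ()),
        hprd_term_conversion=dict(cfg.get("hprd_term_conversion") or {}),
    )


def load_ruleset(config_path: str | Path | None = None) -> GradingRuleset:
    """Load a grading ruleset from YAML; ``None`` loads the shipped default.

    Missing sections default to empty (a warning-free degenerate ruleset in
    which everything grades to class 2 except protein–gene/RNA records).
    """
    if config_path is None:
        text = resources.files("ontoppi").joinpath("data/default_ruleset.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    try:
        cfg = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed ruleset config: {exc}") from exc
    if not isinstance(cfg, Mapping):
        raise ConfigurationError("ruleset config must be a mapping")
    return ruleset_from_mapping(cfg)
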