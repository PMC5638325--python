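# Default evidence-grading ruleset and controlled-vocabulary term lists.
#
# Terms are matched case-insensitively against the term names extracted
# from the source files.  direct_capable_methods and low_confidence_labels
# may name per-source lists; "default" applies to every other source.

direct_interaction_types:
  - direct interaction
  - covalent binding
  - disulfide bond
  - covalent chromatin modification
  - enzymatic reaction
  - phosphorylation reaction
  - dephosphorylation reaction
  - ubiquitination reaction
  - deubiquitination reaction
  - methylation reaction
  - acetylation reaction
  - cleavage reaction
  - biochemical activity

direct_capable_methods:
  default:
    - two hybrid
    - two hybrid array
    - two hybrid pooling approach
    - two hybrid fragment pooling approach
    - lambda repressor two hybrid
    - yeast 2-hybrid
    - x-ray crystallography
    - electron microscopy
    - nuclear magnetic resonance
    - fluorescence resonance energy transfer
    - bimolecular fluorescence complementation
    - protein complementation assay
    - far western blotting
    - biochemical activity
    - protein cross-linking with a bifunctional reagent
    - reconstituted complex

low_confidence_labels:
  default:
    - high throughput
    - high-throughput
    - spoke
    - spoke expansion

protein_gene_rna_terms:
  - protein-rna
  - protein rna
  - affinity capture-rna
  - affinity capture rna
  - nucleic acid
  - dna
  - rna
  - chromatin immunoprecipitation assay
  - electrophoretic mobility shift assay

genetic_interference_terms:
  - genetic interference
  - genetic interaction
  - synthetic genetic interaction defined by inequality
  - suppressive genetic interaction defined by inequality
  - additive genetic interaction defined by inequality
  - synthetic lethality
  - synthetic rescue
  - synthetic growth defect
  - dosage rescue
  - dosage lethality
  - dosage growth defect
  - phenotypic enhancement
  - phenotypic suppression

# HPRD experiment labels converted to their PSI-MI equivalents before grading.
hprd_term_conversion:
  in vivo: coimmunoprecipitation
  in vitro: pull down
  yeast 2-hybrid: two hybrid
  y2h: two hybrid
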