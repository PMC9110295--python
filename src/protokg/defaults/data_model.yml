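# Default graph data model: 36 node labels connected by 47 relationship types.
# This file is the single authoritative definition of the bundled schema; the
# loader enforces that every relationship endpoint is a declared label.
node_labels:
  - Project
  - Subject
  - Biological_sample
  - Analytical_sample
  - Protein
  - Peptide
  - Modified_protein
  - Modification
  - Gene
  - Transcript
  - Metabolite
  - Disease
  - Tissue
  - Drug
  - Side_effect
  - Phenotype
  - Pathway
  - Biological_process
  - Molecular_function
  - Cellular_component
  - Complex
  - Publication
  - Clinical_variable
  - Experimental_factor
  - Chromosome
  - Known_variant
  - Clinically_relevant_variant
  - Functional_region
  - Amino_acid_sequence
  - Food
  - GWAS_study
  - Timepoint
  - Units
  - User
  - Intervention
  - Protein_structure

# relationship type -> list of allowed [source_label, target_label] pairs
relationship_types:
  HAS_PARENT:
    - [Disease, Disease]
    - [Tissue, Tissue]
    - [Pathway, Pathway]
    - [Biological_process, Biological_process]
    - [Molecular_function, Molecular_function]
    - [Cellular_component, Cellular_component]
    - [Phenotype, Phenotype]
    - [Experimental_factor, Experimental_factor]
    - [Clinical_variable, Clinical_variable]
  HAS_QUANTIFIED:
    - [Analytical_sample, Protein]
    - [Analytical_sample, Peptide]
    - [Analytical_sample, Modified_protein]
    - [Biological_sample, Clinical_variable]
  HAS_ENROLLED:
    - [Project, Subject]
  BELONGS_TO_SUBJECT:
    - [Biological_sample, Subject]
  SPLITTED_INTO:
    - [Biological_sample, Analytical_sample]
  STUDIES_DISEASE:
    - [Project, Disease]
  STUDIES_TISSUE:
    - [Project, Tissue]
  STUDIES_INTERVENTION:
    - [Project, Intervention]
  ASSOCIATED_WITH:
    - [Protein, Disease]
    - [Protein, Biological_process]
    - [Protein, Molecular_function]
    - [Protein, Cellular_component]
    - [Metabolite, Disease]
    - [Biological_process, Metabolite]
  ANNOTATED_IN_PATHWAY:
    - [Protein, Pathway]
    - [Metabolite, Pathway]
  ACTS_ON:
    - [Drug, Protein]
  HAS_SIDE_EFFECT:
    - [Drug, Side_effect]
  MENTIONED_IN_PUBLICATION:
    - [Protein, Publication]
    - [Drug, Publication]
    - [Disease, Publication]
    - [Tissue, Publication]
    - [Functional_region, Publication]
  IS_SUBSTRATE_OF:
    - [Protein, Protein]
    - [Modified_protein, Protein]
  IS_SUBUNIT_OF:
    - [Protein, Complex]
  CURATED_INTERACTS_WITH:
    - [Protein, Protein]
  COMPILED_INTERACTS_WITH:
    - [Protein, Protein]
  TRANSLATED_INTO:
    - [Transcript, Protein]
  TRANSCRIBED_INTO:
    - [Gene, Transcript]
  LOCATED_IN:
    - [Gene, Chromosome]
  HAS_MODIFICATION:
    - [Modified_protein, Modification]
  HAS_MODIFIED_SITE:
    - [Protein, Modified_protein]
  DETECTED_IN_PATHOLOGY_SAMPLE:
    - [Protein, Disease]
  EXPRESSED_IN:
    - [Protein, Tissue]
  HAS_SEQUENCE:
    - [Protein, Amino_acid_sequence]
  HAS_STRUCTURE:
    - [Protein, Protein_structure]
  VARIANT_FOUND_IN_GENE:
    - [Known_variant, Gene]
  VARIANT_FOUND_IN_CHROMOSOME:
    - [Known_variant, Chromosome]
  VARIANT_IS_CLINICALLY_RELEVANT:
    - [Known_variant, Clinically_relevant_variant]
  ASSOCIATED_WITH_INTEGRATED:
    - [Protein, Disease]
  HAS_CLINICAL_STATE:
    - [Subject, Phenotype]
  HAS_DISEASE:
    - [Subject, Disease]
  SAMPLE_AT_TIMEPOINT:
    - [Biological_sample, Timepoint]
  TARGETS_CLINICALLY_RELEVANT_VARIANT:
    - [Drug, Clinically_relevant_variant]
  IS_INDICATED_FOR:
    - [Drug, Disease]
  INTERACTS_WITH_DRUG:
    - [Drug, Drug]
  HAS_GWAS_HIT:
    - [GWAS_study, Known_variant]
  PUBLISHED_IN:
    - [GWAS_study, Publication]
  FOUND_IN_FOOD:
    - [Metabolite, Food]
  HAS_EXPERIMENTAL_FACTOR:
    - [Project, Experimental_factor]
  MAPS_TO:
    - [Experimental_factor, Disease]
    - [Clinical_variable, Phenotype]
  HAS_UNIT:
    - [Clinical_variable, Units]
  CREATED_BY:
    - [Project, User]
  IS_SIMILAR_TO:
    - [Project, Project]
  BELONGS_TO_PROTEIN:
    - [Peptide, Protein]
  HAS_FUNCTIONAL_REGION:
    - [Protein, Functional_region]
  IS_BIOMARKER_OF:
    - [Protein, Disease]

# node label -> attribute names that must be present on every node of that
# label (empty by default; projects may ship stricter schemas)
required_attributes: {}
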