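{
  "_comment": [
    "Editable grouping template for collapsing Allen structure-graph leaf",
    "regions into reporting regions and summary categories.  Pass the two",
    "maps to load_ontology(leaf_to_reporting=..., reporting_to_summary=...)",
    "after replacing acronyms with the integer ids of your structure graph.",
    "Only groupings with published precedent are filled in; entries marked",
    "EDIT-ME must be curated for the structure graph revision in use."
  ],
  "reporting_to_summary_by_acronym": {
    "SPIV": "vestibular",
    "MV": "vestibular",
    "LAV": "vestibular",
    "SUV": "vestibular",
    "MDRNd": "medullary reticular",
    "MDRNv": "medullary reticular",
    "GRN": "gigantocellular",
    "MARN": "magnocellular",
    "PGRNl": "paragigantocellular",
    "RN": "red nucleus",
    "PPN": "pedunculopontine",
    "PVH": "paraventricular hypothalamus",
    "PVHd": "paraventricular hypothalamus",
    "LHA": "lateral hypothalamus",
    "DMH": "lateral hypothalamus",
    "BAR": "pontine central gray",
    "LC": "pontine central gray",
    "LDT": "pontine central gray",
    "PB": "parabrachial",
    "NTS": "solitary",
    "EW": "midline midbrain",
    "INC": "midline midbrain",
    "MOp": "corticospinal",
    "MOs": "corticospinal",
    "SSp": "EDIT-ME",
    "MRN": "EDIT-ME"
  }
}
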