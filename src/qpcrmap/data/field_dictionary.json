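{
  "required": {
    "run_location": "Alphanumeric qPCR well name identifying the sample's position on the plate or cartridge (e.g. A1). Primary key joining metadata to raw fluorescence.",
    "run_platform": "The qPCR platform that generated the raw fluorescence output (e.g. mic, biomeme2, biomeme3).",
    "threshold": "User-supplied fluorescence threshold (instrument units, > 0) used to calculate the threshold cycle (Ct) for this well.",
    "organismScope": "The target organism scope: a discrete organism or a kind of organism aggregation (e.g. 'virus', 'multicellular organism').",
    "eventDate": "Collection date of the biological sample, ISO 8601 (YYYY-MM-DD). Darwin Core term.",
    "decimalLatitude": "Sample collection GPS latitude in decimal degrees, [-90, 90]. Darwin Core term.",
    "decimalLongitude": "Sample collection GPS longitude in decimal degrees, [-180, 180]. Darwin Core term. The alias spelling 'decimalLongtitude' is accepted on input.",
    "taxonID": "NCBI Taxonomy identifier of the assay target (positive integer), or a user-created token for higher-taxon assays.",
    "species": "Target assay species in 'Genus species' format, or a user-created unique identifier for higher-taxon assays (set is_higher_taxon)."
  },
  "optional": {
    "is_higher_taxon": "Boolean flag; when true the assay targets a higher-level taxon and the 'Genus species' shape check on species is skipped.",
    "recordedBy": "Sample collector name(s). Darwin Core term.",
    "vernacularName": "Common name of the target species. Darwin Core term."
  },
  "notes": "Unknown extra columns are preserved verbatim on valid records and carried into the merged table."
}
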