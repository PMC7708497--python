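# Workbook column alias map: canonical name -> list of header spellings.
# Edit or extend to match the headers of a supplementary ranking workbook;
# matching is case-insensitive on the stripped header text.  Entries here
# are merged over the built-in defaults.
gene_symbol:
  - "Gene name"
  - "Gene Symbol"
cardiac_enriched:
  - "Cardiac enriched (BioGPS >=3-fold)"
has_cardiac_phenotype:
  - "MGI cardiac phenotype"
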