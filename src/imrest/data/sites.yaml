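# ICD-10 site groupings used for the Granada-style six-sites-per-sex analysis.
# Editable: labels must match the `site` column of input count tables.
aggregate_label: "all sites (except non-melanoma skin)"
sites:
  male:
    stomach: ["C16"]
    colon: ["C18"]
    rectum: ["C19-C20"]
    lung: ["C33-C34"]
    prostate: ["C61"]
    bladder: ["C67", "D09.0", "D41.4"]
    others: ["C00-C15", "C17", "C21-C32", "C35-C43", "C45-C60", "C62-C66", "C68-C96"]
  female:
    colon: ["C18"]
    rectum: ["C19-C20"]
    lung: ["C33-C34"]
    breast: ["C50"]
    corpus uteri: ["C54"]
    ovary: ["C56"]
    others: ["C00-C17", "C21-C32", "C35-C43", "C45-C49", "C51-C53", "C55", "C57-C96"]
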