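# Endpoint display metadata for systematic ADMET profiles.
# Generic suggestion/reference texts; users may extend or replace this file.
logS:
  unit: "log mol/L"
  suggestion: "Aqueous solubility; values above -4 are generally acceptable for oral drugs."
  reference: "Aqueous solubility modeling literature."
logD:
  unit: "log units (pH 7.4)"
  suggestion: "Distribution coefficient at physiological pH; 1-3 is a common target window."
  reference: "Lipophilicity and permeability guidelines."
caco2:
  unit: "log cm/s"
  suggestion: "Caco-2 permeability; higher values indicate better intestinal absorption."
  reference: "Caco-2 permeability assay literature."
hia:
  suggestion: "Human intestinal absorption; '+' favors good oral absorption."
  reference: "HIA classification datasets."
bbb:
  suggestion: "Blood-brain barrier penetration; '+' predicts CNS exposure."
  reference: "BBB permeation datasets."
herg:
  suggestion: "hERG channel blockade; '+' flags cardiotoxicity risk."
  reference: "hERG inhibition screening literature."
ames:
  suggestion: "Ames mutagenicity; '+' flags a mutagenic prediction."
  reference: "Ames test datasets."
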