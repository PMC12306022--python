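{
  "_comment": "Residue component name -> one-letter parent base. Users may extend this table to support additional modified nucleotides without code changes. Parent bases A/G are purines (triad atoms N9, C2, C6); C/U/T are pyrimidines (triad atoms N1, C2, C4).",
  "components": {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T", "I": "G",
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "G",
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "OMU": "U", "UR3": "U",
    "5BU": "U", "DHU": "U", "70U": "U", "3AU": "U", "S4U": "U",
    "1MA": "A", "2MA": "A", "6MA": "A", "MA6": "A", "A2M": "A", "RIA": "A",
    "12A": "A", "T6A": "A", "MIA": "A", "A23": "A", "AP7": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "CBV": "C", "5IC": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G",
    "G7M": "G", "QUO": "G", "GTP": "G", "GDP": "G", "G46": "G", "23G": "G",
    "ATP": "A", "ADP": "A", "AMP": "A", "CTP": "C", "UTP": "U",
    "5FU": "U", "CM0": "U", "UMS": "U", "OMT": "T"
  }
}
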