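{
  "_comment": "Synthetic canned similarity-search responses shaped like PUG-REST property tables; hand-written for offline tests, not downloaded data.",
  "similar_to_benzoic_acid": {
    "query": "OC(=O)c1ccccc1",
    "PropertyTable": {
      "Properties": [
        {"CID": 1001, "CanonicalSMILES": "OC(=O)c1ccccc1"},
        {"CID": 1002, "CanonicalSMILES": "COC(=O)c1ccccc1"},
        {"CID": 1003, "CanonicalSMILES": "CCOC(=O)c1ccccc1"},
        {"CID": 1004, "CanonicalSMILES": "OC(=O)c1ccccc1C"},
        {"CID": 1005, "CanonicalSMILES": "OC(=O)c1ccc(C)cc1"},
        {"CID": 1006, "CanonicalSMILES": "NC(=O)c1ccccc1"},
        {"CID": 1007, "CanonicalSMILES": "OCc1ccccc1"},
        {"CID": 1008, "CanonicalSMILES": "OC(=O)c1ccc(Cl)cc1"},
        {"CID": 1009, "CanonicalSMILES": "not_a_smiles"},
        {"CID": 1010, "CanonicalSMILES": "O=Cc1ccccc1"}
      ]
    }
  },
  "empty": {
    "query": "CCO",
    "PropertyTable": {"Properties": []}
  }
}
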