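{
  "source": "pubchem",
  "inchikey": "LFQSCWFLJHTTHZ-UHFFFAOYSA-N",
  "hit": true,
  "cid": 702,
  "iupac_name": "ethanol",
  "canonical_smiles": "CCO",
  "cas": ["64-17-5", "8024-45-1"],
  "query_date": "2017-09-25"
}
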