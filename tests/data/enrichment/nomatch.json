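{
  "source": "pubchem",
  "inchikey": "ZZZZZZZZZZZZZZ-UHFFFAOYSA-N",
  "hit": false,
  "query_date": "2017-09-25"
}
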