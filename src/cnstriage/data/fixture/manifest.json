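{
  "sha256": {
    "samples.tsv": "fc9c446ba10d42e9b62cdb0126042ea1a04261942281454297fe9810e27de78f",
    "findings.tsv": "24e5958ff4a48210b44049e959eb0b4b8d5f3ffc0f6dbecddb87d853ca627978",
    "gene_modes.tsv": "35048d42454f43e358303aec4a7034b6f026dc4db30b82a8ec6e9f2115e27a7e",
    "metadata.json": "a7d0ccc844266cd7faadf1fc80ad705fccc04d4e3ce366f0d007c1f56063e881"
  }
}
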