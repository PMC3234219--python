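{
  "lipg_carriers.tsv": "ae5fc19ec9f5489602df0f67812790b02faaaf4037dd7f17a427c20143e7bf6c",
  "lipg_cohorts.tsv": "74e99763a9f8f046520c2d036890b6765f1475ea3e1668670bd8c089223b9496",
  "lipg_common_variants.tsv": "bda2a29eba89d628d7bc5bb17745cecd8a9eb1d82302500a7e6e230403f8b511",
  "lipg_functional_calls.tsv": "f9be25b9b353de9a534bf0c22046cb144209a13cda4e774f5ff9af443f743b6c",
  "lipg_rare_variants.tsv": "f84bcd46aa96766070d9306f3e512a21acc44b557e8a1ced2bc1f4fc7e7439a5"
}
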