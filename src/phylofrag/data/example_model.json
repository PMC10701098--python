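{
  "comment": "Example configuration: an eight-species Neotropical small-cat radiation with a puma-like outgroup. Node depths (in generations, 3.8 yr/generation) follow whole-genome divergence-time estimates for the ocelot lineage; Ne values are illustrative. The two pulses emulate the strong inferred exchanges between Geoffroy's cat and the southern tiger cat and from the ancestral small-cat clade into the ocelot.",
  "newick": "(puma:2105263,((ocelot:1063158,(margay:978947,andean_cat:978947)marg_and:84211)ocelot_lineage:107895,(pampas_cat:1007895,(clouded_tiger_cat:628947,((geoffroys_cat:426316,guigna:426316)geo_gui:73684,s_tiger_cat:500000)onc_core:128947)oncifelis:378948)pam_onc:163158)genus:934210)root;",
  "ne": {
    "default": 60000,
    "ocelot": 120000,
    "andean_cat": 15000,
    "root": 80000
  },
  "mu": 0.86e-8,
  "gen_time": 3.8,
  "edges": [
    {"donor": "geoffroys_cat", "recipient": "s_tiger_cat", "time": 26316, "gamma": 0.33},
    {"donor": "oncifelis", "recipient": "ocelot", "time": 657895, "gamma": 0.32}
  ]
}
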