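{
  "name": "calibrated_human_3pop",
  "comment": "Best-fit calibrated three-population human demographic model (African YRI, European CEU, East Asian AS). Times are generations before present; sizes are diploid effective sizes; bottleneck strength is the probability that a pair of lineages coalesces during the event (inbreeding intensity); migration rates are per chromosome per generation and are switched off before the Eurasian split.",
  "populations": [
    {"name": "YRI", "size": 100000},
    {"name": "CEU", "size": 100000},
    {"name": "AS", "size": 100000}
  ],
  "migration": [
    {"from": "YRI", "to": "CEU", "rate": 3.2e-05},
    {"from": "CEU", "to": "YRI", "rate": 3.2e-05},
    {"from": "YRI", "to": "AS", "rate": 8.0e-06},
    {"from": "AS", "to": "YRI", "rate": 8.0e-06}
  ],
  "events": [
    {"time": 200, "kind": "size_change", "pop": "YRI", "size": 24000, "comment": "pre-agriculture African size"},
    {"time": 350, "kind": "size_change", "pop": "CEU", "size": 7700, "comment": "pre-expansion European size"},
    {"time": 400, "kind": "size_change", "pop": "AS", "size": 7700, "comment": "pre-expansion Asian size"},
    {"time": 1995, "kind": "migration_off"},
    {"time": 1997, "kind": "bottleneck", "pop": "YRI", "strength": 0.008},
    {"time": 1998, "kind": "bottleneck", "pop": "AS", "strength": 0.067},
    {"time": 1999, "kind": "bottleneck", "pop": "CEU", "strength": 0.02},
    {"time": 2000, "kind": "split", "pop": "AS", "dest": "CEU", "comment": "Eurasian split: Asian lineages join the European branch"},
    {"time": 3499, "kind": "bottleneck", "pop": "CEU", "strength": 0.085, "comment": "out-of-Africa bottleneck"},
    {"time": 3500, "kind": "split", "pop": "CEU", "dest": "YRI", "comment": "out-of-Africa split"},
    {"time": 17000, "kind": "size_change", "pop": "YRI", "size": 12500, "comment": "ancestral African size"}
  ]
}
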