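{
  "_comment": "Expected rostrocaudal innervation ranges (inclusive) per muscle, from intraoperative nerve-root stimulation literature. Editable: substitute your own table via projectome functions' `expected` argument.",
  "TA": ["L4", "S1"],
  "Gas": ["L4", "S2"],
  "Qd": ["L1", "L4"],
  "Il": ["L1", "L4"],
  "BF": ["L5", "S2"],
  "GMax": ["L5", "S2"]
}
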