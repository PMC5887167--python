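# China cost scenario, 2016 USD.
# Transition probabilities are monthly; each entry carries the published
# base value and one-way sensitivity range.  Model settings are the
# calibrated reproduction conventions (see docs/methods.md).
country: China
wtp_usd_per_qaly: 24840.27   # 3x per-capita GDP
tace_sessions_per_cycle: 1.0
model:
  cycles: 24
  annual_discount_rate: 0.03
  cycle_counting: half
  discount_per_cycle: true
  discount_offset: 1
parameters:
  prob.tace.die_no_prog:            {base: 0.1150, low: 0.0704, high: 0.1371}
  prob.tace.progress:               {base: 0.1946, low: 0.1946, high: 0.3057}
  prob.tace.decomp:                 {base: 0.0240, low: 0.0130, high: 0.0350}
  prob.tace.die_post_prog:          {base: 0.1120, low: 0.0943, high: 0.3196}
  prob.sorafenib_full.die_no_prog:  {base: 0.0690, low: 0.0690, high: 0.1895}
  prob.sorafenib_full.progress:     {base: 0.1319, low: 0.1184, high: 0.2264}
  prob.sorafenib_adjusted.die_no_prog: {base: 0.0650, low: 0.0452, high: 0.0850}
  prob.sorafenib_adjusted.progress: {base: 0.0726, low: 0.0561, high: 0.1026}
  prob.sorafenib.decomp:            {base: 0.0090, low: 0.0060, high: 0.0140}
  prob.sorafenib.die_post_prog:     {base: 0.1399, low: 0.0997, high: 0.2264}
  prob.common.die_decomp:           {base: 0.1900, low: 0.1091, high: 0.3196}
  cost.tace.per_session:            {base: 3347.97, low: 1673.99, high: 6695.95}
  cost.sorafenib_full.initial:      {base: 7600.38, low: 3800.19, high: 15200.76}
  cost.sorafenib_full.later:        {base: 15.06, low: 7.53, high: 30.11}
  cost.sorafenib_adjusted.initial:  {base: 3807.72, low: 1903.86, high: 7615.43}
  cost.sorafenib_adjusted.later:    {base: 15.06, low: 8.03, high: 32.11}
  cost.state.comp_no_prog:          {base: 344.14, low: 172.07, high: 688.29}
  cost.state.comp_prog:             {base: 247.43, low: 123.71, high: 494.86}
  cost.state.decomp:                {base: 1131.82, low: 565.91, high: 2263.65}
  utility.comp_no_prog:             {base: 0.76, low: 0.76, high: 0.80}
  utility.comp_prog:                {base: 0.68, low: 0.60, high: 0.68}
  utility.decomp:                   {base: 0.57, low: 0.46, high: 0.68}
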