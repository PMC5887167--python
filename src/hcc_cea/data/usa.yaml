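# USA cost scenario, 2016 USD.  Transition probabilities and utilities are
# shared with the China scenario; only costs and the WTP threshold differ.
# The post-assistance sorafenib price of $1.2/month is the published value,
# used verbatim.
country: USA
wtp_usd_per_qaly: 50000.0
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
  cost.tace.per_session:            {base: 25961.00, low: 12980.50, high: 51922.00}
  cost.sorafenib_full.initial:      {base: 4592.40, low: 2296.20, high: 9184.80}
  cost.sorafenib_full.later:        {base: 1.20, low: 0.60, high: 2.40}
  cost.sorafenib_adjusted.initial:  {base: 2296.20, low: 1148.10, high: 4592.40}
  cost.sorafenib_adjusted.later:    {base: 1.20, low: 0.60, high: 2.40}
  cost.state.comp_no_prog:          {base: 61.00, low: 30.00, high: 122.00}
  cost.state.comp_prog:             {base: 8072.00, low: 4036.00, high: 16144.00}
  cost.state.decomp:                {base: 1519.00, low: 759.50, high: 3038.00}
  utility.comp_no_prog:             {base: 0.76, low: 0.76, high: 0.80}
  utility.comp_prog:                {base: 0.68, low: 0.60, high: 0.68}
  utility.decomp:                   {base: 0.57, low: 0.46, high: 0.68}
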