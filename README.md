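# hcc-cea

Markov cohort cost-effectiveness analysis of first-line treatment for
advanced hepatocellular carcinoma (BCLC stage C, Child-Pugh A/B):
**full-dose sorafenib**, **dose-adjusted sorafenib**, and **TACE**
(transarterial chemoembolization), under China and USA cost scenarios.
It is written for health-economics and clinical-research users who want a
tested, scriptable reimplementation of this published decision model —
and a reusable four-state cohort engine with one-way/two-way sensitivity
analysis and probabilistic sensitivity analysis (PSA) around it.

## The model

A cohort of patients starts in compensated cirrhosis without tumour
progression and moves monthly between four states — progression-free,
progressed, decompensated cirrhosis, death — for 24 one-month cycles.
Monthly transition probabilities come from published survival summaries
via the constant-hazard (DEALE) conversion `p = 1 - exp(-ln2/m)` for a
median of `m` months, or from random-effects pooling of study-level
proportions on the Freeman-Tukey double-arcsine scale (DerSimonian-Laird
weights, Miller back-transformation, Wilson per-study intervals).

Per cycle `t`, with occupancy weight `w`, utilities `u`, state costs `c`
and discount `d(t)`:

    LY    += sum_s w_s(t) * d(t)                  [alive states, months]
    QALY  += sum_s w_s(t) * u_s / 12 * d(t)
    Cost  += (sum_s w_s(t) * c_s + w_pf(t) * treatment(t)) * d(t)

Strategies are compared by `ICER = dC/dE` ($/QALY) and net monetary
benefit `NMB = WTP * E - C`, with willingness-to-pay thresholds
$24,840.27/QALY (China, 3x per-capita GDP) and $50,000/QALY (USA).
The PSA draws beta (probabilities, utilities) and gamma (costs)
distributions centred on the base case and reports acceptability curves
and median ICER intervals.  Counting and discounting conventions are
explicit, switchable, and calibrated against the published base case
(see `docs/methods.md`).

## Worked example

```python
from hcc_cea import load_builtin, incremental_table

china = load_builtin("china")
for strategy, (trace, res) in china.run().items():
    print(f"{strategy:22s} cost ${res.lifetime_cost:9,.0f}  "
          f"LYG {res.lyg_months:.3f} mo  QALY {res.qaly_years:.4f}")
for c in china.incremental():
    print(f"{c.comparator} vs {c.reference}: dC {c.delta_cost:+,.0f}, "
          f"dE {c.delta_qaly:+.4f}, ICER {c.icer:,.0f} ({c.status})")
```

prints

```
tace                   cost $    9,999  LYG 6.441 mo  QALY 0.3779
sorafenib_full         cost $   18,374  LYG 7.267 mo  QALY 0.4358
sorafenib_adjusted     cost $   11,608  LYG 7.942 mo  QALY 0.4836
sorafenib_full vs tace: dC +8,375, dE +0.0579, ICER 144,700 (none)
sorafenib_adjusted vs sorafenib_full: dC -6,766, dE +0.0478, ICER -141,537 (dominant)
sorafenib_adjusted vs tace: dC +1,608, dE +0.1057, ICER 15,220 (none)
```

Read: dose-adjusted sorafenib yields the most quality-adjusted survival
(0.484 QALYs vs 0.436 full-dose and 0.378 TACE — the published values
are 0.482/0.435/0.375) and *dominates* full-dose sorafenib in China
(more effect, less cost).  Against TACE it costs $15,220 per QALY, well
under the Chinese threshold; full-dose sorafenib versus TACE, at
~$145k/QALY, is not cost-effective at that threshold.

The numbered drivers under `analysis/` run the full study — convention
calibration, base case, tornado + crossover thresholds, two-way grids,
and the 10,000-draw PSA with acceptability curves — writing tidy tables
under `results/`.  The same operations are available from the shell:

```sh
hcc-cea run-base --country china --out results
hcc-cea psa --country usa --n 10000 --seed 0 --out results
hcc-cea tornado --country china --out results
```

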