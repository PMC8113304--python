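# pollenhq

Season-long screening analysis of pesticide residues in **daily bee
pollen samples**: quality control, pollen-hazard-quotient scoring,
persistence and co-application analysis, and quantification of the
dilution bias hidden in pooled sampling designs.

Honey bee colonies collect pollen from sprayed agricultural landscapes,
and nurse bees eat it. Monitoring programmes usually analyse pollen
pooled over weeks or whole seasons, which averages away the short,
intense spray-event pulses that dominate actual exposure. `pollenhq` is
built for the daily-resolution case: a residue matrix (days × analytes,
left-censored at each analyte's limit of quantification) plus a panel of
analyte properties (class, LOQ, spike recovery, acute oral LD₅₀).

The core score is the **pollen hazard quotient**

    PHQ = c / LD50        c  — residue concentration (ng/g pollen, ppb)
                          LD50 — honey-bee acute oral LD50 (μg/bee)

with **PHQmax** = PHQ at the season's maximum concentration per analyte,
and **tPHQday** = Σ PHQ over one daily sample; days with tPHQday > 50
count as *relevant* for bee health. At a nurse-bee consumption of
9.5 mg bee bread/day, PHQ = 100 corresponds to ≈0.1% of the LD₅₀
ingested per day. The package also extracts gap-tolerant **detection
runs** (spray-event persistence periods with peak timing), scores
analyte pairs for **co-application** (shared formulations show
proportional concentration profiles), computes **pooling dilution
factors** (daily maximum ÷ pooled mean), and ships a seeded
**synthetic spray-event generator** with ground-truth reporting for
method validation.

## Worked example

```python
from pollenhq import phq, round_sigfigs, ld50_fraction
from pollenhq.datasets import load_panel_table

row = load_panel_table().loc["Tebuconazole"]
print(round_sigfigs(phq(row.max_conc_ng_g, row.ld50_ug_bee), 2))
# 55.0   — PHQmax of the season's highest residue (4530 ng/g, LD50 83)

daily, period = ld50_fraction(100.0)
print(daily, period)
# 0.095 0.95   — % of LD50 per day / per 10-day nursing period at PHQ 100
```

A full synthetic season through the whole pipeline:

```python
from pollenhq import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(synthetic="paper_like", seed=1))
print(bundle.summary["n_analytes_detected"],
      bundle.summary["samples_without_residues"],
      bundle.summary["n_relevant_days"])
# 29 5 19  — detected analytes, residue-free days, days with tPHQday > 50
```

The `examples/` directory holds one narrative script per capability
(hazard arithmetic, season simulation, detection runs, pooling
dilution, full pipeline); `examples/run_config.yaml` is a complete run
configuration with every default explicit. The same pipeline is
available from the shell:

```sh
pollenhq simulate --seed 1 --out season.csv
pollenhq validate --matrix season.csv
pollenhq run --config examples/run_config.yaml
```

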