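# Example run configuration with every default made explicit.
# Run with:  pollenhq run --config examples/run_config.yaml
synthetic: paper_like        # or give `matrix: path/to/residues.csv` instead
seed: 1
output_dir: pipeline_out
qc:
  recovery_accept_lo: 30     # % recovery below which an analyte is flagged
  recovery_accept_hi: 160
  recovery_exclude_below: 10 # below this, concentrations are masked
hazard:
  relevance_threshold: 50    # tPHQday above this (strict) marks a relevant day
  consumption_mg_day: 9.5    # nurse-bee bee-bread consumption
  nursing_period_days: 10
  report_sigfigs: 2
gap_tolerance: 1             # ND days bridged inside a detection run
windows: ["k_day:10", "calendar_month"]
coapplication_pairs:
  - ["Fluopyram", "Tebuconazole"]
  - ["Fluopyram", "Trifloxystrobin"]
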