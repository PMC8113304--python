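"""Persistence periods and co-application evidence.

Extracts gap-tolerant detection runs (one ND day bridged) for the two
co-applied fungicides of the synthetic season and scores the pair: a
shared formulation shows up as correlation near 1 and a small
concentration-ratio CV.
"""

from pollenhq import generate_series, paper_like_spec
from pollenhq.temporal import coapplication, detect_runs, peak_timing_summary

series, _ = generate_series(paper_like_spec(seed=1))

runs = []
for analyte in ("Tebuconazole", "Fluopyram"):
    for run in detect_runs(series, analyte, gap_tolerance=1):
        runs.append(run)
        print(f"{analyte:<13} D{run.start_day}-D{run.end_day} "
              f"peak {run.peak_conc:7.1f} ng/g on D{run.peak_day} "
              f"(to peak {run.days_to_peak} d, clearance "
              f"{run.days_to_clearance} d, gaps {run.internal_gaps})")

timing = peak_timing_summary(runs)
print(f"\nfraction of runs peaking within 5 days of onset: "
      f"{timing['fraction_peak_within']:.2f}")

score = coapplication(series, "Fluopyram", "Tebuconazole")
print(f"co-application over {score.shared_detection_days} shared days: "
      f"log-corr {score.concentration_correlation:.3f}, "
      f"ratio CV {score.ratio_cv:.3f}")
# On days where both analytes stem from one co-applied event the ratio CV
# approaches sqrt(2) x noise (~0.14 at 10% noise); coincidental shared days
# (background traces during the partner's solo event) inflate it, which is
# exactly the signal separating formulations from coincidence.
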