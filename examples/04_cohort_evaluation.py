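"""Score a cohort: DSC/ICC summaries, volume subgroups and rank-sum tests.

Builds per-case results (as the segmentation pipeline would emit them) with a
deliberate size-dependent accuracy gradient and a mild volumetric bias, and
prints the cohort report: ICC(2,1) across folds, DSC across cases, subgroup
tables, and which subgroup contrasts reach significance.
"""

import numpy as np

from mvseg import CaseResult, evaluate_cohort
from mvseg.evaluation import report_to_text, volume_group
from mvseg.volume_io import Location

rng = np.random.default_rng(7)
results = []
for i in range(60):
    ref = float(rng.uniform(0.5, 25.0))
    group = volume_group(ref)
    # larger tumors segment better; prediction overestimates volume slightly
    base = {"V1": 0.35, "V2": 0.48, "V3": 0.58, "V4": 0.64}[group.name]
    results.append(CaseResult(
        case_id=f"case-{i:03d}",
        dsc=float(np.clip(rng.normal(base, 0.08), 0, 1)),
        ref_volume_cm3=ref,
        pred_volume_cm3=float(max(0.0, ref * 1.25 + rng.normal(0, 2.0))),
        fold=i % 5,
        t_stage=("T2", "T3", "T4")[i % 3],
        n_stage=("N0", "N1", "N2")[(i // 2) % 3],
        location=list(Location)[i % 3],
    ))

report = evaluate_cohort(results, alpha=0.05)
print(report_to_text(report))
print("\nAbsolute-agreement ICC sits below 1 despite the high correlation "
      "because the predictions systematically overestimate volume; the "
      "volume-group contrasts show the size dependence of spatial accuracy.")
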