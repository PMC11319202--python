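"""Quality control a cohort of blows and extract expert features.

Runs the full spirogram preparation: finite-difference flow, length
normalization, cohort percentile bands, and the per-blow QC gates; then
extracts FEV1/FVC/PEF-style features and prints the failure breakdown.
"""

from collections import Counter

from regle.features import spirogram_edf_table, spirogram_edfs
from regle.preprocess import qc_spirogram, spirogram_cohort_stats
from regle.synthgen import SimConfig, simulate_cohort

cohort = simulate_cohort(
    SimConfig(n_individuals=1500, n_variants=50, causal_per_factor=5, seed=3)
)
n = cohort.config.n_individuals

volumes = [cohort.volume_record(i) for i in range(n)]
flows = [cohort.flow_record(i) for i in range(n)]
edfs = [spirogram_edfs(v, f) for v, f in zip(volumes, flows)]

stats = spirogram_cohort_stats(
    [e.fev1 for e in edfs], [e.fvc for e in edfs], [e.pef for e in edfs]
)
reports = [qc_spirogram(f, v, e, stats) for f, v, e in zip(flows, volumes, edfs)]

passed = sum(r.passed for r in reports)
print(f"{passed}/{n} blows pass QC")
reasons = Counter(reason for r in reports for reason in r.reasons)
print("failure reasons:", dict(reasons))
# Failures concentrate in the simulated corrupted blows (weak efforts,
# overshoots, early terminations, device rejections); clean blows pass.

table = spirogram_edf_table([e for e, r in zip(edfs, reports) if r.passed])
print(table.describe().loc[["mean", "std"]].round(3))
# FEV1 and FVC are in liters, PEF and FEF25-75% in liters/second.
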