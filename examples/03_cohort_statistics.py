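"""Group statistics on a synthetic cohort drawn at the study's parameters.

Generates 32 PPE-like and 30 control-like eyes from the configured group
distributions and reproduces the report tables: mean ± sd (range) per
group, unpaired t-test p, and the age/sex-adjusted p from partial
correlation; chi-square for the sex ratio.
"""

from ccflow import generate_cohort, run_table_reports
from ccflow.stats import render_report_markdown
from ccflow.synthetic import CohortParams

cohort = generate_cohort(CohortParams(seed=5))
report = run_table_reports(cohort)
print(render_report_markdown(report))

p = report["flow_voids"]["total_void_area_mm2"]
print(f"total void area: p = {p['p']:.2e}, age/sex-adjusted p = {p['p_adj']:.2e}")
# Both p-values fall far below 0.001: at these effect sizes (1.16 vs 0.91
# mm^2, sd ~0.17) the group difference is detectable at n = 32 + 30.
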