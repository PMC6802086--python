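"""Cohort-manifest arithmetic of the study that defined the panel.

Builds the per-sample manifest from the published cohort table and
recomputes the group totals by summation.
"""

import ctcpanel as cp
from ctcpanel import cohorts

manifest = cohorts.study_manifest()
report = cp.validate_manifest(manifest, {"total": 5028})

print(f"discovery stage:        {cohorts.group_total(manifest, cohorts.DISCOVERY_GROUPS)} samples")
print(f"breast validation:      {cohorts.group_total(manifest, cohorts.BREAST_VALIDATION_GROUPS)} samples")
print(f"pancreatic CTC set:     {cohorts.group_total(manifest, 'validation_pancreatic_ctc')} samples")
print(f"grand total:            {report['total']} samples  (mismatches: {report['mismatches']})")
print(f"tissue classes: {report['per_tissue_class']}")
# 859 discovery + external and experimental validation cohorts sum to 5028.
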