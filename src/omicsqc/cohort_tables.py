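"""Published summary strata of the MSBB Alzheimer's disease cohort.

Small reference tables used for arithmetic consistency checks: the
demographic breakdown by Clinical Dementia Rating (CDR) and the whole-genome
sequencing sample counts by diagnostic group.  Stratum counts must
reconcile with the cohort totals (364 donors, 238 female / 126 male; 349
WGS samples).
"""

from __future__ import annotations

import pandas as pd

#: Donors per CDR stratum: CDR 0 (no dementia) .. 5 (terminal).
DEMOGRAPHICS_BY_CDR = pd.DataFrame(
    {
        "cdr": [0, 0.5, 1, 2, 3, 4, 5],
        "n": [44, 47, 38, 49, 78, 47, 61],
        "female": [32, 24, 26, 31, 56, 30, 39],
        "male": [12, 23, 12, 18, 22, 17, 22],
    }
).set_index("cdr")

COHORT_TOTALS = {"donors": 364, "female": 238, "male": 126}

#: WGS sample counts by diagnostic group.
WGS_SAMPLES_BY_GROUP = pd.Series(
    {"AD": 258, "MCI": 43, "Control": 40, "Unclassified": 8}, name="n_samples"
)

WGS_TOTAL_SAMPLES = 349
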