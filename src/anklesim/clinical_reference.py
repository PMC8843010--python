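"""Published summary statistics of the in-bed ankle-robot hemiplegia trial.

The two-arm clinical study this simulator emulates published only group
summaries (counts, mean ± SD rows, and ANOVA F statistics), not individual
data.  Those printed summaries are entered here as literal inputs for the
statistics layer — e.g., to re-derive the baseline-comparability p-values
from the counts, or partial η² and p from a printed interaction F with its
degrees of freedom.
"""

from .stats import SummaryStat

N_PER_GROUP = 9

# 2x2 count tables, rows = (study, control)
GENDER_TABLE = [[7, 2], [4, 5]]            # men / women
AFFECTED_SIDE_TABLE = [[5, 4], [8, 1]]     # left / right

# mean ± SD rows (study, control)
AGE = (SummaryStat(58.2, 12.1, 9), SummaryStat(55.6, 18.9, 9))
TIME_POST_STROKE = (SummaryStat(28.0, 19.0, 9), SummaryStat(25.0, 17.0, 9))
TRAINING_SESSIONS = (SummaryStat(13.0, 3.0, 9), SummaryStat(10.0, 9.0, 9))
AROM_BASELINE = (SummaryStat(0.38, 0.79, 9), SummaryStat(0.39, 0.69, 9))
AROM_POST = (SummaryStat(9.15, 7.65, 9), SummaryStat(1.75, 1.90, 9))
PF_MVC_BASELINE = (SummaryStat(0.13, 0.21, 9), SummaryStat(0.13, 0.13, 9))
PF_MVC_POST = (SummaryStat(2.63, 2.18, 9), SummaryStat(0.47, 0.47, 9))
DF_MVC_BASELINE = (SummaryStat(0.13, 0.10, 9), SummaryStat(0.10, 0.11, 9))
DF_MVC_POST = (SummaryStat(0.59, 0.79, 9), SummaryStat(0.15, 0.08, 9))

# printed group x time interaction F statistics, all on df (1, 16)
INTERACTION_F = {
    "fmle": 9.653,
    "arom": 8.273,
    "pf_mvc": 8.878,
}
INTERACTION_DF = (1, 16)

# published KM summary for plantarflexion recovery in the study arm
PF_KM_MEDIAN_STUDY_DAYS = 7.0

# sample-size statement: f = 0.25, alpha 0.05, power 0.80, 10% attrition
SAMPLE_SIZE_EFFECT_F = 0.25
SAMPLE_SIZE_ALPHA = 0.05
SAMPLE_SIZE_POWER = 0.80
SAMPLE_SIZE_ATTRITION = 0.10
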