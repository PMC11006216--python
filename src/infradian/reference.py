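"""Published 8-sector onset-count tables used as validation fixtures.

Two large cohort studies of natural menstrual cycles — a merged European
database (26,912 cycles from 2,303 women) and a North American database
(3,137 dated cycles from 562 women) — published the number of menstruation
onsets falling in each of the eight canonical lunar phase sectors, both for
the full cohorts and for the subset of women whose mean cycle length lies
in the closed interval [28, 30] days.  Those count vectors, in canonical
phase order (new moon first), are reproduced here: they pin down the
bin-center angle convention and validate the chi-square and corrected
Rayleigh implementations end to end.
"""

from .lunar import PhaseCountTable

__all__ = [
    "EUROPEAN_TOTAL",
    "NORTH_AMERICAN_TOTAL",
    "EUROPEAN_MEAN_28_30",
    "NORTH_AMERICAN_MEAN_28_30",
]

EUROPEAN_TOTAL = PhaseCountTable(
    counts=(3362, 3533, 3423, 3354, 3393, 3319, 3276, 3252),
    label="European cohort, all cycles",
)

NORTH_AMERICAN_TOTAL = PhaseCountTable(
    counts=(356, 367, 382, 422, 431, 382, 407, 390),
    label="North American cohort, dated cycles",
)

EUROPEAN_MEAN_28_30 = PhaseCountTable(
    counts=(1321, 1440, 1379, 1284, 1273, 1259, 1198, 1189),
    label="European cohort, women with mean cycle length in [28, 30] d",
)

NORTH_AMERICAN_MEAN_28_30 = PhaseCountTable(
    counts=(105, 114, 127, 165, 197, 136, 154, 152),
    label="North American cohort, women with mean cycle length in [28, 30] d",
)
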