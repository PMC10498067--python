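"""Published DIF statistics for the DAI-36 dental anxiety questionnaire.

A printed hybrid OLR/IRT DIF analysis of the 36-item, 5-category Dental
Anxiety Inventory (950 respondents; gender, education and age groupings)
reports, for every item showing DIF, the nonuniform and uniform
likelihood-ratio chi-squares with p-values, the pseudo-R-squared changes
(deltaR2 nonuniform, deltaR1 uniform) and the Crane-van Belle-Larson
slope change (deltaBeta1).  Those printed statistics are bundled here so
the flagging rules can be exercised against real reported numbers: the
raw respondent data themselves are not publicly deposited.
"""

from __future__ import annotations

import pandas as pd

from .dif import classify_item
from .io import RunConfig

__all__ = ["dai36_reference_statistics", "classify_reference_statistics"]

# (grouping, item, chi2_nonuniform, p_nonuniform, deltaR2,
#  chi2_uniform, p_uniform, deltaR1, deltaBeta1)
_DAI36_ROWS = [
    ("gender", 1, 0.351, 0.5534, 0.0001, 8.239, 0.0041, 0.0029, 0.0137),
    ("gender", 3, 6.784, 0.0092, 0.0025, 2.024, 0.1548, 0.0007, 0.0073),
    ("gender", 8, 0.394, 0.5303, 0.0001, 6.224, 0.0126, 0.0023, 0.0124),
    ("gender", 12, 6.582, 0.0103, 0.0024, 0.4335, 0.5103, 0.0002, 0.0046),
    ("gender", 15, 7.247, 0.0071, 0.0027, 0.319, 0.5720, 0.0001, 0.0043),
    ("gender", 22, 5.017, 0.0251, 0.0018, 1.01, 0.3152, 0.0004, 0.0052),
    ("gender", 27, 6.989, 0.0082, 0.0025, 0.098, 0.7537, 0.0000, 0.0021),
    ("gender", 34, 4.762, 0.0291, 0.0018, 2.701, 0.1003, 0.0010, 0.0127),
    ("gender", 36, 15.138, 0.0001, 0.0054, 1.863, 0.1723, 0.0007, 0.0120),
    ("education", 3, 5.238, 0.0221, 0.0019, 0.023, 0.8784, 0.0000, 0.0004),
    ("education", 8, 5.360, 0.0206, 0.0020, 1.064, 0.3023, 0.0004, 0.0014),
    ("education", 9, 0.102, 0.7500, 0.0000, 5.577, 0.0182, 0.0020, 0.0078),
    ("education", 10, 7.0102, 0.0077, 0.0025, 1.789, 0.1810, 0.0006, 0.0016),
    ("education", 14, 6.371, 0.0116, 0.0023, 0.202, 0.6531, 0.0001, 0.0011),
    ("education", 15, 12.532, 0.0004, 0.0048, 6.013, 0.0142, 0.0023, 0.0076),
    ("education", 20, 2.188, 0.1391, 0.0008, 5.586, 0.0181, 0.0020, 0.0097),
    ("education", 21, 0.494, 0.4820, 0.0002, 4.774, 0.0289, 0.0017, 0.0083),
    ("education", 34, 1.371, 0.2417, 0.0005, 5.636, 0.0176, 0.0021, 0.0019),
    ("education", 35, 4.750, 0.0293, 0.0018, 0.397, 0.5285, 0.0001, 0.0018),
    ("education", 36, 5.511, 0.0189, 0.0019, 1.054, 0.3047, 0.0004, 0.0020),
    ("age", 2, 4.923, 0.0265, 0.0018, 13.070, 0.0003, 0.0048, 0.0042),
    ("age", 11, 15.138, 0.0001, 0.0071, 0.670, 0.4130, 0.0002, 0.0040),
    ("age", 22, 0.282, 0.5952, 0.0001, 5.447, 0.0196, 0.0020, 0.0110),
    ("age", 26, 5.596, 0.0180, 0.0020, 0.735, 0.3913, 0.0003, 0.0042),
    ("age", 27, 0.053, 0.8187, 0.0000, 7.033, 0.0080, 0.0025, 0.0136),
    ("age", 29, 15.138, 0.0001, 0.0063, 0.065, 0.7993, 0.0000, 0.0006),
    ("age", 36, 2.193, 0.1386, 0.0008, 4.168, 0.0412, 0.0015, 0.0083),
]


def dai36_reference_statistics() -> pd.DataFrame:
    """The published per-item DIF statistics as a tidy frame."""
    return pd.DataFrame(
        _DAI36_ROWS,
        columns=[
            "grouping",
            "item",
            "chi2_nonuniform",
            "p_nonuniform",
            "deltaR2",
            "chi2_uniform",
            "p_uniform",
            "deltaR1",
            "deltaBeta1",
        ],
    )


def classify_reference_statistics(config: RunConfig | None = None) -> pd.DataFrame:
    """Run the flagging criteria over the published statistics.

    Returns the reference frame with the four flag columns appended —
    the flag counts per grouping are the reproducible part of the printed
    analysis, since the underlying respondent data are unavailable.
    """
    cfg = config if config is not None else RunConfig()
    df = dai36_reference_statistics().copy()
    flags = df.apply(lambda row: classify_item(row.to_dict(), cfg), axis=1, result_type="expand")
    return pd.concat([df, flags], axis=1)
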