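"""Published normative summary of lower-leg muscle volumes in childhood.

This module embeds the group-level summary statistics (mean and SD per
sex and age band) of a cross-sectional MRI cohort of 208 typically
developing children: eight infants under 3 months and 200 children aged
5-15 years, with per-muscle volumes (cm³), tibia/fibula lengths (cm) and
age. These summaries are the calibration targets for the synthetic
cohort generator: the underlying participant-level data are not publicly
deposited, so moment-matched simulation from this table is the
reproducible stand-in.

TSURAE (= LG + MG + SOL) and TOTAL (sum of all 10 muscle groups) are
derived aggregates; they are carried here only so that internal
consistency of the table can be checked against values derived from the
per-muscle entries.
"""

from __future__ import annotations

import pandas as pd

from .muscles import AGE_BANDS, MUSCLES, SEXES, band_label

#: Participants per sex within each age band, in AGE_BANDS order.
GROUP_N: dict[str, tuple[int, ...]] = {
    "boy": (4, 25, 30, 43, 19),
    "girl": (4, 17, 24, 24, 18),
}

# (mean, sd) per age band in AGE_BANDS order, boys then girls.
_SUMMARY: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    "age": {
        "boy": ((0.18, 0.05), (6.50, 0.78), (8.62, 0.68), (11.13, 0.79), (13.75, 0.81)),
        "girl": ((0.21, 0.04), (6.47, 0.69), (8.82, 0.67), (11.10, 0.67), (13.79, 0.81)),
    },
    "body_mass": {
        "boy": ((6.7, 0.8), (23.5, 3.6), (31.1, 6.5), (39.3, 9.1), (53.1, 12.5)),
        "girl": ((5.8, 1.3), (22.8, 3.4), (31.0, 6.6), (38.6, 6.6), (53.6, 8.1)),
    },
    "height": {
        "boy": ((59.1, 2.4), (120.9, 6.7), (135.2, 6.8), (147.7, 8.7), (164.4, 9.5)),
        "girl": ((58.8, 3.6), (120.7, 6.7), (134.2, 7.3), (146.2, 7.8), (163.8, 5.0)),
    },
    "fibula_length": {
        "boy": ((9.0, 0.7), (25.3, 2.0), (29.6, 2.0), (32.9, 2.4), (36.9, 2.0)),
        "girl": ((9.0, 0.5), (25.6, 1.5), (29.2, 2.1), (32.3, 1.8), (36.1, 1.6)),
    },
    "tibia_length": {
        "boy": ((10.1, 0.5), (26.1, 2.0), (30.2, 2.1), (33.9, 2.6), (38.1, 2.3)),
        "girl": ((9.7, 0.6), (26.2, 1.5), (30.1, 2.3), (33.5, 1.9), (37.4, 1.5)),
    },
    "LG": {
        "boy": ((2.4, 0.7), (31.3, 7.0), (46.2, 13.9), (61.9, 20.1), (94.6, 20.9)),
        "girl": ((2.2, 0.5), (27.4, 6.8), (41.2, 11.0), (58.2, 13.1), (93.4, 25.3)),
    },
    "MG": {
        "boy": ((3.2, 0.9), (56.7, 13.2), (85.3, 27.8), (105.5, 29.4), (176.8, 52.0)),
        "girl": ((3.0, 0.6), (54.1, 13.0), (81.0, 18.5), (110.7, 25.2), (162.8, 45.4)),
    },
    "SOL": {
        "boy": ((6.7, 0.6), (117.9, 24.7), (173.9, 48.1), (224.7, 67.7), (346.5, 101.9)),
        "girl": ((6.3, 1.1), (112.6, 23.9), (167.6, 49.1), (223.5, 48.4), (317.0, 56.3)),
    },
    "TA": {
        "boy": ((3.6, 0.8), (33.1, 7.1), (46.8, 10.8), (61.6, 16.6), (94.2, 24.1)),
        "girl": ((3.2, 0.6), (30.5, 6.5), (43.6, 10.5), (61.0, 13.7), (82.4, 16.2)),
    },
    "TP": {
        "boy": ((3.7, 0.3), (33.6, 6.8), (50.7, 11.5), (66.2, 16.1), (96.2, 21.1)),
        "girl": ((3.1, 0.4), (32.1, 6.7), (45.1, 10.2), (62.1, 10.6), (81.0, 12.7)),
    },
    "EEP": {
        "boy": ((3.6, 0.5), (29.5, 5.8), (41.0, 8.5), (51.8, 13.2), (76.3, 16.5)),
        "girl": ((3.1, 0.3), (27.0, 4.6), (36.2, 7.5), (48.7, 9.3), (63.5, 10.5)),
    },
    "PBL": {
        "boy": ((3.4, 0.8), (37.6, 7.9), (53.1, 12.4), (68.6, 19.3), (103.7, 28.7)),
        "girl": ((3.1, 0.7), (34.8, 6.8), (47.8, 12.6), (66.1, 12.8), (90.4, 15.5)),
    },
    "POP": {
        "boy": ((0.6, 0.2), (7.3, 1.6), (10.0, 2.3), (13.1, 3.3), (18.2, 3.5)),
        "girl": ((0.6, 0.1), (6.2, 1.2), (8.6, 1.4), (11.7, 1.8), (15.3, 2.5)),
    },
    "FDL": {
        "boy": ((1.1, 0.2), (11.4, 2.2), (17.0, 3.8), (21.7, 4.6), (29.8, 6.4)),
        "girl": ((0.6, 0.2), (11.0, 2.9), (15.0, 3.4), (19.4, 3.0), (24.3, 5.1)),
    },
    "FHL": {
        "boy": ((2.7, 0.5), (20.8, 4.1), (30.7, 7.1), (39.4, 9.3), (53.5, 9.2)),
        "girl": ((2.1, 0.7), (19.7, 2.8), (26.8, 5.7), (36.9, 5.7), (46.4, 7.5)),
    },
    "TSURAE": {
        "boy": ((12.3, 2.0), (205.9, 43.9), (305.4, 88.1), (392.1, 115.2), (617.9, 169.0)),
        "girl": ((11.6, 1.8), (194.1, 41.9), (289.8, 76.4), (392.4, 84.4), (573.2, 120.2)),
    },
    "TOTAL": {
        "boy": ((31.0, 4.9), (379.1, 75.9), (554.8, 139.1), (714.4, 189.7), (1089.7, 263.8)),
        "girl": ((27.4, 4.0), (355.3, 68.7), (512.9, 123.7), (698.3, 135.7), (976.5, 175.1)),
    },
}

#: Variables in the reference summary besides the muscle volumes.
COVARIATES: tuple[str, ...] = ("age", "body_mass", "height", "fibula_length", "tibia_length")


def reference_summary(include_derived: bool = False) -> pd.DataFrame:
    """Tidy reference summary: one row per sex × age band × variable.

    Parameters
    ----------
    include_derived
        If True, include the TSURAE and TOTAL aggregate rows (useful for
        consistency checks); by default only primitive variables are
        returned, since the aggregates are derived quantities.

    Returns
    -------
    DataFrame with columns
    ``sex, band_lo, band_hi, band, n, variable, mean, sd``.
    """
    variables = list(COVARIATES) + list(MUSCLES)
    if include_derived:
        variables += ["TSURAE", "TOTAL"]
    rows = []
    for sex in SEXES:
        for i, (lo, hi) in enumerate(AGE_BANDS):
            for var in variables:
                mean, sd = _SUMMARY[var][sex][i]
                rows.append(
                    {
                        "sex": sex,
                        "band_lo": lo,
                        "band_hi": hi,
                        "band": band_label(lo, hi),
                        "n": GROUP_N[sex][i],
                        "variable": var,
                        "mean": mean,
                        "sd": sd,
                    }
                )
    return pd.DataFrame(rows)
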