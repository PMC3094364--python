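"""Published five-patient reference cohort (pure data, no computation).

Per-session registration metrics reported for 5 NSCLC patients, each with
three kVCT/MVCT sessions: landmark TRE summaries (mm), lung correspondence
indices (percent volume error V_E, centroid error C_E in mm, Jaccard) for
the right and left lungs, and the global correlation coefficient, all at
both the rigid and the elastic stage.  Also the patient-1 left-lung volume
narrative (cm^3).  These values serve as worked-example fixtures for the
aggregation and index arithmetic; they are not produced by this package.
"""

from __future__ import annotations

import pandas as pd

# (patient, session) -> (n_markers,
#                        rigid (mean, sd, max), elastic (mean, sd, max)) in mm
_TRE = {
    (1, 1): (4, (5.16, 1.16, 6.56), (2.42, 0.73, 3.35)),
    (1, 2): (4, (9.17, 5.46, 16.72), (4.18, 2.17, 7.28)),
    (1, 3): (4, (6.43, 2.65, 10.24), (4.11, 2.17, 7.20)),
    (2, 1): (6, (3.20, 1.60, 5.26), (3.46, 0.92, 4.67)),
    (2, 2): (6, (4.20, 2.19, 6.42), (3.02, 1.26, 4.96)),
    (2, 3): (4, (4.40, 4.13, 10.39), (4.29, 3.58, 9.63)),
    (3, 1): (5, (6.41, 2.68, 10.17), (5.51, 2.44, 8.51)),
    (3, 2): (4, (2.93, 0.90, 4.27), (2.81, 1.06, 4.09)),
    (3, 3): (4, (4.44, 1.66, 6.81), (4.20, 1.45, 6.15)),
    (4, 1): (5, (5.39, 2.51, 8.33), (3.82, 2.89, 8.76)),
    (4, 2): (5, (7.95, 2.62, 11.13), (4.83, 3.73, 11.22)),
    (4, 3): (4, (9.86, 5.34, 14.46), (5.10, 2.87, 8.35)),
    (5, 1): (5, (3.08, 1.13, 4.57), (3.16, 0.94, 4.55)),
    (5, 2): (4, (2.87, 1.38, 3.83), (2.14, 1.00, 3.63)),
    (5, 3): (2, (2.99, 1.64, 4.15), (2.52, 2.13, 4.02)),
}

# (patient, session) -> per lung: rigid (V_E %, C_E mm, JAC), elastic (...)
_RIGHT = {
    (1, 1): ((-8.07, 3.10, 0.89), (-0.69, 0.77, 0.95)),
    (1, 2): ((11.30, 3.98, 0.84), (0.62, 1.22, 0.95)),
    (1, 3): ((-8.54, 4.73, 0.87), (-0.19, 0.53, 0.95)),
    (2, 1): ((4.44, 1.43, 0.90), (2.03, 0.53, 0.93)),
    (2, 2): ((10.12, 2.71, 0.87), (4.78, 0.78, 0.93)),
    (2, 3): ((-2.17, 2.82, 0.71), (1.61, 0.32, 0.93)),
    (3, 1): ((3.33, 2.89, 0.88), (2.09, 0.28, 0.95)),
    (3, 2): ((3.73, 1.77, 0.88), (1.59, 0.33, 0.95)),
    (3, 3): ((-3.73, 1.77, 0.91), (-0.41, 0.39, 0.96)),
    (4, 1): ((-0.55, 0.95, 0.90), (0.48, 0.18, 0.93)),
    (4, 2): ((-1.44, 1.30, 0.89), (-1.15, 0.28, 0.94)),
    (4, 3): ((-11.14, 1.56, 0.82), (-3.11, 0.88, 0.93)),
    (5, 1): ((7.64, 3.01, 0.89), (3.45, 0.73, 0.94)),
    (5, 2): ((0.90, 2.68, 0.91), (-0.72, 0.50, 0.96)),
    (5, 3): ((-16.16, 6.12, 0.80), (-5.23, 5.46, 0.87)),
}

_LEFT = {
    (1, 1): ((24.85, 7.35, 0.72), (1.97, 0.40, 0.95)),
    (1, 2): ((-17.87, 9.76, 0.76), (-0.81, 0.14, 0.96)),
    (1, 3): ((45.14, 7.86, 0.54), (3.10, 0.84, 0.92)),
    (2, 1): ((-5.14, 1.22, 0.90), (0.25, 0.39, 0.94)),
    (2, 2): ((-5.55, 2.05, 0.89), (1.49, 0.26, 0.95)),
    (2, 3): ((2.64, 0.93, 0.89), (1.11, 0.76, 0.92)),
    (3, 1): ((-1.97, 2.15, 0.80), (1.99, 1.94, 0.89)),
    (3, 2): ((-4.53, 2.58, 0.87), (0.01, 2.11, 0.90)),
    (3, 3): ((-17.38, 5.15, 0.81), (-6.82, 3.23, 0.88)),
    (4, 1): ((-0.80, 2.00, 0.91), (0.80, 0.06, 0.95)),
    (4, 2): ((-5.42, 2.14, 0.90), (-0.59, 0.37, 0.96)),
    (4, 3): ((-10.69, 4.06, 0.84), (-2.08, 0.56, 0.95)),
    (5, 1): ((2.35, 0.89, 0.92), (2.23, 0.16, 0.95)),
    (5, 2): ((4.60, 0.96, 0.93), (0.49, 0.09, 0.96)),
    (5, 3): ((4.26, 0.99, 0.90), (2.05, 1.52, 0.94)),
}

# (patient, session) -> (CC rigid, CC elastic)
_CC = {
    (1, 1): (0.92, 0.98), (1, 2): (0.91, 0.98), (1, 3): (0.88, 0.98),
    (2, 1): (0.97, 0.99), (2, 2): (0.97, 0.99), (2, 3): (0.96, 0.98),
    (3, 1): (0.90, 0.98), (3, 2): (0.96, 0.98), (3, 3): (0.90, 0.97),
    (4, 1): (0.92, 0.98), (4, 2): (0.92, 0.97), (4, 3): (0.86, 0.97),
    (5, 1): (0.95, 0.98), (5, 2): (0.96, 0.98), (5, 3): (0.94, 0.97),
}

# Patient 1 left lung, first session: reference volumes in cm^3
PATIENT1_LEFT_LUNG_CM3 = {
    "kvct": 632.39,
    "rigid_mvct": 475.22,
    "elastic_mvct": 619.95,
}


def reference_sessions() -> list:
    """All 15 sessions as flat records usable by ``aggregate_cohort``."""
    rows = []
    for (patient, session), (n_mrk, tre_r, tre_e) in _TRE.items():
        cc_r, cc_e = _CC[(patient, session)]
        right_r, right_e = _RIGHT[(patient, session)]
        left_r, left_e = _LEFT[(patient, session)]
        rows.append({
            "patient": str(patient), "session": str(session),
            "n_markers": n_mrk,
            "cc_rigid": cc_r, "cc_elastic": cc_e,
            "tre_mean_rigid": tre_r[0], "tre_sd_rigid": tre_r[1],
            "tre_max_rigid": tre_r[2],
            "tre_mean_elastic": tre_e[0], "tre_sd_elastic": tre_e[1],
            "tre_max_elastic": tre_e[2],
            "ve_right_rigid": right_r[0], "ce_right_rigid": right_r[1],
            "jac_right_rigid": right_r[2],
            "ve_right_elastic": right_e[0], "ce_right_elastic": right_e[1],
            "jac_right_elastic": right_e[2],
            "ve_left_rigid": left_r[0], "ce_left_rigid": left_r[1],
            "jac_left_rigid": left_r[2],
            "ve_left_elastic": left_e[0], "ce_left_elastic": left_e[1],
            "jac_left_elastic": left_e[2],
        })
    return rows


def reference_dataframe() -> pd.DataFrame:
    return pd.DataFrame(reference_sessions())
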