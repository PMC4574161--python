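"""Published summary tables from the Australian coastal macrogenetics study.

These printed values — the model-selection ladder (DIC and posterior
predictive p per model for both response families) and the per-region
posterior summaries of the best models — are bundled as *inputs* for the
arithmetic utilities (DIC weights, delta-DIC, cross-model regional
correlations), so those derived quantities can be recomputed without access
to the original database.  None of the modelling code reads this module.
"""

from __future__ import annotations

import pandas as pd

#: Gaussian (Z) family ladder: model name -> DIC
Z_LADDER_DIC = {
    "S + n": 2676.3,
    "S + n + L": 2678.5,
    "S + n + L + L2": 2680.9,
    "S + n + R": 2676.2,
    "S + n + L + R": 2677.1,
    "S + n + L + L2 + R": 2680.2,
}

#: beta (H) family ladder: model name -> (DIC, PPP)
H_LADDER = {
    "S + M + n": (-661.8, 1e-4),
    "S + M + n + L": (-681.2, 0.986),
    "S + M + n + L + L2": (-692.1, 0.032),
    "S + M + n + R": (-697.2, 1e-4),
    "S + M + n + L + R": (-711.8, 0.914),
    "S + M + n + L + L2 + R": (-715.5, 0.362),
}

H_LADDER_DIC = {k: v[0] for k, v in H_LADDER.items()}

#: per-region posterior summaries of the best models, plus species/population
#: counts for each data subset.  Columns: region id, species and population
#: counts (all data), Z-model mean/sd, H-model mean/sd, fish subset
#: (sp, pop, mean, sd), mollusc subset (sp, pop, mean, sd); None = not
#: reported (fewer than 10 populations) or region absent from the subset.
_REGIONAL_ROWS = [
    # region, sp, pop, z_mean, z_sd, h_mean, h_sd, f_sp, f_pop, f_mean, f_sd, m_sp, m_pop, m_mean, m_sd
    ("25", 17, 52, 0.146, 0.127, 0.249, 0.139, 9, 33, 0.418, 0.221, None, None, None, None),
    ("26", 11, 21, 0.138, 0.135, 0.584, 0.204, 7, 16, 0.525, 0.270, 1, 2, -2.286, 0.626),
    ("27", 17, 46, -0.154, 0.137, 0.294, 0.144, 8, 18, 0.092, 0.238, 2, 11, -2.130, 0.437),
    ("28", 6, 5, -0.089, 0.145, 0.406, 0.283, 2, 3, 0.224, 0.272, None, None, None, None),
    ("29", 5, 17, 0.070, 0.132, 0.547, 0.259, 2, 2, 0.150, 0.350, None, None, None, None),
    ("30", 5, 16, -0.005, 0.134, -0.172, 0.207, 3, 3, -0.248, 0.320, None, None, None, None),
    ("31", 11, 40, -0.104, 0.112, -0.280, 0.160, 3, 11, -0.547, 0.299, 1, 1, -0.390, 0.633),
    ("32", 7, 15, 0.048, 0.127, -0.524, 0.318, 3, 3, -0.034, 0.332, 1, 1, 0.199, 0.565),
    ("33", 15, 59, -0.062, 0.095, -0.125, 0.132, 4, 10, -0.407, 0.274, 3, 13, 1.132, 0.309),
    ("34", 11, 41, 0.088, 0.105, 0.126, 0.151, 4, 10, 0.095, 0.240, 2, 22, 1.768, 0.325),
    ("35", 14, 39, -0.056, 0.109, -0.181, 0.151, 7, 19, -0.391, 0.234, 3, 10, 0.987, 0.326),
    ("36", 13, 79, -0.069, 0.097, -0.246, 0.131, 6, 17, -0.324, 0.230, 2, 50, 0.742, 0.260),
    ("37", 25, 105, 0.075, 0.095, -0.120, 0.115, 12, 47, 0.160, 0.191, 2, 11, 0.120, 0.269),
    ("38", 23, 102, 0.048, 0.080, -0.127, 0.116, 9, 23, 0.351, 0.228, 3, 16, -0.060, 0.285),
    ("39", 25, 67, -0.053, 0.093, -0.268, 0.130, 11, 22, -0.041, 0.190, 2, 7, -0.241, 0.366),
    ("40", 47, 212, -0.010, 0.072, -0.136, 0.097, 23, 58, -0.230, 0.184, 2, 3, 0.018, 0.382),
    ("41", 18, 43, -0.011, 0.097, -0.027, 0.146, 4, 4, 0.208, 0.288, 1, 1, 0.140, 0.526),
]

#: headline latitude coefficients of the best H model (standardized scale)
H_LATITUDE = 0.558
H_LATITUDE_SQ = -0.920


def regional_table() -> pd.DataFrame:
    """The regional summaries as a DataFrame indexed by region id."""
    cols = ["region", "sp", "pop", "z_mean", "z_sd", "h_mean", "h_sd",
            "fish_sp", "fish_pop", "fish_mean", "fish_sd",
            "mollusc_sp", "mollusc_pop", "mollusc_mean", "mollusc_sd"]
    df = pd.DataFrame(_REGIONAL_ROWS, columns=cols).set_index("region")
    return df
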