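"""Small example datasets and summary helpers.

``SOYBEAN_TAU_ESTIMATES``: published best-fit values of the
fluorescence proportionality τ from Variable-J fits to ten field-grown
soybean CO2-response + fluorescence curves (one value per leaf),
used in examples and as a reference for summary arithmetic.
"""

from __future__ import annotations

import numpy as np

SOYBEAN_TAU_ESTIMATES = (
    0.415, 0.431, 0.465, 0.372, 0.402,
    0.434, 0.502, 0.446, 0.433, 0.362,
)


def summarize_estimates(values, decimals: int | None = None) -> dict:
    """Mean, sample SD, and coefficient of variation (%) of estimates.

    With ``decimals`` set, the mean and SD are rounded to that reporting
    precision before the CV is formed — matching how a CV quoted in a
    summary table is derived from the printed values.
    """
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if decimals is not None:
        mean = round(mean, decimals)
        sd = round(sd, decimals)
    return {
        "mean": mean,
        "sd": sd,
        "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
        "n": int(x.size),
    }
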