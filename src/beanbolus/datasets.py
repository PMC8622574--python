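"""Reference example datasets for cooked black-bean bolus digestion.

Published-style parameter estimates for six participants (three fast
chewers who chewed < 25 s, three slow chewers who chewed > 29 s) who each
masticated three differently processed black-bean samples:

* sample A — PEF-treated, cooked without CaCl2,
* sample B — PEF-treated, cooked in 300 ppm CaCl2,
* sample C — not PEF-treated, cooked in 300 ppm CaCl2.

These tables serve as worked-example inputs for the kinetics and cohort
modules and as realistic defaults for the synthetic generators.  Starch
kinetics are fractional conversion parameters (S0, Sf in mg D-glucose,
ks in 1/min); protein rates are zero-order slopes (kp, reported in the
conventional 1e-2/min presentation); starch fractions are RDS/SDS/RS
percentages of total starch.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "starch_kinetics_examples",
    "protein_rate_examples",
    "starch_fraction_examples",
    "INTESTINAL_TIMEPOINTS_MIN",
    "GASTRIC_TIMEPOINTS_MIN",
    "RR_ALL_PARTICLES_EXAMPLES",
]

#: digesta sampling grid of the simulated small-intestinal phase (min)
INTESTINAL_TIMEPOINTS_MIN = (0.0, 20.0, 30.0, 40.0, 60.0, 90.0, 120.0, 180.0, 240.0)

#: starch digesta sampling grid of the simulated gastric phase (min)
GASTRIC_TIMEPOINTS_MIN = (0.0, 120.0)

# fractional-conversion estimates per participant x sample
# columns: participant, group, sample, S0_mg, Sf_mg, ks_per_min
_STARCH_KINETICS = [
    ("P2", "fast", "A", 78.4, 196.4, 0.027),
    ("P2", "fast", "B", 108.5, 214.6, 0.030),
    ("P2", "fast", "C", 110.6, 186.9, 0.019),
    ("P14", "fast", "A", 90.5, 240.0, 0.023),
    ("P14", "fast", "B", 105.9, 216.0, 0.018),
    ("P14", "fast", "C", 64.4, 154.6, 0.014),
    ("P16", "fast", "A", 50.6, 133.8, 0.016),
    ("P16", "fast", "B", 112.5, 209.5, 0.014),
    ("P16", "fast", "C", 103.4, 200.9, 0.018),
    ("P12", "slow", "A", 107.3, 216.0, 0.015),
    ("P12", "slow", "B", 156.2, 289.2, 0.010),
    ("P12", "slow", "C", 168.0, 303.8, 0.018),
    ("P19", "slow", "A", 152.3, 324.8, 0.023),
    ("P19", "slow", "B", 145.1, 306.4, 0.021),
    ("P19", "slow", "C", 128.6, 306.5, 0.021),
    ("P21", "slow", "A", 102.6, 340.7, 0.019),
    ("P21", "slow", "B", 121.6, 343.0, 0.025),
    ("P21", "slow", "C", 152.9, 338.8, 0.016),
]

# zero-order protein rates (kp, 1e-2 min^-1 presentation)
_PROTEIN_RATES = [
    ("P2", "fast", "A", 6.2),
    ("P2", "fast", "B", 10.4),
    ("P2", "fast", "C", 4.1),
    ("P4", "fast", "A", 5.5),
    ("P4", "fast", "B", 9.2),
    ("P4", "fast", "C", 4.3),
    ("P16", "fast", "A", 4.7),
    ("P16", "fast", "B", 8.4),
    ("P16", "fast", "C", 5.4),
    ("P12", "slow", "A", 10.2),
    ("P12", "slow", "B", 16.1),
    ("P12", "slow", "C", 11.5),
    ("P19", "slow", "A", 6.7),
    ("P19", "slow", "B", 10.5),
    ("P19", "slow", "C", 9.6),
    ("P21", "slow", "A", 7.7),
    ("P21", "slow", "B", 7.5),
    ("P21", "slow", "C", 9.0),
]

# starch fractions (% of total starch)
_STARCH_FRACTIONS = [
    ("P2", "fast", "A", 32.8, 19.5, 47.8),
    ("P2", "fast", "B", 42.91, 17.6, 39.52),
    ("P2", "fast", "C", 38.6, 18.6, 42.9),
    ("P14", "fast", "A", 37.7, 21.8, 40.5),
    ("P14", "fast", "B", 37.0, 19.3, 43.71),
    ("P14", "fast", "C", 27.7, 10.9, 61.32),
    ("P16", "fast", "A", 20.81, 13.6, 65.6),
    ("P16", "fast", "B", 29.6, 18.6, 51.8),
    ("P16", "fast", "C", 34.0, 13.2, 52.8),
    ("P12", "slow", "A", 39.0, 26.2, 33.4),
    ("P12", "slow", "B", 47.8, 24.5, 27.7),
    ("P12", "slow", "C", 57.4, 19.6, 23.0),
    ("P19", "slow", "A", 56.4, 26.4, 17.2),
    ("P19", "slow", "B", 69.1, 19.1, 13.6),
    ("P19", "slow", "C", 51.6, 24.3, 24.2),
    ("P21", "slow", "A", 46.2, 29.9, 24.0),
    ("P21", "slow", "B", 54.9, 27.4, 17.7),
    ("P21", "slow", "C", 61.8, 28.3, 11.7),
]

#: panel-average Rosin-Rammler parameters of "all" particles per sample
RR_ALL_PARTICLES_EXAMPLES = {
    "A": {"x50_mm2": 5.0, "b": 1.63},
    "B": {"x50_mm2": 5.2, "b": 1.60},
    "C": {"x50_mm2": 5.4, "b": 1.53},
}


def starch_kinetics_examples() -> pd.DataFrame:
    """Fractional-conversion starch parameters for six example chewers."""
    return pd.DataFrame(
        _STARCH_KINETICS,
        columns=["participant", "group", "sample", "S0_mg", "Sf_mg", "ks_per_min"],
    )


def protein_rate_examples() -> pd.DataFrame:
    """Zero-order protein digestion rates (kp x 1e-2/min presentation)."""
    return pd.DataFrame(
        _PROTEIN_RATES, columns=["participant", "group", "sample", "kp_1e2_per_min"]
    )


def starch_fraction_examples() -> pd.DataFrame:
    """RDS/SDS/RS starch fractions (%) for six example chewers."""
    return pd.DataFrame(
        _STARCH_FRACTIONS,
        columns=["participant", "group", "sample", "RDS", "SDS", "RS"],
    )
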