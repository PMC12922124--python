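"""Published reference values used as worked-example inputs.

Raw well-level mortality data for the *Coleps hirtus* acute tests were
never deposited; what is available are the reported 24 h LC20/LC50
estimates per compound and the replicate-summary mortalities of the two
binary-mixture experiments (Cd + Zn and Cd + ZnO) on a 16-point toxic-unit
grid.  This module exposes those values as ready-made inputs: LC tables,
curves reconstructed from the (LC20, LC50) pairs, toxic-unit components,
and the mixture-trial summaries.

The printed *expected* column of the Cd + ZnO experiment is not
reproducible by effect summation from the reported LC values and is
therefore deliberately not included here.
"""

from __future__ import annotations

import pandas as pd

from .dose_response import LogitCurve, curve_from_lcs
from .toxic_units import MixtureTrial, TUComponent

__all__ = [
    "lc_table",
    "reconstructed_curve",
    "tu_component",
    "cd_zn_trials",
    "cd_zno_trials",
    "TU_GRID_16",
]

# 24 h LC values (mg L^-1): compound -> (lc20, lc20_se, lc50, lc50_se, r_squared)
_LC_VALUES = {
    "Cu": (0.87, 0.05, 1.62, 0.04, 0.997),
    "Zn": (8.26, 0.68, 20.42, 0.89, 0.987),
    "Cd": (1.47, 0.08, 2.75, 0.06, 0.994),
    "CuO": (256.45, 15.32, 447.83, 11.94, 0.996),
    "ZnO": (138.72, 9.85, 356.18, 16.32, 0.993),
    "TiO2": (6487.15, 462.25, 12879.33, 405.67, 0.995),
}

# The 16-point TU design: totals 0.5-2.0, all quarter-TU splits tested.
TU_GRID_16: tuple[tuple[float, float], ...] = (
    (0.25, 0.25),
    (0.5, 0.25),
    (0.25, 0.5),
    (0.75, 0.25),
    (0.5, 0.5),
    (0.25, 0.75),
    (0.75, 0.5),
    (0.5, 0.75),
    (1.0, 0.25),
    (0.25, 1.0),
    (0.5, 1.0),
    (0.75, 0.75),
    (1.0, 0.5),
    (1.0, 0.75),
    (0.75, 1.0),
    (1.0, 1.0),
)

# (tu_cd, tu_other, observed mean %, observed SD %), n = 3 replicates each
_CD_ZN = (
    (0.25, 0.25, 13.00, 3.04),
    (0.5, 0.25, 27.11, 1.62),
    (0.25, 0.5, 20.89, 1.27),
    (0.75, 0.25, 49.56, 2.60),
    (0.5, 0.5, 34.00, 1.22),
    (0.25, 0.75, 35.44, 3.28),
    (0.75, 0.5, 42.56, 1.33),
    (0.5, 0.75, 56.67, 2.60),
    (1.0, 0.25, 55.00, 2.80),
    (0.25, 1.0, 66.89, 2.52),
    (0.5, 1.0, 72.67, 2.35),
    (0.75, 0.75, 53.00, 1.00),
    (1.0, 0.5, 60.33, 1.58),
    (1.0, 0.75, 81.00, 2.12),
    (0.75, 1.0, 87.00, 2.74),
    (1.0, 1.0, 96.56, 2.60),
)

_CD_ZNO = (
    (0.25, 0.25, 42.33, 1.94),
    (0.5, 0.25, 51.67, 1.87),
    (0.25, 0.5, 74.11, 1.45),
    (0.75, 0.25, 67.44, 2.46),
    (0.5, 0.5, 84.56, 1.42),
    (0.25, 0.75, 100.00, 0.00),
    (0.75, 0.5, 88.67, 1.00),
    (0.5, 0.75, 100.00, 0.00),
    (1.0, 0.25, 76.22, 2.11),
    (0.25, 1.0, 100.00, 0.00),
    (0.5, 1.0, 100.00, 0.00),
    (0.75, 0.75, 100.00, 0.00),
    (1.0, 0.5, 95.11, 1.27),
    (1.0, 0.75, 100.00, 0.00),
    (0.75, 1.0, 100.00, 0.00),
    (1.0, 1.0, 100.00, 0.00),
)


def lc_table() -> pd.DataFrame:
    """Reported 24 h LC20/LC50 estimates (mg L^-1) for every compound with
    a measurable response."""
    rows = []
    for compound, (lc20, se20, lc50, se50, r2) in _LC_VALUES.items():
        rows.append(
            {
                "compound": compound,
                "lc20": lc20,
                "lc20_se": se20,
                "lc50": lc50,
                "lc50_se": se50,
                "r_squared": r2,
            }
        )
    return pd.DataFrame(rows)


def reconstructed_curve(compound: str) -> LogitCurve:
    """Logit-log curve through the compound's reported (LC20, LC50) pair."""
    lc20, _, lc50, _, _ = _LC_VALUES[compound]
    return curve_from_lcs((20.0, lc20), (50.0, lc50))


def tu_component(compound: str) -> TUComponent:
    """Toxic-unit component (curve + LC50 defining 1 TU) for a compound."""
    return TUComponent(
        compound=compound,
        lc50_ref=_LC_VALUES[compound][2],
        curve=reconstructed_curve(compound),
    )


def _trials(raw) -> list[MixtureTrial]:
    return [
        MixtureTrial(
            tu_a=a, tu_b=b, observed_mean=mean, observed_sd=sd, n_replicates=3
        )
        for a, b, mean, sd in raw
    ]


def cd_zn_trials() -> list[MixtureTrial]:
    """Observed Cd + Zn mixture mortalities on the 16-point TU grid."""
    return _trials(_CD_ZN)


def cd_zno_trials() -> list[MixtureTrial]:
    """Observed Cd + ZnO mixture mortalities on the 16-point TU grid."""
    return _trials(_CD_ZNO)
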