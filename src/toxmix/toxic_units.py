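"""Toxic-unit mixture designs and effect-summation interaction analysis.

A Toxic Unit (TU) expresses a compound's concentration as a fraction of its
own 24 h LC50, so 1 TU of any compound is equitoxic by construction.  For a
binary mixture dosed at (tu_a, tu_b) the *effect summation* expectation is
the sum of the single-compound mortalities at each component's
concentration, capped at 100%:

    expected % = min(100, 100 * [F_a(tu_a * LC50_a) + F_b(tu_b * LC50_b)])

Observed replicate mortality is compared with this expectation by a
one-sample two-sided t-test: significantly higher observed mortality is
called synergism, significantly lower antagonism, otherwise no interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import LogitCurve, predict_mortality
from .exceptions import DesignError, ToxmixError

__all__ = [
    "TUComponent",
    "MixtureTrial",
    "tu_to_concentration",
    "expected_mixture_mortality",
    "classify_interaction",
    "build_tu_design",
    "mixture_table",
    "SYNERGISM",
    "ANTAGONISM",
    "NO_INTERACTION",
]

SYNERGISM = "synergism"
ANTAGONISM = "antagonism"
NO_INTERACTION = "no_interaction"


@dataclass(frozen=True)
class TUComponent:
    """One mixture component: its curve and the LC50 that defines 1 TU.

    The reference LC50 must sit on the curve: ``F(lc50_ref)`` is required
    to be 0.5 within 0.01.
    """

    compound: str
    lc50_ref: float
    curve: LogitCurve

    def __post_init__(self) -> None:
        if self.lc50_ref <= 0:
            raise ToxmixError(f"lc50_ref must be > 0, got {self.lc50_ref}")
        f = predict_mortality(self.curve, self.lc50_ref)
        if abs(f - 0.5) > 0.01:
            raise ToxmixError(
                f"{self.compound}: curve predicts {f:.4f} at lc50_ref; expected 0.5 +/- 0.01"
            )


@dataclass(frozen=True)
class MixtureTrial:
    """One TU combination with observed replicate summary and expectation.

    Mortalities are percentages.  ``call`` is filled by
    :func:`classify_interaction`.
    """

    tu_a: float
    tu_b: float
    observed_mean: float
    observed_sd: float
    n_replicates: int
    expected: float = float("nan")
    call: str | None = None

    @property
    def total_tu(self) -> float:
        return self.tu_a + self.tu_b


def tu_to_concentration(component: TUComponent, tu: float) -> float:
    """Concentration (mg L^-1) corresponding to ``tu`` toxic units."""
    if tu < 0:
        raise ToxmixError(f"invalid TU: must be >= 0, got {tu}")
    return tu * component.lc50_ref


def expected_mixture_mortality(
    components: Sequence[TUComponent], tus: Sequence[float]
) -> float:
    """Effect-summation expected mortality (percent) for a binary TU dose.

    Each component contributes its single-compound predicted mortality at
    ``tu_i * lc50_i``; a component at 0 TU contributes nothing.  The sum is
    capped at 100%.
    """
    if len(components) != 2 or len(tus) != 2:
        raise ToxmixError("expected exactly two components and two TU values")
    total = 0.0
    for comp, tu in zip(components, tus):
        conc = tu_to_concentration(comp, tu)
        if conc > 0:
            total += float(predict_mortality(comp.curve, conc))
    return min(100.0, 100.0 * total)


def classify_interaction(trial: MixtureTrial, alpha: float = 0.05) -> MixtureTrial:
    """Classify a mixture trial by one-sample t-test against its expectation.

    The observed replicate mean is tested (two-sided, df = n - 1) against
    the expected point value.  Zero observed SD is treated as an exact
    observation: any difference from the expectation is then significant.

    Returns a copy of the trial with ``call`` filled in.
    """
    if trial.n_replicates < 2:
        raise ToxmixError("no replication: need n_replicates >= 2")
    if trial.observed_sd < 0:
        raise ToxmixError("observed_sd must be >= 0")
    diff = trial.observed_mean - trial.expected
    if trial.observed_sd == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / (trial.observed_sd / np.sqrt(trial.n_replicates))
        p = float(2.0 * stats.t.sf(abs(t), trial.n_replicates - 1))
    if p < alpha and diff > 0:
        call = SYNERGISM
    elif p < alpha and diff < 0:
        call = ANTAGONISM
    else:
        call = NO_INTERACTION
    return replace(trial, call=call)


def build_tu_design(
    total_tus: Sequence[float], splits: Sequence[Sequence[float]], atol: float = 1e-9
) -> list[tuple[float, float]]:
    """Validate and enumerate a TU design grid.

    Each split ``(tu_a, tu_b)`` must sum (within ``atol``) to one of the
    stated totals; the validated pairs are returned in input order.
    """
    totals = sorted(float(t) for t in total_tus)
    if any(t < 0 for t in totals):
        raise DesignError("total TUs must be >= 0")
    pairs: list[tuple[float, float]] = []
    for split in splits:
        a, b = (float(v) for v in split)
        if a < 0 or b < 0:
            raise DesignError(f"TU fractions must be >= 0, got {split}")
        s = a + b
        if not any(abs(s - t) <= atol for t in totals):
            raise DesignError(
                f"inconsistent design: split {split} sums to {s}, not a stated total"
            )
        pairs.append((a, b))
    return pairs


def mixture_table(
    components: Sequence[TUComponent],
    trials: Iterable[MixtureTrial],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Expected mortality and interaction call for every trial.

    Output columns mirror the standard TU-mixture report: total TU, the TU
    of each component, observed mean +/- SD, effect-summation expectation
    and the interaction call.
    """
    comp_a, comp_b = components
    rows = []
    for trial in trials:
        expected = expected_mixture_mortality(components, (trial.tu_a, trial.tu_b))
        classified = classify_interaction(replace(trial, expected=expected), alpha)
        rows.append(
            {
                "total_tu": trial.total_tu,
                f"tu_{comp_a.compound}": trial.tu_a,
                f"tu_{comp_b.compound}": trial.tu_b,
                "obs_mean_pct": trial.observed_mean,
                "obs_sd_pct": trial.observed_sd,
                "n_reps": trial.n_replicates,
                "expected_pct": expected,
                "interaction": classified.call,
            }
        )
    return pd.DataFrame(rows)
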