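"""Seeded synthetic bioassay data with the structure the analysis assumes.

The generators emulate the acute microwell design used throughout the
package: 100 cells per well, 3 wells per concentration, 3 independent
biological replicates, 24 h mortality scored per well.  Acute single
compound assays draw well-level binomial deaths from a logit-log curve;
mixture trials draw replicate mortalities around a CA/IA surface
prediction (binomial at the well level by default, Gaussian optionally);
biomarker panels couple endpoint means across treatments with a
configurable correlation and add Gaussian replicate noise.

Every generator is a pure function of its parameters and an explicit
integer seed; control wells (concentration 0) yield zero deaths because no
background-mortality correction is modelled anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .biomarker_stats import BiomarkerPanel
from .dose_response import LogitCurve, MortalityRecord
from .exceptions import ToxmixError
from .mixture_surface import SurfaceModel
from .toxic_units import MixtureTrial

__all__ = [
    "AssayDesign",
    "GeneratorTruth",
    "default_concentrations",
    "simulate_acute_assay",
    "simulate_mixture_dataset",
    "simulate_biomarker_panel",
]


@dataclass(frozen=True)
class AssayDesign:
    """Microwell acute-assay layout.

    Defaults mirror the standard design: 100 cells per well, 3 wells per
    concentration, 3 biological replicates.
    """

    concentrations: tuple[float, ...]
    cells_per_well: int = 100
    wells_per_conc: int = 3
    bio_replicates: int = 3

    def __post_init__(self) -> None:
        if min(self.cells_per_well, self.wells_per_conc, self.bio_replicates) < 1:
            raise ToxmixError("all design counts must be >= 1")
        if any(c < 0 for c in self.concentrations):
            raise ToxmixError("concentrations must be >= 0")


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth recorded alongside a generated dataset.

    Everything a recovery test needs: the single-compound curves, the
    mixture surface (reference + deviation), biomarker effect sizes, the
    inter-endpoint correlation, and noise scales.
    """

    curves: Mapping[str, LogitCurve] = field(default_factory=dict)
    surface: SurfaceModel | None = None
    biomarker_effects: Mapping[str, float] = field(default_factory=dict)
    rho: float = 0.0
    noise: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "curves": {
                k: {"alpha": c.alpha, "beta": c.beta} for k, c in self.curves.items()
            },
            "surface": None
            if self.surface is None
            else {
                "reference": self.surface.reference,
                "deviation": {
                    "form": self.surface.deviation.form,
                    "a": self.surface.deviation.a,
                    "b": self.surface.deviation.b,
                },
            },
            "biomarker_effects": dict(self.biomarker_effects),
            "rho": self.rho,
            "noise": dict(self.noise),
        }


def default_concentrations(curve: LogitCurve, n: int = 5, span: float = 2.5) -> tuple[float, ...]:
    """Log-spaced test concentrations bracketing the LC50.

    Places ``n`` concentrations so the logit of the expected mortality runs
    from ``-span`` to ``+span`` (about 8% to 92% for the default), the
    range a well-designed acute test aims to cover.
    """
    logits = np.linspace(-span, span, n)
    return tuple(10.0 ** ((logits - curve.alpha) / curve.beta))


def simulate_acute_assay(
    design: AssayDesign,
    curve: LogitCurve,
    seed: int,
    compound: str = "X",
) -> list[MortalityRecord]:
    """Simulate one acute test: binomial deaths per well from the curve.

    Returns one :class:`MortalityRecord` per well, across all biological
    replicates; concentration-0 wells record zero deaths.
    """
    rng = np.random.default_rng(seed)
    records = []
    for b in range(design.bio_replicates):
        for conc in design.concentrations:
            p = float(curve.predict(conc)) if conc > 0 else 0.0
            for w in range(design.wells_per_conc):
                dead = int(rng.binomial(design.cells_per_well, p))
                records.append(
                    MortalityRecord(
                        compound=compound,
                        concentration=float(conc),
                        n_exposed=design.cells_per_well,
                        n_dead=dead,
                        replicate_id=f"b{b + 1}w{w + 1}",
                    )
                )
    return records


def simulate_mixture_dataset(
    tu_pairs: Sequence[Sequence[float]],
    truth: GeneratorTruth,
    seed: int,
    cells_per_well: int = 100,
    wells_per_replicate: int = 3,
    n_replicates: int = 3,
    noise: str = "binomial",
    sigma_pct: float = 2.0,
) -> list[MixtureTrial]:
    """Simulate binary-mixture trials around a surface prediction.

    Each TU pair is converted to concentrations through the surface's own
    LC50s, the surface predicts the mortality fraction, and replicate
    percentages are drawn either binomially (wells of ``cells_per_well``
    cells pooled per biological replicate, the default) or as Gaussian
    noise with standard deviation ``sigma_pct`` percentage points.

    Returns one :class:`MixtureTrial` per pair with the replicate mean and
    SD filled in; the generating expectation is *not* stored in
    ``expected`` (that is the analyst's job).
    """
    if truth.surface is None:
        raise ToxmixError("truth.surface is required")
    rng = np.random.default_rng(seed)
    l1, l2 = truth.surface.lc50s
    trials = []
    for tu_a, tu_b in tu_pairs:
        c1, c2 = tu_a * l1, tu_b * l2
        if c1 == 0 and c2 == 0:
            f = 0.0
        else:
            f = float(truth.surface.predict(c1, c2))
        if noise == "binomial":
            n_cells = cells_per_well * wells_per_replicate
            reps = 100.0 * rng.binomial(n_cells, f, size=n_replicates) / n_cells
        elif noise == "gaussian":
            reps = np.clip(
                100.0 * f + rng.normal(0.0, sigma_pct, size=n_replicates), 0.0, 100.0
            )
        else:
            raise ToxmixError(f"unknown noise model {noise!r}")
        trials.append(
            MixtureTrial(
                tu_a=float(tu_a),
                tu_b=float(tu_b),
                observed_mean=float(np.mean(reps)),
                observed_sd=float(np.std(reps, ddof=1)),
                n_replicates=n_replicates,
            )
        )
    return trials


def simulate_biomarker_panel(
    treatments: Sequence[str],
    effects: Mapping[str, float],
    rho: float,
    seed: int,
    replicates: int = 3,
    baseline: float = 100.0,
    noise_sd: float = 2.0,
) -> list[BiomarkerPanel]:
    """Simulate correlated biomarker panels across treatments.

    Each endpoint's treatment mean is ``baseline + effect * s(t)``, where
    the treatment scores ``s(t)`` load on a shared latent factor with
    weight ``sqrt(|rho|)``, so any two endpoints' mean profiles correlate
    at ``rho`` across many treatments.  Biological replicates add
    independent Gaussian noise with SD ``noise_sd``.  Negative ``rho`` is
    only representable for exactly two endpoints (the second endpoint
    loads with opposite sign).
    """
    if not -1.0 <= rho <= 1.0:
        raise ToxmixError(f"rho must be in [-1, 1], got {rho}")
    if rho < 0 and len(effects) > 2:
        raise ToxmixError("negative rho requires exactly two endpoints")
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=len(treatments))
    panels = []
    for k, (endpoint, effect) in enumerate(effects.items()):
        own = rng.normal(size=len(treatments))
        load = np.sqrt(abs(rho)) * (-1.0 if (rho < 0 and k == 1) else 1.0)
        scores = load * latent + np.sqrt(1.0 - abs(rho)) * own
        groups = {}
        for t, s in zip(treatments, scores):
            mu = baseline + effect * s
            groups[t] = list(mu + rng.normal(0.0, noise_sd, size=replicates))
        panels.append(BiomarkerPanel(endpoint=endpoint, groups=groups))
    return panels
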