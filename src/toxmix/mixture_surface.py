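"""Binary-mixture response surfaces: CA/IA references plus deviation functions.

Two reference models predict the mortality fraction of a binary mixture
from the single-compound logit-log curves:

* **Concentration Addition (CA)** treats the components as dilutions of one
  another; the mixture effect ``F`` solves

      c1 / EC1(F) + c2 / EC2(F) = exp(G)

  where ``ECi(F) = 10**((logit F - alpha_i) / beta_i)`` and ``G = 0`` for
  the plain reference.

* **Independent Action (IA)** multiplies survival probabilities; with a
  deviation the survival product is raised to ``exp(-G)``:

      F = 1 - [(1 - F1(c1)) * (1 - F2(c2))] ** exp(-G)

The deviation function ``G(z1, z2)`` perturbs the reference using the
toxic-unit fractions ``z1 + z2 = 1`` evaluated at the mixture's effect
level:

    S/A:  G = a * z1 * z2
    DR:   G = (a + b * z1) * z1 * z2          (dose-ratio dependent)
    DL:   G = a * z1 * z2 * (1 - b * TUtot)   (dose-level dependent)

Sign convention: ``a < 0`` implies synergism under both references.  For
DL the dose level is ``TUtot = c1/LC50_1 + c2/LC50_2``, so with ``b = 1``
the deviation changes sign at the 1-TU (LC50-equivalent) level.

Models are fitted by least squares on the mortality fraction (equivalently
Gaussian maximum likelihood) with a multi-start derivative-free search, and
nested models are compared by the likelihood-ratio statistic
``chi2 = n * ln(SSE_parent / SSE_child)`` referred to a chi-square
distribution with df equal to the number of added parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .dose_response import LogitCurve
from .exceptions import DegenerateResponseError, InsufficientDesignError, ToxmixError

__all__ = [
    "DeviationSpec",
    "SurfaceModel",
    "FitResult",
    "ModelComparison",
    "ModelSelectionResult",
    "deviation_g",
    "ca_predict",
    "ia_predict",
    "fit_surface",
    "likelihood_ratio_test",
    "model_selection",
    "surface_grid",
    "DEVIATION_FORMS",
]

DEVIATION_FORMS = ("none", "SA", "DR", "DL")
_N_FREE = {"none": 0, "SA": 1, "DR": 2, "DL": 2}
# parent -> children with parent recovered at b=0 (or a=0 for none)
_NESTS = {
    ("none", "SA"),
    ("none", "DR"),
    ("none", "DL"),
    ("SA", "DR"),
    ("SA", "DL"),
}
_FEPS = 1e-9  # effect-fraction bracket edge


@dataclass(frozen=True)
class DeviationSpec:
    """Deviation form and its interaction parameters.

    ``b`` is ignored for forms ``none`` and ``SA``; both parameters are
    ignored for ``none``.
    """

    form: str = "none"
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in DEVIATION_FORMS:
            raise ToxmixError(f"unknown deviation form {self.form!r}")

    @property
    def n_free(self) -> int:
        return _N_FREE[self.form]


@dataclass(frozen=True)
class SurfaceModel:
    """A CA or IA reference surface with an optional deviation."""

    reference: str
    curves: tuple[LogitCurve, LogitCurve]
    deviation: DeviationSpec = field(default_factory=DeviationSpec)

    def __post_init__(self) -> None:
        if self.reference not in ("CA", "IA"):
            raise ToxmixError(f"reference must be 'CA' or 'IA', got {self.reference!r}")

    @property
    def lc50s(self) -> tuple[float, float]:
        return (self.curves[0].lc50, self.curves[1].lc50)

    def predict(self, c1, c2) -> np.ndarray:
        """Predicted mortality fraction(s) at concentrations (mg L^-1)."""
        if self.reference == "CA":
            return ca_predict(self, c1, c2)
        return ia_predict(self, c1, c2)


def deviation_g(spec: DeviationSpec, z1: float, z2: float, tu_total: float = 0.0):
    """Evaluate the deviation function G at toxic-unit fractions (z1, z2).

    ``z1 + z2`` must equal 1 (tolerance 1e-9) elementwise; ``tu_total`` is
    only used by the DL form.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    if np.any(z1 < 0) or np.any(z2 < 0) or np.any(np.abs(z1 + z2 - 1.0) > 1e-9):
        raise ToxmixError("invalid toxic-unit fractions: need z1, z2 >= 0 and z1 + z2 = 1")
    return _g_unchecked(spec, z1, z2, np.asarray(tu_total, float))


def _g_unchecked(spec: DeviationSpec, z1, z2, tu_total):
    if spec.form == "none":
        return np.zeros(np.broadcast(z1, z2).shape)
    if spec.form == "SA":
        return spec.a * z1 * z2
    if spec.form == "DR":
        return (spec.a + spec.b * z1) * z1 * z2
    # DL: sign change where b * tu_total = 1
    return spec.a * z1 * z2 * (1.0 - spec.b * tu_total)


def _ec(curve: LogitCurve, f):
    """Concentration producing effect fraction f on a logit-log curve."""
    return 10.0 ** ((logit(f) - curve.alpha) / curve.beta)


def _marginal(curve: LogitCurve, c):
    c = np.asarray(c, float)
    out = np.zeros_like(c)
    pos = c > 0
    out[pos] = expit(curve.alpha + curve.beta * np.log10(c[pos]))
    return out


def _tu_total(model: SurfaceModel, c1, c2):
    l1, l2 = model.lc50s
    return np.asarray(c1, float) / l1 + np.asarray(c2, float) / l2


def ca_predict(model: SurfaceModel, c1, c2) -> np.ndarray | float:
    """Concentration-addition prediction of the mixture mortality fraction.

    The effect level is located by root-finding on F in
    [1e-9, 1 - 1e-9]; the toxic-unit fractions feeding G are re-evaluated
    at each candidate F, so the deviation is computed at the mixture's own
    effect level.  When the deviation pushes the root outside the bracket
    the prediction saturates at the bracket edge (effectively 0 or 1).

    One component at zero concentration reduces exactly to the other
    component's single-compound curve.
    """
    scalar = np.isscalar(c1) and np.isscalar(c2)
    c1 = np.atleast_1d(np.asarray(c1, float))
    c2 = np.atleast_1d(np.asarray(c2, float))
    c1, c2 = np.broadcast_arrays(c1, c2)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ToxmixError("concentrations must be >= 0")
    if np.any((c1 == 0) & (c2 == 0)):
        raise ToxmixError("CA surface undefined at (0, 0)")
    tut = _tu_total(model, c1, c2)
    out = np.empty(c1.shape)
    only_a = (c2 == 0)
    only_b = (c1 == 0)
    out[only_a] = _marginal(model.curves[0], c1[only_a])
    out[only_b] = _marginal(model.curves[1], c2[only_b])
    mixed = ~(only_a | only_b)
    if np.any(mixed):
        out[mixed] = _ca_solve(model, c1[mixed], c2[mixed], tut[mixed])
    return float(out[0]) if scalar else out


def _ca_residual_vec(model: SurfaceModel, f, c1, c2, tut):
    """Sign of c1/EC1(F) + c2/EC2(F) - exp(G) at candidate effect levels."""
    q1 = c1 / _ec(model.curves[0], f)
    q2 = c2 / _ec(model.curves[1], f)
    total = q1 + q2
    z1 = q1 / total
    g = _g_unchecked(model.deviation, z1, 1.0 - z1, tut)
    return total - np.exp(g)


def _ca_solve(model: SurfaceModel, c1, c2, tut):
    """Vectorized bisection for the CA effect level, one root per point.

    The residual is +inf-like at F -> 0 and negative at F -> 1 for any
    bounded G, so a plain bisection on [1e-9, 1 - 1e-9] is robust; 60
    halvings put the root within ~1e-18 of bracket width, far below the
    1e-8 accuracy the surface identities are held to.
    """
    lo = np.full(c1.shape, _FEPS)
    hi = np.full(c1.shape, 1.0 - _FEPS)
    rlo = _ca_residual_vec(model, lo, c1, c2, tut)
    rhi = _ca_residual_vec(model, hi, c1, c2, tut)
    # saturated cells: root outside the bracket, prediction pinned at edge
    under = rlo <= 0
    over = rhi >= 0
    active = ~(under | over)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rmid = _ca_residual_vec(model, mid, c1, c2, tut)
        go_up = (rmid > 0) & active
        go_dn = (rmid <= 0) & active
        lo[go_up] = mid[go_up]
        hi[go_dn] = mid[go_dn]
    out = 0.5 * (lo + hi)
    out[under] = _FEPS
    out[over] = 1.0 - _FEPS
    return out


def ia_predict(model: SurfaceModel, c1, c2) -> np.ndarray | float:
    """Independent-action prediction of the mixture mortality fraction.

    Reference: ``F = 1 - (1 - F1)(1 - F2)``.  With a deviation the survival
    product is raised to ``exp(-G)``, where G uses toxic-unit fractions
    evaluated at the IA-predicted effect level (solved by fixed-point
    iteration starting from the reference prediction).
    """
    scalar = np.isscalar(c1) and np.isscalar(c2)
    c1 = np.atleast_1d(np.asarray(c1, float))
    c2 = np.atleast_1d(np.asarray(c2, float))
    c1, c2 = np.broadcast_arrays(c1, c2)
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ToxmixError("concentrations must be >= 0")
    surv = (1.0 - _marginal(model.curves[0], c1)) * (1.0 - _marginal(model.curves[1], c2))
    f = 1.0 - surv
    if model.deviation.form != "none":
        tut = _tu_total(model, c1, c2)
        both = (c1 > 0) & (c2 > 0)  # G vanishes when either z is 0
        for it in range(80):
            fc = np.clip(f, _FEPS, 1.0 - _FEPS)
            q1 = np.where(both, c1 / _ec(model.curves[0], fc), 0.0)
            q2 = np.where(both, c2 / _ec(model.curves[1], fc), 0.0)
            tot = q1 + q2
            z1 = np.divide(q1, tot, out=np.zeros_like(q1), where=tot > 0)
            g = np.where(both, _g_unchecked(model.deviation, z1, 1.0 - z1, tut), 0.0)
            f_new = 1.0 - surv ** np.exp(-g)
            if np.max(np.abs(f_new - f)) < 1e-12:
                f = f_new
                break
            # plain iteration while it contracts; damp later in case of cycling
            f = f_new if it < 30 else 0.5 * (f + f_new)
        f = f_new
    return float(f[0]) if scalar else f


@dataclass(frozen=True)
class FitResult:
    """A fitted surface with its goodness-of-fit summary.

    ``loglik`` is the profile Gaussian log-likelihood at the SSE minimum;
    ``n_free`` counts deviation parameters plus refitted curve parameters.
    """

    model: SurfaceModel
    params: dict
    sse: float
    loglik: float
    r_squared: float
    n_obs: int
    n_free: int
    refit_singles: bool
    converged: bool

    @property
    def reference(self) -> str:
        return self.model.reference

    @property
    def form(self) -> str:
        return self.model.deviation.form


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of a nested model pair."""

    parent: FitResult
    child: FitResult
    chi2: float
    df: int
    p_value: float


def _prepare_data(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        c1 = data["conc_a"].to_numpy(float)
        c2 = data["conc_b"].to_numpy(float)
        obs = data["obs_fraction"].to_numpy(float)
        w = data["weight"].to_numpy(float) if "weight" in data else np.ones_like(obs)
    else:
        arr = np.asarray(data, float)
        c1, c2, obs = arr[:, 0], arr[:, 1], arr[:, 2]
        w = arr[:, 3] if arr.shape[1] > 3 else np.ones_like(obs)
    return c1, c2, obs, w


def _gaussian_loglik(sse: float, n: int) -> float:
    if sse <= 0:
        return float("inf")
    return -0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)


def fit_surface(
    data,
    reference: str,
    deviation: str = "none",
    curves: tuple[LogitCurve, LogitCurve] | None = None,
    refit_singles: bool = False,
    extra_starts: Sequence[Sequence[float]] = (),
) -> FitResult:
    """Least-squares fit of a reference (+ deviation) surface.

    Parameters
    ----------
    data
        Frame with columns ``conc_a, conc_b, obs_fraction`` (optional
        ``weight``), or an (n, 3)/(n, 4) array in that column order.
    reference
        ``"CA"`` or ``"IA"``.
    deviation
        One of ``none, SA, DR, DL``.
    curves
        Single-compound curves; required.  Fixed unless ``refit_singles``.
    refit_singles
        Also refit the four curve parameters jointly, starting from
        ``curves``.
    extra_starts
        Additional (a[, b]) start points appended to the built-in 5x5 grid
        over {-10, -5, 0, 5, 10}; used by :func:`model_selection` to seed a
        child from its parent's optimum so SSE never increases along the
        nesting ladder.
    """
    if curves is None:
        raise ToxmixError("curves are required")
    if deviation not in DEVIATION_FORMS:
        raise ToxmixError(f"unknown deviation form {deviation!r}")
    c1, c2, obs, w = _prepare_data(data)
    if len(obs) == 0:
        raise InsufficientDesignError("empty data")
    n_dev = _N_FREE[deviation]
    n_free = n_dev + (4 if refit_singles else 0)
    if len(obs) < n_free + 2:
        raise InsufficientDesignError(
            f"need at least {n_free + 2} observations for {n_free} free parameters"
        )
    sst = float(np.sum(w * (obs - np.average(obs, weights=w)) ** 2))
    if sst == 0 or np.ptp(obs) == 0:
        raise DegenerateResponseError("constant response: SStot is zero")

    def build(theta: np.ndarray) -> SurfaceModel:
        k = 0
        if refit_singles:
            cv = (
                LogitCurve(theta[0], theta[1]),
                LogitCurve(theta[2], theta[3]),
            )
            k = 4
        else:
            cv = curves
        if n_dev == 0:
            spec = DeviationSpec("none")
        elif n_dev == 1:
            spec = DeviationSpec(deviation, a=float(theta[k]))
        else:
            spec = DeviationSpec(deviation, a=float(theta[k]), b=float(theta[k + 1]))
        return SurfaceModel(reference, cv, spec)

    def objective(theta: np.ndarray) -> float:
        if refit_singles and (theta[1] <= 0 or theta[3] <= 0):
            return 1e6  # slopes must stay positive
        model = build(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = model.predict(c1, c2)
        if not np.all(np.isfinite(pred)):
            return 1e6
        return float(np.sum(w * (obs - pred) ** 2))

    curve_start = (
        [curves[0].alpha, curves[0].beta, curves[1].alpha, curves[1].beta]
        if refit_singles
        else []
    )
    grid = (-10.0, -5.0, 0.0, 5.0, 10.0)
    if n_dev == 0:
        dev_starts: list[list[float]] = [[]]
    elif n_dev == 1:
        dev_starts = [[a] for a in grid]
    else:
        dev_starts = [[a, b] for a in grid for b in grid]
    starts = [curve_start + list(s) for s in dev_starts]
    starts += [curve_start + list(map(float, s)) for s in extra_starts]

    best_theta, best_sse, converged = None, np.inf, False
    if n_free == 0:
        theta0 = np.asarray(starts[0], float)
        best_theta, best_sse, converged = theta0, objective(theta0), True
    else:
        # score every grid start once, then polish the most promising ones
        # (extra_starts from a parent model are always polished)
        scored = sorted(starts, key=lambda s: objective(np.asarray(s, float)))
        n_extra = len(extra_starts)
        polish = scored[:4] + [starts[len(starts) - n_extra + i] for i in range(n_extra)]
        for s in polish:
            res = optimize.minimize(
                objective,
                np.asarray(s, float),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000, "maxfev": 2000},
            )
            if res.fun < best_sse:
                best_theta, best_sse = res.x, float(res.fun)
                converged = converged or bool(res.success)
        # a start that is already optimal can beat the polished runs
        theta0 = np.asarray(scored[0], float)
        if objective(theta0) < best_sse:
            best_theta, best_sse = theta0, objective(theta0)
    if best_theta is None:
        raise ToxmixError("surface fit failed from every start")

    model = build(best_theta)
    params: dict = {}
    if refit_singles:
        params.update(
            alpha_1=model.curves[0].alpha,
            beta_1=model.curves[0].beta,
            alpha_2=model.curves[1].alpha,
            beta_2=model.curves[1].beta,
        )
    if n_dev >= 1:
        params["a"] = model.deviation.a
    if n_dev == 2:
        params["b"] = model.deviation.b
    return FitResult(
        model=model,
        params=params,
        sse=best_sse,
        loglik=_gaussian_loglik(best_sse, len(obs)),
        r_squared=1.0 - best_sse / sst,
        n_obs=len(obs),
        n_free=n_free,
        refit_singles=refit_singles,
        converged=converged,
    )


def likelihood_ratio_test(parent: FitResult, child: FitResult) -> ModelComparison:
    """Chi-square likelihood-ratio test of a nested surface pair.

    ``chi2 = n * ln(SSE_parent / SSE_child)`` with df equal to the number
    of added parameters.  A child SSE above the parent's (an optimizer
    artifact; impossible for truly nested optima) floors the statistic at
    zero with a warning.
    """
    if parent.n_obs != child.n_obs:
        raise ToxmixError("not nested: models were fitted to different data sizes")
    same_frame = (
        parent.reference == child.reference
        and parent.refit_singles == child.refit_singles
    )
    if not same_frame or (parent.form, child.form) not in _NESTS:
        raise ToxmixError(f"not nested: {parent.form} vs {child.form}")
    df = child.n_free - parent.n_free
    if child.sse > parent.sse:
        warnings.warn(
            "child SSE exceeds parent SSE; likelihood-ratio statistic floored at 0",
            stacklevel=2,
        )
        chi2 = 0.0
    else:
        chi2 = float(parent.n_obs * np.log(parent.sse / child.sse))
    return ModelComparison(
        parent=parent,
        child=child,
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
    )


@dataclass(frozen=True)
class ModelSelectionResult:
    """Fits and nested comparisons along the reference -> S/A -> {DR, DL} ladder."""

    reference: str
    fits: dict  # form -> FitResult
    comparisons: list  # list of ModelComparison

    def comparison(self, parent_form: str, child_form: str) -> ModelComparison | None:
        for cmp_ in self.comparisons:
            if cmp_.parent.form == parent_form and cmp_.child.form == child_form:
                return cmp_
        return None

    def to_frame(self) -> pd.DataFrame:
        """Report shaped like the standard deviation-model table: one column
        per model, rows a, b, R^2 and the p-values of the nested tests."""
        cols = {}
        for form in ("none", "SA", "DR", "DL"):
            fit = self.fits.get(form)
            if fit is None:
                continue
            ref_cmp = self.comparison("none", form)
            sa_cmp = self.comparison("SA", form)
            cols[self.reference if form == "none" else form] = {
                "a": fit.params.get("a", np.nan),
                "b": fit.params.get("b", np.nan),
                "r_squared": fit.r_squared,
                f"p_chi2_vs_{self.reference}": ref_cmp.p_value if ref_cmp else np.nan,
                "p_chi2_vs_SA": sa_cmp.p_value if sa_cmp else np.nan,
            }
        return pd.DataFrame(cols)


def model_selection(
    data,
    reference: str,
    curves: tuple[LogitCurve, LogitCurve],
    refit_singles: bool = False,
    forms: Sequence[str] = ("none", "SA", "DR", "DL"),
) -> ModelSelectionResult:
    """Fit the deviation-model ladder and run every nested comparison.

    The reference is fitted first, then S/A, then the two-parameter DR and
    DL forms; each child is additionally started from its parent's optimum
    so the SSE sequence is non-increasing along the ladder.
    """
    fits: dict[str, FitResult] = {}
    fits["none"] = fit_surface(
        data, reference, "none", curves=curves, refit_singles=refit_singles
    )

    def seed(parent: FitResult, pad: int) -> list[list[float]]:
        a = parent.params.get("a", 0.0)
        return [[a] + [0.0] * pad]

    if "SA" in forms:
        fits["SA"] = fit_surface(
            data,
            reference,
            "SA",
            curves=curves,
            refit_singles=refit_singles,
            extra_starts=seed(fits["none"], 0),
        )
    for form in ("DR", "DL"):
        if form in forms:
            parent = fits.get("SA", fits["none"])
            fits[form] = fit_surface(
                data,
                reference,
                form,
                curves=curves,
                refit_singles=refit_singles,
                extra_starts=seed(parent, 1),
            )
    comparisons = []
    for parent_form, child_form in (
        ("none", "SA"),
        ("none", "DR"),
        ("none", "DL"),
        ("SA", "DR"),
        ("SA", "DL"),
    ):
        if parent_form in fits and child_form in fits:
            comparisons.append(
                likelihood_ratio_test(fits[parent_form], fits[child_form])
            )
    return ModelSelectionResult(reference=reference, fits=fits, comparisons=comparisons)


def surface_grid(
    model: SurfaceModel,
    tu_a: Iterable[float],
    tu_b: Iterable[float],
) -> pd.DataFrame:
    """Evaluate a fitted surface over a toxic-unit grid.

    Returns one row per (tu_a, tu_b) pair of the Cartesian grid with the
    corresponding concentrations, the predicted mortality fraction and the
    deviation magnitude G at that point (0 for a pure reference).
    """
    l1, l2 = model.lc50s
    rows = []
    for ta in tu_a:
        for tb in tu_b:
            if ta < 0 or tb < 0:
                raise ToxmixError("TU grid bounds must be >= 0")
            c1, c2 = ta * l1, tb * l2
            if c1 == 0 and c2 == 0:
                f, g = 0.0, 0.0
            else:
                f = float(model.predict(c1, c2))
                if model.deviation.form == "none" or c1 == 0 or c2 == 0:
                    g = 0.0
                else:
                    fc = min(max(f, _FEPS), 1 - _FEPS)
                    q1 = c1 / _ec(model.curves[0], fc)
                    q2 = c2 / _ec(model.curves[1], fc)
                    z1 = q1 / (q1 + q2)
                    g = float(
                        _g_unchecked(model.deviation, z1, 1 - z1, ta + tb)
                    )
            rows.append(
                {
                    "tu_a": ta,
                    "tu_b": tb,
                    "conc_a": c1,
                    "conc_b": c2,
                    "predicted": f,
                    "g": g,
                }
            )
    return pd.DataFrame(rows)
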