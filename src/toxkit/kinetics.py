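"""Tight-binding serine-protease inhibition kinetics.

Canonical (Laskowski-mechanism) Kunitz inhibitors such as ShPI-1 bind their
target proteases with dissociation constants comparable to the enzyme
concentration used in the assay, so free and total inhibitor concentrations
differ appreciably and the classical steady-state (Michaelis/Dixon) equations
no longer apply.  The fractional residual activity then follows the quadratic
Morrison equation,

    vi/v0 = 1 - [(E0 + I0 + Ki_app) - sqrt((E0 + I0 + Ki_app)^2 - 4 E0 I0)]
                / (2 E0),

whose single free parameter, the apparent dissociation constant ``Ki_app``,
is estimated by nonlinear least squares with the enzyme concentration ``E0``
fixed (known independently from active-site titration).  Under competitive
inhibition the substrate raises the apparent constant, and the true constant
is recovered as ``Ki = Ki_app / (1 + S0/KM)``.  An inhibitor is operationally
"tight-binding" when Ki <= 1e-7 M.

The module also covers the two standard companion experiments: active-site
titration of the inhibitor against an excess of enzyme ([E0]/Ki >= 100, where
binding is stoichiometric and the activity-versus-inhibitor plot is a straight
line hitting zero at the equivalence point), and the reversibility check
(activity must rise with substrate concentration and be stable over
preincubation time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "AssayCondition",
    "InhibitionCurve",
    "TightBindingFit",
    "KiResult",
    "TitrationSeries",
    "TitrationResult",
    "ReversibilityVerdict",
    "ReversibilityAssessment",
    "KineticsError",
    "NoInhibitionError",
    "TIGHT_BINDING_THRESHOLD_M",
    "morrison_fraction",
    "fit_ki_app",
    "correct_ki",
    "classify_tight_binding",
    "titrate_active_concentration",
    "assess_reversibility",
    "equilibrium_fraction_bisection",
]

#: Operational tight-binding threshold (molar).
TIGHT_BINDING_THRESHOLD_M = 1e-7


class KineticsError(ValueError):
    """Invalid input or undeterminable quantity in a kinetics computation."""


class NoInhibitionError(KineticsError):
    """Raised when a curve carries no inhibition signal to fit."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayCondition:
    """Conditions of one enzyme-inhibition assay.

    ``E0`` is the active enzyme concentration in molar unless
    ``activity_units_only`` is set, in which case the enzyme was quantified in
    activity units and molar-based fitting is unavailable.  ``S0`` and ``KM``
    are the substrate concentration and its Michaelis constant (molar).
    """

    enzyme_id: str
    E0: float
    S0: float = 0.0
    KM: float | None = None
    substrate_id: str = ""
    buffer: str = ""
    activity_units_only: bool = False

    def __post_init__(self) -> None:
        if not self.activity_units_only and not (self.E0 > 0):
            raise KineticsError(f"E0 must be positive (got {self.E0!r})")
        if self.S0 < 0:
            raise KineticsError(f"S0 must be non-negative (got {self.S0!r})")
        if self.KM is not None and not (self.KM > 0):
            raise KineticsError(f"KM must be positive (got {self.KM!r})")


@dataclass(frozen=True)
class InhibitionCurve:
    """Total-inhibitor grid with fractional residual activities vi/v0."""

    condition: AssayCondition
    I_grid: tuple[float, ...]
    fractional_activity: tuple[float, ...]
    replicates: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        I = np.asarray(self.I_grid, dtype=float)
        fa = np.asarray(self.fractional_activity, dtype=float)
        if I.size != fa.size:
            raise KineticsError("I_grid and fractional_activity length mismatch")
        if I.size and not np.all(np.diff(I) > 0):
            raise KineticsError("I_grid must be strictly increasing")
        if I.size and I[0] < 0:
            raise KineticsError("inhibitor concentrations must be non-negative")
        if fa.size and (fa.min() < 0 or fa.max() > 1.05):
            raise KineticsError(
                "fractional activities must lie in [0, 1.05] "
                f"(got range [{fa.min():g}, {fa.max():g}])"
            )


@dataclass(frozen=True)
class TightBindingFit:
    """Result of a Morrison-equation fit of one inhibition curve."""

    Ki_app: float
    Ki_app_se: float
    residual_sum_sq: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class KiResult:
    """Substrate-corrected dissociation constant with classification.

    The correction assumes purely competitive inhibition (the substrate and
    inhibitor compete for the same site), which is the canonical mechanism
    for Kunitz-domain inhibitors.
    """

    Ki_app: float
    Ki: float
    S0_over_KM: float
    tight_binding: bool
    E0_over_Ki: float
    assumes_competitive: bool = True


@dataclass(frozen=True)
class TitrationSeries:
    """Stoichiometric titration of inhibitor against a fixed enzyme amount."""

    E_total: float
    inhibitor_amounts: tuple[float, ...]
    fractional_activity: tuple[float, ...]
    E0_over_Ki: float

    def __post_init__(self) -> None:
        if len(self.inhibitor_amounts) != len(self.fractional_activity):
            raise KineticsError("titration lengths mismatch")


@dataclass(frozen=True)
class TitrationResult:
    active_concentration: float
    slope: float
    intercept: float
    n_linear_points: int
    warnings: tuple[str, ...] = ()


class ReversibilityVerdict(str, Enum):
    reversible_substrate_competitive = "reversible_substrate_competitive"
    equilibrium_not_reached = "equilibrium_not_reached"
    inconsistent = "inconsistent"


@dataclass(frozen=True)
class ReversibilityAssessment:
    S0_levels: tuple[float, ...]
    vi_over_v0_at_levels: tuple[float, ...]
    preincubation_minutes: tuple[float, ...]
    verdict: ReversibilityVerdict


# ---------------------------------------------------------------------------
# Morrison model
# ---------------------------------------------------------------------------


def morrison_fraction(E0: float, I0: float, Ki_app: float) -> float:
    """Fractional activity vi/v0 of a tight-binding inhibition assay.

    Quadratic mass-balance solution for 1:1 binding of total enzyme ``E0``
    and total inhibitor ``I0`` with apparent dissociation constant
    ``Ki_app`` (all molar).  Continuous and non-increasing in ``I0``; equals
    1 at ``I0 = 0`` and tends to ``max(0, 1 - I0/E0)`` in the stoichiometric
    limit ``Ki_app -> 0``.
    """
    E0 = float(E0)
    I0 = float(I0)
    Ki_app = float(Ki_app)
    if not (math.isfinite(E0) and math.isfinite(I0) and math.isfinite(Ki_app)):
        raise KineticsError("morrison_fraction requires finite inputs")
    if E0 <= 0 or I0 < 0 or Ki_app <= 0:
        raise KineticsError(
            f"require E0 > 0, I0 >= 0, Ki_app > 0 (got {E0}, {I0}, {Ki_app})"
        )
    s = E0 + I0 + Ki_app
    disc = s * s - 4.0 * E0 * I0
    # disc >= (E0 - I0)^2 + Ki^2 > 0 analytically; guard rounding.  The
    # complex concentration is the smaller quadratic root, evaluated in the
    # cancellation-free product form 2c/(s + sqrt(disc)).
    ei = 2.0 * E0 * I0 / (s + math.sqrt(max(disc, 0.0)))
    frac = 1.0 - ei / E0
    return min(1.0, max(0.0, frac))


def equilibrium_fraction_bisection(E0: float, I0: float, Ki_app: float) -> float:
    """Independent mass-balance solver for vi/v0 (bisection on [EI]).

    Solves (E0-x)(I0-x) = Ki_app * x for the complex concentration x on
    [0, min(E0, I0)] by bisection run to floating-point exhaustion, without
    using the closed-form quadratic.  Intended as a cross-check oracle for
    :func:`morrison_fraction`.
    """
    if I0 == 0:
        return 1.0

    def poly(x: float) -> float:
        return (E0 - x) * (I0 - x) - Ki_app * x

    lo, hi = 0.0, min(E0, I0)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:
            break
        if poly(mid) > 0:
            lo = mid
        else:
            hi = mid
    x = 0.5 * (lo + hi)
    return 1.0 - x / E0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _initial_ki_app(I: np.ndarray, fa: np.ndarray, E0: float) -> float:
    """Initial guess: the I0 at which vi/v0 crosses 0.5, less bound enzyme.

    Falls back to the median of the positive grid when the curve does not
    cross 0.5.
    """
    below = np.where(fa <= 0.5)[0]
    above = np.where(fa > 0.5)[0]
    if below.size and above.size:
        j = below[0]
        i = j - 1
        if i >= 0 and fa[i] != fa[j]:
            t = (0.5 - fa[i]) / (fa[j] - fa[i])
            i50 = I[i] + t * (I[j] - I[i])
        else:
            i50 = I[j]
        # At vi/v0 = 0.5 half the enzyme is complexed: Ki_app ~= I50 - E0/2.
        guess = i50 - E0 / 2.0
        if guess > 0:
            return float(guess)
    positive = I[I > 0]
    return float(np.median(positive)) if positive.size else E0


def fit_ki_app(curve: InhibitionCurve, co_fit_E0: bool = False) -> TightBindingFit:
    """Fit the Morrison equation to an inhibition curve.

    ``E0`` is fixed from the assay condition (it is known from active-site
    titration); ``co_fit_E0=True`` additionally frees E0 as a diagnostic.
    Unweighted nonlinear least squares on pooled points with ``Ki_app``
    parameterised on a log scale to enforce positivity.

    Raises :class:`NoInhibitionError` when every point sits at full activity
    and :class:`KineticsError` for under-determined input (< 5 points or no
    point below vi/v0 = 0.8).
    """
    cond = curve.condition
    if cond.activity_units_only:
        raise KineticsError(
            f"enzyme {cond.enzyme_id!r} is quantified in activity units only; "
            "molar Morrison fitting is unavailable"
        )
    I = np.asarray(curve.I_grid, dtype=float)
    fa = np.asarray(curve.fractional_activity, dtype=float)
    if I.size < 5:
        raise KineticsError(f"need >= 5 points to fit (got {I.size})")
    if np.all(fa >= 0.98):
        raise NoInhibitionError(
            f"no inhibition detected for enzyme {cond.enzyme_id!r}: "
            "all fractional activities ~ 1"
        )
    if not np.any(fa < 0.8):
        raise KineticsError(
            "curve carries too little inhibition signal (no point below 0.8)"
        )

    E0 = cond.E0
    morrison_vec = np.vectorize(morrison_fraction)

    if co_fit_E0:
        def resid(p: np.ndarray) -> np.ndarray:
            ki, e0 = np.exp(p)
            return morrison_vec(e0, I, ki) - fa
        p0 = np.log([_initial_ki_app(I, fa, E0), E0])
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            return morrison_vec(E0, I, np.exp(p[0])) - fa
        p0 = np.log([_initial_ki_app(I, fa, E0)])

    sol = optimize.least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    ki_app = float(np.exp(sol.x[0]))
    rss = float(np.sum(sol.fun**2))
    converged = bool(sol.success) and math.isfinite(ki_app) and ki_app > 0

    # Standard error from the Gauss-Newton covariance, delta method for the
    # log-parameterisation.
    se = float("nan")
    dof = I.size - sol.x.size
    if converged and dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * rss / dof
            se = float(np.sqrt(cov[0, 0])) * ki_app
        except np.linalg.LinAlgError:
            pass

    return TightBindingFit(
        Ki_app=ki_app,
        Ki_app_se=se,
        residual_sum_sq=rss,
        converged=converged,
        n_points=int(I.size),
    )


def correct_ki(Ki_app: float, S0: float, KM: float | None) -> float:
    """Substrate-corrected dissociation constant, Ki = Ki_app/(1 + S0/KM).

    Assumes competitive inhibition.  Refuses to proceed without ``KM`` rather
    than silently returning the apparent value.
    """
    if Ki_app <= 0:
        raise KineticsError(f"Ki_app must be positive (got {Ki_app!r})")
    if S0 < 0:
        raise KineticsError(f"S0 must be non-negative (got {S0!r})")
    if S0 == 0:
        return float(Ki_app)
    if KM is None:
        raise KineticsError(
            "substrate correction unavailable: KM not provided "
            "(refusing to return the uncorrected Ki_app)"
        )
    if KM <= 0:
        raise KineticsError(f"KM must be positive (got {KM!r})")
    return float(Ki_app) / (S0 / KM + 1.0)


def classify_tight_binding(Ki: float) -> bool:
    """True iff Ki <= 1e-7 M (boundary inclusive)."""
    if not (Ki > 0) or not math.isfinite(Ki):
        raise KineticsError(f"Ki must be positive and finite (got {Ki!r})")
    return Ki <= TIGHT_BINDING_THRESHOLD_M


def analyze_curve(curve: InhibitionCurve) -> tuple[TightBindingFit, KiResult]:
    """Fit, substrate-correct and classify one inhibition curve."""
    fit = fit_ki_app(curve)
    cond = curve.condition
    ki = correct_ki(fit.Ki_app, cond.S0, cond.KM)
    s_over_km = cond.S0 / cond.KM if (cond.KM and cond.S0) else 0.0
    result = KiResult(
        Ki_app=fit.Ki_app,
        Ki=ki,
        S0_over_KM=s_over_km,
        tight_binding=classify_tight_binding(ki),
        E0_over_Ki=cond.E0 / ki,
    )
    return fit, result


# ---------------------------------------------------------------------------
# Active-site titration
# ---------------------------------------------------------------------------


def titrate_active_concentration(
    series: TitrationSeries,
    linear_band: tuple[float, float] = (0.15, 0.85),
) -> TitrationResult:
    """Active inhibitor concentration from a stoichiometric titration.

    Under [E0]/Ki >= 100 binding is effectively stoichiometric and activity
    declines linearly with added inhibitor, reaching zero at the equivalence
    point where total inhibitor equals total enzyme (1:1 complex).  A least-
    squares line through the descending region (activities within
    ``linear_band``) is extrapolated to its x-intercept, reported on the same
    concentration axis as ``inhibitor_amounts``.
    """
    x = np.asarray(series.inhibitor_amounts, dtype=float)
    fa = np.asarray(series.fractional_activity, dtype=float)
    warns: list[str] = []
    if series.E0_over_Ki < 100:
        warns.append(
            f"E0/Ki = {series.E0_over_Ki:g} < 100: titration is not strictly "
            "stoichiometric and the equivalence point may be biased"
        )
    if np.all(fa >= 0.98):
        raise KineticsError("no titration signal: activity never drops below 1")
    if fa[-1] > fa[0]:
        raise KineticsError("no titration signal: series is not decreasing")

    lo, hi = linear_band
    mask = (fa >= lo) & (fa <= hi)
    if mask.sum() < 3:
        raise KineticsError(
            f"titration underdetermined: {int(mask.sum())} points in the "
            f"linear region [{lo}, {hi}] (need >= 3)"
        )
    slope, intercept = np.polyfit(x[mask], fa[mask], 1)
    if slope >= 0:
        raise KineticsError("no titration signal: non-descending linear region")
    x_eq = -intercept / slope
    return TitrationResult(
        active_concentration=float(x_eq),
        slope=float(slope),
        intercept=float(intercept),
        n_linear_points=int(mask.sum()),
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# Reversibility
# ---------------------------------------------------------------------------


def assess_reversibility(
    S0_levels: Sequence[float],
    vi_over_v0_at_levels: Sequence[float],
    preincubation_minutes: Sequence[float],
    vi_over_v0_at_times: Sequence[float],
    substrate_tolerance: float = 0.02,
    time_tolerance: float = 0.05,
    E0_at_levels: Sequence[float] | None = None,
    I0_at_levels: Sequence[float] | None = None,
) -> ReversibilityAssessment:
    """Classify an inhibitor as substrate-competitive-reversible or not.

    Two diagnostics: (i) fractional activity must increase strictly with
    substrate concentration (each step exceeding ``substrate_tolerance``,
    default 2 percentage points), showing that substrate displaces the
    inhibitor; (ii) activity must be stable over preincubation time within
    ``time_tolerance`` (default 5 points), showing that equilibrium is
    reached.  A still-falling time series yields ``equilibrium_not_reached``;
    a flat substrate response yields ``inconsistent``.
    """
    s0 = np.asarray(S0_levels, dtype=float)
    fa_s = np.asarray(vi_over_v0_at_levels, dtype=float)
    t = np.asarray(preincubation_minutes, dtype=float)
    fa_t = np.asarray(vi_over_v0_at_times, dtype=float)
    if s0.size != fa_s.size:
        raise KineticsError("substrate levels/activities length mismatch")
    if not np.all(np.diff(s0) > 0):
        raise KineticsError("S0 levels must be strictly increasing")
    if t.size != fa_t.size:
        raise KineticsError("preincubation times/activities length mismatch")
    if t.size < 2:
        raise KineticsError("need >= 2 preincubation times")
    for name, levels in (("E0", E0_at_levels), ("I0", I0_at_levels)):
        if levels is not None:
            arr = np.asarray(levels, dtype=float)
            if arr.size != s0.size or not np.allclose(arr, arr[0]):
                raise KineticsError(
                    f"{name} must be identical across substrate levels"
                )

    time_stable = float(fa_t.max() - fa_t.min()) <= time_tolerance
    still_falling = (not time_stable) and bool(fa_t[-1] < fa_t[0])
    substrate_competitive = bool(np.all(np.diff(fa_s) > substrate_tolerance))

    if still_falling:
        verdict = ReversibilityVerdict.equilibrium_not_reached
    elif substrate_competitive and time_stable:
        verdict = ReversibilityVerdict.reversible_substrate_competitive
    else:
        verdict = ReversibilityVerdict.inconsistent

    return ReversibilityAssessment(
        S0_levels=tuple(map(float, s0)),
        vi_over_v0_at_levels=tuple(map(float, fa_s)),
        preincubation_minutes=tuple(map(float, t)),
        verdict=verdict,
    )
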