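"""Kv-channel block and gating analysis from steady-state TEVC summaries.

Works on steady-state current summaries (not raw traces): percent block from
paired control/toxin currents, Hill concentration-response fits for the IC50,
conductance-voltage transformation of IV curves, Boltzmann fits of the
activation midpoint V1/2, a paired t-test for toxin-induced V1/2 shifts, and
a voltage-dependence check of the degree of block.

Models:
    percent block   y = 100 * (1 - I_toxin / I_control)
    Hill            y = 100 / (1 + (IC50/[toxin])^h)
    conductance     G(V) = I(V) / (V - Erev), normalised to its maximum
    Boltzmann       G/Gmax = 1 / (1 + exp((V_half - V) / k))
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SteadyStateCurrentPair",
    "DoseResponse",
    "HillFit",
    "IVSeries",
    "ActivationFit",
    "EphysError",
    "percent_block",
    "hill_response",
    "fit_hill",
    "boltzmann_po",
    "conductance_from_iv",
    "fit_boltzmann",
    "compare_v_half",
    "voltage_dependence_of_block",
]


class EphysError(ValueError):
    """Invalid electrophysiology input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyStateCurrentPair:
    """Control/toxin steady-state currents at one test potential."""

    V_test: float  # mV
    I_control: float  # uA
    I_toxin: float  # uA
    toxin_conc: float  # M

    def __post_init__(self) -> None:
        for v in (self.V_test, self.I_control, self.I_toxin):
            if not math.isfinite(v):
                raise EphysError("currents and voltages must be finite")


@dataclass(frozen=True)
class DoseResponse:
    """Percent current block versus toxin concentration for one channel."""

    channel_id: str
    conc: tuple[float, ...]  # M, strictly increasing
    percent_block: tuple[float, ...]  # [0, 100]
    n_per_point: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, dtype=float)
        y = np.asarray(self.percent_block, dtype=float)
        if c.size != y.size:
            raise EphysError("conc and percent_block length mismatch")
        if c.size and not np.all(np.diff(c) > 0):
            raise EphysError("concentrations must be strictly increasing")
        if y.size and (y.min() < 0 or y.max() > 100):
            raise EphysError("percent block must lie in [0, 100]")


@dataclass(frozen=True)
class HillFit:
    IC50: float  # M
    h: float
    IC50_se: float
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class IVSeries:
    """Steady-state current-voltage relationship under one condition."""

    V: tuple[float, ...]  # mV, strictly increasing
    I: tuple[float, ...]  # uA
    condition: str = "control"  # "control" | "toxin"
    Erev: float | None = None  # mV

    def __post_init__(self) -> None:
        v = np.asarray(self.V, dtype=float)
        if v.size != len(self.I):
            raise EphysError("V and I length mismatch")
        if v.size and not np.all(np.diff(v) > 0):
            raise EphysError("voltage grid must be strictly increasing")


@dataclass(frozen=True)
class ActivationFit:
    V_half: float  # mV
    slope_k: float  # mV
    Gmax: float
    converged: bool
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Percent block
# ---------------------------------------------------------------------------


def percent_block(I_control: float, I_toxin: float) -> float:
    """Percent current block, 100*(1 - I_toxin/I_control), clamped to [0, 100].

    Both currents must share sign (the same driving-force direction);
    ``I_control = 0`` leaves the block undefined.
    """
    if I_control == 0:
        raise EphysError("undefined block: control current is zero")
    if I_control * I_toxin < 0:
        raise EphysError("control and toxin currents must share sign")
    raw = 100.0 * (1.0 - I_toxin / I_control)
    return min(100.0, max(0.0, raw))


# ---------------------------------------------------------------------------
# Hill concentration-response
# ---------------------------------------------------------------------------


def hill_response(conc, IC50: float, h: float = 1.0):
    """Percent block predicted by the Hill equation y = 100/(1+(IC50/c)^h)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        y = 100.0 / (1.0 + (IC50 / c) ** h)
    return np.where(c > 0, y, 0.0)


def fit_hill(
    dr: DoseResponse,
    fix_h: float | None = None,
    monotonicity_tolerance: float = 5.0,
) -> HillFit:
    """Fit the Hill equation to a concentration-response curve.

    ``IC50`` (and the Hill coefficient ``h`` unless ``fix_h`` is given) are
    estimated by unweighted nonlinear least squares with log-scale
    positivity parameterisation.  Diagnostic flags:

    * ``"IC50 extrapolated"`` -- the observed plateau never reaches 50%, so
      the midpoint lies beyond the sampled range;
    * ``"bracketing"`` -- no points on both sides of 50% block;
    * ``"non-monotonic"`` -- response decreases by more than
      ``monotonicity_tolerance`` percentage points anywhere along the grid.
    """
    c = np.asarray(dr.conc, dtype=float)
    y = np.asarray(dr.percent_block, dtype=float)
    if c.size < 4:
        raise EphysError(f"need >= 4 concentrations (got {c.size})")

    flags: list[str] = []
    if np.min(np.diff(y)) < -monotonicity_tolerance:
        flags.append("non-monotonic")
    if y.max() < 50.0:
        flags.append("IC50 extrapolated")
    if not (np.any(y < 50.0) and np.any(y > 50.0)):
        if "IC50 extrapolated" not in flags:
            flags.append("bracketing")

    # Initial IC50: concentration where the response crosses 50%, else the
    # geometric median of the grid.
    above = np.where(y >= 50.0)[0]
    if above.size and above[0] > 0:
        i, j = above[0] - 1, above[0]
        t = (50.0 - y[i]) / (y[j] - y[i]) if y[j] != y[i] else 0.5
        ic50_0 = c[i] * (c[j] / c[i]) ** t
    else:
        ic50_0 = float(np.exp(np.mean(np.log(c))))

    if fix_h is not None:
        def resid(p: np.ndarray) -> np.ndarray:
            return hill_response(c, np.exp(p[0]), fix_h) - y
        p0 = np.array([np.log(ic50_0)])
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            return hill_response(c, np.exp(p[0]), np.exp(p[1])) - y
        p0 = np.array([np.log(ic50_0), 0.0])

    sol = optimize.least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    ic50 = float(np.exp(sol.x[0]))
    h = fix_h if fix_h is not None else float(np.exp(sol.x[1]))
    converged = bool(sol.success) and math.isfinite(ic50) and ic50 > 0

    se = float("nan")
    dof = c.size - sol.x.size
    rss = float(np.sum(sol.fun**2))
    if converged and dof > 0:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
            se = float(np.sqrt(cov[0, 0])) * ic50
        except np.linalg.LinAlgError:
            pass

    return HillFit(IC50=ic50, h=float(h), IC50_se=se, converged=converged,
                   flags=tuple(flags))


# ---------------------------------------------------------------------------
# Conductance and activation
# ---------------------------------------------------------------------------


def boltzmann_po(V, V_half: float, slope_k: float):
    """Open probability 1/(1 + exp((V_half - V)/k))."""
    v = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + np.exp((V_half - v) / slope_k))


def estimate_erev(iv: IVSeries) -> float:
    """Reversal potential as the zero-crossing of the IV by interpolation."""
    v = np.asarray(iv.V, dtype=float)
    i = np.asarray(iv.I, dtype=float)
    sign_change = np.where(np.sign(i[:-1]) * np.sign(i[1:]) < 0)[0]
    if not sign_change.size:
        raise EphysError("cannot estimate Erev: IV does not cross zero")
    j = sign_change[0]
    t = -i[j] / (i[j + 1] - i[j])
    return float(v[j] + t * (v[j + 1] - v[j]))


def conductance_from_iv(
    iv: IVSeries,
    Erev: float | None = None,
    exclusion_mV: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised chord conductance G(V) = I/(V - Erev) from an IV series.

    Points within ``exclusion_mV`` of the reversal potential are dropped
    (the chord conductance is numerically unstable there).  Returns
    ``(V_kept, G_normalised)`` with G scaled to its maximum.
    """
    if Erev is None:
        Erev = iv.Erev if iv.Erev is not None else estimate_erev(iv)
    v = np.asarray(iv.V, dtype=float)
    i = np.asarray(iv.I, dtype=float)
    keep = np.abs(v - Erev) >= exclusion_mV
    if not keep.any():
        raise EphysError(
            f"all voltages within {exclusion_mV} mV of Erev = {Erev:g} mV"
        )
    v, i = v[keep], i[keep]
    g = i / (v - Erev)
    g = np.where(g < 0, 0.0, g)  # sign convention: conductance is >= 0
    gmax = g.max()
    if gmax == 0:
        raise EphysError("all-zero conductance: no current in the series")
    return v, g / gmax


def fit_boltzmann(
    V: Sequence[float],
    G: Sequence[float],
) -> ActivationFit:
    """Fit a Boltzmann activation curve G = Gmax/(1 + exp((V_half - V)/k)).

    ``V_half`` (midpoint), ``slope_k`` (steepness, mV, positive) and ``Gmax``
    are estimated by nonlinear least squares.  A ``"transition not spanned"``
    flag is set when the data do not cover the sigmoid transition
    (min G > 0.3 or max G < 0.7 of the observed maximum), and
    ``converged=False`` on degenerate flat input.
    """
    v = np.asarray(V, dtype=float)
    g = np.asarray(G, dtype=float)
    if v.size != g.size or v.size < 4:
        raise EphysError("need >= 4 (V, G) points")

    flags: list[str] = []
    gmax_obs = g.max()
    if gmax_obs <= 0 or g.max() - g.min() < 1e-12:
        return ActivationFit(
            V_half=float("nan"), slope_k=float("nan"), Gmax=float(gmax_obs),
            converged=False, flags=("degenerate flat series",),
        )
    gn = g / gmax_obs
    if gn.min() > 0.3 or gn.max() < 0.7:
        flags.append("transition not spanned")

    # Initial guesses: midpoint at the half-max crossing, slope from range.
    half_idx = int(np.argmin(np.abs(gn - 0.5)))
    p0 = np.array([v[half_idx], max((v.max() - v.min()) / 8.0, 1.0), gmax_obs])

    def resid(p: np.ndarray) -> np.ndarray:
        v_half, log_k, gmax = p[0], p[1], p[2]
        return gmax * boltzmann_po(v, v_half, np.exp(log_k)) - g

    p0[1] = np.log(p0[1])
    sol = optimize.least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    v_half = float(sol.x[0])
    slope_k = float(np.exp(sol.x[1]))
    gmax = float(sol.x[2])
    converged = bool(sol.success) and math.isfinite(v_half)
    return ActivationFit(V_half=v_half, slope_k=slope_k, Gmax=gmax,
                         converged=converged, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VHalfComparison:
    t_statistic: float
    p_value: float
    mean_shift_mV: float
    n_pairs: int
    shift_detected: bool

    @property
    def verdict(self) -> str:
        return "shift detected" if self.shift_detected else "no shift"


def compare_v_half(
    fits_control: Sequence[ActivationFit | float],
    fits_toxin: Sequence[ActivationFit | float],
    alpha: float = 0.05,
) -> VHalfComparison:
    """Paired two-sided t-test for a toxin-induced shift of V1/2.

    Accepts paired replicate :class:`ActivationFit` objects (or bare V1/2
    values).  Verdict is "no shift" iff p >= ``alpha``.  Identical pairs give
    t = 0, p = 1.
    """
    def vhalf(x):
        return x.V_half if isinstance(x, ActivationFit) else float(x)

    a = np.asarray([vhalf(f) for f in fits_control], dtype=float)
    b = np.asarray([vhalf(f) for f in fits_toxin], dtype=float)
    if a.size != b.size or a.size < 2:
        raise EphysError("need >= 2 paired replicates")
    d = b - a
    if np.allclose(d, 0.0):
        t_stat, p = 0.0, 1.0
    elif np.allclose(d, d[0]):
        # Zero within-pair variance with a constant offset: certain shift.
        t_stat, p = math.copysign(math.inf, d[0]), 0.0
    else:
        t_stat, p = stats.ttest_rel(b, a)
    return VHalfComparison(
        t_statistic=float(t_stat),
        p_value=float(p),
        mean_shift_mV=float(d.mean()),
        n_pairs=int(a.size),
        shift_detected=bool(p < alpha),
    )


@dataclass(frozen=True)
class VoltageDependenceReport:
    V: tuple[float, ...]
    percent_block: tuple[float, ...]
    block_range: float
    trend_p_value: float
    voltage_independent: bool

    @property
    def verdict(self) -> str:
        return ("voltage independent" if self.voltage_independent
                else "voltage dependent")


def voltage_dependence_of_block(
    pairs: Sequence[SteadyStateCurrentPair],
    tolerance_points: float = 5.0,
    alpha: float = 0.05,
) -> VoltageDependenceReport:
    """Assess whether the degree of block varies with test potential.

    Requires >= 3 voltages spanning >= 40 mV.  The block is called voltage
    independent when the max-min spread of percent block across the grid is
    within ``tolerance_points`` percentage points, or when a linear trend
    test (slope of block vs V) is non-significant at ``alpha``.
    """
    if len(pairs) < 3:
        raise EphysError("need >= 3 test potentials")
    v = np.asarray([p.V_test for p in pairs], dtype=float)
    if v.max() - v.min() < 40.0:
        raise EphysError("voltage grid must span >= 40 mV")
    blocks = np.asarray(
        [percent_block(p.I_control, p.I_toxin) for p in pairs], dtype=float
    )
    spread = float(blocks.max() - blocks.min())
    if np.allclose(blocks, blocks[0]) or np.allclose(v, v[0]):
        trend_p = 1.0
    else:
        trend_p = float(stats.linregress(v, blocks).pvalue)
    independent = spread <= tolerance_points or trend_p >= alpha
    return VoltageDependenceReport(
        V=tuple(map(float, v)),
        percent_block=tuple(map(float, blocks)),
        block_range=spread,
        trend_p_value=trend_p,
        voltage_independent=bool(independent),
    )
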