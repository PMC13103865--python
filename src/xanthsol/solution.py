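"""Solution-side metrics: qNMR molality, solubility-increase factor,
linear-vs-hydrotrope curve discrimination, breakpoints, phase domains.

The quantitative-NMR molality uses the water signal as internal standard:
with ``A_c`` the integral of a solute peak carrying ``N_c`` protons per
molecule and ``A_w`` the water integral (two protons per molecule),

    m = (A_c / N_c) / (A_w / 2) / M_W,       M_W = 0.0180153 kg/mol,

i.e. the solute-to-water mole ratio times the 55.508 mol/kg of water in a
kilogram of itself.  The solubility-increase factor is the plain quotient
``F_SI = s_SA / s0`` of the saturation molality with and without the
solubilizing agent.

Curve discrimination contrasts a linear law ``s = s0 + a*c`` (stoichiometric
complexation keeps dissolving xanthine as agent is added) against the
classical hydrotrope signature: flat at ``s0`` up to a minimum hydrotropic
concentration (MHC) and exponential above it, ``s0*exp(b*(c - MHC))``.  Both
are least-squares fitted (the MHC profile over a breakpoint grid) and
compared by small-sample-corrected AIC with the conventional decisiveness
threshold of 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: molecular weight of water, kg/mol
M_W = 0.0180153

WATER_COMPOUND = "water"


# ---------------------------------------------------------------------------
# qNMR
# ---------------------------------------------------------------------------

def molality_from_integrals(table: pd.DataFrame) -> dict[str, float]:
    """Per-compound molality (mol/kg water) from an integral table.

    ``table`` needs columns ``compound, peak, integral, n_protons`` and
    exactly one row with compound ``"water"`` (its integral covers both
    protons and is divided by 2).  When a compound has several peaks, the
    per-proton integrals are averaged first.
    """
    required = {"compound", "peak", "integral", "n_protons"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    water = table[table["compound"] == WATER_COMPOUND]
    if len(water) != 1:
        raise ValueError("table must contain exactly one water row")
    a_w = float(water["integral"].iloc[0])
    if a_w <= 0:
        raise ValueError("water integral must be positive")
    if (table["n_protons"] < 1).any():
        raise ValueError("proton counts must be >= 1")
    per_proton_water = a_w / 2.0
    out: dict[str, float] = {}
    for compound, grp in table[table["compound"] != WATER_COMPOUND].groupby("compound"):
        per_proton = (grp["integral"] / grp["n_protons"]).mean()
        out[str(compound)] = float(per_proton / per_proton_water / M_W)
    return out


def fsi(s_sa: float, s0: float) -> float:
    """Solubility-increase factor: saturation molality with the agent over
    the pure-water value."""
    if s0 <= 0:
        raise ValueError("pure-water solubility s0 must be positive")
    if s_sa < 0:
        raise ValueError("solubility cannot be negative")
    return s_sa / s0


# ---------------------------------------------------------------------------
# solubility curves
# ---------------------------------------------------------------------------

@dataclass
class SolubilityCurve:
    """Measured xanthine solubility versus solubilizing-agent molality."""

    c: np.ndarray          # agent molality grid, mol/kg, strictly increasing
    s: np.ndarray          # xanthine solubility, mol/kg
    sd: np.ndarray | None = None
    xanthine: str = ""
    agent: str = ""

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.c.shape != self.s.shape or self.c.ndim != 1:
            raise ValueError("c and s must be 1-D arrays of equal length")
        if np.any(self.c < 0) or np.any(np.diff(self.c) <= 0):
            raise ValueError("agent molalities must be non-negative and "
                             "strictly increasing")
        if np.any(self.s < 0):
            raise ValueError("solubilities must be non-negative")

    def __len__(self) -> int:
        return len(self.c)


@dataclass
class LinearFit:
    s0: float
    slope: float
    rss: float

    def predict(self, c: np.ndarray) -> np.ndarray:
        return self.s0 + self.slope * np.asarray(c, dtype=float)


@dataclass
class MHCFit:
    s0: float
    mhc: float
    rate: float
    rss: float

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return np.where(c < self.mhc, self.s0,
                        self.s0 * np.exp(self.rate * (c - self.mhc)))


@dataclass
class ModelFit:
    linear: LinearFit
    mhc: MHCFit
    aicc_linear: float
    aicc_mhc: float
    verdict: str  # "linear" (complexation-like), "mhc" (hydrotrope-like), "indeterminate"

    @property
    def delta_aicc(self) -> float:
        """AICc(mhc) - AICc(linear); decisively linear above +2, decisively
        MHC below -2."""
        return self.aicc_mhc - self.aicc_linear


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * 1e-30)  # guard exact fits
    penalty = 2 * k + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return n * np.log(rss / n) + penalty


def _fit_linear(c: np.ndarray, s: np.ndarray) -> LinearFit:
    A = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    rss = float(np.sum((A @ coef - s) ** 2))
    return LinearFit(s0=float(coef[0]), slope=float(coef[1]), rss=rss)


def _fit_mhc_fixed(c: np.ndarray, s: np.ndarray, mhc: float) -> tuple[float, float, float]:
    below = c < mhc
    s0_0 = float(np.mean(s[below])) if below.any() else float(s[0])
    s0_0 = max(s0_0, 1e-6)
    span = max(float(c[-1] - mhc), 1e-6)
    tail = max(float(s[-1]), 1e-9)
    b0 = max(np.log(tail / s0_0) / span, 1e-3)

    def resid(p: np.ndarray) -> np.ndarray:
        s0, b = p
        return np.where(c < mhc, s0, s0 * np.exp(b * (c - mhc))) - s

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(resid, x0=[s0_0, b0],
                            bounds=([1e-12, 0.0], [np.inf, np.inf]),
                            max_nfev=200)
    return float(res.x[0]), float(res.x[1]), float(np.sum(res.fun ** 2))


def _mhc_candidates(c: np.ndarray, n_grid: int = 25) -> np.ndarray:
    lo, hi = float(c[1]), float(c[-2])
    if hi <= lo:
        return np.array([float(np.median(c))])
    cand = np.concatenate([c[(c >= lo) & (c <= hi)], np.linspace(lo, hi, n_grid)])
    return np.unique(np.round(cand, 12))


def fit_solubility_models(curve: SolubilityCurve) -> ModelFit:
    """Fit linear and MHC models and pronounce a verdict by AICc.

    The MHC breakpoint is profiled over a grid containing the interior data
    abscissae (so noiseless breakpoints at a data point are recovered
    exactly) plus a uniform refinement.  ``verdict`` is ``indeterminate``
    when the AICc difference is below 2 or the curve is degenerate.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to discriminate models")
    c, s = curve.c, curve.s
    n = len(c)
    lin = _fit_linear(c, s)
    best: tuple[float, float, float, float] | None = None  # (rss, s0, b, mhc)
    for cand in _mhc_candidates(c):
        s0, b, rss = _fit_mhc_fixed(c, s, cand)
        if best is None or rss < best[0]:
            best = (rss, s0, b, cand)
    assert best is not None
    mhc_fit = MHCFit(s0=best[1], mhc=best[3], rate=best[2], rss=best[0])
    aicc_lin = _aicc(lin.rss, n, k=3)       # s0, slope, noise variance
    aicc_mhc = _aicc(mhc_fit.rss, n, k=4)   # s0, MHC, rate, noise variance
    if np.ptp(s) < 1e-12:
        warnings.warn("degenerate (constant) solubility curve; verdict indeterminate")
        verdict = "indeterminate"
    elif aicc_mhc - aicc_lin > 2:
        verdict = "linear"
    elif aicc_lin - aicc_mhc > 2:
        verdict = "mhc"
    else:
        verdict = "indeterminate"
    return ModelFit(linear=lin, mhc=mhc_fit, aicc_linear=aicc_lin,
                    aicc_mhc=aicc_mhc, verdict=verdict)


@dataclass
class Breakpoint:
    c_star: float
    slope_before: float
    slope_after: float
    delta_aicc: float       # AICc improvement of the kinked fit over the line
    plateau: bool


def detect_breakpoint(
    curve: SolubilityCurve,
    min_improvement: float = 2.0,
    plateau_ratio: float = 0.1,
) -> Breakpoint | None:
    """Best continuous two-segment linear fit, reported only when decisive.

    Candidate kinks sit at interior data abscissae (two points required on
    each side).  The kink is reported when it improves AICc over the single
    line by at least ``min_improvement``; a plateau is flagged when the
    outgoing slope falls to ``plateau_ratio`` of the incoming one or less.
    Returning ``None`` (no breakpoint) is a valid outcome.
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 points for breakpoint detection")
    c, s = curve.c, curve.s
    n = len(c)
    lin = _fit_linear(c, s)
    best: tuple[float, float, np.ndarray] | None = None  # (rss, c*, coefs)
    for i in range(2, n - 2):
        cs = c[i]
        A = np.column_stack([np.ones_like(c), c, np.maximum(0.0, c - cs)])
        coef, *_ = np.linalg.lstsq(A, s, rcond=None)
        rss = float(np.sum((A @ coef - s) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(cs), coef)
    assert best is not None
    delta = _aicc(lin.rss, n, k=3) - _aicc(best[0], n, k=4)
    if delta < min_improvement:
        return None
    b1, b2 = float(best[2][1]), float(best[2][2])
    before, after = b1, b1 + b2
    plateau = before > 0 and after <= plateau_ratio * before
    return Breakpoint(c_star=best[1], slope_before=before, slope_after=after,
                      delta_aicc=float(delta), plateau=bool(plateau))


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Two binodal polylines over agent molality.

    ``upper`` traces xanthine-saturated solutions (above it the xanthine
    precipitates); ``lower`` traces agent-saturated solutions (below it the
    agent precipitates).  Both are ``(k, 2)`` arrays of
    ``(agent molality, xanthine molality)`` sorted by agent molality.
    """

    upper: np.ndarray
    lower: np.ndarray
    agent_solubility_pure_water: float | None = None

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        for name, poly in (("upper", self.upper), ("lower", self.lower)):
            if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
                raise ValueError(f"{name} binodal must be a (k>=2, 2) array")
            if np.any(np.diff(poly[:, 0]) <= 0):
                raise ValueError(f"{name} binodal must be sorted by agent molality")


def classify_phase_point(
    diagram: PhaseDiagram,
    c_agent: float,
    c_xanthine: float,
    eps: float = 0.01,
) -> str:
    """Locate a composition among the three phase domains.

    Returns ``homogeneous``, ``xanthine_saturated`` (above the upper
    binodal), ``agent_saturated`` (below the lower binodal) or ``boundary``
    (within ``eps`` mol/kg of either curve).  Binodals are interpolated
    linearly; no extrapolation: querying outside the common agent-molality
    span of the two polylines raises.
    """
    lo = max(diagram.upper[0, 0], diagram.lower[0, 0])
    hi = min(diagram.upper[-1, 0], diagram.lower[-1, 0])
    if not (lo <= c_agent <= hi):
        raise ValueError(
            f"agent molality {c_agent} outside the binodal span [{lo}, {hi}]")
    su = float(np.interp(c_agent, diagram.upper[:, 0], diagram.upper[:, 1]))
    sl = float(np.interp(c_agent, diagram.lower[:, 0], diagram.lower[:, 1]))
    if abs(c_xanthine - su) <= eps or abs(c_xanthine - sl) <= eps:
        return "boundary"
    if c_xanthine > su:
        return "xanthine_saturated"
    if c_xanthine < sl:
        return "agent_saturated"
    return "homogeneous"
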