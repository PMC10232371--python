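"""Metal-binding equilibria: chelator buffering, Hill fits, desorption midpoints.

Picomolar protein-metal affinities cannot be titrated directly - free metal
at those levels is set with a competitive chelator buffer.  This module
solves the 1:1 conditional-complexation mass balance for free metal, models
the cooperative conformational response as a Hill curve, fits apparent
dissociation constants (K_d,app) and Hill coefficients with bootstrap
standard errors, and extracts chelator-desorption midpoints ([chelator]_1/2)
whose ratios between two metals quantify single-pair selectivity.

The conditional stability constant ``K_cond`` folds chelator protonation at
the working pH into a single 1:1 constant and is user-supplied; see
``EXAMPLE_CONDITIONAL_CONSTANTS`` for non-authoritative orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "BufferSystem",
    "TitrationDataset",
    "BindingFit",
    "DesorptionFit",
    "free_metal",
    "hill_signal",
    "fit_hill",
    "fit_desorption",
    "selectivity_ratio",
    "aggregate_replicates",
    "EXAMPLE_CONDITIONAL_CONSTANTS",
]

#: Illustrative 1:1 conditional stability constants (L/mol) around pH 5 for
#: common carboxylate chelators with trivalent lanthanides.  These are rough
#: example values for demos and synthetic data only - NOT authoritative;
#: supply constants appropriate to your pH and ionic strength.
EXAMPLE_CONDITIONAL_CONSTANTS = {
    "citrate_pH5_Ln3+": 1e7,
    "malonate_pH5_Ln3+": 1e4,
    "acetate_pH5_Ln3+": 1e2,
}


class SpeciationError(ArithmeticError):
    """Raised when the mass-balance quadratic has no physical root."""


@dataclass(frozen=True)
class BufferSystem:
    """A 1:1 chelator-buffered metal pool.

    total_metal and total_chelator in mol/L; K_cond is the conditional
    (pH-specific) 1:1 stability constant in L/mol.
    """

    total_metal: float
    total_chelator: float
    K_cond: float

    def __post_init__(self) -> None:
        if self.total_metal < 0 or self.total_chelator < 0 or self.K_cond < 0:
            raise ValueError("concentrations and K_cond must be non-negative")
        if not math.isfinite(self.K_cond):
            raise ValueError("K_cond must be finite")


@dataclass
class TitrationDataset:
    """Concentration/normalized-signal points for one titration.

    ``conc`` is free metal unless ``buffered`` is set, in which case
    ``buffers`` carries one BufferSystem per point and the fit converts to
    free metal through the speciation solver.
    """

    conc: np.ndarray
    signal: np.ndarray
    signal_kind: str = "CD"
    buffered: bool = False
    buffers: list[BufferSystem] | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.conc.shape != self.signal.shape:
            raise ValueError("conc and signal must have the same length")
        if np.any(np.diff(self.conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.buffered and (
            self.buffers is None or len(self.buffers) != len(self.conc)
        ):
            raise ValueError("buffered dataset needs one BufferSystem per point")

    def free_metal_axis(self) -> np.ndarray:
        if self.buffered:
            return np.array([free_metal(b) for b in self.buffers])
        return self.conc


@dataclass
class BindingFit:
    K_d_app: float
    hill_n: float
    S0: float
    S1: float
    se: dict = field(default_factory=dict)
    n_boot: int = 0
    ok: bool = True
    message: str = ""


@dataclass
class DesorptionFit:
    midpoint: float
    slope: float
    pre_plateau: float
    post_plateau: float
    ok: bool = True
    message: str = ""


def free_metal(buffer: BufferSystem) -> float:
    """Free metal concentration under 1:1 conditional complexation.

    Solves K·x² − (K·M_T + K·L_T + 1)·x + K·M_T·L_T = 0 for the complex
    concentration x = [ML] (physical root) and returns M_T − x.  Uses the
    numerically stable quadratic form; conservation is checked to 1e-10
    relative.
    """
    M, L, K = buffer.total_metal, buffer.total_chelator, buffer.K_cond
    if K == 0.0 or L == 0.0 or M == 0.0:
        return M
    b = K * (M + L) + 1.0
    disc = b * b - 4.0 * K * K * M * L
    if disc < 0:
        raise SpeciationError("no real root for the complexation mass balance")
    # smaller root of K x^2 - b x + K M L = 0, stable for b > 0
    x = 2.0 * K * M * L / (b + math.sqrt(disc))
    if not 0.0 <= x <= min(M, L) * (1 + 1e-12):
        raise SpeciationError(f"complex concentration {x} outside [0, min(M_T, L_T)]")
    x = min(x, min(M, L))
    free = M - x
    free_L = L - x
    # conservation closure (exact by construction; guards the root choice)
    scale = max(M, L)
    if abs((free + x) - M) > 1e-10 * scale or abs((free_L + x) - L) > 1e-10 * scale:
        raise SpeciationError("mass-balance closure failed")
    return free


def hill_signal(
    x: float | np.ndarray, K: float, n: float, S0: float = 0.0, S1: float = 1.0
) -> float | np.ndarray:
    """Cooperative (Hill) response: S0 + (S1−S0)·x^n / (K^n + x^n)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        frac = np.where(x > 0, x**n / (K**n + x**n), 0.0)
    out = S0 + (S1 - S0) * frac
    return float(out) if out.ndim == 0 else out


def _hill_residual(params, logx, y):
    K = 10.0 ** params["logK"].value
    model = hill_signal(10.0**logx, K, params["n"].value, params["S0"].value, params["S1"].value)
    return model - y


def fit_hill(
    data: TitrationDataset,
    *,
    n_boot: int = 500,
    seed: int = 0,
) -> BindingFit:
    """Fit K_d,app, Hill n and plateaus to a titration.

    Fitting is on a log10 free-metal axis (titrations span several decades).
    Initialization: K from the concentration at the signal midpoint, n = 1;
    bounds n in [0.3, 4] and K within the data range times [1e-2, 1e2].
    Standard errors come from seeded residual-resampling bootstrap.
    Monotone-decreasing (desorption-shaped) data and flat data return a
    flagged failure, never a silent boundary fit.
    """
    x = data.free_metal_axis()
    y = data.signal
    if len(x) < 5:
        raise ValueError("at least 5 points required for a Hill fit")
    if np.any(x <= 0):
        raise ValueError("free-metal concentrations must be positive for a log-axis fit")
    span = float(np.ptp(y))
    if span <= 0 or span < 1e-6 * max(1.0, float(np.max(np.abs(y)))):
        return BindingFit(np.nan, np.nan, np.nan, np.nan, ok=False, message="flat signal")
    # direction guard: binding response must rise with free metal
    rho = np.corrcoef(np.log10(x), y)[0, 1]
    if rho < 0:
        return BindingFit(
            np.nan, np.nan, np.nan, np.nan, ok=False,
            message="signal decreases with concentration (desorption-shaped data?)",
        )

    logx = np.log10(x)
    mid = 0.5 * (np.min(y) + np.max(y))
    k0 = float(np.interp(mid, y, x))  # y increasing => valid midpoint estimate
    params = Parameters()
    params.add("logK", value=np.log10(k0),
               min=np.log10(np.min(x) * 1e-2), max=np.log10(np.max(x) * 1e2))
    params.add("n", value=1.0, min=0.3, max=4.0)
    params.add("S0", value=float(np.min(y)))
    params.add("S1", value=float(np.max(y)))

    res = minimize(_hill_residual, params, args=(logx, y), method="leastsq")
    if not res.success:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, ok=False, message=res.message)
    p = res.params
    at_bound = (
        abs(p["logK"].value - p["logK"].min) < 1e-6
        or abs(p["logK"].value - p["logK"].max) < 1e-6
    )
    fit = BindingFit(
        K_d_app=10.0 ** p["logK"].value,
        hill_n=p["n"].value,
        S0=p["S0"].value,
        S1=p["S1"].value,
        n_boot=n_boot,
        ok=not at_bound,
        message="K at fitting bound" if at_bound else "",
    )
    if not fit.ok or n_boot <= 0:
        return fit

    rng = np.random.default_rng(seed)
    resid = _hill_residual(p, logx, y)
    boot = {"K_d_app": [], "hill_n": [], "S0": [], "S1": []}
    yhat = y + resid  # model prediction
    for _ in range(n_boot):
        y_star = yhat - rng.choice(resid, size=len(resid), replace=True)
        try:
            r = minimize(_hill_residual, params.copy(), args=(logx, y_star), method="leastsq")
        except Exception:
            continue
        if r.success:
            boot["K_d_app"].append(10.0 ** r.params["logK"].value)
            boot["hill_n"].append(r.params["n"].value)
            boot["S0"].append(r.params["S0"].value)
            boot["S1"].append(r.params["S1"].value)
    fit.se = {k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan for k, v in boot.items()}
    return fit


def _logistic4(logc, mid, slope, pre, post):
    return post + (pre - post) / (1.0 + 10.0 ** (slope * (logc - np.log10(mid))))


def _desorption_residual(params, logc, y):
    return _logistic4(
        logc, 10.0 ** params["logmid"].value, params["slope"].value,
        params["pre"].value, params["post"].value,
    ) - y


def fit_desorption(data: TitrationDataset) -> DesorptionFit:
    """4-parameter logistic fit on log10 chelator concentration.

    Returns the midpoint [chelator]_1/2, the concentration at 50% desorption.
    Works for decreasing (desorption) signals; requires plateau separation.
    """
    c = data.conc
    y = data.signal
    if np.any(c <= 0):
        raise ValueError("chelator concentrations must be positive")
    span = float(np.ptp(y))
    if span <= 0 or span < 1e-6 * max(1.0, float(np.max(np.abs(y)))):
        return DesorptionFit(np.nan, np.nan, np.nan, np.nan, ok=False,
                             message="no plateau separation")
    logc = np.log10(c)
    mid = 0.5 * (y[0] + y[-1])
    # first crossing of the midpoint, interpolated on the log axis
    crossings = np.nonzero(np.diff(np.sign(y - mid)))[0]
    i = int(crossings[0]) if len(crossings) else len(c) // 2
    frac = (mid - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.5
    logmid0 = logc[i] + frac * (logc[i + 1] - logc[i])

    params = Parameters()
    params.add("logmid", value=logmid0, min=logc[0], max=logc[-1])
    params.add("slope", value=1.0, min=0.05, max=20.0)
    params.add("pre", value=float(y[0]))
    params.add("post", value=float(y[-1]))
    res = minimize(_desorption_residual, params, args=(logc, y), method="leastsq")
    if not res.success:
        return DesorptionFit(np.nan, np.nan, np.nan, np.nan, ok=False, message=res.message)
    p = res.params
    return DesorptionFit(
        midpoint=10.0 ** p["logmid"].value,
        slope=p["slope"].value,
        pre_plateau=p["pre"].value,
        post_plateau=p["post"].value,
    )


def selectivity_ratio(fit_a: DesorptionFit, fit_b: DesorptionFit) -> float:
    """Ratio of desorption midpoints ([chelator]_1/2,A / [chelator]_1/2,B)."""
    if not (fit_a.ok and fit_b.ok):
        raise ValueError("both desorption fits must have converged")
    if fit_b.midpoint == 0:
        raise ZeroDivisionError("reference midpoint is zero")
    return fit_a.midpoint / fit_b.midpoint


def aggregate_replicates(values) -> dict:
    """Mean ± s.e.m. across independent replicate fits."""
    v = np.asarray(list(values), dtype=float)
    return {
        "mean": float(np.mean(v)),
        "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        "n": int(len(v)),
    }
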