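"""Monomer-dimer equilibrium and dilution-ITC dimer-dissociation modelling.

For the equilibrium D <-> 2M with dissociation constant
K_dimer = [M]^2/[D] and total monomer-equivalents [P] = [M] + 2[D], the free
monomer concentration is the positive root of

    2[M]^2 + K_dimer*[M] - K_dimer*[P] = 0.

A protein whose dimer is weak monomerizes on dilution; injecting a
concentrated stock into buffer in a calorimeter therefore releases (or
absorbs) the heat of dimer dissociation.  The forward model here tracks
cell composition through a perfusion-cell displacement convention
(instantaneous mixing with overflow at constant cell volume) and assigns
each injection the heat of the dimer moles that dissociate relative to the
no-reaction mixture of cell carryover plus injected syringe speciation.
Delta-H is per mole of dimer; endothermic dissociation gives positive heats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

__all__ = [
    "DimerSystem",
    "ITCExperiment",
    "ThermoSummary",
    "monomer_concentration",
    "dimer_concentration",
    "speciate",
    "weight_average_mw",
    "default_injection_schedule",
    "itc_forward",
    "fit_itc",
    "R_GAS",
]

R_GAS = 8.31446261815324  # J/(mol K)


def monomer_concentration(P_total: float, K_dimer: float) -> float:
    """Free monomer [M] from total monomer-equivalents and K_dimer (mol/L).

    Positive root of 2[M]^2 + K[M] - K[P] = 0:
    [M] = (-K + sqrt(K^2 + 8*K*P)) / 4, computed in a cancellation-safe form.
    """
    if P_total < 0 or K_dimer <= 0:
        raise ValueError("P_total must be >= 0 and K_dimer > 0")
    if P_total == 0.0:
        return 0.0
    # (-K + sqrt(K^2 + 8KP))/4 == 2P / (1 + sqrt(1 + 8P/K)) (stable for P << K)
    return 2.0 * P_total / (1.0 + math.sqrt(1.0 + 8.0 * P_total / K_dimer))


def dimer_concentration(P_total: float, K_dimer: float) -> float:
    """Dimer concentration [D] = ([P] − [M])/2."""
    return 0.5 * (P_total - monomer_concentration(P_total, K_dimer))


@dataclass
class DimerSystem:
    """Speciated monomer-dimer state at one total protein concentration."""

    K_dimer: float
    P_total: float
    M: float
    D: float
    M_mono: float = 0.0

    @property
    def monomer_fraction(self) -> float:
        return self.M / self.P_total if self.P_total > 0 else 1.0


def speciate(P_total: float, K_dimer: float, M_mono: float = 0.0) -> DimerSystem:
    M = monomer_concentration(P_total, K_dimer)
    return DimerSystem(K_dimer=K_dimer, P_total=P_total, M=M, D=0.5 * (P_total - M),
                       M_mono=M_mono)


def weight_average_mw(P_total: float, K_dimer: float, M_mono: float) -> float:
    """Mass-weighted mean MW of the monomer-dimer mixture (Da).

    M_w = M_mono*([M] + 4[D])/([M] + 2[D]); bounded in [M_mono, 2*M_mono].
    Interprets a SEC-MALS apparent MW: e.g. a 2:1 molar monomer/dimer
    mixture gives 1.5*M_mono.  At P_total = 0 the monomer MW is returned.
    """
    if M_mono <= 0:
        raise ValueError("M_mono must be positive")
    if P_total == 0.0:
        import warnings

        warnings.warn("P_total = 0: returning monomer MW", stacklevel=2)
        return M_mono
    s = speciate(P_total, K_dimer)
    return M_mono * (s.M + 4.0 * s.D) / (s.M + 2.0 * s.D)


def default_injection_schedule() -> list[float]:
    """Standard dilution-ITC schedule: one 0.2 µl pre-injection + 17 × 2 µl (litres)."""
    return [0.2e-6] + [2.0e-6] * 17


@dataclass
class ITCExperiment:
    """A dilution-ITC experiment: schedule, conditions and (optionally) heats.

    syringe_conc in mol/L monomer-equivalents; cell_volume and injection
    volumes in litres; temperature in kelvin; heats in joules per injection
    (positive = endothermic with the per-mole-of-dimer dH_diss convention).
    """

    syringe_conc: float
    cell_volume: float = 185e-6
    injections: list[float] = field(default_factory=default_injection_schedule)
    temperature: float = 303.15
    heats: np.ndarray | None = None
    K_dimer: float | None = None
    dH_diss: float | None = None
    q_blank: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.injections):
            raise ValueError("injection volumes must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injections):
                raise ValueError("heats length must equal injections length")


@dataclass
class ThermoSummary:
    """Fitted dimer-dissociation thermodynamics (per mole of dimer, 1 M standard state)."""

    K_dimer: float
    dH: float
    dG: float
    dS: float
    temperature: float
    q_blank: float = 0.0
    ok: bool = True
    bound_only: bool = False
    message: str = ""


def itc_forward(
    exp: ITCExperiment,
    K_dimer: float | None = None,
    dH_diss: float | None = None,
    q_blank: float | None = None,
) -> np.ndarray:
    """Predicted heat (J) per injection for the dimer-dissociation model.

    Displacement convention: after injecting volume v into cell volume V0,
    total protein P_i = P_{i-1}(1 - v/V0) + P_syr*(v/V0).  The injection heat
    is dH_diss times the dimer moles that dissociate relative to no-reaction
    mixing of the carried-over cell speciation and the injected syringe
    speciation, plus a per-injection blank.
    """
    K = exp.K_dimer if K_dimer is None else K_dimer
    dH = exp.dH_diss if dH_diss is None else dH_diss
    qb = exp.q_blank if q_blank is None else q_blank
    if K is None or dH is None:
        raise ValueError("K_dimer and dH_diss must be set")
    V0 = exp.cell_volume
    D_syr = dimer_concentration(exp.syringe_conc, K)
    P = 0.0
    D_prev = 0.0
    heats = np.empty(len(exp.injections))
    for i, v in enumerate(exp.injections):
        f = v / V0
        P = P * (1.0 - f) + exp.syringe_conc * f
        D_mix = D_prev * (1.0 - f) + D_syr * f  # no-reaction mixture
        D_eq = dimer_concentration(P, K)
        heats[i] = dH * (D_mix - D_eq) * V0 + qb
        D_prev = D_eq
    return heats


def fit_itc(
    exp: ITCExperiment,
    *,
    exclude_first: bool = True,
    log10K_bounds: tuple[float, float] = (-9.0, -1.0),
    weighting: str = "relative",
) -> ThermoSummary:
    """Least-squares fit of (K_dimer, dH_diss, q_blank) to injection heats.

    The small pre-injection is excluded by default.  ``weighting="relative"``
    (default) scales residuals by the observed heat magnitudes, the correct
    likelihood when heat uncertainty is proportional to heat size, as it is
    for this instrument class; ``"absolute"`` fits raw residuals.
    dG = -RT ln(K/1 M) and dS = (dH - dG)/T.  When K_dimer is too small for
    observable monomerization at the experiment's concentrations, the
    dissociation term no longer explains the data better than a flat blank
    (F-test); the result is then flagged ``bound_only`` - read it as
    "K_dimer beyond the reported value", not as an estimate.
    """
    if exp.heats is None:
        raise ValueError("experiment has no measured heats")
    if weighting not in ("relative", "absolute"):
        raise ValueError("weighting must be 'relative' or 'absolute'")
    mask = np.ones(len(exp.injections), dtype=bool)
    if exclude_first:
        mask[0] = False
    if mask.sum() < 8:
        raise ValueError("at least 8 usable injections required")
    y = exp.heats[mask]
    if weighting == "relative":
        scale = np.maximum(np.abs(y), 0.05 * float(np.max(np.abs(y))))
    else:
        scale = np.ones_like(y)

    def residual(params):
        pred = itc_forward(
            exp,
            K_dimer=10.0 ** params["logK"].value,
            dH_diss=params["dH"].value,
            q_blank=params["qb"].value,
        )
        return (pred[mask] - y) / scale

    total = float(np.sum(y))
    params = Parameters()
    params.add("logK", value=math.log10(max(exp.syringe_conc / 3.0, 10 ** log10K_bounds[0])),
               min=log10K_bounds[0], max=log10K_bounds[1])
    # rough scale: all syringe protein as dimer dissociating once
    n_dimer = exp.syringe_conc * sum(exp.injections) / 2.0
    params.add("dH", value=total / n_dimer if n_dimer > 0 else 1.0)
    params.add("qb", value=float(np.median(y[-3:])))

    res = minimize(residual, params, method="leastsq")
    p = res.params
    logK = p["logK"].value
    at_lower = abs(logK - log10K_bounds[0]) < 1e-3
    at_upper = abs(logK - log10K_bounds[1]) < 1e-3
    K = 10.0**logK
    # identifiability: does the dissociation model beat a flat blank?  If
    # not, the heats are indistinguishable from pure mixing and only a bound
    # on K_dimer is supported (the tight-dimer case).
    from scipy.stats import f as f_dist

    ssr_full = float(np.sum(residual(p) ** 2))
    qb_flat = float(np.sum(y / scale**2) / np.sum(1.0 / scale**2))
    ssr_flat = float(np.sum(((y - qb_flat) / scale) ** 2))
    dof = mask.sum() - 3
    if ssr_full <= 0 or dof <= 0:
        p_flat = 0.0
    else:
        f_stat = ((ssr_flat - ssr_full) / 2.0) / (ssr_full / dof)
        p_flat = float(f_dist.sf(max(f_stat, 0.0), 2, dof))
    insensitive = p_flat > 0.01
    T = exp.temperature
    dG = -R_GAS * T * math.log(K)  # K in M against 1 M standard state
    dH = p["dH"].value
    bound_only = at_lower or at_upper or insensitive
    summary = ThermoSummary(
        K_dimer=K, dH=dH, dG=dG, dS=(dH - dG) / T, temperature=T,
        q_blank=p["qb"].value, ok=res.success and not bound_only,
        bound_only=bound_only,
    )
    if at_lower or (insensitive and logK < math.log10(exp.syringe_conc)):
        summary.message = (
            "dimer too tight to observe monomerization at these concentrations; "
            f"result supports only an upper bound, K_dimer < {K:.3g} M"
        )
    elif at_upper or insensitive:
        summary.message = (
            "no detectable dimerization signal; result supports only a lower "
            f"bound, K_dimer > {K:.3g} M"
        )
    elif not res.success:
        summary.message = res.message
        summary.ok = False
    return summary
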