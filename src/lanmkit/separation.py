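"""Rare-earth distribution ratios, separation factors, purity and yield.

Batch sorption experiments equilibrate a metal feed with protein-bearing
microbeads; the liquid phase is sampled ([M]_ad) and the beads stripped with
acid into volume V_de ([M]_de).  Because free liquid clings to the beads,
the bead-phase concentration is carryover-corrected:

    [M]_Liquid = [M]_ad
    [M]_LanM   = (V_de*[M]_de - V_bead*[M]_ad) / V_de

which with the default volumes (V_de = 4 ml, V_bead = 1 ml) is the familiar
(4*[M]_de - [M]_ad)/4.  The distribution ratio is D = [M]_LanM/[M]_Liquid,
the separation factor SF = D_RE1/D_RE2, and column-run fraction tables are
pooled into per-window purity (C_RE1/(C_RE1+C_RE2), generalized to the
multi-metal C_RE1/sum(C)) and yield (recovered/loaded) percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchEquilibrium",
    "SeparationTable",
    "SeparationSummary",
    "distribution_ratio",
    "separation_factor",
    "separation_factor_matrix",
    "purity_yield",
    "breakthrough_point",
]


@dataclass
class BatchEquilibrium:
    """Batch-contact concentrations per metal (mol/L) with strip/bead volumes (ml)."""

    M_ad: dict[str, float]
    M_de: dict[str, float]
    V_de: float = 4.0
    V_bead: float = 1.0

    def __post_init__(self) -> None:
        if self.V_de <= 0 or self.V_bead <= 0:
            raise ValueError("volumes must be positive")
        if set(self.M_ad) != set(self.M_de):
            raise ValueError("M_ad and M_de must cover the same metals")
        if any(v < 0 for v in list(self.M_ad.values()) + list(self.M_de.values())):
            raise ValueError("concentrations must be non-negative")


@dataclass
class SeparationTable:
    """Ordered elution fractions: bed-volume axis plus per-metal concentrations.

    ``fractions`` is a DataFrame with a strictly increasing ``bed_volume``
    column, one mol/L column per metal, and optionally ``eluent`` labels and
    an explicit ``volume_ml`` column.  Fraction volume defaults to
    delta(bed_volume) x bed_volume_ml (first fraction measured from zero).
    """

    fractions: pd.DataFrame
    bed_volume_ml: float = 0.7
    metals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "bed_volume" not in self.fractions.columns:
            raise ValueError("fractions table needs a 'bed_volume' column")
        bv = self.fractions["bed_volume"].to_numpy(dtype=float)
        if np.any(np.diff(bv) <= 0):
            raise ValueError("bed_volume must be strictly increasing")
        if not self.metals:
            self.metals = [
                c for c in self.fractions.columns
                if c not in ("bed_volume", "eluent", "volume_ml")
            ]
        if len(self.metals) < 2:
            raise ValueError("at least 2 metals must be tracked")

    def fraction_volumes_ml(self) -> np.ndarray:
        if "volume_ml" in self.fractions.columns:
            return self.fractions["volume_ml"].to_numpy(dtype=float)
        bv = self.fractions["bed_volume"].to_numpy(dtype=float)
        return np.diff(bv, prepend=0.0) * self.bed_volume_ml


@dataclass
class SeparationSummary:
    D: dict[str, float] | None
    SF: pd.DataFrame | None
    purity: pd.DataFrame | None
    yield_: pd.DataFrame | None


def distribution_ratio(batch: BatchEquilibrium) -> dict[str, float]:
    """Carryover-corrected distribution ratio D per metal.

    Negative corrected bead-phase concentrations (noise near zero) clamp to
    0 with a warning; a metal absent from the liquid but present in the
    strip reports infinite D rather than raising.
    """
    out: dict[str, float] = {}
    for metal in batch.M_ad:
        ad = batch.M_ad[metal]
        de = batch.M_de[metal]
        m_lanm = (batch.V_de * de - batch.V_bead * ad) / batch.V_de
        if m_lanm < 0:
            warnings.warn(
                f"{metal}: carryover correction gave negative bead-phase "
                f"concentration ({m_lanm:.3g}); clamped to 0",
                stacklevel=2,
            )
            m_lanm = 0.0
        if ad == 0:
            out[metal] = float("inf") if de > 0 else float("nan")
            if de > 0:
                warnings.warn(f"{metal}: no metal left in liquid; D is infinite",
                              stacklevel=2)
        else:
            out[metal] = m_lanm / ad
    return out


def separation_factor(D1: float, D2: float) -> float:
    """SF = D_RE1 / D_RE2."""
    if D2 == 0:
        raise ZeroDivisionError("reference distribution ratio is zero")
    return D1 / D2


def separation_factor_matrix(D: dict[str, float]) -> pd.DataFrame:
    """Pairwise SF matrix (rows = RE1, columns = RE2); unit diagonal."""
    metals = list(D)
    mat = pd.DataFrame(index=metals, columns=metals, dtype=float)
    for a in metals:
        for b in metals:
            mat.loc[a, b] = D[a] / D[b] if D[b] != 0 else float("inf")
    return mat


def purity_yield(
    table: SeparationTable,
    pooling: dict[str, tuple[float, float]],
    loaded: dict[str, float],
) -> SeparationSummary:
    """Pooled purity and yield per metal for named bed-volume windows.

    ``pooling`` maps window name -> (start_bv, end_bv), inclusive; windows
    must not overlap.  ``loaded`` gives moles loaded per metal.  Pooled
    moles are concentration x fraction volume; purity is the metal's share
    of pooled moles (percent) and yield the pooled fraction of the load
    (percent).
    """
    windows = sorted(pooling.items(), key=lambda kv: kv[1][0])
    for (na, (a0, a1)), (nb, (b0, b1)) in zip(windows, windows[1:]):
        if b0 <= a1:
            raise ValueError(f"pooling windows '{na}' and '{nb}' overlap")
    for name, (lo, hi) in pooling.items():
        if hi < lo:
            raise ValueError(f"window '{name}' has end before start")
    missing = [m for m in table.metals if m not in loaded]
    if missing:
        raise ValueError(f"loaded amounts missing for {missing}")
    if any(v <= 0 for v in loaded.values()):
        raise ValueError("loaded amounts must be positive")

    bv = table.fractions["bed_volume"].to_numpy(dtype=float)
    vol_l = table.fraction_volumes_ml() * 1e-3
    purity_rows, yield_rows = [], []
    for name, (lo, hi) in pooling.items():
        # tolerate accumulated floating-point error in the bed-volume axis
        eps = 1e-9 * max(1.0, abs(hi), abs(lo))
        sel = (bv >= lo - eps) & (bv <= hi + eps)
        moles = {
            m: float(np.sum(table.fractions[m].to_numpy(dtype=float)[sel] * vol_l[sel]))
            for m in table.metals
        }
        total = sum(moles.values())
        purity_rows.append(
            {"window": name, **{
                m: (100.0 * moles[m] / total if total > 0 else float("nan"))
                for m in table.metals
            }}
        )
        yield_rows.append(
            {"window": name, **{m: 100.0 * moles[m] / loaded[m] for m in table.metals}}
        )
    return SeparationSummary(
        D=None,
        SF=None,
        purity=pd.DataFrame(purity_rows).set_index("window"),
        yield_=pd.DataFrame(yield_rows).set_index("window"),
    )


def breakthrough_point(
    table: SeparationTable,
    metal: str,
    feed_conc: float,
    threshold_fraction: float = 0.1,
) -> float | None:
    """First bed volume where effluent/feed reaches the threshold.

    The crossing is linearly interpolated between adjacent fractions when
    the previous fraction already shows effluent; a jump from exactly zero
    (effluent first appears within a fraction) reports that fraction's bed
    volume.  Returns None when the effluent never reaches the threshold.
    """
    if feed_conc <= 0:
        raise ValueError("feed concentration must be positive")
    bv = table.fractions["bed_volume"].to_numpy(dtype=float)
    ratio = table.fractions[metal].to_numpy(dtype=float) / feed_conc
    above = ratio >= threshold_fraction
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or ratio[i - 1] == 0.0:
        return float(bv[i])
    frac = (threshold_fraction - ratio[i - 1]) / (ratio[i] - ratio[i - 1])
    return float(bv[i - 1] + frac * (bv[i] - bv[i - 1]))
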