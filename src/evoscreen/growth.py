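"""Growth-rate, doubling-time and spectrophotometric rate calculators.

Batch growth rates come from a linear regression of raw optical density
against batch time inside a fixed window (default 12.5-37.5 h after
transfer to the bioreactor); an optional log-OD mode fits exponential
growth instead.  Doubling time is t = ln(2) / growth rate.  The RuBP-
dependent NADH-depletion assay converts an absorbance slope (A340 per
second) into an apparent catalytic rate k_app: absorbance -> concentration
via the NADH calibration factor beta (default 1569 L/mol) divided by two
(two 3-phosphoglycerate per RuBP), then k_app = -(slope in nM/s) / (protein
concentration in nM), so a decreasing absorbance trace yields positive
k_app in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ODSeries",
    "GrowthRate",
    "AssayResult",
    "batch_growth_rate",
    "doubling_time",
    "slope_to_kapp",
]

DEFAULT_WINDOW = (12.5, 37.5)  # hours after transfer to the bioreactor
DEFAULT_BETA = 1569.0          # L/mol, NADH absorbance-to-concentration factor
DEFAULT_PROTEIN_CONC = 500e-9  # mol/L active-site concentration in the assay


@dataclass
class ODSeries:
    """An optical-density time course (time in hours)."""

    time: np.ndarray
    od: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.shape != self.od.shape:
            raise ValueError("time and od must have equal length")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("negative OD reading")


@dataclass(frozen=True)
class GrowthRate:
    slope: float          # OD/h (raw mode) or 1/h (log mode)
    stderr: float
    n_points: int
    mode: str             # "raw" or "log"

    def doubling_time(self) -> float:
        return doubling_time(self.slope)


@dataclass(frozen=True)
class AssayResult:
    absorbance_slope: float      # A340 per second
    concentration_slope: float   # mol/L per second
    k_app: float                 # 1/s
    beta: float
    protein_conc: float


def batch_growth_rate(
    series: ODSeries,
    window: tuple[float, float] = DEFAULT_WINDOW,
    log_od: bool = False,
) -> GrowthRate:
    """OLS slope of OD (or log OD) against time within ``window``.

    ``log_od=False`` regresses raw OD readings (the stated batch protocol);
    ``log_od=True`` regresses ln(OD), giving the specific (exponential)
    growth rate in 1/h.
    """
    lo, hi = window
    mask = (series.time >= lo) & (series.time <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points inside window {window}, found {int(mask.sum())}"
        )
    t = series.time[mask]
    y = series.od[mask]
    if log_od:
        if (y <= 0).any():
            raise ValueError("log-OD mode requires strictly positive OD")
        y = np.log(y)
    res = stats.linregress(t, y)
    return GrowthRate(
        slope=float(res.slope),
        stderr=float(res.stderr),
        n_points=int(mask.sum()),
        mode="log" if log_od else "raw",
    )


def doubling_time(growth_rate: float) -> float:
    """Duration of one generation: t = ln(2) / growth rate (rate in 1/h)."""
    if not growth_rate > 0:
        raise ValueError(f"growth rate must be positive, got {growth_rate}")
    return float(np.log(2) / growth_rate)


def slope_to_kapp(
    slope: float,
    beta: float = DEFAULT_BETA,
    protein_conc: float = DEFAULT_PROTEIN_CONC,
) -> AssayResult:
    """Convert an A340/s slope into the apparent rate constant k_app (1/s).

    The absorbance slope becomes a concentration slope c' = (slope/beta)/2
    in mol/L/s; expressed in nM/s and divided by the protein concentration
    in nM this gives k_app = -c' / protein_conc, positive for NADH depletion.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    if not protein_conc > 0:
        raise ValueError("protein concentration must be positive")
    conc_slope = (slope / beta) / 2.0              # mol/L per second
    k_app = -(conc_slope * 1e9) / (protein_conc * 1e9)
    return AssayResult(
        absorbance_slope=float(slope),
        concentration_slope=float(conc_slope),
        k_app=float(k_app),
        beta=float(beta),
        protein_conc=float(protein_conc),
    )
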