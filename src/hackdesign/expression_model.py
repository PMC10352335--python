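"""Predict GOI protein levels from driver abundance.

Two measured ratios characterize a bicistron built on a driver:

* coupling ``eta`` — GOI protein as a fraction of the driver protein
  within the bicistron (default 0.55, observed range 0.31-0.76);
* retention ``rho`` — the driver's level in the bicistron relative to
  its monocistronic level (default 0.50, the midpoint of the observed
  0.38-0.64 range).

The point prediction composes the two multiplicatively:
``GOI level = eta * rho * driver_abundance``.  Composing them is this
module's modeling choice; each ratio is measured independently, and
the interval bounds multiply the extreme range products
(0.31*0.38, 0.76*0.64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ETA = 0.55
DEFAULT_RHO = 0.50
DEFAULT_ETA_RANGE = (0.31, 0.76)
DEFAULT_RHO_RANGE = (0.38, 0.64)


@dataclass(frozen=True)
class CouplingParams:
    eta: float = DEFAULT_ETA
    rho: float = DEFAULT_RHO
    eta_range: tuple[float, float] = DEFAULT_ETA_RANGE
    rho_range: tuple[float, float] = DEFAULT_RHO_RANGE

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        for name, (lo, hi) in (
            ("eta_range", self.eta_range),
            ("rho_range", self.rho_range),
        ):
            if not 0 < lo <= hi <= 1:
                raise ValueError(f"{name} bounds must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class ExpressionEstimate:
    gene_id: str
    driver_abundance: float
    point: float
    low: float
    high: float
    coupling_percent: float

    def __post_init__(self) -> None:
        if not self.low <= self.point <= self.high:
            raise ValueError("interval must bracket the point estimate")


def predict_goi_level(
    driver_abundance: float,
    params: CouplingParams | None = None,
    gene_id: str = "",
) -> ExpressionEstimate:
    """Expected GOI protein level for a driver of given abundance.

    ``point = eta * rho * abundance``; the interval multiplies the
    range extremes.  ``coupling_percent`` reports 100*eta, the
    GOI:driver ratio within the bicistron.
    """
    if driver_abundance < 0:
        raise ValueError("driver abundance must be nonnegative")
    p = params or CouplingParams()
    return ExpressionEstimate(
        gene_id=gene_id,
        driver_abundance=driver_abundance,
        point=p.eta * p.rho * driver_abundance,
        low=p.eta_range[0] * p.rho_range[0] * driver_abundance,
        high=p.eta_range[1] * p.rho_range[1] * driver_abundance,
        coupling_percent=100 * p.eta,
    )


def select_driver_for_target(
    target_level: float,
    candidates: list,
    params: CouplingParams | None = None,
):
    """The candidate whose predicted GOI level is closest to the target.

    Ties prefer the more abundant driver, then lexicographic gene_id.
    ``candidates`` are :class:`~hackdesign.driver_select.DriverCandidate`
    (anything with ``abundance`` and ``gene_id`` works).
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    p = params or CouplingParams()

    def key(c):
        point = p.eta * p.rho * c.abundance
        return (abs(point - target_level), -c.abundance, c.gene_id)

    return min(candidates, key=key)


def fit_coupling(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """OLS fit (with intercept) of GOI signal against driver abundance.

    Returns ``(slope, r_squared)`` with r² the squared Pearson
    correlation.  Needs at least 3 pairs and nonconstant x.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (abundance, signal) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("driver abundances are constant; cannot fit")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def stability_ratio(fi_gen1: float, fi_gen10: float) -> float:
    """First-generation fluorescence divided by tenth-generation.

    A value near 1 indicates the integrated bicistron is stable over
    serial subculture.
    """
    if fi_gen10 <= 0:
        raise ValueError("tenth-generation intensity must be positive")
    return fi_gen1 / fi_gen10
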