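"""Domain types and scalar metrics for fructan membrane fractionation.

Agave fructans are fractionated by tight ultrafiltration (1 kDa MWCO) into a
permeate enriched in short-chain fructooligosaccharides (FOS, degree of
polymerization 3-10) and a retentate enriched in long-chain fructans
(Fc, DP > 10).  Mono- and disaccharides (MD, DP 1-2) are carried along but
play no role in the separation metrics.

The central figures of merit are:

* the **separation factor** ``SF = (FOS:Fc)_permeate / (FOS:Fc)_feed``,
  which is > 1 whenever the permeate is FOS-enriched relative to the feed;
* the **solute flux** ``Ji = F_P * C_P / A`` (reported in kg h^-1 m^-2);
* the **apparent rejection** ``Ro = 1 - C_P / C`` of a solute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Composition",
    "ProcessConditions",
    "SolutePair",
    "StreamSample",
    "fos_fc_ratio",
    "separation_factor",
    "solute_flux",
    "apparent_rejection",
    "permeate_conc",
    "sum_squared_error",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Mass-fraction composition of a fructan stream.

    Fractions must sum to one; inputs looking like percentages (summing to
    ~100) are accepted through :meth:`from_percent`.  Construction never
    renormalizes silently — an inconsistent composition raises.

    Parameters
    ----------
    fc_frac : float
        Long-chain fructan mass fraction (DP > 10).
    fos_frac : float
        Fructooligosaccharide mass fraction (DP 3-10).
    md_frac : float
        Mono-/disaccharide mass fraction (DP 1-2).
    """

    fc_frac: float
    fos_frac: float
    md_frac: float

    def __post_init__(self) -> None:
        for name in ("fc_frac", "fos_frac", "md_frac"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} must be a finite fraction in [0, 1]")
        total = self.fc_frac + self.fos_frac + self.md_frac
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"fractions sum to {total!r}, not 1; use Composition.from_percent "
                "or normalized() for explicit rescaling"
            )

    @classmethod
    def from_percent(cls, fc: float, fos: float, md: float) -> "Composition":
        """Build from percentages (values summing to ~100)."""
        return cls(fc / 100.0, fos / 100.0, md / 100.0)

    @classmethod
    def normalized(cls, fc: float, fos: float, md: float) -> "Composition":
        """Build from arbitrary non-negative weights, rescaling to sum 1."""
        total = fc + fos + md
        if total <= 0:
            raise ValueError("weights must have a positive sum")
        return cls(fc / total, fos / total, md / total)

    @property
    def fos_fc_ratio(self) -> float:
        return fos_fc_ratio(self)


@dataclass(frozen=True)
class ProcessConditions:
    """Operating point of the ultrafiltration unit.

    Temperature in °C, transmembrane pressure (TMP) in bar and feed
    concentration in kg m^-3 when ``unit_system='actual'``; dimensionless
    coded coordinates (design box mapped to [-1, 1]^3) otherwise.
    """

    temperature: float
    tmp: float
    feed_conc: float
    unit_system: Literal["actual", "coded"] = "actual"

    def as_array(self) -> np.ndarray:
        return np.array([self.temperature, self.tmp, self.feed_conc], dtype=float)


@dataclass(frozen=True)
class SolutePair:
    """Per-solute scalar container for the two simulated species (Fc, FOS)."""

    fc: float
    fos: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fc) and np.isfinite(self.fos)):
            raise ValueError("both solute entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.fc, self.fos], dtype=float)


@dataclass(frozen=True)
class StreamSample:
    """A sampled process stream (feed, retentate or permeate).

    ``flow`` is volumetric (m^3 s^-1) and ``conc`` the per-solute
    concentration (kg m^-3).  Feed and retentate flows are bookkeeping only:
    in batch concentration mode the tank, feed and retentate share one
    concentration, and the balances use only the permeate flow.
    """

    flow: float
    conc: SolutePair
    composition: Composition
    role: Literal["feed", "retentate", "permeate"]

    def __post_init__(self) -> None:
        if self.flow < 0:
            raise ValueError("flow must be non-negative")
        if self.conc.fc < 0 or self.conc.fos < 0:
            raise ValueError("concentrations must be non-negative")


def fos_fc_ratio(c: Composition) -> float:
    """FOS:Fc mass ratio of a composition.

    Raises
    ------
    ZeroDivisionError
        If the Fc fraction is zero (the ratio is undefined).
    """
    if c.fc_frac == 0:
        raise ZeroDivisionError("FOS:Fc ratio undefined for fc_frac = 0")
    return c.fos_frac / c.fc_frac


def separation_factor(permeate: Composition, feed: Composition) -> float:
    """Separation factor SF = (FOS:Fc)_P / (FOS:Fc)_F.

    SF > 1 means the permeate is FOS-enriched relative to the feed.  The
    MD fraction is carried in the compositions but never enters SF.
    """
    feed_ratio = fos_fc_ratio(feed)
    if feed_ratio == 0:
        raise ZeroDivisionError("separation factor undefined for feed FOS:Fc = 0")
    return fos_fc_ratio(permeate) / feed_ratio


def solute_flux(permeate_flow: float, permeate_conc: float, area: float) -> float:
    """Solute mass flux Ji = F_P * C_P / A, reported in kg h^-1 m^-2.

    Parameters
    ----------
    permeate_flow : float
        Permeate volumetric flow, m^3 s^-1.
    permeate_conc : float
        Permeate solute concentration, kg m^-3.
    area : float
        Membrane area, m^2.
    """
    if area <= 0:
        raise ValueError("membrane area must be positive")
    return permeate_flow * permeate_conc / area * 3600.0


def apparent_rejection(cp: float, ci: float) -> float:
    """Apparent rejection Ro = 1 - C_P / C of a solute.

    Ro = 1 is total rejection, Ro = 0 free passage; negative values indicate
    permeate enrichment.
    """
    if ci <= 0:
        raise ValueError("bulk concentration must be positive")
    return 1.0 - cp / ci

def permeate_conc(cr: float, ro: float) -> float:
    """Permeate concentration C_P = C_r * (1 - Ro); inverse of rejection."""
    if ro > 1:
        raise ValueError("rejection cannot exceed 1")
    return cr * (1.0 - ro)


def sum_squared_error(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Sum of squared deviations between paired predicted and observed series."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 1:
        raise ValueError("series must contain at least one point")
    return float(np.sum((pred - obs) ** 2))
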