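"""Three-factor Box-Behnken designs and coded/actual factor transforms.

The ultrafiltration screening campaign varies temperature (°C),
transmembrane pressure (bar) and feed concentration (kg m^-3) on three
levels each.  A Box-Behnken design places runs at the midpoints of the
edges of the factor cube (12 runs for 3 factors) plus replicated center
points, so quadratic response surfaces are estimable with few experiments.

Coded units map each factor's (low, center, high) onto (-1, 0, +1) via
``x = (X - center) / half_range``; all model fitting happens in coded
units, where the design is orthogonal for linear and interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FactorLevels", "DesignTable", "box_behnken", "BBD_EDGE_PATTERN"]

#: Coded edge-midpoint pattern of the standard 3-factor Box-Behnken design.
BBD_EDGE_PATTERN: tuple[tuple[int, int, int], ...] = (
    (-1, -1, 0), (1, -1, 0), (-1, 1, 0), (1, 1, 0),
    (-1, 0, -1), (1, 0, -1), (-1, 0, 1), (1, 0, 1),
    (0, -1, -1), (0, 1, -1), (0, -1, 1), (0, 1, 1),
)

FACTOR_COLUMNS = ["t_c", "tmp_bar", "conc_kgm3"]
CODED_COLUMNS = ["x1", "x2", "x3"]
RESPONSE_COLUMNS = ["sf", "ji"]


@dataclass(frozen=True)
class FactorLevels:
    """(low, center, high) levels for the three process factors.

    Provides the affine coded<->actual transform.  Out-of-box points are
    allowed (extrapolation) — coding is a pure change of units.
    """

    temperature: tuple[float, float, float]
    tmp: tuple[float, float, float]
    feed_conc: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("temperature", "tmp", "feed_conc"):
            lo, mid, hi = getattr(self, name)
            if not (lo < mid < hi):
                raise ValueError(f"{name} levels {lo, mid, hi} must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.array([self.temperature[1], self.tmp[1], self.feed_conc[1]])

    @property
    def half_ranges(self) -> np.ndarray:
        return np.array(
            [
                (self.temperature[2] - self.temperature[0]) / 2.0,
                (self.tmp[2] - self.tmp[0]) / 2.0,
                (self.feed_conc[2] - self.feed_conc[0]) / 2.0,
            ]
        )

    def code(self, actual: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map actual-unit points (n, 3) or (3,) to coded units."""
        a = np.asarray(actual, dtype=float)
        return (a - self.centers) / self.half_ranges

    def decode(self, coded: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map coded points back to actual units (inverse of :meth:`code`)."""
        c = np.asarray(coded, dtype=float)
        return c * self.half_ranges + self.centers

    def in_box(self, actual: Sequence[float] | np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: does each point lie inside the design box?"""
        coded = np.atleast_2d(self.code(actual))
        return np.all(np.abs(coded) <= 1 + tol, axis=1)


#: Levels used throughout the pilot-scale fractionation study.
PILOT_LEVELS = FactorLevels(
    temperature=(30.0, 45.0, 60.0),
    tmp=(1.0, 3.0, 5.0),
    feed_conc=(50.0, 100.0, 150.0),
)


class DesignTable:
    """A Box-Behnken run table with optional responses.

    Wraps a :class:`pandas.DataFrame` with columns ``run_id``, actual
    factors (``t_c``, ``tmp_bar``, ``conc_kgm3``), coded factors
    (``x1 .. x3``) and, once measured, the responses ``sf`` (separation
    factor) and ``ji`` (solute flux, kg h^-1 m^-2).
    """

    def __init__(self, frame: pd.DataFrame, levels: FactorLevels):
        missing = [c for c in ["run_id", *FACTOR_COLUMNS] if c not in frame.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        frame = frame.copy().reset_index(drop=True)
        coded = levels.code(frame[FACTOR_COLUMNS].to_numpy())
        if all(c in frame.columns for c in CODED_COLUMNS):
            if not np.allclose(frame[CODED_COLUMNS].to_numpy(), coded, atol=1e-6):
                raise ValueError("coded columns inconsistent with actual columns under the coding map")
        frame[CODED_COLUMNS] = coded
        self.frame = frame
        self.levels = levels

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coded(self) -> np.ndarray:
        return self.frame[CODED_COLUMNS].to_numpy()

    @property
    def actual(self) -> np.ndarray:
        return self.frame[FACTOR_COLUMNS].to_numpy()

    def response(self, name: str) -> np.ndarray:
        key = name.lower()
        if key not in self.frame.columns or self.frame[key].isna().any():
            raise ValueError(f"response {name!r} absent or incomplete")
        return self.frame[key].to_numpy(dtype=float)

    @property
    def has_responses(self) -> bool:
        return all(
            c in self.frame.columns and not self.frame[c].isna().any()
            for c in RESPONSE_COLUMNS
        )

    def center_mask(self, tol: float = 1e-9) -> np.ndarray:
        return np.all(np.abs(self.coded) <= tol, axis=1)

    @property
    def n_center(self) -> int:
        return int(self.center_mask().sum())

    def is_box_behnken(self) -> bool:
        """Check the coded rows form a 3-factor BBD (as a multiset)."""
        rounded = [tuple(int(round(v)) for v in row) for row in self.coded]
        if not np.allclose(self.coded, np.round(self.coded), atol=1e-6):
            return False
        edges = [r for r in rounded if r != (0, 0, 0)]
        return sorted(edges) == sorted(BBD_EDGE_PATTERN) and (0, 0, 0) in rounded

    def with_responses(self, sf: Sequence[float] | None = None,
                       ji: Sequence[float] | None = None) -> "DesignTable":
        frame = self.frame.copy()
        if sf is not None:
            frame["sf"] = np.asarray(sf, dtype=float)
        if ji is not None:
            frame["ji"] = np.asarray(ji, dtype=float)
        return DesignTable(frame, self.levels)


def box_behnken(levels: FactorLevels, n_center: int = 4) -> DesignTable:
    """Construct a 3-factor Box-Behnken design (responses empty).

    Parameters
    ----------
    levels : FactorLevels
        (low, center, high) per factor; the coded pattern is placed on them.
    n_center : int
        Number of replicated center runs (>= 1); replication provides the
        pure-error estimate for lack-of-fit testing.
    """
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    coded = np.array(list(BBD_EDGE_PATTERN) + [(0, 0, 0)] * n_center, dtype=float)
    actual = levels.decode(coded)
    frame = pd.DataFrame(actual, columns=FACTOR_COLUMNS)
    frame.insert(0, "run_id", np.arange(1, len(frame) + 1))
    return DesignTable(frame, levels)
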