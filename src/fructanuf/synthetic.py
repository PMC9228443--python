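"""Seeded synthetic-data generators mirroring the pilot study's data shapes.

Each generator is a pure function of its parameters and a seed, producing
data with the statistical structure the downstream estimators assume:

* commercial fructan batch compositions, with ~10% mono-/disaccharides
  and the complementary linear trade-off between FOS and Fc percentages
  seen across production batches;
* Box-Behnken response columns from a known truth polynomial plus
  Gaussian noise;
* limiting-flux curves from the film-theory model with multiplicative
  noise (fluxes span an order of magnitude, so a constant CV is the
  natural noise scale);
* noisy concentration time series from the batch simulator.

Zero noise always reproduces the underlying model exactly, which makes
generator/estimator pairs exact round trips — the backbone of the
parameter-recovery tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import SolutePair
from .design import DesignTable
from .dynamics import UFSystemSpec, limiting_flux, simulate
from .calibration import FluxCurve
from .rsm import _basis, term_names

__all__ = ["gen_batches", "gen_bbd_responses", "gen_flux_curve", "gen_uf_timeseries"]


def gen_batches(n: int, seed: int) -> pd.DataFrame:
    """Synthetic commercial-batch compositions (percent columns).

    Fc% ~ Uniform(60, 75); MD% ~ Normal(10, 1) truncated to [7, 13];
    FOS% is the complement, so rows sum to 100 exactly and FOS falls
    linearly as Fc rises — the batch-to-batch structure of native agave
    fructan syrups.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fc = rng.uniform(60.0, 75.0, size=n)
    md = rng.normal(10.0, 1.0, size=n)
    # truncation by redraw keeps the distribution shape near the mode
    bad = (md < 7.0) | (md > 13.0)
    while bad.any():
        md[bad] = rng.normal(10.0, 1.0, size=int(bad.sum()))
        bad = (md < 7.0) | (md > 13.0)
    fos = 100.0 - fc - md
    return pd.DataFrame({
        "batch_id": np.arange(1, n + 1),
        "pct_fc": fc,
        "pct_fos": fos,
        "pct_md": md,
    })


def gen_bbd_responses(
    design: DesignTable,
    truth: dict[str, float],
    sigma: float,
    seed: int,
    response: str = "sf",
) -> DesignTable:
    """Fill a design's response column from a truth polynomial plus noise.

    ``truth`` maps coded term names ('const', 'x1', ..., 'x3^2') to
    coefficients; missing terms are zero.  ``sigma = 0`` reproduces the
    polynomial exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    terms = term_names("quadratic")
    beta = np.array([truth.get("const", 0.0)] + [truth.get(t, 0.0) for t in terms])
    y = _basis(design.coded, terms) @ beta
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=len(y))
    return design.with_responses(**{response: y})


def gen_flux_curve(
    k: float,
    c_lim: float,
    ro: float,
    conc_grid: Sequence[float],
    cv: float,
    seed: int,
) -> FluxCurve:
    """Film-theory flux curve with multiplicative Gaussian noise.

    J = limiting_flux(C) * (1 + N(0, cv)); negative noisy fluxes are
    clipped to 0 with a warning (only possible near the limit
    concentration).
    """
    from .dynamics import FluxModelParams

    if cv < 0:
        raise ValueError("cv must be >= 0")
    grid = np.asarray(conc_grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= c_lim):
        raise ValueError("concentration grid must lie strictly inside (0, c_lim)")
    p = FluxModelParams(k=k, c_lim=c_lim)
    j = np.array([limiting_flux(c, ro, p) for c in grid])
    if cv > 0:
        j = j * (1.0 + np.random.default_rng(seed).normal(0.0, cv, size=grid.size))
        if np.any(j < 0):
            import warnings

            warnings.warn("noisy flux clipped at 0 near the limit concentration",
                          stacklevel=2)
            j = np.clip(j, 0.0, None)
    return FluxCurve(conc=tuple(grid), flux=tuple(j), flux_unit="m_s")


def gen_uf_timeseries(
    spec: UFSystemSpec,
    sample_times: Sequence[float],
    sigma: float,
    seed: int,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Noisy observed concentration table from a simulated batch run.

    Simulates the batch, samples retentate and permeate concentrations at
    ``sample_times`` and adds independent Gaussian noise (sd ``sigma``,
    kg m^-3) per observation.  Returns the tidy format consumed by
    :func:`fructanuf.calibration.validate_profiles`.
    """
    from .dynamics import concentration_profiles

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = np.asarray(sample_times, dtype=float)
    traj = simulate(spec, t_end=t_end if t_end is not None else float(times.max()))
    prof = concentration_profiles(traj, times)
    rng = np.random.default_rng(seed)
    rows = []
    for stream, suffix in (("retentate", "ret"), ("permeate", "perm")):
        for solute in ("fc", "fos"):
            clean = prof[f"c_{solute}_{suffix}"].to_numpy()
            noisy = clean + (rng.normal(0.0, sigma, size=clean.size) if sigma > 0 else 0.0)
            rows.append(pd.DataFrame({
                "time_s": times,
                "stream": stream,
                "solute": solute,
                "conc_kgm3": noisy,
            }))
    return pd.concat(rows, ignore_index=True)
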