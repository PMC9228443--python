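"""Batch-mode ultrafiltration simulator with concentration-dependent limiting flux.

In batch concentration mode the retentate returns to the feed tank while
permeate is withdrawn, so tank volume shrinks and retained solutes
concentrate.  Under film theory with a limit (gel) concentration C_lim at
the membrane wall, the permeate flux is

    J_lim = k * ln( C_lim / (Ro * C) - (1 - Ro) / Ro )

where k is the mass-transfer coefficient (m s^-1), C the bulk
concentration of the flux-driving solute and Ro its apparent rejection
(for Ro = 1 this reduces to the classic k*ln(C_lim/C)).  The flux vanishes
exactly at C = C_lim.  The coupled balances

    dV/dt   = -J_lim * A
    dC_i/dt = (C_i / V) * J_lim * A * Ro_i ,   i in {Fc, FOS}

are integrated with an adaptive solver; permeate concentrations follow
pointwise from C_P,i = C_i * (1 - Ro_i).  Rejections are held constant
over a run, and osmotic pressure and fouling resistance are neglected —
assumptions that hold for dilute fructan solutions over the few hours a
pilot batch lasts.

Mono-/disaccharides are not simulated: they permeate a 1 kDa membrane
essentially freely and play no role in the Fc/FOS split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .core import SolutePair

__all__ = [
    "FluxModelParams",
    "UFSystemSpec",
    "UFTrajectory",
    "limiting_flux",
    "rhs",
    "simulate",
    "concentration_profiles",
]


@dataclass(frozen=True)
class FluxModelParams:
    """Film-theory flux parameters.

    k : mass-transfer coefficient, m s^-1.
    c_lim : limit (gel) concentration at the membrane boundary layer, kg m^-3.
    driving_solute : which bulk concentration drives the flux — the
        long-chain fraction ('fc', default: Fc dominates the boundary
        layer) or the total fructan concentration ('total').
    """

    k: float
    c_lim: float
    driving_solute: Literal["fc", "total"] = "fc"

    def __post_init__(self) -> None:
        if self.k <= 0 or self.c_lim <= 0:
            raise ValueError("k and c_lim must be positive")


@dataclass(frozen=True)
class UFSystemSpec:
    """Geometry, initial charge and rejections for one batch run.

    area : membrane area, m^2.
    v0 : initial tank volume, m^3.
    c0 : initial per-solute concentrations (kg m^-3).
    ro : per-solute apparent rejections, constant over the run.
    flux_params : limiting-flux parameters.
    """

    area: float
    v0: float
    c0: SolutePair
    ro: SolutePair
    flux_params: FluxModelParams

    def __post_init__(self) -> None:
        if self.area <= 0 or self.v0 <= 0:
            raise ValueError("area and v0 must be positive")
        if self.c0.fc < 0 or self.c0.fos < 0:
            raise ValueError("initial concentrations must be non-negative")
        if not (0 < self.ro.fc <= 1):
            raise ValueError("driving-solute rejection must lie in (0, 1]")
        if not (self.ro.fc <= 1 and self.ro.fos <= 1):
            raise ValueError("rejections cannot exceed 1")

    def driving_conc(self, c_fc: float, c_fos: float) -> float:
        if self.flux_params.driving_solute == "total":
            return c_fc + c_fos
        return c_fc

    @property
    def driving_ro(self) -> float:
        # one membrane, one boundary layer: the Fc rejection governs the
        # polarization layer in both driving conventions
        return self.ro.fc


@dataclass
class UFTrajectory:
    """Time-resolved state of a batch ultrafiltration run (SI units)."""

    t: np.ndarray                 # s
    volume: np.ndarray            # m^3
    c_ret: dict[str, np.ndarray]  # kg m^-3, keys 'fc', 'fos'
    c_perm: dict[str, np.ndarray]
    j_lim: np.ndarray             # m s^-1
    v_perm: np.ndarray            # cumulative permeate volume, m^3
    m_perm: dict[str, np.ndarray]  # cumulative permeate mass per solute, kg
    termination: Literal["t_end", "v_min", "flux_zero"]
    spec: UFSystemSpec

    def as_frame(self) -> pd.DataFrame:
        """Tidy table: one row per time per stream per solute."""
        rows = []
        for stream, conc in (("retentate", self.c_ret), ("permeate", self.c_perm)):
            for solute in ("fc", "fos"):
                rows.append(pd.DataFrame({
                    "time_s": self.t,
                    "stream": stream,
                    "solute": solute,
                    "conc_kgm3": conc[solute],
                }))
        return pd.concat(rows, ignore_index=True)


def limiting_flux(c_drive: float, ro: float, p: FluxModelParams) -> float:
    """Limiting permeate flux (m s^-1) at a bulk driving concentration.

    Returns exactly 0 whenever the log argument is <= 1, i.e. at and
    beyond the limit concentration.
    """
    if not (0 < ro <= 1):
        raise ValueError("rejection must lie in (0, 1]")
    if c_drive <= 0:
        raise ValueError("driving concentration must be positive")
    arg = p.c_lim / (ro * c_drive) - (1.0 - ro) / ro
    if arg <= 1.0:
        return 0.0
    return p.k * np.log(arg)


def rhs(state: Sequence[float], spec: UFSystemSpec) -> np.ndarray:
    """Time derivatives (dV/dt, dC_fc/dt, dC_fos/dt) of the batch balances."""
    v, c_fc, c_fos = state
    if v <= 0:
        raise ValueError("tank volume must be positive")
    j = limiting_flux(spec.driving_conc(c_fc, c_fos), spec.driving_ro, spec.flux_params)
    ja = j * spec.area
    return np.array([
        -ja,
        c_fc / v * ja * spec.ro.fc,
        c_fos / v * ja * spec.ro.fos,
    ])


def simulate(
    spec: UFSystemSpec,
    t_end: float,
    v_min_frac: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = np.inf,
    n_output: int = 601,
) -> UFTrajectory:
    """Integrate a batch run until ``t_end``, volume depletion, or zero flux.

    Parameters
    ----------
    t_end : float
        Horizon, s.
    v_min_frac : float
        Stop when V falls to this fraction of the initial volume
        (default 5% — a practical empty-tank limit).
    rtol, atol : float
        Adaptive solver tolerances (tight defaults so mass balances close
        to ~1e-6 relative).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not (0 < v_min_frac < 1):
        raise ValueError("v_min_frac must lie in (0, 1)")

    c0_drive = spec.driving_conc(spec.c0.fc, spec.c0.fos)
    j0 = limiting_flux(c0_drive, spec.driving_ro, spec.flux_params)
    if j0 <= 0.0:
        t = np.array([0.0])
        return UFTrajectory(
            t=t,
            volume=np.array([spec.v0]),
            c_ret={"fc": np.array([spec.c0.fc]), "fos": np.array([spec.c0.fos])},
            c_perm={"fc": np.array([spec.c0.fc * (1 - spec.ro.fc)]),
                    "fos": np.array([spec.c0.fos * (1 - spec.ro.fos)])},
            j_lim=np.array([0.0]),
            v_perm=np.array([0.0]),
            m_perm={"fc": np.array([0.0]), "fos": np.array([0.0])},
            termination="flux_zero",
            spec=spec,
        )

    # state augmented with cumulative permeate masses so the solute mass
    # audit closes at solver accuracy: dM_i/dt = C_P,i * Jlim * A
    def f(t, y):
        core = rhs(y[:3], spec)
        j_a = -core[0]  # Jlim * A
        return np.concatenate([core, [
            y[1] * (1.0 - spec.ro.fc) * j_a,
            y[2] * (1.0 - spec.ro.fos) * j_a,
        ]])

    def ev_vmin(t, y):
        return y[0] - v_min_frac * spec.v0

    ev_vmin.terminal = True
    ev_vmin.direction = -1

    def ev_flux(t, y):
        return limiting_flux(spec.driving_conc(y[1], y[2]), spec.driving_ro,
                             spec.flux_params) - 1e-15

    ev_flux.terminal = True
    ev_flux.direction = -1

    sol = solve_ivp(
        f,
        (0.0, t_end),
        np.array([spec.v0, spec.c0.fc, spec.c0.fos, 0.0, 0.0]),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=max_step,
        events=[ev_vmin, ev_flux],
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}; last state {sol.y[:, -1]}")

    if sol.t_events[0].size:
        termination = "v_min"
    elif sol.t_events[1].size:
        termination = "flux_zero"
    else:
        termination = "t_end"

    # uniform output grid over the integrated span, from the dense solution
    # (the adaptive step points alone are too sparse to interpolate well)
    t = np.linspace(0.0, sol.t[-1], max(n_output, 2))
    v, c_fc, c_fos, m_fc, m_fos = sol.sol(t)
    v[0], c_fc[0], c_fos[0] = spec.v0, spec.c0.fc, spec.c0.fos
    m_fc[0] = m_fos[0] = 0.0

    j = np.array([
        limiting_flux(spec.driving_conc(a, b), spec.driving_ro, spec.flux_params)
        for a, b in zip(c_fc, c_fos)
    ])
    return UFTrajectory(
        t=t,
        volume=v,
        c_ret={"fc": c_fc, "fos": c_fos},
        c_perm={"fc": c_fc * (1 - spec.ro.fc), "fos": c_fos * (1 - spec.ro.fos)},
        j_lim=j,
        v_perm=spec.v0 - v,
        m_perm={"fc": m_fc, "fos": m_fos},
        termination=termination,
        spec=spec,
    )


def concentration_profiles(traj: UFTrajectory, sample_times: Sequence[float]) -> pd.DataFrame:
    """Interpolate a trajectory at requested times (monotone cubic).

    Returns a wide table with retentate and permeate concentrations per
    solute.  Sampling exactly at stored grid points reproduces the stored
    values.
    """
    times = np.asarray(sample_times, dtype=float)
    if times.min() < traj.t[0] - 1e-12 or times.max() > traj.t[-1] + 1e-12:
        raise ValueError(
            f"sample times must lie within the trajectory span "
            f"[{traj.t[0]}, {traj.t[-1]}]"
        )
    if traj.t.size < 2:
        # degenerate single-point trajectory: only t=0 is sampleable
        out = {"time_s": times}
        for key, label in (("fc", "c_fc_ret"), ("fos", "c_fos_ret")):
            out[label] = np.full_like(times, traj.c_ret[key][0])
        for key, label in (("fc", "c_fc_perm"), ("fos", "c_fos_perm")):
            out[label] = np.full_like(times, traj.c_perm[key][0])
        return pd.DataFrame(out)
    cols = {"time_s": times}
    for key in ("fc", "fos"):
        cols[f"c_{key}_ret"] = PchipInterpolator(traj.t, traj.c_ret[key])(times)
        cols[f"c_{key}_perm"] = PchipInterpolator(traj.t, traj.c_perm[key])(times)
    return pd.DataFrame(cols)
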