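"""Stochastic delay-differential model of Her6 expression on a cell lattice.

Two model variants share the same equations.  In the single-cell variant
("Model 1", ``coupled=False``) each cell obeys a delayed negative-feedback
loop: Her6 protein represses its own transcription through a Hill function
evaluated at a delayed time point.  In the coupled variant ("Model 2",
``coupled=True``) cells sit on a hexagonal lattice and additionally repress
transcription in their neighbours through a second, delayed Hill function
representing Notch-Delta lateral inhibition.

Per cell (i, j)::

    dm/dt = alpha_m * H_auto(p(t - tau_auto)) * H_LI(<p>(t - tau_LI)) - mu_m * m + eta_m
    dp/dt = alpha_p * m - mu_p * p + eta_p

with ``H(x) = 1 / (1 + (x / P0)^n)`` and ``<p>`` the mean protein level over
the cell's hexagonal neighbours.  The noise terms ``eta_m, eta_p`` follow the
chemical Langevin convention: Gaussian white noise scaled by the square root
of the summed reaction propensities.  Integration is Euler-Maruyama with
delays read from the stored trajectory at the nearest grid time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "Lattice",
    "SimulationResult",
    "hill_auto",
    "hill_li",
    "neighbour_average",
    "langevin_noise",
    "deterministic_steady_state",
    "simulate",
]


@dataclass(frozen=True)
class ModelParams:
    """All rate constants, Hill parameters, delays and run settings.

    Rates are per hour, abundances are molecule counts (arbitrary
    calibration), delays and times are hours.
    """

    alpha_m: float = 300.0      # mRNA synthesis rate (molecules/h)
    alpha_p: float = 20.0       # protein synthesis rate (1/h per mRNA)
    mu_m: float = 2.0           # mRNA degradation rate (1/h)
    mu_p: float = 3.78          # protein degradation rate (1/h); ln2/(11 min)
    degradation_multiplier: float = 1.0  # scale on mu_p (1.1 = destabilised)
    P0_auto: float = 1500.0     # autoinhibition repression threshold (molecules)
    n_auto: float = 4.0         # autoinhibition Hill coefficient
    tau_auto: float = 0.3       # autoinhibition delay (h)
    P0_LI: float = 1500.0       # lateral-inhibition repression threshold
    n_LI: float = 3.0           # lateral-inhibition Hill coefficient
    tau_LI: float = 0.3         # lateral-inhibition delay (h)
    coupled: bool = True        # False -> single-cell model (H_LI = 1)
    rows: int = 10
    cols: int = 6
    dt: float = 1.0 / 60.0      # integration step (h); 1 min
    t_end: float = 100.0        # simulated duration (h)
    noise_on: bool = True
    periodic: bool = False      # wraparound lattice boundaries
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_m", "alpha_p", "mu_m", "mu_p", "P0_auto",
                     "P0_LI", "tau_auto", "tau_LI", "dt", "t_end",
                     "degradation_multiplier"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.n_auto < 1 or self.n_LI < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.rows * self.cols < 1:
            raise ValueError("lattice must contain at least one cell")
        if self.dt >= min(self.tau_auto, self.tau_LI) + 1e-12:
            raise ValueError("dt must be smaller than both delays")

    @property
    def mu_p_effective(self) -> float:
        return self.mu_p * self.degradation_multiplier

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def with_multiplier(self, multiplier: float) -> "ModelParams":
        return replace(self, degradation_multiplier=multiplier)


class Lattice:
    """Hexagonal lattice in odd-r offset layout (odd rows shifted right).

    Interior cells have six neighbours; boundary cells keep only their
    geometric neighbours unless ``periodic`` wraps both axes.
    """

    def __init__(self, rows: int, cols: int, periodic: bool = False):
        if rows < 1 or cols < 1:
            raise ValueError("rows and cols must be >= 1")
        self.rows = rows
        self.cols = cols
        self.periodic = periodic
        self.neighbour_sets: list[list[int]] = self._build()
        # flat CSR-style arrays for the integration kernel
        counts = [len(s) for s in self.neighbour_sets]
        self.ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.idx = np.array(
            [j for s in self.neighbour_sets for j in s], dtype=np.int64
        )

    # odd-r offset neighbour displacements, keyed by row parity
    _EVEN = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
    _ODD = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]

    def _build(self) -> list[list[int]]:
        sets: list[list[int]] = []
        for r in range(self.rows):
            for c in range(self.cols):
                offsets = self._ODD if r % 2 else self._EVEN
                nbrs = set()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if self.periodic:
                        rr %= self.rows
                        cc %= self.cols
                    elif not (0 <= rr < self.rows and 0 <= cc < self.cols):
                        continue
                    j = rr * self.cols + cc
                    if j != r * self.cols + c:
                        nbrs.add(j)
                sets.append(sorted(nbrs))
        return sets

    def __len__(self) -> int:
        return self.rows * self.cols

    def degree(self, cell: int) -> int:
        return len(self.neighbour_sets[cell])


@dataclass
class SimulationResult:
    """Trajectories of one simulation plus full parameter provenance."""

    times: np.ndarray           # (n_times,) hours, starting at 0
    m: np.ndarray               # (n_cells, n_times) mRNA
    p: np.ndarray               # (n_cells, n_times) protein
    params: ModelParams
    seed: int
    clip_count: int = 0         # negative states clipped to zero

    def to_track_table(self):
        """Tidy per-cell table (cell_id, time_h, mrna, protein)."""
        import pandas as pd

        n_cells, n_t = self.p.shape
        ids = [
            f"{i // self.params.cols}_{i % self.params.cols}"
            for i in range(n_cells)
        ]
        return pd.DataFrame(
            {
                "cell_id": np.repeat(ids, n_t),
                "time_h": np.tile(self.times, n_cells),
                "mrna": self.m.ravel(),
                "protein": self.p.ravel(),
            }
        )


def hill_auto(p_delayed, P0_auto: float, n_auto: float):
    """Autoinhibition repression factor ``1 / (1 + (p/P0)^n)`` in (0, 1]."""
    p = np.asarray(p_delayed, dtype=float)
    if not np.all(np.isfinite(p)) or np.any(p < 0):
        raise ValueError("protein state must be finite and non-negative")
    if P0_auto <= 0 or n_auto < 1:
        raise ValueError("require P0 > 0 and Hill coefficient >= 1")
    out = 1.0 / (1.0 + (p / P0_auto) ** n_auto)
    return float(out) if np.isscalar(p_delayed) else out


def hill_li(p_bar_delayed, P0_LI: float, n_LI: float):
    """Lateral-inhibition repression factor applied to the delayed
    neighbour-average protein level."""
    return hill_auto(p_bar_delayed, P0_LI, n_LI)


def neighbour_average(p_state: np.ndarray, lattice: Lattice, cell: int) -> float:
    """Arithmetic mean protein level over the neighbours of ``cell``."""
    nbrs = lattice.neighbour_sets[cell]
    if not nbrs:
        raise ValueError(f"cell {cell} has an empty neighbour set")
    return float(np.mean(np.asarray(p_state, dtype=float)[nbrs]))


def langevin_noise(m, p, production_m, production_p, params: ModelParams,
                   rng: np.random.Generator):
    """One chemical-Langevin increment pair for the current step.

    Each increment is zero-mean Gaussian with variance equal to the summed
    production and degradation propensities times ``dt``.
    """
    if not params.noise_on:
        return np.zeros_like(np.asarray(m, float)), np.zeros_like(np.asarray(p, float))
    m = np.asarray(m, float)
    p = np.asarray(p, float)
    var_m = (np.asarray(production_m, float) + params.mu_m * m) * params.dt
    var_p = (np.asarray(production_p, float) + params.mu_p_effective * p) * params.dt
    if np.any(var_m < 0) or np.any(var_p < 0):
        raise ValueError("negative propensity encountered")
    eta_m = np.sqrt(var_m) * rng.standard_normal(m.shape)
    eta_p = np.sqrt(var_p) * rng.standard_normal(p.shape)
    return eta_m, eta_p


def deterministic_steady_state(params: ModelParams) -> tuple[float, float]:
    """Fixed point (m*, p*) of the noise-free equations, per cell.

    For the coupled model the homogeneous fixed point is returned (every
    cell at the same level, so the neighbour average equals the cell's own
    protein).  The fixed-point map is strictly decreasing in p, so the root
    is unique; it is bracketed on [0, p_max] and solved with Brent's method.
    """
    mu_p = params.mu_p_effective

    def balance(p: float) -> float:
        h = 1.0 / (1.0 + (p / params.P0_auto) ** params.n_auto)
        if params.coupled:
            h *= 1.0 / (1.0 + (p / params.P0_LI) ** params.n_LI)
        return params.alpha_p * params.alpha_m * h / (params.mu_m * mu_p) - p

    p_max = params.alpha_p * params.alpha_m / (params.mu_m * mu_p)
    lo, hi = 0.0, p_max * (1.0 + 1e-9) + 1.0
    if balance(lo) < 0 or balance(hi) > 0:
        raise ValueError("no steady-state root bracketed in [0, p_max]")
    p_star = brentq(balance, lo, hi, xtol=1e-12, rtol=1e-14)
    m_star = mu_p * p_star / params.alpha_p
    return m_star, p_star


@njit(cache=True)
def _integrate(m, p, n_hist, n_steps, dt, alpha_m, alpha_p, mu_m, mu_p_eff,
               P0_auto, n_auto, P0_LI, n_LI, d_auto, d_li, coupled,
               nbr_idx, nbr_ptr, noise):  # pragma: no cover - numba kernel
    n_cells = m.shape[0]
    clip = 0
    for k in range(n_hist, n_hist + n_steps):
        for i in range(n_cells):
            p_del = p[i, k - d_auto]
            h = 1.0 / (1.0 + (p_del / P0_auto) ** n_auto)
            if coupled:
                lo = nbr_ptr[i]
                hi = nbr_ptr[i + 1]
                if hi > lo:
                    s = 0.0
                    for q in range(lo, hi):
                        s += p[nbr_idx[q], k - d_li]
                    p_bar = s / (hi - lo)
                    h *= 1.0 / (1.0 + (p_bar / P0_LI) ** n_LI)
            prod_m = alpha_m * h
            deg_m = mu_m * m[i, k]
            prod_p = alpha_p * m[i, k]
            deg_p = mu_p_eff * p[i, k]
            step = k - n_hist
            eta_m = np.sqrt((prod_m + deg_m) * dt) * noise[0, step, i]
            eta_p = np.sqrt((prod_p + deg_p) * dt) * noise[1, step, i]
            mv = m[i, k] + dt * (prod_m - deg_m) + eta_m
            pv = p[i, k] + dt * (prod_p - deg_p) + eta_p
            if mv < 0.0:
                mv = 0.0
                clip += 1
            if pv < 0.0:
                pv = 0.0
                clip += 1
            m[i, k + 1] = mv
            p[i, k + 1] = pv
    return clip


def _delay_steps(tau: float, dt: float) -> int:
    d = int(round(tau / dt))
    if abs(d * dt - tau) > dt / 2 + 1e-12:
        raise ValueError(f"delay {tau} h is not representable on the dt grid")
    return max(d, 1)


def simulate(params: ModelParams,
             history: tuple[np.ndarray, np.ndarray] | None = None,
             lattice: Lattice | None = None) -> SimulationResult:
    """Integrate the model with Euler-Maruyama and return full trajectories.

    Parameters
    ----------
    params
        Model parameters; ``params.seed`` drives a counter-based Philox
        generator so identical inputs reproduce identical trajectories.
    history
        Optional per-cell constant history ``(m0, p0)`` applied on
        ``[-max(tau), 0]``.  By default each cell starts from the uncoupled
        deterministic fixed point scaled by an independent uniform(0.5, 1.5)
        factor, which avoids artificial synchrony across the lattice.
    """
    rng = np.random.Generator(np.random.Philox(params.seed))
    n_cells = params.n_cells
    d_auto = _delay_steps(params.tau_auto, params.dt)
    d_li = _delay_steps(params.tau_LI, params.dt)
    n_hist = max(d_auto, d_li)
    n_steps = int(round(params.t_end / params.dt))
    if n_steps < 1:
        raise ValueError("t_end/dt must give at least one step")

    if lattice is None:
        lattice = Lattice(params.rows, params.cols, periodic=params.periodic)

    if history is None:
        m_star, p_star = deterministic_steady_state(
            replace(params, coupled=False)
        )
        scale = rng.uniform(0.5, 1.5, size=(2, n_cells))
        m0 = m_star * scale[0]
        p0 = p_star * scale[1]
    else:
        m0 = np.broadcast_to(np.asarray(history[0], float), (n_cells,)).copy()
        p0 = np.broadcast_to(np.asarray(history[1], float), (n_cells,)).copy()
        if np.any(m0 < 0) or np.any(p0 < 0):
            raise ValueError("history states must be non-negative")

    n_total = n_hist + n_steps + 1
    m = np.empty((n_cells, n_total))
    p = np.empty((n_cells, n_total))
    m[:, : n_hist + 1] = m0[:, None]
    p[:, : n_hist + 1] = p0[:, None]

    if params.noise_on:
        noise = rng.standard_normal((2, n_steps, n_cells))
    else:
        noise = np.zeros((2, n_steps, n_cells))

    clip = _integrate(
        m, p, n_hist, n_steps, params.dt, params.alpha_m, params.alpha_p,
        params.mu_m, params.mu_p_effective, params.P0_auto, params.n_auto,
        params.P0_LI, params.n_LI, d_auto, d_li,
        bool(params.coupled), lattice.idx, lattice.ptr, noise,
    )

    m_out = m[:, n_hist:]
    p_out = p[:, n_hist:]
    if not (np.all(np.isfinite(m_out)) and np.all(np.isfinite(p_out))):
        bad = int(np.argmax(~np.isfinite(p_out).all(axis=0)))
        raise FloatingPointError(
            f"non-finite state at step {bad} (t={bad * params.dt:.3f} h); "
            "reduce dt or check parameters"
        )
    times = np.arange(n_steps + 1) * params.dt
    return SimulationResult(times=times, m=m_out, p=p_out, params=params,
                            seed=params.seed, clip_count=int(clip))
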