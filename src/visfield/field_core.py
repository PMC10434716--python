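"""Stochastic two-layer neural field dynamics with memory trace and adaptation.

The model is an Amari-type activation dynamics on a 1-D spatial grid.  An
excitatory field ``u`` receives localized stimulus input, recurrent
self-excitation, and recurrent inhibition from an inhibitory field ``v`` that
is itself driven by ``u``.  Suprathreshold activation (``u > 0``) lays down a
slow memory trace ``m`` that locally raises the resting level, and drives
adaptation ``a`` that multiplicatively weakens stimulus input.  Stochasticity
comes from a spatially uniform, slowly drifting resting-level offset ``n``
(an Ornstein–Uhlenbeck process, emulating trial-to-trial drift of perceptual
sensitivity) plus weak fast white noise per grid point.

Euler–Maruyama integration at a fixed step ``dt``::

    tau_u du = (-u + h_u + n + trace_gain*m + S_eff
                + k_uu * f(u) - k_uv * f(v)) dt + fast noise
    tau_v dv = (-v + h_v + k_vu * f(u)) dt
    dm = (1 - m)/trace_build_tau dt      where suprathreshold activity is
                                         present within the trace spread
       = -m/trace_decay_tau dt           elsewhere
    da = (1 - a)/adapt_tau dt            where suprathreshold activity is
                                         present within the trace spread
       = -a/adapt_tau dt                 elsewhere
    dn = -n/noise_slow_tau dt + noise_slow_amp*sqrt(2 dt/noise_slow_tau) dW

with ``f`` a logistic sigmoid with steepness ``beta`` (value 0.5 at the
visibility threshold ``u = 0``), ``*`` spatial convolution with
integral-normalized Gaussian kernels, and ``S_eff = S*(1 - adapt_gain*a)``
clipped at zero.

The memory trace and adaptation are *regional*: suprathreshold activation
anywhere builds both over a wide surrounding neighborhood
(``trace_spread_width``, the region where the Gaussian-smoothed
suprathreshold indicator exceeds ``TRACE_COVER_THETA``).  The trace is the
spread of subthreshold preactivation that links presentations at
unpredictable nearby locations; regional adaptation likewise transfers
across relocations.  Their asymmetry is temporal: the trace saturates
within about one presentation (fast build), while adaptation integrates
slowly over repeated visible presentations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "FieldGrid",
    "FieldParams",
    "FieldState",
    "ActivationRecord",
    "InvalidParameterError",
    "IntegrationDivergedError",
    "ConvergenceError",
    "sigmoid",
    "gaussian_kernel",
    "effective_input",
    "gaussian_input",
    "step",
    "simulate_frames",
    "find_stationary_states",
    "scan_bistability",
]


#: Smoothed-suprathreshold-coverage level above which the memory trace
#: builds (fixed convention; the trace region is where the
#: trace_spread_width Gaussian smoothing of 1[u > 0] exceeds this).
TRACE_COVER_THETA = 0.02


class InvalidParameterError(ValueError):
    """A model parameter violates its admissible range."""


class IntegrationDivergedError(RuntimeError):
    """A state variable became non-finite during integration."""


class ConvergenceError(RuntimeError):
    """Deterministic relaxation failed to settle within the step budget."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldGrid:
    """Uniform 1-D spatial grid in abstract field units.

    Positions are centered on zero and strictly increasing.
    """

    n_points: int = 201
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidParameterError("n_points must be >= 3")
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be > 0")

    @property
    def extent(self) -> float:
        return (self.n_points - 1) * self.spacing

    @property
    def positions(self) -> np.ndarray:
        half = self.extent / 2.0
        return np.linspace(-half, half, self.n_points)


@dataclass(frozen=True)
class FieldParams:
    """The single shared parameter set of the model.

    One instance is used for every experiment simulation; only the stimulus
    protocols differ between experiments.  Time constants are in ms, spatial
    widths in field units, amplitudes in activation units.
    """

    tau_u: float = 20.0
    tau_v: float = 10.0
    h_u: float = -5.18
    h_v: float = -4.7
    beta: float = 4.0
    w_uu_amp: float = 5.5
    w_uu_width: float = 3.8
    w_uv_amp: float = 40.0
    w_uv_width: float = 10.0
    w_vu_amp: float = 8.0
    w_vu_width: float = 5.0
    trace_build_tau: float = 500.0
    trace_decay_tau: float = 5000.0
    trace_gain: float = 0.9
    trace_spread_width: float = 20.0
    adapt_tau: float = 10000.0
    adapt_gain: float = 1.1
    noise_slow_tau: float = 16000.0
    noise_slow_amp: float = 0.38
    noise_fast_amp: float = 0.15
    input_width: float = 3.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "tau_u",
            "tau_v",
            "trace_build_tau",
            "trace_decay_tau",
            "adapt_tau",
            "noise_slow_tau",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in (
            "w_uu_width", "w_uv_width", "w_vu_width", "input_width",
            "trace_spread_width",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.beta <= 0:
            raise InvalidParameterError("beta must be > 0")
        if self.h_u >= 0 or self.h_v >= 0:
            raise InvalidParameterError(
                "resting levels h_u and h_v must lie below the zero threshold"
            )
        if self.noise_slow_amp < 0 or self.noise_fast_amp < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")
        if self.adapt_gain < 0 or self.trace_gain < 0:
            raise InvalidParameterError("gains must be >= 0")
        if self.dt > min(self.tau_u, self.tau_v) / 5.0:
            raise InvalidParameterError("dt must be <= min(tau_u, tau_v)/5")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "FieldParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        return cls(**d)


@dataclass
class FieldState:
    """Instantaneous model state: u, v, m, a over the grid, plus scalar n."""

    u: np.ndarray
    v: np.ndarray
    m: np.ndarray
    a: np.ndarray
    n: float = 0.0
    t: float = 0.0

    @classmethod
    def resting(
        cls, grid: FieldGrid, params: FieldParams, n: float = 0.0
    ) -> "FieldState":
        k = grid.n_points
        return cls(
            u=np.full(k, params.h_u, dtype=np.float64),
            v=np.full(k, params.h_v, dtype=np.float64),
            m=np.zeros(k, dtype=np.float64),
            a=np.zeros(k, dtype=np.float64),
            n=float(n),
            t=0.0,
        )

    def copy(self) -> "FieldState":
        return FieldState(
            self.u.copy(), self.v.copy(), self.m.copy(), self.a.copy(),
            self.n, self.t,
        )


@dataclass
class ActivationRecord:
    """Sampled excitatory-field activation across one simulated trial."""

    times: np.ndarray           # (n_samples,) ms, strictly increasing
    u_trace: np.ndarray         # (n_samples, n_points)
    frame_index: np.ndarray     # (n_samples,) int, -1 for the initial sample
    grid: FieldGrid
    final_state: FieldState

    def frame_samples(self, index: int) -> np.ndarray:
        """Rows of ``u_trace`` recorded during protocol frame ``index``."""
        return self.u_trace[self.frame_index == index]

    def to_frame(self):
        """Export as a tidy table (time_ms, frame_index, u@position...)."""
        import pandas as pd

        cols = {f"u_{x:+.1f}": self.u_trace[:, i]
                for i, x in enumerate(self.grid.positions)}
        return pd.DataFrame(
            {"time_ms": self.times, "frame_index": self.frame_index, **cols}
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def sigmoid(activation, beta: float):
    """Logistic rate function; 0.5 at the visibility threshold (zero)."""
    if beta <= 0:
        raise InvalidParameterError("beta must be > 0")
    x = np.asarray(activation, dtype=np.float64)
    out = np.empty_like(x)
    np.clip(x * beta, -700.0, 700.0, out=out)
    out = 1.0 / (1.0 + np.exp(-out))
    if np.ndim(activation) == 0:
        return float(out)
    return out


def gaussian_kernel(amp: float, width: float, grid: FieldGrid) -> np.ndarray:
    """Integral-normalized Gaussian coupling kernel over grid offsets.

    Returned values are a density (activation per field unit) scaled by
    ``amp``; convolving with a rate field and multiplying by the grid spacing
    yields a total coupling that is independent of discretization.  Support is
    truncated at four widths.
    """
    if width <= 0:
        raise InvalidParameterError("kernel width must be > 0")
    half = int(math.ceil(4.0 * width / grid.spacing))
    offsets = np.arange(-half, half + 1) * grid.spacing
    dens = np.exp(-0.5 * (offsets / width) ** 2) / (width * math.sqrt(2 * math.pi))
    # renormalize the truncated, discretized density so the coupling
    # integral is exactly amp regardless of spacing
    dens /= dens.sum() * grid.spacing
    return amp * dens


def gaussian_input(
    grid: FieldGrid, centers_amps: Sequence[tuple[float, float]], width: float
) -> np.ndarray:
    """Stimulus input field: a Gaussian bump of peak ``amp`` per stimulus."""
    x = grid.positions
    s = np.zeros(grid.n_points)
    for center, amp in centers_amps:
        if amp < 0:
            raise InvalidParameterError("input amplitude must be >= 0")
        s += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    return s


def effective_input(
    raw_input: np.ndarray, a: np.ndarray, adapt_gain: float
) -> np.ndarray:
    """Adaptation-weakened stimulus input, clipped below at zero."""
    return np.clip(raw_input * (1.0 - adapt_gain * np.asarray(a)), 0.0, None)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _conv_same(kernel_times_dx: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Zero-padded 'same' convolution (open field boundaries)."""
    half = (len(kernel_times_dx) - 1) // 2
    full = np.convolve(rate, kernel_times_dx)
    return full[half : half + len(rate)]


def step(
    state: FieldState,
    raw_input: np.ndarray,
    params: FieldParams,
    grid: FieldGrid,
    rng: np.random.Generator | None = None,
) -> FieldState:
    """One Euler–Maruyama update (reference implementation).

    ``simulate_frames`` runs the identical scheme through a compiled kernel;
    with noise amplitudes at zero the two paths agree to machine precision.
    """
    p = params
    u, v, m, a, n = state.u, state.v, state.m, state.a, state.n
    dx = grid.spacing
    k_uu = gaussian_kernel(p.w_uu_amp, p.w_uu_width, grid) * dx
    k_uv = gaussian_kernel(p.w_uv_amp, p.w_uv_width, grid) * dx
    k_vu = gaussian_kernel(p.w_vu_amp, p.w_vu_width, grid) * dx
    k_ms = gaussian_kernel(1.0, p.trace_spread_width, grid) * dx

    fu = sigmoid(u, p.beta)
    fv = sigmoid(v, p.beta)
    s_eff = effective_input(raw_input, a, p.adapt_gain)

    if rng is not None and (p.noise_fast_amp > 0 or p.noise_slow_amp > 0):
        eps = rng.standard_normal(grid.n_points + 1)
    else:
        eps = np.zeros(grid.n_points + 1)

    du = (p.dt / p.tau_u) * (
        -u + p.h_u + n + p.trace_gain * m + s_eff
        + _conv_same(k_uu, fu) - _conv_same(k_uv, fv)
    ) + p.noise_fast_amp * math.sqrt(2.0 * p.dt / p.tau_u) * eps[:-1]
    dv = (p.dt / p.tau_v) * (-v + p.h_v + _conv_same(k_vu, fu))

    above = u > 0.0
    cover = _conv_same(k_ms, above.astype(np.float64))
    in_region = cover > TRACE_COVER_THETA
    m_new = np.where(
        in_region,
        m + (1.0 - m) * (p.dt / p.trace_build_tau),
        m - m * (p.dt / p.trace_decay_tau),
    )
    a_new = np.where(
        in_region,
        a + (1.0 - a) * (p.dt / p.adapt_tau),
        a - a * (p.dt / p.adapt_tau),
    )
    # flush decayed tails to zero (avoids denormal arithmetic)
    m_new[~in_region & (m_new < 1e-12)] = 0.0
    a_new[~in_region & (a_new < 1e-12)] = 0.0
    dm = m_new - m
    da = a_new - a
    dn = -n * p.dt / p.noise_slow_tau + p.noise_slow_amp * math.sqrt(
        2.0 * p.dt / p.noise_slow_tau
    ) * eps[-1]

    new = FieldState(u + du, v + dv, m + dm, a + da, n + dn, state.t + p.dt)
    for name in ("u", "v", "m", "a"):
        arr = getattr(new, name)
        if not np.all(np.isfinite(arr)):
            raise IntegrationDivergedError(
                f"field '{name}' became non-finite at t={new.t:.1f} ms"
            )
    if not math.isfinite(new.n):
        raise IntegrationDivergedError(
            f"field 'n' became non-finite at t={new.t:.1f} ms"
        )
    return new


@njit(cache=True, fastmath=True)
def _kernel_loop(
    u, v, m, a, n0,
    s_raw, k_uu, k_uv, k_vu, k_ms, noise,
    dt, tau_u, tau_v, h_u, h_v, beta,
    trace_gain, trace_build_tau, trace_decay_tau, trace_theta,
    adapt_tau, adapt_gain,
    noise_slow_tau, noise_slow_amp, noise_fast_amp,
    start_step, stride, out_u,
):  # pragma: no cover - exercised through simulate_frames
    npts = u.shape[0]
    n_steps = noise.shape[0]
    h_uu = (k_uu.shape[0] - 1) // 2
    h_uv = (k_uv.shape[0] - 1) // 2
    h_vu = (k_vu.shape[0] - 1) // 2
    h_ms = (k_ms.shape[0] - 1) // 2
    len_ms = k_ms.shape[0]
    # prefix sums of the spread kernel: cover over a contiguous run of
    # suprathreshold points reduces to two prefix lookups per grid point
    pref = np.empty(len_ms + 1)
    pref[0] = 0.0
    for j in range(len_ms):
        pref[j + 1] = pref[j] + k_ms[j]
    fu = np.empty(npts)
    fv = np.empty(npts)
    du = np.empty(npts)
    dv = np.empty(npts)
    cover = np.empty(npts)
    fast_scale = noise_fast_amp * math.sqrt(2.0 * dt / tau_u)
    slow_scale = noise_slow_amp * math.sqrt(2.0 * dt / noise_slow_tau)
    n = n0
    rec = 0
    for k in range(n_steps):
        for i in range(npts):
            fu[i] = 1.0 / (1.0 + math.exp(-beta * u[i]))
            fv[i] = 1.0 / (1.0 + math.exp(-beta * v[i]))
            cover[i] = 0.0
        # accumulate spread-kernel mass over each contiguous run of
        # suprathreshold points via kernel prefix sums
        j = 0
        while j < npts:
            if u[j] > 0.0:
                run_start = j
                while j < npts and u[j] > 0.0:
                    j += 1
                run_end = j - 1
                for i in range(npts):
                    lo = h_ms + i - run_end
                    if lo < 0:
                        lo = 0
                    hi = h_ms + i - run_start + 1
                    if hi > len_ms:
                        hi = len_ms
                    if hi > lo:
                        cover[i] += pref[hi] - pref[lo]
            else:
                j += 1
        for i in range(npts):
            exc = 0.0
            lo = i - h_uu
            if lo < 0:
                lo = 0
            hi = i + h_uu + 1
            if hi > npts:
                hi = npts
            for j in range(lo, hi):
                exc += k_uu[h_uu + i - j] * fu[j]
            inh = 0.0
            lo = i - h_uv
            if lo < 0:
                lo = 0
            hi = i + h_uv + 1
            if hi > npts:
                hi = npts
            for j in range(lo, hi):
                inh += k_uv[h_uv + i - j] * fv[j]
            s_eff = s_raw[i] * (1.0 - adapt_gain * a[i])
            if s_eff < 0.0:
                s_eff = 0.0
            du[i] = (dt / tau_u) * (
                -u[i] + h_u + n + trace_gain * m[i] + s_eff + exc - inh
            ) + fast_scale * noise[k, i]
            drv = 0.0
            lo = i - h_vu
            if lo < 0:
                lo = 0
            hi = i + h_vu + 1
            if hi > npts:
                hi = npts
            for j in range(lo, hi):
                drv += k_vu[h_vu + i - j] * fu[j]
            dv[i] = (dt / tau_v) * (-v[i] + h_v + drv)
        for i in range(npts):
            if cover[i] > trace_theta:
                m[i] += (1.0 - m[i]) * (dt / trace_build_tau)
                a[i] += (1.0 - a[i]) * (dt / adapt_tau)
            else:
                m[i] += -m[i] * (dt / trace_decay_tau)
                a[i] += -a[i] * (dt / adapt_tau)
                # flush decayed tails to zero (avoids denormal arithmetic)
                if m[i] < 1e-12:
                    m[i] = 0.0
                if a[i] < 1e-12:
                    a[i] = 0.0
            u[i] += du[i]
            v[i] += dv[i]
        n += -n * dt / noise_slow_tau + slow_scale * noise[k, npts]
        if (start_step + k + 1) % stride == 0:
            for i in range(npts):
                out_u[rec, i] = u[i]
            rec += 1
    return n


def _run_frame(
    state: FieldState,
    raw_input: np.ndarray,
    n_steps: int,
    params: FieldParams,
    grid: FieldGrid,
    kernels: tuple[np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator | None,
    start_step: int,
    stride: int,
) -> np.ndarray:
    """Integrate ``n_steps`` steps in place; return recorded u rows."""
    p = params
    if rng is not None and (p.noise_fast_amp > 0 or p.noise_slow_amp > 0):
        noise = rng.standard_normal((n_steps, grid.n_points + 1))
    else:
        noise = np.zeros((n_steps, grid.n_points + 1))
    n_rec = sum(
        1 for k in range(n_steps) if (start_step + k + 1) % stride == 0
    )
    out_u = np.empty((n_rec, grid.n_points))
    state.n = _kernel_loop(
        state.u, state.v, state.m, state.a, state.n,
        np.ascontiguousarray(raw_input, dtype=np.float64),
        kernels[0], kernels[1], kernels[2], kernels[3], noise,
        p.dt, p.tau_u, p.tau_v, p.h_u, p.h_v, p.beta,
        p.trace_gain, p.trace_build_tau, p.trace_decay_tau,
        TRACE_COVER_THETA,
        p.adapt_tau, p.adapt_gain,
        p.noise_slow_tau, p.noise_slow_amp, p.noise_fast_amp,
        start_step, stride, out_u,
    )
    state.t += n_steps * p.dt
    for name in ("u", "v", "m", "a"):
        arr = getattr(state, name)
        if not np.all(np.isfinite(arr)):
            raise IntegrationDivergedError(
                f"field '{name}' became non-finite at t={state.t:.1f} ms"
            )
    if not math.isfinite(state.n):
        raise IntegrationDivergedError(
            f"field 'n' became non-finite at t={state.t:.1f} ms"
        )
    return out_u


def _field_kernels(params: FieldParams, grid: FieldGrid):
    dx = grid.spacing
    return (
        np.ascontiguousarray(gaussian_kernel(params.w_uu_amp, params.w_uu_width, grid) * dx),
        np.ascontiguousarray(gaussian_kernel(params.w_uv_amp, params.w_uv_width, grid) * dx),
        np.ascontiguousarray(gaussian_kernel(params.w_vu_amp, params.w_vu_width, grid) * dx),
        np.ascontiguousarray(gaussian_kernel(1.0, params.trace_spread_width, grid) * dx),
    )


def simulate_frames(
    protocol,
    params: FieldParams,
    seed: int | np.random.Generator,
    grid: FieldGrid | None = None,
    record_stride_ms: float = 5.0,
    initial_state: FieldState | None = None,
) -> ActivationRecord:
    """Simulate one trial protocol; deterministic given (protocol, params, seed).

    The state carries over across frames (no reset at frame boundaries).  The
    initial slow-noise offset is drawn from its stationary distribution.
    Samples are taken every ``record_stride_ms``; the first sample is the
    initial resting state (frame index -1).
    """
    grid = grid or FieldGrid()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    stride = max(1, int(round(record_stride_ms / params.dt)))
    if initial_state is None:
        n0 = (
            params.noise_slow_amp * rng.standard_normal()
            if params.noise_slow_amp > 0
            else 0.0
        )
        state = FieldState.resting(grid, params, n=n0)
    else:
        state = initial_state.copy()

    kernels = _field_kernels(params, grid)
    rows = [state.u.copy()[None, :]]
    times = [state.t]
    frame_ids = [-1]
    start_step = 0
    for f_idx, frame in enumerate(protocol.frames):
        n_steps = int(round(frame.duration / params.dt))
        if n_steps <= 0:
            raise InvalidParameterError(
                f"frame {f_idx} duration {frame.duration} ms below dt"
            )
        s = gaussian_input(grid, frame.inputs, params.input_width)
        out_u = _run_frame(
            state, s, n_steps, params, grid, kernels, rng, start_step, stride
        )
        rec_times = [
            (k + start_step + 1) * params.dt
            for k in range(n_steps)
            if (start_step + k + 1) % stride == 0
        ]
        if len(rec_times):
            rows.append(out_u)
            times.extend(rec_times)
            frame_ids.extend([f_idx] * len(rec_times))
        start_step += n_steps

    return ActivationRecord(
        times=np.asarray(times, dtype=np.float64),
        u_trace=np.concatenate(rows, axis=0),
        frame_index=np.asarray(frame_ids, dtype=np.int64),
        grid=grid,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# Stationary-state analysis (deterministic)
# ---------------------------------------------------------------------------


def _deterministic(params: FieldParams) -> FieldParams:
    """Noise off, trace and adaptation frozen (their gains zeroed)."""
    return replace(
        params,
        noise_slow_amp=0.0,
        noise_fast_amp=0.0,
        trace_gain=0.0,
        adapt_gain=0.0,
    )


def _relax(
    state: FieldState,
    s: np.ndarray,
    params: FieldParams,
    grid: FieldGrid,
    kernels,
    tol: float = 1e-9,
    max_steps: int = 60000,
    chunk: int = 500,
) -> FieldState:
    done = 0
    while done < max_steps:
        u_before = state.u.copy()
        _run_frame(state, s, chunk, params, grid, kernels, None, 0, 10**9)
        done += chunk
        if np.max(np.abs(state.u - u_before)) < tol * chunk:
            return state
    raise ConvergenceError(
        f"relaxation did not settle within {max_steps} steps"
    )


def find_stationary_states(
    input_amp: float,
    params: FieldParams,
    grid: FieldGrid | None = None,
    center: float = 0.0,
) -> list[FieldState]:
    """Stable states of the noise-free dynamics under a fixed localized input.

    Relaxes from (i) the resting state and (ii) a pre-formed suprathreshold
    peak, with the memory trace and adaptation frozen at zero.  Returns one
    state (monostable) or two (bistable: one subthreshold, one suprathreshold,
    distinguished by peak ``u`` relative to the zero threshold).
    """
    grid = grid or FieldGrid()
    p = _deterministic(params)
    kernels = _field_kernels(p, grid)
    s = gaussian_input(grid, [(center, input_amp)], p.input_width)

    low = _relax(FieldState.resting(grid, p), s, p, grid, kernels)

    seeded = FieldState.resting(grid, p)
    seeded.u = seeded.u + gaussian_input(
        grid, [(center, -p.h_u + 2.0)], p.input_width
    )
    high = _relax(seeded, s, p, grid, kernels)

    if abs(float(low.u.max()) - float(high.u.max())) < 1e-4:
        return [low]
    return [low, high]


def scan_bistability(
    amps: Sequence[float],
    params: FieldParams,
    grid: FieldGrid | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Classify each input amplitude as monostable-sub / bistable / monostable-supra.

    Scanning upward must traverse the ordering sub -> bistable -> supra; the
    detection instability is the lowest amplitude whose subthreshold state is
    lost, the reverse detection instability the lowest amplitude at which a
    suprathreshold peak can persist.
    """
    import pandas as pd

    rows = []
    for amp in amps:
        states = find_stationary_states(amp, params, grid)
        peaks = [float(st.u.max()) for st in states]
        if len(states) == 2:
            regime = "bistable"
        elif peaks[0] > 0:
            regime = "monostable_supra"
        else:
            regime = "monostable_sub"
        rows.append(
            {"amp": float(amp), "regime": regime, "peaks": tuple(peaks)}
        )
    return pd.DataFrame(rows)
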