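"""Coupled Lorenz benchmark simulator.

The benchmark system is a chain of ``n`` three-dimensional Lorenz subsystems
(state order ``x_1, y_1, z_1, ..., x_n, y_n, z_n``) in which subsystem ``n``
is driven by its predecessor through a coupling term ``gamma * z_{n-1}``:

    dx_n/dt = sigma * (y_n - x_n) + gamma * z_{n-1}
    dy_n/dt = x_n * (rho - z_n) - y_n          (variant "standard")
    dz_n/dt = -beta * z_n + x_n * y_n

With the classic parameters ``sigma=10, rho=28, beta=8/3`` each subsystem is
chaotic; ``gamma`` (default 0.1) sets how strongly information propagates
down the chain.  The first subsystem sees ``z_0 = 0`` ("zero" boundary) or
``z_0 = z_n`` ("ring").  Two further regimes mirror the study conditions:
additive Gaussian observation noise on the recorded samples, and a
time-varying regime where ``sigma`` drifts linearly with the sample index,
``sigma(t) = 10 + 0.2 * (t / 10)``.

Integration is fixed-step classical Runge-Kutta (RK4), recording every
``steps_per_sample`` steps, so a given config + seed reproduces bit-identical
output.  The "literal" dy/dt variant ``x_n * (rho - z_n) - x_n * y_n`` is
exposed for completeness (some presentations of the coupled system print it);
the standard form is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .series import MultivariateSeries

__all__ = [
    "LorenzConfig",
    "lorenz_derivative",
    "simulate_coupled_lorenz",
    "add_observation_noise",
    "split_series",
]

#: |value| above this aborts a simulation as divergent.
OVERFLOW_GUARD = 1e6


@dataclass
class LorenzConfig:
    """Configuration of the coupled-Lorenz benchmark generator.

    Defaults reproduce the 30-variable time-invariant, noise-free dataset:
    10 subsystems, classic parameters, ``gamma=0.1``, 5000 samples at
    ``dt=0.01`` with one recorded sample per integrator step.
    """

    n_subsystems: int = 10
    sigma0: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    gamma: float = 0.1
    time_varying: bool = False
    #: sigma(t) = sigma0 + sigma_drift_rate * t with t the elapsed
    #: integration time; 0.02 realizes sigma(t) = 10 + 0.2 * (t / 10).
    #: (Reading t as the sample index instead drives sigma past the Hopf
    #: threshold early on and the chain collapses to a fixed point, which
    #: contradicts the sustained oscillations this regime is meant to show.)
    sigma_drift_rate: float = 0.02
    noise_sigma: float = 0.0
    dt: float = 0.01
    steps_per_sample: int = 1
    n_samples: int = 5000
    y_equation_variant: str = "standard"  # or "literal"
    boundary: str = "zero"  # or "ring"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsystems < 1:
            raise ValueError("n_subsystems must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.steps_per_sample < 1:
            raise ValueError("steps_per_sample must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.y_equation_variant not in ("standard", "literal"):
            raise ValueError(f"unknown y_equation_variant {self.y_equation_variant!r}")
        if self.boundary not in ("zero", "ring"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    def channel_names(self) -> list[str]:
        names = []
        for i in range(1, self.n_subsystems + 1):
            names += [f"x{i}", f"y{i}", f"z{i}"]
        return names

    def initial_state(self) -> np.ndarray:
        """Printed initial conditions of the benchmark.

        ``x_n(0) = -0.1 + 0.003 n``, ``y_n(0) = -0.097 + 0.003 n``,
        ``z_n(0) = -0.094 + 0.003 n`` for subsystem index ``n = 1..n_subsystems``.
        """
        n = np.arange(1, self.n_subsystems + 1)
        state = np.empty(3 * self.n_subsystems)
        state[0::3] = -0.1 + 0.003 * n
        state[1::3] = -0.097 + 0.003 * n
        state[2::3] = -0.094 + 0.003 * n
        return state

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def lorenz_derivative(
    state: np.ndarray,
    sigma: float,
    rho: float,
    beta: float,
    gamma: float,
    variant: str = "standard",
    boundary: str = "zero",
) -> np.ndarray:
    """Time derivative of the coupled chain at ``state``.

    ``state`` is ordered ``(x_1, y_1, z_1, ..., x_n, y_n, z_n)``.  The
    coupling ``gamma * z_{n-1}`` enters dx_n/dt; ``z_0`` is 0 under the
    "zero" boundary or ``z_{n_subsystems}`` under "ring".
    """
    state = np.asarray(state, dtype=np.float64)
    if state.ndim != 1 or state.size % 3 != 0 or state.size == 0:
        raise ValueError(f"state length must be a positive multiple of 3, got {state.size}")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    x, y, z = state[0::3], state[1::3], state[2::3]
    z_prev = np.empty_like(z)
    z_prev[1:] = z[:-1]
    z_prev[0] = z[-1] if boundary == "ring" else 0.0
    dx = sigma * (y - x) + gamma * z_prev
    if variant == "standard":
        dy = x * (rho - z) - y
    elif variant == "literal":
        dy = x * (rho - z) - x * y
    else:
        raise ValueError(f"unknown variant {variant!r}")
    dz = -beta * z + x * y
    out = np.empty_like(state)
    out[0::3], out[1::3], out[2::3] = dx, dy, dz
    return out


def _rk4_step(state: np.ndarray, dt: float, sigma: float, cfg: LorenzConfig) -> np.ndarray:
    def f(s: np.ndarray) -> np.ndarray:
        return lorenz_derivative(
            s, sigma, cfg.rho, cfg.beta, cfg.gamma, cfg.y_equation_variant, cfg.boundary
        )

    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_coupled_lorenz(
    config: LorenzConfig, initial_state: np.ndarray | None = None
) -> MultivariateSeries:
    """Integrate the chain from the printed initial conditions.

    Returns a noise-free ``n_samples x (3 n_subsystems)`` series whose first
    row is the initial condition.  In the time-varying regime sigma drifts
    with elapsed integration time and is held constant across the integrator
    steps of each sampling interval.

    Raises
    ------
    FloatingPointError
        If any |value| exceeds the overflow guard, naming the first bad sample.
    """
    if initial_state is None:
        state = config.initial_state()
    else:
        state = np.asarray(initial_state, dtype=np.float64).copy()
        if state.size != 3 * config.n_subsystems:
            raise ValueError(
                f"initial_state needs {3 * config.n_subsystems} entries, got {state.size}"
            )
    out = np.empty((config.n_samples, state.size))
    out[0] = state
    dt_sample = config.dt * config.steps_per_sample
    for t in range(1, config.n_samples):
        sigma = config.sigma0
        if config.time_varying:
            # sigma held at its value at the start of the sampling interval
            sigma = config.sigma0 + config.sigma_drift_rate * ((t - 1) * dt_sample)
        try:
            for _ in range(config.steps_per_sample):
                state = _rk4_step(state, config.dt, sigma, config)
        except ValueError:
            # a sub-step already produced non-finite values
            raise FloatingPointError(f"trajectory diverged at sample {t}") from None
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > OVERFLOW_GUARD:
            raise FloatingPointError(f"trajectory diverged at sample {t}")
        out[t] = state
    return MultivariateSeries(
        values=out,
        channel_names=config.channel_names(),
        dt_sample=config.dt * config.steps_per_sample,
        provenance=f"simulate_coupled_lorenz {config.to_json()}",
    )


def add_observation_noise(
    series: MultivariateSeries, noise_sigma: float, seed: int
) -> MultivariateSeries:
    """Add i.i.d. ``N(0, noise_sigma^2)`` measurement noise to every entry."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return MultivariateSeries(
            series.values.copy(), list(series.channel_names), series.dt_sample, series.provenance
        )
    rng = np.random.default_rng(seed)
    noisy = series.values + rng.normal(0.0, noise_sigma, size=series.values.shape)
    return MultivariateSeries(
        values=noisy,
        channel_names=list(series.channel_names),
        dt_sample=series.dt_sample,
        provenance=series.provenance + f" + noise(sigma={noise_sigma}, seed={seed})",
    )


def split_series(
    series: MultivariateSeries, n_train: int, n_val: int, n_test: int
) -> tuple[MultivariateSeries, MultivariateSeries, MultivariateSeries]:
    """Chronological (non-shuffled) train/val/test partition.

    The default benchmark split of a 5000-point series is 3500/500/1000.
    Concatenating the three parts reproduces the first
    ``n_train + n_val + n_test`` rows of the input.
    """
    for name, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    total = n_train + n_val + n_test
    if total > series.n_samples:
        raise ValueError(
            f"split {n_train}+{n_val}+{n_test}={total} exceeds series length {series.n_samples}"
        )
    a = series.slice_time(0, n_train)
    b = series.slice_time(n_train, n_train + n_val)
    c = series.slice_time(n_train + n_val, total)
    return a, b, c
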