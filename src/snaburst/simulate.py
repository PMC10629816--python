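"""Synthetic single-nucleus MS2-MCP trajectories from a two-state promoter.

The generator stands in for a segmented/tracked live-imaging movie of an
early *Drosophila* embryo entering nuclear cycle 14: nuclei are placed along
the dorsoventral (DV) axis, each promoter switches stochastically between an
OFF and an ON state with rates ``k_on``/``k_off`` (the telegraph model), ON
periods load polymerases whose nascent transcripts contribute fluorescence
for a finite dwell time, and the recorded intensity carries additive
measurement noise.  Every trace retains its generating ground truth so that
downstream inference (feature extraction, burst-kinetics HMM) can be tested
by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GENOTYPES",
    "EmbryoConfig",
    "KineticField",
    "Trace",
    "default_field",
    "simulate_promoter_path",
    "render_ms2_signal",
    "generate_embryo",
]

#: Genotype labels: wildtype and the studied binding-site mutants.
GENOTYPES = ("WT", "Dl1", "Dl2", "Dl1/2", "Twi2")

#: Default multiplicative effect of a binding-site mutation on promoter
#: kinetics: mutants destabilise the ON state (higher k_off) and load Pol II
#: less effectively (lower loading rate).  Magnitudes are configuration, not
#: biological claims.
MUTANT_KOFF_FACTOR = 2.0
MUTANT_LOADING_FACTOR = 0.5


def _as_rate_fn(value: float | Callable[[float], float]) -> Callable[[float], float]:
    if callable(value):
        return value
    v = float(value)
    return lambda x: v


@dataclass(frozen=True)
class KineticField:
    """Promoter kinetics as a function of normalized DV position ``x``.

    Rates are per minute; ``loading_rate`` is in AU/min; ``dwell_time`` is the
    time (minutes) a nascent transcript contributes fluorescence;
    ``noise_sd`` is the additive Gaussian measurement noise (AU).
    """

    kon: float | Callable[[float], float] = 0.5
    koff: float | Callable[[float], float] = 0.25
    loading_rate: float | Callable[[float], float] = 200.0
    dwell_time: float = 2.5
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def at(self, x: float, genotype: str = "WT") -> tuple[float, float, float]:
        """Evaluate (kon, koff, loading_rate) at DV position ``x``.

        Mutant genotypes scale ``koff`` up and ``loading_rate`` down.
        """
        kon = _as_rate_fn(self.kon)(x)
        koff = _as_rate_fn(self.koff)(x)
        load = _as_rate_fn(self.loading_rate)(x)
        if min(kon, koff, load) < 0:
            raise ValueError("kinetic rates must be >= 0")
        if genotype != "WT":
            koff *= MUTANT_KOFF_FACTOR
            load *= MUTANT_LOADING_FACTOR
        return kon, koff, load


def default_field(sigma: float = 0.35) -> KineticField:
    """Wildtype kinetic field: spatially graded Pol II loading, uniform rates.

    The loading rate follows a Gaussian bump centred on the ventral midline
    (mirroring the nuclear Dorsal gradient that patterns *sna*), so mRNA
    output is maximal at ``x = 0`` and decays towards the lateral edges.
    """
    return KineticField(
        kon=0.5,
        koff=0.25,
        loading_rate=lambda x: 200.0 * float(np.exp(-(x**2) / (2 * sigma**2))),
    )


@dataclass(frozen=True)
class EmbryoConfig:
    """Configuration for one synthetic embryo (one genotype)."""

    n_nuclei: int = 200
    dv_positions: Sequence[float] | None = None
    frame_interval: float = 21.0  # seconds/frame
    duration: float = 50.0  # minutes (~NC14 interphase)
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.dv_positions is not None:
            pos = np.asarray(self.dv_positions, dtype=float)
            if pos.size != self.n_nuclei:
                raise ValueError("dv_positions length must equal n_nuclei")
            if pos.size and (pos.min() < -1 or pos.max() > 1):
                raise ValueError("dv_positions must lie in [-1, 1]")


@dataclass
class Trace:
    """One nucleus's fluorescence time series plus metadata.

    ``t`` is in seconds on a uniform grid; ``intensity`` in arbitrary units
    (AU, clipped at zero).  ``truth`` optionally records the simulated
    promoter path and generating parameters for recovery tests.
    """

    nucleus_id: str
    dv_position: float
    genotype: str
    t: np.ndarray
    intensity: np.ndarray
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("trace needs at least two time points")
        if self.t.size != self.intensity.size:
            raise ValueError("t and intensity must have equal length")
        dt = np.diff(self.t)
        if not np.all(dt > 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("t must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        """Frame interval in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


def simulate_promoter_path(
    kon: float,
    koff: float,
    duration: float,
    dt: float,
    rng: np.random.Generator | int | None = None,
    initial_state: int = 0,
) -> np.ndarray:
    """Simulate a two-state promoter path and sample it on the frame grid.

    The continuous-time chain is simulated exactly with exponential waiting
    times (Gillespie) and point-sampled at frame times ``0, dt, 2*dt, ...``
    up to ``duration``.  ``kon``/``koff`` are per minute, ``duration`` in
    minutes, ``dt`` in seconds.  The promoter starts OFF (state 0) by
    default, matching imaging that begins at NC14 entry.

    Returns an int8 array of 0/1 states, one per frame.
    """
    if kon < 0 or koff < 0:
        raise ValueError("rates must be >= 0")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    rng = np.random.default_rng(rng)
    dt_min = dt / 60.0
    n_frames = int(np.floor(duration / dt_min + 1e-9)) + 1

    switch_times = [0.0]
    states = [int(initial_state)]
    t, s = 0.0, int(initial_state)
    while t < duration:
        rate = kon if s == 0 else koff
        if rate <= 0:
            break  # absorbing state
        t += rng.exponential(1.0 / rate)
        s ^= 1
        switch_times.append(t)
        states.append(s)

    frame_t = np.arange(n_frames) * dt_min
    idx = np.searchsorted(switch_times, frame_t, side="right") - 1
    return np.asarray(states, dtype=np.int8)[idx]


def render_ms2_signal(
    path: np.ndarray,
    loading_rate: float,
    dwell_time: float,
    dt: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Forward model linking the promoter path to MS2 fluorescence.

    Each minute the promoter spends ON within the preceding ``dwell_time``
    window contributes ``loading_rate`` AU: the noiseless signal is

        I(t) = loading_rate * (ON time in [t - dwell_time, t]),

    i.e. the box-kernel convolution of the path.  During a sustained ON
    period the signal therefore rises linearly with slope ``loading_rate``
    (AU/min) and plateaus at ``loading_rate * dwell_time``.  Additive
    Gaussian noise is applied and the result clipped at zero.

    ``path`` holds the frame-sampled promoter state (piecewise constant over
    each frame interval); ``dwell_time`` in minutes, ``dt`` in seconds.
    """
    path = np.asarray(path)
    if not np.isin(path, (0, 1)).all():
        raise ValueError("path must be binary")
    if dwell_time <= 0:
        raise ValueError("dwell_time must be > 0")
    if loading_rate < 0 or noise_sd < 0:
        raise ValueError("loading_rate and noise_sd must be >= 0")
    rng = np.random.default_rng(rng)
    dt_min = dt / 60.0
    n = path.size
    frame_t = np.arange(n) * dt_min
    # Integral of the piecewise-constant path up to each frame time.
    cum = np.concatenate([[0.0], np.cumsum(path[:-1]) * dt_min])

    def integral(times: np.ndarray) -> np.ndarray:
        times = np.clip(times, 0.0, frame_t[-1])
        i = np.clip(np.searchsorted(frame_t, times, side="right") - 1, 0, n - 1)
        return cum[i] + (times - frame_t[i]) * path[np.minimum(i, n - 1)]

    signal = loading_rate * (integral(frame_t) - integral(frame_t - dwell_time))
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n)
    return np.clip(signal, 0.0, None)


def generate_embryo(config: EmbryoConfig, kinetics: KineticField | None = None) -> list[Trace]:
    """Generate one synthetic embryo: one :class:`Trace` per nucleus.

    Kinetics are evaluated at each nucleus's DV position; mutant genotypes
    modify the field (see :meth:`KineticField.at`).  Identical seeds give
    bit-identical traces.
    """
    if kinetics is None:
        kinetics = default_field()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(max(config.n_nuclei, 1))
    if config.dv_positions is not None:
        positions = np.asarray(config.dv_positions, dtype=float)
    else:
        positions = np.random.default_rng(root.spawn(1)[0]).uniform(-1.0, 1.0, config.n_nuclei)

    traces: list[Trace] = []
    for i in range(config.n_nuclei):
        rng = np.random.default_rng(children[i])
        x = float(positions[i])
        kon, koff, load = kinetics.at(x, config.genotype)
        path = simulate_promoter_path(kon, koff, config.duration, config.frame_interval, rng)
        intensity = render_ms2_signal(
            path, load, kinetics.dwell_time, config.frame_interval, kinetics.noise_sd, rng
        )
        t = np.arange(path.size) * config.frame_interval
        traces.append(
            Trace(
                nucleus_id=f"{config.genotype}:{i:04d}",
                dv_position=x,
                genotype=config.genotype,
                t=t,
                intensity=intensity,
                truth={
                    "path": path.tolist(),
                    "kon": kon,
                    "koff": koff,
                    "loading_rate": load,
                    "dwell_time": kinetics.dwell_time,
                    "noise_sd": kinetics.noise_sd,
                },
            )
        )
    return traces
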