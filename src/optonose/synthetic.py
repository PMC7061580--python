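"""Synthetic optical e-nose traces.

Forward model for a single-channel photodiode recording of a liquid-crystal
gel film cycling through VOC exposure and clean-air recovery.  The generator
reproduces the acquisition structure of the instrument (fixed exposure /
recovery schedule, fixed sampling rate, duplicate assays) and the qualitative
film physics: thicker films transmit more light and therefore sit on a lower
baseline, VOC exposure produces a positive deflection that rises along a
saturating logistic-type curve and relaxes exponentially during recovery, and
protic VOCs slowly shift the baseline from cycle to cycle (matrix drift).

All numeric parameter values of the default VOC library and film set are
inventions of this simulator, chosen only to respect the published trends;
they are not measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AssaySchedule",
    "VOCKinetics",
    "FilmModel",
    "SignalTrace",
    "VOC_NAMES",
    "default_voc_library",
    "default_film_set",
    "simulate_cycle_values",
    "simulate_assay",
    "simulate_experiment",
    "write_trace",
    "read_trace",
]

#: The 11 solvent labels used as class names, in canonical (reporting) order.
VOC_NAMES: tuple[str, ...] = (
    "heptane",
    "hexane",
    "chloroform",
    "toluene",
    "dichloromethane",
    "diethyl ether",
    "ethyl acetate",
    "acetonitrile",
    "acetone",
    "ethanol",
    "methanol",
)

#: Guaranteed minimum gap between consecutive default amplitudes after the
#: seed jitter is applied (base gap 2.0, jitter at most +-0.2 per profile).
MIN_AMPLITUDE_MARGIN = 1.6


@dataclass(frozen=True)
class AssaySchedule:
    """Timing of one continuous assay: identical exposure/recovery cycles."""

    n_cycles: int = 45
    exposure_s: float = 5.0
    recovery_s: float = 15.0
    sampling_hz: float = 90.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.exposure_s <= 0 or self.recovery_s <= 0:
            raise ValueError("exposure_s and recovery_s must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")

    @property
    def cycle_duration_s(self) -> float:
        return self.exposure_s + self.recovery_s

    @property
    def cycle_samples(self) -> int:
        """Samples per cycle; identical for every cycle by construction."""
        return int(round(self.cycle_duration_s * self.sampling_hz))

    @property
    def total_samples(self) -> int:
        return self.n_cycles * self.cycle_samples

    @property
    def total_duration_s(self) -> float:
        return self.n_cycles * self.cycle_duration_s

    def cycle_times(self) -> np.ndarray:
        """Time axis of one cycle, starting at 0."""
        return np.arange(self.cycle_samples) / self.sampling_hz


@dataclass(frozen=True)
class VOCKinetics:
    """Response parameters of one VOC class.

    ``matrix_shift`` is a per-cycle additive baseline offset modelling the
    slow gel-matrix reorganization seen under protic VOCs.
    """

    name: str
    amplitude: float
    rise_rate: float
    decay_rate: float
    matrix_shift: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rise_rate <= 0 or self.decay_rate <= 0:
            raise ValueError("rise_rate and decay_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FilmModel:
    """One sensing film: nominal and measured thickness plus optics."""

    predefined_um: float
    measured_um: float
    baseline_level: float
    active_area_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_area_fraction <= 1.0:
            raise ValueError("active_area_fraction must lie in [0, 1]")


@dataclass
class SignalTrace:
    """A uniformly sampled intensity series with acquisition metadata."""

    values: np.ndarray
    sampling_hz: float
    voc: str
    thickness_um: float
    replicate_id: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_hz


# --------------------------------------------------------------------------
# default libraries

# Base (pre-jitter) kinetic parameters, one row per VOC in VOC_NAMES order.
# Amplitudes are spaced by 2.0 units so classes stay separable after jitter;
# rise/decay rates and matrix shifts add further pairwise distinction.
_BASE_PARAMS = {
    #                      amplitude  rise  decay  matrix_shift
    "heptane":         (4.0, 0.9, 0.40, 0.0),
    "hexane":          (6.0, 1.2, 0.55, 0.0),
    "chloroform":      (8.0, 1.5, 0.70, 0.0),
    "toluene":         (10.0, 1.8, 0.85, 0.0),
    "dichloromethane": (12.0, 2.1, 1.00, 0.0),
    "diethyl ether":   (14.0, 2.4, 1.15, 0.02),
    "ethyl acetate":   (16.0, 2.7, 1.30, 0.0),
    "acetonitrile":    (18.0, 3.0, 1.45, 0.03),
    "acetone":         (20.0, 3.3, 1.60, 0.0),
    "ethanol":         (22.0, 3.6, 1.75, 0.05),
    "methanol":        (24.0, 3.9, 1.90, 0.08),
}

DEFAULT_NOISE_SD = 0.3


def default_voc_library(seed: int, noise_sd: float = DEFAULT_NOISE_SD) -> list[VOCKinetics]:
    """Build the 11-class VOC kinetics library.

    Parameters are the base table above plus a small deterministic jitter
    drawn from ``seed`` (amplitude +-0.2, rates +-0.05), so different seeds
    give different numeric parameters while names and separability margins
    (see :data:`MIN_AMPLITUDE_MARGIN`) are preserved.
    """
    rng = np.random.default_rng(seed)
    library = []
    for name in VOC_NAMES:
        amp, rise, decay, shift = _BASE_PARAMS[name]
        library.append(
            VOCKinetics(
                name=name,
                amplitude=amp + rng.uniform(-0.2, 0.2),
                rise_rate=rise + rng.uniform(-0.05, 0.05),
                decay_rate=decay + rng.uniform(-0.05, 0.05),
                matrix_shift=shift,
                noise_sd=noise_sd,
            )
        )
    return library


def default_film_set() -> list[FilmModel]:
    """The four-film set: baseline falls and active area grows with thickness."""
    rows = [
        # predefined, measured, baseline, active fraction
        (15.0, 18.5, 160.0, 0.35),
        (30.0, 36.0, 140.0, 0.55),
        (60.0, 44.0, 115.0, 0.72),
        (90.0, 62.0, 95.0, 0.88),
    ]
    return [FilmModel(*row) for row in rows]


# --------------------------------------------------------------------------
# forward model


def _cycle_response(voc: VOCKinetics, schedule: AssaySchedule) -> np.ndarray:
    """Noiseless, baseline-free response of one cycle (always >= 0).

    Exposure phase: logistic rise toward ``amplitude``, re-anchored so the
    response starts at exactly zero; midpoint fixed at 2/rise_rate so the
    long-exposure limit plateaus at ``amplitude``.  Recovery phase:
    first-order exponential decay from the end-of-exposure value.
    """
    t = schedule.cycle_times()
    k = voc.rise_rate
    t_mid = 2.0 / k
    logistic = 1.0 / (1.0 + np.exp(-k * (t - t_mid)))
    l0 = 1.0 / (1.0 + np.exp(k * t_mid))
    rise = voc.amplitude * (logistic - l0) / (1.0 - l0)

    exposure = t < schedule.exposure_s
    response = np.where(exposure, rise, 0.0)
    if not exposure.all():
        # decay from the response value reached at the end of exposure
        k_end = 1.0 / (1.0 + np.exp(-k * (schedule.exposure_s - t_mid)))
        r_end = voc.amplitude * (k_end - l0) / (1.0 - l0)
        rec_t = t[~exposure] - schedule.exposure_s
        response[~exposure] = r_end * np.exp(-voc.decay_rate * rec_t)
    return response


def simulate_cycle_values(
    voc: VOCKinetics,
    film: FilmModel,
    schedule: AssaySchedule,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One cycle of samples: baseline + response + (optional) Gaussian noise."""
    values = film.baseline_level + _cycle_response(voc, schedule)
    if rng is not None and voc.noise_sd > 0:
        values = values + rng.normal(0.0, voc.noise_sd, size=values.size)
    return values


def simulate_assay(
    voc: VOCKinetics,
    film: FilmModel,
    schedule: AssaySchedule,
    replicate_id: int = 1,
    seed: int = 0,
) -> SignalTrace:
    """Simulate one continuous assay of ``schedule.n_cycles`` cycles.

    Cycle ``k`` (1-based) sits on baseline ``baseline_level +
    (k - 1) * matrix_shift``: the matrix drift accumulates linearly.
    """
    rng = np.random.default_rng(seed)
    response = _cycle_response(voc, schedule)
    n = schedule.cycle_samples
    values = np.empty(schedule.total_samples)
    for k in range(schedule.n_cycles):
        values[k * n : (k + 1) * n] = film.baseline_level + k * voc.matrix_shift + response
    if voc.noise_sd > 0:
        values += rng.normal(0.0, voc.noise_sd, size=values.size)
    return SignalTrace(
        values=values,
        sampling_hz=schedule.sampling_hz,
        voc=voc.name,
        thickness_um=film.predefined_um,
        replicate_id=replicate_id,
        seed=seed,
    )


def trace_seed(master_seed: int, voc_index: int, film_index: int, replicate_id: int) -> int:
    """Deterministic per-trace seed so any trace is reproducible in isolation."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(voc_index, film_index, replicate_id))
    return int(ss.generate_state(1)[0])


def simulate_experiment(
    vocs: Sequence[VOCKinetics],
    films: Sequence[FilmModel],
    schedule: AssaySchedule,
    n_replicates: int = 2,
    seed: int = 0,
) -> list[SignalTrace]:
    """One trace per (voc x film x replicate), seeded from the master seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    traces = []
    for fi, film in enumerate(films):
        for vi, voc in enumerate(vocs):
            for rep in range(1, n_replicates + 1):
                traces.append(
                    simulate_assay(
                        voc,
                        film,
                        schedule,
                        replicate_id=rep,
                        seed=trace_seed(seed, vi, fi, rep),
                    )
                )
    return traces


# --------------------------------------------------------------------------
# serialization: CSV (time_s,intensity) + JSON sidecar


def write_trace(trace: SignalTrace, csv_path: str | Path) -> Path:
    """Write a trace as ``time_s,intensity`` CSV plus a ``.json`` sidecar."""
    csv_path = Path(csv_path)
    t = trace.times()
    with open(csv_path, "w") as fh:
        fh.write("time_s,intensity\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{ti:.9g},{vi:.12g}\n")
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "voc": trace.voc,
        "thickness_um": trace.thickness_um,
        "replicate_id": trace.replicate_id,
        "seed": trace.seed,
        "sampling_hz": trace.sampling_hz,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trace(csv_path: str | Path) -> SignalTrace:
    """Read a trace written by :func:`write_trace`."""
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return SignalTrace(
        values=data[:, 1],
        sampling_hz=float(meta["sampling_hz"]),
        voc=str(meta["voc"]),
        thickness_um=float(meta["thickness_um"]),
        replicate_id=int(meta["replicate_id"]),
        seed=int(meta["seed"]),
    )
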