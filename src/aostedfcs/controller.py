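"""Sensorless modal adaptive-optics loop for z-STED-FCS.

For each correction mode a symmetric set of bias amplitudes is applied on
top of the current correction, a photon trace is acquired per bias, and
the molecule-number metric N (smallest N ⇔ smallest observation volume)
is computed from count moments on re-binned sub-traces.  A quadratic fit
of metric versus bias locates the optimum, which is accumulated into the
correction state; a "round" walks a list of modes once.  Presets encode
the published measurement schedules for dye solutions and for the
cytoplasm of living cells.

The loop talks to any acquisition callable
``acquire(state, duration) -> PhotonTrace`` — the built-in simulated
microscope or a wrapper around recorded traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .moments import MetricConfig, MetricValue, metric_from_trace
from .optics import (AberrationState, TIP_SHIFT_NM_PER_RAD,
                     TILT_SHIFT_NM_PER_RAD, DEFOCUS_SHIFT_NM_PER_RAD)

__all__ = [
    "BiasScan",
    "ScheduleEntry",
    "ModeSchedule",
    "make_bias_list",
    "run_bias_scan",
    "quadratic_optimum",
    "correction_round",
    "run_schedule",
    "solution_schedule",
    "cell_schedule",
    "shift_to_modes",
    "modes_to_shift",
]


@dataclass
class BiasScan:
    mode_id: str
    biases: np.ndarray
    metric: list                    # MetricValue per bias
    fit: tuple = ()                 # quadratic coefficients (a, b, c)
    optimum: float = 0.0
    flags: list = field(default_factory=list)


@dataclass
class ScheduleEntry:
    modes: tuple
    n_points: int = 7
    max_bias: float = 0.8           # rad rms
    acquisition_time: float = 3.0   # s

    def __post_init__(self):
        if self.n_points < 5 or self.n_points % 2 == 0:
            raise ValueError("n_points must be odd and >= 5")
        if self.max_bias <= 0:
            raise ValueError("max_bias must be positive")


@dataclass
class ModeSchedule:
    rounds: list                    # of ScheduleEntry
    preset_name: str = "custom"


def make_bias_list(max_bias: float, n: int = 7) -> np.ndarray:
    """Uniform symmetric bias grid including 0."""
    if n < 5 or n % 2 == 0:
        raise ValueError("n must be odd and >= 5")
    if max_bias <= 0:
        raise ValueError("max_bias must be positive")
    return np.linspace(-max_bias, max_bias, n)


def run_bias_scan(mode_id, entry: ScheduleEntry, state: AberrationState,
                  acquire, metric_cfg: MetricConfig = MetricConfig()) -> BiasScan:
    """Measure the metric across biases of one mode; the state is not mutated."""
    biases = make_bias_list(entry.max_bias, entry.n_points)
    values = []
    for b in biases:
        trace = acquire(state.add(mode_id, float(b)),
                        duration=entry.acquisition_time)
        values.append(metric_from_trace(trace, metric_cfg.bin_factor,
                                        metric_cfg.n_splits, metric_cfg.kind))
    scan = BiasScan(str(mode_id), biases, values)
    quadratic_optimum(scan)
    return scan


def quadratic_optimum(scan: BiasScan):
    """Least-squares parabola through the valid scan points.

    The vertex is the estimated optimum; it is clamped to the scanned
    range (flagged), and concave-down fits apply zero correction with a
    ``wrong_curvature`` flag — extrapolating an inverted parabola is how
    sensorless loops run away to spurious optima.
    """
    valid = np.array([m.valid and np.isfinite(m.value) for m in scan.metric])
    if valid.sum() < 4:
        scan.flags.append("insufficient_valid_points")
        scan.optimum = 0.0
        return scan.optimum, scan.flags
    x = scan.biases[valid]
    y = np.array([m.value for m in scan.metric])[valid]
    a, b, c = np.polyfit(x, y, 2)
    scan.fit = (float(a), float(b), float(c))
    if a <= 0:
        scan.flags.append("wrong_curvature")
        scan.optimum = 0.0
        return scan.optimum, scan.flags
    vertex = -b / (2.0 * a)
    lo, hi = float(scan.biases.min()), float(scan.biases.max())
    if vertex < lo or vertex > hi:
        scan.flags.append("clamped")
        vertex = min(max(vertex, lo), hi)
    scan.optimum = float(vertex)
    return scan.optimum, scan.flags


def correction_round(modes, state: AberrationState, acquire,
                     entry: ScheduleEntry,
                     metric_cfg: MetricConfig = MetricConfig(),
                     log: list | None = None) -> AberrationState:
    """Scan each mode in order and accumulate the optima into the state.

    Flagged scans (wrong curvature, too few valid points) leave the mode
    untouched.
    """
    for mode_id in modes:
        scan = run_bias_scan(mode_id, entry, state, acquire, metric_cfg)
        if log is not None:
            log.append(scan)
        if not ({"wrong_curvature", "insufficient_valid_points", "clamped"}
                & set(scan.flags)):
            state = state.add(mode_id, scan.optimum)
    return state


LOW_ORDER_MODES = ("tip", "tilt", "noll:5", "noll:6", "noll:7", "noll:8")
SPHERICAL_MODES = ("hnd_defocus", "noll:11", "noll:22")
CELL_MODES = ("tip", "tilt", "hnd_defocus", "noll:7", "noll:8", "noll:11")


def solution_schedule(acquisition_time: float = 3.0, n_points: int = 7
                      ) -> ModeSchedule:
    """Dye-in-solution preset: one round of tip/tilt/astigmatism/coma, three
    rounds of defocus + primary/secondary spherical at 0.8 rad, then two
    more spherical rounds at 0.6 rad."""
    rounds = [ScheduleEntry(LOW_ORDER_MODES, n_points, 0.8, acquisition_time)]
    rounds += [ScheduleEntry(SPHERICAL_MODES, n_points, 0.8, acquisition_time)
               for _ in range(3)]
    rounds += [ScheduleEntry(SPHERICAL_MODES, n_points, 0.6, acquisition_time)
               for _ in range(2)]
    return ModeSchedule(rounds, "solution")


def cell_schedule(acquisition_time: float = 4.0, n_points: int = 7
                  ) -> ModeSchedule:
    """Live-cell preset: astigmatism and secondary spherical are left out
    (negligible amplitude / poor cost-benefit in cells).  Two passes over
    the remaining modes: the metric curve is strongly asymmetric around a
    large aberration, so a single quadratic scan under-corrects; the
    second pass, running near the optimum, refines it."""
    rounds = [ScheduleEntry(CELL_MODES, n_points, 0.8, acquisition_time),
              ScheduleEntry(CELL_MODES, n_points, 0.8, acquisition_time)]
    return ModeSchedule(rounds, "cell")


def run_schedule(schedule: ModeSchedule | str, acquire,
                 metric_cfg: MetricConfig = MetricConfig(),
                 state: AberrationState | None = None,
                 acquisition_time: float | None = None):
    """Execute a correction schedule; returns (final state, scan log)."""
    if isinstance(schedule, str):
        if schedule == "solution":
            schedule = solution_schedule()
        elif schedule == "cell":
            schedule = cell_schedule()
        else:
            raise ValueError(f"unknown preset {schedule!r}")
    state = state or AberrationState()
    log: list = []
    for entry in schedule.rounds:
        if acquisition_time is not None:
            entry = ScheduleEntry(entry.modes, entry.n_points, entry.max_bias,
                                  acquisition_time)
        state = correction_round(entry.modes, state, acquire, entry,
                                 metric_cfg, log)
    return state, log


# ---------------------------------------------------------------------------
# beam repositioning <-> mode amplitudes
# ---------------------------------------------------------------------------

def shift_to_modes(dx: float, dy: float, dz: float) -> AberrationState:
    """Spatial repositioning (nm) expressed as tip/tilt/defocus amplitudes."""
    return AberrationState({
        "tip": dx / TIP_SHIFT_NM_PER_RAD,
        "tilt": dy / TILT_SHIFT_NM_PER_RAD,
        "hnd_defocus": dz / DEFOCUS_SHIFT_NM_PER_RAD,
    })


def modes_to_shift(state: AberrationState):
    """Inverse of :func:`shift_to_modes`: (dx, dy, dz) in nm."""
    return (state.amplitude("tip") * TIP_SHIFT_NM_PER_RAD,
            state.amplitude("tilt") * TILT_SHIFT_NM_PER_RAD,
            state.amplitude("hnd_defocus") * DEFOCUS_SHIFT_NM_PER_RAD)
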