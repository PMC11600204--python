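"""Digital twin of the two-probe micromanipulation bench.

Couples a constitutive sample model (:mod:`fibermech.samples`) to the
sensing-probe spring (:mod:`fibermech.probe`) and a pixel-quantized 5 Hz
camera, and integrates the loading protocols used on the real instrument:
oscillatory stretching, a slow optimal-length ramp, and electrically
stimulated contraction at fixed length.

The coupling is quasi-static (micro-scale masses, loading at or below
1 Hz): at every instant the probe force ``k x`` balances the sample force
at strain ``eps = (L_m - x) / L_0``.  The Maxwell arm of the Zener solid
carries internal state integrated on a fine grid, then the deflection is
decimated to the camera rate, dithered with Gaussian read noise and
floor-quantized to whole pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .probe import ProbeSpec, probe_preset, stiffness
from .samples import (
    PlantParams,
    active_force,
    condition_to_params,
    cross_section_area,
    passive_stress,
    pulse_train,
)

__all__ = [
    "Recording",
    "PlantSimulator",
    "apply_camera",
    "FixationError",
    "FIXATION_LIMIT",
    "CAMERA_RATE",
    "run_oscillation",
    "run_length_sweep",
    "run_stimulation",
    "generate_population",
]

#: Liquid-bridge adhesion force holding the fiber on the probes, N.
FIXATION_LIMIT = 120e-6

#: Camera frame rate, Hz; the readout (and the force controller) run at
#: this rate.
CAMERA_RATE = 5.0

#: Default camera read noise on the tip deflection, px (std, pre-quantization).
DEFAULT_NOISE_PX = 0.3

#: Default oscillation protocol: settle + measured cycles.
DEFAULT_CYCLES = 5
SETTLE_CYCLES = 1


class FixationError(RuntimeError):
    """Raised when the instantaneous probe force exceeds the liquid-bridge
    adhesion limit and the sample detaches."""


@dataclass
class Recording:
    """Time-sampled trace of one loading protocol on one sample.

    ``force`` is always ``stiffness * tip_deflection`` with the quantized
    deflection; ``tip_deflection_true`` keeps the pre-noise, pre-quantization
    deflection for diagnostics.
    """

    sample_id: str
    time: np.ndarray  # s, uniform grid
    probe_displacement: np.ndarray  # L_m, m
    tip_deflection: np.ndarray  # x, m (pixel-quantized)
    force: np.ndarray  # F_s, N
    stimulus: np.ndarray  # bool flags
    medium: str
    protocol: str  # oscillation | ramp | stimulation
    metadata: dict = field(default_factory=dict)
    command_force: np.ndarray | None = None  # F_cmd, N (controlled runs)
    tip_deflection_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("probe_displacement", "tip_deflection", "force", "stimulus"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n > 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be uniform")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def strain(self) -> np.ndarray:
        l0 = float(self.metadata["rest_length"])
        return (self.probe_displacement - self.tip_deflection) / l0


# -- core integrator --------------------------------------------------------


class PlantSimulator:
    """Stateful quasi-static integrator of the probe/sample force balance.

    At each sub-step the tip deflection ``x`` solves

        k x = A_0 [sigma_p(eps) + sigma_arm + gamma deps/dt]
              + F_active(eps, activation),    eps = (L_m - x) / L_0,

    with the Maxwell-arm stress advanced by its exact constant-rate
    exponential update.  ``advance`` moves the probe to a new position over
    one camera interval (linearly interpolated sub-steps) and returns the
    true deflection at the frame instant — this is the interface the force
    controller closes its loop around.
    """

    def __init__(
        self,
        params: PlantParams,
        probe: ProbeSpec,
        medium: str = "solution",
        enforce_fixation: bool = True,
    ) -> None:
        self.params = params
        self.probe = probe
        self.medium = medium
        self.enforce_fixation = enforce_fixation
        self.k = stiffness(probe)
        self.a0 = cross_section_area(params)
        self.l0 = params.rest_length
        self.gamma = params.drag_coefficient if medium == "solution" else 0.0
        self.sigma_arm = 0.0
        self.eps_prev = 0.0
        self.eps_prev2: float | None = None
        self.x = 0.0
        self.lm = 0.0
        self.t = 0.0

    def _arm_update(self, deps_dt: float, dt: float) -> float:
        p = self.params
        tau = p.relaxation_time
        if tau <= 0.0:
            # no elastic arm: a bare dashpot, or nothing at all
            return p.arm_viscosity * deps_dt if p.arm_modulus == 0.0 else 0.0
        decay = math.exp(-dt / tau)
        return self.sigma_arm * decay + p.arm_viscosity * deps_dt * (1.0 - decay)

    def _step(self, lm: float, dt: float, activation: float) -> float:
        p, l0 = self.params, self.l0

        def residual(xi: float) -> float:
            eps = (lm - xi) / l0
            deps = (eps - self.eps_prev) / dt
            # drag acts on the instantaneous end-of-step rate; the BDF2
            # estimate removes the half-step phase lag of the backward
            # difference (the arm update is exact for the piecewise-linear
            # strain path and keeps the average rate)
            if self.eps_prev2 is None:
                deps_end = deps
            else:
                deps_end = (3.0 * eps - 4.0 * self.eps_prev
                            + self.eps_prev2) / (2.0 * dt)
            sig = (
                passive_stress(p, eps)
                + self._arm_update(deps, dt)
                + self.gamma * deps_end
            )
            return self.k * xi - self.a0 * sig - active_force(p, eps, activation)

        lo = self.x - 0.2 * l0
        hi = min(self.x + 0.2 * l0, lm + 0.9 * l0)
        flo, fhi = residual(lo), residual(hi)
        tries = 0
        while flo > 0.0 and tries < 60:  # expand bracket (rare)
            lo -= 0.2 * l0
            flo = residual(lo)
            tries += 1
        while fhi < 0.0 and tries < 60:
            hi = min(hi + 0.2 * l0, lm + 0.99 * l0)
            fhi = residual(hi)
            tries += 1
        if flo > 0.0 or fhi < 0.0:
            raise RuntimeError("force-balance bracket failed")
        xi = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16)
        eps = (lm - xi) / l0
        deps = (eps - self.eps_prev) / dt
        self.sigma_arm = self._arm_update(deps, dt)
        self.eps_prev2 = self.eps_prev
        self.eps_prev = eps
        self.x = xi
        self.lm = lm
        self.t += dt
        if self.enforce_fixation and self.k * abs(xi) > FIXATION_LIMIT * (1.0 + 1e-9):
            raise FixationError(
                f"probe force {self.k * xi * 1e6:.1f} uN exceeds the "
                f"{FIXATION_LIMIT * 1e6:.0f} uN liquid-bridge adhesion at "
                f"t = {self.t:.2f} s"
            )
        return xi

    def advance(
        self,
        lm_target: float,
        dt: float,
        n_sub: int = 1,
        activation: float = 0.0,
    ) -> float:
        """Move the probe linearly to ``lm_target`` over ``dt`` seconds in
        ``n_sub`` sub-steps; return the true tip deflection at the end."""
        lm0 = self.lm
        sub_dt = dt / n_sub
        xi = self.x
        for j in range(1, n_sub + 1):
            xi = self._step(lm0 + (lm_target - lm0) * j / n_sub, sub_dt, activation)
        return xi


def apply_camera(
    x_true: np.ndarray,
    pixel_size: float,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Camera readout: Gaussian read noise then floor pixel quantization."""
    x = np.asarray(x_true, dtype=float)
    if noise_px > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + rng.normal(0.0, noise_px * pixel_size, x.shape)
    if quantize:
        x = np.sign(x) * np.floor(np.abs(x) / pixel_size) * pixel_size
    return x


def _simulate(
    params: PlantParams,
    probe: ProbeSpec,
    lm_fn: Callable[[np.ndarray], np.ndarray],
    duration: float,
    *,
    medium: str = "solution",
    activation_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    sample_rate: float = CAMERA_RATE,
    oversample: int = 1,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    seed: int | None = None,
    enforce_fixation: bool = True,
) -> tuple[np.ndarray, ...]:
    """Integrate a pre-planned probe trajectory; return camera-rate arrays
    ``(t, L_m, x_true, x_quantized, activation)``."""
    dt = 1.0 / (sample_rate * oversample)
    n_int = int(round(duration * sample_rate)) * oversample + 1
    t_int = np.arange(n_int) * dt
    lm = np.asarray(lm_fn(t_int), dtype=float)
    act = (
        np.zeros(n_int)
        if activation_fn is None
        else np.asarray(activation_fn(t_int), dtype=float)
    )

    sim = PlantSimulator(params, probe, medium, enforce_fixation)
    sim.lm = lm[0]
    sim.eps_prev = lm[0] / sim.l0
    x = np.zeros(n_int)
    for i in range(1, n_int):
        x[i] = sim._step(lm[i], dt, act[i])
    if lm[0] != 0.0:
        # start from static balance rather than an artificial transient
        x[0] = x[1]

    sl = slice(None, None, oversample)
    t_cam, lm_cam, x_cam, act_cam = t_int[sl], lm[sl], x[sl], act[sl]
    rng = np.random.default_rng(seed)
    x_q = apply_camera(x_cam, probe.pixel_size, noise_px, quantize, rng)
    return t_cam, lm_cam, x_cam, x_q, act_cam


def _oversample_for(frequency: float, sample_rate: float = CAMERA_RATE) -> int:
    """Internal sub-steps per camera frame: >= 200 integration steps per
    loading cycle (the 5 Hz camera is deliberately coarse at 1 Hz)."""
    return max(1, math.ceil(200.0 * frequency / sample_rate))


def _pack(sample_id, t, lm, x_true, x_q, stim, medium, protocol, probe,
          params, extra_meta=None, command=None) -> Recording:
    k = stiffness(probe)
    meta = {
        "stiffness": k,
        "pixel_size": probe.pixel_size,
        "diameter": params.diameter,
        "rest_length": params.rest_length,
    }
    if extra_meta:
        meta.update(extra_meta)
    return Recording(
        sample_id=sample_id,
        time=t,
        probe_displacement=lm,
        tip_deflection=x_q,
        force=k * x_q,
        stimulus=np.asarray(stim, dtype=bool),
        medium=medium,
        protocol=protocol,
        metadata=meta,
        command_force=command,
        tip_deflection_true=x_true,
    )


# -- protocols --------------------------------------------------------------


def run_oscillation(
    params: PlantParams,
    probe: ProbeSpec,
    amplitude_strain: float = 0.10,
    frequency: float = 0.1,
    n_cycles: int = DEFAULT_CYCLES,
    *,
    controlled: bool = False,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    settle_cycles: int = SETTLE_CYCLES,
    sample_id: str = "sample",
) -> Recording:
    """Oscillatory stretching protocol.

    Uncontrolled: the moving probe follows
    ``L_m(t) = L_0 * amplitude_strain * (1 - cos(2 pi f t)) / 2`` — the
    peak nominal strain equals ``amplitude_strain`` (default 10 %) and the
    fiber is never compressed.  One settling cycle precedes the
    ``n_cycles`` measured cycles and is kept in the trace (analysis drops
    it).  With ``controlled=True`` the moving-probe trajectory is shaped by
    the model-predictive force controller to track an equivalent sinusoidal
    force command (see :mod:`fibermech.control`).
    """
    if n_cycles < 3:
        raise ValueError("need at least 3 oscillation cycles")
    if controlled:
        from . import control  # local import: control builds on this module

        return control.run_closed_loop_oscillation(
            params,
            probe,
            amplitude_strain=amplitude_strain,
            frequency=frequency,
            n_cycles=n_cycles,
            medium=medium,
            seed=seed,
            noise_px=noise_px,
            quantize=quantize,
            settle_cycles=settle_cycles,
            sample_id=sample_id,
        )
    l0 = params.rest_length
    omega = 2.0 * math.pi * frequency
    duration = (n_cycles + settle_cycles) / frequency

    def lm_fn(t: np.ndarray) -> np.ndarray:
        return l0 * amplitude_strain * 0.5 * (1.0 - np.cos(omega * t))

    t, lm, x_true, x_q, _ = _simulate(
        params,
        probe,
        lm_fn,
        duration,
        medium=medium,
        oversample=_oversample_for(frequency),
        noise_px=noise_px,
        quantize=quantize,
        seed=seed,
    )
    return _pack(
        sample_id, t, lm, x_true, x_q, np.zeros_like(t, dtype=bool), medium,
        "oscillation", probe, params,
        extra_meta={
            "frequency": frequency,
            "amplitude_strain": amplitude_strain,
            "settle_cycles": settle_cycles,
            "seed": seed,
        },
    )


def run_length_sweep(
    params: PlantParams,
    probe: ProbeSpec,
    max_strain: float = 0.15,
    *,
    stimulate: bool = False,
    strain_rate: float = 0.005,
    stimulus_frequency: float = 5.0,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    sample_id: str = "sample",
) -> Recording:
    """Slow nominal-strain ramp, optionally under tetanic stimulation.

    Ramps ``L_m`` so the nominal strain rises linearly to ``max_strain``
    (default 15 %, hard cap 30 %: beyond that the core detaches or
    yields).  With ``stimulate=True`` a continuous 5 Hz pulse train drives
    a fused tetanic activation, so subtracting the passive ramp recovers
    the Gaussian active force-length curve and the optimal strain L_o.
    """
    if max_strain > 0.30:
        raise ValueError("stretch is limited to 30 % of the core length")
    if stimulate and medium == "air":
        raise ValueError("electrical stimulation requires a solution medium")
    l0 = params.rest_length
    duration = max_strain / strain_rate

    def lm_fn(t: np.ndarray) -> np.ndarray:
        return l0 * strain_rate * t

    activation_fn = None
    stim_flag = stimulate
    if stimulate:
        pulses = pulse_train(stimulus_frequency, duration)
        from .samples import activation_from_stimulus

        def activation_fn(t: np.ndarray) -> np.ndarray:
            return activation_from_stimulus(pulses, t, params.twitch_time)

    t, lm, x_true, x_q, act = _simulate(
        params,
        probe,
        lm_fn,
        duration,
        medium=medium,
        activation_fn=activation_fn,
        oversample=4,
        noise_px=noise_px,
        quantize=quantize,
        seed=seed,
    )
    return _pack(
        sample_id, t, lm, x_true, x_q,
        np.full_like(t, stim_flag, dtype=bool), medium, "ramp", probe, params,
        extra_meta={
            "max_strain": max_strain,
            "strain_rate": strain_rate,
            "stimulated": stimulate,
            "seed": seed,
        },
    )


def run_stimulation(
    params: PlantParams,
    probe: ProbeSpec,
    hold_strain: float = 0.05,
    pulse_frequency: float = 1.0,
    duration: float = 5.0,
    *,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    sample_rate: float = CAMERA_RATE,
    sample_id: str = "sample",
) -> Recording:
    """Electrical stimulation at fixed probe position.

    Holds ``L_m`` at ``hold_strain * L_0`` and applies a square-wave pulse
    train (10 ms pulses, 1-5 Hz).  At 1 Hz the force shows distinct
    twitches; at 5 Hz they fuse into a stronger tetanic plateau.  The
    solution medium is mandatory — it carries the stimulation field.
    """
    if medium != "solution":
        raise ValueError("electrical stimulation requires a solution medium")
    l0 = params.rest_length
    pulses = pulse_train(pulse_frequency, duration, start=1.0 / sample_rate)
    from .samples import activation_from_stimulus

    t, lm, x_true, x_q, act = _simulate(
        params,
        probe,
        lambda tt: np.full_like(tt, hold_strain * l0),
        duration,
        medium=medium,
        activation_fn=lambda tt: activation_from_stimulus(
            pulses, tt, params.twitch_time
        ),
        sample_rate=sample_rate,
        oversample=max(1, math.ceil(40.0 * pulse_frequency / sample_rate)),
        noise_px=noise_px,
        quantize=quantize,
        seed=seed,
    )
    stim = np.zeros_like(t, dtype=bool)
    for tp in pulses:
        stim[np.argmin(np.abs(t - tp))] = True
    return _pack(
        sample_id, t, lm, x_true, x_q, stim, medium, "stimulation", probe,
        params,
        extra_meta={
            "hold_strain": hold_strain,
            "pulse_frequency": pulse_frequency,
            "seed": seed,
        },
    )


# -- populations ------------------------------------------------------------


def generate_population(
    grid: Iterable[Mapping[str, object]],
    n_replicates: int,
    probe: ProbeSpec | str = "short",
    *,
    seed: int = 0,
    medium: str = "solution",
    amplitude_strain: float = 0.10,
    frequency: float = 0.1,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
) -> tuple[list[Recording], pd.DataFrame]:
    """Seeded oscillation recordings over a condition grid.

    Runs the default oscillation protocol on ``n_replicates`` independent
    samples per condition.  Sphere-forming conditions cannot be suspended
    between the probes; they appear in the manifest flagged
    ``measurable = False`` and produce no recording.  Returns the
    recordings and a manifest mapping sample id -> condition -> seed.
    """
    if isinstance(probe, str):
        probe = probe_preset(probe)
    recordings: list[Recording] = []
    rows: list[dict] = []
    for ci, condition in enumerate(grid):
        for rep in range(n_replicates):
            state = condition_to_params(condition, seed=seed, replicate=rep)
            sub_seed = (seed * 100003 + ci * 1009 + rep) % (2**31)
            sample_id = f"c{ci:03d}_r{rep:02d}"
            row = {
                "sample_id": sample_id,
                **{k: v for k, v in dict(condition).items()},
                "label": state.label,
                "measurable": state.measurable,
                "seed": sub_seed,
                "protocol": "oscillation",
            }
            rows.append(row)
            if not state.measurable:
                continue
            rec = run_oscillation(
                state.params,
                probe,
                amplitude_strain=amplitude_strain,
                frequency=frequency,
                medium=medium,
                seed=sub_seed,
                noise_px=noise_px,
                quantize=quantize,
                sample_id=sample_id,
            )
            rec.metadata["condition"] = dict(condition)
            rec.metadata["label"] = state.label
            recordings.append(rec)
    return recordings, pd.DataFrame(rows)
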