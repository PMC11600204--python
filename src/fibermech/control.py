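"""Model-predictive force control of the moving probe.

The instrument has no force actuator: the moving probe position ``L_m`` is
the only input, and the measured probe force ``F_s`` (vision-derived, 5 Hz,
pixel-quantized) must track a sinusoidal command ``F_cmd`` without ever
approaching the ~120 uN liquid-bridge adhesion that holds the fiber on the
probes.  A receding-horizon quadratic program over position increments
does the tracking; the adhesion limit enters as a hard bound on the
predicted force.

The plant model is identified from a short dithered calibration ramp as a
first-order-plus-gain discrete model with one force lag and two position
taps,

    F[k+1] = a F[k] + b1 L_m[k+1] + b0 L_m[k],

whose static gain ``(b0 + b1)/(1 - a)`` is the series stiffness of probe
and sample, and whose instantaneous gain ``b1`` additionally carries the
rate-dependent (solution-drag) response at the control rate — without the
second tap the controller badly underestimates the move gain of a drag-
dominated fiber and goes unstable.  The real controller's prediction model
and weights are not public, so horizon 10 with equal tracking weight and a
small move penalty is used as a conventional baseline — a reconstruction,
not a reproduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .bench import (
    CAMERA_RATE,
    DEFAULT_NOISE_PX,
    FIXATION_LIMIT,
    PlantSimulator,
    Recording,
    apply_camera,
    _oversample_for,
    _pack,
)
from .probe import ProbeSpec, stiffness
from .samples import PlantParams, complex_modulus_closed_form, cross_section_area

__all__ = [
    "ControllerConfig",
    "PlantModel",
    "identify_plant",
    "simulate_calibration_ramp",
    "mpc_step",
    "run_closed_loop",
    "run_closed_loop_oscillation",
    "run_open_loop",
]

#: Stepper-motor granularity of the moving probe, m.
ACTUATOR_STEP = 0.2e-6

#: Output-disturbance estimator gain (offset-free correction filter).
_DHAT_GAIN = 0.3


@dataclass(frozen=True)
class PlantModel:
    """Identified discrete model F[k+1] = a F[k] + b1 L[k+1] + b0 L[k]."""

    a: float
    b1: float  # instantaneous gain, N/m
    b0: float  # N/m
    residual: float  # rms fit residual, N

    @property
    def static_gain(self) -> float:
        """Steady-state force per unit probe displacement, N/m."""
        return (self.b0 + self.b1) / (1.0 - self.a)


@dataclass(frozen=True)
class ControllerConfig:
    """Receding-horizon controller settings.

    ``force_limit`` is the liquid-bridge bound on the instantaneous (and
    hence peak-to-peak, since commands start from zero) force.  The QP
    enforces it with a three-pixel force margin: one pixel for the
    quantized feedback's uncertainty, the rest for transient model
    mismatch.
    """

    horizon: int = 10
    tracking_weight: float = 1.0
    move_weight_rel: float = 0.05  # move penalty relative to b1^2 * q
    force_limit: float = FIXATION_LIMIT
    step_time: float = 1.0 / CAMERA_RATE
    actuator_step: float = ACTUATOR_STEP

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.tracking_weight <= 0.0 or self.move_weight_rel <= 0.0:
            raise ValueError("weights must be positive")
        if self.force_limit <= 0.0:
            raise ValueError("force_limit must be positive")


# -- identification ---------------------------------------------------------


def identify_plant(
    probe: ProbeSpec, calibration: Recording
) -> PlantModel:
    """Least-squares fit of the first-order force model from a calibration
    recording (a small-amplitude dithered ramp).

    Regresses F[k+1] on (F[k], L_m[k+1], L_m[k]).  Raises if the recording
    carries no excitation.  On a purely elastic sample the fit collapses to
    the series stiffness (static and instantaneous gains coincide).
    """
    f = np.asarray(calibration.force, dtype=float)
    lm = np.asarray(calibration.probe_displacement, dtype=float)
    if len(f) < 8:
        raise ValueError("calibration recording too short")
    if np.ptp(lm) == 0.0:
        raise ValueError("calibration recording carries no excitation")
    y = f[1:]
    regressors = np.column_stack([f[:-1], lm[1:], lm[:-1]])
    coef, _, rank, _ = np.linalg.lstsq(regressors, y, rcond=None)
    if rank < 2:
        raise ValueError("calibration recording carries no excitation")
    rms = float(np.sqrt(np.mean((regressors @ coef - y) ** 2)))
    return PlantModel(a=float(coef[0]), b1=float(coef[1]), b0=float(coef[2]),
                      residual=rms)


def simulate_calibration_ramp(
    params: PlantParams,
    probe: ProbeSpec,
    *,
    max_strain: float = 0.02,
    duration: float = 20.0,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
) -> Recording:
    """Small-amplitude dithered ramp used to identify the plant.

    A slow ramp to ``max_strain`` with a superimposed zero-mean step
    dither, so the regression sees both the static gain and the
    step-to-step (rate-dependent) response at the control rate.
    """
    from .bench import _simulate

    l0 = params.rest_length
    rng = np.random.default_rng(None if seed is None else seed + 17)
    n = int(round(duration * CAMERA_RATE)) + 1
    frame_t = np.arange(n) / CAMERA_RATE
    targets = (l0 * max_strain * frame_t / duration
               + rng.normal(0.0, 0.05 * max_strain * l0, n))
    targets[0] = 0.0

    def lm_fn(t: np.ndarray) -> np.ndarray:
        # same linearly-interpolated move profile the controller uses
        return np.interp(t, frame_t, targets)

    t, lm, x_true, x_q, _ = _simulate(
        params, probe, lm_fn, duration,
        medium=medium, oversample=2, noise_px=noise_px, quantize=quantize,
        seed=seed,
    )
    return _pack(
        "calibration", t, lm, x_true, x_q, np.zeros_like(t, dtype=bool),
        medium, "ramp", probe, params, extra_meta={"calibration": True},
    )


# -- the QP -----------------------------------------------------------------


def _prediction_matrices(
    model: PlantModel, horizon: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alpha, beta, S) with F_hat = alpha * F0 + beta * L0 + S u.

    Built by unrolling the recursion F_hat[i+1] = a F_hat[i]
    + b1 L_hat[i+1] + b0 L_hat[i] with L_hat[i] = L0 + sum_{j<i} u_j.
    """
    a, b1, b0 = model.a, model.b1, model.b0
    h = horizon
    alpha = np.zeros(h + 1)
    beta = np.zeros(h + 1)
    g = np.zeros((h + 1, h))
    # position-coefficient rows: L_hat[i] depends on u_0..u_{i-1}
    lu = np.tril(np.ones((h + 1, h)), k=-1)
    alpha[0] = 1.0
    for i in range(1, h + 1):
        alpha[i] = a * alpha[i - 1]
        beta[i] = a * beta[i - 1] + b1 + b0
        g[i] = a * g[i - 1] + b1 * lu[i] + b0 * lu[i - 1]
    return alpha[1:], beta[1:], g[1:]


def mpc_step(
    config: ControllerConfig,
    model: PlantModel,
    force_now: float,
    lm_now: float,
    command_window: np.ndarray,
    disturbance: float = 0.0,
) -> tuple[float, bool]:
    """One receding-horizon move of the moving probe.

    Minimises ``q ||F_hat - F_cmd||^2 + r ||u||^2`` over the horizon's
    position increments subject to ``|F_hat| <= force_limit`` (with a
    one-pixel margin applied by the caller via the command clip and here as
    a hard constraint).  ``disturbance`` is a constant output-disturbance
    estimate added to every predicted force — the offset-free correction
    that removes the steady tracking bias a static-gain model error would
    otherwise leave.  Returns the first increment, rounded to the actuator
    granularity, and a flag set when the QP had to fall back to a zero
    move.
    """
    h = config.horizon
    cmd = np.asarray(command_window, dtype=float)
    if len(cmd) < h:
        cmd = np.concatenate([cmd, np.full(h - len(cmd), cmd[-1])])
    cmd = cmd[:h]

    powers, free_l, s = _prediction_matrices(model, h)
    free = powers * force_now + free_l * lm_now + disturbance
    target = cmd - free
    q = config.tracking_weight
    r = config.move_weight_rel * q * model.b1**2
    # unconstrained ridge solution
    gram = q * (s.T @ s) + r * np.eye(h)
    u = np.linalg.solve(gram, q * s.T @ target)

    limit = config.force_limit
    pred = free + s @ u
    if np.any(np.abs(pred) > limit):
        cons = (
            {"type": "ineq", "fun": lambda v: limit - (free + s @ v)},
            {"type": "ineq", "fun": lambda v: (free + s @ v) + limit},
        )
        res = minimize(
            lambda v: q * np.sum((s @ v - target) ** 2) + r * np.sum(v**2),
            np.clip(u, -1.0, 1.0),
            jac=lambda v: 2.0 * q * s.T @ (s @ v - target) + 2.0 * r * v,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 80},
        )
        if not res.success:
            return 0.0, True
        u = res.x

    du = float(u[0])
    du = round(du / config.actuator_step) * config.actuator_step
    return du, False


# -- closed and open loop runs ----------------------------------------------


def run_closed_loop(
    params: PlantParams,
    probe: ProbeSpec,
    command_fn,
    duration: float,
    *,
    config: ControllerConfig | None = None,
    model: PlantModel | None = None,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    oversample: int = 4,
    sample_id: str = "sample",
    metadata: dict | None = None,
) -> Recording:
    """Force-controlled run: MPC shapes ``L_m`` so ``F_s`` tracks
    ``command_fn(t)``.

    The loop runs at the camera rate.  Each step: read the quantized
    deflection, form the measured force, solve the QP against the upcoming
    command window (clipped to the force limit minus one pixel of margin),
    apply the first move and integrate the plant across the interval.
    """
    if config is None:
        config = ControllerConfig()
    if model is None:
        cal = simulate_calibration_ramp(
            params, probe, medium=medium, seed=seed,
            noise_px=noise_px, quantize=quantize,
        )
        model = identify_plant(probe, cal)

    k = stiffness(probe)
    dt = config.step_time
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    # three pixels of force headroom below the adhesion limit: one for the
    # quantized feedback, the rest for transient model mismatch
    margin = 3.0 * k * probe.pixel_size
    cmd_full = np.clip(
        np.asarray(command_fn(t), dtype=float),
        -(config.force_limit - margin),
        config.force_limit - margin,
    )

    rng = np.random.default_rng(seed)
    sim = PlantSimulator(params, probe, medium)
    lm = np.zeros(n)
    x_true = np.zeros(n)
    x_meas = np.zeros(n)
    flags = 0
    cons_cfg = ControllerConfig(
        horizon=config.horizon,
        tracking_weight=config.tracking_weight,
        move_weight_rel=config.move_weight_rel,
        force_limit=config.force_limit - margin,
        step_time=config.step_time,
        actuator_step=config.actuator_step,
    )
    dhat = 0.0  # filtered output-disturbance estimate
    f_prev = 0.0
    for i in range(n - 1):
        x_meas[i] = apply_camera(
            np.array([x_true[i]]), probe.pixel_size, noise_px, quantize, rng
        )[0]
        # debias the floor quantizer (+0.5 px expected) in the feedback
        # path only; the recorded readout stays the raw pixel value
        x_fb = x_meas[i] + (0.5 * probe.pixel_size * np.sign(x_meas[i])
                            if quantize else 0.0)
        f_meas = k * x_fb
        if i > 0:
            predicted = model.a * f_prev + model.b1 * lm[i] + model.b0 * lm[i - 1]
            dhat = (1.0 - _DHAT_GAIN) * dhat + _DHAT_GAIN * (f_meas - predicted)
        f_prev = f_meas
        window = cmd_full[i + 1 : i + 1 + config.horizon]
        du, fell_back = mpc_step(cons_cfg, model, f_meas, lm[i], window, dhat)
        flags += fell_back
        # detachment supervisor (overrides the QP, as a real instrument's
        # safety interlock would): upward moves may consume at most a
        # third of the remaining force headroom even if the true gain is
        # 3x the identified one; at the soft ceiling, retreat outright
        b_eff = max(abs(model.b1), abs(model.static_gain), 1e-9)
        headroom = config.force_limit - 2.0 * margin - f_meas
        if du > 0.0:
            du = min(du, max(0.0, headroom) / (3.0 * b_eff))
        if f_meas > config.force_limit - margin:
            du = min(du, -abs(headroom) / b_eff)
        du = round(du / config.actuator_step) * config.actuator_step
        lm[i + 1] = lm[i] + du
        x_true[i + 1] = sim.advance(lm[i + 1], dt, n_sub=oversample)
    x_meas[n - 1] = apply_camera(
        np.array([x_true[n - 1]]), probe.pixel_size, noise_px, quantize, rng
    )[0]

    px = probe.pixel_size
    meta = {"controlled": True, "qp_fallbacks": int(flags), "seed": seed}
    if metadata:
        meta.update(metadata)
    return _pack(
        sample_id, t, lm, x_true,
        x_meas if quantize or noise_px > 0 else x_true,
        np.zeros(n, dtype=bool), medium, "oscillation", probe, params,
        extra_meta=meta, command=cmd_full,
    )


def run_closed_loop_oscillation(
    params: PlantParams,
    probe: ProbeSpec,
    *,
    amplitude_strain: float | None = 0.10,
    command_peak: float | None = None,
    frequency: float = 0.1,
    n_cycles: int = 5,
    settle_cycles: int = 1,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    config: ControllerConfig | None = None,
    sample_id: str = "sample",
) -> Recording:
    """Closed-loop oscillatory loading with a raised-cosine force command.

    ``F_cmd(t) = F_pk (1 - cos(2 pi f (t - t0))) / 2`` rises from zero to
    ``F_pk`` once per cycle, so the commanded peak equals ``F_pk`` and the
    commanded peak-to-peak equals ``F_pk`` as well.  The small phase ``t0``
    aligns the command peak with a camera frame — at 1 Hz the 5 Hz frames
    otherwise straddle the crest and the sampled peak under-reads by ~10 %.
    If ``command_peak`` is not given it is sized from the closed-form
    complex modulus so the peak strain matches ``amplitude_strain``.
    """
    if command_peak is None:
        if amplitude_strain is None:
            raise ValueError("give either command_peak or amplitude_strain")
        e_star, _ = complex_modulus_closed_form(params, frequency, medium)
        command_peak = cross_section_area(params) * e_star * amplitude_strain
    omega = 2.0 * math.pi * frequency
    duration = (n_cycles + settle_cycles) / frequency
    if config is None:
        config = ControllerConfig()
    dt = config.step_time
    half_period = 0.5 / frequency
    t0 = (dt - half_period % dt) % dt  # put the crest on a camera frame

    rec = run_closed_loop(
        params,
        probe,
        lambda t: command_peak * 0.5 * (1.0 - np.cos(omega * (t - t0))),
        duration,
        config=config,
        medium=medium,
        seed=seed,
        noise_px=noise_px,
        quantize=quantize,
        oversample=_oversample_for(frequency),
        sample_id=sample_id,
        metadata={
            "frequency": frequency,
            "settle_cycles": settle_cycles,
            "command_peak": command_peak,
        },
    )
    return rec


def run_open_loop(
    params: PlantParams,
    probe: ProbeSpec,
    command_peak: float = 15e-6,
    frequency: float = 0.1,
    n_cycles: int = 5,
    *,
    medium: str = "solution",
    seed: int | None = None,
    noise_px: float = DEFAULT_NOISE_PX,
    quantize: bool = True,
    sample_id: str = "sample",
) -> Recording:
    """Naive uncontrolled loading sized from the static gain only.

    The probe follows a raised-cosine displacement whose amplitude is
    ``command_peak`` divided by the static series stiffness — correct for
    a purely elastic sample, but on a viscoelastic one the rate-dependent
    stress makes the measured force waveform distorted and its peak
    overshoot the intended amplitude (the overshoot grows with the
    loss/storage ratio at the loading frequency).
    """
    from .bench import _simulate

    k = stiffness(probe)
    l0 = params.rest_length
    a0 = cross_section_area(params)
    k_sample = a0 * params.equilibrium_modulus / l0
    k_series = k * k_sample / (k + k_sample)
    lm_peak = command_peak / k_series
    omega = 2.0 * math.pi * frequency

    t, lm, x_true, x_q, _ = _simulate(
        params, probe,
        lambda tt: lm_peak * 0.5 * (1.0 - np.cos(omega * tt)),
        n_cycles / frequency,
        medium=medium, oversample=_oversample_for(frequency),
        noise_px=noise_px, quantize=quantize, seed=seed,
    )
    cmd = command_peak * 0.5 * (1.0 - np.cos(omega * t))
    return _pack(
        sample_id, t, lm, x_true, x_q, np.zeros_like(t, dtype=bool), medium,
        "oscillation", probe, params,
        extra_meta={"controlled": False, "frequency": frequency,
                    "command_peak": command_peak, "seed": seed},
        command=cmd,
    )
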