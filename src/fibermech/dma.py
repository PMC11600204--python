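"""Measurement pipeline: stress/strain, spectral viscoelasticity, Lissajous
modulus and contractile-force summaries.

Viscoelasticity is extracted by a single-bin discrete Fourier projection of
the stress and strain records at exactly the analysis frequency (0.1 Hz,
the cell mechanosensing frequency): the complex modulus magnitude is the
stress/strain amplitude ratio, and the loss factor is the tangent of the
stress-strain phase lag.  The first (settling) cycle is excluded, the
record is truncated to an integer number of periods, and no window is
applied — on integer-period records the exact projection and the nearest
FFT bin coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bench import Recording

__all__ = [
    "ViscoSummary",
    "ContractionSummary",
    "stress_strain",
    "extract_viscoelasticity",
    "lissajous_modulus",
    "analyze_oscillation",
    "find_optimal_length",
    "cf_criterion_value",
    "summarize_run",
]

ANALYSIS_FREQUENCY = 0.1  # Hz

#: Default CF criterion threshold: active excess over the same-diameter
#: passive baseline, N.
CF_THRESHOLD = 3e-6


@dataclass(frozen=True)
class ViscoSummary:
    """Single-frequency viscoelasticity of one sample."""

    e_star: float  # |E*|, Pa
    tan_delta: float
    e_lissajous: float  # Pa
    frequency: float  # Hz
    stress_amplitude: float  # Pa
    strain_amplitude: float
    stress_phase: float  # rad
    strain_phase: float  # rad
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContractionSummary:
    """Contractile-force summary from paired stimulated/passive ramps."""

    optimal_strain: float  # L_o, dimensionless
    force_at_optimum: float  # stimulated F_s at L_o, N
    active_peak: float  # max (stimulated - passive), N
    max_passive: float  # F_pmax, N
    passive_at_optimum: float  # passive F_s at L_o, N
    cf_generated: bool
    flags: tuple[str, ...] = ()


def stress_strain(recording: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Engineering stress and strain time series of a recording.

    sigma_s = 4 F_s / (pi d_0^2);  eps_s = (L_m - x) / L_0,

    with ``d_0`` and ``L_0`` the initial core diameter and length from the
    recording metadata (the core geometry is never re-measured).
    """
    try:
        d0 = float(recording.metadata["diameter"])
        l0 = float(recording.metadata["rest_length"])
    except KeyError as exc:
        raise ValueError(f"recording metadata missing geometry: {exc}") from exc
    if d0 <= 0.0 or l0 <= 0.0:
        raise ValueError("diameter and rest_length must be positive")
    sigma = 4.0 * recording.force / (math.pi * d0**2)
    eps = (recording.probe_displacement - recording.tip_deflection) / l0
    return sigma, eps


def _single_bin(
    series: np.ndarray, t: np.ndarray, frequency: float
) -> tuple[float, float]:
    """Amplitude and phase of ``series`` at exactly ``frequency``.

    Mean-removed projection C = (2/N) sum s[n] exp(-i 2 pi f t[n]) over an
    integer number of periods; returns (|C|, angle(C)) with the phase of a
    pure ``sin(2 pi f t)`` defined as 0.
    """
    s = series - series.mean()
    phase = np.exp(-2j * math.pi * frequency * t)
    c = 2.0 / len(s) * np.sum(s * phase)
    # rotate so that sin(w t) -> phase 0
    c *= 1j
    return float(np.abs(c)), float(np.angle(c))


def extract_viscoelasticity(
    sigma: np.ndarray,
    eps: np.ndarray,
    t: np.ndarray,
    frequency: float = ANALYSIS_FREQUENCY,
    *,
    settle_cycles: int = 1,
) -> ViscoSummary:
    """Complex modulus and loss factor from oscillatory stress/strain.

    Drops ``settle_cycles`` leading cycles, truncates to an integer number
    of periods of ``frequency`` (flagging leakage if samples were
    discarded), projects both series onto the analysis frequency and forms

        |E*| = A_sigma / A_eps,   tan delta = tan(phi_sigma - phi_eps)

    with the phase difference wrapped into [0, pi/2); small negative
    differences (noise on nearly elastic samples) are clamped to zero and
    flagged.  Also reports the Lissajous modulus of the final loop.
    """
    sigma = np.asarray(sigma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (len(sigma) == len(eps) == len(t)):
        raise ValueError("series length mismatch")
    dt = float(t[1] - t[0])
    per_cycle = 1.0 / (frequency * dt)
    n_start = int(round(settle_cycles * per_cycle))
    if n_start >= len(t):
        raise ValueError("record shorter than the settling portion")
    sigma, eps, t = sigma[n_start:], eps[n_start:], t[n_start:]

    n_cycles = int(math.floor((len(t) - 1) / per_cycle))
    if n_cycles < 3:
        raise ValueError(
            f"need >= 3 full periods of {frequency} Hz after settling, "
            f"got {n_cycles}"
        )
    flags: list[str] = []
    n_keep = int(round(n_cycles * per_cycle))
    if n_keep < len(t) - 1:
        flags.append("leakage_trimmed")
    sigma_w, eps_w, t_w = sigma[:n_keep], eps[:n_keep], t[:n_keep]

    a_eps, phi_eps = _single_bin(eps_w, t_w, frequency)
    if a_eps < 1e-6:
        raise ValueError("no strain excitation at the analysis frequency")
    a_sig, phi_sig = _single_bin(sigma_w, t_w, frequency)

    dphi = phi_sig - phi_eps
    dphi = (dphi + math.pi) % (2.0 * math.pi) - math.pi  # principal value
    if dphi < 0.0:
        flags.append("negative_phase_clamped")
        dphi = 0.0
    if dphi >= math.pi / 2.0:
        flags.append("phase_wrapped")
        dphi = math.nextafter(math.pi / 2.0, 0.0)

    e_liss = lissajous_modulus(sigma, eps, t, frequency=frequency)
    return ViscoSummary(
        e_star=a_sig / a_eps,
        tan_delta=math.tan(dphi),
        e_lissajous=e_liss,
        frequency=frequency,
        stress_amplitude=a_sig,
        strain_amplitude=a_eps,
        stress_phase=phi_sig,
        strain_phase=phi_eps,
        flags=tuple(flags),
    )


def lissajous_modulus(
    sigma: np.ndarray,
    eps: np.ndarray,
    t: np.ndarray | None = None,
    frequency: float = ANALYSIS_FREQUENCY,
) -> float:
    """Peak-to-peak modulus of the final stress-strain loop, Pa.

    E = (sigma_max - sigma_min) / (eps_max - eps_min) over the last full
    cycle only, so start-up transients do not contaminate the estimate.
    """
    sigma = np.asarray(sigma, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if t is None:
        sl = slice(None)
    else:
        t = np.asarray(t, dtype=float)
        dt = float(t[1] - t[0])
        n_cycle = int(round(1.0 / (frequency * dt)))
        if n_cycle + 1 > len(sigma):
            raise ValueError("record shorter than one full cycle")
        sl = slice(len(sigma) - n_cycle - 1, None)
    s, e = sigma[sl], eps[sl]
    de = e.max() - e.min()
    if de <= 0.0:
        raise ValueError("constant strain: Lissajous modulus undefined")
    return float((s.max() - s.min()) / de)


def analyze_oscillation(recording: Recording,
                        frequency: float | None = None) -> ViscoSummary:
    """Full viscoelasticity summary of one oscillation recording."""
    if frequency is None:
        frequency = float(recording.metadata.get("frequency", ANALYSIS_FREQUENCY))
    settle = int(recording.metadata.get("settle_cycles", 1))
    sigma, eps = stress_strain(recording)
    return extract_viscoelasticity(
        sigma, eps, recording.time, frequency, settle_cycles=settle
    )


# -- contractile force ------------------------------------------------------


def find_optimal_length(
    stimulated: Recording,
    passive: Recording,
    *,
    cf_threshold: float = CF_THRESHOLD,
) -> ContractionSummary:
    """Optimal strain and contractile force from paired length sweeps.

    The active force-length curve is the pointwise difference between the
    stimulated and passive ramps on a common strain grid; its argmax is
    the optimal strain L_o (actin-myosin overlap maximum), and the
    stimulated force there is the reported ``F_s`` at ``L_o``.
    """
    flags: list[str] = []
    eps_s = stimulated.strain
    eps_p = passive.strain
    f_s = stimulated.force
    f_p = passive.force
    if len(eps_s) != len(eps_p) or not np.allclose(eps_s, eps_p, atol=5e-3):
        flags.append("grid_resampled")
        order = np.argsort(eps_p)
        f_p = np.interp(eps_s, eps_p[order], f_p[order])
    active = f_s - f_p
    i_opt = int(np.argmax(active))
    active_peak = float(active[i_opt])
    summary = ContractionSummary(
        optimal_strain=float(eps_s[i_opt]),
        force_at_optimum=float(f_s[i_opt]),
        active_peak=active_peak,
        max_passive=float(f_p.max()),
        passive_at_optimum=float(f_p[i_opt]),
        cf_generated=active_peak > cf_threshold,
        flags=tuple(flags),
    )
    return summary


def cf_criterion_value(
    force_at_optimum: float,
    group_passive_forces: Sequence[float],
    *,
    own_passive: float | None = None,
    threshold: float = CF_THRESHOLD,
) -> tuple[float, bool, tuple[str, ...]]:
    """CF criterion: F_s at L_o minus the same-diameter passive baseline.

    ``group_passive_forces`` are the passive tensions (at the same strain)
    of samples sharing the diameter; their mean is the baseline ``F_sa``.
    For a singleton group the sample's own passive ramp is the fallback
    baseline, flagged accordingly.  Returns (difference, cf_generated,
    flags).
    """
    group = [float(f) for f in group_passive_forces]
    flags: tuple[str, ...] = ()
    if len(group) >= 2:
        baseline = float(np.mean(group))
    elif own_passive is not None:
        baseline = float(own_passive)
        flags = ("singleton_group_own_baseline",)
    else:
        raise ValueError(
            "need >= 2 samples in the diameter group or an own passive baseline"
        )
    diff = force_at_optimum - baseline
    return diff, diff > threshold, flags


# -- run-level summaries ----------------------------------------------------


def summarize_run(recordings: Iterable[Recording]) -> pd.DataFrame:
    """Per-sample summary table of a directory of oscillation recordings.

    Columns: sample_id, E_star_kPa, tan_delta, E_lissajous_kPa plus any
    condition factors found in the metadata.
    """
    rows = []
    for rec in recordings:
        if rec.protocol != "oscillation":
            continue
        vs = analyze_oscillation(rec)
        row = {
            "sample_id": rec.sample_id,
            "E_star_kPa": vs.e_star / 1e3,
            "tan_delta": vs.tan_delta,
            "E_lissajous_kPa": vs.e_lissajous / 1e3,
            "flags": ";".join(vs.flags),
        }
        cond = rec.metadata.get("condition")
        if isinstance(cond, dict):
            row.update(cond)
        if "label" in rec.metadata:
            row["label"] = rec.metadata["label"]
        rows.append(row)
    if not rows:
        raise ValueError("no oscillation recordings to summarize")
    return pd.DataFrame(rows)
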