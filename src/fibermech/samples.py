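"""Constitutive and physiological models of fiber-shaped microtissues.

A sample (a hydrogel core, a cellular bundle, or a differentiated
myobundle) is modelled as a standard linear (Zener) solid — an equilibrium
spring ``E_e`` in parallel with a Maxwell arm (``E_1``, ``eta_1``) — plus
an additive Newtonian loss term ``gamma`` that is active only when the
fiber is measured in solution.  The drag term lumps the viscous friction
between the porous microfiber and the surrounding medium into an
equivalent bulk viscosity; it is what elevates the in-solution loss factor
of acellular hydrogel fibers well above their in-air value, while cellular
bundles (whose water is held inside cells) have ``gamma ~ 0``.

Active muscle behaviour is a Gaussian force-length relation centred on an
optimal strain ``lambda_opt`` (actin-myosin overlap) scaled by a peak
tetanic force ``F_a``, driven by an alpha-function twitch kernel per
stimulus pulse.

``condition_to_params`` maps experimental condition grids (hydrogel
formulation, CoCl2 hypoxia dose, composite-bioink ratio) to calibrated
parameter sets with seeded replicate scatter.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PlantParams",
    "SampleState",
    "complex_modulus_closed_form",
    "cross_section_area",
    "passive_stress",
    "active_force",
    "total_force",
    "activation_from_stimulus",
    "condition_to_params",
    "plant_preset",
    "PLANT_PRESETS",
    "condition_grid",
    "CONDITION_GRIDS",
    "GELMA12_LABELS",
]

MEDIA = ("solution", "air")

#: Cell mechanosensing frequency at which viscoelasticity is reported, Hz.
MECHANOSENSING_FREQUENCY = 0.1


@dataclass(frozen=True)
class PlantParams:
    """Constitutive parameters of one simulated microtissue fiber.

    Parameters
    ----------
    equilibrium_modulus:
        Long-time elastic modulus ``E_e``, Pa.
    arm_modulus, arm_viscosity:
        Maxwell arm ``E_1`` (Pa) and ``eta_1`` (Pa s); relaxation time
        ``tau_1 = eta_1 / E_1``.
    drag_coefficient:
        Equivalent bulk viscosity of solution drag, Pa s; contributes
        ``omega * gamma`` to the loss modulus in solution, nothing in air.
    diameter, rest_length:
        Initial core diameter ``d_0`` and gauge length ``L_0``, m; used for
        stress/strain normalisation throughout (the core is never
        re-measured).
    passive_stiffening:
        Dimensionless exponent ``c_p`` of the exponential passive
        stress-strain curve; 0 gives a linear solid.
    active_peak:
        Peak tetanic active force ``F_a``, N (0 for acellular samples).
    optimal_strain, active_width:
        Centre and width of the Gaussian force-length relation
        (dimensionless strain).
    twitch_time:
        Alpha-function twitch time constant ``tau``, s.
    """

    equilibrium_modulus: float
    arm_modulus: float = 0.0
    arm_viscosity: float = 0.0
    drag_coefficient: float = 0.0
    diameter: float = 200e-6
    rest_length: float = 5e-3
    passive_stiffening: float = 0.0
    active_peak: float = 0.0
    optimal_strain: float = 0.05
    active_width: float = 0.03
    twitch_time: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "equilibrium_modulus",
            "arm_modulus",
            "arm_viscosity",
            "drag_coefficient",
            "passive_stiffening",
            "active_peak",
            "twitch_time",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.diameter <= 0.0 or self.rest_length <= 0.0:
            raise ValueError("diameter and rest_length must be positive")
        if not 0.0 < self.optimal_strain < 0.15:
            raise ValueError("optimal_strain must lie in (0, 0.15)")
        if self.active_width <= 0.0:
            raise ValueError("active_width must be positive")

    @property
    def relaxation_time(self) -> float:
        """Maxwell arm relaxation time tau_1 = eta_1/E_1 (0 if no arm)."""
        if self.arm_modulus == 0.0:
            return 0.0
        return self.arm_viscosity / self.arm_modulus


#: Labels of the distinguishable construct types.
SAMPLE_LABELS = (
    "pre_culture_core",
    "c_bundle",
    "cg_bundle",
    "cell_sphere",
    "myobundle",
    "g_myobundle",
    "ca_myobundle",
)


@dataclass(frozen=True)
class SampleState:
    """One sample: construct label, measurement medium, and parameters."""

    label: str
    params: PlantParams
    medium: str = "solution"

    def __post_init__(self) -> None:
        if self.label not in SAMPLE_LABELS:
            raise ValueError(f"unknown label {self.label!r}; valid: {SAMPLE_LABELS}")
        if self.medium not in MEDIA:
            raise ValueError(f"medium must be one of {MEDIA}")

    @property
    def measurable(self) -> bool:
        """Cell spheres have no fiber to suspend between the probes."""
        return self.label != "cell_sphere"


def cross_section_area(params: PlantParams) -> float:
    """Initial cross-section area A_0 = pi d_0^2 / 4, m^2."""
    return math.pi * params.diameter**2 / 4.0


def complex_modulus_closed_form(
    params: PlantParams, frequency: float, medium: str = "solution"
) -> tuple[float, float]:
    """Closed-form (|E*|, tan delta) of the Zener solid with additive drag.

    At angular frequency ``omega = 2 pi f`` with ``x = omega tau_1``:

        E' = E_e + E_1 x^2 / (1 + x^2)
        E'' = E_1 x / (1 + x^2) + omega * gamma_medium

    where ``gamma_medium = gamma`` in solution and 0 in air.  Returns
    ``(sqrt(E'^2 + E''^2), E''/E')``.
    """
    if frequency <= 0.0:
        raise ValueError("frequency must be positive")
    if medium not in MEDIA:
        raise ValueError(f"medium must be one of {MEDIA}")
    omega = 2.0 * math.pi * frequency
    x = omega * params.relaxation_time
    storage = params.equilibrium_modulus + params.arm_modulus * x**2 / (1.0 + x**2)
    loss = params.arm_modulus * x / (1.0 + x**2)
    if medium == "solution":
        loss += omega * params.drag_coefficient
    if storage <= 0.0:
        raise ValueError("storage modulus is zero: fluid-like sample unsupported")
    return math.hypot(storage, loss), loss / storage


def passive_stress(params: PlantParams, strain: float) -> float:
    """Quasi-static passive stress, Pa (exponential strain stiffening).

    sigma_p(eps) = E_e (exp(c_p eps) - 1) / c_p, reducing to E_e * eps for
    c_p -> 0 so the small-strain modulus is always ``E_e``.
    """
    if strain <= -1.0:
        raise ValueError("strain must exceed -1")
    c = params.passive_stiffening
    if c == 0.0:
        return params.equilibrium_modulus * strain
    return params.equilibrium_modulus * math.expm1(c * strain) / c


def active_force(params: PlantParams, strain: float, activation: float) -> float:
    """Active contractile force, N: Gaussian force-length relation.

    F_act = activation * F_a * exp(-((eps - lambda_opt)/w)^2).  The active
    term vanishes in the Gaussian tails far above the optimal strain, where
    actin-myosin overlap is lost.
    """
    z = (strain - params.optimal_strain) / params.active_width
    return activation * params.active_peak * math.exp(-(z**2))


def total_force(
    params: PlantParams,
    strain: float,
    strain_rate: float = 0.0,
    activation: float = 0.0,
    medium: str = "solution",
) -> float:
    """Total axial force, N, at a given strain, strain rate and activation.

    Quasi-static form: the Maxwell arm is taken at its constant-rate steady
    state (stress ``eta_1 * strain_rate``), so

        F = A_0 [sigma_p(eps) + (eta_1 + gamma_medium) * deps/dt]
            + activation * F_a * exp(-((eps - lambda_opt)/w)^2)
    """
    if medium not in MEDIA:
        raise ValueError(f"medium must be one of {MEDIA}")
    eta = params.arm_viscosity
    if medium == "solution":
        eta += params.drag_coefficient
    sigma = passive_stress(params, strain) + eta * strain_rate
    return cross_section_area(params) * sigma + active_force(params, strain, activation)


# -- electrical stimulation -------------------------------------------------

#: Peak activation contributed by one isolated twitch (so a fused train can
#: exceed a single twitch before the [0, 1] ceiling).
TWITCH_GAIN = 0.4


def activation_from_stimulus(
    pulse_times: Sequence[float],
    t: np.ndarray,
    twitch_time: float,
    gain: float = TWITCH_GAIN,
) -> np.ndarray:
    """Activation time series from a train of stimulus pulses.

    Each pulse at ``t_i`` adds an alpha-function twitch
    ``gain * (s) exp(1 - s)`` with ``s = (t - t_i)/tau``, peaking at
    ``gain`` one time constant after the pulse.  Contributions sum and are
    clipped to [0, 1]; at 5 Hz with the default tau = 0.1 s the twitches
    fuse into a tetanic plateau that exceeds the 1 Hz single-twitch peak.
    """
    pulses = np.asarray(pulse_times, dtype=float)
    if pulses.size and np.any(np.diff(pulses) <= 0.0):
        raise ValueError("pulse times must be strictly increasing")
    if twitch_time <= 0.0:
        raise ValueError("twitch_time must be positive")
    t = np.asarray(t, dtype=float)
    act = np.zeros_like(t)
    for tp in pulses:
        s = (t - tp) / twitch_time
        mask = s > 0.0
        act[mask] += gain * s[mask] * np.exp(1.0 - s[mask])
    return np.clip(act, 0.0, 1.0)


def pulse_train(frequency: float, duration: float, start: float = 0.0) -> np.ndarray:
    """Pulse onset times for a square-wave stimulus train (10 ms pulses)."""
    if frequency <= 0.0:
        raise ValueError("frequency must be positive")
    return start + np.arange(0.0, duration, 1.0 / frequency)


# -- presets ----------------------------------------------------------------

# Calibrated so that, at the 0.1 Hz mechanosensing frequency:
#   * pre-culture GelMA cores read |E*| in 0.81-4.23 kPa and in-solution
#     tan delta in 0.45-1.1 (drag-dominated loss),
#   * C-bundles / myobundles (gamma ~ 0) read tan delta in 0.1-0.4,
#   * hydrogel fibers measured in air read tan delta < 0.4.
# omega = 2 pi 0.1 = 0.6283 rad/s throughout these comments.
PLANT_PRESETS: dict[str, PlantParams] = {
    # E' = 1.49 kPa, E'' = 0.29 + 0.91 kPa -> tan delta ~ 0.81 (solution),
    # 0.19 (air); |E*| ~ 1.9 kPa, near the geometric centre of the
    # 0.81-4.23 kPa pre-culture band so replicate scatter stays inside it.
    "pre_culture_core": PlantParams(
        equilibrium_modulus=1400.0,
        arm_modulus=1050.0,
        arm_viscosity=1050.0 * 0.3 / (2.0 * math.pi * 0.1),  # omega tau_1 = 0.3
        drag_coefficient=1450.0,
        diameter=200e-6,
        rest_length=5e-3,
        passive_stiffening=4.0,
    ),
    # GelMA-like acellular hydrogel fiber (rheometer tan delta ~ 0.2 in air).
    "gelma_fiber": PlantParams(
        equilibrium_modulus=3700.0,
        arm_modulus=2800.0,
        arm_viscosity=2800.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=3800.0,
        diameter=200e-6,
        rest_length=5e-3,
        passive_stiffening=4.0,
    ),
    # Ca-alginate-like fiber (tan delta ~ 0.2 in air, stiffer).
    "ca_alginate_fiber": PlantParams(
        equilibrium_modulus=24000.0,
        arm_modulus=18000.0,
        arm_viscosity=18000.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=25000.0,
        diameter=200e-6,
        rest_length=5e-3,
        passive_stiffening=3.0,
    ),
    # Chitosan-like fiber (nearly elastic in air, tan delta < 0.1).
    "chitosan_fiber": PlantParams(
        equilibrium_modulus=8000.0,
        arm_modulus=2000.0,
        arm_viscosity=2000.0 * 0.15 / (2.0 * math.pi * 0.1),
        drag_coefficient=8500.0,
        diameter=200e-6,
        rest_length=5e-3,
        passive_stiffening=3.0,
    ),
    # Pure cellular bundle after hydrogel degradation: cells hold their
    # water, so drag is negligible and tan delta drops to ~0.2.
    "c_bundle": PlantParams(
        equilibrium_modulus=1500.0,
        arm_modulus=1200.0,
        arm_viscosity=1200.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=0.0,
        diameter=180e-6,
        rest_length=5e-3,
        passive_stiffening=5.0,
    ),
    # Bundle with residual GelMA: intermediate drag keeps tan delta high.
    "cg_bundle": PlantParams(
        equilibrium_modulus=1800.0,
        arm_modulus=1400.0,
        arm_viscosity=1400.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=1400.0,
        diameter=190e-6,
        rest_length=5e-3,
        passive_stiffening=4.5,
    ),
    # Differentiated myobundle: stiffer than its C-bundle parent (the E*
    # increase marks functional recovery), contractile, drag-free.
    # Passive tension at the optimal strain (~5 %) is ~4 uN; the fused
    # tetanic excess above it is ~4.5 uN, so the total force at L_o sits
    # near the 8-9 uN observed for healthy bundles.
    "myobundle": PlantParams(
        equilibrium_modulus=2700.0,
        arm_modulus=2000.0,
        arm_viscosity=2000.0 * 0.35 / (2.0 * math.pi * 0.1),
        drag_coefficient=0.0,
        diameter=180e-6,
        rest_length=5e-3,
        passive_stiffening=6.0,
        active_peak=7.0e-6,
        optimal_strain=0.05,
        active_width=0.03,
        twitch_time=0.15,
    ),
    # Myobundle differentiated inside residual GelMA: generates CF but the
    # hydrogel residue keeps the in-solution tan delta above 0.4.
    "g_myobundle": PlantParams(
        equilibrium_modulus=2200.0,
        arm_modulus=1800.0,
        arm_viscosity=1800.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=1500.0,
        diameter=190e-6,
        rest_length=5e-3,
        passive_stiffening=5.0,
        active_peak=3.5e-6,
        optimal_strain=0.05,
        active_width=0.03,
        twitch_time=0.15,
    ),
    # Stiff, large-diameter core used for force-controlled loading demos:
    # reaches a 15 uN force at ~6% strain, well inside the 30% stretch cap.
    "control_demo_core": PlantParams(
        equilibrium_modulus=3500.0,
        arm_modulus=2600.0,
        arm_viscosity=2600.0 * 0.3 / (2.0 * math.pi * 0.1),
        drag_coefficient=3600.0,
        diameter=300e-6,
        rest_length=5e-3,
        passive_stiffening=3.0,
    ),
}


def plant_preset(name: str) -> PlantParams:
    try:
        return PLANT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown plant preset {name!r}; valid: {sorted(PLANT_PRESETS)}"
        ) from None


# -- condition grids --------------------------------------------------------

#: Outcome partition of the 12 GelMA formulation combinations (degree of
#: methacryloyl substitution x GelMA concentration x photoinitiator): which
#: construct each combination yields after 3 days of culture.  The mapping
#: is a lookup, not a degradation model; combination numbering is abstract.
GELMA12_LABELS: dict[int, str] = {
    1: "cell_sphere",
    2: "cell_sphere",
    3: "cell_sphere",
    4: "c_bundle",
    5: "cell_sphere",
    6: "cell_sphere",
    7: "cg_bundle",
    8: "c_bundle",
    9: "cg_bundle",
    10: "cg_bundle",
    11: "cg_bundle",
    12: "cg_bundle",
}

#: Hypoxia dose grids, uM CoCl2 (11- and 14-condition variants).
COCL2_11_DOSES = tuple(float(d) for d in range(0, 201, 20))
COCL2_14_DOSES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0,
                  120.0, 140.0, 160.0, 180.0, 200.0)

#: Composite-bioink grid: alginate % w/v x CaCl2 % w/v x fiber diameter um.
BIOINK_ALGINATE = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
BIOINK_CACL2 = (0.5, 1.0, 1.5)
BIOINK_DIAMETER = (110.0, 200.0, 300.0)


def _bioink_grid() -> list[dict[str, float]]:
    return [
        {"alginate": a, "cacl2": c, "diameter_um": d}
        for a in BIOINK_ALGINATE
        for c in BIOINK_CACL2
        for d in BIOINK_DIAMETER
    ]


CONDITION_GRIDS: dict[str, list[Mapping[str, object]]] = {
    "gelma12": [{"combination": i} for i in range(1, 13)],
    "cocl2_11": [{"cocl2_uM": d} for d in COCL2_11_DOSES],
    "cocl2_14": [{"cocl2_uM": d} for d in COCL2_14_DOSES],
    "bioink54": _bioink_grid(),
}


def condition_grid(name: str) -> list[Mapping[str, object]]:
    try:
        return [dict(c) for c in CONDITION_GRIDS[name]]
    except KeyError:
        raise KeyError(
            f"unknown condition grid {name!r}; valid: {sorted(CONDITION_GRIDS)}"
        ) from None


# -- condition -> parameter maps --------------------------------------------

#: Relative scatter of the overall stiffness scale (tan delta invariant)
#: and of the loss ratio, per replicate.
STIFFNESS_CV = 0.15
LOSS_CV = 0.08


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _cocl2_state(dose: float, optimized_period: bool) -> SampleState:
    """Dose-dependent myobundle degradation under CoCl2 hypoxia.

    Contractile force declines with dose through a four-strength logistic;
    the half-decline dose sits at 140 uM with the optimized culture
    period (4 d culture + 1 d differentiation) and at 100 uM with the
    original 3+3 d period, so the CF criterion passes through 120 uM only
    after optimization.  Above ~150 uM the hydrogel-to-tissue
    transition also fails: drag (hence tan delta) rises and the bundle
    softens toward an aggregate.
    """
    base = PLANT_PRESETS["myobundle"]
    d50 = 140.0 if optimized_period else 100.0
    cf_scale = 1.0 - _logistic((dose - d50) / 8.0)
    damage = _logistic((dose - 150.0) / 15.0)  # HCT failure fraction
    params = replace(
        base,
        active_peak=base.active_peak * cf_scale,
        drag_coefficient=2000.0 * damage,
        equilibrium_modulus=base.equilibrium_modulus * (1.0 - 0.6 * damage),
        arm_modulus=base.arm_modulus * (1.0 - 0.6 * damage),
        arm_viscosity=base.arm_viscosity * (1.0 - 0.6 * damage),
    )
    label = "myobundle" if damage < 0.5 else "cell_sphere"
    # heavily damaged samples collapse toward aggregates but remain fibrous
    # enough to suspend below 180 uM
    if label == "cell_sphere" and dose < 180.0:
        label = "myobundle"
    return SampleState(label=label, params=params)


def _bioink_state(condition: Mapping[str, object]) -> SampleState:
    """Composite GelMA/Ca-alginate myobundle parameter map.

    Alginate and CaCl2 concentrations set crosslinking quality; fiber
    diameter sets the passive-force scale.  Mid-high alginate with full
    CaCl2 at the 200 um diameter gives the best myotube formation
    (CF-positive, drag-free, large modulus gain after CA degradation).
    """
    a = float(condition["alginate"])
    c = float(condition["cacl2"])
    d_um = float(condition["diameter_um"])
    base = PLANT_PRESETS["myobundle"]

    # myotube formation quality in [0, 1]
    q_a = math.exp(-(((a - 0.75) / 0.15) ** 2))
    q_c = math.exp(-(((c - 1.0) / 0.45) ** 2))
    q_d = {110.0: 0.45, 200.0: 1.0, 300.0: 0.55}[d_um]
    quality = q_a * q_c * q_d

    cf_peak = base.active_peak * (1.6 * quality) * (d_um / 180.0) ** 2
    # residual hydrogel (poor degradation) raises drag; thick fibers retain
    # more residue
    residue = (1.0 - quality) * (0.4 + 0.6 * (d_um / 300.0))
    drag = 2600.0 * residue
    stiffness_gain = 1.0 + 2.5 * quality  # modulus recovery vs degraded state
    params = replace(
        base,
        active_peak=cf_peak,
        drag_coefficient=drag,
        equilibrium_modulus=base.equilibrium_modulus * stiffness_gain * 0.6,
        arm_modulus=base.arm_modulus * stiffness_gain * 0.6,
        arm_viscosity=base.arm_viscosity * stiffness_gain * 0.6,
        diameter=d_um * 1e-6,
    )
    return SampleState(label="ca_myobundle", params=params)


def condition_to_params(
    condition: Mapping[str, object],
    seed: int | None = None,
    replicate: int = 0,
) -> SampleState:
    """Map one condition dict to a (possibly noisy) sample state.

    Recognised keys:

    ``{"combination": 1..12}``
        GelMA formulation grid; label per the observed outcome partition.
    ``{"cocl2_uM": dose, "optimized_period": bool}``
        CoCl2 hypoxia dose on the default myobundle.
    ``{"alginate": a, "cacl2": c, "diameter_um": d}``
        Composite-bioink grid.
    ``{"preset": name}``
        Direct plant preset.

    With ``seed`` given, replicate-level log-normal scatter is applied:
    one common factor on all moduli/viscosities (CV 15 %, leaves tan delta
    untouched) plus a smaller independent factor on the drag (CV 8 %) and
    on the active peak (CV 15 %).  The same ``(seed, replicate, condition)``
    always yields bit-identical parameters.
    """
    condition = dict(condition)
    optimized = bool(condition.pop("optimized_period", True))
    if "combination" in condition:
        combo = int(condition["combination"])
        if combo not in GELMA12_LABELS:
            raise ValueError(
                f"unknown GelMA combination {combo}; valid: 1..12"
            )
        label = GELMA12_LABELS[combo]
        preset = {
            "cell_sphere": "pre_culture_core",  # geometry placeholder
            "c_bundle": "c_bundle",
            "cg_bundle": "cg_bundle",
        }[label]
        state = SampleState(label=label, params=PLANT_PRESETS[preset])
    elif "cocl2_uM" in condition:
        state = _cocl2_state(float(condition["cocl2_uM"]), optimized)
    elif "alginate" in condition:
        missing = {"alginate", "cacl2", "diameter_um"} - condition.keys()
        if missing:
            raise ValueError(f"bioink condition missing keys: {sorted(missing)}")
        if float(condition["alginate"]) not in BIOINK_ALGINATE:
            raise ValueError(
                f"unknown alginate level {condition['alginate']}; "
                f"valid: {BIOINK_ALGINATE}"
            )
        if float(condition["cacl2"]) not in BIOINK_CACL2:
            raise ValueError(
                f"unknown CaCl2 level {condition['cacl2']}; valid: {BIOINK_CACL2}"
            )
        if float(condition["diameter_um"]) not in BIOINK_DIAMETER:
            raise ValueError(
                f"unknown diameter {condition['diameter_um']}; "
                f"valid: {BIOINK_DIAMETER}"
            )
        state = _bioink_state(condition)
    elif "preset" in condition:
        name = str(condition["preset"])
        state = SampleState(
            label="pre_culture_core" if "core" in name or "fiber" in name
            else ("myobundle" if "myobundle" in name else "c_bundle"),
            params=plant_preset(name),
        )
    else:
        raise ValueError(
            "unrecognised condition keys "
            f"{sorted(condition)}; expected one of: combination / cocl2_uM / "
            "alginate+cacl2+diameter_um / preset"
        )

    if seed is None:
        return state

    key = repr(sorted((k, repr(v)) for k, v in condition.items())).encode()
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31),
                                spawn_key=(zlib.crc32(key), replicate))
    rng = np.random.default_rng(ss)
    scale = float(rng.lognormal(0.0, STIFFNESS_CV))
    drag_scale = float(rng.lognormal(0.0, LOSS_CV))
    cf_scale = float(rng.lognormal(0.0, STIFFNESS_CV))
    p = state.params
    noisy = replace(
        p,
        equilibrium_modulus=p.equilibrium_modulus * scale,
        arm_modulus=p.arm_modulus * scale,
        arm_viscosity=p.arm_viscosity * scale,
        drag_coefficient=p.drag_coefficient * scale * drag_scale,
        active_peak=p.active_peak * cf_scale,
    )
    return replace(state, params=noisy)
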