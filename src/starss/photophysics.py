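"""Orientation-resolved photoswitching kinetics of reversibly switchable FPs.

A reversibly switchable fluorescent protein (rsFP) such as rsEGFP2 is cycled
between a fluorescent ON state and a dark OFF state with 405-nm (OFF -> ON)
and 488-nm (ON -> OFF, simultaneously exciting fluorescence) light.  All
light-driven rates follow the one-photon photoselection law: for linear
polarization along a unit vector e the rate is proportional to (mu . e)^2
where mu is the absorption dipole; for circular polarization in the plane
perpendicular to the optical axis z it is proportional to (1 - mu_z^2)/2.

The module couples these orientation-dependent rate kernels to rotational
diffusion (see :mod:`starss.sphere`) via Strang operator splitting, and
computes polarization-resolved emission fluxes into the parallel (x) and
perpendicular (y) detection channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.optimize import brentq
from scipy.special import exprel

from .sizes import EnvironmentParams, tau_from_diameter
from .sphere import OrientationField, SphereGrid

__all__ = [
    "Illumination",
    "FluorophoreModel",
    "RotorModel",
    "excitation_rate_kernel",
    "detection_weights",
    "evolve_populations",
    "onswitch_fraction",
    "calibrate_power_for_on_fraction",
]

_ROLES = ("switch_on_405", "probe_488")
_POLARIZATIONS = ("linear", "circular")


def _p2(x):
    return 0.5 * (3.0 * x * x - 1.0)


@dataclass(frozen=True)
class Illumination:
    """One illumination beam: role, polarization, power density and duration.

    ``role`` selects which photo-transition the beam drives
    ('switch_on_405' drives OFF->ON; 'probe_488' drives ON->OFF and excites
    fluorescence).  ``axis`` is the linear polarization direction in the
    sample plane (ignored for circular polarization, which lies in the plane
    perpendicular to the optical axis z).
    """

    role: str
    polarization: str = "linear"
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    power_density: float = 0.0  # W/cm^2
    duration: float = 1.0e-6  # s

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.polarization not in _POLARIZATIONS:
            raise ValueError(
                f"polarization must be one of {_POLARIZATIONS}, got {self.polarization!r}"
            )
        if self.power_density < 0:
            raise ValueError("power_density must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.polarization == "linear":
            ax = np.asarray(self.axis, dtype=float)
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError("linear polarization axis must be a unit vector")
            if abs(ax[2]) > 1e-9:
                raise ValueError(
                    "linear polarization axis must lie in the sample plane (z = 0)"
                )


@dataclass(frozen=True)
class FluorophoreModel:
    """Switching and brightness parameters of an rsFP.

    Rates with suffix ``_peak`` are per unit power density (1/s per W/cm^2)
    for a dipole parallel to the polarization.  ``brightness`` is the expected
    number of detected photons per excitation event (quantum yield times
    collection efficiency).  ``dipole_angle_abs_em`` is the angle between
    absorption and emission dipoles; 0 means collinear.  A finite
    ``intermediate_rate`` enables a dark ground-state shelving intermediate
    (decay rate ``intermediate_rate``, equal branching back to ON and on to
    OFF), making high-power OFF-switching bi-exponential with a slow tail
    at about half that rate.
    """

    k_on_peak: float
    k_off_peak: float
    k_exc_peak: float
    brightness: float
    dipole_angle_abs_em: float = 0.0
    intermediate_rate: float | None = None
    bleach_rate: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        for attr in ("k_on_peak", "k_off_peak", "k_exc_peak", "brightness", "bleach_rate"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be nonnegative")
        if not 0.0 <= self.dipole_angle_abs_em <= np.pi / 2:
            raise ValueError("dipole_angle_abs_em must lie in [0, pi/2]")
        if self.intermediate_rate is not None and self.intermediate_rate <= 0:
            raise ValueError("intermediate_rate must be positive when set")

    @classmethod
    def from_preset(cls, name: str) -> "FluorophoreModel":
        """Load a shipped fluorophore preset (``rsEGFP2``, ``DronpaM159T``)."""
        try:
            text = (
                resources.files("starss").joinpath(f"presets/{name}.json").read_text()
            )
        except FileNotFoundError as exc:
            raise KeyError(f"unknown fluorophore preset {name!r}") from exc
        data = json.loads(text)
        data.pop("provenance", None)
        return cls(name=name, **data)

    def with_intermediate(self, rate: float) -> "FluorophoreModel":
        return replace(self, intermediate_rate=rate)


@dataclass(frozen=True)
class RotorModel:
    """Rigid-rotor description: rotational diffusion plus a static fraction.

    Exactly one of ``diffusion_coefficient`` (D_r, 1/s) or
    ``rotational_correlation_time`` (tau_rot = 1/(6 D_r), s) must be given.
    ``static_fraction`` is the sub-population with D_r = 0 (immobile or very
    large objects), which contributes a constant anisotropy offset.
    """

    diffusion_coefficient: float | None = None
    rotational_correlation_time: float | None = None
    static_fraction: float = 0.0

    def __post_init__(self):
        if (self.diffusion_coefficient is None) == (
            self.rotational_correlation_time is None
        ):
            raise ValueError(
                "give exactly one of diffusion_coefficient or rotational_correlation_time"
            )
        if self.diffusion_coefficient is not None and self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be nonnegative")
        if (
            self.rotational_correlation_time is not None
            and self.rotational_correlation_time <= 0
        ):
            raise ValueError("rotational_correlation_time must be positive")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ValueError("static_fraction must lie in [0, 1]")

    @property
    def D(self) -> float:
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        return 1.0 / (6.0 * self.rotational_correlation_time)

    @property
    def tau_rot(self) -> float:
        if self.rotational_correlation_time is not None:
            return self.rotational_correlation_time
        if self.diffusion_coefficient == 0.0:
            return np.inf
        return 1.0 / (6.0 * self.diffusion_coefficient)

    @classmethod
    def from_diameter(
        cls,
        diameter: float,
        env: EnvironmentParams | None = None,
        static_fraction: float = 0.0,
    ) -> "RotorModel":
        return cls(
            rotational_correlation_time=tau_from_diameter(diameter, env),
            static_fraction=static_fraction,
        )

    @classmethod
    def static(cls) -> "RotorModel":
        return cls(diffusion_coefficient=0.0)


# ----------------------------------------------------------------------
# rate kernels
# ----------------------------------------------------------------------

def excitation_rate_kernel(
    dipole_orientation: np.ndarray, illumination: Illumination, peak_rate: float
) -> np.ndarray:
    """Photoselection rate for dipole(s) mu under an illumination beam.

    Linear polarization along e:  rate = peak * P * (mu . e)^2.
    Circular in the plane perpendicular to z:  rate = peak * P * (1 - mu_z^2)/2.
    """
    if peak_rate < 0:
        raise ValueError("peak_rate must be nonnegative")
    mu = np.asarray(dipole_orientation, dtype=float)
    norms = np.linalg.norm(mu, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("dipole orientation must be a unit vector")
    scale = peak_rate * illumination.power_density
    if illumination.polarization == "linear":
        ax = np.asarray(illumination.axis, dtype=float)
        proj = mu @ ax
        out = scale * proj * proj
    else:
        out = scale * 0.5 * (1.0 - mu[..., 2] ** 2)
    return out


def detection_weights(
    grid: SphereGrid, dipole_angle_abs_em: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation detection weights for the x (parallel) and y channels.

    For an emission dipole at angle beta from the absorption dipole
    (azimuthally averaged around it), the probability weight for an analyzer
    along e is w = (1 + 2 P2(cos beta) P2(mu . e)) / 2, which reduces to
    (3/2)(mu . e)^2 for collinear dipoles and is normalized so an isotropic
    emitter splits its ``brightness`` photons equally between both channels.
    """
    depol = _p2(np.cos(dipole_angle_abs_em))
    mu = grid.mu
    w_par = 0.5 * (1.0 + 2.0 * depol * _p2(mu[..., 0]))
    w_perp = 0.5 * (1.0 + 2.0 * depol * _p2(mu[..., 1]))
    return w_par, w_perp


# ----------------------------------------------------------------------
# reaction steps (exact per-cell solutions of the linear kinetics)
# ----------------------------------------------------------------------

def _react_switch_on(field: OrientationField, rate_on: np.ndarray, dt: float) -> None:
    """OFF -> ON transfer at orientation-dependent rate, exact in dt (in place)."""
    off = field.state("off")
    on = field.state("on")
    transfer = off * -np.expm1(-rate_on * dt)
    off -= transfer
    on += transfer


#: branching of the dark intermediate: half returns to ON, half completes
#: the switch to OFF (equal branching; see the methods note)
_INT_RETURN_FRACTION = 0.5


def _react_probe(
    field: OrientationField,
    k_off_map: np.ndarray,
    k_exc_map: np.ndarray,
    fluor: FluorophoreModel,
    w_par: np.ndarray,
    w_perp: np.ndarray,
    dt: float,
) -> tuple[float, float]:
    """ON (-> INTERMEDIATE) -> OFF kinetics plus emission, exact in dt.

    Returns expected detected photons (parallel, perpendicular) in the step.
    Closed-form solution of the per-cell linear system; emission integrates
    the fluorescent ON population analytically over the step.

    With the intermediate enabled, OFF-switching shelves molecules into a
    dark ground-state intermediate (ON -> INT at the 488-driven rate) that
    decays at ``intermediate_rate``, returning to ON or completing the
    switch to OFF with equal probability.  At high probe power this makes
    the observed fluorescence decay bi-exponential: a dominant fast
    component at the shelving rate plus a weak slow tail governed by the
    intermediate's decay.
    """
    grid = field.grid
    on = field.state("on")
    off = field.state("off")
    c = fluor.bleach_rate

    if fluor.intermediate_rate is None:
        beta = k_off_map + c  # total ON depletion rate
        int_on = on * dt * exprel(-beta * dt)  # integral of n_ON over the step
        on_new = on * np.exp(-beta * dt)
        depleted = on - on_new
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_off = np.where(beta > 0, k_off_map / np.where(beta == 0, 1.0, beta), 0.0)
        off += depleted * frac_off
        if c > 0:
            field.state("bleached")[...] += depleted * (1.0 - frac_off)
        field.populations["on"] = on_new
    else:
        g = fluor.intermediate_rate
        phi = _INT_RETURN_FRACTION
        inter = field.state("intermediate")
        b = k_off_map
        # per-cell 2x2 linear system  d/dt (ON, INT) = A (ON, INT)
        #   A = [[-(b+c), phi*g], [b, -g]]
        tr = -(b + c + g)
        det = (b + c) * g - phi * g * b
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        lam1 = 0.5 * (tr + disc)  # slow eigenvalue (closer to zero)
        lam2 = 0.5 * (tr - disc)
        e1 = np.exp(lam1 * dt)
        e2 = np.exp(lam2 * dt)
        # integral of e^{lam t} over the step, stable for lam -> 0
        i1 = dt * exprel(lam1 * dt)
        i2 = dt * exprel(lam2 * dt)
        gap = np.where(disc > 0, disc, 1.0)
        # propagator entries via the spectral decomposition of A
        a11, a12, a21, a22 = -(b + c), phi * g, b, -g

        def prop(e_a, e_b):
            # matrix function f(A) with f(lam1)=e_a, f(lam2)=e_b
            f11 = (e_a * (a11 - lam2) - e_b * (a11 - lam1)) / gap
            f12 = (e_a - e_b) * a12 / gap
            f21 = (e_a - e_b) * a21 / gap
            f22 = (e_a * (a22 - lam2) - e_b * (a22 - lam1)) / gap
            return f11, f12, f21, f22

        p11, p12, p21, p22 = prop(e1, e2)
        q11, q12, q21, q22 = prop(i1, i2)
        on_new = p11 * on + p12 * inter
        inter_new = p21 * on + p22 * inter
        int_on = q11 * on + q12 * inter  # time-integral of n_ON
        int_inter = q21 * on + q22 * inter
        off += (1.0 - phi) * g * int_inter
        if c > 0:
            field.state("bleached")[...] += c * int_on
        field.populations["on"] = on_new
        field.populations["intermediate"] = inter_new

    emit = fluor.brightness * k_exc_map * int_on
    photons_par = grid.integrate(emit * w_par)
    photons_perp = grid.integrate(emit * w_perp)
    return photons_par, photons_perp


def evolve_populations(
    field: OrientationField,
    illumination: Illumination,
    fluor: FluorophoreModel,
    rotor: RotorModel,
    dt: float,
    detection: str = "polarized",
) -> tuple[OrientationField, tuple[float, float]]:
    """One Strang-split step: diffuse dt/2, react dt, diffuse dt/2.

    Returns the evolved field and the emitted flux (photons/s) into the
    parallel and perpendicular detection channels during the step (nonzero
    only under 'probe_488' illumination).  ``detection='unpolarized'``
    removes the analyzers: each channel collects half of every emitted
    photon regardless of dipole orientation (single-detector readout).
    """
    if detection not in ("polarized", "unpolarized"):
        raise ValueError("detection must be 'polarized' or 'unpolarized'")
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = field.grid
    D = rotor.D

    def half_diffuse(f: OrientationField) -> OrientationField:
        if D == 0.0:
            return f.copy()
        return OrientationField(
            grid, {k: grid.diffuse(v, D, dt / 2.0) for k, v in f.populations.items()}
        )

    out = half_diffuse(field)
    photons = (0.0, 0.0)
    if illumination.role == "switch_on_405":
        rate = excitation_rate_kernel(grid.mu, illumination, fluor.k_on_peak)
        _react_switch_on(out, rate, dt)
    elif illumination.role == "probe_488":
        k_off_map = excitation_rate_kernel(grid.mu, illumination, fluor.k_off_peak)
        k_exc_map = excitation_rate_kernel(grid.mu, illumination, fluor.k_exc_peak)
        if detection == "polarized":
            w_par, w_perp = detection_weights(grid, fluor.dipole_angle_abs_em)
        else:
            w_par = w_perp = np.full((grid.n_theta, grid.n_phi), 0.5)
        photons = _react_probe(out, k_off_map, k_exc_map, fluor, w_par, w_perp, dt)
    else:  # pragma: no cover - Illumination validates roles
        raise ValueError(f"unsupported illumination role {illumination.role!r}")
    out = half_diffuse(out)
    return out, (photons[0] / dt, photons[1] / dt)


# ----------------------------------------------------------------------
# pulse calibration
# ----------------------------------------------------------------------

def onswitch_fraction(
    pulse: Illumination, fluor: FluorophoreModel, grid: SphereGrid | None = None
) -> float:
    """Orientation-averaged ON fraction after one 405-nm pulse.

    Starting from a fully OFF, isotropic population:
    f = (1/4pi) * integral (1 - exp(-k_on(Omega) * duration)) dOmega.
    Monotone in fluence and saturating at 1.
    """
    if pulse.role != "switch_on_405":
        raise ValueError("onswitch_fraction requires a 'switch_on_405' pulse")
    grid = grid or SphereGrid(32, 64)
    rate = excitation_rate_kernel(grid.mu, pulse, fluor.k_on_peak)
    frac = -np.expm1(-rate * pulse.duration)
    return grid.integrate(frac) / (4.0 * np.pi)


def calibrate_power_for_on_fraction(
    target_fraction: float,
    duration: float,
    fluor: FluorophoreModel,
    polarization: str = "linear",
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0),
    grid: SphereGrid | None = None,
) -> Illumination:
    """405-nm pulse whose orientation-averaged ON fraction equals the target.

    Inverts :func:`onswitch_fraction` over power density by root finding.
    Used to realize the published operating points (e.g. ~10% ON-switched
    for the photoselection pulse, ~50% for the delayed-pulse-pair scheme).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie strictly between 0 and 1")
    if fluor.k_on_peak <= 0:
        raise ValueError("fluorophore has zero ON-switching rate")
    grid = grid or SphereGrid(32, 64)

    def frac_at(power: float) -> float:
        pulse = Illumination(
            role="switch_on_405",
            polarization=polarization,
            axis=axis,
            power_density=power,
            duration=duration,
        )
        return onswitch_fraction(pulse, fluor, grid)

    # bracket the root in log-power
    lo, hi = 1e-12, 1.0
    while frac_at(hi) < target_fraction:
        hi *= 10.0
        if hi > 1e18:
            raise RuntimeError("could not bracket the requested ON fraction")
    power = brentq(lambda p: frac_at(p) - target_fraction, lo, hi, xtol=1e-300, rtol=1e-12)
    return Illumination(
        role="switch_on_405",
        polarization=polarization,
        axis=axis,
        power_density=power,
        duration=duration,
    )
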