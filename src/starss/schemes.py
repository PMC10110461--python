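"""The three STARSS pulse schemes and the polarization-resolved detector model.

Scheme 1 (``method1``): a short linearly polarized 405-nm pulse photoselects
a cos^2-distributed subset of molecules into the ON state (~10% by default);
a long circularly polarized 488-nm probe reads their fluorescence in two
orthogonal analyzer channels while rotational diffusion randomizes the
selected orientations, so the anisotropy r(t) decays with the rotational
correlation time.

Scheme 2 (``method2``): all molecules start ON (saturating circular 405-nm
activation); a linearly polarized 488-nm probe simultaneously excites and
OFF-switches, burning an orientation hole.  Whether the anisotropy decays is
set by the competition between OFF-switching and rotation.

Scheme 3 (``method3``): two linearly polarized ~50-ns 405-nm pulses separated
by a variable delay, then a circular 488-nm readout.  The total signal,
normalized to a single-pulse reference, increases with delay when rotation
refills the orientation hole left by the first pulse between the pulses.

Simulations return either noiseless expectations or Poisson-sampled photon
counts (bit-reproducible given a seed).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from .photophysics import (
    FluorophoreModel,
    Illumination,
    RotorModel,
    calibrate_power_for_on_fraction,
    evolve_populations,
)
from .sizes import EnvironmentParams
from .sphere import OrientationField, SphereGrid, propagate_rotation

__all__ = [
    "SchemeSegment",
    "PulseScheme",
    "DetectorPair",
    "DecayCurve",
    "ModulationCurve",
    "simulate_method1",
    "simulate_method2",
    "simulate_method3",
    "simulate_scheme",
    "sweep_method3_on_fraction",
    "estimate_background",
    "default_grid",
]

MIN_BIN_WIDTH = 10e-9  # hardware-like floor on photon-counting bins


def default_grid() -> SphereGrid:
    """Default orientation grid (64 Gauss-Legendre x 128 azimuthal nodes)."""
    return SphereGrid(64, 128)


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one top-level seed."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SchemeSegment:
    """One stage of a pulse scheme: illumination (or dark) and gating."""

    duration: float
    illumination: Illumination | None = None
    detect: bool = False
    bin_width: float | None = None
    label: str = ""
    detection: str = "polarized"  # or 'unpolarized' (no analyzers)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.detection not in ("polarized", "unpolarized"):
            raise ValueError("detection must be 'polarized' or 'unpolarized'")
        if self.detect:
            if self.bin_width is None:
                raise ValueError("a detecting segment needs a bin_width")
            if self.bin_width < MIN_BIN_WIDTH:
                raise ValueError(f"bin_width must be >= {MIN_BIN_WIDTH:g} s")
            n = round(self.duration / self.bin_width)
            if n < 1 or abs(self.duration - n * self.bin_width) > self.bin_width:
                raise ValueError("bin_width must divide the duration to within one bin")

    @property
    def n_bins(self) -> int:
        return round(self.duration / self.bin_width) if self.detect else 0


@dataclass(frozen=True)
class PulseScheme:
    """Ordered illumination/detection program, repeated ``cycles`` times."""

    segments: tuple[SchemeSegment, ...]
    preset: str = "custom"
    cycles: int = 1

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a scheme needs at least one segment")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.cycles > 1 and self.segments[-1].label != "reset":
            raise ValueError("multi-cycle schemes must end with a reset segment")


@dataclass(frozen=True)
class DetectorPair:
    """Two analyzer channels with gain imbalance G and additive count rates.

    G multiplies the parallel channel's gain relative to the perpendicular
    one, so an isotropic sample yields mean(I_par)/mean(I_perp) = G.
    ``background_rate`` models cross-talk fluorescence (counts/s/channel);
    ``dark_rate`` the detector dark counts.
    """

    g_factor: float = 1.0
    background_rate: float = 0.0
    dark_rate: float = 0.0

    def __post_init__(self):
        if self.g_factor <= 0:
            raise ValueError("g_factor must be positive")
        if self.background_rate < 0 or self.dark_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class DecayCurve:
    """Time-binned counts in the parallel and perpendicular channels."""

    bin_centers: np.ndarray
    counts_parallel: np.ndarray
    counts_perpendicular: np.ndarray
    bin_widths: np.ndarray
    segment_labels: np.ndarray  # per-bin label ('probe', 'reset', ...)
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        n = len(self.bin_centers)
        for arr in (self.counts_parallel, self.counts_perpendicular, self.bin_widths):
            if len(arr) != n:
                raise ValueError("all per-bin arrays must have equal length")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if np.any(self.counts_parallel < 0) or np.any(self.counts_perpendicular < 0):
            raise ValueError("counts must be nonnegative")

    def select(self, label: str) -> "DecayCurve":
        """Sub-curve restricted to bins of one segment label."""
        m = self.segment_labels == label
        if not m.any():
            raise ValueError(f"no bins labelled {label!r}")
        return DecayCurve(
            self.bin_centers[m],
            self.counts_parallel[m],
            self.counts_perpendicular[m],
            self.bin_widths[m],
            self.segment_labels[m],
            dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.bin_centers,
                "bin_width_s": self.bin_widths,
                "counts_par": self.counts_parallel,
                "counts_perp": self.counts_perpendicular,
                "segment": self.segment_labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecayCurve":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            df["time_s"].to_numpy(),
            df["counts_par"].to_numpy(),
            df["counts_perp"].to_numpy(),
            df["bin_width_s"].to_numpy(),
            df["segment"].to_numpy(dtype=object),
            meta,
        )


@dataclass
class ModulationCurve:
    """Delay-series total counts of scheme 3, with single-pulse reference."""

    delays: np.ndarray
    total_counts: np.ndarray
    reference_counts: float
    counts_parallel: np.ndarray | None = None
    counts_perpendicular: np.ndarray | None = None
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if len(self.delays) != len(self.total_counts):
            raise ValueError("delays and total_counts must have equal length")
        if self.reference_counts <= 0:
            raise ValueError("reference_counts must be positive")

    @property
    def normalized(self) -> np.ndarray:
        return np.asarray(self.total_counts, dtype=float) / self.reference_counts

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {"delay_s": self.delays, "counts": self.total_counts, "norm_counts": self.normalized}
        ).to_csv(path, index=False)
        meta = dict(self.metadata, reference_counts=self.reference_counts)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=str)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModulationCurve":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        ref = float(meta.pop("reference_counts"))
        return cls(df["delay_s"].to_numpy(), df["counts"].to_numpy(), ref, metadata=meta)


# ----------------------------------------------------------------------
# core expectation engine
# ----------------------------------------------------------------------

def _max_switch_rate(ill: Illumination, fluor: FluorophoreModel) -> float:
    peak = fluor.k_on_peak if ill.role == "switch_on_405" else fluor.k_off_peak
    geom = 1.0 if ill.polarization == "linear" else 0.5
    rate = peak * ill.power_density * geom + fluor.bleach_rate
    if ill.role == "probe_488" and fluor.intermediate_rate is not None:
        rate = max(rate, fluor.intermediate_rate)
    return rate


def _simulate_expectation(
    segments: tuple[SchemeSegment, ...],
    fluor: FluorophoreModel,
    D: float,
    grid: SphereGrid,
):
    """Noiseless single-cycle expectation for one rigid-rotor component.

    Returns (bin_centers, widths, labels, par, perp, final_field) with
    per-bin expected signal photons, detector gains not applied.
    """
    return _simulate_with_field(segments, fluor, D, grid, OrientationField.fully_off(grid))


def simulate_scheme(
    scheme: PulseScheme,
    fluor: FluorophoreModel,
    rotor: RotorModel,
    detector: DetectorPair | None = None,
    grid: SphereGrid | None = None,
    mode: str = "expectation",
    seed: int | None = None,
    initial_on_fraction: float = 0.0,
) -> DecayCurve:
    """Run an arbitrary pulse scheme and return the detected decay record.

    ``mode='expectation'`` returns noiseless expected counts;
    ``mode='poisson'`` draws bin-level Poisson counts (signal, cross-talk
    background and dark counts as independent streams) from them.  A single
    cycle is propagated and expectations are scaled by ``scheme.cycles``,
    assuming the trailing reset returns the system to its initial state.
    ``initial_on_fraction`` starts the cycle with that isotropic fraction of
    molecules already ON (ideal saturating activation).
    """
    if mode not in ("expectation", "poisson"):
        raise ValueError("mode must be 'expectation' or 'poisson'")
    if not 0.0 <= initial_on_fraction <= 1.0:
        raise ValueError("initial_on_fraction must lie in [0, 1]")
    detector = detector or DetectorPair()
    grid = grid or default_grid()

    def initial_field() -> OrientationField:
        f = OrientationField.fully_off(grid)
        if initial_on_fraction > 0.0:
            f.state("on")[...] = f.state("off") * initial_on_fraction
            f.state("off")[...] *= 1.0 - initial_on_fraction
        return f

    centers, widths, labels, par, perp, final = _simulate_with_field(
        scheme.segments, fluor, rotor.D, grid, initial_field()
    )
    if rotor.static_fraction > 0.0:
        _, _, _, par_s, perp_s, _ = _simulate_with_field(
            scheme.segments, fluor, 0.0, grid, initial_field()
        )
        fs = rotor.static_fraction
        par = (1.0 - fs) * par + fs * par_s
        perp = (1.0 - fs) * perp + fs * perp_s

    probe_bins = labels == "probe"
    if probe_bins.any():
        sig = par + perp
        first = np.flatnonzero(probe_bins)[0]
        rest = sig[probe_bins].sum()
        if rest > 0 and sig[first] / rest > 0.99:
            warnings.warn(
                "probe depletes >99% of the signal within the first bin; "
                "the decay is undersampled",
                stacklevel=2,
            )

    cyc = scheme.cycles
    exp_par = detector.g_factor * par * cyc
    exp_perp = perp * cyc
    extra = (detector.background_rate + detector.dark_rate) * widths * cyc

    meta = {
        "preset": scheme.preset,
        "cycles": cyc,
        "mode": mode,
        "seed": seed,
        "g_factor": detector.g_factor,
        "background_rate": detector.background_rate,
        "dark_rate": detector.dark_rate,
        "grid": [grid.n_theta, grid.n_phi],
        "initial_on_fraction": initial_on_fraction,
        "residual_on_mass": final.mass_by_state().get("on", 0.0),
    }
    if mode == "expectation":
        return DecayCurve(centers, exp_par + extra, exp_perp + extra, widths, labels, meta)
    rng_sig = substream(seed, "signal")
    rng_bg = substream(seed, "background")
    rng_dark = substream(seed, "dark")
    bg = detector.background_rate * widths * cyc
    dark = detector.dark_rate * widths * cyc
    cp = rng_sig.poisson(exp_par) + rng_bg.poisson(bg) + rng_dark.poisson(dark)
    cq = rng_sig.poisson(exp_perp) + rng_bg.poisson(bg) + rng_dark.poisson(dark)
    return DecayCurve(centers, cp, cq, widths, labels, meta)


# ----------------------------------------------------------------------
# scheme presets
# ----------------------------------------------------------------------

_CALIBRATION_CACHE: dict[tuple, Illumination] = {}


def _calibrated_pulse(
    fluor: FluorophoreModel,
    on_fraction: float,
    duration: float,
    polarization: str = "linear",
) -> Illumination:
    key = (fluor, on_fraction, duration, polarization)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = calibrate_power_for_on_fraction(
            on_fraction, duration, fluor, polarization=polarization
        )
    return _CALIBRATION_CACHE[key]


def _resolve_rotor(rotor, env: EnvironmentParams | None) -> RotorModel:
    if isinstance(rotor, RotorModel):
        return rotor
    return RotorModel.from_diameter(float(rotor), env)


def _default_probe(
    polarization: str, power_density: float = 100.0, duration: float = 1e-3
) -> Illumination:
    return Illumination(
        role="probe_488",
        polarization=polarization,
        power_density=power_density,
        duration=duration,
    )


def _reset_segment(fluor: FluorophoreModel, detect: bool, bin_width: float) -> SchemeSegment:
    # strong circular 488 pulse that drives everything back to OFF
    if fluor.k_off_peak <= 0:
        raise ValueError("cannot build a reset segment: fluorophore never OFF-switches")
    power = 2000.0
    duration = 20.0 / (fluor.k_off_peak * power * 0.5)
    if detect:
        duration = max(duration, 50 * bin_width)
        duration = np.ceil(duration / bin_width) * bin_width
    ill = Illumination(
        role="probe_488", polarization="circular", power_density=power, duration=duration
    )
    return SchemeSegment(
        duration, ill, detect=detect, bin_width=bin_width if detect else None, label="reset"
    )


def method1_scheme(
    fluor: FluorophoreModel,
    pulse_405: Illumination | None = None,
    probe_488: Illumination | None = None,
    bin_width: float = 2e-6,
    cycles: int = 1,
    include_reset: bool = False,
    on_fraction: float = 0.10,
) -> tuple[PulseScheme, Illumination, Illumination]:
    """Scheme-1 preset: 250-ns linear 405-nm pulse (~10% ON), circular probe."""
    if pulse_405 is None:
        pulse_405 = _calibrated_pulse(fluor, on_fraction, 250e-9)
    if pulse_405.polarization != "linear":
        raise ValueError("scheme 1 photoselects with a linearly polarized 405-nm pulse")
    if probe_488 is None:
        probe_488 = _default_probe("circular")
    if probe_488.polarization != "circular":
        raise ValueError("scheme 1 probes with circularly polarized 488-nm light")
    segments = [
        SchemeSegment(pulse_405.duration, pulse_405, label="pulse405"),
        SchemeSegment(probe_488.duration, probe_488, detect=True, bin_width=bin_width, label="probe"),
    ]
    if include_reset or cycles > 1:
        segments.append(_reset_segment(fluor, detect=include_reset, bin_width=bin_width))
    return PulseScheme(tuple(segments), preset="method1", cycles=cycles), pulse_405, probe_488


def simulate_method1(
    fluor: FluorophoreModel,
    rotor: RotorModel | float,
    env: EnvironmentParams | None = None,
    detector: DetectorPair | None = None,
    pulse_405: Illumination | None = None,
    probe_488: Illumination | None = None,
    cycles: int = 1,
    seed: int | None = None,
    grid: SphereGrid | None = None,
    mode: str = "expectation",
    bin_width: float = 2e-6,
    include_reset: bool = False,
) -> DecayCurve:
    """STARSS scheme 1: ON-switching photoselection, circular probe.

    ``rotor`` may be a :class:`RotorModel` or a hydrodynamic diameter in
    meters (converted through ``env`` by the Stokes-Einstein-Debye relation).
    """
    rotor = _resolve_rotor(rotor, env)
    scheme, _, _ = method1_scheme(
        fluor, pulse_405, probe_488, bin_width, cycles, include_reset
    )
    return simulate_scheme(scheme, fluor, rotor, detector, grid, mode, seed)


def simulate_method2(
    fluor: FluorophoreModel,
    rotor: RotorModel | float,
    env: EnvironmentParams | None = None,
    detector: DetectorPair | None = None,
    activation_405: Illumination | None = None,
    probe_488: Illumination | None = None,
    cycles: int = 1,
    seed: int | None = None,
    grid: SphereGrid | None = None,
    mode: str = "expectation",
    bin_width: float = 2e-6,
    include_reset: bool = False,
    on_fraction: float = 1.0,
) -> DecayCurve:
    """STARSS scheme 2: photoselection during OFF-switching, linear probe.

    By default the circular activation is taken as ideally saturating (the
    cycle starts with 100% of molecules ON and isotropic); pass an explicit
    ``activation_405`` to simulate a finite activation pulse instead.
    """
    rotor = _resolve_rotor(rotor, env)
    grid = grid or default_grid()
    if probe_488 is None:
        probe_488 = _default_probe("linear")
    if probe_488.polarization != "linear":
        raise ValueError("scheme 2 probes with linearly polarized 488-nm light")
    segments = []
    if activation_405 is not None:
        if activation_405.polarization != "circular":
            raise ValueError("scheme 2 activates with circularly polarized 405-nm light")
        segments.append(SchemeSegment(activation_405.duration, activation_405, label="activation"))
    segments.append(
        SchemeSegment(probe_488.duration, probe_488, detect=True, bin_width=bin_width, label="probe")
    )
    if include_reset or cycles > 1:
        segments.append(_reset_segment(fluor, detect=include_reset, bin_width=bin_width))
    scheme = PulseScheme(tuple(segments), preset="method2", cycles=cycles)
    if activation_405 is not None:
        return simulate_scheme(scheme, fluor, rotor, detector, grid, mode, seed)
    # ideal saturating activation: start fully ON (scaled by on_fraction)
    return simulate_scheme(
        scheme, fluor, rotor, detector, grid, mode, seed, initial_on_fraction=on_fraction
    )


def _simulate_with_field(segments, fluor, D, grid, f):
    """Strang-split expectation run of a segment list from a given field."""
    rotor = RotorModel(diffusion_coefficient=D)
    t = 0.0
    centers, widths, labels, par, perp = [], [], [], [], []
    for seg in segments:
        if seg.illumination is None:
            if seg.detect:
                nb = seg.n_bins
                bw = seg.duration / nb
                for i in range(nb):
                    centers.append(t + (i + 0.5) * bw)
                    widths.append(bw)
                    labels.append(seg.label or "dark")
                    par.append(0.0)
                    perp.append(0.0)
            if D > 0:
                f = propagate_rotation(f, D, seg.duration)
            t += seg.duration
            continue
        max_rate = _max_switch_rate(seg.illumination, fluor)
        dt_max = 0.1 / max_rate if max_rate > 0 else np.inf
        # the reaction step is exact for constant rates, so sub-stepping is
        # only needed to interleave rotation; a segment during which the
        # rotor barely moves can be taken in one step regardless of rate
        dt_rot = 0.02 / (6.0 * D) if D > 0 else np.inf
        if dt_rot >= seg.duration:
            dt_max = seg.duration
        if seg.detect:
            nb = seg.n_bins
            bw = seg.duration / nb
            for i in range(nb):
                nsub = max(1, int(np.ceil(bw / dt_max)))
                dt = bw / nsub
                p = q = 0.0
                for _ in range(nsub):
                    f, (fx, fy) = evolve_populations(
                        f, seg.illumination, fluor, rotor, dt, detection=seg.detection
                    )
                    p += fx * dt
                    q += fy * dt
                centers.append(t + (i + 0.5) * bw)
                widths.append(bw)
                labels.append(seg.label or seg.illumination.role)
                par.append(p)
                perp.append(q)
        else:
            nsub = max(1, int(np.ceil(seg.duration / dt_max)))
            dt = seg.duration / nsub
            for _ in range(nsub):
                f, _ = evolve_populations(f, seg.illumination, fluor, rotor, dt)
        t += seg.duration
    return (
        np.asarray(centers),
        np.asarray(widths),
        np.asarray(labels, dtype=object),
        np.asarray(par),
        np.asarray(perp),
        f,
    )


def simulate_method3(
    fluor: FluorophoreModel,
    rotor: RotorModel | float,
    env: EnvironmentParams | None = None,
    detector: DetectorPair | None = None,
    delays: np.ndarray | list | None = None,
    pulse_405: Illumination | None = None,
    second_pulse: Illumination | None = None,
    probe_488: Illumination | None = None,
    cycles: int = 1,
    seed: int | None = None,
    grid: SphereGrid | None = None,
    mode: str = "expectation",
    on_fraction: float = 0.50,
    pulse_duration: float = 50e-9,
    probe_bin_width: float = 10e-6,
    delay_range: tuple[float, float] = (0.2e-6, 500e-6),
    polarization_resolved: bool = False,
) -> ModulationCurve:
    """STARSS scheme 3: delayed pair of linear 405-nm pulses, circular readout.

    For each delay the total probed signal is normalized by a matched
    single-pulse reference acquisition.  Rotation during the delay refills
    the orientation hole burnt by the first pulse, so slow rotors show
    normalized counts that rise with delay while static samples stay flat.
    By default the readout is polarization-summed; set
    ``polarization_resolved=True`` to keep the two analyzer channels.
    """
    rotor = _resolve_rotor(rotor, env)
    grid = grid or default_grid()
    detector = detector or DetectorPair()
    if delays is None:
        delays = np.geomspace(delay_range[0], delay_range[1], 9)
    delays = np.asarray(delays, dtype=float)
    if pulse_405 is None:
        pulse_405 = _calibrated_pulse(fluor, on_fraction, pulse_duration)
    if pulse_405.polarization != "linear":
        raise ValueError("scheme 3 pulses must be linearly polarized")
    if second_pulse is None:
        second_pulse = pulse_405
    if second_pulse.polarization != "linear" or not np.allclose(
        second_pulse.axis, pulse_405.axis
    ):
        raise ValueError("both 405-nm pulses must be linear along the same axis")
    if np.any(delays < pulse_405.duration):
        raise ValueError("delays must not be shorter than the first pulse")
    if np.any((delays < delay_range[0]) | (delays > delay_range[1])):
        raise ValueError(f"delays must lie within {delay_range}")
    if probe_488 is None:
        # strong, long readout that depletes the ON population essentially
        # completely, so total counts report the switched-ON number itself
        probe_488 = _default_probe("circular", power_density=2000.0, duration=1e-3)
    if probe_488.polarization != "circular":
        raise ValueError("scheme 3 reads out with circularly polarized 488-nm light")

    def total_counts(segments, stream):
        _, widths, labels, par, perp, _ = _simulate_expectation(segments, fluor, rotor.D, grid)
        if rotor.static_fraction > 0:
            _, _, _, ps, qs, _ = _simulate_expectation(segments, fluor, 0.0, grid)
            fs = rotor.static_fraction
            par = (1 - fs) * par + fs * ps
            perp = (1 - fs) * perp + fs * qs
        m = labels == "probe"
        exp_par = detector.g_factor * par[m].sum() * cycles
        exp_perp = perp[m].sum() * cycles
        extra = (detector.background_rate + detector.dark_rate) * widths[m].sum() * cycles
        if mode == "expectation":
            return exp_par + extra, exp_perp + extra
        rng = substream(seed, stream)
        return (
            rng.poisson(exp_par + extra),
            rng.poisson(exp_perp + extra),
        )

    probe_seg = SchemeSegment(
        probe_488.duration, probe_488, detect=True, bin_width=probe_bin_width,
        label="probe",
        detection="polarized" if polarization_resolved else "unpolarized",
    )
    ref_segments = (
        SchemeSegment(pulse_405.duration, pulse_405, label="pulse405"),
        probe_seg,
    )
    ref_par, ref_perp = total_counts(ref_segments, "reference")
    ref_total = float(ref_par + ref_perp)

    tot, pars, perps = [], [], []
    for i, d in enumerate(delays):
        segments = (
            SchemeSegment(pulse_405.duration, pulse_405, label="pulse405"),
            SchemeSegment(float(d), None, label="delay"),
            SchemeSegment(second_pulse.duration, second_pulse, label="pulse405b"),
            probe_seg,
        )
        p, q = total_counts(segments, f"delay{i}")
        pars.append(p)
        perps.append(q)
        tot.append(p + q)

    meta = {
        "preset": "method3",
        "cycles": cycles,
        "mode": mode,
        "seed": seed,
        "on_fraction_first_pulse": on_fraction,
        "polarization_resolved": polarization_resolved,
        "grid": [grid.n_theta, grid.n_phi],
    }
    return ModulationCurve(
        delays,
        np.asarray(tot, dtype=float),
        ref_total,
        counts_parallel=np.asarray(pars, dtype=float) if polarization_resolved else None,
        counts_perpendicular=np.asarray(perps, dtype=float) if polarization_resolved else None,
        metadata=meta,
    )


def sweep_method3_on_fraction(
    fluor: FluorophoreModel,
    rotor: RotorModel | float,
    fractions: np.ndarray | list | None = None,
    delay_short: float = 0.2e-6,
    delay_long: float = 500e-6,
    grid: SphereGrid | None = None,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Modulation depth of scheme 3 versus the first-pulse ON fraction.

    Both 405-nm pulses share the same fluence and axis, so the sweep varies
    them together.  Modulation depth is the normalized-signal difference
    between a delay much longer and one much shorter than the rotor's
    correlation time; the depth is maximal when the first pulse switches ON
    about half of the molecules (too few and there is no hole to refill, too
    many and the second pulse saturates).  Returns (fractions, depths).
    """
    if fractions is None:
        fractions = np.arange(0.05, 0.951, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    depths = np.empty_like(fractions)
    for i, f in enumerate(fractions):
        mod = simulate_method3(
            fluor,
            rotor,
            delays=[delay_short, delay_long],
            grid=grid,
            mode="expectation",
            on_fraction=float(f),
            **kwargs,
        )
        n = mod.normalized
        depths[i] = n[1] - n[0]
    return fractions, depths


# ----------------------------------------------------------------------
# background
# ----------------------------------------------------------------------

def estimate_background(
    curve: DecayCurve, tail_fraction: float = 0.5, min_bins: int = 10
) -> tuple[float, float]:
    """Cross-talk background rate (counts/s/channel) from the reset window.

    The fluorescence level at the end of the OFF-switching reset is pure
    background; the estimate averages the trailing ``tail_fraction`` of the
    reset bins.  Returns (rate_parallel, rate_perpendicular); divide into
    per-bin counts downstream as rate * bin_width.
    """
    mask = curve.segment_labels == "reset"
    n = int(mask.sum())
    if n < min_bins:
        raise ValueError(
            "no (or too short) reset window in the record; pass an explicit "
            "background level instead"
        )
    idx = np.flatnonzero(mask)
    tail = idx[int(np.ceil(n * (1 - tail_fraction))):]
    if len(tail) < min_bins:
        tail = idx[-min_bins:]
    w = curve.bin_widths[tail]
    rate_par = float(curve.counts_parallel[tail].sum() / w.sum())
    rate_perp = float(curve.counts_perpendicular[tail].sum() / w.sum())
    return rate_par, rate_perp
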