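"""Self-contained synthetic datasets for tests, demos and CLI smoke runs.

Each scenario emulates a class of experiments from the anisotropy study of
slow rotational diffusion with switchable fluorophores:

- ``static_reference``: an immobilized sample (flat anisotropy at the
  photoselection ceiling), the negative control for decay fitting.
- ``beads``: rigid spheres of known diameters (default 30/60/100 nm), the
  size-calibration series.
- ``vlp_like``: two particle populations - a constrained, slowly tumbling
  one with a high anisotropy plateau (immature lattice-anchored tag) and a
  freely tumbling fast one (mature, released tag).
- ``arc_like``: a cell-like field of view with mid-intensity cytosol
  (tau = 8.1 us preset) and bright micrometric clusters (tau = 22.2 us
  preset), exercising the segmentation path.

Every scenario emits both curve-mode CSV files and an image-mode record
(TIFF pair + JSON sidecar) plus a ground-truth JSON, so tests never need
external data.  Generated photon counts are Poisson-sampled from forward-
model expectations unless ``noise='none'``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from .photophysics import FluorophoreModel, RotorModel
from .schemes import simulate_method1, substream
from .sphere import SphereGrid
from .imaging import StarssImageRecord, write_record

__all__ = ["FixtureSpec", "generate_fixture", "SCENARIOS"]

SCENARIOS = ("static_reference", "beads", "vlp_like", "arc_like")


@dataclass
class FixtureSpec:
    """What to generate: scenario, noise level, photon budget and seed."""

    scenario: str = "arc_like"
    seed: int = 0
    noise: str = "poisson"  # or "none"
    photons: float = 1.0e6  # target detected photons per curve
    diameters: tuple[float, ...] = (30e-9, 60e-9, 100e-9)
    static_fraction: float = 0.0
    image_shape: tuple[int, int] = (24, 24)
    bin_width: float = 2e-6
    probe_duration: float = 400e-6
    grid_shape: tuple[int, int] = (32, 64)
    fluorophore: str = "rsEGFP2"
    extras: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


def _components(spec: FixtureSpec) -> dict[str, tuple[RotorModel, float]]:
    """Scenario components: name -> (rotor, relative brightness)."""
    if spec.scenario == "static_reference":
        return {"static": (RotorModel.static(), 1.0)}
    if spec.scenario == "beads":
        return {
            f"bead_{round(d * 1e9)}nm": (
                RotorModel.from_diameter(d, static_fraction=spec.static_fraction),
                1.0,
            )
            for d in spec.diameters
        }
    if spec.scenario == "vlp_like":
        return {
            "immature": (
                RotorModel(rotational_correlation_time=100e-6, static_fraction=0.5),
                1.0,
            ),
            "mature": (RotorModel(rotational_correlation_time=0.5e-6), 1.0),
        }
    # arc_like: published rotor presets for clusters and cytosol
    return {
        "cluster": (RotorModel(rotational_correlation_time=22.2e-6), 1.0),
        "cytosol": (RotorModel(rotational_correlation_time=8.1e-6), 0.2),
    }


def _arc_intensity_template(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Boolean masks: bright cluster blobs inside a cytosol disk."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * min(ny, nx)) ** 2
    clusters = np.zeros(shape, bool)
    for fy, fx in ((0.35, 0.4), (0.6, 0.62)):
        clusters |= (yy - fy * ny) ** 2 + (xx - fx * nx) ** 2 <= (0.08 * min(ny, nx)) ** 2
    clusters &= cell
    return {"cluster": clusters, "cytosol": cell & ~clusters}


def _two_region_template(shape: tuple[int, int], names) -> dict[str, np.ndarray]:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    left = xx < nx // 2
    return {names[0]: left, names[1]: ~left}


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Generate curve- and image-mode data; returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fluor = FluorophoreModel.from_preset(spec.fluorophore)
    grid = SphereGrid(*spec.grid_shape)
    comps = _components(spec)

    manifest: dict = {"scenario": spec.scenario, "seed": spec.seed, "curves": {}, "truth": {}}
    expectations = {}
    for name, (rotor, rel) in comps.items():
        from .photophysics import Illumination

        probe = Illumination(
            role="probe_488",
            polarization="circular",
            power_density=100.0,
            duration=spec.probe_duration,
        )
        curve = simulate_method1(
            fluor,
            rotor,
            probe_488=probe,
            grid=grid,
            mode="expectation",
            bin_width=spec.bin_width,
        )
        total = curve.counts_parallel.sum() + curve.counts_perpendicular.sum()
        scale = spec.photons / total if total > 0 else 1.0
        exp_par = curve.counts_parallel * scale
        exp_perp = curve.counts_perpendicular * scale
        if spec.noise == "poisson":
            rng = substream(spec.seed, f"curve:{name}")
            par = rng.poisson(exp_par).astype(float)
            perp = rng.poisson(exp_perp).astype(float)
        else:
            par, perp = exp_par, exp_perp
        out = curve.__class__(
            curve.bin_centers, par, perp, curve.bin_widths, curve.segment_labels,
            {**curve.metadata, "component": name, "noise": spec.noise, "seed": spec.seed},
        )
        path = outdir / f"{name}.csv"
        out.to_csv(path)
        manifest["curves"][name] = str(path)
        manifest["truth"][name] = {
            "tau_rot_s": None if not np.isfinite(rotor.tau_rot) else rotor.tau_rot,
            "static_fraction": rotor.static_fraction,
            "relative_brightness": rel,
        }
        expectations[name] = (exp_par, exp_perp, rel)

    # image-mode record built from the same per-component expectations
    if spec.scenario == "arc_like":
        masks = _arc_intensity_template(spec.image_shape)
    elif len(comps) >= 2:
        masks = _two_region_template(spec.image_shape, list(comps)[:2])
    else:
        masks = {next(iter(comps)): np.ones(spec.image_shape, bool)}

    nt = len(next(iter(expectations.values()))[0])
    ny, nx = spec.image_shape
    exp_par_img = np.zeros((ny, nx, nt))
    exp_perp_img = np.zeros((ny, nx, nt))
    for name, m in masks.items():
        if name not in expectations:
            continue
        ep, eq, rel = expectations[name]
        npix = max(int(m.sum()), 1)
        exp_par_img[m] = rel * ep / npix * 40.0
        exp_perp_img[m] = rel * eq / npix * 40.0
    rng = substream(spec.seed, "image")
    if spec.noise == "poisson":
        par_img = rng.poisson(exp_par_img).astype(np.uint16)
        perp_img = rng.poisson(exp_perp_img).astype(np.uint16)
    else:
        par_img = np.round(exp_par_img).astype(np.uint16)
        perp_img = np.round(exp_perp_img).astype(np.uint16)
    bin_edges = np.concatenate([[0.0], np.cumsum(np.full(nt, spec.bin_width))])
    record = StarssImageRecord(
        par_img,
        perp_img,
        pixel_size=100e-9,
        bin_edges=bin_edges,
        scheme={"preset": "method1", "scenario": spec.scenario, "seed": spec.seed},
        detector={"g_factor": 1.0},
    )
    stem = outdir / "record"
    write_record(record, stem)
    manifest["image_stem"] = str(stem)
    manifest["truth"]["image_regions"] = {k: int(v.sum()) for k, v in masks.items()}

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(manifest, indent=2))
    manifest["truth_path"] = str(truth_path)
    return manifest
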