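"""Spatially resolved records: segmentation, region decays, anisotropy maps.

A scanned acquisition yields, per detector, a three-dimensional photon-count
array with two spatial dimensions (y, x) and one temporal dimension (the
pulse-scheme time bins).  This module containers such paired stacks, derives
intensity-based segmentation maps (normalized-band thresholding, as used to
separate bright clusters from cytosol, or Otsu for generic two-class
nucleus-style splits), integrates photons per region into decay curves, and
computes per-pixel anisotropy maps over a time window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .analysis import compute_anisotropy
from .schemes import DecayCurve

__all__ = [
    "StarssImageRecord",
    "SegmentationMap",
    "ARC_BANDS",
    "segment_by_intensity",
    "aggregate_region_decays",
    "anisotropy_map",
    "read_record",
    "write_record",
]

#: normalized-intensity bands (lo, hi], values relative to the brightest
#: structure: mid-intensity pixels are cytosol, >0.5 are micrometric clusters
ARC_BANDS = {"cytosol": (0.05, 0.30), "cluster": (0.50, 1.00)}


@dataclass
class StarssImageRecord:
    """Paired (y, x, t) photon-count stacks plus acquisition metadata."""

    counts_parallel: np.ndarray
    counts_perpendicular: np.ndarray
    pixel_size: float  # m
    bin_edges: np.ndarray  # s, length t + 1
    scheme: dict = dataclass_field(default_factory=dict)
    detector: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        a, b = self.counts_parallel, self.counts_perpendicular
        if a.ndim != 3 or a.shape != b.shape:
            raise ValueError("count stacks must be two equal-shape (y, x, t) arrays")
        if len(self.bin_edges) != a.shape[2] + 1:
            raise ValueError(
                f"bin_edges has {len(self.bin_edges)} edges but stacks have "
                f"{a.shape[2]} time bins"
            )
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("counts must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts_parallel.shape

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges, dtype=float)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.bin_edges, dtype=float))

    def intensity_image(self) -> np.ndarray:
        """Time- and channel-integrated 2-D intensity."""
        return self.counts_parallel.sum(axis=2) + self.counts_perpendicular.sum(axis=2)


@dataclass
class SegmentationMap:
    """Integer label image plus the rule that produced it (reproducible)."""

    labels: np.ndarray  # 2-D int, 0 = background
    legend: dict  # name -> label integer
    provenance: dict  # thresholds, normalizer, filter size

    def mask(self, name: str) -> np.ndarray:
        if name == "background":
            return self.labels == 0
        return self.labels == self.legend[name]


def segment_by_intensity(
    record: StarssImageRecord | np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
    median_size: int = 3,
) -> SegmentationMap:
    """Deterministic segmentation of the intensity image by normalized bands.

    The image is normalized by the maximum of its median-filtered version
    (the brightest structure, robust to single hot pixels; ``median_size=1``
    disables the filter), then each pixel is labelled by the half-open band
    (lo, hi] its normalized value falls into; pixels in no band are
    background.  ``bands=None`` uses a two-class Otsu threshold instead
    (generic nucleus-style foreground/background split).  Rescaling the
    image by any positive constant leaves the map unchanged.
    """
    img = record.intensity_image() if isinstance(record, StarssImageRecord) else np.asarray(record)
    img = img.astype(float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if not np.any(img > 0):
        raise ValueError("cannot segment an all-zero image")
    if bands is None:
        thr = threshold_otsu(img)
        labels = (img > thr).astype(np.uint8)
        return SegmentationMap(
            labels,
            {"foreground": 1},
            {"rule": "otsu", "threshold": float(thr), "median_size": None},
        )
    ref = median_filter(img, size=median_size) if median_size > 1 else img
    norm_max = float(ref.max())
    if norm_max <= 0:
        raise ValueError("normalizer (filtered maximum) is zero")
    normed = img / norm_max
    labels = np.zeros(img.shape, dtype=np.uint8)
    legend = {}
    for i, (name, (lo, hi)) in enumerate(bands.items(), start=1):
        legend[name] = i
        sel = (normed > lo) & (normed <= hi)
        labels[sel] = i
    return SegmentationMap(
        labels,
        legend,
        {
            "rule": "normalized-bands",
            "bands": {k: list(v) for k, v in bands.items()},
            "normalizer_max": norm_max,
            "median_size": median_size,
        },
    )


def aggregate_region_decays(
    record: StarssImageRecord, segmentation: SegmentationMap
) -> dict[str, DecayCurve]:
    """Per-region decay curves: integer photon sums per label and time bin.

    The returned curves (one per label, plus ``background``) conserve
    photons exactly: summed over all labels they equal the whole-frame
    totals.  Empty labels are omitted with a warning.
    """
    import warnings

    if segmentation.labels.shape != record.shape[:2]:
        raise ValueError("segmentation shape does not match the record")
    centers = record.bin_centers
    widths = record.bin_widths
    out: dict[str, DecayCurve] = {}
    names = {"background": 0, **segmentation.legend}
    for name, lab in names.items():
        m = segmentation.labels == lab
        if not m.any():
            warnings.warn(f"label {name!r} has no pixels; omitted", stacklevel=2)
            continue
        par = record.counts_parallel[m].sum(axis=0)
        perp = record.counts_perpendicular[m].sum(axis=0)
        out[name] = DecayCurve(
            centers,
            par,
            perp,
            widths,
            np.asarray(["probe"] * len(centers), dtype=object),
            {"region": name, "n_pixels": int(m.sum()), **record.scheme},
        )
    return out


def anisotropy_map(
    record: StarssImageRecord,
    time_window: tuple[float, float] | None = None,
    G: float = 1.0,
    background: tuple[float, float] = (0.0, 0.0),
    min_counts: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel anisotropy from counts summed over a time window.

    ``background`` is the per-pixel cross-talk rate (counts/s/channel).
    Returns (r_map, valid_mask); pixels whose windowed total is below
    ``min_counts``, or whose corrected denominator is not positive, are
    masked and set to nan.
    """
    edges = np.asarray(record.bin_edges, dtype=float)
    if time_window is None:
        sel = slice(None)
        duration = edges[-1] - edges[0]
    else:
        t0, t1 = time_window
        if t0 < edges[0] - 1e-15 or t1 > edges[-1] + 1e-15 or t1 <= t0:
            raise ValueError("time_window must lie within the record's bins")
        idx = np.flatnonzero((edges[:-1] >= t0 - 1e-15) & (edges[1:] <= t1 + 1e-15))
        if len(idx) == 0:
            raise ValueError("time_window covers no complete bins")
        sel = idx
        duration = record.bin_widths[idx].sum()
    par = record.counts_parallel[:, :, sel].sum(axis=2).astype(float)
    perp = record.counts_perpendicular[:, :, sel].sum(axis=2).astype(float)
    p = par - background[0] * duration
    q = perp - background[1] * duration
    den = p + 2.0 * G * q
    valid = (den > 0) & ((par + perp) >= min_counts)
    r = np.full(par.shape, np.nan)
    np.divide(p - G * q, den, out=r, where=valid)
    return r, valid


# ----------------------------------------------------------------------
# I/O: two multi-page 16-bit TIFF stacks + JSON sidecar
# ----------------------------------------------------------------------

def _paths(stem: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    return (
        stem.with_name(stem.name + "_par.tif"),
        stem.with_name(stem.name + "_perp.tif"),
        stem.with_name(stem.name + ".json"),
    )


def write_record(record: StarssImageRecord, stem: str | Path) -> None:
    """Write a record as ``<stem>_par.tif``, ``<stem>_perp.tif``, ``<stem>.json``.

    Stacks are stored as multi-page 16-bit TIFFs with one page per time bin;
    the sidecar carries pixel size, bin edges and scheme/detector metadata.
    ``read_record(stem)`` restores the record bit-exactly.
    """
    par_p, perp_p, side_p = _paths(stem)
    for arr in (record.counts_parallel, record.counts_perpendicular):
        if arr.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("counts exceed the 16-bit TIFF range")
    for path, arr in ((par_p, record.counts_parallel), (perp_p, record.counts_perpendicular)):
        tifffile.imwrite(path, np.ascontiguousarray(arr.astype(np.uint16).transpose(2, 0, 1)))
    side_p.write_text(
        json.dumps(
            {
                "pixel_size": record.pixel_size,
                "bin_edges": list(np.asarray(record.bin_edges, dtype=float)),
                "scheme": record.scheme,
                "detector": record.detector,
            },
            indent=2,
            default=str,
        )
    )


def read_record(stem: str | Path) -> StarssImageRecord:
    """Read a record written by :func:`write_record`; validates consistency."""
    par_p, perp_p, side_p = _paths(stem)
    if not side_p.exists():
        raise FileNotFoundError(f"missing sidecar file {side_p}")
    for p in (par_p, perp_p):
        if not p.exists():
            raise FileNotFoundError(f"missing TIFF stack {p}")
    meta = json.loads(side_p.read_text())
    par = tifffile.imread(par_p)
    perp = tifffile.imread(perp_p)
    if par.ndim == 2:  # single page
        par = par[None]
    if perp.ndim == 2:
        perp = perp[None]
    n_bins = len(meta["bin_edges"]) - 1
    if par.shape[0] != n_bins or perp.shape[0] != n_bins:
        raise ValueError(
            f"sidecar declares {n_bins} time bins but TIFF stacks have "
            f"{par.shape[0]}/{perp.shape[0]} pages"
        )
    return StarssImageRecord(
        par.transpose(1, 2, 0),
        perp.transpose(1, 2, 0),
        pixel_size=float(meta["pixel_size"]),
        bin_edges=np.asarray(meta["bin_edges"], dtype=float),
        scheme=meta.get("scheme", {}),
        detector=meta.get("detector", {}),
    )
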