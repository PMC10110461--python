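"""Discretized orientation space and rotational diffusion on the unit sphere.

The forward model tracks, for every molecular state (ON, OFF, ...), a density
over molecular dipole orientations Omega = (theta, phi).  Rotational diffusion
of a spherical rotor is the heat equation on the sphere,

    dn/dt = D_r * Laplacian_sphere n,

whose eigenfunctions are the spherical harmonics Y_lm with eigenvalues
-l(l+1).  The grid uses Gauss-Legendre nodes in cos(theta) and a uniform
azimuthal grid, so densities band-limited to degree < n_theta are integrated
exactly and the diffusion propagator exp(dt * D_r * Laplacian) can be applied
exactly (per retained mode) by filtering the spherical-harmonic spectrum.
This makes the diffusion step unconditionally stable for any dt.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereGrid", "OrientationField", "propagate_rotation"]


def _normalized_legendre_table(l_max: int, m: int, x: np.ndarray) -> np.ndarray:
    """Orthonormal associated Legendre functions N_l^m(x) for l = m..l_max.

    Normalized so that integral_{-1}^{1} N_l^m N_l'^m dx = delta_{l l'}.
    Stable three-term recurrence; returns array of shape (l_max - m + 1, x.size).
    """
    x = np.asarray(x, dtype=float)
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    # seed N_m^m by the diagonal recurrence
    pmm = np.full_like(x, 1.0 / np.sqrt(2.0))
    for k in range(1, m + 1):
        pmm = np.sqrt((2 * k + 1) / (2.0 * k)) * s * pmm
    rows = [pmm]
    if l_max > m:
        rows.append(np.sqrt(2 * m + 3.0) * x * pmm)
    for l in range(m + 2, l_max + 1):
        a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
        b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
        rows.append(a * (x * rows[-1] - b * rows[-2]))
    return np.vstack(rows)


class SphereGrid:
    """Gauss-Legendre (theta) x uniform (phi) quadrature grid on S^2.

    Parameters
    ----------
    n_theta
        Number of Gauss-Legendre nodes in cos(theta); the spherical-harmonic
        band limit is l_max = n_theta - 1.
    n_phi
        Number of uniform azimuthal nodes (default 2 * n_theta).
    """

    def __init__(self, n_theta: int = 64, n_phi: int | None = None):
        if n_theta < 4:
            raise ValueError("n_theta must be >= 4")
        if n_phi is None:
            n_phi = 2 * n_theta
        if n_phi < 4:
            raise ValueError("n_phi must be >= 4")
        self.n_theta = int(n_theta)
        self.n_phi = int(n_phi)
        self.l_max = self.n_theta - 1

        x, w = np.polynomial.legendre.leggauss(self.n_theta)
        self.cos_theta = x  # (n_theta,)
        self.gl_weights = w
        self.phi = 2.0 * np.pi * np.arange(self.n_phi) / self.n_phi

        sin_theta = np.sqrt(1.0 - x * x)
        ct = x[:, None]
        st = sin_theta[:, None]
        self.mu = np.empty((self.n_theta, self.n_phi, 3))
        self.mu[..., 0] = st * np.cos(self.phi)[None, :]
        self.mu[..., 1] = st * np.sin(self.phi)[None, :]
        self.mu[..., 2] = ct

        # solid-angle weight per cell; sums to 4 pi
        self.cell_weights = (w[:, None] * (2.0 * np.pi / self.n_phi)) * np.ones(
            (1, self.n_phi)
        )

        # orthonormal Legendre tables per azimuthal order m (m <= l_max)
        self._plm = [
            _normalized_legendre_table(self.l_max, m, x) for m in range(self.l_max + 1)
        ]
        self._prop_cache: OrderedDict[float, list[np.ndarray]] = OrderedDict()
        self._prop_cache_size = 32

    # ------------------------------------------------------------------
    def integrate(self, values: np.ndarray) -> float:
        """Integral of a grid function over the sphere (d Omega)."""
        return float(np.sum(values * self.cell_weights))

    def uniform_density(self, total_mass: float = 1.0) -> np.ndarray:
        """Constant density with the requested total mass."""
        return np.full((self.n_theta, self.n_phi), total_mass / (4.0 * np.pi))

    # ------------------------------------------------------------------
    def _propagator(self, tau: float) -> list[np.ndarray]:
        """Per-m theta propagator matrices for dimensionless time tau = D*dt."""
        key = float(tau)
        cached = self._prop_cache.get(key)
        if cached is not None:
            self._prop_cache.move_to_end(key)
            return cached
        mats = []
        ls = np.arange(self.l_max + 1)
        decay = np.exp(-ls * (ls + 1.0) * tau)
        for m in range(self.l_max + 1):
            P = self._plm[m]  # (n_l, n_theta)
            # analysis uses GL quadrature; synthesis is plain evaluation
            mats.append((P.T * decay[m:]) @ (P * self.gl_weights[None, :]))
        self._prop_cache[key] = mats
        if len(self._prop_cache) > self._prop_cache_size:
            self._prop_cache.popitem(last=False)
        return mats

    def diffuse(self, density: np.ndarray, diffusion_coefficient: float, dt: float) -> np.ndarray:
        """Apply exp(dt * D * Laplacian_sphere) to a grid density."""
        tau = diffusion_coefficient * dt
        if tau == 0.0:
            return density.copy()
        mats = self._propagator(tau)
        F = np.fft.rfft(density, axis=1)
        n_m = F.shape[1]
        out = np.zeros_like(F)
        for m in range(min(n_m, self.l_max + 1)):
            out[:, m] = mats[m] @ F[:, m]
        # azimuthal orders beyond the band limit are dropped (spectral filter)
        res = np.fft.irfft(out, n=self.n_phi, axis=1)
        # spectral truncation can produce tiny negative undershoots; clamp
        np.clip(res, 0.0, None, out=res)
        return res


@dataclass
class OrientationField:
    """Per-state orientation densities on a :class:`SphereGrid`.

    ``populations`` maps state names ('on', 'off', optionally 'intermediate',
    'bleached') to nonnegative densities of shape (n_theta, n_phi).  Total
    mass (states summed, integrated over the sphere) is conserved by switching
    and diffusion; only bleaching removes mass.
    """

    grid: SphereGrid
    populations: dict[str, np.ndarray] = field(default_factory=dict)

    # -- constructors ---------------------------------------------------
    @classmethod
    def fully_off(cls, grid: SphereGrid, total_mass: float = 1.0) -> "OrientationField":
        zero = np.zeros((grid.n_theta, grid.n_phi))
        return cls(grid, {"off": grid.uniform_density(total_mass), "on": zero.copy()})

    @classmethod
    def fully_on(cls, grid: SphereGrid, total_mass: float = 1.0) -> "OrientationField":
        zero = np.zeros((grid.n_theta, grid.n_phi))
        return cls(grid, {"off": zero.copy(), "on": grid.uniform_density(total_mass)})

    # -- bookkeeping ----------------------------------------------------
    def copy(self) -> "OrientationField":
        return OrientationField(
            self.grid, {k: v.copy() for k, v in self.populations.items()}
        )

    def state(self, name: str) -> np.ndarray:
        if name not in self.populations:
            self.populations[name] = np.zeros((self.grid.n_theta, self.grid.n_phi))
        return self.populations[name]

    def mass_by_state(self) -> dict[str, float]:
        return {k: self.grid.integrate(v) for k, v in self.populations.items()}

    @property
    def total_mass(self) -> float:
        return sum(self.mass_by_state().values())

    def validate(self, tol: float = 1e-9) -> None:
        for name, dens in self.populations.items():
            if dens.shape != (self.grid.n_theta, self.grid.n_phi):
                raise ValueError(f"state {name!r} has shape {dens.shape}")
            if dens.min() < -tol * max(1.0, dens.max()):
                raise ValueError(f"state {name!r} has negative density")


def propagate_rotation(
    field: OrientationField, diffusion_coefficient: float, dt: float
) -> OrientationField:
    """Rotational diffusion of every state for a time dt.

    Exact spectral propagation (per retained mode); mass per state is
    conserved and a uniform density is a fixed point for any D and dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if diffusion_coefficient < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    if diffusion_coefficient == 0.0:
        return field.copy()
    grid = field.grid
    out = {
        name: grid.diffuse(dens, diffusion_coefficient, dt)
        for name, dens in field.populations.items()
    }
    return OrientationField(grid, out)
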