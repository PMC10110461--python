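"""Legendre-mode solver for axially symmetric switching/diffusion problems.

When every beam is linearly polarized along one common axis, densities depend
on orientation only through u = cos(angle to that axis) and can be expanded
in Legendre polynomials, n(u, t) = sum_l c_l(t) P_l(u).  Rotational diffusion
is diagonal in this basis (mode l decays at l(l+1) D_r) and the cos^2
photoselection kernel couples l -> l, l +/- 2 through the exact product
formula

    u^2 P_l = A_l P_{l+2} + B_l P_l + C_l P_{l-2}.

The reaction-diffusion system is then a linear constant-coefficient ODE in
mode space, solved exactly with a matrix exponential — no operator splitting
and no angular grid.  This is an independent computational route from the
sphere-grid engine in :mod:`starss.photophysics` and serves as its
cross-check for axially symmetric pulse schemes; it is also usable as a fast
solver in its own right for such schemes.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .photophysics import FluorophoreModel

__all__ = ["LegendreModeSolver"]


def _u2_matrix(l_max: int) -> np.ndarray:
    """Matrix of multiplication by u^2 acting on Legendre coefficients."""
    M = np.zeros((l_max + 1, l_max + 1))
    for l in range(l_max + 1):
        A = (l + 1.0) * (l + 2.0) / ((2 * l + 1.0) * (2 * l + 3.0))
        B = (l + 1.0) ** 2 / ((2 * l + 1.0) * (2 * l + 3.0))
        if l >= 1:
            B += l * l / ((2 * l + 1.0) * (2 * l - 1.0))
        if l + 2 <= l_max:
            M[l + 2, l] = A
        M[l, l] = B
        if l >= 2:
            M[l - 2, l] = l * (l - 1.0) / ((2 * l + 1.0) * (2 * l - 1.0))
    return M


class LegendreModeSolver:
    """Two-state (OFF/ON) axially symmetric forward model in Legendre modes.

    All beams must be linearly polarized along the common symmetry axis; the
    detection analyzers are parallel and perpendicular to it.  State vector:
    Legendre coefficients of the OFF then ON densities (l = 0..l_max).
    """

    def __init__(self, fluor: FluorophoreModel, diffusion_coefficient: float, l_max: int = 20):
        if fluor.intermediate_rate is not None:
            raise ValueError("the mode solver supports the two-state model only")
        if l_max < 4:
            raise ValueError("l_max must be >= 4")
        self.fluor = fluor
        self.D = float(diffusion_coefficient)
        self.l_max = int(l_max)
        n = l_max + 1
        self._U2 = _u2_matrix(l_max)
        ls = np.arange(n)
        self._lap = np.diag(-ls * (ls + 1.0) * self.D)
        # start fully OFF and isotropic with unit total mass
        self.coeffs_off = np.zeros(n)
        self.coeffs_off[0] = 1.0 / (4.0 * np.pi)
        self.coeffs_on = np.zeros(n)

        # observable rows: 2 pi * integral g(u) P_l(u) du via Gauss quadrature
        u, w = np.polynomial.legendre.leggauss(2 * l_max + 4)
        P = np.polynomial.legendre.legvander(u, l_max)  # (nq, n)
        self._quad_u, self._quad_w, self._P = u, w, P

    def _observable_row(self, g_of_u: np.ndarray) -> np.ndarray:
        return 2.0 * np.pi * (self._P * (self._quad_w * g_of_u)[:, None]).sum(axis=0)

    @property
    def masses(self) -> tuple[float, float]:
        """(OFF, ON) total populations."""
        return 4.0 * np.pi * self.coeffs_off[0], 4.0 * np.pi * self.coeffs_on[0]

    def dark(self, duration: float) -> None:
        """Free rotational diffusion with no light."""
        ls = np.arange(self.l_max + 1)
        decay = np.exp(-ls * (ls + 1.0) * self.D * duration)
        self.coeffs_off *= decay
        self.coeffs_on *= decay

    def pulse_405(self, power_density: float, duration: float) -> None:
        """Linear 405-nm pulse along the symmetry axis (OFF -> ON)."""
        n = self.l_max + 1
        K = self.fluor.k_on_peak * power_density * self._U2
        A = np.zeros((2 * n, 2 * n))
        A[:n, :n] = -K + self._lap
        A[n:, :n] = K
        A[n:, n:] = self._lap
        v = np.concatenate([self.coeffs_off, self.coeffs_on])
        v = expm(A * duration) @ v
        self.coeffs_off, self.coeffs_on = v[:n], v[n:]

    def probe_488(
        self, power_density: float, duration: float, n_bins: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Linear 488-nm probe along the axis: OFF-switching plus emission.

        Returns expected detected photons per time bin in the parallel and
        perpendicular channels (collinear dipoles assumed).
        """
        n = self.l_max + 1
        K_off = self.fluor.k_off_peak * power_density * self._U2
        A = np.zeros((2 * n + 2, 2 * n + 2))
        A[:n, :n] = self._lap
        A[:n, n : 2 * n] = K_off
        A[n : 2 * n, n : 2 * n] = -K_off + self._lap
        u = self._quad_u
        k_exc = self.fluor.k_exc_peak * power_density * u * u
        w_par = 1.5 * u * u
        w_perp = 1.5 * 0.5 * (1.0 - u * u)
        A[2 * n, n : 2 * n] = self.fluor.brightness * self._observable_row(k_exc * w_par)
        A[2 * n + 1, n : 2 * n] = self.fluor.brightness * self._observable_row(
            k_exc * w_perp
        )
        dt = duration / n_bins
        prop = expm(A * dt)
        v = np.concatenate([self.coeffs_off, self.coeffs_on, [0.0, 0.0]])
        par = np.empty(n_bins)
        perp = np.empty(n_bins)
        for i in range(n_bins):
            v[-2:] = 0.0
            v = prop @ v
            par[i], perp[i] = v[-2], v[-1]
        self.coeffs_off, self.coeffs_on = v[: n], v[n : 2 * n]
        return par, perp
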