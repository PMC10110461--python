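"""From photon counts to anisotropy curves, decay fits and particle sizes.

The fluorescence anisotropy of a pair of background-corrected analyzer
channels is

    r = (I_par - G * I_perp) / (I_par + 2 * G * I_perp),

where G corrects the gain imbalance of the detectors (measured on an
isotropic sample under circular excitation) and the cross-talk background is
subtracted from both channels first.  Poisson counting noise is propagated
to r either by a first-order delta method or by a seeded parametric
bootstrap.  Decay models (single exponential or stretched exponential, each
on top of a constant static component) are fitted by weighted nonlinear
least squares, and the fitted correlation time is converted to an apparent
hydrodynamic diameter through the Stokes-Einstein-Debye relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import curve_fit

from .schemes import DecayCurve, ModulationCurve
from .sizes import EnvironmentParams, diameter_from_tau

__all__ = [
    "AnisotropyCurve",
    "FitResult",
    "Method3Result",
    "compute_anisotropy",
    "confidence_interval_95",
    "calibrate_g",
    "fit_monoexponential",
    "fit_stretched",
    "analyze_method3",
    "build_method3_calibration",
]

_Z95 = 1.959963984540054


@dataclass
class AnisotropyCurve:
    """Per-bin anisotropy with 95% confidence band and validity flags."""

    bin_centers: np.ndarray
    r: np.ndarray
    ci95_lo: np.ndarray
    ci95_hi: np.ndarray
    valid: np.ndarray
    corrections: dict = dataclass_field(default_factory=dict)
    metadata: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        n = len(self.bin_centers)
        for arr in (self.r, self.ci95_lo, self.ci95_hi, self.valid):
            if len(arr) != n:
                raise ValueError("all per-bin arrays must have equal length")

    @property
    def sigma(self) -> np.ndarray:
        """1-sigma uncertainty implied by the 95% band (nan where undefined)."""
        return (self.ci95_hi - self.ci95_lo) / (2.0 * _Z95)


def _corrected(counts_par, counts_perp, background, bin_widths):
    bg_par, bg_perp = background
    bg_par = np.asarray(bg_par, dtype=float) * bin_widths
    bg_perp = np.asarray(bg_perp, dtype=float) * bin_widths
    p = np.asarray(counts_par, dtype=float) - bg_par
    q = np.asarray(counts_perp, dtype=float) - bg_perp
    return p, q


def compute_anisotropy(
    curve: DecayCurve,
    G: float = 1.0,
    background: tuple[float, float] = (0.0, 0.0),
    segment: str | None = "probe",
) -> AnisotropyCurve:
    """Anisotropy r(t) of a decay record, with G and background corrections.

    ``background`` is the per-channel cross-talk rate in counts/s on the
    record's accumulated scale (as returned by
    :func:`starss.schemes.estimate_background`); it is converted to counts
    per bin through the bin widths.  Bins whose corrected denominator is not
    positive are flagged invalid rather than dropped, so the time axis stays
    intact.
    """
    if G <= 0:
        raise ValueError("G must be positive")
    if np.any(np.asarray(background) < 0):
        raise ValueError("background rates must be nonnegative")
    if segment is not None and (curve.segment_labels == segment).any():
        curve = curve.select(segment)
    p, q = _corrected(curve.counts_parallel, curve.counts_perpendicular, background, curve.bin_widths)
    den = p + 2.0 * G * q
    valid = den > 0
    r = np.full_like(den, np.nan)
    np.divide(p - G * q, den, out=r, where=valid)
    lo, hi = confidence_interval_95(
        curve.counts_parallel, curve.counts_perpendicular, G, background, curve.bin_widths
    )
    return AnisotropyCurve(
        curve.bin_centers,
        r,
        lo,
        hi,
        valid,
        corrections={"G": G, "background": tuple(np.broadcast_to(b, (1,))[0] if np.ndim(b) == 0 else "per-bin" for b in background)},
        metadata=dict(curve.metadata),
    )


def confidence_interval_95(
    counts_par,
    counts_perp,
    G: float = 1.0,
    background: tuple[float, float] = (0.0, 0.0),
    bin_widths=1.0,
    method: str = "delta",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """95% confidence interval of r per bin from Poisson counting noise.

    ``method='delta'`` propagates Var = N through the anisotropy formula to
    first order; ``method='bootstrap'`` draws parametric Poisson replicates
    (seeded) and takes percentiles.  Bins with zero total counts have an
    undefined (nan) interval.
    """
    Np = np.atleast_1d(np.asarray(counts_par, dtype=float))
    Nq = np.atleast_1d(np.asarray(counts_perp, dtype=float))
    widths = np.broadcast_to(np.asarray(bin_widths, dtype=float), Np.shape)
    p, q = _corrected(Np, Nq, background, widths)
    den = p + 2.0 * G * q
    ok = (den > 0) & ((Np + Nq) > 0)
    r = np.where(ok, (p - G * q) / np.where(ok, den, 1.0), np.nan)
    if method == "delta":
        var = 9.0 * G * G * (q * q * Np + p * p * Nq) / np.where(ok, den, 1.0) ** 4
        half = _Z95 * np.sqrt(np.where(ok, var, np.nan))
        return r - half, r + half
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        bp = rng.poisson(np.clip(Np, 0, None), size=(n_boot,) + Np.shape).astype(float)
        bq = rng.poisson(np.clip(Nq, 0, None), size=(n_boot,) + Nq.shape).astype(float)
        pp, qq = _corrected(bp, bq, background, widths)
        dd = pp + 2.0 * G * qq
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = np.where(dd > 0, (pp - G * qq) / dd, np.nan)
        lo = np.nanpercentile(rr, 2.5, axis=0)
        hi = np.nanpercentile(rr, 97.5, axis=0)
        return np.where(ok, lo, np.nan), np.where(ok, hi, np.nan)
    raise ValueError("method must be 'delta' or 'bootstrap'")


def calibrate_g(curve: DecayCurve, segment: str | None = None) -> float:
    """Detector G-factor from an isotropic steady sample, circularly excited.

    G = mean(I_par) / mean(I_perp); with this G the anisotropy of the
    calibration record is zero within its confidence interval.  A time trend
    in the channel ratio (anisotropic or decaying calibration sample) raises
    a warning.
    """
    if segment is not None and (curve.segment_labels == segment).any():
        curve = curve.select(segment)
    p = np.asarray(curve.counts_parallel, dtype=float)
    q = np.asarray(curve.counts_perpendicular, dtype=float)
    if q.sum() <= 0:
        raise ValueError("perpendicular channel has no counts")
    G = float(p.sum() / q.sum())
    if len(p) >= 8:
        ratio = np.divide(p, q, out=np.full_like(p, np.nan), where=q > 0)
        t = curve.bin_centers
        ok = np.isfinite(ratio)
        if ok.sum() >= 8:
            A = np.vstack([np.ones(ok.sum()), t[ok] - t[ok].mean()]).T
            coef, res, *_ = np.linalg.lstsq(A, ratio[ok], rcond=None)
            dof = ok.sum() - 2
            s2 = (res[0] / dof) if len(res) and dof > 0 else np.nanvar(ratio[ok])
            se = np.sqrt(s2 / np.sum(A[:, 1] ** 2)) if np.sum(A[:, 1] ** 2) > 0 else np.inf
            if se > 0 and abs(coef[1]) > 3 * se:
                warnings.warn(
                    "channel ratio shows a time trend; calibration sample may "
                    "not be isotropic/steady",
                    stacklevel=2,
                )
    return G


# ----------------------------------------------------------------------
# decay fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted anisotropy decay model and derived rotor quantities."""

    model: str
    r_static: float
    amplitude: float
    tau: float
    beta: float
    covariance: np.ndarray | None
    tau_ci95: tuple[float, float]
    diffusion_coefficient: float
    diameter: float
    diameter_ci95: tuple[float, float]
    aicc: float
    n_bins_used: int
    tau_unconstrained: bool = False
    beta_at_bound: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["covariance"] = None if self.covariance is None else np.asarray(self.covariance).tolist()
        for k in ("tau_ci95", "diameter_ci95"):
            d[k] = list(d[k])
        return d


def _fit_inputs(aniso: AnisotropyCurve):
    sig = aniso.sigma
    ok = aniso.valid & np.isfinite(aniso.r)
    t = aniso.bin_centers[ok]
    r = aniso.r[ok]
    s = sig[ok]
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} invalid bins from the fit", stacklevel=3)
    if len(t) < 8:
        raise ValueError("need at least 8 valid bins to fit a decay model")
    # noiseless expectation curves carry no Poisson noise: fit unweighted
    noiseless = aniso.metadata.get("mode") == "expectation"
    weighted = (not noiseless) and np.all(np.isfinite(s)) and np.all(s > 0)
    return t, r, (s if weighted else None)


def _weighted_cost(resid, sigma):
    if sigma is None:
        return float(np.sum(resid**2))
    return float(np.sum((resid / sigma) ** 2))


def _aicc(cost, n, k):
    # cost is (weighted) RSS; Gaussian log-likelihood up to constants
    aic = n * np.log(max(cost, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return float(aic)


def _derive_size(tau, tau_ci, env):
    env = env or EnvironmentParams()
    D = 1.0 / (6.0 * tau) if tau > 0 else np.nan
    dia = diameter_from_tau(tau, env) if tau > 0 else np.nan
    # cube-root transform maps the tau interval endpoints directly
    ci = tuple(
        diameter_from_tau(x, env) if np.isfinite(x) and x > 0 else np.nan for x in tau_ci
    )
    return D, dia, ci


def _constant_fit(t, r, sigma):
    if sigma is None:
        c = float(np.mean(r))
    else:
        w = 1.0 / sigma**2
        c = float(np.sum(w * r) / np.sum(w))
    return c, _weighted_cost(r - c, sigma)


def fit_monoexponential(
    aniso: AnisotropyCurve, env: EnvironmentParams | None = None
) -> FitResult:
    """Weighted fit of r(t) = r_static + A * exp(-t / tau).

    Multi-starts tau on a logarithmic grid spanning the time axis (amplitude
    and offset solved linearly at each start), then polishes with
    Levenberg-Marquardt.  A curve with no resolvable decay returns the
    static fit with ``tau_unconstrained=True`` instead of an arbitrary tau.
    """
    t, r, sigma = _fit_inputs(aniso)
    c0, cost0 = _constant_fit(t, r, sigma)
    span_lo = max(np.min(np.diff(t)) * 0.3, 1e-12)
    span_hi = (t[-1] - t[0]) * 30.0
    best = None
    for tau0 in np.geomspace(span_lo, span_hi, 15):
        X = np.vstack([np.ones_like(t), np.exp(-t / tau0)]).T
        Xw = X if sigma is None else X / sigma[:, None]
        yw = r if sigma is None else r / sigma
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cost = _weighted_cost(r - X @ coef, sigma)
        if best is None or cost < best[0]:
            best = (cost, tau0, coef)
    _, tau0, coef0 = best

    def model(tt, rs, A, log_tau):
        return rs + A * np.exp(-tt / np.exp(log_tau))

    p0 = [coef0[0], coef0[1], np.log(tau0)]
    try:
        popt, pcov = curve_fit(
            model, t, r, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            maxfev=20000,
        )
        cost = _weighted_cost(r - model(t, *popt), sigma)
    except RuntimeError:
        popt, pcov, cost = np.asarray(p0), None, best[0]

    rs, A, log_tau = popt
    tau = float(np.exp(log_tau))
    n = len(t)

    if sigma is not None:
        unconstrained = (cost0 - cost) < 6.0  # ~95% chi-square gain for 2 dof
    else:
        unconstrained = (cost0 - cost) < 1e-9 * max(cost0, 1e-30)
    if not (span_lo / 30 < tau < span_hi * 30):
        unconstrained = True

    if unconstrained:
        env = env or EnvironmentParams()
        return FitResult(
            model="monoexp_static",
            r_static=c0,
            amplitude=0.0,
            tau=np.nan,
            beta=1.0,
            covariance=None,
            tau_ci95=(np.nan, np.nan),
            diffusion_coefficient=np.nan,
            diameter=np.nan,
            diameter_ci95=(np.nan, np.nan),
            aicc=_aicc(cost0, n, 1),
            n_bins_used=n,
            tau_unconstrained=True,
        )

    if pcov is not None and np.all(np.isfinite(pcov)):
        se_log_tau = float(np.sqrt(max(pcov[2, 2], 0.0)))
        if sigma is None and n > 3:
            se_log_tau *= np.sqrt(cost / (n - 3))  # scale by reduced chi-square
    else:
        se_log_tau = np.nan
    tau_ci = (tau * np.exp(-_Z95 * se_log_tau), tau * np.exp(_Z95 * se_log_tau))
    D, dia, dia_ci = _derive_size(tau, tau_ci, env)
    return FitResult(
        model="monoexp_static",
        r_static=float(rs),
        amplitude=float(A),
        tau=tau,
        beta=1.0,
        covariance=pcov,
        tau_ci95=tau_ci,
        diffusion_coefficient=D,
        diameter=dia,
        diameter_ci95=dia_ci,
        aicc=_aicc(cost, n, 3),
        n_bins_used=n,
    )


_BETA_MIN = 0.05


def fit_stretched(
    aniso: AnisotropyCurve, env: EnvironmentParams | None = None
) -> FitResult:
    """Weighted fit of r(t) = r_static + A * exp(-(t / tau)^beta), beta in (0, 1].

    Reports AICc so the stretched model can be compared against the nested
    single-exponential fit (beta = 1); ``beta_at_bound`` flags solutions
    pinned at the lower search bound.
    """
    t, r, sigma = _fit_inputs(aniso)
    c0, cost0 = _constant_fit(t, r, sigma)
    mono = fit_monoexponential(aniso, env)
    span_lo = max(np.min(np.diff(t)) * 0.3, 1e-12)
    span_hi = (t[-1] - t[0]) * 30.0

    def model(tt, rs, A, log_tau, beta):
        return rs + A * np.exp(-np.power(tt / np.exp(log_tau), beta))

    starts = []
    tau_starts = (
        [mono.tau] if np.isfinite(mono.tau) else list(np.geomspace(span_lo, span_hi, 5))
    )
    for tau0 in tau_starts:
        for beta0 in (0.5, 0.8, 1.0):
            starts.append(
                [
                    mono.r_static if np.isfinite(mono.tau) else c0,
                    mono.amplitude if np.isfinite(mono.tau) else (r[0] - c0),
                    np.log(tau0),
                    beta0,
                ]
            )
    best = None
    bounds = ([-np.inf, -np.inf, np.log(span_lo / 30), _BETA_MIN], [np.inf, np.inf, np.log(span_hi * 30), 1.0])
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                model, t, r, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                bounds=bounds, maxfev=20000,
            )
        except RuntimeError:
            continue
        cost = _weighted_cost(r - model(t, *popt), sigma)
        if best is None or cost < best[0]:
            best = (cost, popt, pcov)
    if best is None:
        raise RuntimeError("stretched-exponential fit failed to converge")
    cost, popt, pcov = best
    rs, A, log_tau, beta = popt
    tau = float(np.exp(log_tau))
    n = len(t)

    if sigma is not None:
        unconstrained = (cost0 - cost) < 7.8  # ~95% chi-square gain for 3 dof
    else:
        unconstrained = (cost0 - cost) < 1e-9 * max(cost0, 1e-30)
    if unconstrained:
        res = fit_monoexponential(aniso, env)
        res.model = "stretched_static"
        return res

    if pcov is not None and np.all(np.isfinite(pcov)):
        se_log_tau = float(np.sqrt(max(pcov[2, 2], 0.0)))
        if sigma is None and n > 4:
            se_log_tau *= np.sqrt(cost / (n - 4))
    else:
        se_log_tau = np.nan
    tau_ci = (tau * np.exp(-_Z95 * se_log_tau), tau * np.exp(_Z95 * se_log_tau))
    D, dia, dia_ci = _derive_size(tau, tau_ci, env)
    return FitResult(
        model="stretched_static",
        r_static=float(rs),
        amplitude=float(A),
        tau=tau,
        beta=float(beta),
        covariance=pcov,
        tau_ci95=tau_ci,
        diffusion_coefficient=D,
        diameter=dia,
        diameter_ci95=dia_ci,
        aicc=_aicc(cost, n, 4),
        n_bins_used=n,
        beta_at_bound=bool(beta <= _BETA_MIN * 1.01),
    )


# ----------------------------------------------------------------------
# scheme-3 analysis
# ----------------------------------------------------------------------

@dataclass
class Method3Result:
    """Delay-modulation fit and the rotor correlation time it implies."""

    tau_eff: float
    tau_eff_ci95: tuple[float, float]
    tau_rot: float
    tau_rot_ci95: tuple[float, float]
    f0: float
    f_inf: float
    tau_unconstrained: bool = False
    below_resolution: bool = False


def build_method3_calibration(
    fluor,
    tau_rot_grid,
    delays=None,
    grid=None,
    **scheme_kwargs,
):
    """Map the fitted modulation time constant tau_eff to tau_rot.

    Runs the forward model for each tau_rot on the grid, fits the resulting
    noiseless modulation curves, and returns the (tau_eff, tau_rot) table
    used for interpolation.  The refilling of the orientation hole mixes
    several diffusion modes, so tau_eff is close to, but not identical with,
    the rotor correlation time; this closed-loop calibration absorbs that
    bias.
    """
    from .photophysics import RotorModel
    from .schemes import simulate_method3

    rows = []
    for tau in np.asarray(tau_rot_grid, dtype=float):
        mod = simulate_method3(
            fluor,
            RotorModel(rotational_correlation_time=tau),
            delays=delays,
            grid=grid,
            mode="expectation",
            **scheme_kwargs,
        )
        fit = _fit_modulation(mod.delays, mod.normalized, sigma=None)
        if fit is not None and np.isfinite(fit[0]):
            rows.append((fit[0], tau))
    if len(rows) < 2:
        raise RuntimeError("calibration failed: too few usable forward runs")
    rows.sort()
    return np.asarray(rows)


def _fit_modulation(delays, norm, sigma):
    """Fit F(d) = F_inf - (F_inf - F_0) exp(-d / tau_eff); None if flat."""
    d = np.asarray(delays, dtype=float)
    y = np.asarray(norm, dtype=float)
    c0 = float(np.mean(y))
    cost0 = _weighted_cost(y - c0, sigma)

    def model(dd, f_inf, f0, log_tau):
        return f_inf - (f_inf - f0) * np.exp(-dd / np.exp(log_tau))

    best = None
    for tau0 in np.geomspace(d.min(), d.max(), 9):
        try:
            popt, pcov = curve_fit(
                model, d, y, p0=[y[-1], y[0], np.log(tau0)], sigma=sigma,
                absolute_sigma=sigma is not None, maxfev=10000,
            )
        except RuntimeError:
            continue
        cost = _weighted_cost(y - model(d, *popt), sigma)
        if best is None or cost < best[0]:
            best = (cost, popt, pcov)
    if best is None:
        return None
    cost, popt, pcov = best
    if sigma is not None:
        flat = (cost0 - cost) < 6.0
    else:
        flat = (cost0 - cost) < 1e-10 * max(cost0, 1e-30) or np.ptp(y) < 1e-9
    if flat:
        return (np.nan, (np.nan, np.nan), c0, c0, True)
    f_inf, f0, log_tau = popt
    tau = float(np.exp(log_tau))
    se = float(np.sqrt(max(pcov[2, 2], 0.0))) if np.all(np.isfinite(pcov)) else np.nan
    ci = (tau * np.exp(-_Z95 * se), tau * np.exp(_Z95 * se))
    return (tau, ci, float(f0), float(f_inf), False)


def analyze_method3(
    mod: ModulationCurve,
    calibration: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> Method3Result:
    """Rotor correlation time from a scheme-3 modulation curve.

    Fits the normalized counts versus delay with a saturating exponential
    and maps the fitted time constant to tau_rot through a forward-model
    calibration table (from :func:`build_method3_calibration`).  Without a
    table the raw tau_eff is reported as tau_rot.  Static samples (flat
    curves) return tau flagged unconstrained; rotors faster than the
    shortest delay are flagged below resolution.
    """
    if len(mod.delays) < 5:
        raise ValueError("need at least 5 delays to analyze the modulation")
    y = mod.normalized
    if mod.metadata.get("mode") == "expectation":
        drops = np.diff(y) < -1e-9 * max(1.0, np.abs(y).max())
        if drops.any():
            warnings.warn(
                "noiseless modulation curve is not monotone; the saturating-"
                "exponential model may not describe these data",
                stacklevel=2,
            )
    fit = _fit_modulation(mod.delays, y, sigma)
    if fit is None:
        raise RuntimeError("modulation fit failed")
    tau_eff, ci, f0, f_inf, flat = fit
    if flat:
        return Method3Result(np.nan, (np.nan, np.nan), np.nan, (np.nan, np.nan), f0, f_inf, tau_unconstrained=True)
    below = tau_eff < np.min(mod.delays)
    if calibration is None:
        tau_rot, ci_rot = tau_eff, ci
    else:
        te, tr = calibration[:, 0], calibration[:, 1]

        def map_tau(x):
            return float(np.exp(np.interp(np.log(x), np.log(te), np.log(tr))))

        tau_rot = map_tau(tau_eff)
        ci_rot = tuple(
            map_tau(x) if np.isfinite(x) and x > 0 else np.nan for x in ci
        )
    return Method3Result(tau_eff, ci, tau_rot, ci_rot, f0, f_inf, below_resolution=bool(below))
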