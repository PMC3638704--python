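"""Two-compartment pharmacokinetic model and voxelwise curve fitting.

The enhancement model is a Brix-type constant-infusion two-compartment
exchange model.  Contrast is infused at a constant rate for a bolus
duration ``tau``; it exchanges between the vascular (primary) and
extravascular-extracellular (secondary) compartment with back-transfer
rate ``k_ep`` and is eliminated from plasma with rate ``k_el``.  The
relative signal enhancement of a voxel is

    E(t) = (A / tau') * k_ep * [h(k_el, t) - h(k_ep, t)] / (k_ep - k_el)

with ``h(k, t) = ((exp(k * min(t, tau')) - 1) / k) * exp(-k t)`` and
``tau'`` the infusion duration in the rate units (minutes).  ``A`` is a
dimensionless amplitude; the *peak* of the fitted curve (``A_peak``) is
what the parameter pseudoimage reports, since the peak enhancement
reached during the acquisition is the quantity radiologists read.

Fitting operates on relative enhancement ``(S(t) - S(0)) / S(0)`` with
bounded least squares, multi-started from a small grid of rate
candidates; the model is linear in ``A`` so the amplitude is profiled
analytically at each candidate before gradient refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu

__all__ = [
    "DceSeries",
    "PkFit",
    "ParameterPseudoImages",
    "brix_enhancement",
    "fit_voxel_curve",
    "fit_volume",
    "compute_body_mask",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT_GRID",
]

#: (lower, upper) per parameter: A amplitude, k_ep [1/min], k_el [1/min]
DEFAULT_BOUNDS = ((0.0, 0.0, 0.0), (50.0, 10.0, 2.0))

#: multi-start candidates for (k_ep, k_el) in 1/min
DEFAULT_INIT_GRID = tuple(
    (kep, kel) for kep in (0.1, 0.5, 2.0) for kel in (0.01, 0.1, 0.5)
)

_K_EQUAL_EPS = 1e-6  # 1/min; below this |k_ep - k_el| uses the analytic limit
_K_ZERO_EPS = 1e-12


@dataclass
class DceSeries:
    """A 4D dynamic contrast-enhanced acquisition.

    Parameters
    ----------
    intensities
        Non-negative array of shape ``(x, y, z, t)``.
    timepoints
        Sample times in seconds since injection start; strictly
        increasing, first element 0 (pre-contrast baseline).
    tau
        Bolus injection duration in seconds.
    voxel_spacing
        Physical voxel size in mm per axis.
    """

    intensities: np.ndarray
    timepoints: np.ndarray
    tau: float = 7.0
    voxel_spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4D (x, y, z, t)")
        if self.timepoints.ndim != 1 or self.timepoints.size < 3:
            raise ValueError("need at least 3 timepoints")
        if self.intensities.shape[3] != self.timepoints.size:
            raise ValueError("time extent of intensities must match timepoints")
        if self.timepoints[0] != 0:
            raise ValueError("first timepoint must be the t=0 baseline")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def baseline(self) -> np.ndarray:
        """The pre-contrast volume S(0)."""
        return self.intensities[..., 0]


@dataclass
class PkFit:
    """Result of fitting one voxel's time-intensity curve."""

    A_amp: float
    k_ep: float
    k_el: float
    A_peak: float
    rss: float
    converged: bool
    # named for completeness of the compartment model; not fitted
    k_pe: float = 0.0
    k_in: float = 0.0


@dataclass
class ParameterPseudoImages:
    """Co-registered pharmacokinetic parameter volumes (A, k_ep, k_el)."""

    A: np.ndarray
    k_ep: np.ndarray
    k_el: np.ndarray
    body_mask: np.ndarray
    fit_quality: np.ndarray = field(default=None)  # residual sum of squares

    def __post_init__(self) -> None:
        shapes = {self.A.shape, self.k_ep.shape, self.k_el.shape, self.body_mask.shape}
        if len(shapes) != 1:
            raise ValueError("parameter volumes and body mask must share one shape")
        if self.fit_quality is None:
            self.fit_quality = np.zeros_like(self.A)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.A.shape

    def volumes(self) -> dict[str, np.ndarray]:
        return {"A": self.A, "k_ep": self.k_ep, "k_el": self.k_el}


def _h(k: float, t_min: np.ndarray, tau_min: float) -> np.ndarray:
    """Infusion kernel h(k, t) = ((e^{k u} - 1)/k) e^{-k t}, u = min(t, tau')."""
    u = np.minimum(t_min, tau_min)
    if k < _K_ZERO_EPS:
        return u * np.exp(-k * t_min)
    return np.expm1(k * u) / k * np.exp(-k * t_min)


def _dh_dk(k: float, t_min: np.ndarray, tau_min: float) -> np.ndarray:
    """d/dk of the infusion kernel (for the k_ep == k_el limit)."""
    u = np.minimum(t_min, tau_min)
    if k < _K_ZERO_EPS:
        # series: h = u - k(t u - u^2/2) + O(k^2)
        return -(t_min * u - 0.5 * u**2)
    eku = np.exp(k * u)
    term = (u * eku * k - (eku - 1.0)) / k**2
    return (term - np.expm1(k * u) / k * t_min) * np.exp(-k * t_min)


def brix_enhancement(t, A_amp: float, k_ep: float, k_el: float, tau: float):
    """Relative enhancement of the two-compartment constant-infusion model.

    Parameters
    ----------
    t
        Time(s) since injection start, seconds; scalar or array, >= 0.
    A_amp
        Dimensionless model amplitude.
    k_ep, k_el
        Back-transfer and elimination rate constants, 1/min, >= 0.
    tau
        Bolus infusion duration, seconds, > 0.

    Returns
    -------
    E(t), dimensionless, same shape as ``t``.  Continuous in all
    arguments; analytic limits are substituted for k -> 0 and for
    k_ep ~= k_el.  E(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if k_ep < 0 or k_el < 0:
        raise ValueError("rate constants must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")

    t_min = t / 60.0
    tau_min = tau / 60.0
    if A_amp == 0.0 or k_ep < _K_ZERO_EPS:
        return np.zeros_like(t_min)

    if abs(k_ep - k_el) < _K_EQUAL_EPS:
        k = 0.5 * (k_ep + k_el)
        # lim (h(k_el) - h(k_ep)) / (k_ep - k_el) = -dh/dk at k
        core = -_dh_dk(k, t_min, tau_min)
        E = (A_amp / tau_min) * k_ep * core
    else:
        E = (
            (A_amp / tau_min)
            * k_ep
            * (_h(k_el, t_min, tau_min) - _h(k_ep, t_min, tau_min))
            / (k_ep - k_el)
        )
    return E


def _unit_curves(timepoints: np.ndarray, candidates, tau: float) -> np.ndarray:
    """Model curves with A=1 for each (k_ep, k_el) candidate; shape (n, T)."""
    return np.array(
        [brix_enhancement(timepoints, 1.0, kep, kel, tau) for kep, kel in candidates]
    )


def fit_voxel_curve(
    timepoints,
    intensities,
    tau: float = 7.0,
    bounds=DEFAULT_BOUNDS,
    init_grid=DEFAULT_INIT_GRID,
    _unit_basis: np.ndarray | None = None,
) -> PkFit:
    """Fit the enhancement model to one voxel's time-intensity curve.

    The observed curve is converted to relative enhancement
    ``(S(t) - S(0)) / S(0)``.  Each ``init_grid`` rate candidate is scored
    with the analytically profiled optimal amplitude, and the two best
    candidates seed bounded least-squares refinements; the lowest-RSS
    refinement wins.  ``A_peak`` is the maximum of the fitted curve on a
    1-second grid over the acquisition window.

    The model curve is invariant under swapping (k_ep, k_el) with the
    amplitude rescaled so that A*k_ep is preserved; fits are therefore
    canonicalized to the physiological branch k_ep >= k_el (back-transfer
    faster than plasma elimination).

    A non-positive baseline marks the voxel unfittable: all parameters 0
    and ``converged=False``.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if timepoints.size < 4:
        raise ValueError("need the baseline plus at least 3 post-baseline points")
    s0 = intensities[0]
    if s0 <= 0:
        return PkFit(0.0, 0.0, 0.0, 0.0, 0.0, False)

    e_obs = (intensities - s0) / s0
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)

    basis = _unit_basis
    if basis is None:
        basis = _unit_curves(timepoints, init_grid, tau)
    # profile the amplitude: E = A * f, A* = <f, e>/<f, f>
    ff = np.einsum("ct,ct->c", basis, basis)
    fe = basis @ e_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        a_star = np.where(ff > 0, fe / np.maximum(ff, 1e-300), 0.0)
    a_star = np.clip(a_star, lo[0], hi[0])
    rss_grid = np.sum((a_star[:, None] * basis - e_obs) ** 2, axis=1)

    order = np.argsort(rss_grid, kind="stable")
    best = None
    converged = False
    for idx in order[:2]:
        kep0, kel0 = init_grid[idx]
        x0 = np.clip(
            np.array([a_star[idx], kep0, kel0]),
            lo + 1e-9,
            hi - 1e-9,
        )

        def resid(x):
            return brix_enhancement(timepoints, x[0], x[1], x[2], tau) - e_obs

        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol.x, rss)
            converged = bool(sol.success)

    x, rss = best
    if x[1] < x[2] and x[2] > 0:
        # mirrored representation of the same curve; swap to k_ep >= k_el
        x = np.array([x[0] * x[1] / x[2], x[2], x[1]])
    t_fine = np.arange(0.0, timepoints[-1] + 0.5, 1.0)
    curve = brix_enhancement(t_fine, x[0], x[1], x[2], tau)
    a_peak = float(max(curve.max(), 0.0))
    return PkFit(float(x[0]), float(x[1]), float(x[2]), a_peak, rss, converged)


def _brix_batch(t_min: np.ndarray, A: np.ndarray, k_ep: np.ndarray, k_el: np.ndarray, tau_min: float) -> np.ndarray:
    """Model curves for per-voxel parameter vectors; shapes (n,) -> (n, T).

    Vectorized twin of :func:`brix_enhancement` (times pre-converted to
    minutes); the k -> 0 and k_ep ~= k_el limits are substituted
    elementwise.
    """
    t = t_min[None, :]
    u = np.minimum(t, tau_min)

    def h(k):
        k = k[:, None]
        safe = np.maximum(k, _K_ZERO_EPS)
        return np.where(
            k < _K_ZERO_EPS, u, np.expm1(safe * u) / safe
        ) * np.exp(-k * t)

    def dh_dk(k):
        k = k[:, None]
        safe = np.maximum(k, _K_ZERO_EPS)
        eku = np.exp(safe * u)
        generic = ((u * eku * safe - (eku - 1.0)) / safe**2 - np.expm1(safe * u) / safe * t) * np.exp(-safe * t)
        series0 = -(t * u - 0.5 * u**2)
        return np.where(k < _K_ZERO_EPS, series0, generic)

    kep = k_ep[:, None]
    kel = k_el[:, None]
    degenerate = np.abs(kep - kel) < _K_EQUAL_EPS
    km = 0.5 * (k_ep + k_el)
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = (h(k_el) - h(k_ep)) / np.where(degenerate, 1.0, kep - kel)
    core = np.where(degenerate, -dh_dk(km), generic)
    E = (A[:, None] / tau_min) * kep * core
    return np.where(kep < _K_ZERO_EPS, 0.0, E)


def _fit_batch(Y: np.ndarray, timepoints: np.ndarray, tau: float, bounds, init_grid,
               max_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Bounded Levenberg-Marquardt fit of many curves at once.

    ``Y`` holds relative-enhancement curves, one row per voxel.  Each
    row is multi-started from the best init-grid candidate (amplitude
    profiled analytically) and refined with a damped Gauss-Newton
    iteration, all rows in lockstep.  Returns (params (n, 3), rss (n,)).
    """
    n, T = Y.shape
    t_min = timepoints / 60.0
    tau_min = tau / 60.0
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)

    F = _unit_curves(timepoints, init_grid, tau)  # (C, T)
    ff = np.einsum("ct,ct->c", F, F)
    a_star = np.clip((Y @ F.T) / np.maximum(ff, 1e-300), lo[0], hi[0])  # (n, C)
    rss_grid = (Y**2).sum(1)[:, None] - 2 * a_star * (Y @ F.T) + a_star**2 * ff
    best = np.argmin(rss_grid, axis=1)
    grid = np.asarray(init_grid, float)
    theta = np.column_stack(
        [a_star[np.arange(n), best], grid[best, 0], grid[best, 1]]
    )
    theta = np.clip(theta, lo, hi)

    def model(th):
        return _brix_batch(t_min, th[:, 0], th[:, 1], th[:, 2], tau_min)

    def rss_of(th):
        return ((model(th) - Y) ** 2).sum(1)

    lam = np.full(n, 1e-3)
    rss = rss_of(theta)
    eye = np.eye(3)
    stalled = 0
    for _ in range(max_iter):
        r = model(theta) - Y  # (n, T)
        J = np.empty((n, T, 3))
        for j in range(3):
            step = 1e-6 * np.maximum(np.abs(theta[:, j]), 1e-2)
            up = theta.copy()
            up[:, j] += step
            dn = theta.copy()
            dn[:, j] -= step
            J[:, :, j] = (model(up) - model(dn)) / (2 * step)[:, None]
        JtJ = np.einsum("ntj,ntk->njk", J, J)
        g = np.einsum("ntj,nt->nj", J, r)
        Aug = JtJ + lam[:, None, None] * (
            np.einsum("njj->nj", JtJ)[:, None, :] * eye + 1e-12 * eye
        )
        try:
            delta = np.linalg.solve(Aug, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - extreme degeneracy
            delta = np.zeros_like(g)
        cand = np.clip(theta + delta, lo, hi)
        rss_cand = rss_of(cand)
        improved = rss_cand < rss - 1e-16
        theta[improved] = cand[improved]
        rss = np.where(improved, rss_cand, rss)
        lam = np.where(improved, lam / 3.0, lam * 10.0)
        np.clip(lam, 1e-10, 1e10, out=lam)
        if improved.any():
            stalled = 0
        else:
            stalled += 1
            if stalled >= 5:
                break

    # canonical branch: k_ep >= k_el (mirror solutions are identical curves)
    swap = (theta[:, 1] < theta[:, 2]) & (theta[:, 2] > 0)
    a_swapped = theta[swap, 0] * theta[swap, 1] / theta[swap, 2]
    theta[swap, 0], theta[swap, 1], theta[swap, 2] = (
        a_swapped,
        theta[swap, 2].copy(),
        theta[swap, 1].copy(),
    )
    return theta, rss


def fit_volume(
    series: DceSeries,
    body_mask: np.ndarray,
    bounds=DEFAULT_BOUNDS,
    init_grid=DEFAULT_INIT_GRID,
) -> ParameterPseudoImages:
    """Voxelwise model fit inside ``body_mask`` -> parameter pseudoimages.

    Minimizes the same multi-start bounded least-squares objective as
    :func:`fit_voxel_curve` for every masked voxel, with all voxels
    iterated in lockstep (batched Levenberg-Marquardt) so whole-volume
    fitting stays at desk scale.  The A pseudoimage stores the
    fitted-curve peak ``A_peak``.  Deterministic given series, mask,
    bounds and init grid; voxels outside the mask (and voxels with a
    non-positive baseline) are zero.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if body_mask.shape != series.spatial_shape:
        raise ValueError("body_mask shape must match the series' spatial shape")

    shape = series.spatial_shape
    A = np.zeros(shape)
    k_ep = np.zeros(shape)
    k_el = np.zeros(shape)
    rss = np.zeros(shape)
    if not body_mask.any():
        return ParameterPseudoImages(A, k_ep, k_el, body_mask, rss)

    curves = series.intensities[body_mask]  # (n, T)
    s0 = curves[:, 0]
    fittable = s0 > 0
    Y = np.zeros_like(curves)
    Y[fittable] = curves[fittable] / s0[fittable, None] - 1.0

    theta = np.zeros((curves.shape[0], 3))
    rss_v = np.zeros(curves.shape[0])
    if fittable.any():
        th, rv = _fit_batch(Y[fittable], series.timepoints, series.tau, bounds, init_grid)
        theta[fittable] = th
        rss_v[fittable] = rv

    # peak of each fitted curve on a 1 s grid, chunked to bound memory
    t_fine = np.arange(0.0, series.timepoints[-1] + 0.5, 1.0) / 60.0
    a_peak = np.zeros(curves.shape[0])
    tau_min = series.tau / 60.0
    for start in range(0, curves.shape[0], 4096):
        sl = slice(start, start + 4096)
        E = _brix_batch(t_fine, theta[sl, 0], theta[sl, 1], theta[sl, 2], tau_min)
        a_peak[sl] = np.maximum(E.max(axis=1), 0.0)

    A[body_mask] = a_peak
    k_ep[body_mask] = theta[:, 1]
    k_el[body_mask] = theta[:, 2]
    rss[body_mask] = rss_v
    return ParameterPseudoImages(A, k_ep, k_el, body_mask, rss)


def compute_body_mask(baseline_volume: np.ndarray) -> np.ndarray:
    """Tissue-vs-air mask: Otsu threshold on the baseline, one closing."""
    vol = np.asarray(baseline_volume, dtype=float)
    if np.any(vol < 0):
        raise ValueError("baseline volume must be non-negative")
    if np.ptp(vol) == 0:
        warnings.warn("constant baseline volume: returning empty body mask")
        return np.zeros(vol.shape, dtype=bool)
    thr = threshold_otsu(vol)
    mask = vol > thr
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_closing(mask, structure=structure)
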