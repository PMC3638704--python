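"""Synthetic DCE-MR mammography phantom.

Generates a 4D dynamic series that emulates the target acquisition: one
pre-contrast baseline plus five post-contrast volumes 120 s apart, a 7 s
bolus, an ellipsoidal "body" of tissue with benign-like kinetics in air,
and embedded ellipsoidal lesions whose enhancement follows the
two-compartment model with class-specific (A, k_ep, k_el).  Malignant
tissue enhances fast and strongly (leaky, dense microvasculature),
benign tissue moderately, normal parenchyma weakly.  Additive Gaussian
noise (a stated fraction of the baseline signal) and optional in-plane
rigid motion of individual time frames emulate acquisition artifacts.

A simulated "second reader" segmentation — the truth mask randomly
eroded/dilated per lesion, with a per-lesion miss probability — lets the
reader-comparison t-test machinery be exercised without patient data.

The phantom makes no attempt at realistic breast anatomy, coil
inhomogeneity or k-space effects; it provides exact voxel ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pk import DceSeries, brix_enhancement

__all__ = [
    "KineticsClass",
    "Lesion",
    "PhantomSpec",
    "generate_phantom",
    "simulate_second_reader",
    "add_motion_artifact",
]

DEFAULT_TIMEPOINTS = (0.0, 120.0, 240.0, 360.0, 480.0, 600.0)


@dataclass(frozen=True)
class KineticsClass:
    """Two-compartment parameters of one tissue class."""

    A_amp: float
    k_ep: float  # 1/min
    k_el: float  # 1/min


DEFAULT_KINETICS = {
    "normal": KineticsClass(0.2, 0.2, 0.01),
    "benign": KineticsClass(1.0, 0.4, 0.02),
    "malignant": KineticsClass(2.0, 1.2, 0.05),
}


@dataclass(frozen=True)
class Lesion:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    kinetics: str = "malignant"  # key into the kinetics table


def _default_lesions(shape) -> tuple[Lesion, ...]:
    """Two malignant + one benign lesion, scaled from the 64x64x16 layout."""
    s = (shape[0] / 64.0, shape[1] / 64.0, shape[2] / 16.0)

    def scale(center, radii):
        return (
            tuple(c * f for c, f in zip(center, s)),
            tuple(max(r * f, 1.0) for r, f in zip(radii, s)),
        )

    return (
        Lesion(*scale((20, 24, 8), (5, 5, 3)), "malignant"),
        Lesion(*scale((40, 38, 7), (4, 4, 2)), "malignant"),
        Lesion(*scale((32, 18, 9), (4, 4, 2)), "benign"),
    )


@dataclass
class PhantomSpec:
    """Geometry, kinetics, acquisition and noise of one synthetic subject."""

    shape: tuple[int, int, int] = (64, 64, 16)
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    tau: float = 7.0
    body_center: tuple[float, float, float] | None = None   # default: volume centre
    body_radii: tuple[float, float, float] | None = None    # default: 0.45 * shape
    lesions: tuple[Lesion, ...] | None = None  # None -> shape-scaled defaults
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    baseline_intensity: float = 100.0
    noise_sd: float = 0.01          # fraction of the baseline signal
    noise_model: str = "gaussian"   # or "rician"
    motion_amplitude: int = 0       # voxels of in-plane shift
    reader2_error: tuple[int, float] = (1, 0.0)  # (morph radius, miss probability)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)
        if self.lesions is None:
            self.lesions = _default_lesions(self.shape)
        self.lesions = tuple(
            les if isinstance(les, Lesion) else Lesion(
                tuple(les["center"]), tuple(les["radii"]), les.get("kinetics", "malignant")
            )
            for les in self.lesions
        )
        self.kinetics = {
            k: v if isinstance(v, KineticsClass) else KineticsClass(*v)
            for k, v in self.kinetics.items()
        }
        if self.body_center is None:
            self.body_center = tuple((s - 1) / 2.0 for s in self.shape)
        if self.body_radii is None:
            self.body_radii = tuple(0.45 * s for s in self.shape)
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at the t=0 baseline")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = sum(((g - c) / rr) ** 2 for g, c, rr in zip(grids, center, radii))
    return r <= 1.0


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[DceSeries, np.ndarray, np.ndarray, np.ndarray]:
    """Build the synthetic series and its ground-truth masks.

    Returns ``(series, malignant_mask, benign_mask, body_mask)``.  Per
    voxel, S(t) = S0 * (1 + E(t; class)) inside the body (S0 the
    baseline intensity), 0 in air, plus i.i.d. noise of sd
    ``noise_sd * S0``; intensities are clipped at 0.  Deterministic per
    seed.
    """
    spec = spec or PhantomSpec()
    body = _ellipsoid_mask(spec.shape, spec.body_center, spec.body_radii)
    malignant = np.zeros(spec.shape, bool)
    benign = np.zeros(spec.shape, bool)
    class_map = np.full(spec.shape, -1, dtype=np.int8)  # -1 air
    names = list(spec.kinetics)
    class_map[body] = names.index("normal")
    for les in spec.lesions:
        m = _ellipsoid_mask(spec.shape, les.center, les.radii)
        if np.any(m & ~body):
            raise ValueError(f"lesion at {les.center} extends outside the body")
        class_map[m] = names.index(les.kinetics)
        if les.kinetics == "malignant":
            malignant |= m
        elif les.kinetics == "benign":
            benign |= m

    t = np.asarray(spec.timepoints, float)
    curves = np.zeros((len(names) + 1, t.size))  # last row: air (all zero)
    for ci, name in enumerate(names):
        k = spec.kinetics[name]
        curves[ci] = spec.baseline_intensity * (
            1.0 + brix_enhancement(t, k.A_amp, k.k_ep, k.k_el, spec.tau)
        )
    intensities = curves[class_map]  # air (-1) picks the zero row

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        sd = spec.noise_sd * spec.baseline_intensity
        if spec.noise_model == "gaussian":
            intensities = intensities + rng.normal(0.0, sd, intensities.shape)
        else:
            re = intensities + rng.normal(0.0, sd, intensities.shape)
            im = rng.normal(0.0, sd, intensities.shape)
            intensities = np.hypot(re, im)
        np.clip(intensities, 0.0, None, out=intensities)

    series = DceSeries(intensities, t, spec.tau)
    if spec.motion_amplitude > 0:
        series = add_motion_artifact(series, spec.motion_amplitude, spec.seed + 1)
    return series, malignant, benign, body


def simulate_second_reader(
    truth_mask: np.ndarray,
    reader2_error: tuple[int, float] = (1, 0.0),
    seed: int = 0,
    operation: str = "random",
) -> np.ndarray:
    """Perturb the truth segmentation like an independent human reader.

    Each connected lesion is independently missed with the stated
    probability; surviving lesions are eroded or dilated (``operation``
    'random', 'erode' or 'dilate') by the stated radius, emulating
    conservative/liberal boundary drawing.  Radius 0 with miss
    probability 0 reproduces the truth exactly.  Deterministic per seed.
    """
    truth = np.asarray(truth_mask, bool)
    if not truth.any():
        raise ValueError("truth mask is empty")
    radius, miss_p = reader2_error
    rng = np.random.default_rng(seed)
    labels, n = ndimage.label(truth)
    out = np.zeros(truth.shape, bool)
    structure = ndimage.generate_binary_structure(3, 1)
    for lab in range(1, n + 1):
        component = labels == lab
        if rng.random() < miss_p:
            continue
        if radius > 0:
            op = operation
            if op == "random":
                op = "dilate" if rng.random() < 0.5 else "erode"
            fn = ndimage.binary_dilation if op == "dilate" else ndimage.binary_erosion
            component = fn(component, structure=structure, iterations=radius)
        out |= component
    return out


def add_motion_artifact(series: DceSeries, amplitude: int, seed: int = 0) -> DceSeries:
    """Rigid in-plane shifts of a random subset of post-baseline frames.

    Each non-baseline frame is shifted (probability 1/2) by integer
    in-plane offsets drawn uniformly from [-amplitude, amplitude],
    producing edge intensity discontinuities between frames like patient
    motion does.  Amplitude 0 is the identity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return series
    rng = np.random.default_rng(seed)
    vol = series.intensities.copy()
    for ti in range(1, vol.shape[3]):
        if rng.random() < 0.5:
            dx, dy = rng.integers(-amplitude, amplitude + 1, size=2)
            vol[..., ti] = np.roll(vol[..., ti], (int(dx), int(dy)), axis=(0, 1))
    return DceSeries(vol, series.timepoints, series.tau, series.voxel_spacing)
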