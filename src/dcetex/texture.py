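"""3D co-occurrence (GLCM) texture analysis over a scanning volume of interest.

A small scanning volume of interest (SVOI, default 5x5x2 voxels with the
short axis through-plane) is raster scanned across each pharmacokinetic
parameter pseudoimage.  Within every window, one gray-level
co-occurrence matrix P_{theta,d}(a, b) is tallied per principal
direction (distance d=1, chessboard metric), symmetrized and normalized;
ten Haralick statistics of each matrix are assigned to the window
centroid, yielding one texture pseudoimage per (parameter, statistic,
direction) — 90 volumes per subject under the defaults.

The statistics are angular second moment, correlation, contrast, inverse
difference moment, variance, sum average, sum variance, sum entropy,
entropy and difference variance.  Difference entropy, the information
measures of correlation and the maximal correlation coefficient are
deliberately not part of the set.  Entropies are in bits; sum variance
is computed about the sum average (the accepted correction of the
original 1973 formula); correlation of a constant window is defined 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "STATISTIC_NAMES",
    "TextureConfig",
    "CooccurrenceMatrix",
    "TexturePseudoImages",
    "quantize_volume",
    "cooccurrence_matrix",
    "haralick_stats",
    "sliding_texture_maps",
    "texture_stage",
]

STATISTIC_NAMES = (
    "asm",
    "correlation",
    "contrast",
    "idm",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
)

PARAM_ORDER = ("A", "k_ep", "k_el")

_SIGMA_EPS = 1e-12


@dataclass
class TextureConfig:
    """Configuration of the SVOI texture scan."""

    svoi_shape: tuple[int, int, int] = (5, 5, 2)
    distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    levels: int = 16
    statistics: tuple[str, ...] = STATISTIC_NAMES

    def __post_init__(self) -> None:
        m, n, l = self.svoi_shape
        if l > m or l > n:
            raise ValueError("through-plane SVOI length must be the shortest")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        unknown = set(self.statistics) - set(STATISTIC_NAMES)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")
        for off in self.directions:
            if all(o == 0 for o in off):
                raise ValueError("zero direction offset")
            if self._pair_count(off) < 1:
                raise ValueError(f"direction {off} does not fit inside the SVOI")

    def _pair_count(self, direction) -> int:
        return int(
            np.prod(
                [
                    max(w - self.distance * abs(o), 0)
                    for w, o in zip(self.svoi_shape, direction)
                ]
            )
        )

    @property
    def centroid(self) -> tuple[int, int, int]:
        """Window-local index receiving the statistics (lower slice on even axes)."""
        return tuple((s - 1) // 2 for s in self.svoi_shape)


@dataclass
class CooccurrenceMatrix:
    """Symmetric normalized gray-level pair frequency matrix."""

    P: np.ndarray
    direction: tuple[int, int, int]
    d: int
    pair_count: int


@dataclass
class TexturePseudoImages:
    """Texture statistic volumes keyed by (parameter, statistic, direction)."""

    maps: dict[tuple[str, str, tuple[int, int, int]], np.ndarray]
    validity_mask: np.ndarray
    config: TextureConfig = field(default_factory=TextureConfig)

    def __len__(self) -> int:
        return len(self.maps)

    def parameters(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p, _, _ in self.maps:
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    def feature_stack(self) -> tuple[np.ndarray, list[tuple[str, str, tuple[int, int, int]]]]:
        """Stack maps into an (x, y, z, F) array with a deterministic key order."""
        keys = [
            (p, s, d)
            for p in self.parameters()
            for s in self.config.statistics
            for d in self.config.directions
        ]
        stack = np.stack([self.maps[k] for k in keys], axis=-1)
        return stack, keys


def quantize_volume(param_volume: np.ndarray, body_mask: np.ndarray, levels: int = 16) -> np.ndarray:
    """Linear gray-level binning of a continuous parameter volume.

    Bin edges are uniform between the 1st and 99th percentile of in-mask
    values (values outside are clipped), so a few extreme fit outliers
    cannot swallow the dynamic range.  Levels run 1..``levels``; voxels
    outside the mask get level 1.
    """
    vol = np.asarray(param_volume, dtype=float)
    mask = np.asarray(body_mask, dtype=bool)
    if levels < 2:
        raise ValueError("need at least 2 levels")
    if not mask.any():
        raise ValueError("body mask is empty")
    vals = vol[mask]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    out = np.ones(vol.shape, dtype=np.int32)
    if hi <= lo:
        warnings.warn("constant in-mask volume: all voxels assigned level 1")
        return out
    clipped = np.clip(vol, lo, hi)
    lev = 1 + np.floor((clipped - lo) / (hi - lo) * levels).astype(np.int32)
    np.clip(lev, 1, levels, out=lev)
    out[mask] = lev[mask]
    return out


def _pair_fields(vol: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (a, b) views such that b is a displaced by ``offset``."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, vol.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return vol[tuple(sl_a)], vol[tuple(sl_b)]


def cooccurrence_matrix(window: np.ndarray, direction, d: int = 1, levels: int = 16) -> CooccurrenceMatrix:
    """Symmetric normalized co-occurrence matrix of one integer window.

    Ordered pairs ``(v[x], v[x + d*direction])`` are tallied for every
    in-window position, the reverse pairs are added (symmetrization) and
    the matrix is normalized to sum 1.  ``pair_count`` is the number of
    ordered pairs, i.e. twice the forward pairs.
    """
    window = np.asarray(window)
    if window.min() < 1 or window.max() > levels:
        raise ValueError("window values must lie in 1..levels")
    offset = tuple(int(d) * int(o) for o in direction)
    a, b = _pair_fields(window, offset)
    if a.size == 0:
        raise ValueError(f"no valid pair for offset {offset} in window {window.shape}")
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (a.ravel() - 1, b.ravel() - 1), 1)
    counts = counts + counts.T
    total = counts.sum()
    P = counts / total
    return CooccurrenceMatrix(P, tuple(int(o) for o in direction), int(d), int(total))


def _marginal_reducer(levels: int):
    """Precompute permutations for the i+j and |i-j| GLCM marginals."""
    i = np.arange(1, levels + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    sum_key = (I + J).ravel()          # 2 .. 2G
    diff_key = np.abs(I - J).ravel()   # 0 .. G-1
    out = {}
    for name, key, kmin, ngroups in (
        ("sum", sum_key, 2, 2 * levels - 1),
        ("diff", diff_key, 0, levels),
    ):
        order = np.argsort(key, kind="stable")
        starts = np.searchsorted(key[order], np.arange(ngroups) + kmin)
        out[name] = (order, starts, np.arange(ngroups) + kmin)
    return i, I, J, out


def _haralick_batch(P: np.ndarray, levels: int) -> np.ndarray:
    """All ten statistics for a batch of normalized symmetric matrices.

    ``P`` has shape (n, G, G); returns (n, 10) in STATISTIC_NAMES order.
    """
    n = P.shape[0]
    i, I, J, reducers = _marginal_reducer(levels)
    flat = P.reshape(n, levels * levels)

    order_s, starts_s, ns = reducers["sum"]
    p_sum = np.add.reduceat(flat[:, order_s], starts_s, axis=1)
    order_d, starts_d, nd = reducers["diff"]
    p_diff = np.add.reduceat(flat[:, order_d], starts_d, axis=1)

    px = P.sum(axis=2)  # symmetric: px == py
    mu = px @ i
    sigma2 = ((i[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)

    asm = (P**2).sum(axis=(1, 2))
    corr_num = np.einsum("nij,ij->n", P, I * J) - mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(sigma2 > _SIGMA_EPS, corr_num / np.maximum(sigma2, _SIGMA_EPS), 0.0)
    contrast = p_diff @ (nd.astype(float) ** 2)
    idm = np.einsum("nij,ij->n", P, 1.0 / (1.0 + (I - J) ** 2))
    variance = ((I[None] - mu[:, None, None]) ** 2 * P).sum(axis=(1, 2))
    sa = p_sum @ ns.astype(float)
    sum_variance = ((ns[None, :] - sa[:, None]) ** 2 * p_sum).sum(axis=1)
    sum_entropy = -np.sum(np.where(p_sum > 0, p_sum * np.log2(np.maximum(p_sum, 1e-300)), 0.0), axis=1)
    entropy = -np.sum(np.where(flat > 0, flat * np.log2(np.maximum(flat, 1e-300)), 0.0), axis=1)
    da = p_diff @ nd.astype(float)
    difference_variance = ((nd[None, :] - da[:, None]) ** 2 * p_diff).sum(axis=1)

    return np.stack(
        [
            asm,
            correlation,
            contrast,
            idm,
            variance,
            sa,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
        ],
        axis=1,
    )


def haralick_stats(P) -> np.ndarray:
    """Ordered 10-vector of Haralick statistics of one co-occurrence matrix.

    Accepts a :class:`CooccurrenceMatrix` or a normalized square array.
    """
    if isinstance(P, CooccurrenceMatrix):
        P = P.P
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("P must be normalized to sum 1")
    return _haralick_batch(P[None], P.shape[0])[0]


def _canonical_direction(direction) -> tuple[int, int, int]:
    """Mirror-image directions give identical symmetric matrices; use the
    representative whose first non-zero component is positive."""
    off = tuple(int(o) for o in direction)
    for o in off:
        if o != 0:
            return off if o > 0 else tuple(-x for x in off)
    raise ValueError("zero direction offset")


def sliding_texture_maps(
    quantized_volume: np.ndarray,
    config: TextureConfig | None = None,
    param_name: str = "param",
) -> TexturePseudoImages:
    """Raster-scan the SVOI over one quantized parameter volume.

    For every position where the whole SVOI fits, one co-occurrence
    matrix per direction is computed and the ten statistics are written
    to the window centroid, producing ``len(statistics) * len(directions)``
    maps.  Border voxels never covered by a full window are zero and
    flagged false in the validity mask.
    """
    config = config or TextureConfig()
    vol = np.asarray(quantized_volume)
    w = config.svoi_shape
    if any(s < ws for s, ws in zip(vol.shape, w)):
        raise ValueError("volume smaller than the SVOI")
    G = config.levels
    if vol.min() < 1 or vol.max() > G:
        raise ValueError("quantized volume must hold levels 1..G")

    nwin_shape = tuple(s - ws + 1 for s, ws in zip(vol.shape, w))
    nwin = int(np.prod(nwin_shape))
    c = config.centroid
    validity = np.zeros(vol.shape, dtype=bool)
    validity[
        c[0] : c[0] + nwin_shape[0],
        c[1] : c[1] + nwin_shape[1],
        c[2] : c[2] + nwin_shape[2],
    ] = True

    stat_idx = [STATISTIC_NAMES.index(s) for s in config.statistics]
    maps: dict[tuple[str, str, tuple[int, int, int]], np.ndarray] = {}
    for direction in config.directions:
        off = tuple(config.distance * o for o in _canonical_direction(direction))
        a, b = _pair_fields(vol, off)
        codes = (a.astype(np.int64) - 1) * G + (b.astype(np.int64) - 1)
        pair_window = tuple(ws - abs(o) for ws, o in zip(w, off))
        win = sliding_window_view(codes, pair_window)
        win = win.reshape(nwin, -1)
        idx = np.arange(nwin, dtype=np.int64)[:, None] * (G * G) + win
        counts = np.bincount(idx.ravel(), minlength=nwin * G * G).reshape(nwin, G, G)
        counts = counts + counts.transpose(0, 2, 1)
        P = counts / counts.sum(axis=(1, 2), keepdims=True)
        stats = _haralick_batch(P, G)  # (nwin, 10)
        for si, sname in zip(stat_idx, config.statistics):
            m = np.zeros(vol.shape)
            m[validity] = stats[:, si]
            maps[(param_name, sname, direction)] = m
    return TexturePseudoImages(maps, validity, config)


def texture_stage(pseudo, config: TextureConfig | None = None) -> TexturePseudoImages:
    """Texture maps for all three pharmacokinetic parameter volumes.

    With the default configuration this yields exactly 90 maps
    (3 parameters x 10 statistics x 3 directions) sharing one validity
    mask.
    """
    config = config or TextureConfig()
    vols = pseudo.volumes()
    missing = [p for p in PARAM_ORDER if p not in vols]
    if missing:
        raise ValueError(f"missing parameter volumes: {missing}")
    maps: dict[tuple[str, str, tuple[int, int, int]], np.ndarray] = {}
    validity = None
    for p in PARAM_ORDER:
        q = quantize_volume(vols[p], pseudo.body_mask, config.levels)
        tp = sliding_texture_maps(q, config, param_name=p)
        maps.update(tp.maps)
        validity = tp.validity_mask
    return TexturePseudoImages(maps, validity, config)
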