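"""Rendering of capillary networks into OCT-like en-face frames.

A smoothed network is rendered by pasting an isotropic 2D Gaussian spot

    f(x, y) = Ic * exp(-[(x - x0)^2 + (y - y0)^2] / (2 sigma_c^2))

at every curve point; overlapping spots combine by pixelwise maximum, which
for identical spots is equivalent to evaluating the spot profile at the
distance to the nearest curve point.  The paired ground truth is the set of
pixels within ``gt_radius_mult * sigma_c`` of the curve — a purely geometric
rule, independent of intensity and of every noise parameter.

On top of the noiseless render the module adds (in order) bright speckle
patches — wide Gaussians of width ``k * sigma_c`` mimicking granular
speckle from melanin granules and backscattering tissue — and a Gaussian
background whose standard deviation realises a requested signal-to-noise
ratio ``SNR = 10 log10(Ic^2 / sigma_noise^2)`` in dB.  Capillary visibility
is intermittent in real data (red blood cells pass in bursts), which is
emulated by randomly fragmenting the curves before rendering, so each frame
shows a different subset of the same network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RenderParams",
    "FragmentationParams",
    "FramePair",
    "render_capillary_frame",
    "make_ground_truth",
    "add_gaussian_background",
    "add_speckle_patches",
    "fragment_curves",
    "synthesize_frame",
]


@dataclass(frozen=True)
class RenderParams:
    """Rendering, noise and speckle parameters for one frame.

    ic               : capillary peak intensity, normalised units (0.05-0.08).
    sigma_c          : Gaussian spread width of capillary spots in px (5-8);
                       sets the capillary lumen diameter.
    snr_db           : target signal-to-noise ratio in dB (1-10).
    k_speckle        : speckle width multiplier, sigma_speckle = k * sigma_c
                       (must exceed 4; default 8).
    i_speckle        : speckle patch peak; defaults to ic.
    n_speckle        : mean number of speckle patches per frame (Poisson);
                       0 gives a smooth background.
    gt_radius_mult   : ground-truth radius as a multiple of sigma_c.
    background_level : constant background offset so the additive noise is
                       not clipped at zero.
    noise_std        : optional direct override of the noise standard
                       deviation; when set it takes precedence over snr_db.
    """

    ic: float = 0.065
    sigma_c: float = 6.5
    snr_db: float = 5.0
    k_speckle: float = 8.0
    i_speckle: Optional[float] = None
    n_speckle: float = 3.0
    gt_radius_mult: float = 1.0
    background_level: float = 0.25
    noise_std: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ic <= 0:
            raise ValueError(f"ic must be positive, got {self.ic}")
        if self.sigma_c <= 0:
            raise ValueError(f"sigma_c must be positive, got {self.sigma_c}")
        if self.k_speckle <= 4:
            raise ValueError(
                f"k_speckle must exceed 4, got {self.k_speckle}"
            )
        if self.n_speckle < 0:
            raise ValueError(f"n_speckle must be >= 0, got {self.n_speckle}")
        if self.gt_radius_mult <= 0:
            raise ValueError("gt_radius_mult must be positive")

    @property
    def speckle_peak(self) -> float:
        return self.ic if self.i_speckle is None else self.i_speckle

    @property
    def sigma_noise(self) -> float:
        if self.noise_std is not None:
            return self.noise_std
        return self.ic / 10.0 ** (self.snr_db / 20.0)

    @classmethod
    def sample(cls, rng: np.random.Generator, speckled: bool = True,
               **overrides) -> "RenderParams":
        """Draw per-frame parameters from their default study ranges."""
        base = cls(
            ic=float(rng.uniform(0.05, 0.08)),
            sigma_c=float(rng.uniform(5.0, 8.0)),
            snr_db=float(rng.uniform(1.0, 10.0)),
            n_speckle=3.0 if speckled else 0.0,
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class FragmentationParams:
    """Random fragmentation of curve arclength into visible segments.

    Kept segments and gaps alternate along each curve with exponentially
    distributed lengths; ``keep_fraction`` is the approximate expected
    fraction of arclength visible in one frame.
    """

    keep_fraction: float = 0.6
    mean_segment_len: float = 20.0
    mean_gap_len: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.keep_fraction <= 1.0:
            raise ValueError(
                f"keep_fraction must lie in [0, 1], got {self.keep_fraction}"
            )
        if self.mean_segment_len <= 0 or self.mean_gap_len <= 0:
            raise ValueError("segment and gap means must be positive")


@dataclass
class FramePair:
    """One rendered intensity frame with its binary ground-truth mask."""

    intensity: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity {self.intensity.shape} and mask "
                f"{self.mask.shape} shapes differ"
            )


def _min_distance_map(
    curves: Sequence[np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    """Distance from every pixel center to the nearest curve point."""
    pts = [np.asarray(c, dtype=float).reshape(-1, 2) for c in curves if len(c)]
    if not pts:
        return np.full(shape, np.inf)
    allpts = np.concatenate(pts, axis=0)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    grid = np.stack([xs.ravel(), ys.ravel()], axis=-1).astype(float)
    d, _ = cKDTree(allpts).query(grid, k=1)
    return d.reshape(shape)


def render_capillary_frame(
    curves: Sequence[np.ndarray],
    shape: tuple[int, int],
    params: RenderParams,
) -> np.ndarray:
    """Noiseless render: Gaussian spots of peak ``ic`` and width ``sigma_c``
    pasted along the curves, combined by pixelwise maximum; background 0.

    For identical spots the maximum over spot centers equals the spot
    profile evaluated at the distance to the nearest curve point, which is
    how the render is computed (exactly, at subpixel precision).
    """
    d = _min_distance_map(curves, shape)
    out = np.zeros(shape, dtype=float)
    finite = np.isfinite(d)
    out[finite] = params.ic * np.exp(
        -(d[finite] ** 2) / (2.0 * params.sigma_c**2)
    )
    return out


def make_ground_truth(
    curves: Sequence[np.ndarray],
    shape: tuple[int, int],
    params: RenderParams,
) -> np.ndarray:
    """Binary mask of pixels within ``gt_radius_mult * sigma_c`` of the
    curves.  Depends only on geometry and sigma_c — never on intensity or
    noise parameters."""
    d = _min_distance_map(curves, shape)
    return d <= params.gt_radius_mult * params.sigma_c


def add_gaussian_background(
    image: np.ndarray,
    params: RenderParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add the constant background level plus white Gaussian noise whose
    standard deviation realises ``10 log10(ic^2 / sigma^2) = snr_db`` (or
    the explicit ``noise_std`` override), then clip to [0, 1]."""
    sigma = params.sigma_noise
    out = image + params.background_level + sigma * rng.standard_normal(image.shape)
    return np.clip(out, 0.0, 1.0)


def add_speckle_patches(
    image: np.ndarray,
    params: RenderParams,
    rng: np.random.Generator,
    count: Optional[int] = None,
) -> np.ndarray:
    """Add bright Gaussian patches of width ``k_speckle * sigma_c`` and peak
    ``i_speckle`` at uniformly random centers, combined with the existing
    intensities by pixelwise maximum.

    ``count`` fixes the number of patches; by default it is drawn from a
    Poisson law with mean ``n_speckle``.
    """
    if count is None:
        count = int(rng.poisson(params.n_speckle))
    if count < 0:
        raise ValueError("count must be >= 0")
    out = np.asarray(image, dtype=float).copy()
    if count == 0:
        return out
    sigma_sp = params.k_speckle * params.sigma_c
    ly, lx = image.shape
    ys, xs = np.mgrid[0:ly, 0:lx]
    for _ in range(count):
        cx = rng.uniform(0, lx - 1)
        cy = rng.uniform(0, ly - 1)
        patch = params.speckle_peak * np.exp(
            -((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma_sp**2)
        )
        out = np.maximum(out, patch)
    return out


def fragment_curves(
    curves: Sequence[np.ndarray],
    fparams: FragmentationParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Keep alternating exponential-length segments of each curve's
    arclength, dropping the gaps in between.

    The returned point sets are subsets of the input points; independent
    draws model the frame-to-frame intermittency of red-blood-cell flow.
    ``keep_fraction`` 1 keeps everything, 0 removes everything.
    """
    if fparams.keep_fraction >= 1.0:
        return [np.asarray(c, dtype=float).copy() for c in curves]
    if fparams.keep_fraction <= 0.0:
        return []
    out: list[np.ndarray] = []
    for curve in curves:
        pts = np.asarray(curve, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            continue
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        keep = np.zeros(len(pts), dtype=bool)
        pos = 0.0
        kept_state = bool(rng.random() < fparams.keep_fraction)
        while pos <= total:
            mean = (
                fparams.mean_segment_len if kept_state else fparams.mean_gap_len
            )
            length = float(rng.exponential(mean))
            if kept_state:
                keep |= (s >= pos) & (s < pos + length)
            pos += length
            kept_state = not kept_state
        if keep.any():
            out.append(pts[keep])
    return out


def synthesize_frame(
    network,
    rparams: RenderParams,
    fparams: FragmentationParams = FragmentationParams(),
    rng: Optional[np.random.Generator] = None,
    background_only: bool = False,
    shape: Optional[tuple[int, int]] = None,
) -> FramePair:
    """Full frame pipeline: fragment -> render -> ground truth (from the
    same fragmented curves) -> speckle patches -> Gaussian background.

    With ``background_only`` the intensity holds noise and speckle only and
    the mask is empty (a frame with no red-blood-cell flow).
    """
    if rng is None:
        rng = np.random.default_rng()
    if shape is None:
        if network is None:
            raise ValueError("shape is required when no network is given")
        shape = (network.domain.ly, network.domain.lx)
    if background_only or network is None:
        img = np.zeros(shape, dtype=float)
        mask = np.zeros(shape, dtype=bool)
    else:
        frag = fragment_curves(network.smoothed, fparams, rng)
        img = render_capillary_frame(frag, shape, rparams)
        mask = make_ground_truth(frag, shape, rparams)
    img = add_speckle_patches(img, rparams, rng)
    img = add_gaussian_background(img, rparams, rng)
    return FramePair(
        intensity=img,
        mask=mask,
        meta={
            "background_only": bool(background_only or network is None),
            "ic": rparams.ic,
            "sigma_c": rparams.sigma_c,
            "snr_db": rparams.snr_db,
        },
    )
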