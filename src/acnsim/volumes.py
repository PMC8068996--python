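"""Assembly of frames into sub-volumes and paired target image volumes.

A *sub-volume* stacks ~20 frames that share one capillary network but are
independently fragmented, with a few pure-background layers interlaced to
emulate instants with no red-blood-cell flow.  One or two sub-volumes of
different networks are embedded into a 128 x 128 x 64 target volume, kept
apart from each other and from the top/bottom z-boundaries; all remaining
slices are background-only frames.  Volumes are stored as 8-bit unsigned
multi-page TIFF stacks (input and ground truth separately) with a JSON
sidecar carrying placements and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .frames import FragmentationParams, RenderParams, synthesize_frame
from .pathways import (
    CapillaryNetwork,
    PotentialParams,
    WorkingDomain,
    build_network,
)

__all__ = [
    "SubVolume",
    "ACNVolume",
    "DatasetSpec",
    "VolumeFormatError",
    "build_subvolume",
    "assemble_target_volume",
    "quantize_to_8bit",
    "dequantize_8bit",
    "save_volume",
    "load_volume",
    "generate_dataset",
    "generate_desk_volume",
    "generate_volume",
    "validate_volume",
]


class VolumeFormatError(ValueError):
    """Raised when an on-disk volume is malformed or has wrong dimensions."""


@dataclass
class SubVolume:
    """Paired layer stacks (float [0,1] input, boolean GT) from one network."""

    input_stack: np.ndarray  # (n_layers, ly, lx) float
    gt_stack: np.ndarray  # (n_layers, ly, lx) bool
    background_layer_indices: list[int] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return self.input_stack.shape[0]


@dataclass
class ACNVolume:
    """Paired 8-bit input / ground-truth stacks with placement metadata.

    ``dims`` is (lx, ly, lz); arrays are indexed ``[z, y, x]``.  GT voxels
    are 0 or 255.  ``placements`` lists the half-open z-extents
    ``(z_start, z_stop)`` of each embedded sub-volume.
    """

    input_volume: np.ndarray  # (lz, ly, lx) uint8
    gt_volume: np.ndarray  # (lz, ly, lx) uint8, values {0, 255}
    placements: list[tuple[int, int]] = field(default_factory=list)
    seed: Optional[int] = None

    @property
    def dims(self) -> tuple[int, int, int]:
        lz, ly, lx = self.input_volume.shape
        return (lx, ly, lz)


@dataclass(frozen=True)
class DatasetSpec:
    """Recipe for a reproducible dataset of paired volumes.

    The full study scale is 10,400 smooth-background volumes split
    7000/3000/400 and 7,000 speckled volumes split 5200/1400/400; the
    defaults here are a desk-scale stand-in with the same structure.
    """

    n_volumes: int = 10
    background_kind: str = "speckled"  # "smooth" or "speckled"
    n_train: int = 7
    n_val: int = 2
    n_test: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_kind not in ("smooth", "speckled"):
            raise ValueError(
                f"background_kind must be 'smooth' or 'speckled', "
                f"got {self.background_kind!r}"
            )
        if self.n_train + self.n_val + self.n_test != self.n_volumes:
            raise ValueError(
                f"splits {self.n_train}+{self.n_val}+{self.n_test} "
                f"do not sum to n_volumes={self.n_volumes}"
            )

    def split_of(self, index: int) -> str:
        if index < self.n_train:
            return "train"
        if index < self.n_train + self.n_val:
            return "val"
        return "test"


def build_subvolume(
    network: CapillaryNetwork,
    rparams: RenderParams,
    fparams: FragmentationParams,
    n_layers: int = 20,
    n_background: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SubVolume:
    """Stack ``n_layers`` frames of one network with independent
    fragmentation per layer, inserting ``n_background`` pure-background
    layers (default: uniform in {1, 2, 3}) at random positions."""
    if rng is None:
        rng = np.random.default_rng()
    if n_background is None:
        n_background = int(rng.integers(1, 4))
    if n_background >= n_layers:
        raise ValueError(
            f"n_background={n_background} must be < n_layers={n_layers}"
        )
    bg_idx = sorted(
        int(i) for i in rng.choice(n_layers, size=n_background, replace=False)
    )
    bg_set = set(bg_idx)
    frames = [
        synthesize_frame(
            network, rparams, fparams, rng, background_only=(i in bg_set)
        )
        for i in range(n_layers)
    ]
    return SubVolume(
        input_stack=np.stack([f.intensity for f in frames]),
        gt_stack=np.stack([f.mask for f in frames]),
        background_layer_indices=bg_idx,
    )


def assemble_target_volume(
    subvolumes: Sequence[SubVolume],
    rparams: RenderParams,
    dims: tuple[int, int, int] = (128, 128, 64),
    rng: Optional[np.random.Generator] = None,
    min_gap: int = 2,
    margin: int = 1,
    seed: Optional[int] = None,
) -> ACNVolume:
    """Embed 1-2 sub-volumes at random, well-separated z-positions.

    Placements keep at least ``margin`` background slices at the top and
    bottom of the stack and at least ``min_gap`` between sub-volumes; every
    slice not covered by a sub-volume is a background-only frame.  Raises
    when the sub-volumes cannot fit with the required margins.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 1 <= len(subvolumes) <= 2:
        raise ValueError(f"expected 1 or 2 sub-volumes, got {len(subvolumes)}")
    lx, ly, lz = dims
    lengths = [sv.n_layers for sv in subvolumes]
    k = len(subvolumes)
    free = lz - 2 * margin - sum(lengths) - min_gap * (k - 1)
    if free < 0:
        raise ValueError(
            f"sub-volumes of lengths {lengths} do not fit in depth {lz} "
            f"with margin {margin} and gap {min_gap}"
        )
    # distribute the slack uniformly over the k+1 inter-block gaps
    extra = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    placements: list[tuple[int, int]] = []
    z = margin + int(extra[0])
    for i, sv in enumerate(subvolumes):
        placements.append((z, z + lengths[i]))
        z += lengths[i] + int(extra[i + 1])
        if i < k - 1:
            z += min_gap

    input_vol = np.zeros((lz, ly, lx), dtype=float)
    gt_vol = np.zeros((lz, ly, lx), dtype=bool)
    covered = np.zeros(lz, dtype=bool)
    for (z0, z1), sv in zip(placements, subvolumes):
        if sv.input_stack.shape[1:] != (ly, lx):
            raise ValueError(
                f"sub-volume layer shape {sv.input_stack.shape[1:]} does not "
                f"match target ({ly}, {lx})"
            )
        input_vol[z0:z1] = sv.input_stack
        gt_vol[z0:z1] = sv.gt_stack
        covered[z0:z1] = True
    for zi in np.flatnonzero(~covered):
        pair = synthesize_frame(
            None, rparams, rng=rng, background_only=True, shape=(ly, lx)
        )
        input_vol[zi] = pair.intensity
    return ACNVolume(
        input_volume=quantize_to_8bit(input_vol),
        gt_volume=np.where(gt_vol, np.uint8(255), np.uint8(0)),
        placements=placements,
        seed=seed,
    )


def quantize_to_8bit(volume: np.ndarray) -> np.ndarray:
    """Map reals in [0, 1] to uint8 by ``round(v * 255)`` (half away from
    zero).  Out-of-range values are an error — clipping is the renderer's
    responsibility."""
    v = np.asarray(volume, dtype=float)
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise ValueError(
            f"values outside [0, 1]: min={v.min():.4g}, max={v.max():.4g}"
        )
    return np.floor(v * 255.0 + 0.5).astype(np.uint8)


def dequantize_8bit(volume: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quantize_to_8bit` up to the 1/510 quantization bound."""
    return np.asarray(volume, dtype=float) / 255.0


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _stack_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return (
        base.with_name(base.name + "_input.tif"),
        base.with_name(base.name + "_gt.tif"),
    )


def save_volume(vol: ACNVolume, path: str | Path) -> None:
    """Write a volume as two multi-page 8-bit TIFF stacks plus a JSON
    sidecar (``<path>_input.tif``, ``<path>_gt.tif``, ``<path>.json``)."""
    path = Path(path)
    inp, gt = _stack_paths(path)
    tifffile.imwrite(inp, vol.input_volume, photometric="minisblack")
    tifffile.imwrite(gt, vol.gt_volume, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "dims": list(vol.dims),
                "placements": [list(p) for p in vol.placements],
                "seed": vol.seed,
            }
        )
    )


def load_volume(path: str | Path) -> ACNVolume:
    """Read a volume written by :func:`save_volume`; lossless round trip."""
    path = Path(path)
    try:
        meta = json.loads(_sidecar(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise VolumeFormatError(f"cannot read sidecar for {path}: {exc}") from exc
    inp_path, gt_path = _stack_paths(path)
    try:
        input_volume = tifffile.imread(inp_path)
        gt_volume = tifffile.imread(gt_path)
    except (OSError, ValueError) as exc:
        raise VolumeFormatError(f"cannot read stacks for {path}: {exc}") from exc
    lx, ly, lz = meta["dims"]
    for name, arr in (("input", input_volume), ("gt", gt_volume)):
        if arr.shape != (lz, ly, lx):
            raise VolumeFormatError(
                f"{name} stack shape {arr.shape} does not match recorded "
                f"dims (lz={lz}, ly={ly}, lx={lx})"
            )
    return ACNVolume(
        input_volume=input_volume,
        gt_volume=gt_volume,
        placements=[tuple(p) for p in meta["placements"]],
        seed=meta["seed"],
    )


def _derived_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_volume(
    seed: int,
    dims: tuple[int, int, int] = (128, 128, 64),
    background_kind: str = "speckled",
    n_layers: int = 20,
    potential: PotentialParams = PotentialParams(),
    fparams: FragmentationParams = FragmentationParams(),
) -> ACNVolume:
    """Generate one paired volume from a single seed: 1-2 sub-volumes of
    different networks (3-6 end points each), per-network render parameters
    drawn from the study ranges."""
    rng = np.random.default_rng(seed)
    lx, ly, lz = dims
    domain = WorkingDomain(lx=lx, ly=ly)
    n_sub = int(rng.integers(1, 3))
    speckled = background_kind == "speckled"
    subvols = []
    rparams = None
    for _ in range(n_sub):
        rparams = RenderParams.sample(rng, speckled=speckled)
        net = build_network(
            domain,
            n_endpoints=int(rng.integers(3, 7)),
            params=potential,
            seed=int(rng.integers(2**31)),
        )
        subvols.append(
            build_subvolume(net, rparams, fparams, n_layers=n_layers, rng=rng)
        )
    return assemble_target_volume(
        subvols, rparams, dims=dims, rng=rng, seed=seed
    )


def generate_desk_volume(
    seed: int,
    dims: tuple[int, int, int] = (32, 32, 8),
    n_layers: int = 5,
    rparams: Optional[RenderParams] = None,
    fparams: FragmentationParams = FragmentationParams(keep_fraction=0.7),
) -> ACNVolume:
    """One small paired volume for desk-scale experiments.

    Uses a single 3-end-point network and render parameters scaled to the
    small domain (capillary width proportional to the frame), so the
    capillaries still occupy a minor fraction of each frame and the
    background remains the modal pixel value, as in full-size volumes.
    """
    rng = np.random.default_rng(seed)
    lx, ly, lz = dims
    if rparams is None:
        rparams = RenderParams(
            ic=0.065, sigma_c=2.5, snr_db=6.0, n_speckle=0.0
        )
    net = build_network(
        WorkingDomain(lx=lx, ly=ly), 3, seed=seed, margin=4
    )
    sv = build_subvolume(
        net, rparams, fparams, n_layers=n_layers, n_background=1, rng=rng
    )
    return assemble_target_volume([sv], rparams, dims=dims, rng=rng, seed=seed)


def generate_dataset(
    spec: DatasetSpec,
    out_dir: str | Path,
    dims: tuple[int, int, int] = (128, 128, 64),
    n_layers: int = 20,
) -> dict:
    """Generate ``spec.n_volumes`` paired volumes with per-volume seeds
    derived from the master seed, write them under ``out_dir`` and return
    (and write) a manifest of paths, seeds and split assignments."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(spec.n_volumes):
        vol_seed = _derived_seed(spec.seed, i)
        try:
            vol = generate_volume(
                vol_seed,
                dims=dims,
                background_kind=spec.background_kind,
                n_layers=n_layers,
            )
            stem = f"vol_{i:05d}"
            save_volume(vol, out_dir / stem)
        except OSError as exc:
            raise OSError(f"failed writing volume {i}: {exc}") from exc
        entries.append(
            {
                "index": i,
                "path": stem,
                "seed": vol_seed,
                "split": spec.split_of(i),
            }
        )
    manifest = {
        "master_seed": spec.seed,
        "background_kind": spec.background_kind,
        "dims": list(dims),
        "n_layers": n_layers,
        "volumes": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_volume(
    vol: ACNVolume,
    dims: tuple[int, int, int] = (128, 128, 64),
    min_gap: int = 2,
    margin: int = 1,
) -> list[str]:
    """Check every structural invariant of a generated volume; returns a
    list of violation messages (empty when the volume is valid)."""
    problems: list[str] = []
    if vol.dims != tuple(dims):
        problems.append(f"dims {vol.dims} != expected {tuple(dims)}")
    for name, arr in (("input", vol.input_volume), ("gt", vol.gt_volume)):
        if arr.dtype != np.uint8:
            problems.append(f"{name} dtype {arr.dtype} is not uint8")
    vals = np.unique(vol.gt_volume)
    if not np.all(np.isin(vals, [0, 255])):
        problems.append(f"gt values {vals.tolist()} are not binary {{0, 255}}")
    lz = vol.input_volume.shape[0]
    if not 1 <= len(vol.placements) <= 2:
        problems.append(f"{len(vol.placements)} placements (expected 1 or 2)")
    prev_end = None
    for z0, z1 in sorted(vol.placements):
        if z0 < margin or z1 > lz - margin:
            problems.append(
                f"placement ({z0}, {z1}) violates the {margin}-slice "
                f"top/bottom margin"
            )
        if prev_end is not None and z0 - prev_end < min_gap:
            problems.append(
                f"placements separated by {z0 - prev_end} < {min_gap} slices"
            )
        prev_end = z1
    covered = np.zeros(lz, dtype=bool)
    for z0, z1 in vol.placements:
        covered[max(z0, 0) : min(z1, lz)] = True
    outside = vol.gt_volume[~covered]
    if outside.size and outside.max() > 0:
        problems.append("ground-truth foreground outside every sub-volume")
    return problems
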