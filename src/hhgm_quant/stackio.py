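"""Stack I/O and shared intensity primitives.

Reading/writing goes through :mod:`tifffile` (OME-TIFF, axes ZCYX) with the
physical voxel sizes stored in the OME metadata and, for synthetic stacks, a
JSON sidecar holding the ground truth. The enhancement and thresholding
primitives here (histogram truncation, CLAHE, local-background threshold
estimation) are shared by the segmentation, collagen and orientation stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage import exposure

from .volume import VolumeStack
from .synthstack import SceneTruth

__all__ = [
    "ThresholdEstimate",
    "read_stack",
    "write_stack",
    "histogram_truncate",
    "clahe_enhance",
    "estimate_background_threshold",
]


@dataclass
class ThresholdEstimate:
    """Intensity threshold from averaged local background regions."""

    value: float
    n_regions: int
    region_means: list[float]
    channel: str

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_stack(stack: VolumeStack, path, truth: SceneTruth | None = None) -> Path:
    """Write a stack as OME-TIFF (axes ZCYX, float32) with voxel metadata.

    If ``truth`` is given, a ``<stem>.truth.json`` sidecar is written next to
    the TIFF.
    """
    path = Path(path)
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=1)  # Z C Y X
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.voxel_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel_z,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )
    if truth is not None:
        path.with_suffix(".truth.json").write_text(truth.to_json())
    return path


def read_stack(
    path,
    channel_map: dict[int, str] | list[str] | None = None,
    voxel_xy: float | None = None,
    voxel_z: float | None = None,
    stack_id: str = "",
    group: str = "",
) -> VolumeStack:
    """Read a multichannel z-stack from TIFF.

    ``channel_map`` names the channels in index order (list) or by index
    (dict). For OME-TIFFs written by :func:`write_stack` the channel names
    and voxel sizes stored in the file are used; explicit ``voxel_xy`` /
    ``voxel_z`` arguments override file metadata. Reading fails if voxel
    sizes are available neither from the file nor from the arguments, and if
    ``channel_map`` names more channels than the file holds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
        meta_names: list[str] | None = None
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            pix = root.find(".//ome:Pixels", ns)
            if pix is not None:
                if voxel_xy is None and pix.get("PhysicalSizeX"):
                    voxel_xy = float(pix.get("PhysicalSizeX"))
                if voxel_z is None and pix.get("PhysicalSizeZ"):
                    voxel_z = float(pix.get("PhysicalSizeZ"))
                chans = pix.findall("ome:Channel", ns)
                names = [c.get("Name") for c in chans]
                if names and all(names):
                    meta_names = names
    if voxel_xy is None or voxel_z is None:
        raise ValueError(
            f"{path}: voxel sizes unknown; file metadata lacks them and no "
            "explicit voxel_xy/voxel_z given"
        )
    # normalize array to (Z, C, Y, X)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if axes == "CYX":
            arr = arr[None]
        else:  # treat leading axis as Z, single channel
            arr = arr[:, None]
    elif arr.ndim == 4:
        if axes == "CZYX":
            arr = np.moveaxis(arr, 0, 1)
        # else assume ZCYX
    else:
        raise ValueError(f"{path}: unsupported array rank {arr.ndim}")
    n_chan = arr.shape[1]
    if channel_map is None:
        names = meta_names or [f"ch{i}" for i in range(n_chan)]
    elif isinstance(channel_map, dict):
        names = [channel_map.get(i, f"ch{i}") for i in range(n_chan)]
        if max(channel_map) >= n_chan:
            raise ValueError(
                f"{path}: channel_map names channel {max(channel_map)} but "
                f"file holds only {n_chan} channel(s)"
            )
    else:
        names = list(channel_map)
        if len(names) != n_chan:
            raise ValueError(
                f"{path}: channel_map names {len(names)} channels but file "
                f"holds {n_chan}"
            )
    channels = {name: arr[:, i] for i, name in enumerate(names)}
    return VolumeStack(channels, voxel_xy, voxel_z,
                       stack_id or path.stem, group)


def read_truth(path) -> SceneTruth:
    """Read the ground-truth sidecar written by :func:`write_stack`."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".truth.json")
    return SceneTruth.from_json(path.read_text())


# ---------------------------------------------------------------------------
# enhancement / thresholding primitives
# ---------------------------------------------------------------------------

def histogram_truncate(image: np.ndarray, upper_percentile: float = 99.5) -> np.ndarray:
    """Clip outlier-bright pixels to the given upper percentile.

    Monotone and idempotent; a constant image is returned unchanged.
    """
    if not (0.0 < upper_percentile <= 100.0):
        raise ValueError("upper_percentile must lie in (0, 100]")
    image = np.asarray(image, dtype=float)
    if image.size == 0 or image.max() == image.min():
        return image.copy()
    # "lower" keeps the cap an actual data value, making clipping idempotent
    cap = np.percentile(image, upper_percentile, method="lower")
    return np.minimum(image, cap)


def clahe_enhance(image: np.ndarray, clip_limit: float = 0.01,
                  tile_shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1]."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    norm = (image - lo) / (hi - lo)
    kernel = tuple(min(t, s) for t, s in zip(tile_shape, image.shape))
    return exposure.equalize_adapthist(norm, kernel_size=kernel,
                                       clip_limit=clip_limit)


def estimate_background_threshold(
    stack: VolumeStack,
    channel: str,
    region_size_px: int = 32,
    n_regions: int = 5,
    selection: str = "auto",
    regions: list[tuple[int, int, int]] | None = None,
    seed: int = 0,
) -> ThresholdEstimate:
    """Estimate the background intensity threshold of a channel.

    The threshold is the mean of the mean intensities of several local
    background regions. With ``selection="auto"`` the candidate regions are
    square patches on a stratified grid over all layers and the ``n_regions``
    lowest-mean patches are taken (a reproducible stand-in for picking
    background areas by eye); with ``selection="manual"``, ``regions`` gives
    explicit (layer, y, x) upper-left corners.
    """
    img = stack.channel(channel)
    nz, ny, nx = img.shape
    s = int(region_size_px)
    if s > ny or s > nx:
        raise ValueError(f"region size {s} exceeds layer shape {(ny, nx)}")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    means = []
    if selection == "manual":
        if not regions:
            raise ValueError("manual selection requires explicit regions")
        for (z, y, x) in regions:
            patch = img[z, y:y + s, x:x + s]
            if patch.shape != (s, s):
                raise ValueError(f"region at {(z, y, x)} does not fit the layer")
            means.append(float(patch.mean()))
    elif selection == "auto":
        grid_means = []
        for z in range(nz):
            for y in range(0, ny - s + 1, s):
                for x in range(0, nx - s + 1, s):
                    grid_means.append(float(img[z, y:y + s, x:x + s].mean()))
        grid_means.sort()
        means = grid_means[: n_regions]
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    value = float(np.mean(means))
    return ThresholdEstimate(value, len(means), means, channel)
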