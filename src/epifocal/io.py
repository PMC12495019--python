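"""Reading and writing stacks, in-focus images, labels and reports.

Stacks are multi-page TIFF (plain or OME); acquisition metadata that TIFF
does not carry natively (channel roles, pixel size) travels in a small JSON
sidecar written next to the image, which round-trips exactly.  For OME-TIFF
input, channel roles may alternatively be resolved by OME channel *name*.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import tifffile

from .focal import DAPI, ImageStack, InFocusImage

SIDECAR_SUFFIX = ".meta.json"

#: deterministic channel order used when writing in-focus images
INFOCUS_ORDER = ("dapi", "protein_a", "protein_b")


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + SIDECAR_SUFFIX)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(stack.voxels, dtype=np.float32),
        photometric="minisblack",
    )
    meta = {
        "channel_roles": stack.channel_roles,
        "pixel_size_um": stack.pixel_size_um,
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str]:
    if not tif.ome_metadata:
        return []
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return []
    names = []
    for ch in root.iter():
        if ch.tag.endswith("Channel"):
            names.append(ch.attrib.get("Name", ""))
    return names


def read_stack(
    path: str | Path,
    channel_map: dict[str, int | str] | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a multichannel z-stack into an :class:`ImageStack`.

    ``channel_map`` maps role names to channel indices (or, for OME-TIFF,
    to channel names).  When omitted, the JSON sidecar written by
    :func:`write_stack` supplies roles and pixel size; an explicit
    ``pixel_size_um`` overrides everything.  A stack without a resolvable
    DAPI channel or pixel size is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        ome_names = _ome_channel_names(tif)
    if voxels.ndim == 3:  # single channel (z, y, x)
        voxels = voxels[None]
    if voxels.ndim != 4:
        raise ValueError(f"expected a (C, Z, Y, X) stack, got shape {voxels.shape}")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    roles: dict[str, int] = {}
    cmap = channel_map if channel_map is not None else meta.get("channel_roles")
    if cmap is None:
        raise ValueError("no channel map given and no metadata sidecar found")
    for role, ref in cmap.items():
        if isinstance(ref, str):
            if ref not in ome_names:
                raise ValueError(
                    f"channel name {ref!r} not present in OME metadata {ome_names}"
                )
            roles[role] = ome_names.index(ref)
        else:
            roles[role] = int(ref)
    if DAPI not in roles:
        raise ValueError("channel map must include a DAPI channel")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            "pixel size not found in metadata; pass pixel_size_um explicitly"
        )
    return ImageStack(voxels=voxels, channel_roles=roles, pixel_size_um=float(px))


def write_infocus(infocus: InFocusImage, path: str | Path) -> Path:
    """Write an in-focus image as a 16-bit multichannel TIFF + sidecar.

    Channels are stored in the fixed order DAPI, protein A, protein B
    (whichever are present), rounded and clipped to the uint16 range.
    """
    path = Path(path)
    roles = [r for r in INFOCUS_ORDER if r in infocus.channels]
    data = np.stack(
        [np.clip(np.rint(infocus[r]), 0, 65535).astype(np.uint16) for r in roles]
    )
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"channel_order": roles, "pixel_size_um": infocus.pixel_size_um}
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def read_infocus(path: str | Path) -> InFocusImage:
    """Read back an in-focus image written by :func:`write_infocus`."""
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if data.ndim == 2:
        data = data[None]
    channels = {
        role: data[i].astype(float) for i, role in enumerate(meta["channel_order"])
    }
    return InFocusImage(channels=channels, pixel_size_um=meta["pixel_size_um"])


def write_labels(cell_id: np.ndarray, compartment: np.ndarray, path: str | Path) -> Path:
    """Write cell ids (uint16) and compartments (uint8) as a 2-page TIFF pair."""
    path = Path(path)
    tifffile.imwrite(path, cell_id.astype(np.uint16), photometric="minisblack")
    comp_path = path.with_name(path.stem + "_compartments" + path.suffix)
    tifffile.imwrite(comp_path, compartment.astype(np.uint8), photometric="minisblack")
    return path


def write_json(obj, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, repr floats)."""
    path = Path(path)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not isinstance(v, np.ndarray)}
    raise TypeError(f"not JSON serializable: {type(obj)}")
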