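"""Multi-channel image container and TIFF round-trip.

A :class:`ChannelStack` is a set of co-registered 2D intensity arrays keyed by
*channel role* — what the channel shows, not which detector produced it.
Canonical roles used throughout the package:

``membrane_marker``
    sarcolemmal/plasma-membrane reference (SGCA immunostain or DiD dye)
``target``
    protein of interest (POPDC1/POPDC2 immunostain)
``nucleus``
    DAPI / Hoechst-33342 counterstain
``transfection_control``
    internal transfection reporter (mRFP in BiFC fields)
``interaction``
    reconstituted split-fluorophore (Venus) signal

Reporter channels in co-transfection fields use free-form roles (e.g.
``reporter_popdc1``); any role string is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

MEMBRANE_MARKER = "membrane_marker"
TARGET = "target"
NUCLEUS = "nucleus"
TRANSFECTION_CONTROL = "transfection_control"
INTERACTION = "interaction"


class ChannelRoleError(KeyError):
    """A required channel role is missing from the stack."""


@dataclass
class ChannelStack:
    """Co-registered multi-channel 2D image with a channel-role map.

    Parameters
    ----------
    channels
        Mapping of role name to a 2D non-negative float array. All arrays
        must share one shape.
    pixel_size_um
        Physical pixel edge length in micrometres; must be positive.
    image_id
        Free-form identifier propagated into every measurement row.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    image_id: str = "image"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2D arrays")
        clean = {}
        for role, arr in self.channels.items():
            a = np.asarray(arr, dtype=float)
            if np.any(a < 0):
                raise ValueError(f"channel {role!r} has negative intensities")
            clean[role] = a
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise ChannelRoleError(
                f"channel role {role!r} not present; have {sorted(self.channels)}"
            ) from None

    def has(self, role: str) -> bool:
        return role in self.channels

    def with_channels(self, channels: dict[str, np.ndarray]) -> "ChannelStack":
        """Copy of the stack with ``channels`` replaced."""
        return ChannelStack(channels, self.pixel_size_um, self.image_id)

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path: str | Path) -> Path:
        """Write a multi-page TIFF (one page per role, sorted) with the role
        map and pixel size embedded as JSON in the ImageDescription tag.

        Intensities are quantised to 16-bit on export.
        """
        path = Path(path)
        roles = sorted(self.channels)
        pages = []
        for role in roles:
            a = self.channels[role]
            pages.append(np.clip(np.round(a), 0, 65535).astype(np.uint16))
        meta = {
            "popdcquant": {
                "roles": roles,
                "pixel_size_um": self.pixel_size_um,
                "image_id": self.image_id,
            }
        }
        tifffile.imwrite(
            path,
            np.stack(pages),
            photometric="minisblack",
            description=json.dumps(meta, sort_keys=True),
        )
        return path

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        channel_map: dict[str, int] | None = None,
        pixel_size_um: float | None = None,
        image_id: str | None = None,
    ) -> "ChannelStack":
        """Read a multi-page TIFF.

        If the file was written by :meth:`to_tiff` the embedded role map is
        used; otherwise ``channel_map`` (role -> page index) is required.
        """
        path = Path(path)
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        if data.ndim == 2:
            data = data[None]
        meta = None
        if desc:
            try:
                meta = json.loads(desc).get("popdcquant")
            except (ValueError, AttributeError):
                meta = None
        if meta is not None and channel_map is None:
            roles = meta["roles"]
            channels = {role: data[i].astype(float) for i, role in enumerate(roles)}
            px = pixel_size_um if pixel_size_um is not None else float(meta["pixel_size_um"])
            iid = image_id if image_id is not None else str(meta["image_id"])
        else:
            if channel_map is None:
                raise ValueError(
                    f"{path} has no embedded role map; supply channel_map (role -> page index)"
                )
            indices = list(channel_map.values())
            if len(set(indices)) != len(indices):
                raise ValueError("channel_map page indices must be unique")
            channels = {role: data[i].astype(float) for role, i in channel_map.items()}
            px = pixel_size_um if pixel_size_um is not None else 1.0
            iid = image_id if image_id is not None else path.stem
        return cls(channels, px, iid)


@dataclass
class ChannelMap:
    """Role -> TIFF page index map for externally produced images."""

    roles: dict[str, int]
    pixel_size_um: float = 1.0
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = list(self.roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "ChannelMap":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            roles={str(k): int(v) for k, v in cfg["roles"].items()},
            pixel_size_um=float(cfg.get("pixel_size_um", 1.0)),
            display_names=cfg.get("display_names", {}) or {},
        )
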