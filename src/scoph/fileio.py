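"""Image-file organization and TIFF IO.

Acquisition software writes one file per position/channel/frame (or one
multi-frame stack per position/channel); before analysis the files are
sorted into a per-position, per-channel manifest in acquisition order.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["DEFAULT_PATTERN", "STACK_PATTERN", "sort_images", "load_position_stacks"]

# Per-frame files: pos{P:03d}_{channel}_t{frame:03d}.tif
DEFAULT_PATTERN = r"pos(?P<position>\d+)_(?P<channel>[A-Za-z0-9_]+?)_t(?P<frame>\d+)\.tiff?$"
# Multi-frame stacks: pos{P:03d}_{CHANNEL}.tif
STACK_PATTERN = r"pos(?P<position>\d+)_(?P<channel>[A-Za-z0-9_]+)\.tiff?$"


class DataError(RuntimeError):
    """Malformed or inconsistent input data."""


def sort_images(input_dir, pattern: str = DEFAULT_PATTERN) -> tuple[pd.DataFrame, list[str]]:
    """Build a position/channel/frame manifest from a directory of images.

    Filenames matching ``pattern`` (named groups ``position``, ``channel``
    and optionally ``frame``) are grouped by position then channel with
    frames in acquisition order; files that do not match are returned in
    the ``unmatched`` list, never silently dropped.  Duplicate
    (position, channel, frame) triples raise :class:`DataError`.
    """
    input_dir = Path(input_dir)
    regexes = [re.compile(pattern)]
    if pattern == DEFAULT_PATTERN:
        # also accept one-multi-frame-stack-per-channel naming
        regexes.append(re.compile(STACK_PATTERN))
    rows = []
    unmatched: list[str] = []
    for path in sorted(input_dir.iterdir()):
        if not path.is_file():
            continue
        m = next((r.match(path.name) for r in regexes if r.match(path.name)), None)
        if m is None:
            unmatched.append(path.name)
            continue
        groups = m.groupdict()
        rows.append(
            {
                "position": int(groups["position"]),
                "channel": groups["channel"],
                "frame": int(groups["frame"]) if groups.get("frame") is not None else -1,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows, columns=["position", "channel", "frame", "path"])
    if len(manifest) == 0:
        warnings.warn(f"no images matched in {input_dir}", stacklevel=2)
        return manifest, unmatched
    dup = manifest.duplicated(subset=["position", "channel", "frame"])
    if dup.any():
        bad = manifest[dup].iloc[0]
        raise DataError(
            f"duplicate image for position {bad.position}, channel {bad.channel}, "
            f"frame {bad.frame}"
        )
    manifest = manifest.sort_values(["position", "channel", "frame"]).reset_index(drop=True)
    return manifest, unmatched


def load_position_stacks(manifest: pd.DataFrame, position: int) -> dict[str, np.ndarray]:
    """Load all channels of one position as (T, H, W) arrays.

    Handles both per-frame files (frame >= 0) and multi-frame stacks
    (frame == -1).
    """
    sel = manifest[manifest["position"] == position]
    if len(sel) == 0:
        raise DataError(f"position {position} not present in manifest")
    stacks: dict[str, np.ndarray] = {}
    for channel, group in sel.groupby("channel"):
        group = group.sort_values("frame")
        if (group["frame"] < 0).all() and len(group) == 1:
            arr = tifffile.imread(group["path"].iloc[0])
            if arr.ndim == 2:
                arr = arr[None, ...]
        else:
            arr = np.stack([tifffile.imread(p) for p in group["path"]])
        stacks[channel] = arr
    return stacks
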