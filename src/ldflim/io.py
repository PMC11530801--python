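"""Reading and writing the package's on-disk formats.

Stacks are multipage 16-bit TIFFs (one page per time bin) with a JSON
sidecar carrying bin edges, the generating config and the seed; label maps
are single-page 16-bit TIFFs with a JSON class table; gated intensity
images are single-page 32-bit TIFFs.  Tables go to CSV and reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .decay import Gate
from .gating import IntensityImage
from .simulate import FLIMStack, LabelImage, OrganelleClass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FLIMStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.counts.astype(np.uint16))
    meta = {"bin_edges_ns": stack.bin_edges.tolist(), **stack.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path) -> FLIMStack:
    path = Path(path)
    counts = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    edges = np.asarray(meta.pop("bin_edges_ns"))
    return FLIMStack(counts, edges, meta)


def write_labels(labels: LabelImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    meta = {"class_of": {str(k): v.value for k, v in labels.class_of.items()}}
    if labels.body_mask is not None:
        meta["body_mask_rle"] = _rle_encode(labels.body_mask)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_labels(path) -> LabelImage:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    class_of = {int(k): OrganelleClass(v)
                for k, v in meta["class_of"].items()}
    body = None
    if "body_mask_rle" in meta:
        body = _rle_decode(meta["body_mask_rle"], arr.shape)
    return LabelImage(arr, class_of, body_mask=body)


def write_intensity(image: IntensityImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.values.astype(np.uint32))
    _sidecar(path).write_text(json.dumps(
        {"gate_ns": [image.gate.t_min, image.gate.t_max]}))


def read_intensity(path) -> IntensityImage:
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return IntensityImage(values, Gate(*meta["gate_ns"]))


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of a flattened boolean mask, starting with a False run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds).tolist()
    return ([0] + runs) if flat[0] else runs


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for r in runs:
        if value:
            flat[pos:pos + r] = True
        pos += r
        value = not value
    return flat.reshape(shape)
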