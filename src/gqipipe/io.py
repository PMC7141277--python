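"""NIfTI round-tripping for scalar index maps.

The map type (GFA/ISO/NQA/QA) is encoded in the filename suffix, e.g.
``sub001_GFA.nii.gz``; loading recovers it from there.
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .gqi import MAP_TYPES, IndexMap

__all__ = ["save_index_map", "load_index_map", "index_map_filename"]

_SUFFIX_RE = re.compile(r"_(" + "|".join(MAP_TYPES) + r")$")


def index_map_filename(subject_id: str, map_type: str) -> str:
    if map_type not in MAP_TYPES:
        raise ValueError(f"map_type must be one of {MAP_TYPES}")
    return f"{subject_id}_{map_type}.nii.gz"


def _stem(path: Path) -> str:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return name[: -len(ext)]
    return path.stem


def save_index_map(imap: IndexMap, path: str | Path) -> Path:
    """Write one index map as NIfTI-1; the filename must end in
    ``_<MAPTYPE>`` (it is appended when absent)."""
    path = Path(path)
    stem = _stem(path)
    if not _SUFFIX_RE.search(stem):
        path = path.parent / index_map_filename(stem, imap.map_type)
    else:
        suffix = _SUFFIX_RE.search(stem).group(1)
        if suffix != imap.map_type:
            raise ValueError(f"filename suffix _{suffix} does not match map type {imap.map_type}")
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([imap.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(imap.data, dtype=np.float32), affine), path)
    return path


def load_index_map(path: str | Path) -> IndexMap:
    """Load a 3D index map; the map type is parsed from the filename."""
    path = Path(path)
    match = _SUFFIX_RE.search(_stem(path))
    if not match:
        raise ValueError(
            f"cannot infer map type from {path.name}: expected a _GFA/_ISO/_NQA/_QA suffix"
        )
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"index maps are 3D; {path} has {data.ndim} dimensions")
    voxel = float(img.header.get_zooms()[0])
    return IndexMap(data=data, map_type=match.group(1), voxel_size=voxel)
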