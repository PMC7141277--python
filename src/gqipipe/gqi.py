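"""Generalized q-sampling imaging (GQI) reconstruction and scalar index maps.

GQI relates multi-shell diffusion signals to the spin distribution function
(SDF), a model-free orientation distribution function (ODF), through a
sinc-kernel sum over acquisitions::

    psi(u_j) = sum_i S_i * sinc( sigma * sqrt(6 * D * b_i) * (g_i . u_j) )

with the unnormalized sinc ``sin(x)/x``, sampling-length ratio ``sigma`` and
free-water diffusion constant ``D``.  From the per-voxel ODF the module
derives:

- GFA: population standard deviation of the ODF divided by its root mean
  square (anisotropy of water diffusion, in [0, 1)),
- ISO: the minimum ODF value (background isotropic diffusion),
- QA:  ODF value at the per-voxel global peak minus ISO,
- NQA: QA normalized by the per-subject maximum QA (in [0, 1]).

ODF directions sample one hemisphere of a subdivided icosahedron
(antipodally deduplicated, since diffusion is symmetric under inversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .synthetic import DWIVolume, GradientTable

__all__ = [
    "DirectionSet",
    "GQIConfig",
    "ODFField",
    "IndexMap",
    "make_direction_set",
    "nearest_neighbor_angle",
    "gqi_kernel",
    "reconstruct_odf",
    "compute_gfa",
    "compute_iso",
    "compute_qa_nqa",
    "build_index_maps",
]

MAP_TYPES = ("GFA", "ISO", "NQA", "QA")


@dataclass(frozen=True)
class DirectionSet:
    """Hemisphere ODF sampling directions from an order-k icosphere."""

    vectors: np.ndarray  # (m, 3) unit vectors
    order: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vectors must be (m, 3)")
        if np.any(np.abs(np.linalg.norm(v, axis=1) - 1.0) > 1e-8):
            raise ValueError("directions must be unit vectors")
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class GQIConfig:
    """Reconstruction constants.

    ``sampling_length_ratio`` (sigma) scales the diffusion displacement
    window; 1.25 is the conventional choice.  ``free_diffusion_constant`` is
    the free-water diffusivity (mm^2/s).  ``odf_direction_order`` is the
    icosphere subdivision order of the ODF direction set.
    """

    sampling_length_ratio: float = 1.25
    free_diffusion_constant: float = 2.5e-3
    odf_direction_order: int = 3

    def __post_init__(self) -> None:
        if self.sampling_length_ratio <= 0:
            raise ValueError("sampling_length_ratio must be positive")
        if self.free_diffusion_constant <= 0:
            raise ValueError("free_diffusion_constant must be positive")
        if self.odf_direction_order < 0:
            raise ValueError("odf_direction_order must be >= 0")


@dataclass(frozen=True)
class ODFField:
    """Per-voxel ODF values over a shared direction set."""

    values: np.ndarray  # (x, y, z, m), non-negative
    direction_set: DirectionSet

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 4 or v.shape[3] != len(self.direction_set):
            raise ValueError("values must be (x, y, z, n_directions)")
        if v.size and float(v.min()) < 0:
            raise ValueError("ODF values must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IndexMap:
    """A scalar 3D index volume (GFA, ISO, NQA or QA) on the template grid."""

    data: np.ndarray
    map_type: str
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if self.map_type not in MAP_TYPES:
            raise ValueError(f"map_type must be one of {MAP_TYPES}")
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("index map data must be 3D")
        object.__setattr__(self, "data", data)


# ---------------------------------------------------------------------------
# direction set


def _icosahedron() -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    return verts, faces


def _subdivide(verts: np.ndarray, faces: list[tuple[int, int, int]]):
    verts = list(map(np.asarray, verts))
    cache: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = verts[a] + verts[b]
            m = m / np.linalg.norm(m)
            verts.append(m)
            cache[key] = len(verts) - 1
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.vstack(verts), new_faces


@lru_cache(maxsize=8)
def make_direction_set(order: int = 3) -> DirectionSet:
    """Hemisphere vertex set of the ``order``-times-subdivided icosahedron.

    Full-sphere vertex count is ``10 * 4**order + 2``; after antipodal
    deduplication the set holds half of that.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(order):
        verts, faces = _subdivide(verts, faces)
    # canonical hemisphere representative: z > 0, ties broken by y then x
    tol = 1e-9
    canon = verts.copy()
    flip = (canon[:, 2] < -tol) | (
        (np.abs(canon[:, 2]) <= tol)
        & ((canon[:, 1] < -tol) | ((np.abs(canon[:, 1]) <= tol) & (canon[:, 0] < 0)))
    )
    canon[flip] *= -1
    _, idx = np.unique(np.round(canon, 6), axis=0, return_index=True)
    hemi = canon[np.sort(idx)]
    return DirectionSet(vectors=hemi, order=order)


def nearest_neighbor_angle(dirs: DirectionSet) -> float:
    """Largest nearest-neighbor angular spacing (degrees), folding antipodes."""
    dots = np.abs(dirs.vectors @ dirs.vectors.T)
    np.fill_diagonal(dots, -1.0)
    nearest = np.clip(dots.max(axis=1), -1.0, 1.0)
    return float(np.degrees(np.arccos(nearest)).max())


# ---------------------------------------------------------------------------
# reconstruction


def gqi_kernel(gtab: GradientTable, dirs: DirectionSet, cfg: GQIConfig) -> np.ndarray:
    """(n_acquisitions, n_directions) sinc reconstruction matrix."""
    scale = cfg.sampling_length_ratio * np.sqrt(6.0 * cfg.free_diffusion_constant * gtab.bvals)
    x = scale[:, None] * (gtab.bvecs @ dirs.vectors.T)
    return np.sinc(x / np.pi)  # np.sinc is normalized; rescale to sin(x)/x


def reconstruct_odf(
    signal: np.ndarray,
    gtab: GradientTable,
    dirs: DirectionSet,
    cfg: GQIConfig | None = None,
) -> np.ndarray:
    """Reconstruct one voxel's ODF; negative values are truncated to zero."""
    cfg = cfg or GQIConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(gtab),):
        raise ValueError(
            f"signal length {signal.shape} does not match gradient table ({len(gtab)} rows)"
        )
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    odf = signal @ gqi_kernel(gtab, dirs, cfg)
    return np.maximum(odf, 0.0)


# ---------------------------------------------------------------------------
# scalar indices


def compute_gfa(odf: np.ndarray) -> float:
    """Generalized fractional anisotropy: population std over RMS of the ODF.

    Scale-invariant; 0 for a constant ODF and at most sqrt((N-1)/N) for a
    one-hot ODF of length N.  An all-zero ODF maps to 0 by convention.
    """
    odf = np.asarray(odf, dtype=float)
    if odf.size == 0:
        raise ValueError("ODF must be non-empty")
    if np.any(odf < 0):
        raise ValueError("ODF values must be non-negative")
    rms = math.sqrt(float(np.mean(odf * odf)))
    if rms == 0.0:
        return 0.0
    return float(np.std(odf) / rms)


def compute_iso(odf: np.ndarray) -> float:
    """ISO index: the minimum distribution value of the ODF."""
    odf = np.asarray(odf, dtype=float)
    if odf.size == 0:
        raise ValueError("ODF must be non-empty")
    return float(odf.min())


def _gfa_rows(odfs: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(odfs * odfs, axis=1))
    std = np.std(odfs, axis=1)
    out = np.zeros(odfs.shape[0])
    nz = rms > 0
    out[nz] = std[nz] / rms[nz]
    return out


def compute_qa_nqa(odf_field: ODFField, voxel_size: float = 2.0) -> tuple[IndexMap, IndexMap]:
    """Quantitative anisotropy (peak minus ISO) and its field-normalized form.

    A field of constant ODFs yields all-zero QA and NQA (degenerate but
    valid); otherwise the voxel attaining the maximum QA has NQA exactly 1.
    """
    vals = odf_field.values
    qa = np.maximum(vals.max(axis=3) - vals.min(axis=3), 0.0)
    qmax = float(qa.max()) if qa.size else 0.0
    nqa = qa / qmax if qmax > 0 else np.zeros_like(qa)
    return (
        IndexMap(data=qa, map_type="QA", voxel_size=voxel_size),
        IndexMap(data=nqa, map_type="NQA", voxel_size=voxel_size),
    )


def build_index_maps(
    dwi: DWIVolume,
    cfg: GQIConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[IndexMap, IndexMap, IndexMap]:
    """Reconstruct GFA, ISO and NQA maps for one subject.

    The default mask keeps voxels whose mean b=0 signal is positive; outside
    the mask every map is zero.  NQA is normalized by the maximum QA over
    this subject's masked field.
    """
    cfg = cfg or GQIConfig()
    data = np.asarray(dwi.data)
    if mask is None:
        mask = data[..., dwi.gradient_table.b0_mask].mean(axis=3) > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dwi.grid_shape:
            raise ValueError("mask shape must match the DWI spatial grid")
    dirs = make_direction_set(cfg.odf_direction_order)
    kernel = gqi_kernel(dwi.gradient_table, dirs, cfg).astype(np.float32)
    signals = data[mask].astype(np.float32)
    odfs = np.maximum(signals @ kernel, 0.0).astype(np.float64)

    gfa_v = _gfa_rows(odfs)
    iso_v = odfs.min(axis=1)
    qa_v = np.maximum(odfs.max(axis=1) - iso_v, 0.0)
    qmax = float(qa_v.max()) if qa_v.size else 0.0
    nqa_v = qa_v / qmax if qmax > 0 else np.zeros_like(qa_v)

    maps = []
    for vec, map_type in ((gfa_v, "GFA"), (iso_v, "ISO"), (nqa_v, "NQA")):
        vol = np.zeros(dwi.grid_shape)
        vol[mask] = vec
        maps.append(IndexMap(data=vol, map_type=map_type, voxel_size=dwi.voxel_size))
    return tuple(maps)
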