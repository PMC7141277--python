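"""Synthetic multi-shell diffusion-MRI cohorts.

Generates diffusion-weighted volumes for a four-group cohort (healthy
controls HC, depressed non-ideation NS, depressed with suicidal ideation SI,
suicide attempters SA) with a multi-tensor forward model, Rician noise, and a
group-dependent reduction of the anisotropic volume fraction inside a
configurable region of interest.  Volumes are generated already aligned on a
shared grid, so no registration stage exists downstream.

Signal model per voxel::

    S(g, b) = S0 * [ sum_k f_k * exp(-b * g^T D_k g) + f_iso * exp(-b * d_iso) ]

with axially symmetric tensors D_k parameterised by an axial and a radial
diffusivity.  Rician noise is applied as ``|S + n1 + i*n2|`` with
``n1, n2 ~ N(0, sigma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GradientTable",
    "FiberCompartment",
    "FiberConfig",
    "CohortSpec",
    "DWIVolume",
    "Subject",
    "make_gradient_table",
    "simulate_voxel_signal",
    "attenuation",
    "make_cohort",
    "iter_cohort",
    "default_effect_roi",
    "save_dwi",
    "load_dwi",
    "write_cohort",
]

DEFAULT_GROUP_SIZES = {"HC": 58, "NS": 54, "SI": 41, "SA": 33}

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


# ---------------------------------------------------------------------------
# gradient table


@dataclass(frozen=True)
class GradientTable:
    """q-space sampling scheme: one b-value and one unit direction per row.

    Rows with ``b == 0`` carry a zero direction vector; every row with
    ``b > 0`` must have a unit-norm direction.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError("bvals must be (n,) and bvecs (n, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(bvals == 0):
            raise ValueError("gradient table must contain at least one b=0 row")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-8):
            raise ValueError("weighted directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct positive b-values."""
        return np.unique(self.bvals[self.bvals > 0])

    def to_fsl(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write FSL-style ``<prefix>.bval`` / ``<prefix>.bvec`` text files."""
        prefix = Path(prefix)
        bval_path = prefix.with_suffix(".bval")
        bvec_path = prefix.with_suffix(".bvec")
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")
        return bval_path, bvec_path

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientTable":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


def _fibonacci_sphere(n: int, phase: float = 0.0) -> np.ndarray:
    """``n`` near-uniform unit vectors on the full sphere (spiral layout).

    ``phase`` rotates the azimuthal spiral so that different shells sample
    interleaved direction sets.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = _GOLDEN_ANGLE * i + phase
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_gradient_table(
    n_per_shell: int = 64,
    shell_bvalues: Sequence[float] = (1000.0, 1500.0, 2000.0),
    seed: int = 0,
) -> GradientTable:
    """Build a multi-shell scheme: one b=0 row plus ``n_per_shell`` directions
    per shell.

    Directions follow a deterministic spherical-Fibonacci layout per shell
    (phase-shifted between shells so shells do not repeat directions); the
    seed only permutes the acquisition order within each shell.
    """
    if n_per_shell < 0:
        raise ValueError("n_per_shell must be >= 0")
    shell_bvalues = [float(b) for b in shell_bvalues]
    if any(b <= 0 for b in shell_bvalues):
        raise ValueError("shell b-values must be positive")
    rng = np.random.default_rng(seed)
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for m, b in enumerate(shell_bvalues):
        dirs = _fibonacci_sphere(n_per_shell, phase=2.0 * math.pi * m / max(len(shell_bvalues), 1) * 0.618)
        order = rng.permutation(n_per_shell)
        for j in order:
            bvals.append(b)
            bvecs.append(dirs[j])
    return GradientTable(bvals=np.array(bvals), bvecs=np.vstack(bvecs))


# ---------------------------------------------------------------------------
# fiber model


@dataclass(frozen=True)
class FiberCompartment:
    """One axially symmetric tensor compartment."""

    fraction: float
    direction: tuple[float, float, float]
    axial_diffusivity: float = 1.7e-3  # mm^2/s, typical white matter
    radial_diffusivity: float = 0.3e-3

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("compartment fraction must be >= 0")
        if not (self.axial_diffusivity >= self.radial_diffusivity >= 0):
            raise ValueError("require axial >= radial >= 0 diffusivity")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("compartment direction must be a non-zero vector")
        object.__setattr__(self, "direction", tuple(d / n))


@dataclass(frozen=True)
class FiberConfig:
    """Per-voxel mixture of fiber compartments plus an isotropic pool."""

    compartments: tuple[FiberCompartment, ...]
    isotropic_fraction: float = 0.0
    isotropic_diffusivity: float = 3.0e-3  # mm^2/s, free water

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        if self.isotropic_fraction < 0:
            raise ValueError("isotropic fraction must be >= 0")
        total = sum(c.fraction for c in comps) + self.isotropic_fraction
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"volume fractions must sum to 1, got {total}")
        object.__setattr__(self, "compartments", comps)


def attenuation(fibers: FiberConfig, gtab: GradientTable) -> np.ndarray:
    """Noise-free normalized signal (S/S0) for every gradient-table row."""
    b = gtab.bvals
    out = np.full(len(gtab), fibers.isotropic_fraction * 1.0) * np.exp(
        -b * fibers.isotropic_diffusivity
    )
    for comp in fibers.compartments:
        v = np.asarray(comp.direction)
        c2 = (gtab.bvecs @ v) ** 2
        adc = comp.radial_diffusivity + (comp.axial_diffusivity - comp.radial_diffusivity) * c2
        out = out + comp.fraction * np.exp(-b * adc)
    return out


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(real * real + imag * imag)


def _add_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator, model: str
) -> np.ndarray:
    if model == "rician":
        return _rician(signal, sigma, rng)
    if model == "gaussian":  # debugging aid; clipped to keep signals valid
        return np.maximum(signal + rng.normal(0.0, sigma, signal.shape), 0.0)
    raise ValueError("noise_model must be 'rician' or 'gaussian'")


def simulate_voxel_signal(
    fibers: FiberConfig,
    gtab: GradientTable,
    s0: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise_model: str = "rician",
) -> np.ndarray:
    """Simulate one voxel's signal vector (one value per gradient-table row)."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    signal = s0 * attenuation(fibers, gtab)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        signal = _add_noise(signal, noise_sigma, rng, noise_model)
    return signal


# ---------------------------------------------------------------------------
# cohort


def default_effect_roi(grid_shape: Sequence[int], side_fraction: float = 1 / 3) -> np.ndarray:
    """Central cube covering ``side_fraction`` of each axis, as (n, 3) voxel
    coordinates."""
    grid = tuple(int(g) for g in grid_shape)
    sides = [max(1, int(round(g * side_fraction))) for g in grid]
    starts = [(g - s) // 2 for g, s in zip(grid, sides)]
    axes = [np.arange(st, st + s) for st, s in zip(starts, sides)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


@dataclass(frozen=True)
class CohortSpec:
    """Study-level description of a synthetic cohort.

    Defaults mirror the reference study conditions: four groups of
    58/54/41/33 subjects, three b-shells at 1000/1500/2000 s/mm^2 with 64
    weighted directions each plus one b=0 volume, and an anisotropy-reducing
    effect applied to ideation (SI) and attempter (SA) subjects inside a
    central white-matter region.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    effect_roi: np.ndarray | None = None  # (n, 3) voxel coords; None -> central cube
    effect_delta: float = 0.4
    affected_groups: tuple[str, ...] = ("SI", "SA")
    noise_sigma: float = 2.0
    noise_model: str = "rician"
    seed: int = 0
    n_per_shell: int = 64
    shell_bvalues: tuple[float, ...] = (1000.0, 1500.0, 2000.0)
    s0: float = 100.0
    base_fiber_fraction: float = 0.65
    fraction_jitter_sd: float = 0.03
    orientation_jitter_deg: float = 5.0
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.3e-3
    iso_diffusivity: float = 3.0e-3
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not (0.0 <= self.effect_delta <= 1.0):
            raise ValueError("effect_delta must lie in [0, 1]")
        grid = tuple(int(g) for g in self.grid_shape)
        if len(grid) != 3 or any(g < 1 for g in grid):
            raise ValueError("grid_shape must be three positive integers")
        object.__setattr__(self, "grid_shape", grid)
        roi = self.effect_roi
        if roi is None:
            roi = default_effect_roi(grid)
        roi = np.asarray(roi, dtype=int)
        if roi.ndim != 2 or roi.shape[1] != 3:
            raise ValueError("effect_roi must be an (n, 3) coordinate array")
        if np.any(roi < 0) or np.any(roi >= np.array(grid)):
            raise ValueError("grid too small for effect_roi: coordinates out of bounds")
        object.__setattr__(self, "effect_roi", roi)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes.values()))

    def roi_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.effect_roi.T)] = True
        return mask

    def brain_mask(self) -> np.ndarray:
        """Ellipsoid inscribed in the grid (everything outside has zero signal)."""
        grid = np.array(self.grid_shape, dtype=float)
        coords = np.indices(self.grid_shape).astype(float)
        center = (grid - 1) / 2.0
        semi = grid * 0.45
        d2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
        return d2 <= 1.0


@dataclass(frozen=True)
class DWIVolume:
    """4D diffusion-weighted dataset: (x, y, z, acquisition)."""

    data: np.ndarray
    gradient_table: GradientTable
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, acquisition)")
        if data.shape[3] != len(self.gradient_table):
            raise ValueError(
                "fourth dimension must match gradient-table row count "
                f"({data.shape[3]} != {len(self.gradient_table)})"
            )
        if data.size and float(data.min()) < 0:
            raise ValueError("signals must be non-negative")
        object.__setattr__(self, "data", data)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class Subject:
    """One simulated subject, with the ground truth used to generate it."""

    subject_id: str
    group: str
    dwi: DWIVolume
    fiber_axis: tuple[float, float, float]
    fiber_fraction: float
    roi_fiber_fraction: float


def _jittered_axis(rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    sd = math.radians(jitter_deg)
    v = np.array([rng.normal(0.0, sd), rng.normal(0.0, sd), 1.0])
    return v / np.linalg.norm(v)


def iter_cohort(spec: CohortSpec) -> Iterator[Subject]:
    """Yield subjects one at a time (memory-friendly for large cohorts).

    Deterministic for a fixed spec and seed: each subject draws from an
    independent child of ``SeedSequence(spec.seed)``.
    """
    gtab = make_gradient_table(spec.n_per_shell, spec.shell_bvalues, seed=spec.seed)
    brain = spec.brain_mask()
    roi = spec.roi_mask()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    b = gtab.bvals
    e_iso = np.exp(-b * spec.iso_diffusivity)
    child_iter = iter(children)
    for group, count in spec.group_sizes.items():
        affected = group in spec.affected_groups
        for i in range(count):
            rng = np.random.default_rng(next(child_iter))
            axis = _jittered_axis(rng, spec.orientation_jitter_deg)
            f_subj = float(
                np.clip(
                    spec.base_fiber_fraction + rng.normal(0.0, spec.fraction_jitter_sd),
                    0.05,
                    0.95,
                )
            )
            f_map = np.where(brain, f_subj, 0.0)
            if affected and spec.effect_delta > 0:
                f_map = np.where(roi & brain, np.maximum(f_map - spec.effect_delta, 0.0), f_map)
            c2 = (gtab.bvecs @ axis) ** 2
            adc = spec.radial_diffusivity + (spec.axial_diffusivity - spec.radial_diffusivity) * c2
            e_fib = np.exp(-b * adc)  # (n_acq,)
            f_flat = f_map[brain][:, None]  # (n_brain, 1)
            signal = spec.s0 * (f_flat * e_fib[None, :] + (1.0 - f_flat) * e_iso[None, :])
            if spec.noise_sigma > 0:
                signal = _add_noise(signal, spec.noise_sigma, rng, spec.noise_model)
            data = np.zeros(spec.grid_shape + (len(gtab),), dtype=np.float32)
            data[brain] = signal.astype(np.float32)
            dwi = DWIVolume(data=data, gradient_table=gtab, voxel_size=spec.voxel_size)
            in_roi = roi & brain
            roi_f = float(f_map[in_roi].mean()) if in_roi.any() else float("nan")
            yield Subject(
                subject_id=f"{group}{i + 1:03d}",
                group=group,
                dwi=dwi,
                fiber_axis=tuple(axis),
                fiber_fraction=f_subj,
                roi_fiber_fraction=roi_f,
            )


def make_cohort(spec: CohortSpec) -> list[Subject]:
    """Materialize the whole cohort as a list (use :func:`iter_cohort` for
    large grids)."""
    return list(iter_cohort(spec))


# ---------------------------------------------------------------------------
# I/O


def save_dwi(dwi: DWIVolume, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.nii.gz`` plus FSL ``.bval``/``.bvec`` files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([dwi.voxel_size] * 3 + [1.0])
    nii_path = prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), affine), nii_path)
    bval_path, bvec_path = dwi.gradient_table.to_fsl(prefix)
    return {"dwi": nii_path, "bval": bval_path, "bvec": bvec_path}


def load_dwi(nii_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DWIVolume:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    gtab = GradientTable.from_fsl(bval_path, bvec_path)
    voxel = float(img.header.get_zooms()[0])
    return DWIVolume(data=data, gradient_table=gtab, voxel_size=voxel)


def write_cohort(subjects: Sequence[Subject], outdir: str | Path, seed: int) -> pd.DataFrame:
    """Write every subject's DWI and a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in subjects:
        paths = save_dwi(subj.dwi, outdir / subj.subject_id)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "dwi": str(paths["dwi"]),
                "bval": str(paths["bval"]),
                "bvec": str(paths["bvec"]),
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "cohort_manifest.csv", index=False)
    return manifest
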