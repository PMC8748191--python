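"""Seed-based voxel-wise structural covariance GLMs.

Structural covariance treats the across-subject correlation between a
seed region's grey-matter (GM) volume and every other voxel as a
trait-level analogue of connectivity.  The model here reproduces the
standard VBM second-level setup: per-subject modulated GM maps, a seed
regressor (mean GM in small spheres at fixed MNI coordinates), nuisance
covariates entered in a fixed order and sequentially orthogonalized by
Gram-Schmidt (age, sex, global GM volume, the other hypothalamic seed,
then the seed of interest), and a voxel-wise least-squares fit with
per-group seed slopes whose pairwise contrasts form the seed-by-group
interaction t maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import nibabel as nib

__all__ = [
    "SeedSpec",
    "VolumeStack",
    "DesignMatrix",
    "StatMap",
    "make_gm_mask",
    "extract_seed",
    "global_gm_volume",
    "build_design",
    "orthogonalize_design",
    "fit_interaction_glm",
    "InteractionGLMResult",
]

logger = logging.getLogger(__name__)

DESIGN_ORDER = ["age", "sex", "global_gmv", "other_seed", "seed"]


@dataclass(frozen=True)
class SeedSpec:
    """Spherical seed given by one or more MNI centers (mm) and a radius.

    Bilateral seeds list both hemisphere centers; their sphere means are
    averaged into a single per-subject value.
    """

    name: str
    mni_coords: tuple[tuple[float, float, float], ...]
    radius: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("seed radius must be positive")
        coords = tuple(tuple(float(v) for v in c) for c in self.mni_coords)
        object.__setattr__(self, "mni_coords", coords)
        if not np.all(np.isfinite(np.asarray(coords))):
            raise ValueError("seed coordinates must be finite")


@dataclass
class VolumeStack:
    """Subjects x 3-D grey-matter images sharing one affine."""

    subject_ids: list[str]
    data: np.ndarray          # (n_subjects, X, Y, Z)
    affine: np.ndarray        # 4x4 voxel -> MNI mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, X, Y, Z)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids inconsistent with data")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volumes contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mni_to_voxel(self, mni: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of an MNI coordinate."""
        inv = np.linalg.inv(self.affine)
        return (inv @ np.append(np.asarray(mni, float), 1.0))[:3]

    def voxel_to_mni(self, ijk: Sequence[float]) -> np.ndarray:
        return (self.affine @ np.append(np.asarray(ijk, float), 1.0))[:3]

    def to_niftis(self, directory) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for sid, vol in zip(self.subject_ids, self.data):
            p = directory / f"{sid}_gm.nii"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine), p)
            paths.append(p)
        return paths

    @classmethod
    def from_niftis(cls, paths: Sequence, subject_ids: Sequence[str] | None = None):
        imgs = [nib.load(str(p)) for p in paths]
        affine = imgs[0].affine
        for img in imgs[1:]:
            if not np.allclose(img.affine, affine, atol=1e-6):
                raise ValueError("all volumes must share one affine")
        data = np.stack([np.asarray(img.dataobj, float) for img in imgs])
        if subject_ids is None:
            subject_ids = [Path(p).name.replace("_gm.nii", "").replace(".nii", "")
                           for p in paths]
        return cls(list(subject_ids), data, np.asarray(affine, float))


@dataclass
class DesignMatrix:
    """Ordered covariate columns plus the group factor.

    ``column_names`` follow the fixed entry order age, sex, global GMV,
    other seed, seed of interest; ``orthogonalized`` records whether the
    sequential Gram-Schmidt pass has been applied.
    """

    column_names: list[str]
    values: np.ndarray           # subjects x columns
    group_factor: np.ndarray     # subject group labels
    orthogonalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.group_factor = np.asarray(self.group_factor)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values inconsistent with column_names")
        if self.group_factor.shape[0] != self.values.shape[0]:
            raise ValueError("group_factor inconsistent with values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def group_levels(self, reference: str = "non-obese") -> list[str]:
        levels = sorted(set(self.group_factor))
        if reference in levels:
            levels.remove(reference)
            levels.insert(0, reference)
        return levels


@dataclass
class StatMap:
    """A voxel-wise statistic volume with contrast metadata.

    Values are defined (finite) inside the mask and NaN outside.
    """

    kind: str                    # 't', 'F', 'TFCE', 'p_fwe'
    values: np.ndarray
    contrast: str
    mask: np.ndarray
    df: float | None = None
    n_permutations: int | None = None
    affine: np.ndarray | None = None

    def masked(self) -> np.ndarray:
        return self.values[self.mask]

    def save(self, path) -> None:
        if self.affine is None:
            raise ValueError("StatMap has no affine; cannot write NIfTI")
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))


# ---------------------------------------------------------------------------
# masks and seeds


def make_gm_mask(stack: VolumeStack, threshold: float = 0.2) -> np.ndarray:
    """Boolean mask of voxels whose mean GM value across subjects exceeds
    ``threshold`` (the conventional GM-probability cutoff)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    mask = stack.data.mean(axis=0) > threshold
    if not mask.any():
        raise ValueError(f"GM mask is empty at threshold {threshold}")
    return mask


def _sphere_voxels(stack: VolumeStack, center_mni, radius_mm) -> np.ndarray:
    """Indices (N, 3) of voxels whose center lies within radius (inclusive)
    of the MNI coordinate, after snapping the center to the voxel grid."""
    ijk = stack.mni_to_voxel(center_mni)
    snapped = np.rint(ijk).astype(int)
    if np.any(snapped < 0) or np.any(snapped >= np.array(stack.shape)):
        raise ValueError(f"seed center {tuple(center_mni)} maps outside the grid")
    if np.max(np.abs(ijk - snapped)) > 0.5:
        logger.warning("seed center %s snapped by more than half a voxel", center_mni)
    center_mm = stack.voxel_to_mni(snapped)
    vs = stack.voxel_size
    span = np.ceil(radius_mm / vs).astype(int)
    lo = np.maximum(snapped - span, 0)
    hi = np.minimum(snapped + span, np.array(stack.shape) - 1)
    rng = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    gi, gj, gk = np.meshgrid(*rng, indexing="ij")
    pts = np.column_stack([gi.ravel(), gj.ravel(), gk.ravel()])
    mm = pts @ stack.affine[:3, :3].T + stack.affine[:3, 3]
    d = np.linalg.norm(mm - center_mm, axis=1)
    inside = pts[d <= radius_mm + 1e-9]
    if inside.size == 0:
        raise ValueError(f"sphere at {tuple(center_mni)} contains no voxels")
    return inside


def extract_seed(stack: VolumeStack, seed: SeedSpec) -> np.ndarray:
    """Per-subject mean GM in the seed sphere(s); bilateral spheres are
    averaged into one value per subject."""
    per_center = []
    for c in seed.mni_coords:
        vox = _sphere_voxels(stack, c, seed.radius)
        vals = stack.data[:, vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=1)
        per_center.append(vals)
    return np.mean(per_center, axis=0)


def global_gm_volume(stack: VolumeStack) -> np.ndarray:
    """Per-subject global GM volume: sum of all modulated voxel values,
    scaled by the voxel volume and expressed in ml."""
    return stack.data.reshape(stack.n_subjects, -1).sum(axis=1) * stack.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# design


def build_design(
    stack: VolumeStack,
    phenotypes: pd.DataFrame,
    seed: SeedSpec,
    other_seed: SeedSpec,
    group_column: str = "obesity",
) -> DesignMatrix:
    """Assemble the fixed-order design [age, sex, global_gmv, other_seed,
    seed] plus the group factor from a phenotype table aligned with the
    stack's subjects."""
    pheno = phenotypes.set_index(phenotypes["subject_id"].astype(str))
    pheno = pheno.loc[stack.subject_ids]
    cols = np.column_stack([
        pheno["age"].to_numpy(float),
        (pheno["sex"].to_numpy() == "male").astype(float),
        global_gm_volume(stack),
        extract_seed(stack, other_seed),
        extract_seed(stack, seed),
    ])
    return DesignMatrix(list(DESIGN_ORDER), cols, pheno[group_column].to_numpy())


def orthogonalize_design(design: DesignMatrix) -> DesignMatrix:
    """Sequential Gram-Schmidt pass over the design columns.

    Each column is centered, then residualized on every previously
    entered (already orthogonalized) column, so the last column — the
    seed of interest — is purged of age, sex, global GM volume and the
    other seed.  Raises on rank deficiency, naming the column.
    """
    X = design.values.copy()
    n, k = X.shape
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j] - X[:, j].mean()
        orig = float(col @ col)
        for p in range(j):
            prev = out[:, p]
            denom = float(prev @ prev)
            if denom > 0:
                col = col - (col @ prev) / denom * prev
        if orig == 0.0 or float(col @ col) < 1e-10 * max(orig, 1e-30):
            raise np.linalg.LinAlgError(
                f"column {design.column_names[j]!r} is rank-deficient given "
                "the previously entered columns"
            )
        out[:, j] = col
    return DesignMatrix(list(design.column_names), out,
                        design.group_factor.copy(), orthogonalized=True)


# ---------------------------------------------------------------------------
# voxel-wise GLM


def _full_model(design: DesignMatrix, reference: str = "non-obese"):
    """Design matrix with per-group seed slopes.

    Columns: [intercept, age, sex, global_gmv, other_seed, group
    indicators (non-reference), seed x I_g for every group level].
    Returns (X, column names, levels).
    """
    levels = design.group_levels(reference)
    g = design.group_factor
    seed = design.column("seed")
    nuis = [design.values[:, design.column_names.index(c)]
            for c in design.column_names if c != "seed"]
    names = ["intercept"] + [c for c in design.column_names if c != "seed"]
    cols = [np.ones(design.n_subjects)] + nuis
    for lev in levels[1:]:
        cols.append((g == lev).astype(float))
        names.append(f"group[{lev}]")
    for lev in levels:
        cols.append(seed * (g == lev))
        names.append(f"seed:{lev}")
    return np.column_stack(cols), names, levels


@dataclass
class InteractionGLMResult:
    """Voxel-wise GLM output: interaction and per-group slope t maps."""

    t_maps: dict                  # contrast name -> StatMap
    slope_maps: dict              # group level -> StatMap (within-group seed t)
    df: int
    X: np.ndarray
    column_names: list[str]
    levels: list[str]
    n_singular: int = 0


def _t_stats(Y: np.ndarray, X: np.ndarray, cvec: np.ndarray):
    """t statistic of contrast c'beta at every column of Y (voxels)."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    var_c = float(cvec @ np.linalg.pinv(X.T @ X) @ cvec)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (cvec @ beta) / np.sqrt(sigma2 * var_c)
    return t, dof


def fit_interaction_glm(
    stack: VolumeStack,
    design: DesignMatrix,
    mask: np.ndarray,
    n_groups: int | None = None,
    reference: str = "non-obese",
) -> InteractionGLMResult:
    """Fit the seed-by-group structural covariance GLM at every masked voxel.

    With two group levels the single interaction contrast (difference of
    per-group seed slopes, signed both ways) is returned; with three,
    every pairwise slope contrast.  Per-group slope t maps (the
    within-group covariance maps) are always included.
    """
    X, names, levels = _full_model(design, reference)
    if n_groups is not None and len(levels) != n_groups:
        raise ValueError(f"expected {n_groups} group levels, found {levels}")
    counts = pd.Series(design.group_factor).value_counts()
    if counts.min() < 3:
        raise ValueError("every group needs at least 3 subjects")
    Y = stack.data[:, mask]

    def cvec_for(pos: str, neg: str | None = None) -> np.ndarray:
        c = np.zeros(X.shape[1])
        c[names.index(f"seed:{pos}")] = 1.0
        if neg is not None:
            c[names.index(f"seed:{neg}")] = -1.0
        return c

    def to_map(tvals, contrast, dof) -> StatMap:
        vol = np.full(mask.shape, np.nan)
        vol[mask] = tvals
        return StatMap("t", vol, contrast, mask, df=dof, affine=stack.affine)

    t_maps = {}
    pairs = [(levels[i], levels[j]) for i in range(len(levels))
             for j in range(i + 1, len(levels))]
    dof = None
    for a, b in pairs:
        t, dof = _t_stats(Y, X, cvec_for(b, a))
        t_maps[f"{b}>{a}"] = to_map(t, f"seed slope: {b} > {a}", dof)
    slope_maps = {}
    for lev in levels:
        t, dof = _t_stats(Y, X, cvec_for(lev))
        slope_maps[lev] = to_map(t, f"within-group seed slope: {lev}", dof)
    n_singular = int(np.sum(~np.isfinite(next(iter(t_maps.values())).masked())))
    if n_singular:
        logger.warning("%d singular voxel fits set to NaN", n_singular)
    return InteractionGLMResult(t_maps, slope_maps, int(dof), X, names, levels,
                                n_singular)
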