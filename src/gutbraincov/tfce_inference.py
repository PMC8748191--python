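"""TFCE transform and max-statistic permutation FWE inference.

Family-wise error control follows the standard non-parametric recipe:
the observed t map is enhanced with TFCE, the same statistic is
recomputed under permutations (Freedman-Lane residual exchange under
the reduced model by default, or simple group-label exchange), and each
voxel's FWE-corrected p value is the proportion of permutations whose
*maximum* TFCE anywhere in the mask reaches the observed value,

    p_fwe(v) = (1 + #{perm max >= TFCE_obs(v)}) / (n_permutations + 1).

Positive and negative contrast directions are tested separately.  A
small-volume correction restricts the null maximum to an a-priori
sphere (3-mm radius for subcortical regions, 5-mm for cortical, by
convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np

from ._tfce_engine import neighbor_csr, tfce_positive_tail
from .structcov import DesignMatrix, StatMap, VolumeStack, _full_model

__all__ = [
    "TFCEParams",
    "PermutationScheme",
    "PermutationResult",
    "tfce_transform",
    "permutation_fwe",
    "small_volume_correction",
]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE parameters: the canonical defaults E=0.5, H=2, 26-connectivity,
    with the step dh defaulting to max|t| / n_steps per map."""

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("exponents must be nonnegative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class PermutationScheme:
    n_permutations: int = 500
    rng_seed: int = 0
    strategy: str = "freedman-lane"  # or 'group-exchange'

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.strategy not in ("freedman-lane", "group-exchange"):
            raise ValueError(f"unknown permutation strategy {self.strategy!r}")


def _tfce_masked(vals: np.ndarray, nbrs, params: TFCEParams) -> np.ndarray:
    """Signed TFCE of masked stat values (positive and negative tails
    enhanced separately with per-tail dh from the tail maximum)."""
    flat, ptr = nbrs
    out = np.zeros_like(vals)
    for sign in (1.0, -1.0):
        tail = np.where(sign * vals > 0, sign * vals, 0.0)
        mx = tail.max() if tail.size else 0.0
        if mx <= 0:
            continue
        dh = params.dh if params.dh is not None else mx / params.n_steps
        n_steps = int(math.floor(mx / dh + 1e-12))
        if n_steps < 1:
            continue
        enh = tfce_positive_tail(
            tail, flat, ptr, dh, n_steps,
            params.extent_exponent, params.height_exponent,
        )
        out += sign * enh
    return out


def tfce_transform(tmap: StatMap, params: TFCEParams = TFCEParams()) -> StatMap:
    """TFCE-enhance a stat map (sign preserved; all-zero maps pass through)."""
    vals = tmap.masked()
    if not np.all(np.isfinite(vals)):
        vals = np.nan_to_num(vals, nan=0.0)
    nbrs = neighbor_csr(tmap.mask, params.connectivity)
    enh = _tfce_masked(vals.astype(float), nbrs, params)
    vol = np.full(tmap.mask.shape, np.nan)
    vol[tmap.mask] = enh
    return StatMap("TFCE", vol, tmap.contrast, tmap.mask, df=tmap.df,
                   affine=tmap.affine)


# ---------------------------------------------------------------------------
# permutation engine


def _contrast_partition(X: np.ndarray, cvec: np.ndarray):
    """Reparameterize the full model as [Z, w] with w carrying the tested
    1-df combination and Z spanning the nuisance space.

    Supports contrasts with one nonzero weight or two opposite weights
    on per-group seed-slope columns (the cases this pipeline needs); the
    column span of [Z, w] equals the span of X, so the t statistic on w
    equals the t of the contrast in the full model.
    """
    nz = np.flatnonzero(cvec)
    if len(nz) == 1:
        w = X[:, nz[0]] * cvec[nz[0]]
        Z = np.delete(X, nz[0], axis=1)
    elif len(nz) == 2 and np.isclose(cvec[nz[0]], -cvec[nz[1]]):
        a, b = nz
        w = (X[:, a] * cvec[a] + X[:, b] * cvec[b]) / 2.0
        s = (X[:, a] + X[:, b]) / 2.0
        Z = np.column_stack([np.delete(X, [a, b], axis=1), s])
    else:
        raise ValueError("contrast must touch one column or two with opposite weights")
    return Z, w


def _draw_permutations(n: int, scheme: PermutationScheme) -> np.ndarray:
    """Row-permutation matrix (n_perms, n); falls back to exhaustive
    enumeration (with a warning) when n! is below the requested count."""
    if math.factorial(n) <= scheme.n_permutations:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations exist for n={n}; "
            "enumerating exhaustively"
        )
        return np.array(list(iter_permutations(range(n))), dtype=int)
    rng = np.random.default_rng(scheme.rng_seed)
    return np.vstack([rng.permutation(n) for _ in range(scheme.n_permutations)])


@dataclass
class PermutationResult:
    """Observed maps plus the permutation null needed for (restricted) FWE."""

    p_fwe: dict                      # direction -> StatMap
    tfce_obs: StatMap                # signed observed TFCE
    t_obs: StatMap
    null_max: dict                   # direction -> (n_perms,) max TFCE
    null_tfce: np.ndarray | None     # (n_perms, n_masked) signed TFCE, if kept
    mask: np.ndarray
    scheme: PermutationScheme
    params: TFCEParams

    def min_p(self, direction: str = "pos") -> float:
        return float(np.nanmin(self.p_fwe[direction].masked()))


def _p_from_null(obs: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    """(1 + #{perm max >= obs}) / (n_perm + 1), vectorized over voxels."""
    srt = np.sort(null_max)
    n = len(srt)
    cnt = n - np.searchsorted(srt, obs, side="left")
    return (1.0 + cnt) / (n + 1.0)


def permutation_fwe(
    stack: VolumeStack,
    design: DesignMatrix,
    mask: np.ndarray,
    contrast: str,
    params: TFCEParams = TFCEParams(),
    scheme: PermutationScheme = PermutationScheme(),
    reference: str = "non-obese",
    keep_null_maps: bool = True,
    directions: tuple[str, ...] = ("pos", "neg"),
) -> PermutationResult:
    """Max-TFCE permutation FWE inference for a seed-slope contrast.

    ``contrast`` is either ``"levelB>levelA"`` (pairwise interaction) or a
    single group level name (within-group covariance).  Directions are
    tested separately: 'pos' is evidence for the contrast as written,
    'neg' for its reversal.  Set ``keep_null_maps=False`` to drop the
    per-permutation TFCE maps (required by small-volume correction) and
    save memory.
    """
    X, names, levels = _full_model(design, reference)
    cvec = np.zeros(X.shape[1])
    if ">" in contrast:
        b, a = contrast.split(">")
        cvec[names.index(f"seed:{b.strip()}")] = 1.0
        cvec[names.index(f"seed:{a.strip()}")] = -1.0
    else:
        cvec[names.index(f"seed:{contrast.strip()}")] = 1.0

    Y = stack.data[:, mask]
    n = X.shape[0]
    nbrs = neighbor_csr(mask, params.connectivity)

    Z, w = _contrast_partition(X, cvec)
    M = np.column_stack([Z, w])
    rank = np.linalg.matrix_rank(M)
    dof = n - rank
    qm, _ = np.linalg.qr(M)
    pinv_m = np.linalg.pinv(M)
    a_row = pinv_m[-1]                      # beta_w = a_row @ Y
    var_w = float(np.linalg.pinv(M.T @ M)[-1, -1])

    def t_of(Ymat: np.ndarray) -> np.ndarray:
        beta_w = a_row @ Ymat
        fit = qm.T @ Ymat
        rss = np.einsum("ij,ij->j", Ymat, Ymat) - np.einsum("ij,ij->j", fit, fit)
        rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta_w / np.sqrt(rss / dof * var_w)
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)

    t_obs_vals = t_of(Y)
    tfce_obs_vals = _tfce_masked(t_obs_vals, nbrs, params)

    perms = _draw_permutations(n, scheme)
    n_perms = perms.shape[0]

    if scheme.strategy == "freedman-lane":
        qz, _ = np.linalg.qr(Z)
        Hzy = qz @ (qz.T @ Y)
        Ez = Y - Hzy
    else:  # group-exchange: permute the rows of Y wholesale
        Hzy = None
        Ez = None

    null_max = {d: np.empty(n_perms) for d in directions}
    null_tfce = np.empty((n_perms, Y.shape[1]), np.float32) if keep_null_maps else None
    for p in range(n_perms):
        perm = perms[p]
        if scheme.strategy == "freedman-lane":
            Ystar = Hzy + Ez[perm]
        else:
            Ystar = Y[perm]
        t_p = t_of(Ystar)
        tf = _tfce_masked(t_p, nbrs, params)
        if "pos" in null_max:
            null_max["pos"][p] = tf.max(initial=0.0)
        if "neg" in null_max:
            null_max["neg"][p] = (-tf).max(initial=0.0)
        if null_tfce is not None:
            null_tfce[p] = tf

    def wrap(vals, kind, contrast_lbl, nperm=None) -> StatMap:
        vol = np.full(mask.shape, np.nan)
        vol[mask] = vals
        return StatMap(kind, vol, contrast_lbl, mask, df=dof,
                       n_permutations=nperm, affine=stack.affine)

    p_fwe = {}
    for d in directions:
        obs = tfce_obs_vals if d == "pos" else -tfce_obs_vals
        p_fwe[d] = wrap(_p_from_null(obs, null_max[d]), "p_fwe",
                        f"{contrast} ({d})", n_perms)
    return PermutationResult(
        p_fwe,
        wrap(tfce_obs_vals, "TFCE", contrast),
        wrap(t_obs_vals, "t", contrast),
        null_max,
        null_tfce,
        mask,
        scheme,
        params,
    )


_SVC_RADII = {"subcortical": 3.0, "cortical": 5.0}


def small_volume_correction(
    result: PermutationResult,
    stack: VolumeStack,
    center_mni,
    radius_mm: float | None = None,
    region: str = "subcortical",
    direction: str = "pos",
) -> StatMap:
    """FWE p values against the permutation null restricted to a sphere.

    The sphere is centered on an a-priori MNI coordinate with the radius
    chosen by region class (3 mm subcortical, 5 mm cortical) unless
    given explicitly.  Requires the per-permutation TFCE maps
    (``keep_null_maps=True`` in :func:`permutation_fwe`).
    """
    if result.null_tfce is None:
        raise ValueError("permutation result did not keep null TFCE maps")
    if radius_mm is None:
        radius_mm = _SVC_RADII[region]
    from .structcov import _sphere_voxels

    vox = _sphere_voxels(stack, center_mni, radius_mm)
    inside = np.zeros(result.mask.shape, bool)
    inside[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    sel = inside[result.mask]
    if not sel.any():
        raise ValueError("sphere does not intersect the analysis mask")

    sign = 1.0 if direction == "pos" else -1.0
    null_restricted = np.maximum((sign * result.null_tfce[:, sel]).max(axis=1), 0.0)
    obs = sign * result.tfce_obs.masked()[sel]
    pvals = _p_from_null(obs, null_restricted)
    vol = np.full(result.mask.shape, np.nan)
    flat_idx = np.flatnonzero(result.mask.ravel())[sel]
    vol.ravel()[flat_idx] = pvals
    return StatMap("p_fwe", vol, f"{result.t_obs.contrast} SVC {tuple(center_mni)} "
                   f"r={radius_mm}mm ({direction})", result.mask,
                   df=result.t_obs.df, n_permutations=result.null_tfce.shape[0],
                   affine=result.t_obs.affine)
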