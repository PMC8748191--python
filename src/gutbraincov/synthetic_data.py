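"""Synthetic cohorts: phylum tables, phenotypes, and grey-matter volumes.

The generator emulates the two inputs of the gut-brain pipeline so every
downstream stage can be exercised and validated without external data:

* a phylum-level abundance table with a planted 2-vs-3 balance whose
  value drives BMI linearly (the effect size is calibrated so the
  theoretical squared correlation between BMI and the planted balance
  matches a target, 0.3249 by default, i.e. r ~ 0.57);
* a stack of already-preprocessed (modulated, smoothed, MNI-space,
  2-mm) grey-matter volumes in which seed spheres carry a per-subject
  signal whose covariance with planted target networks differs between
  groups, on top of age / sex / global-volume confound fields and voxel
  noise.

Everything is a pure function of the :class:`CohortSpec`, including its
``rng_seed``; deterministic sub-streams are used for the structural
"truth" fields (templates, masks) and for per-subject draws, so the
truth is recomputable independently of the subject data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .compositional import AbundanceTable
from .structcov import SeedSpec, VolumeStack

__all__ = [
    "CohortSpec",
    "NetworkSpec",
    "PHYLA",
    "gen_microbiome",
    "gen_volume_stack",
    "volume_truth",
    "planted_balance_sd",
    "planted_balance_effect",
]

# 31 bacterial / archaeal phyla, matching the scale of a 16S phylum table
# after prevalence filtering.
PHYLA = [
    "Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria",
    "Verrucomicrobia", "Fusobacteria", "Cyanobacteria", "Chloroflexi",
    "Chlorobi", "Spirochaetes", "Fibrobacteres", "Tenericutes",
    "Lentisphaerae", "Elusimicrobia", "Euryarchaeota", "Synergistetes",
    "Planctomycetes", "Acidobacteria", "Deferribacteres", "Saccharibacteria",
    "Gemmatimonadetes", "Nitrospirae", "Chlamydiae", "Deinococcus-Thermus",
    "Thermotogae", "Aquificae", "Dictyoglomi", "Caldiserica",
    "Armatimonadetes", "Chrysiogenetes", "Ignavibacteriae",
]

_DEFAULT_SEEDS = (
    SeedSpec("MH", ((4.0, 2.0, -12.0), (-4.0, 2.0, -12.0)), 2.0),
    SeedSpec("LH", ((6.0, -10.0, -10.0), (-6.0, -10.0, -10.0)), 2.0),
)

@dataclass(frozen=True)
class NetworkSpec:
    """A planted covariance target region for one seed.

    ``slopes`` maps group labels to the covariance slope of the region on
    the seed signal (dimensionless GM per GM).
    """

    name: str
    seed: str
    center: tuple[float, float, float]
    radius: float
    slopes: dict

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.slopes.values()))):
            raise ValueError(f"non-finite group slope in network {self.name!r}")


# Default planted networks.  Each seed has a contrast region plus a
# mirrored region with complementary slopes, so every group carries the
# same total seed loading: covariance *reorganizes* between groups
# rather than appearing from nothing.  (This also keeps the global-GM
# covariate free of group-specific seed signal, which at desk scale
# would otherwise leak a diffuse artifact into the interaction maps.)
_DEFAULT_NETWORK_SPECS = (
    NetworkSpec("MH-target", "MH", (-14.0, -18.0, 10.0), 8.0,
                {"non-obese": 0.0, "obese-no-dysbiosis": 0.5, "obese-dysbiosis": 0.5}),
    NetworkSpec("MH-mirror", "MH", (14.0, -18.0, 10.0), 8.0,
                {"non-obese": 0.5, "obese-no-dysbiosis": 0.0, "obese-dysbiosis": 0.0}),
    NetworkSpec("LH-target", "LH", (16.0, 14.0, 6.0), 8.0,
                {"non-obese": 0.0, "obese-no-dysbiosis": 0.1, "obese-dysbiosis": 0.6}),
    NetworkSpec("LH-mirror", "LH", (-16.0, 14.0, 6.0), 8.0,
                {"non-obese": 0.6, "obese-no-dysbiosis": 0.5, "obese-dysbiosis": 0.0}),
)


@dataclass
class CohortSpec:
    """Full generative description of a synthetic cohort.

    Microbiome / phenotype parameters
    ---------------------------------
    n_subjects, n_taxa : cohort and table sizes (104 subjects, 31 phyla
        by default, the scale of the motivating study design).
    planted_numerator / planted_denominator : the taxa of the planted
        balance (2 dominant vs 3 rare phyla by default).
    balance_effect : slope of BMI on the planted balance in kg/m^2 per
        log-unit; ``None`` calibrates it with
        :func:`planted_balance_effect` to hit ``target_r2``.
    target_r2 : theoretical variance share of BMI explained by the
        planted balance (default 0.3249, i.e. r ~ 0.57).
    bmi_mean, bmi_noise_sd : kg/m^2; the mean is placed so that roughly
        55% of subjects exceed the BMI-30 obesity threshold.
    read_depth : multinomial reads per sample (None emits proportions).

    Volume parameters
    -----------------
    volume_dims, voxel_size : grid (2-mm isotropic by default) with MNI
        (0,0,0) at the central voxel.
    seed_specs : hypothalamic seed definitions (bilateral MH and LH).
    network_specs : per-seed target-region spheres (center mm, radius mm).
    group_slopes : per-seed, per-stratum covariance slope of the network
        on the seed signal.
    confound_effects : loadings of the age, sex and global-volume
        confound fields.
    smoothing_fwhm : mm, applied to the finished volumes (the synthetic
        counterpart of smoothed VBM output).
    """

    n_subjects: int = 104
    n_taxa: int = 31
    planted_numerator: tuple[str, ...] = ("Firmicutes", "Fibrobacteres")
    planted_denominator: tuple[str, ...] = ("Chloroflexi", "Chlorobi", "Spirochaetes")
    balance_effect: float | None = None
    target_r2: float = 0.3249
    bmi_mean: float = 31.0
    bmi_noise_sd: float = 6.0
    read_depth: int | None = 5000
    taxon_log_sd: float = 0.7
    numerator_log_means: tuple[float, ...] = (3.6, 2.8)
    denominator_log_means: tuple[float, ...] = (-2.7, -2.8, -2.9)
    other_log_mean_sd: tuple[float, float] = (-1.0, 1.2)
    structural_zero_fraction: float = 0.25
    structural_zero_rate: float = 0.4
    age_mean: float = 47.0
    age_sd: float = 9.0
    age_bmi_slope: float = -0.25
    p_female: float = 0.66
    stroop_mean: float = 44.0
    stroop_balance_slope: float = -6.0
    stroop_noise_sd: float = 8.0
    phq9_mean: float = 6.0
    phq9_balance_slope: float = 3.0
    phq9_noise_sd: float = 3.5

    volume_dims: tuple[int, int, int] = (32, 38, 32)
    voxel_size: float = 2.0
    seed_specs: tuple[SeedSpec, ...] = _DEFAULT_SEEDS
    networks: tuple = _DEFAULT_NETWORK_SPECS
    confound_effects: dict = field(default_factory=lambda: {
        "age": 0.03, "sex": 0.02, "global": 0.05
    })
    seed_signal_sd: float = 0.15
    noise_sd: float = 0.05
    smoothing_fwhm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        a, b = set(self.planted_numerator), set(self.planted_denominator)
        if not a or not b:
            raise ValueError("planted numerator and denominator must be nonempty")
        if a & b:
            raise ValueError("planted numerator and denominator overlap")
        if self.n_taxa < len(a) + len(b):
            raise ValueError("n_taxa smaller than the planted signature")
        if any(d <= 0 for d in self.volume_dims):
            raise ValueError("volume_dims must be positive")
        seed_names = {sd.name for sd in self.seed_specs}
        for net in self.networks:
            if net.seed not in seed_names:
                raise ValueError(f"network {net.name!r} references unknown seed {net.seed!r}")

    # deterministic sub-streams -------------------------------------------
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.rng_seed), stream]))

    def taxon_ids(self) -> list[str]:
        planted = list(self.planted_numerator) + list(self.planted_denominator)
        pool = [p for p in PHYLA if p not in planted]
        extra = [f"Phylum{i:02d}" for i in range(max(0, self.n_taxa - len(planted) - len(pool)))]
        others = (pool + extra)[: self.n_taxa - len(planted)]
        return planted + others

    def taxon_log_means(self) -> pd.Series:
        ids = self.taxon_ids()
        mus = np.empty(len(ids))
        na, nb = len(self.planted_numerator), len(self.planted_denominator)
        mus[:na] = np.resize(self.numerator_log_means, na)
        mus[na:na + nb] = np.resize(self.denominator_log_means, nb)
        loc, sd = self.other_log_mean_sd
        mus[na + nb:] = self._rng(11).normal(loc, sd, len(ids) - na - nb)
        return pd.Series(mus, index=ids)

    def planted_balance_mean(self) -> float:
        mus = self.taxon_log_means()
        return float(
            mus[list(self.planted_numerator)].mean()
            - mus[list(self.planted_denominator)].mean()
        )


def planted_balance_sd(spec: CohortSpec, n_sim: int = 4000) -> float:
    """Empirical SD of the planted (latent) balance under the baseline
    log-normal model, from a dedicated simulation stream."""
    rng = spec._rng(17)
    na, nb = len(spec.planted_numerator), len(spec.planted_denominator)
    z = rng.normal(0.0, spec.taxon_log_sd, size=(n_sim, na + nb))
    bal = z[:, :na].mean(axis=1) - z[:, na:].mean(axis=1)
    return float(bal.std(ddof=1))


def planted_balance_effect(spec: CohortSpec) -> float:
    """BMI slope on the planted balance achieving the spec's target R^2.

    From R^2 = b^2 Var(B) / (b^2 Var(B) + sigma^2):
    b = sqrt(R^2 / (1 - R^2)) * sigma / sd(B).
    """
    if spec.balance_effect is not None:
        return float(spec.balance_effect)
    sd_b = planted_balance_sd(spec)
    r2 = spec.target_r2
    return math.sqrt(r2 / (1.0 - r2)) * spec.bmi_noise_sd / sd_b


# ---------------------------------------------------------------------------
# microbiome + phenotypes


def gen_microbiome(spec: CohortSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate the abundance table and phenotype table of a cohort.

    The table holds multinomial counts at ``spec.read_depth`` reads per
    sample (proportions if depth is None); a fraction of the non-planted
    taxa carries structural zeros so prevalence filtering has something
    to remove.  The phenotype table includes the generator truth columns
    ``true_balance`` (latent planted balance) and ``true_stratum``.
    """
    n = spec.n_subjects
    ids = spec.taxon_ids()
    mus = spec.taxon_log_means().to_numpy()
    rng = spec._rng(23)

    log_intensity = mus + rng.normal(0.0, spec.taxon_log_sd, size=(n, len(ids)))
    intensity = np.exp(log_intensity)

    # structural zeros in some non-planted taxa (exercises the 20% filter)
    n_planted = len(spec.planted_numerator) + len(spec.planted_denominator)
    n_struct = int(round(spec.structural_zero_fraction * (len(ids) - n_planted)))
    struct_taxa = rng.choice(
        np.arange(n_planted, len(ids)), size=n_struct, replace=False
    )
    for t in struct_taxa:
        absent = rng.random(n) < spec.structural_zero_rate
        intensity[absent, t] = 0.0

    props = intensity / intensity.sum(axis=1, keepdims=True)
    if spec.read_depth is not None:
        values = np.vstack(
            [rng.multinomial(spec.read_depth, p) for p in props]
        ).astype(float)
    else:
        values = props
    table = AbundanceTable([f"S{i + 1:03d}" for i in range(n)], ids, values)

    # latent planted balance drives BMI
    na = len(spec.planted_numerator)
    lm = log_intensity[:, : na + len(spec.planted_denominator)]
    bal = lm[:, :na].mean(axis=1) - lm[:, na:].mean(axis=1)
    b_eff = planted_balance_effect(spec)
    bal_c = bal - spec.planted_balance_mean()
    bmi = spec.bmi_mean + b_eff * bal_c + rng.normal(0.0, spec.bmi_noise_sd, n)
    bmi = np.clip(bmi, 17.0, 65.0)

    age = spec.age_mean + spec.age_bmi_slope * (bmi - spec.bmi_mean)
    age = np.clip(age + rng.normal(0.0, spec.age_sd, n), 20.0, 75.0)
    sex = np.where(rng.random(n) < spec.p_female, "female", "male")
    obesity = np.where(bmi > 30.0, "obese", "non-obese")

    stroop = (
        spec.stroop_mean + spec.stroop_balance_slope * bal_c
        + rng.normal(0.0, spec.stroop_noise_sd, n)
    )
    phq9 = np.clip(np.rint(
        spec.phq9_mean + spec.phq9_balance_slope * bal_c
        + rng.normal(0.0, spec.phq9_noise_sd, n)
    ), 0, 27)

    pheno = pd.DataFrame({
        "subject_id": table.sample_ids,
        "bmi": bmi,
        "age": age,
        "sex": sex,
        "obesity": obesity,
        "stroop_interference": stroop,
        "phq9": phq9.astype(int),
        "true_balance": bal,
    })

    # generator-truth stratum: median split of the latent balance in the
    # obese group (the pipeline re-derives strata from the fitted balance)
    obese = pheno["obesity"] == "obese"
    stratum = np.where(obese, "obese-no-dysbiosis", "non-obese")
    if obese.any():
        med = np.median(bal[obese.to_numpy()])
        stratum[obese.to_numpy() & (bal > med)] = "obese-dysbiosis"
    pheno["true_stratum"] = stratum
    return table, pheno


# ---------------------------------------------------------------------------
# volumes


def _smooth(vol: np.ndarray, fwhm_mm: float, voxel_size: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return vol
    sigma = fwhm_mm / 2.3548 / voxel_size
    return gaussian_filter(vol, sigma, mode="constant")


@dataclass
class VolumeTruth:
    """Deterministic structural fields of a cohort's volume model."""

    affine: np.ndarray
    template_raw: np.ndarray
    template: np.ndarray          # smoothed; equals the data when all effects are off
    brain: np.ndarray             # boolean support of the synthetic brain
    seed_fields: dict             # seed name -> indicator volume (both hemispheres)
    network_masks: dict           # region name -> boolean planted target region
    network_support: dict         # region name -> boolean post-smoothing support
    network_seed: dict            # region name -> seed name
    confound_fields: dict         # 'age'/'sex' -> smooth random fields

    def support_union(self, seed: str | None = None, dilate: int = 0) -> np.ndarray:
        """Union of planted-network supports (optionally for one seed).

        ``dilate`` grows the union by that many voxels; cluster-forming
        statistics (TFCE) legitimately extend significance a voxel or
        two past the smoothed effect support, so exclusion zones for
        specificity checks should include a small margin.
        """
        out = np.zeros(self.template.shape, bool)
        for name, sup in self.network_support.items():
            if seed is None or self.network_seed[name] == seed:
                out |= sup
        if dilate > 0:
            from scipy.ndimage import binary_dilation
            out = binary_dilation(out, np.ones((3, 3, 3), bool), iterations=dilate)
        return out

    def mni_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dims = self.template.shape
        ax = [self.affine[i, i] * np.arange(dims[i]) + self.affine[i, 3] for i in range(3)]
        return np.meshgrid(*ax, indexing="ij")


def _sphere_mask(truth_grid, center, radius) -> np.ndarray:
    gx, gy, gz = truth_grid
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    return d2 <= radius**2


def volume_truth(spec: CohortSpec) -> VolumeTruth:
    """Recompute the structural truth fields (pure function of the spec)."""
    dims = tuple(spec.volume_dims)
    vs = spec.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = [-(d // 2) * vs for d in dims]

    ax = [affine[i, i] * np.arange(dims[i]) + affine[i, 3] for i in range(3)]
    grid = np.meshgrid(*ax, indexing="ij")
    gx, gy, gz = grid
    half = [(d // 2) * vs for d in dims]
    radii = [h - 3.0 * vs for h in half]
    e = (gx / radii[0]) ** 2 + (gy / radii[1]) ** 2 + (gz / radii[2]) ** 2
    template_raw = np.where(e <= 1.0, 0.6, np.where(e <= 1.3, 0.1, 0.0))
    brain = e <= 1.0

    seed_fields = {}
    for seed in spec.seed_specs:
        f = np.zeros(dims)
        for c in seed.mni_coords:
            m = _sphere_mask(grid, c, seed.radius)
            if not m.any():
                raise ValueError(f"seed {seed.name} coordinate {c} is outside the grid")
            f[m] = 1.0
        seed_fields[seed.name] = f

    network_masks, network_support, network_seed = {}, {}, {}
    for net in spec.networks:
        m = _sphere_mask(grid, net.center, net.radius)
        if not m.any():
            raise ValueError(f"network {net.name!r} is outside the grid")
        network_masks[net.name] = m
        sm = _smooth(m.astype(float), spec.smoothing_fwhm, vs)
        network_support[net.name] = sm > 1e-3 * sm.max()
        network_seed[net.name] = net.seed

    rng = spec._rng(101)
    confound_fields = {}
    for key in ("age", "sex"):
        f = _smooth(rng.standard_normal(dims), 3 * vs, vs)
        f *= brain
        rms = np.sqrt(np.mean(f[brain] ** 2))
        confound_fields[key] = f / rms

    template = _smooth(template_raw, spec.smoothing_fwhm, vs)
    return VolumeTruth(affine, template_raw, template, brain, seed_fields,
                       network_masks, network_support, network_seed, confound_fields)


def gen_volume_stack(spec: CohortSpec, phenotypes: pd.DataFrame) -> VolumeStack:
    """Generate per-subject grey-matter volumes for a phenotype table.

    Each subject volume is ``template + seed signals + group-dependent
    network signal + confound fields + noise``, then smoothed at
    ``spec.smoothing_fwhm``.  Network slopes are looked up by the
    ``true_stratum`` column (or ``obesity`` when strata are absent).
    """
    for col in ("age", "sex"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotypes must carry an {col!r} column")
    truth = volume_truth(spec)
    rng = spec._rng(202)
    n = len(phenotypes)
    dims = tuple(spec.volume_dims)

    age_z = (phenotypes["age"].to_numpy(float) - spec.age_mean) / spec.age_sd
    sex_z = (phenotypes["sex"].to_numpy() == "female").astype(float)
    sex_z -= sex_z.mean()
    groups = phenotypes.get("true_stratum", phenotypes.get("obesity"))
    if groups is None:
        raise ValueError("phenotypes must carry group labels (true_stratum or obesity)")
    groups = groups.to_numpy()

    seed_signals = {
        s.name: rng.normal(0.0, spec.seed_signal_sd, n) for s in spec.seed_specs
    }
    global_scale = rng.normal(0.0, 1.0, n)
    ce = spec.confound_effects

    data = np.empty((n,) + dims, dtype=np.float64)
    for i in range(n):
        vol = truth.template_raw * (1.0 + ce.get("global", 0.0) * global_scale[i])
        for s in spec.seed_specs:
            vol = vol + seed_signals[s.name][i] * truth.seed_fields[s.name]
        for net in spec.networks:
            slope = net.slopes.get(groups[i], 0.0)
            if slope:
                vol = vol + slope * seed_signals[net.seed][i] * truth.network_masks[net.name]
        vol = vol + ce.get("age", 0.0) * age_z[i] * truth.confound_fields["age"]
        vol = vol + ce.get("sex", 0.0) * sex_z[i] * truth.confound_fields["sex"]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, dims)
        data[i] = _smooth(vol, spec.smoothing_fwhm, spec.voxel_size)

    return VolumeStack(list(phenotypes["subject_id"].astype(str)), data, truth.affine)
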