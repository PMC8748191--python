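"""End-to-end orchestration: signature -> strata -> covariance -> inference.

`run_pipeline` chains the stages in the order of the underlying study
design: prevalence-filter the phylum table and select the BMI-predictive
balance by cross-validated forward search; split the obese subjects at
the obese-group median of the fitted balance into dysbiosis strata;
fit the seed-based structural covariance GLMs (sequentially
orthogonalized covariates, seed-by-group interaction) for each
hypothalamic seed; run TFCE max-statistic permutation FWE inference;
and compare cognition / mood scores between strata.  All outputs are
plain TSV/JSON plus NIfTI stat maps, and every random stage is driven
by the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .balance_selection import cross_validate_signature
from .compositional import AbundanceTable, compute_balance, filter_prevalence, replace_zeros
from .stratification import compare_groups, stratify_by_median
from .structcov import (
    SeedSpec, VolumeStack, build_design, fit_interaction_glm, make_gm_mask,
    orthogonalize_design,
)
from .synthetic_data import CohortSpec, gen_microbiome, gen_volume_stack
from .tfce_inference import PermutationScheme, TFCEParams, permutation_fwe

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "cluster_table"]

_DEFAULT_SEEDS = (
    SeedSpec("MH", ((4.0, 2.0, -12.0), (-4.0, 2.0, -12.0)), 2.0),
    SeedSpec("LH", ((6.0, -10.0, -10.0), (-6.0, -10.0, -10.0)), 2.0),
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and analysis parameters of a full run."""

    abundance_tsv: str | None = None
    phenotype_tsv: str | None = None
    volume_manifest: str | None = None   # TSV: subject_id, path
    output_dir: str = "gutbraincov_out"
    prevalence_threshold: float = 0.20
    pseudocount: float = 0.5
    gm_threshold: float = 0.2
    cv_folds: int = 5
    cv_repeats: int = 10
    max_signature_size: int = 8
    seeds: tuple[SeedSpec, ...] = _DEFAULT_SEEDS
    contrast_groups: str = "obesity"      # 'obesity' (2 groups) or 'stratum' (3)
    n_permutations: int = 500
    tfce: TFCEParams = field(default_factory=TFCEParams)
    alpha_fwe: float = 0.05
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seeds" in raw:
            raw["seeds"] = tuple(
                SeedSpec(s["name"], tuple(tuple(c) for c in s["mni_coords"]),
                         s.get("radius", 2.0))
                for s in raw["seeds"]
            )
        if "tfce" in raw:
            raw["tfce"] = TFCEParams(**raw["tfce"])
        return cls(**raw)


@dataclass
class PipelineReport:
    """In-memory summary of a pipeline run (everything is also on disk)."""

    signature: object
    optimal_size: int
    balance_bmi_r: float
    phenotypes: pd.DataFrame
    balance_median: float
    strata_sizes: dict
    permutation_results: dict      # (seed, contrast) -> PermutationResult
    cluster_tables: dict           # (seed, contrast, direction) -> DataFrame
    group_stats: pd.DataFrame
    output_dir: Path


def cluster_table(result, stack, alpha: float = 0.05, direction: str = "pos") -> pd.DataFrame:
    """Peak table of FWE-significant clusters: peak MNI coordinates, peak t,
    peak TFCE and cluster extent (voxels), 26-connectivity."""
    p = result.p_fwe[direction].values
    sig = np.where(np.isnan(p), False, p < alpha)
    rows = []
    lab, n = ndimage.label(sig, structure=np.ones((3, 3, 3), bool))
    sign = 1.0 if direction == "pos" else -1.0
    tf = sign * result.tfce_obs.values
    tvals = sign * result.t_obs.values
    for c in range(1, n + 1):
        comp = lab == c
        idx = np.argwhere(comp)
        peak = idx[np.nanargmax(tf[comp])]
        mni = stack.voxel_to_mni(peak)
        rows.append({
            "x": mni[0], "y": mni[1], "z": mni[2],
            "t": float(tvals[tuple(peak)]),
            "tfce": float(tf[tuple(peak)]),
            "p_fwe": float(np.nanmin(p[comp])),
            "extent": int(comp.sum()),
        })
    cols = ["x", "y", "z", "t", "tfce", "p_fwe", "extent"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        "tfce", ascending=False, ignore_index=True
    ) if rows else pd.DataFrame(columns=cols)


def _load_inputs(config: PipelineConfig):
    table = AbundanceTable.from_tsv(config.abundance_tsv)
    pheno = pd.read_csv(config.phenotype_tsv, sep="\t")
    stack = None
    if config.volume_manifest:
        man = pd.read_csv(config.volume_manifest, sep="\t")
        base = Path(config.volume_manifest).parent
        paths = [Path(p) if Path(p).is_absolute() else base / p for p in man["path"]]
        stack = VolumeStack.from_niftis(paths, list(man["subject_id"].astype(str)))
    return table, pheno, stack


def run_pipeline(config: PipelineConfig, inputs=None) -> PipelineReport:
    """Run every stage and write the report bundle to ``config.output_dir``.

    ``inputs`` may pre-supply ``(table, phenotypes, stack)`` (e.g. from
    the synthetic generator) to skip file loading; ``stack=None`` skips
    the imaging stages.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, pheno, stack = inputs if inputs is not None else _load_inputs(config)
    pheno = pheno.copy()

    # --- microbial signature ------------------------------------------------
    try:
        filtered = filter_prevalence(table, config.prevalence_threshold)
        positive = replace_zeros(filtered, config.pseudocount)
        bmi = pheno.set_index(pheno["subject_id"].astype(str)).loc[
            table.sample_ids, "bmi"].to_numpy(float)
        cv = cross_validate_signature(
            positive, bmi, folds=config.cv_folds, repeats=config.cv_repeats,
            max_size=config.max_signature_size, rng_seed=config.rng_seed,
        )
    except Exception as err:
        raise RuntimeError(f"signature stage failed: {err}") from err
    signature = cv.signature
    (out / "signature.json").write_text(
        json.dumps(signature.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    cv.robustness.to_tsv(out / "robustness.tsv")

    balance = compute_balance(positive, signature)
    pheno["balance_value"] = balance
    balance_bmi_r = float(np.corrcoef(balance, bmi)[0, 1])

    # --- stratification -----------------------------------------------------
    try:
        pheno = stratify_by_median(pheno)
    except Exception as err:
        raise RuntimeError(f"stratification stage failed: {err}") from err
    strata_sizes = pheno["stratum"].value_counts().to_dict()
    pheno.to_csv(out / "phenotypes_stratified.tsv", sep="\t", index=False,
                 float_format="%.6g")

    # --- group comparisons --------------------------------------------------
    stats_rows = []
    pair = ("obese-no-dysbiosis", "obese-dysbiosis")
    for var in ("stroop_interference", "phq9"):
        if var in pheno.columns:
            for covs in (None, ["age"]):
                try:
                    cmp_ = compare_groups(pheno, var, pair, covariates=covs)
                except ValueError:
                    continue
                stats_rows.append({
                    "variable": var, "groups": " vs ".join(pair),
                    "adjusted": "+".join(covs) if covs else "",
                    "t": cmp_.t, "p": cmp_.p, "df": cmp_.df,
                    **{f"mean_{g}": cmp_.means[g][0] for g in pair},
                    **{f"sd_{g}": cmp_.means[g][1] for g in pair},
                })
    group_stats = pd.DataFrame(stats_rows)
    group_stats.to_csv(out / "group_comparisons.tsv", sep="\t", index=False,
                       float_format="%.6g")

    # --- structural covariance + inference ----------------------------------
    perm_results: dict = {}
    cluster_tables: dict = {}
    if stack is not None:
        mask = make_gm_mask(stack, config.gm_threshold)
        group_col = config.contrast_groups if config.contrast_groups in pheno else "obesity"
        levels = sorted(pheno[group_col].unique())
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for i, seed in enumerate(config.seeds):
            other = config.seeds[1 - i] if len(config.seeds) == 2 else config.seeds[(i + 1) % len(config.seeds)]
            try:
                design = orthogonalize_design(
                    build_design(stack, pheno, seed, other, group_column=group_col)
                )
                glm = fit_interaction_glm(stack, design, mask)
                contrasts = list(glm.t_maps)
                for contrast in contrasts:
                    scheme = PermutationScheme(config.n_permutations,
                                               rng_seed=config.rng_seed)
                    res = permutation_fwe(stack, design, mask, contrast,
                                          config.tfce, scheme)
                    perm_results[(seed.name, contrast)] = res
                    slug = f"{seed.name}_{contrast.replace('>', '_gt_')}"
                    res.t_obs.save(maps_dir / f"{slug}_t.nii")
                    res.tfce_obs.save(maps_dir / f"{slug}_tfce.nii")
                    for d in ("pos", "neg"):
                        res.p_fwe[d].save(maps_dir / f"{slug}_pfwe_{d}.nii")
                        tab = cluster_table(res, stack, config.alpha_fwe, d)
                        cluster_tables[(seed.name, contrast, d)] = tab
                        tab.to_csv(out / f"clusters_{slug}_{d}.tsv", sep="\t",
                                   index=False, float_format="%.6g")
            except Exception as err:
                raise RuntimeError(
                    f"covariance stage failed for seed {seed.name}: {err}"
                ) from err

    # --- run log ------------------------------------------------------------
    log = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, (tuple, TFCEParams))
        },
        "tfce": dataclasses.asdict(config.tfce),
        "seeds": [dataclasses.asdict(s) for s in config.seeds],
        "signature": signature.as_dict(),
        "optimal_size": cv.optimal_size,
        "balance_bmi_r": balance_bmi_r,
        "balance_median_obese": pheno.attrs.get("balance_median"),
        "strata_sizes": strata_sizes,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True,
                                                 default=str) + "\n")

    return PipelineReport(signature, cv.optimal_size, balance_bmi_r, pheno,
                          float(pheno.attrs.get("balance_median")), strata_sizes,
                          perm_results, cluster_tables, group_stats, out)


def synthesize_cohort(spec: CohortSpec, output_dir, with_volumes: bool = True):
    """Generate a cohort and write it in the pipeline's input formats."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, pheno = gen_microbiome(spec)
    table.to_tsv(out / "abundance.tsv")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False, float_format="%.6g")
    stack = None
    if with_volumes:
        stack = gen_volume_stack(spec, pheno)
        vol_dir = out / "volumes"
        paths = stack.to_niftis(vol_dir)
        pd.DataFrame({
            "subject_id": stack.subject_ids,
            "path": [str(p.relative_to(out)) for p in paths],
        }).to_csv(out / "volumes.tsv", sep="\t", index=False)
    return table, pheno, stack
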