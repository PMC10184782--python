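"""End-to-end orchestration of the cohort analysis.

``run_all`` composes the stages — synthetic cohort generation, per-
species genome measurement (optional), PSMC demography, phylogenetic
statistics, and random-forest prediction — under a single resolved
configuration and seed, and writes a manifest with file checksums so
identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import demography, load_metrics, phylo_stats, risk_prediction, roh_het, synthetic_cohort, variant_effects
from .errors import InvalidParameterError
from .synthetic_cohort import SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

STAGES = ("cohort", "demography", "genome", "stats", "predict")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults follow the study constants.

    window_size 50,000 bp; phyloP threshold 2.27 (strict >); harmonic-mean
    age cutoff 10,000 years; contigs shorter than ``min_contig_length``
    (50 kb) are excluded from demography input preparation. ``mu`` and
    ``gen_time`` have no universal default in the source analyses and
    must be supplied per species cohort; the synthetic defaults here are
    a generic mammalian rate and generation time.
    """

    out_dir: str = "genomerisk_run"
    seed: int = 0
    synthetic: bool = True
    n_species: int = 240
    window_size: int = 50_000
    phylop_threshold: float = 2.27
    min_age_years: float = 10_000.0
    min_contig_length: int = 50_000
    mu: float = 1e-8
    gen_time: float = 5.0
    n_dd: int = 3
    n_boot: int = 200
    rf_grid: str = "small"  # "small" | "default"
    genome_stage_species: int = 0  # 0 disables the per-species genome stage
    genome_window_size: int = 2_000
    genome_contig_length: int = 100_000
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    cohort: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise InvalidParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class RunResult:
    features: pd.DataFrame
    stats: dict
    rf_reports: pd.DataFrame | None
    dd_predictions: pd.Series | None
    dd_refusals: dict
    manifest: dict


def _require_stage(config: RunConfig, stage: str, needed_by: str) -> None:
    if not config.stages.get(stage, True):
        raise InvalidParameterError(
            f"stage '{needed_by}' requires stage '{stage}', which is toggled off")


def measure_species_genome(
    bundle: synthetic_cohort.ToyGenomeBundle,
    window_size: int,
    phylop_threshold: float = 2.27,
    seed: int = 0,
) -> dict[str, float]:
    """Measure the load/diversity summary statistics from a genome bundle.

    Runs the windowed-heterozygosity + GMM RoH caller, the derived-
    substitution caller, the consequence annotator, and the load
    summarizer, returning one feature row.
    """
    wtab = roh_het.compute_window_het(bundle.variants, bundle.callable_mask, window_size)
    fit = roh_het.fit_gmm_2(wtab.loc[wtab.assessed, "ratio"], seed=seed)
    calls = roh_het.assign_roh(wtab, fit)

    subs = variant_effects.call_derived_substitutions(bundle.reference, bundle.ancestral)
    genes = variant_effects.load_gene_models(bundle.gene_models, bundle.impc_table)
    sub_variants = subs.records.rename(columns={"ancestral": "base_from", "derived": "base_to"})
    hets = variant_effects.read_het_variants(bundle.variants)
    hets["zygosity"] = "heterozygous"
    all_variants = pd.concat([sub_variants, hets], ignore_index=True)
    annotated = variant_effects.annotate_variants(all_variants, genes, bundle.reference)
    summary = load_metrics.summarize_load(
        annotated, subs.records, bundle.phylop_track,
        impc_classes={g.gene_id: g.impc_class for g in genes},
        threshold=phylop_threshold,
    )
    row = load_metrics.summary_row(summary)
    row.update({
        "froh": calls.froh,
        "het_genomewide": calls.het_genomewide,
        "het_outbred": calls.het_outbred,
    })
    return row


def _demography_roundtrip(ne: float, mu: float, gen_time: float) -> float:
    """Constant-Ne trajectory through the PSMC write/parse/rescale path."""
    traj = demography.NeTrajectory(
        epochs=(
            demography.Epoch(0.0, 1.0e5, ne),
            demography.Epoch(1.0e5, 2.0e6, ne),
        ),
        gen_time=gen_time, mu=mu,
    )
    text = synthetic_cohort.simulate_psmc_output(traj, mu, gen_time)
    rec = demography.parse_psmc(text)
    back = demography.rescale_trajectory(rec, mu, gen_time)
    return demography.harmonic_mean_ne(back)


def run_all(config: RunConfig) -> RunResult:
    """Execute the configured stages end-to-end and write all outputs."""
    os.makedirs(config.out_dir, exist_ok=True)
    if not config.synthetic:
        raise InvalidParameterError(
            "only synthetic mode is implemented; provide synthetic=True")
    _require_stage(config, "cohort", "cohort")

    params = synthetic_cohort.CohortParams(
        n_species=config.n_species, seed=config.seed, **config.cohort)
    tree = synthetic_cohort.generate_tree(params.n_species, params.birth_rate, seed=params.seed)
    cohort = synthetic_cohort.simulate_species_traits(tree, params)
    feats = cohort.features.copy()

    # demography: push every species' Ne through the PSMC text round trip
    if config.stages.get("demography", True):
        measured = [
            _demography_roundtrip(ne, config.mu, config.gen_time)
            for ne in feats["ne_harmonic"]
        ]
        feats["ne_harmonic"] = measured

    # genome stage: replace trait-level stats with measured ones for a subset
    if config.genome_stage_species > 0:
        _require_stage(config, "genome", "genome")
        rng = np.random.default_rng(config.seed + 1)
        subset = list(feats.index[: config.genome_stage_species])
        for i, sp in enumerate(subset):
            gp = synthetic_cohort.GenomeParams(
                contig_lengths=(config.genome_contig_length,),
                f_roh=float(np.clip(feats.loc[sp, "froh"], 0.0, 0.8)),
                het_rate=float(np.clip(feats.loc[sp, "het_genomewide"] * 1.3, 1e-5, 0.1)),
                frac_missense=float(feats.loc[sp, "prop_missense_het"]),
                frac_lof=float(feats.loc[sp, "prop_lof_het"]),
                frac_synonymous=float(
                    1.0 - feats.loc[sp, "prop_missense_het"] - feats.loc[sp, "prop_lof_het"]),
                conserved_fraction=float(feats.loc[sp, "prop_conserved_subs"]),
                n_coding_subs=400, n_coding_hets=None,
            )
            bundle = synthetic_cohort.simulate_genome(
                gp, os.path.join(config.out_dir, "genomes", sp),
                seed=int(rng.integers(2**31 - 1)),
            )
            row = measure_species_genome(
                bundle, config.genome_window_size, config.phylop_threshold,
                seed=config.seed)
            for k, v in row.items():
                if k in feats.columns and np.isfinite(v):
                    feats.loc[sp, k] = v

    stats_out: dict = {}
    if config.stages.get("stats", True):
        cov = phylo_stats.tree_to_covariance(tree).reordered(list(feats.index))
        log_ne = np.log(feats["ne_harmonic"].to_numpy(dtype=float))
        x = pd.DataFrame({"log_ne": log_ne}, index=feats.index)
        pgls = phylo_stats.fit_pgls(x, feats["prop_missense_fixed"].to_numpy(float), cov)
        y_thr = feats["threatened"].astype(bool).to_numpy()
        glm = phylo_stats.fit_phylo_logistic(
            pd.DataFrame({"prop_missense_fixed": feats["prop_missense_fixed"]}),
            y_thr.astype(float), cov, n_boot=config.n_boot, seed=config.seed)
        ordx = pd.concat([
            pd.DataFrame({"log_ne": log_ne}, index=feats.index).reset_index(drop=True),
            phylo_stats.order_dummies(feats["tax_order"]),
        ], axis=1)
        try:
            ordfit = phylo_stats.fit_ordinal(ordx, feats["iucn"])
            ord_summary = {
                "slope_log_ne": float(ordfit.coef[0]),
                "p_log_ne": float(ordfit.pvalues[0]),
            }
        except Exception as exc:  # taxonomic dummies can alias in tiny cohorts
            logger.warning("ordinal fit skipped: %s", exc)
            ord_summary = None
        pcr = phylo_stats.pc_regression(
            feats[list(SUMMARY_COLUMNS)], y_thr.astype(float), cov,
            n_components=5, seed=config.seed)
        mean_thr = float(feats.loc[y_thr, "ne_harmonic"].mean())
        mean_non = float(feats.loc[~y_thr, "ne_harmonic"].mean())
        stats_out = {
            "pgls_missense_on_log_ne": {
                "slope": float(pgls.coef[1]), "se": float(pgls.se[1]),
                "p": float(pgls.pvalues[1]), "lambda": pgls.lambda_,
            },
            "phyloglm_threat_on_missense": {
                "coef": float(glm.coef[1]),
                "p_boot": float(glm.p_boot[1]) if glm.p_boot is not None else None,
                "p_wald": float(glm.pvalues[1]),
            },
            "ordinal_iucn_on_log_ne": ord_summary,
            "pc_regression": {
                "explained_variance": [float(v) for v in pcr.explained_variance[:5]],
                "pc_pvalues": [float(p) for p in pcr.glm.pvalues[1:]],
            },
            "mean_ne_threatened": mean_thr,
            "mean_ne_nonthreatened": mean_non,
        }

    rf_reports = None
    dd_pred, dd_ref = None, {}
    if config.stages.get("predict", True):
        _require_stage(config, "stats", "predict")
        rng = np.random.default_rng(config.seed + 2)
        labels = feats["threatened"].astype(object).copy()
        dd_species = list(rng.choice(feats.index, size=min(config.n_dd, len(feats) // 10),
                                     replace=False))
        labels.loc[dd_species] = np.nan
        eco_cols = [c for c in feats.columns if c.startswith("eco_")]
        fmatrix = risk_prediction.build_feature_matrix(
            feats[list(SUMMARY_COLUMNS)], labels,
            ecological=feats[eco_cols] if eco_cols else None,
        )
        grid = (risk_prediction.DEFAULT_GRID if config.rf_grid == "default"
                else risk_prediction.SMALL_GRID)
        rf_reports = risk_prediction.compare_feature_sets(fmatrix, seed=config.seed, grid=grid)
        model = risk_prediction.train_rf(
            fmatrix, group_set=("summary", "ecological"), seed=config.seed, grid=grid)
        dd_pred, dd_ref = risk_prediction.predict_unlabeled(model, fmatrix)

    # ---- outputs ----------------------------------------------------------
    paths = {}
    feats_path = os.path.join(config.out_dir, "features.tsv")
    feats.to_csv(feats_path, sep="\t", float_format="%.10g")
    paths["features"] = feats_path
    stats_path = os.path.join(config.out_dir, "stats.json")
    with open(stats_path, "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True)
    paths["stats"] = stats_path
    if rf_reports is not None:
        rf_path = os.path.join(config.out_dir, "rf_reports.tsv")
        rf_reports.to_csv(rf_path, sep="\t", index=False, float_format="%.10g")
        paths["rf_reports"] = rf_path
    if dd_pred is not None:
        dd_path = os.path.join(config.out_dir, "dd_predictions.tsv")
        dd_pred.rename("p_threatened").to_frame().to_csv(dd_path, sep="\t", float_format="%.10g")
        paths["dd_predictions"] = dd_path

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "checksums": {
            name: hashlib.sha256(open(p, "rb").read()).hexdigest()
            for name, p in paths.items()
        },
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.out_dir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    return RunResult(
        features=feats, stats=stats_out, rf_reports=rf_reports,
        dd_predictions=dd_pred, dd_refusals=dd_ref, manifest=manifest,
    )
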