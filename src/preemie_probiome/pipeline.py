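"""Config-driven orchestration of the full cohort analysis.

One YAML config (paths, covariate order, windows, permutations, NMDS and
typing settings, engraftment stratum, a single global seed) drives every
stage; per-stage seeds are derived deterministically from the global seed
by hashing the stage name, so stages are reproducible in isolation.
Stages communicate only through the written tables; figures are leaves.
Each output is written atomically (temp file + rename) and a JSON
manifest records the config hash, seed, package version, warnings and
any stage errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    TIME_WINDOWS,
    covariate_table,
    read_metadata,
    read_profiles,
    reconcile,
)
from .community import (
    fit_community_types,
    probiotic_associated_types,
    type_proportions_by_group,
)
from .diversity import (
    NMDS,
    distance_matrix,
    diversity_mixed_model,
    group_centroids,
    shannon_table,
)
from .engraftment import compare_groups, engraftment_table
from .permanova import DEFAULT_COVARIATES, plot_variance_grid, variance_grid

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    profiles: str = "profiles.tsv"
    infants: str = "infants.csv"
    samples: str = "samples.csv"
    outdir: str = "analysis_out"
    covariates: tuple[str, ...] = ("group",) + DEFAULT_COVARIATES
    n_perm: int = 999
    min_window_n: int = 15
    permanova_mode: str = "sequential"
    nmds_dimensions: int = 2
    nmds_restarts: int = 2
    nmds_max_iter: int = 150
    nmds_max_samples: int = 400
    typing_k: int = 5
    typing_depth: int = 10000
    typing_restarts: int = 2
    engraftment_stratum: str = "product"
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.typing_k < 1 or self.nmds_dimensions < 1:
            raise ValueError("typing_k and nmds_dimensions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_table(df: pd.DataFrame, path, index=False) -> None:
    path = Path(path)
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=index))


@dataclass
class RunReport:
    outdir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def run_full_analysis(
    config: AnalysisConfig,
    infants=None,
    samples=None,
    profiles=None,
    make_figures: bool = True,
) -> RunReport:
    """Run every analysis stage and write the report bundle.

    The cohort can be passed in-memory (as produced by the synthetic
    generator) or loaded from the configured paths. Independent stages
    keep running when one fails; failures are collected in the manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("preemie_probiome")
    root.addHandler(handler)
    try:
        if profiles is None or infants is None or samples is None:
            infants, samples = read_metadata(config.infants, config.samples)
            profiles = read_profiles(config.profiles)
        reconcile(profiles, samples)
        cov = covariate_table(infants, samples)

        # --- variance grid -------------------------------------------------
        try:
            grid = variance_grid(
                profiles,
                infants,
                samples,
                covariates=config.covariates,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "permanova"),
                min_n=config.min_window_n,
                mode=config.permanova_mode,
            )
            write_table(grid, outdir / "variance_grid.tsv")
            report.tables["variance_grid"] = outdir / "variance_grid.tsv"
            if make_figures and len(grid):
                plot_variance_grid(grid, outdir / "variance_grid.png")
            mean_r2 = grid.groupby("covariate")["R2"].mean().sort_values(ascending=False)
            report.summary["top_covariate"] = str(mean_r2.index[0]) if len(mean_r2) else None
            report.summary["mean_r2"] = {k: float(v) for k, v in mean_r2.items()}
            gcells = grid[grid["covariate"] == "group"]
            report.summary["group_significant_cells"] = int(gcells["significant"].sum())
        except Exception as exc:
            logger.exception("variance grid stage failed")
            report.errors["variance_grid"] = str(exc)

        # --- restrict to samples during probiotic use ----------------------
        use_ids = [s.sample_id for s in samples if s.during_probiotic_use]

        # --- NMDS -----------------------------------------------------------
        try:
            if len(use_ids) < 3:
                raise ValueError("too few during-use samples for ordination")
            ord_ids = use_ids
            if len(ord_ids) > config.nmds_max_samples:
                # ordination cost is quadratic in n; subsample (seeded) for display
                rng = np.random.default_rng(stage_seed(config.seed, "nmds-subsample"))
                ord_ids = sorted(
                    rng.choice(ord_ids, size=config.nmds_max_samples, replace=False)
                )
                logger.info("NMDS subsampled to %d during-use samples", len(ord_ids))
            sub = profiles.subset(ord_ids)
            dm = distance_matrix(sub)
            ord_ = NMDS(
                n_components=config.nmds_dimensions,
                n_init=config.nmds_restarts,
                max_iter=config.nmds_max_iter,
                random_state=stage_seed(config.seed, "nmds"),
            ).fit(dm)
            coords = ord_.coordinates_frame()
            labels = cov.loc[ord_ids, "group"].to_numpy()
            coords["group"] = labels
            write_table(coords, outdir / "nmds_coordinates.tsv", index=True)
            report.tables["nmds"] = outdir / "nmds_coordinates.tsv"
            centroids = group_centroids(ord_.embedding_, labels)
            report.summary["nmds_stress"] = ord_.stress_
            report.summary["nmds_converged"] = ord_.converged_
            if make_figures:
                _plot_nmds(coords, centroids, ord_.stress_, outdir / "nmds.png")
        except Exception as exc:
            logger.exception("NMDS stage failed")
            report.errors["nmds"] = str(exc)

        # --- community typing ----------------------------------------------
        try:
            if len(use_ids) < config.typing_k:
                raise ValueError("too few during-use samples for typing")
            sub = profiles.subset(use_ids)
            model = fit_community_types(
                sub,
                k=config.typing_k,
                depth=config.typing_depth,
                seed=stage_seed(config.seed, "typing"),
                restarts=config.typing_restarts,
            )
            assignments = pd.Series(model.labels_, index=use_ids, name="type")
            ptypes = probiotic_associated_types(model)
            props = type_proportions_by_group(
                assignments, samples, infants, probiotic_types=ptypes
            )
            long = props.proportions.stack().rename("proportion").reset_index()
            long = long.merge(
                props.counts.stack().rename("count").reset_index(), on=["group", "type"]
            )
            write_table(long, outdir / "community_type_proportions.tsv")
            report.tables["community_types"] = outdir / "community_type_proportions.tsv"
            report.summary["probiotic_types"] = sorted(int(t) for t in ptypes)
            report.summary["probiotic_associated_proportion"] = {
                str(g): float(v) for g, v in props.probiotic_associated.items()
            }
        except Exception as exc:
            logger.exception("community typing stage failed")
            report.errors["community_types"] = str(exc)

        # --- engraftment ----------------------------------------------------
        try:
            eng = engraftment_table(profiles, infants, samples, stratum=config.engraftment_stratum)
            write_table(eng, outdir / "engraftment.tsv")
            report.tables["engraftment"] = outdir / "engraftment.tsv"
            comp = compare_groups(eng)
            summary = comp.table.copy()
            summary["responder_proportion"] = comp.responder_proportions
            summary["z_median"] = comp.z_medians
            summary["fisher_p"] = comp.fisher_p
            summary["ranksum_p"] = comp.ranksum_p
            write_table(summary.reset_index(), outdir / "engraftment_summary.tsv")
            report.tables["engraftment_summary"] = outdir / "engraftment_summary.tsv"
            report.summary["responder_proportions"] = {
                str(g): float(v) for g, v in comp.responder_proportions.items()
            }
            report.summary["fisher_p"] = comp.fisher_p
            report.summary["ranksum_p"] = comp.ranksum_p
        except Exception as exc:
            logger.exception("engraftment stage failed")
            report.errors["engraftment"] = str(exc)

        # --- Shannon mixed model --------------------------------------------
        try:
            windowed = [s.sample_id for s in samples if s.timepoint is not None]
            ht = shannon_table(profiles.subset(windowed), cov)
            mm = diversity_mixed_model(
                ht, seed=stage_seed(config.seed, "diversity")
            )
            mm_df = pd.DataFrame(
                [
                    {
                        "effect": mm.effect,
                        "p": mm.p_value,
                        "method": mm.method,
                        "n_infants": mm.n_infants,
                        "n_samples": mm.n_samples,
                    }
                ]
            )
            write_table(mm_df, outdir / "shannon_mixed_model.tsv")
            report.tables["shannon_model"] = outdir / "shannon_mixed_model.tsv"
            report.summary["shannon_group_p"] = mm.p_value
            report.summary["shannon_group_effect"] = mm.effect
        except Exception as exc:
            logger.exception("diversity stage failed")
            report.errors["shannon_model"] = str(exc)
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "tables": {k: str(v) for k, v in report.tables.items()},
        "errors": report.errors,
        "summary": _plain_json(report.summary),
    }
    _atomic_write(
        outdir / "manifest.json",
        lambda tmp: Path(tmp).write_text(json.dumps(manifest, indent=2, sort_keys=True)),
    )
    return report


def _plain_json(obj):
    if isinstance(obj, dict):
        return {k: _plain_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain_json(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _plot_nmds(coords: pd.DataFrame, centroids: pd.DataFrame, stress: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for g, sub in coords.groupby("group"):
        ax.scatter(sub["NMDS1"], sub["NMDS2"], s=12, alpha=0.5, label=str(g))
    for g, row in centroids.iterrows():
        ax.scatter(row[0], row[1], marker="X", s=180, edgecolor="black", zorder=5)
    ax.legend()
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"NMDS of profiles during probiotic use (stress = {stress:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
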