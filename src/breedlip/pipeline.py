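"""End-to-end workflow: simulate -> bin -> meta-class model -> confounder
filter -> pairwise grid -> unique signals -> annotation.

Replays the full breed-discrimination analysis on a synthetic cohort (or a
user-supplied matrix + metadata) and writes every stage output plus a
machine-readable manifest that links each artefact to the thresholds and
per-stage seeds used. Classification and ranking run on log2 intensities;
trees are invariant to the monotone transform but t-tests and direction
calls are not, so the log scale is the modelling scale throughout. The
filtered matrix is written on the raw intensity scale (a column subset of
the binned matrix).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import DEFAULT_RULES, bundled_formulas, ppm_match
from .classify import pc_lda, rf_bootstrap_classify
from .config import RunConfig, stage_seed
from .confound import filter_confounder
from .discover import pairwise_grid, unique_signals
from .matrix import FeatureMatrix, bin_mz, read_matrix, read_metadata, \
    validate_metadata
from .rank import assign_clusters, correlation_clusters, rank_features
from .synthetic import generate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "metaclass_labels"]


def metaclass_labels(
    meta: pd.DataFrame, group1: tuple[str, ...], exclude: tuple[str, ...] = (),
) -> np.ndarray:
    """Binary meta-class labels ('group1'/'group2'), None for excluded breeds."""
    out = np.empty(len(meta), dtype=object)
    for i, breed in enumerate(meta["breed"]):
        if breed in exclude:
            out[i] = None
        else:
            out[i] = "group1" if breed in group1 else "group2"
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    matrix: FeatureMatrix | None = None,
    meta: pd.DataFrame | None = None,
    matrix_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> dict:
    """Execute the full workflow; returns the manifest (also written to disk).

    With no input matrix, a synthetic cohort is generated from
    ``config.synthetic`` (stage seed overrides its ``seed``). Any stage
    failure propagates with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {},
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        files = {}
        for key, val in list(info.items()):
            if isinstance(val, Path):
                files[key] = {"path": val.name, "sha256": _sha256(val)}
                del info[key]
        manifest["stages"][stage] = {**info, "files": files}

    stage = "simulate"
    try:
        truth = None
        if matrix is None and matrix_path is not None:
            matrix = read_matrix(matrix_path)
            meta = read_metadata(meta_path)
        if matrix is None:
            syn = replace(config.synthetic, seed=stage_seed(config.seed, stage))
            manifest["stage_seeds"][stage] = syn.seed
            matrix, meta, truth = generate(syn)
            mpath, dpath, tpath = (outdir / "matrix.tsv", outdir / "meta.tsv",
                                   outdir / "truth.json")
            matrix.to_tsv(mpath)
            meta.to_csv(dpath, sep="\t", index=False)
            truth.to_json(tpath)
            record(stage, n_samples=matrix.n_samples,
                   n_features=matrix.n_features, matrix=mpath, meta=dpath,
                   truth=tpath)
        else:
            record(stage, skipped="user-supplied matrix",
                   n_samples=matrix.n_samples, n_features=matrix.n_features)
        meta = validate_metadata(matrix, meta).reset_index()

        stage = "bin"
        binned = bin_mz(matrix, config.bin_width)
        bpath = outdir / "binned.tsv"
        binned.to_tsv(bpath)
        record(stage, bin_width=config.bin_width, n_features=binned.n_features,
               binned=bpath)
        logm = binned.log2()

        stage = "metaclass"
        group1 = tuple(config.synthetic.group1)
        exclude = (config.synthetic.mixed_diet_breed,)
        labels = metaclass_labels(meta, group1, exclude)
        mask = np.array([l is not None for l in labels])
        sub = logm.subset_samples([s for s, m in zip(logm.sample_ids, mask) if m])
        mc_scheme = config.scheme(stage)
        manifest["stage_seeds"][stage] = mc_scheme.seed
        model = rf_bootstrap_classify(sub, labels[mask], mc_scheme)
        lda = pc_lda(logm, meta["breed"], config.var_kept)
        mc_path = outdir / "metaclass_model.json"
        mc_path.write_text(json.dumps({
            "model": model.to_dict(),
            "breed_pc_lda": {"tw": list(map(float, lda.tw)),
                             "pcs_retained": lda.pcs_retained},
        }, indent=1))
        df_path = outdir / "df_scores.tsv"
        pd.DataFrame(lda.df_scores[:, :2], index=logm.sample_ids,
                     columns=["DF1", "DF2"]).to_csv(df_path, sep="\t")
        record(stage, group1=list(group1), excluded=list(exclude),
               margin=model.margin, auc=model.auc, acc=model.acc,
               adequate=model.adequate, tw=list(map(float, lda.tw[:2])),
               report=mc_path, df_scores=df_path)

        stage = "rank"
        rk_scheme = config.scheme(stage)
        manifest["stage_seeds"][stage] = rk_scheme.seed
        ranked = rank_features(sub, labels[mask], rk_scheme,
                               classes=("group2", "group1"))
        top = [f.name for f in ranked if f.rfis > config.rfis_metaclass
               and f.q_value < config.q_threshold]
        clusters = correlation_clusters(logm, top, config.corr_threshold) \
            if len(top) >= 2 else []
        assign_clusters(ranked, clusters)
        rank_path = outdir / "metaclass_ranked.tsv"
        pd.DataFrame([vars(f) for f in ranked]).to_csv(rank_path, sep="\t",
                                                       index=False)
        record(stage, rfis_threshold=config.rfis_metaclass,
               q_threshold=config.q_threshold, n_explanatory=len(top),
               n_clusters=len(clusters), ranked=rank_path)

        stage = "filter"
        if config.filter_enabled:
            fl_scheme = config.scheme(stage)
            manifest["stage_seeds"][stage] = fl_scheme.seed
            logf, freport = filter_confounder(
                logm, labels, ranked, config.filter_schedule,
                config.corr_threshold, fl_scheme)
            filtered = binned.subset_features(logf.feature_names)
            fpath = outdir / "filtered.tsv"
            rpath = outdir / "filter_report.json"
            filtered.to_tsv(fpath)
            rpath.write_text(json.dumps(freport.to_dict(), indent=1))
            record(stage, collapsed=freport.collapsed,
                   final_cutoff=freport.final_cutoff,
                   n_removed=freport.n_before - freport.n_after,
                   filtered=fpath, report=rpath)
            grid_input = logf
        else:
            record(stage, skipped="filtering disabled")
            grid_input = logm

        stage = "grid"
        gd_scheme = config.scheme(stage)
        manifest["stage_seeds"][stage] = gd_scheme.seed
        grid = pairwise_grid(grid_input, meta["breed"], gd_scheme,
                             collect_rankings=True)
        gpath = outdir / "pairwise_grid.json"
        gpath.write_text(json.dumps(grid.to_dict(), indent=1))
        tpath = outdir / "pairwise_grid.tsv"
        pd.DataFrame([
            {"pair": f"{a} vs {b}", "margin": r.margin, "auc": r.auc,
             "acc": r.acc, "adequate": r.adequate}
            for (a, b), r in sorted(grid.reports.items(),
                                    key=lambda kv: -kv[1].margin)
        ]).to_csv(tpath, sep="\t", index=False)
        record(stage, n_pairs=len(grid.reports),
               adequate_count=grid.adequate_count, grid=gpath, table=tpath)

        stage = "unique"
        signals = unique_signals(
            grid, grid_input, meta["breed"], config.min_adequate,
            config.rfis_pairwise, config.p_threshold, gd_scheme)
        upath = outdir / "unique_signals.tsv"
        pd.DataFrame([vars(s) for s in signals]).to_csv(upath, sep="\t",
                                                        index=False)
        record(stage, min_adequate=config.min_adequate,
               rfis_threshold=config.rfis_pairwise,
               p_threshold=config.p_threshold,
               n_signals=len(signals),
               per_breed={b: sum(s.breed == b for s in signals)
                          for b in grid.breeds},
               signals=upath)

        stage = "annotate"
        formulas = bundled_formulas()
        cands = [(f, rule, name) for f, name in formulas
                 for rule in DEFAULT_RULES.values() if rule.charge > 0]
        rows = []
        feats = grid_input.features
        for s in signals:
            mz_obs = float(feats.loc[s.name].get("mz_weighted", s.mz))
            for ann in ppm_match(mz_obs, cands, config.ppm_window):
                rows.append({
                    "breed": s.breed, "feature": s.name, "observed_mz": mz_obs,
                    "rule": ann.rule.name, "formula": str(ann.formula),
                    "theoretical_mz": round(ann.theoretical_mz, 6),
                    "ppm_error": round(ann.ppm_error, 3),
                    "putative_name": ann.putative_name,
                })
        apath = outdir / "annotations.tsv"
        pd.DataFrame(rows).to_csv(apath, sep="\t", index=False)
        record(stage, ppm_window=config.ppm_window, n_annotations=len(rows),
               annotations=apath)
    except Exception as exc:  # attach the failing stage for the caller
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d stages -> %s",
                len(manifest["stages"]), outdir)
    return manifest
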