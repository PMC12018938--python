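"""Pipeline orchestration: simulate -> normalize -> compare -> profile ->
network -> (optionally) classify, persisting every intermediate table and a
run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import TwoStageClassifier
from .compare import MarkerComparison
from .config import RunConfig
from .network import build_restricted_network, estimate_unrestricted_size, \
    spearman_matrix, subsample_comparison, _upper_vec
from .preprocess import normalize_markers
from .profile import DiProPerm, group_mean_quantiles, quantile_ranks
from .simulate import generate_cohort

log = logging.getLogger("immunoprofile")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "simulation": config.simulation.to_dict(),
            "covariates": config.covariates,
            "thresholds": [config.corr_deselect_threshold, config.fdr,
                           config.rho_min, config.sig_p, config.sig_q],
            "resampling": [config.n_subsamples, config.n_permutations,
                           config.rfe_repeats, config.backward_repeats,
                           config.k_folds],
            "seed": config.seed,
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        rng = np.random.default_rng(config.seed)
        seeds = {k: int(rng.integers(2**31 - 1))
                 for k in ("impute", "diproperm", "subsample", "classify")}
        cohort = generate_cohort(config.simulation)
        cohort.to_csv(out / "cohort")
        manifest["stages"][stage] = {
            "n_participants": cohort.n_participants,
            "n_markers": cohort.n_markers,
        }

        stage = "preprocess"
        norm = normalize_markers(
            cohort, config.corr_deselect_threshold, config.impute_iterations,
            seeds["impute"],
        )
        norm.values.to_csv(out / "normalized.csv")
        report = {
            "dropped": [list(d) for d in norm.dropped],
            "n_imputed_cells": int(norm.imputation_mask.to_numpy().sum()),
            "beta_days": norm.residualization.slopes.to_dict(),
        }
        (out / "preprocessing_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"][stage] = {
            "markers_dropped": len(norm.dropped),
            "markers_retained": len(norm.marker_ids),
        }

        stage = "compare"
        comp = MarkerComparison(cohort, config.covariates).fit()
        comp.summary().to_csv(out / "marker_comparisons.csv", index=False)
        manifest["stages"][stage] = {
            "n_rows": int(len(comp.frame)),
            "n_significant": int(comp.frame["significant"].sum())
            if "significant" in comp.frame else 0,
        }

        stage = "profile"
        prof = quantile_ranks(norm)
        meta = cohort.metadata.loc[norm.values.index]
        polar = group_mean_quantiles(prof, meta["hiv_status"], meta["severity"])
        polar.to_csv(out / "polar_table.csv", index=False)
        dpp = DiProPerm(norm, meta["hiv_status"]).fit(
            config.n_permutations, seeds["diproperm"]
        )
        (out / "diproperm.json").write_text(
            json.dumps({"statistic": dpp.statistic, "p_value": dpp.pvalue,
                        "B": dpp.n_permutations}, indent=2)
        )
        manifest["stages"][stage] = {"diproperm_p": dpp.pvalue}

        stage = "network"
        net_stats = {}
        for group in ("PWOH", "PLWH"):
            vals = norm.values[meta["hiv_status"] == group]
            rho, p = spearman_matrix(vals)
            net = build_restricted_network(rho, p, config.fdr, config.rho_min)
            net.edge_frame().to_csv(out / f"network_{group}_edges.csv", index=False)
            net.to_graphml(out / f"network_{group}.graphml")
            pd.DataFrame(
                [{"marker_id": mk, "cluster": ci}
                 for ci, cl in enumerate(net.clusters) for mk in sorted(cl)]
            ).to_csv(out / f"network_{group}_clusters.csv", index=False)
            pvec = _upper_vec(p)
            pi0, size, avg = estimate_unrestricted_size(
                pvec[~np.isnan(pvec)], len(net.markers)
            )
            net_stats[group] = {
                "restricted_size": net.restricted_size,
                "pi0": pi0,
                "unrestricted_size": size,
                "average_degree": avg,
            }
        sub = subsample_comparison(
            norm.values[meta["hiv_status"] == "PWOH"],
            norm.values[meta["hiv_status"] == "PLWH"],
            "restricted_size", config.n_subsamples, seeds["subsample"],
            config.fdr, config.rho_min,
        )
        (out / "network_summary.json").write_text(
            json.dumps({"per_group": net_stats,
                        "subsampling": sub.summary().to_dict()}, indent=2,
                       default=float)
        )
        manifest["stages"][stage] = {
            "restricted_size_pwoh": net_stats["PWOH"]["restricted_size"],
            "restricted_size_plwh": net_stats["PLWH"]["restricted_size"],
            "prob_pwoh_gt_plwh": sub.prob_pwoh_gt_plwh,
            "n_subsamples_excluded": sub.n_excluded,
        }

        if config.run_classifier:
            stage = "classify"
            labels = (meta["hiv_status"] == "PLWH").astype(int)
            clf = TwoStageClassifier(
                norm, labels, repeats=config.rfe_repeats,
                k_folds=config.k_folds, threshold=config.rfe_threshold,
                backward_repeats=config.backward_repeats,
                seed=seeds["classify"],
            )
            report = clf.fit()
            report.roc.to_csv(out / "roc.csv", index=False)
            (out / "classifier_report.json").write_text(json.dumps(
                {
                    "selected_stage1": list(map(str, report.selected_stage1)),
                    "selected": list(map(str, report.selected)),
                    "cv_auc": report.cv_auc,
                    "ci": list(report.ci),
                    "frequencies": report.frequency_table.frequencies.to_dict(),
                },
                indent=2,
            ))
            manifest["stages"][stage] = {
                "n_selected": len(report.selected),
                "cv_auc": report.cv_auc,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=float))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    log.info("pipeline complete: %s", out)
    return manifest
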