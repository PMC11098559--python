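"""End-to-end pipeline stages chaining simulation, fitting and statistics.

Each ``cmd_*`` function is one CLI stage: it reads/writes CSV + JSON in a run
directory, validates its inputs, and records a manifest so seeded runs are
reproducible file-for-file.  The ``report`` stage assembles group means,
signed percent differences versus the baseline condition, temperature
ratios and one-way ANOVA results into a single JSON analysis summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import energetics, group_stats, mant_atp, omics, synthetic, xray
from .config import RunConfig, write_manifest

logger = logging.getLogger(__name__)

TRACE_COLUMNS = [
    "fiber_id", "animal_id", "condition", "fiber_type", "temperature_C",
    "time_s", "raw_fluor", "background_fluor",
]


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def cmd_simulate(config: RunConfig, outdir) -> dict:
    """Generate a synthetic study (traces + truth) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design.build(config.seed)
    effects = config.effects.build()
    traces, truth = synthetic.simulate_study(design, effects)
    traces_path = outdir / "traces.csv"
    truth_path = outdir / "truth.csv"
    traces.to_csv(traces_path, index=False)
    truth.to_csv(truth_path, index=False)
    write_manifest(outdir, "simulate", config, outputs=[traces_path, truth_path])
    logger.info("simulated %d fibers", truth.shape[0])
    return {"traces": traces_path, "truth": truth_path}


def cmd_fit(config: RunConfig, traces_path, outdir) -> dict:
    """Fit every fiber trace and write fits + a QC report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = pd.read_csv(traces_path)
    _require_columns(traces, TRACE_COLUMNS, "trace table")
    fits = mant_atp.fit_traces(
        traces,
        unconstrained=config.fit.unconstrained,
        rel_tol=config.fit.rel_tol,
        max_nfev=config.fit.max_nfev,
    )
    thresholds = mant_atp.QCThresholds(
        require_converged=config.qc.require_converged,
        max_rel_se_t1=config.qc.max_rel_se_t1,
        max_rel_se_t2=config.qc.max_rel_se_t2,
        reject_amplitude_sum_gt_100=config.qc.reject_amplitude_sum_gt_100,
        reject_lifetimes_close=config.qc.reject_lifetimes_close,
    )
    accepted, rejected = mant_atp.qc_filter(fits, thresholds)
    fits_path = outdir / "fits.csv"
    accepted.to_csv(fits_path, index=False)
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(
        json.dumps(
            {
                "n_fibers": int(len(fits)),
                "n_accepted": int(len(accepted)),
                "n_rejected": int(len(rejected)),
                "rejections": rejected[["fiber_id", "reject_reason"]].to_dict("records"),
            },
            indent=2,
        )
    )
    write_manifest(outdir, "fit", config, inputs=[traces_path],
                   outputs=[fits_path, qc_path])
    return {"fits": fits_path, "qc_report": qc_path}


def cmd_energetics(config: RunConfig, fits_path, outdir) -> dict:
    """Derive fiber records, animal summaries, temperature ratios and tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fits = pd.read_csv(fits_path)
    _require_columns(
        fits,
        ["fiber_id", "animal_id", "condition", "fiber_type", "temperature_C",
         "p1_pct", "t1_s", "p2_pct", "t2_s", "converged"],
        "fit table",
    )
    records = energetics.add_atp_consumption(
        fits, config.energetics.head_concentration_uM
    )
    summaries = group_stats.aggregate_by_animal(records)
    records_path = outdir / "fiber_records.csv"
    summary_path = outdir / "animal_summary.csv"
    records.to_csv(records_path, index=False)
    summaries.to_csv(summary_path, index=False)

    outputs = [records_path, summary_path]
    ratio_path = None
    temps = sorted(records["temperature_C"].unique())
    if {config.energetics.warm_C, config.energetics.cold_C} <= set(temps):
        ratios = energetics.temperature_ratios(
            records, config.energetics.warm_C, config.energetics.cold_C
        )
        ratio_path = outdir / "temperature_ratios.csv"
        ratios.to_csv(ratio_path, index=False)
        outputs.append(ratio_path)

    report = analysis_report(records, summaries, config.energetics.baseline_condition)
    report_path = outdir / "energetics_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs.append(report_path)
    write_manifest(outdir, "energetics", config, inputs=[fits_path], outputs=outputs)
    out = {"fiber_records": records_path, "animal_summary": summary_path,
           "report": report_path}
    if ratio_path:
        out["temperature_ratios"] = ratio_path
    return out


def analysis_report(records: pd.DataFrame, summaries: pd.DataFrame,
                    baseline_condition: str) -> dict:
    """Group means on animal level, percent differences vs baseline, ANOVA.

    One block per fiber type x temperature x metric.  No multiplicity
    correction is applied across these one-way ANOVAs (stated in the output).
    """
    metrics = [m for m in ("p1_pct", "p2_pct", "t1_s", "t2_s",
                           "atp_consumption_uM_per_min")
               if f"{m}_mean" in summaries.columns]
    report = {
        "baseline_condition": baseline_condition,
        "note": "one-way ANOVA on animal means per stratum; "
                "no correction across strata/metrics",
        "strata": [],
    }
    for (ftype, temp), block in summaries.groupby(["fiber_type", "temperature_C"]):
        conditions = sorted(block["condition"].unique())
        if baseline_condition in conditions:
            conditions = [baseline_condition] + [
                c for c in conditions if c != baseline_condition
            ]
        stratum = {"fiber_type": ftype, "temperature_C": float(temp), "metrics": {}}
        for metric in metrics:
            col = f"{metric}_mean"
            by_cond = {
                c: block.loc[block["condition"] == c, col].to_numpy(float)
                for c in conditions
            }
            entry = {
                "group_means": {c: float(v.mean()) for c, v in by_cond.items()},
                "n_animals": {c: int(v.size) for c, v in by_cond.items()},
            }
            base = by_cond.get(baseline_condition)
            if base is not None and base.size and base.mean() != 0:
                entry["percent_difference_vs_baseline"] = {
                    c: energetics.percent_difference(base.mean(), v.mean())
                    for c, v in by_cond.items()
                    if c != baseline_condition
                }
            usable = [v for v in by_cond.values() if v.size >= 2]
            if len(usable) >= 2:
                t = group_stats.one_way_anova(usable)
                entry["one_way_anova"] = {
                    "F": t.statistic, "df": list(t.df),
                    "p_value": t.p_value, "stars": t.stars,
                }
            stratum["metrics"][metric] = entry
        report["strata"].append(stratum)
    return report


def cmd_xray(config: RunConfig, profiles_path, outdir,
             targets=None, equatorial_targets=None) -> dict:
    """Measure named reflections on every profile in a long-format CSV.

    The CSV needs columns bundle_id, axis, radius_mm, intensity (condition
    optional).  Meridional profiles are measured at the M3/M6 spacings,
    equatorial profiles at the 1,0/1,1 lattice spacings (``*_targets``
    override the expected d-spacings in nm).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = pd.read_csv(profiles_path)
    _require_columns(profiles, ["bundle_id", "axis", "radius_mm", "intensity"],
                     "profile table")
    geometry = config.geometry.build()
    rows = []
    for (bundle, axis), grp in profiles.groupby(["bundle_id", "axis"]):
        grp = grp.sort_values("radius_mm")
        profile = xray.DiffractionProfile(
            radius_mm=grp["radius_mm"].to_numpy(float),
            intensity=grp["intensity"].to_numpy(float),
            axis=axis,
            bundle_id=str(bundle),
            condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
        )
        if axis == "meridional":
            wanted = targets or xray.DEFAULT_MERIDIONAL_TARGETS
        else:
            if equatorial_targets is None:
                raise ValueError(
                    "equatorial profiles need explicit expected spacings "
                    "(lattice-dependent); pass equatorial_targets"
                )
            wanted = equatorial_targets
        measures = xray.measure_reflections(profile, wanted, geometry)
        for name, m in measures.items():
            rows.append({
                "bundle_id": bundle, "axis": axis, "reflection": name,
                "condition": profile.condition,
                "center_mm": m.center_mm, "width_mm": m.width_mm,
                "intensity_au": m.intensity, "spacing_nm": m.spacing_nm,
                "rss": m.rss,
            })
        if axis == "equatorial" and {"1,0", "1,1"} <= set(measures):
            rows.append({
                "bundle_id": bundle, "axis": axis, "reflection": "I11/I10",
                "condition": profile.condition,
                "center_mm": np.nan, "width_mm": np.nan,
                "intensity_au": xray.equatorial_ratio(measures["1,0"], measures["1,1"]),
                "spacing_nm": np.nan, "rss": np.nan,
            })
    out = pd.DataFrame(rows)
    path = Path(outdir) / "reflections.csv"
    out.to_csv(path, index=False)
    write_manifest(outdir, "xray", config, inputs=[profiles_path], outputs=[path])
    return {"reflections": path}


def cmd_omics(config: RunConfig, matrix_path, annotation_path, outdir,
              group_a=None, group_b=None) -> dict:
    """Preprocess a matrix and run DE, PTM z-scores and PCA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = pd.read_csv(matrix_path, index_col=0)
    annot = pd.read_csv(annotation_path)
    _require_columns(annot, ["sample", "group"], "sample annotation")
    groups = annot.set_index("sample")["group"]

    processed = omics.preprocess(
        matrix, groups,
        min_valid_per_group=config.omics.min_valid_per_group,
        already_log2=config.omics.already_log2,
        seed=config.seed,
    )
    levels = list(dict.fromkeys(groups))
    group_a = group_a or levels[0]
    group_b = group_b or levels[-1]
    de = omics.differential_expression(
        processed, groups, group_a, group_b,
        equal_var=config.omics.equal_var,
        fc_threshold=config.omics.fc_threshold,
        fdr_threshold=config.omics.fdr_threshold,
    )
    de["neg_log10_fdr"] = -np.log10(np.clip(de["fdr"], np.finfo(float).tiny, None))
    z, z_summary = omics.ptm_zscores(processed, groups)
    n_pc = min(5, len(processed.columns) - 1)
    scores, explained = omics.pca_samples(processed, n_components=n_pc)
    scores["group"] = groups.reindex(scores.index)

    de_path = outdir / "de_results.csv"
    z_path = outdir / "zscores.csv"
    zsum_path = outdir / "zscore_summary.csv"
    pca_path = outdir / "pca_scores.csv"
    de.to_csv(de_path)
    z.to_csv(z_path)
    z_summary.to_csv(zsum_path, index=False)
    scores.to_csv(pca_path)
    meta = {
        "comparison": f"{group_b} vs {group_a}",
        "n_features_tested": int(len(de)),
        "n_significant": int(de["significant"].sum()),
        "pca_explained_pct": [float(v) for v in explained],
    }
    meta_path = outdir / "omics_report.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    write_manifest(outdir, "omics", config,
                   inputs=[matrix_path, annotation_path],
                   outputs=[de_path, z_path, zsum_path, pca_path, meta_path])
    return {"de": de_path, "zscores": z_path, "zscore_summary": zsum_path,
            "pca": pca_path, "report": meta_path}


def cmd_report(outdir) -> dict:
    """Merge per-stage JSON reports in ``outdir`` into report.json + summary."""
    outdir = Path(outdir)
    merged = {}
    for name in ("qc_report", "energetics_report", "omics_report"):
        path = outdir / f"{name}.json"
        if path.exists():
            merged[name] = json.loads(path.read_text())
    if not merged:
        raise FileNotFoundError(f"no stage reports found under {outdir}")
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(merged, indent=2, sort_keys=True))

    lines = ["Myosin metabolic-state analysis summary", "=" * 40]
    if "qc_report" in merged:
        qc = merged["qc_report"]
        lines.append(
            f"Fibers: {qc['n_fibers']} fit, {qc['n_accepted']} accepted, "
            f"{qc['n_rejected']} rejected by QC"
        )
    for stratum in merged.get("energetics_report", {}).get("strata", []):
        lines.append(
            f"\nType {stratum['fiber_type']} fibers at "
            f"{stratum['temperature_C']:g} C:"
        )
        for metric, entry in stratum["metrics"].items():
            means = ", ".join(
                f"{c}={v:.3g}" for c, v in entry["group_means"].items()
            )
            line = f"  {metric}: {means}"
            if "percent_difference_vs_baseline" in entry:
                diffs = ", ".join(
                    f"{c} {d:+.1f}%"
                    for c, d in entry["percent_difference_vs_baseline"].items()
                )
                line += f" | vs baseline: {diffs}"
            if "one_way_anova" in entry:
                a = entry["one_way_anova"]
                line += f" | ANOVA p={a['p_value']:.3g} {a['stars']}"
            lines.append(line)
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    return {"report": report_path, "summary": summary_path}
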