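"""End-to-end orchestration: simulate/load -> dual regression -> ROI discovery
-> classifier grid -> network selection -> biomarker evaluation -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .classify import run_grid
from .cohort import (
    ICNTemplateSet,
    SimulationConfig,
    SubjectRecord,
    generate_scans,
    make_template_set,
    MHE,
)
from .dualreg import analysis_mask, dual_regress
from .gamma import GammaParams, GammaModel, fit_gamma, roi_volume
from .io import (
    GridMismatchError,
    RunConfig,
    load_scan,
    load_subject_table,
    load_templates,
    save_subject_table,
    save_templates,
)
from .selection import (
    best_thresholds,
    factorial_anova,
    pairwise_classifier_tests,
    select_representative,
    stability_probability,
)

__all__ = ["load_inputs", "compute_zmaps", "run_pipeline"]

log = logging.getLogger("icnmhe")


def load_inputs(
    cfg: RunConfig,
) -> tuple[ICNTemplateSet, dict[str, Path], list[SubjectRecord]]:
    """Load and validate templates, scan paths and the subject table.

    Scans are returned as paths (loaded lazily, one subject at a time); grid
    agreement of each scan with the templates is checked during
    :func:`compute_zmaps`.
    """
    if not (cfg.templates_dir and cfg.scans_dir and cfg.subject_table):
        raise ValueError("templates_dir, scans_dir and subject_table are all required")
    templates = load_templates(cfg.templates_dir)
    records = load_subject_table(cfg.subject_table)
    scans_dir = Path(cfg.scans_dir)
    scan_paths: dict[str, Path] = {}
    missing = []
    for r in records:
        p = scans_dir / f"{r.subject_id}.nii.gz"
        if not p.exists():
            missing.append(r.subject_id)
        scan_paths[r.subject_id] = p
    if missing:
        raise FileNotFoundError(f"missing scans for subjects: {missing}")
    return templates, scan_paths, records


def compute_zmaps(
    templates: ICNTemplateSet,
    scan_iter,
    *,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Dual-regress every subject; returns {icn: (n, X, Y, Z) z stack}.

    ``scan_iter`` yields (subject_id, Scan4D) pairs; scans are processed one at
    a time so full cohorts fit in memory.
    """
    if mask is None:
        mask = analysis_mask(templates)
    per_icn: list[list[np.ndarray]] = [[] for _ in templates.names]
    subject_ids = []
    for subject_id, scan in scan_iter:
        if scan.grid_shape != templates.grid_shape:
            raise GridMismatchError(
                f"scan {subject_id} grid {scan.grid_shape} != template grid "
                f"{templates.grid_shape}"
            )
        maps = dual_regress(scan, templates, subject_id=subject_id, mask=mask)
        for k in range(templates.n_templates):
            per_icn[k].append(maps.z[k].astype(np.float32))
        subject_ids.append(subject_id)
    zmaps = {
        name: np.stack(stack) for name, stack in zip(templates.names, per_icn)
    }
    return zmaps, subject_ids


def _evaluate_biomarkers(
    cfg: RunConfig,
    zmaps: dict[str, np.ndarray],
    records: list[SubjectRecord],
    labels: np.ndarray,
    grid: pd.DataFrame,
    selected: list[str],
    params: GammaParams,
    mask: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GammaModel]]:
    """Group-difference and partial-correlation tables for the selected
    networks at their best thresholds (leading ROI per network)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    groups = df["group"].to_numpy()
    cov_cols = []
    for c in cfg.covariates:
        col = df[c]
        cov_cols.append((col == "M").astype(float) if c == "gender" else col.astype(float))
    cov = np.column_stack(cov_cols) if cov_cols else None

    diff_rows, corr_rows = [], []
    models: dict[str, GammaModel] = {}
    clinical = ["tmt_a", "tmt_b", "dst", "bdt", "child_pugh"]
    for icn in selected:
        thrs, _ = best_thresholds(grid, icn)
        thr = thrs[0]
        maps = zmaps[icn] > thr
        model = fit_gamma(
            maps, labels, params, mask=mask, icn=icn, threshold=thr
        )
        models[icn] = model
        if model.n_rois == 0:
            log.warning("no validated ROI for selected network %s at z>%s", icn, thr)
            continue
        roi = roi_volume(model.rois[0], maps.shape[1:])
        pat = bm.integration_patterns(
            zmaps[icn], roi, thr, subject_ids=df["subject_id"].tolist(), icn=icn
        )
        for metric in ("n_overlap", "mean_fc"):
            vals = pat[metric].to_numpy(dtype=float)
            res = bm.group_difference_tests(vals, groups)
            diff_rows.append(
                {
                    "icn": icn,
                    "threshold": thr,
                    "pattern": metric,
                    "mean_mhe": vals[groups == MHE].mean(),
                    "mean_nmhe": vals[groups != MHE].mean(),
                    "t": res.statistic,
                    "p": res.p,
                }
            )
            for score in clinical:
                pc = bm.partial_correlation(vals, df[score].to_numpy(float), cov)
                corr_rows.append(
                    {
                        "icn": icn,
                        "pattern": metric,
                        "clinical": score,
                        "r": pc.statistic,
                        "p": pc.p,
                    }
                )
    diff = pd.DataFrame(diff_rows)
    corr = pd.DataFrame(corr_rows)
    if not corr.empty:
        corr["significant"] = bm.bonferroni_flags(corr["p"], cfg.bonferroni_m)
    return diff, corr, models


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write stage artifacts plus a JSON+text report.

    With ``cfg.templates_dir`` unset, a synthetic cohort is generated from
    ``cfg.simulate`` (and written alongside the outputs); otherwise templates,
    scans and the subject table are loaded from the configured paths.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = GammaParams(**{"seed": cfg.seed, **cfg.gamma})

    if cfg.templates_dir is None:
        sim = SimulationConfig(**{"seed": cfg.seed, **cfg.simulate})
        log.info("simulating cohort: %d MHE / %d NMHE", sim.n_mhe, sim.n_nmhe)
        templates = make_template_set(sim.n_templates, sim.grid_shape, sim.seed)
        save_templates(templates, out / "templates")
        records = []

        def scan_iter():
            for record, scan in generate_scans(sim, templates):
                records.append(record)
                yield record.subject_id, scan

        mask = analysis_mask(templates)
        zmaps, subject_ids = compute_zmaps(templates, scan_iter(), mask=mask)
        save_subject_table(records, out / "subjects.tsv")
    else:
        templates, scan_paths, records = load_inputs(cfg)
        mask = analysis_mask(templates)
        zmaps, subject_ids = compute_zmaps(
            templates,
            ((sid, load_scan(p)) for sid, p in scan_paths.items()),
            mask=mask,
        )
    labels = np.array([r.group == MHE for r in records])

    log.info("running %d x %d x %d grid", len(zmaps), len(cfg.thresholds), len(cfg.classifiers))
    grid = run_grid(
        zmaps,
        labels,
        tuple(cfg.thresholds),
        params,
        mask=mask,
        k_folds=cfg.cv_folds,
        seed=cfg.seed,
        classifiers=tuple(cfg.classifiers),
    )
    grid.to_csv(out / "performance_grid.tsv", sep="\t", index=False)

    pairwise = pairwise_classifier_tests(grid)
    pairwise.to_csv(out / "pairwise_classifier_tests.tsv", sep="\t", index=False)
    anova = {m: factorial_anova(grid, m) for m in ("acc", "sen", "spe")}
    for m, tab in anova.items():
        tab.to_csv(out / f"anova_{m}.tsv", sep="\t", index=False)
    stability = stability_probability(grid, cfg.acc_cut)
    stability.to_csv(out / "stability.tsv", sep="\t", index=False)
    selected = select_representative(stability, cfg.p_cut)

    diff, corr, models = _evaluate_biomarkers(
        cfg, zmaps, records, labels, grid, selected, params, mask
    )
    diff.to_csv(out / "group_differences.tsv", sep="\t", index=False)
    corr.to_csv(out / "partial_correlations.tsv", sep="\t", index=False)
    (out / "models").mkdir(exist_ok=True)
    for icn, model in models.items():
        (out / "models" / f"{icn}_gamma.json").write_text(model.to_json())
    demo = bm.demographics_table(records)
    demo.to_csv(out / "demographics.tsv", sep="\t", index=False)

    report = {
        "n_subjects": len(records),
        "n_mhe": int(labels.sum()),
        "n_nmhe": int((~labels).sum()),
        "networks": list(zmaps),
        "thresholds": [float(t) for t in cfg.thresholds],
        "classifiers": list(cfg.classifiers),
        "seed": cfg.seed,
        "gamma_params": params.__dict__,
        "selected_icns": selected,
        "stability": stability.to_dict("records"),
        "best_thresholds": {
            icn: {
                "thresholds": best_thresholds(grid, icn)[0],
                "metrics": best_thresholds(grid, icn)[1],
            }
            for icn in selected
        },
        "group_differences": diff.to_dict("records"),
        "partial_correlations": corr.to_dict("records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    lines = [
        f"Subjects: {report['n_mhe']} MHE / {report['n_nmhe']} NMHE",
        f"Selected networks (stability >= {cfg.p_cut}% of cells with Acc > {cfg.acc_cut}%): "
        + (", ".join(selected) if selected else "none"),
    ]
    for icn in selected:
        bt = report["best_thresholds"][icn]
        m = bt["metrics"]
        lines.append(
            f"  {icn}: best thresholds {bt['thresholds']} "
            f"(Acc {m['acc']:.1f}%, Sen {m['sen']:.1f}%, Spe {m['spe']:.1f}%)"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
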