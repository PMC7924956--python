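"""End-to-end orchestration: sessions in, CSV results + manifest out.

Each task type triggers the analyses that apply to it; per-session results
are written as CSV, cross-session averages are computed where the analyses
average over recording days, and a run manifest records the config, derived
seeds and output hashes so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoding import average_confusions, loo_confusion
from .dynamics import (
    crossnobis_timecourse,
    default_onsets,
    dynamic_classification,
    dynamic_format_correlation,
    unit_dynamic_pca,
)
from .io import AnalysisConfig, read_session
from .latency import bootstrap_latency, population_pc1
from .preprocess import bin_spikes, select_units, window_rates
from .receptive_field import field_count_matrix, fit_rf_gaussian
from .session import ConditionLabel
from .similarity import cv_condition_correlation
from .tuning import anova_discrimination, fdr_correct, fit_linear_tuning, population_summary

__all__ = ["run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _save_matrix(path: Path, mat: np.ndarray, labels) -> None:
    pd.DataFrame(mat, index=[str(c) for c in labels], columns=[str(c) for c in labels]).to_csv(path)


def _stim_and_baseline(session, config: AnalysisConfig):
    stim = window_rates(session, "go_onset", *config.stim_window)
    base = window_rates(session, "cue_onset", *config.baseline_window)
    return stim, base


def _analyze_touch_map(session, config, out: Path, seed: int):
    stim, base = _stim_and_baseline(session, config)
    tuning = fit_linear_tuning(stim, base, q=config.fdr_q)
    summary = population_summary(
        tuning, alpha=config.fdr_q, n_boot=config.n_boot, seed=derive_seed(seed, "boot")
    )
    rows = []
    for res in tuning:
        for j, cond in enumerate(res.conditions):
            rows.append(
                {
                    "unit_id": res.unit_id,
                    "condition": str(cond),
                    "beta": res.beta[j],
                    "t": res.t[j],
                    "p": res.p[j],
                    "responsive": res.responsive[j],
                    "tuned": res.tuned,
                }
            )
    pd.DataFrame(rows).to_csv(out / "tuning.csv", index=False)

    confusion = loo_confusion(stim)
    _save_matrix(out / "confusion.csv", confusion.accuracy, confusion.classes)
    corr = cv_condition_correlation(
        stim, n_splits=config.n_corr_splits, seed=derive_seed(seed, "corr")
    )
    _save_matrix(out / "correlation.csv", corr.mean_corr, corr.conditions)
    counts = field_count_matrix(tuning)
    pd.DataFrame(counts.counts).to_csv(out / "field_counts.csv")
    return {
        "n_units": session.n_units,
        "n_responsive": summary.n_responsive,
        "n_tuned": summary.n_tuned,
        "chi2": summary.chi2,
        "decode_accuracy": confusion.overall_accuracy,
        "_confusion": confusion,
    }


def _analyze_latency(session, config, out: Path, seed: int):
    binned = bin_spikes(session, "contact_time", -0.150, 0.252, 0.002)
    result = {}
    samples = {}
    for side in ("left", "right"):
        conds = [ConditionLabel(p, side, "actual") for p in ("cheek", "shoulder")]
        ts = population_pc1(binned, conds)
        est = bootstrap_latency(ts, n_boot=config.n_boot, seed=derive_seed(seed, f"lat-{side}"))
        result[f"latency_{side}_ms"] = 1000 * est.latency
        result[f"iqr_{side}_ms"] = [1000 * est.iqr[0], 1000 * est.iqr[1]]
        samples[side] = est.bootstrap_samples
    from .latency import latency_side_test

    result["side_diff_p"] = latency_side_test(
        samples["left"], samples["right"], n_perm=config.n_perm, seed=derive_seed(seed, "side")
    )
    with open(out / "latency.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result


def _analyze_rf_gradient(session, config, out: Path, seed: int):
    stim, _ = _stim_and_baseline(session, config)
    sites = [ConditionLabel(f"site{k}", "right", "actual") for k in range(1, 10)]
    sub = stim.subset_conditions(sites)
    _, p = anova_discrimination(sub)
    selective, _ = fdr_correct(p, config.fdr_q)
    profiles = np.stack([sub.rates[:, sub.condition_trials(c)].mean(axis=1) for c in sites], axis=1)
    preferred = np.argmax(profiles, axis=1)
    rows = []
    for group in range(9):
        members = np.flatnonzero(selective & (preferred == group))
        if members.size == 0:
            continue
        mean_profile = profiles[members].mean(axis=0)
        rf = fit_rf_gaussian(mean_profile, group)
        rows.append(
            {
                "preferred_site": group + 1,
                "n_units": members.size,
                "sigma_cm": rf.sigma,
                "fwhm_cm": rf.fwhm,
                "amplitude_hz": rf.amplitude,
                "offset_hz": rf.offset,
                "flagged": rf.flagged,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "rf_gaussian.csv", index=False)
    ok = df[~df["flagged"]] if len(df) else df
    return {
        "n_selective": int(selective.sum()),
        "median_fwhm_cm": float(ok["fwhm_cm"].median()) if len(ok) else float("nan"),
    }


def _analyze_imagery(session, config, out: Path, seed: int):
    stim, _ = _stim_and_baseline(session, config)
    confusion = loo_confusion(stim)
    _save_matrix(out / "confusion.csv", confusion.accuracy, confusion.classes)
    corr = cv_condition_correlation(
        stim, n_splits=config.n_corr_splits, seed=derive_seed(seed, "corr")
    )
    _save_matrix(out / "correlation.csv", corr.mean_corr, corr.conditions)

    task_go = session.trials[0].events["go_onset"] - session.trials[0].events["cue_onset"]
    stim_end = task_go + 3.0
    # 50 ms base bins so the 100 ms window steps and the 0.25-0.75 s
    # crossnobis reference all fall on bin edges
    binned = bin_spikes(session, "cue_onset", -0.7, stim_end + 0.5, 0.05)
    imag_conds = [ConditionLabel(p, "right", "imagery") for p in ("cheek", "shoulder", "hand")]
    onsets = default_onsets(-0.7, stim_end, config.dyn_step)
    dyn = dynamic_classification(
        binned, imag_conds, window=config.dyn_window, step=config.dyn_step, onsets=onsets
    )
    pd.DataFrame(dyn.accuracy, index=onsets, columns=onsets).to_csv(out / "dyn_class.csv")
    xnobis = crossnobis_timecourse(
        binned,
        imag_conds,
        window=config.dyn_window,
        step=config.dyn_step,
        onsets=onsets,
        seed=derive_seed(seed, "xnobis"),
    )
    pd.DataFrame({"onset": onsets, "distance": xnobis.distance}).to_csv(
        out / "crossnobis.csv", index=False
    )
    per_unit = dynamic_classification(
        binned,
        imag_conds,
        window=config.dyn_window,
        step=config.dyn_step,
        onsets=onsets,
        scope="single_unit",
    )
    pca = unit_dynamic_pca(per_unit)
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.variance_explained) + 1),
            "variance_explained": pca.variance_explained,
        }
    ).to_csv(out / "unit_dyn_pca_varexp.csv", index=False)
    for i in range(min(3, len(pca.components))):
        pd.DataFrame(pca.components[i]).to_csv(out / f"unit_dyn_pc{i + 1}.csv")

    fmt_binned = bin_spikes(session, "cue_onset", -0.5, stim_end + 1.0, 0.05)
    fmt = dynamic_format_correlation(
        fmt_binned,
        window=config.dyn_window,
        step=config.dyn_step,
        onsets=default_onsets(-0.5, stim_end + 0.5, config.dyn_step),
        seed=derive_seed(seed, "fmtcorr"),
    )
    for a in fmt.formats:
        for b in fmt.formats:
            pd.DataFrame(fmt.pair(a, b)).to_csv(out / f"format_corr_{a}_{b}.csv")
    return {
        "decode_accuracy": confusion.overall_accuracy,
        "dyn_diag_max": float(np.max(np.diag(dyn.accuracy))),
        "_confusion": confusion,
    }


_DISPATCH = {
    "touch_map": _analyze_touch_map,
    "latency": _analyze_latency,
    "rf_gradient": _analyze_rf_gradient,
    "imagery": _analyze_imagery,
}


def _hash_tree(root: Path) -> dict:
    hashes = {}
    for f in sorted(root.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            hashes[str(f.relative_to(root))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return hashes


def run_pipeline(config: AnalysisConfig, session_paths: list, out_dir) -> Path:
    """Run every applicable analysis for each session; write a report directory.

    Returns the report path.  Identical config + sessions always produce
    byte-identical outputs (all randomness flows from config.seed through
    named substreams).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    confusions: dict = {}
    for spath in session_paths:
        session = read_session(spath)
        session = select_units(session, config.min_rate, config.min_snr)
        stage_out = out_dir / session.session_id
        stage_out.mkdir(exist_ok=True)
        fn = _DISPATCH[session.task]
        t0 = time.perf_counter()
        result = fn(session, config, stage_out, derive_seed(config.seed, session.session_id))
        logger.info(
            "stage=%s task=%s n_units=%d elapsed=%.1fs",
            session.session_id,
            session.task,
            session.n_units,
            time.perf_counter() - t0,
        )
        cm = result.pop("_confusion", None)
        if cm is not None:
            confusions.setdefault(session.task, []).append(cm)
        summaries[session.session_id] = result

    for task, cms in confusions.items():
        if len(cms) > 1:
            avg = average_confusions(cms)
            _save_matrix(out_dir / f"confusion_mean_{task}.csv", avg.accuracy, avg.classes)

    manifest = {
        "tool_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()
        },
        "sessions": [str(p) for p in session_paths],
        "output_hashes": _hash_tree(out_dir),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "summary.txt", "w") as fh:
        for sid, res in summaries.items():
            fh.write(f"{sid}: {json.dumps(res, default=str)}\n")
    return out_dir
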