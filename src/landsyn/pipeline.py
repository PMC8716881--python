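"""File-based orchestration of the landing-synergy workflow.

Stages communicate through a run directory of plain CSV/JSON artifacts::

    run/
      config.yaml
      raw/<cond>/trial_NNNN/{emg,grf,cop}.csv + trial.json
      envelopes/<cond>/trial_NNNN.csv          conditioned full-length EMG
      segmentation/<cond>/trial_NNNN.json      event indices (+ failed.json)
      normalized/<cond>/trial_NNNN.csv         300-point cycle, all channels
      synergies/<cond>/trial_NNNN_{modules,primitives}.csv + .json
      classification/<cond>/{classification,centroids}.csv + meta.json
      metrics/{primitive_metrics,overlaps,cai,cop_area}.csv
      report/summary.json

Each stage reads only upstream artifacts, so re-running a stage from
cached inputs reproduces identical downstream outputs. Seeds are derived
deterministically from the global seed, the stage and the trial, never
from execution order. Trials whose segmentation fails are quarantined
(recorded in ``segmentation/failed.json``), not silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .classification import SynergyClassifier
from .config import RunConfig
from .events import (LandingSegmentation, cop_ellipse_area, segment_landing,
                     time_normalize_channels)
from .exceptions import DataError, LandsynError, SegmentationError
from .extraction import SynergyNMF
from .metrics import coactivation_index, coa, fwhm, overlaps
from .muscles import JOINTS, MUSCLES
from .signals import EmgEnvelope, condition_emg, normalize_amplitude


def _stage_seed(config: RunConfig, *key: int) -> int:
    state = np.random.SeedSequence([config.seed, *key]).generate_state(1)[0]
    return int(state % 2**31)


def _trial_dirs(root: Path, condition: str) -> list[Path]:
    base = root / condition
    if not base.is_dir():
        raise DataError(f"missing stage input directory {base}")
    return sorted(p for p in base.iterdir() if p.is_dir())


def _trial_ids(root: Path, condition: str, suffix: str) -> list[str]:
    base = root / condition
    if not base.is_dir():
        raise DataError(f"missing stage input directory {base}")
    return sorted(p.name[: -len(suffix)] for p in base.glob(f"*{suffix}"))


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    """Generate the synthetic cohorts and write them as fixture trials."""
    for ci, cond in enumerate(config.conditions):
        trials = simulate.make_cohort(
            config.n_trials, condition=cond,
            seed=_stage_seed(config, 0, ci),
            noise_snr=config.noise_snr, bodyweight=config.bodyweight)
        for i, trial in enumerate(trials):
            simulate.write_trial(trial, run_dir / "raw" / cond / f"trial_{i:04d}")


def stage_preprocess(config: RunConfig, run_dir: Path) -> None:
    """Condition raw EMG into full-length linear envelopes."""
    for cond in config.conditions:
        out = run_dir / "envelopes" / cond
        out.mkdir(parents=True, exist_ok=True)
        for tdir in _trial_dirs(run_dir / "raw", cond):
            trial = simulate.read_trial(tdir)
            env = condition_emg(
                trial.emg_raw, rate=trial.rate,
                highpass=config.highpass_hz, lowpass=config.lowpass_hz,
                order=config.filter_order)
            t = np.arange(env.n_samples) / env.rate
            pd.DataFrame({"time": t, **{m: env.values[i] for i, m in
                                        enumerate(MUSCLES)}}
                         ).to_csv(out / f"{tdir.name}.csv", index=False)


def _load_envelope(path: Path, rate: float) -> EmgEnvelope:
    df = pd.read_csv(path)
    return EmgEnvelope(values=df[list(MUSCLES)].to_numpy().T, rate=rate)


def _series_slice(config: RunConfig, n: int) -> slice:
    return slice(1, n - 1) if config.drop_first_last and n > 2 else slice(0, n)


def stage_segment(config: RunConfig, run_dir: Path) -> None:
    """Detect events, amplitude-normalize envelopes, build 300-point trials.

    The amplitude reference is the per-muscle maximum over all samples of
    all stable-ground (SG) intervals of interest; unstable-ground trials
    are normalized against the same reference.
    """
    segs: dict[str, dict[str, LandingSegmentation]] = {}
    failed: dict[str, str] = {}
    for cond in config.conditions:
        out = run_dir / "segmentation" / cond
        out.mkdir(parents=True, exist_ok=True)
        segs[cond] = {}
        tdirs = _trial_dirs(run_dir / "raw", cond)
        for tdir in tdirs[_series_slice(config, len(tdirs))]:
            trial = simulate.read_trial(tdir)
            try:
                seg = segment_landing(
                    trial.vgrf, trial.bodyweight, rate=trial.rate,
                    threshold=config.touchdown_threshold_n,
                    band=config.bodyweight_band)
            except SegmentationError as exc:
                failed[f"{cond}/{tdir.name}"] = str(exc)
                continue
            segs[cond][tdir.name] = seg
            (out / f"{tdir.name}.json").write_text(json.dumps({
                "touchdown_index": seg.touchdown_index,
                "interval_start_index": seg.interval_start_index,
                "stance_end_index": seg.stance_end_index,
                "stance_duration_s": seg.stance_duration,
                "rate": seg.rate,
            }, indent=1))
    (run_dir / "segmentation" / "failed.json").write_text(
        json.dumps(failed, indent=1))

    if "SG" not in segs or not segs["SG"]:
        raise LandsynError("no segmentable SG trials: amplitude reference empty")
    reference = []
    for name, seg in segs["SG"].items():
        env = _load_envelope(run_dir / "envelopes" / "SG" / f"{name}.csv",
                             config.rate)
        cropped = env.values[:, seg.interval_start_index:seg.stance_end_index + 1]
        reference.append(EmgEnvelope(values=cropped, rate=config.rate))

    for cond in config.conditions:
        out = run_dir / "normalized" / cond
        out.mkdir(parents=True, exist_ok=True)
        for name, seg in segs[cond].items():
            trial = simulate.read_trial(run_dir / "raw" / cond / name)
            env = _load_envelope(run_dir / "envelopes" / cond / f"{name}.csv",
                                 config.rate)
            norm_env = normalize_amplitude(env, reference)
            emg300 = time_normalize_channels(norm_env.values, seg)
            grf300 = time_normalize_channels(
                np.linalg.norm(trial.grf, axis=0), seg)[0]
            cop300 = time_normalize_channels(trial.cop, seg)
            df = pd.DataFrame({m: emg300[i] for i, m in enumerate(MUSCLES)})
            df["grf_norm"] = grf300
            df["cop_x"], df["cop_y"] = cop300[0], cop300[1]
            df.to_csv(out / f"{name}.csv", index=False)


def stage_extract(config: RunConfig, run_dir: Path) -> None:
    """Factorize each normalized trial and select its model order."""
    for ci, cond in enumerate(config.conditions):
        out = run_dir / "synergies" / cond
        out.mkdir(parents=True, exist_ok=True)
        for name in _trial_ids(run_dir / "normalized", cond, ".csv"):
            df = pd.read_csv(run_dir / "normalized" / cond / f"{name}.csv")
            V = df[list(MUSCLES)].to_numpy().T
            trial_idx = int(name.split("_")[-1])
            nmf = SynergyNMF(
                n_restarts=config.nmf_restarts, tol=config.nmf_tol,
                patience=config.nmf_patience, max_iter=config.nmf_max_iter,
                rank_mse_threshold=config.rank_mse_threshold,
                random_state=_stage_seed(config, 1, ci, trial_idx),
            ).fit(V)
            pd.DataFrame(nmf.modules_, index=list(MUSCLES),
                         columns=[f"syn_{j}" for j in range(nmf.rank_)]
                         ).to_csv(out / f"{name}_modules.csv")
            pd.DataFrame(nmf.primitives_.T,
                         columns=[f"syn_{j}" for j in range(nmf.rank_)]
                         ).to_csv(out / f"{name}_primitives.csv", index=False)
            (out / f"{name}.json").write_text(json.dumps({
                "rank": int(nmf.rank_),
                "r_squared": float(nmf.r_squared_),
                "r_squared_curve": [float(v) for v in nmf.r_squared_curve_],
                "rank_flagged": bool(nmf.rank_flagged_),
                "seed": int(nmf.random_state),
            }, indent=1))


def _load_synergies(run_dir: Path, cond: str):
    """Pool per-trial synergies of one condition: ids, primitives, modules."""
    base = run_dir / "synergies" / cond
    ids, prims, mods = [], [], []
    for name in _trial_ids(run_dir / "synergies", cond, ".json"):
        P = pd.read_csv(base / f"{name}_primitives.csv").to_numpy().T
        M = pd.read_csv(base / f"{name}_modules.csv", index_col=0).to_numpy()
        for j in range(P.shape[0]):
            ids.append((name, j))
            prims.append(P[j])
            mods.append(M[:, j])
    if not ids:
        raise DataError(f"no synergies found for condition {cond}")
    return ids, np.vstack(prims), np.vstack(mods)


def stage_classify(config: RunConfig, run_dir: Path) -> None:
    """Cluster pooled synergies per condition, label fundamental/combined."""
    for ci, cond in enumerate(config.conditions):
        ids, prims, mods = _load_synergies(run_dir, cond)
        clf = SynergyClassifier(
            n_init=config.kmeans_restarts,
            elbow_mse_threshold=config.elbow_mse_threshold,
            score_tol=config.score_tol, min_agreement=config.min_agreement,
            random_state=_stage_seed(config, 2, ci),
        ).fit(prims, mods)
        out = run_dir / "classification" / cond
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "trial": [t for t, _ in ids],
            "synergy": [j for _, j in ids],
            "cluster": clf.assignments_primitive_,
            "cluster_module": clf.assignments_module_,
            "functional_name": [clf.functional_names_[c]
                                for c in clf.assignments_primitive_],
            "label": clf.labels_,
        }).to_csv(out / "classification.csv", index=False)
        pd.DataFrame(clf.centroid_primitives_.T,
                     columns=[f"cluster_{c}" for c in range(clf.k_)]
                     ).to_csv(out / "centroids.csv", index=False)
        (out / "meta.json").write_text(json.dumps({
            "k": int(clf.k_),
            "wss_curve": [float(v) for v in clf.wss_curve_],
            "score_primitive": clf.score_primitive_,
            "score_module": clf.score_module_,
            "matching_failed": bool(clf.matching_failed_),
            "functional_names": list(clf.functional_names_),
        }, indent=1))


def stage_metrics(config: RunConfig, run_dir: Path) -> None:
    """Per-synergy FWHM/CoA, per-trial overlaps, CaI and CoP ellipse area."""
    rows, cai_rows, cop_rows, overlap_rows = [], [], [], []
    for cond in config.conditions:
        cls = pd.read_csv(
            run_dir / "classification" / cond / "classification.csv")
        labels = {(t, j): (f, l) for t, j, f, l in zip(
            cls["trial"], cls["synergy"], cls["functional_name"], cls["label"])}
        base = run_dir / "synergies" / cond
        for name in _trial_ids(run_dir / "synergies", cond, ".json"):
            P = pd.read_csv(base / f"{name}_primitives.csv").to_numpy().T
            M = pd.read_csv(base / f"{name}_modules.csv", index_col=0)
            for j, prim in enumerate(P):
                fname, label = labels.get((name, j), ("unclassified", ""))
                rows.append({
                    "condition": cond, "trial": name, "synergy": j,
                    "functional_name": fname, "label": label,
                    "fwhm": fwhm(prim),
                    "coa": coa(prim, subtract_min=config.coa_subtract_min),
                })
                for joint in JOINTS:
                    ci_res = coactivation_index(M.iloc[:, j].to_numpy(), joint)
                    cai_rows.append({
                        "condition": cond, "trial": name, "synergy": j,
                        "joint": joint, "cai": ci_res.cai,
                    })
            prof = overlaps(P)
            overlap_rows.append({
                "condition": cond, "trial": name,
                "overlap_points": int(prof.overlap_indicator.sum()),
            })
            seg = json.loads((run_dir / "segmentation" / cond /
                              f"{name}.json").read_text())
            trial = simulate.read_trial(run_dir / "raw" / cond / name)
            stance_cop = trial.cop[:, seg["touchdown_index"]:
                                   seg["stance_end_index"] + 1]
            cop_rows.append({
                "condition": cond, "trial": name,
                "cop_area_m2": cop_ellipse_area(
                    stance_cop, coverage=config.cop_coverage),
                "stance_duration_s": seg["stance_duration_s"],
            })
    out = run_dir / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "primitive_metrics.csv", index=False)
    pd.DataFrame(cai_rows).to_csv(out / "cai.csv", index=False)
    pd.DataFrame(overlap_rows).to_csv(out / "overlaps.csv", index=False)
    pd.DataFrame(cop_rows).to_csv(out / "cop_area.csv", index=False)


def stage_report(config: RunConfig, run_dir: Path) -> dict:
    """Aggregate a run into a summary JSON."""
    pm = pd.read_csv(run_dir / "metrics" / "primitive_metrics.csv")
    cop = pd.read_csv(run_dir / "metrics" / "cop_area.csv")
    summary: dict = {"conditions": {}}
    for cond in config.conditions:
        meta = json.loads((run_dir / "classification" / cond /
                           "meta.json").read_text())
        sub = pm[pm["condition"] == cond]
        ranks = []
        for name in _trial_ids(run_dir / "synergies", cond, ".json"):
            ranks.append(json.loads((run_dir / "synergies" / cond /
                                     f"{name}.json").read_text())["rank"])
        fund = sub[sub["label"] == "fundamental"]
        summary["conditions"][cond] = {
            "n_trials": len(ranks),
            "modal_rank": int(pd.Series(ranks).mode().iloc[0]),
            "k_clusters": meta["k"],
            "matching_failed": meta["matching_failed"],
            "fundamental_fraction": float((sub["label"] == "fundamental").mean()),
            "fwhm_by_cluster": {
                n: float(g["fwhm"].mean())
                for n, g in fund.groupby("functional_name")},
            "coa_by_cluster": {
                n: float(g["coa"].mean())
                for n, g in fund.groupby("functional_name")},
            "mean_cop_area_m2": float(
                cop[cop["condition"] == cond]["cop_area_m2"].mean()),
        }
    (run_dir / "report").mkdir(parents=True, exist_ok=True)
    (run_dir / "report" / "summary.json").write_text(
        json.dumps(summary, indent=1))
    return summary


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "segment": stage_segment,
    "extract": stage_extract,
    "classify": stage_classify,
    "metrics": stage_metrics,
    "report": stage_report,
}

STAGE_ORDER = tuple(STAGES)


def run_pipeline(config: RunConfig, run_dir, stages=STAGE_ORDER) -> dict | None:
    """Run the requested stages in order; returns the report summary if run."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    result = None
    for stage in stages:
        if stage not in STAGES:
            raise LandsynError(f"unknown stage {stage!r}")
        result = STAGES[stage](config, run_dir)
    return result
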