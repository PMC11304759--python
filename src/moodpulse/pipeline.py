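"""End-to-end orchestration: simulate -> SMM -> QMM -> aggregate -> CCM -> ads.

Stages hand data to each other through plain files (CSV/JSONL) under the
run's output directory, so each stage is independently inspectable and
substitutable; ``run_pipeline`` returns (and writes) a manifest with the
derived per-stage seeds, timings, and output paths, sufficient for an exact
rerun.

``run_two_step`` is the core experiment: it trains the query mood model with
and without sensor-model label augmentation on one synthetic cohort and
reports the test AUC of both conditions (test labels are always
annotation-sourced).
"""

from __future__ import annotations

import datetime as dt
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ads as ads_mod
from . import aggregation, ccm, qmm, smm
from . import synthetic_data as synth

__all__ = ["run_two_step", "TwoStepResult", "run_pipeline", "load_config"]


# --------------------------------------------------------------------------
# the two-step experiment


@dataclass
class TwoStepResult:
    """Paired evaluation of QMM with vs without SMM label augmentation."""

    auc_with: float
    auc_without: float
    n_labels_with: int
    n_labels_without: int
    n_test: int
    smm_train_accuracy: float
    scores: pd.DataFrame  # user_id, frame_start, score (with-SMM model, all frames)
    model_with: qmm.QMMModel
    model_without: qmm.QMMModel

    @property
    def gain(self) -> float:
        return self.auc_with - self.auc_without


def _subset_frames(qf: qmm.QueryFrameSet, mask: np.ndarray) -> qmm.QueryFrameSet:
    return qmm.QueryFrameSet(X=qf.X[mask], vocabulary=qf.vocabulary,
                             index=qf.index.loc[mask].reset_index(drop=True))


def run_two_step(bundle: synth.CohortBundle, test_frac: float = 0.3,
                 seed: int = 0, smm_mode: str = "fit", min_frequency: int = 5,
                 l2_lambda: float = 1e-4) -> TwoStepResult:
    """Train and evaluate the query mood model with and without augmentation.

    Query frames are split at the (user, frame) level into train/test; the
    test set keeps only frames with a non-neutral annotation label (SMM-
    sourced labels never enter the test set). The SMM is trained on annotated
    sensor frames belonging to the train split only. ``smm_mode='permuted'``
    trains the SMM on label-permuted data — a deliberately useless
    augmentation source that serves as the negative control.
    """
    if smm_mode not in ("fit", "permuted"):
        raise ValueError(f"unknown smm_mode {smm_mode!r}")
    rng = np.random.default_rng(seed)

    qf = qmm.build_query_features(bundle.queries, min_frequency=min_frequency)
    n = len(qf)
    test_mask = rng.random(n) < test_frac
    qf_train = _subset_frames(qf, ~test_mask)
    qf_test = _subset_frames(qf, test_mask)

    # annotation labels per frame
    ann_labels = qmm.annotation_frame_labels(bundle.annotations)

    # SMM trained on annotated sensor frames outside the test query frames
    labeled = smm.frame_join(bundle.sensor_frames, bundle.annotations)
    test_keys = set(map(tuple, qf_test.index[["user_id", "frame_start"]].itertuples(index=False)))
    keys = list(map(tuple, labeled[["user_id", "frame_start"]].itertuples(index=False)))
    in_test = np.array([k in test_keys for k in keys])
    smm_train = labeled.loc[~in_test].copy()
    if smm_mode == "permuted":
        lab = smm_train["label"].to_numpy().copy()
        ok = np.isfinite(lab)
        lab[ok] = rng.permutation(lab[ok])
        smm_train["label"] = lab
    smm_model = smm.train_smm(smm_train, seed=int(rng.integers(2**31)))
    train_rows = smm_train.loc[smm_train["label"].notna()]
    smm_acc = float(
        (smm.predict_frames(smm_model, train_rows) == train_rows["label"]).mean())

    # SMM predictions on the training query frames (join to sensor features)
    feats = bundle.sensor_frames.merge(qf_train.index, on=["user_id", "frame_start"])
    pred_class = smm.predict_frames(smm_model, feats)
    smm_pred = feats[["user_id", "frame_start"]].copy()
    smm_pred["predicted_class"] = pred_class.astype(int)

    lab_without = qmm.augment_labels(qf_train, bundle.annotations, None)
    lab_with = qmm.augment_labels(qf_train, bundle.annotations, smm_pred)

    model_without = qmm.train_qmm(lab_without.X, lab_without.labels, qf.vocabulary,
                                  l2_lambda=l2_lambda, seed=seed)
    model_with = qmm.train_qmm(lab_with.X, lab_with.labels, qf.vocabulary,
                               l2_lambda=l2_lambda, seed=seed)

    # test set: annotation-sourced, non-neutral labels only
    test_lab = qf_test.index.merge(ann_labels, on=["user_id", "frame_start"], how="left")
    keep = test_lab["label"].notna().to_numpy()
    y_test = test_lab["label"].to_numpy()[keep].astype(int)
    Xt = qf_test.X[keep]
    rep_with = qmm.evaluate_auc(qmm.score_mood(model_with, Xt), y_test,
                                condition="with_smm",
                                n_train_labels=len(lab_with.labels))
    rep_without = qmm.evaluate_auc(qmm.score_mood(model_without, Xt), y_test,
                                   condition="without_smm",
                                   n_train_labels=len(lab_without.labels))

    scores = qf.index.copy()
    scores["score"] = qmm.score_mood(model_with, qf)
    return TwoStepResult(
        auc_with=rep_with.auc, auc_without=rep_without.auc,
        n_labels_with=rep_with.n_train_labels,
        n_labels_without=rep_without.n_train_labels,
        n_test=int(keep.sum()), smm_train_accuracy=smm_acc,
        scores=scores, model_with=model_with, model_without=model_without)


# --------------------------------------------------------------------------
# full pipeline


_DEFAULT_CONFIG = {
    "cohort": {"n_users": 200, "n_days": 28, "start_date": "2019-07-01"},
    "generator": {},
    "qmm": {"min_frequency": 5, "l2_lambda": 1e-4, "test_frac": 0.3},
    "epidemic": {"mood_coupling": -0.5, "mood_lag": 7},
    "ccm": {"E": 2, "n_draws": 50},
    "ads": {"n_blind": 20, "n_sensitive": 2, "delta": 3.0,
            "impressions_per_day": 500, "base_rate": 0.01, "n_iter": 100000},
    "rhythm": {"holidays": []},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merged_config(config: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v
           for k, v in _DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage from one config; returns the manifest.

    ``config`` (dict or YAML path) must contain an integer ``seed``; every
    stage derives its own substream from it. Outputs land under ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if "seed" not in config or not isinstance(config["seed"], (int, np.integer)):
        raise ValueError("config must declare an integer 'seed' before any stage runs")
    cfg = _merged_config(config)
    seed = int(config["seed"])
    stage_seeds = [int(s % (2**31)) for s in
                   np.random.SeedSequence(seed).generate_state(6)]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": cfg, "stages": {}, "outputs": {}}

    def _stage(name):
        manifest["stages"][name] = {"started": time.time()}

    def _done(name, **outputs):
        st = manifest["stages"][name]
        st["seconds"] = round(time.time() - st.pop("started"), 3)
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})

    try:
        # 1. simulate cohort
        _stage("simulate")
        c = cfg["cohort"]
        config_obj = synth.CohortConfig(
            n_users=int(c["n_users"]), n_days=int(c["n_days"]),
            start_date=dt.date.fromisoformat(str(c["start_date"])),
            seed=stage_seeds[0])
        params = synth.GeneratorParams(**cfg["generator"])
        bundle = synth.simulate_cohort(config_obj, params)
        paths = synth.write_bundle(bundle, out)
        _done("simulate", **paths)

        # 2+3. SMM + QMM two-step experiment
        _stage("two_step")
        ts = run_two_step(bundle, test_frac=cfg["qmm"]["test_frac"],
                          seed=stage_seeds[1],
                          min_frequency=cfg["qmm"]["min_frequency"],
                          l2_lambda=cfg["qmm"]["l2_lambda"])
        ts.model_with.to_json(out / "qmm_model.json")
        ts.scores.to_csv(out / "scores.csv", index=False)
        (out / "auc_report.json").write_text(json.dumps({
            "with_smm": {"auc": ts.auc_with, "n_train_labels": ts.n_labels_with},
            "without_smm": {"auc": ts.auc_without,
                            "n_train_labels": ts.n_labels_without},
            "n_test": ts.n_test, "smm_train_accuracy": ts.smm_train_accuracy,
        }, indent=2))
        _done("two_step", qmm_model=out / "qmm_model.json",
              scores=out / "scores.csv", auc_report=out / "auc_report.json")

        # 4. aggregation + weekly rhythm
        _stage("aggregate")
        daily = aggregation.nationwide_score(ts.scores, granularity="daily")
        daily.to_csv(out / "nationwide.csv")
        rhythm = aggregation.weekly_rhythm(daily, cfg["rhythm"]["holidays"])
        rhythm.to_csv(out / "rhythm_table.csv")
        _done("aggregate", nationwide=out / "nationwide.csv",
              rhythm=out / "rhythm_table.csv")

        # 5. epidemic + CCM
        _stage("ccm")
        n_days = config_obj.n_days
        pop_mood = bundle.daily_population_mood().to_numpy()
        epi_cfg = dict(cfg["epidemic"])
        waves = epi_cfg.pop("waves", None)
        epi_kwargs = {"mood_coupling": float(epi_cfg.get("mood_coupling", -0.5)),
                      "mood_lag": int(epi_cfg.get("mood_lag", 7))}
        if waves is not None:
            epi_kwargs["waves"] = tuple(tuple(w) for w in waves)
        else:
            # scale default wave centers into the simulated period
            centers = np.linspace(0.15, 0.85, 3) * n_days
            epi_kwargs["waves"] = tuple((float(cc), max(n_days / 18.0, 2.0), 500.0)
                                        for cc in centers)
        epi = synth.simulate_epidemic(
            n_days, synth.EpidemicParams(**epi_kwargs), mood=pop_mood,
            start_date=config_obj.start_date, seed=stage_seeds[2])
        epi.to_csv(out / "cases.csv", index=False)
        window = min(7, max(2, n_days // 8))
        if n_days - window + 1 >= 40:
            mood_s = ccm.smooth_standardize(pop_mood, window=window, name="Score")
            case_s = ccm.smooth_standardize(epi["new_cases"], window=window,
                                            name="NewCase")
            results = ccm.ccm_both_directions(
                mood_s, case_s, names=("Score", "NewCase"),
                E=int(cfg["ccm"]["E"]), n_draws=int(cfg["ccm"]["n_draws"]),
                seed=stage_seeds[3])
            pd.concat([r.to_frame() for r in results.values()]).to_csv(
                out / "ccm_report.csv", index=False)
            _done("ccm", cases=out / "cases.csv", ccm_report=out / "ccm_report.csv")
        else:
            manifest["stages"]["ccm"]["skipped"] = "series too short for CCM"
            _done("ccm", cases=out / "cases.csv")

        # 6. ads
        _stage("ads")
        a = cfg["ads"]
        specs = [synth.AdSpec(ad_id=f"blind{i:03d}", delta=0.0,
                              impressions_per_day=int(a["impressions_per_day"]),
                              base_rate=float(a["base_rate"]))
                 for i in range(int(a["n_blind"]))]
        specs += [synth.AdSpec(ad_id=f"sens{i:03d}", delta=float(a["delta"]),
                               impressions_per_day=int(a["impressions_per_day"]),
                               base_rate=float(a["base_rate"]))
                  for i in range(int(a["n_sensitive"]))]
        events = synth.simulate_ad_logs(specs, ts.scores, seed=stage_seeds[4])
        events.to_csv(out / "ad_events.csv", index=False)
        day_results = ads_mod.pairwise_all_days(events, n_iter=int(a["n_iter"]),
                                                seed=stage_seeds[5])
        pd.DataFrame([vars(r) for r in day_results]).to_csv(
            out / "pairwise_days.csv", index=False)
        dist = ads_mod.wins_distribution(day_results)
        pd.DataFrame({"k": np.arange(15), "n_ads": dist.counts,
                      "fraction": dist.fractions}).to_csv(
            out / "wins_distribution.csv", index=False)
        enr = ads_mod.enrichment(dist, ads_mod.binomial_null(14))
        enr.to_csv(out / "enrichment.csv", index=False)
        _done("ads", ad_events=out / "ad_events.csv",
              pairwise_days=out / "pairwise_days.csv",
              wins_distribution=out / "wins_distribution.csv",
              enrichment=out / "enrichment.csv")
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if "started" in v]
        manifest["failed_stage"] = failed[-1] if failed else None
        for k in failed:
            manifest["stages"][k].pop("started", None)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(
            f"pipeline stage {manifest['failed_stage']!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
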