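"""End-to-end experiment orchestration.

Reproduces the two-arm design — per-channel time-domain EMG features versus
NMF synergy features, both decoded by an ELM — on synthetic sessions:

1. generate training and testing sessions from a planted synergy model;
2. compute offline (zero-phase) envelopes for training, causal envelopes
   for the simulated online testing phase;
3. train the configured feature pathway(s): stratified 50/50 split of the
   training windows for the offline accuracy estimate, optional 2-fold CV
   over the hidden-layer grid, then a refit on all training windows for the
   online decoder;
4. run the simulated testing phase and compute every performance metric.

The report is a plain nested dict (JSON-serializable, deterministically
ordered) so identical (config, seed) runs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from . import elm as elm_mod
from . import metrics as metrics_mod
from .features import FeatureMatrix, WindowSpec, extract_emg_features
from .online_sim import OnlineConfig, OnlineDecoder, run_testing_phase
from .preprocess import envelope
from .synergy import (SynergyModel, extract_synergy_features,
                      motion_envelope_matrix)
from .synth import (REST_LABEL, ConfigurationError, EmgSession, SynthConfig,
                    generate_session, make_ground_truth)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElmSettings:
    hidden_grid: tuple[int, ...] = elm_mod.DEFAULT_HIDDEN_GRID
    n_hidden: int | None = None      # set to skip CV and use a fixed size
    lam: float = elm_mod.DEFAULT_LAMBDA
    activation: str = "tribas"
    cv_folds: int = 2


@dataclass(frozen=True)
class SynergySettings:
    k_override: int | None = None    # fixed synergy count; None = select
    variance_threshold: float = 0.90
    slope_threshold: float = 0.05
    centered_variance: bool = False
    #: decimation factor applied to the (10 Hz-bandwidth) envelope before
    #: the NMF fit; purely a numerical economy, the factorization is
    #: insensitive to it because the envelopes are heavily oversampled.
    fit_decimate: int = 10
    max_iter: int = 200
    tol: float = 1e-5


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    synth: SynthConfig = SynthConfig()
    window: WindowSpec = WindowSpec()
    pathways: tuple[str, ...] = ("emg", "synergy")
    elm: ElmSettings = ElmSettings()
    synergy: SynergySettings = SynergySettings()
    online: OnlineConfig = OnlineConfig()
    separation: float = 0.85
    offline_split: float = 0.5       # held-out fraction of training windows

    def validate(self) -> None:
        self.synth.validate()
        if self.window.window > self.synth.trial_samples:
            raise ConfigurationError("window longer than a trial")
        for p in self.pathways:
            if p not in ("emg", "synergy"):
                raise ConfigurationError(f"unknown pathway {p!r}")
        if not 0 < self.offline_split < 1:
            raise ConfigurationError("offline_split must be in (0, 1)")

    # -- YAML round trip --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            synth = dict(d["synth"])
            if "class_labels" in synth and synth["class_labels"] is not None:
                synth["class_labels"] = tuple(synth["class_labels"])
            d["synth"] = SynthConfig(**synth)
        if "window" in d:
            d["window"] = WindowSpec(**d["window"])
        if "elm" in d:
            e = dict(d["elm"])
            if "hidden_grid" in e:
                e["hidden_grid"] = tuple(e["hidden_grid"])
            d["elm"] = ElmSettings(**e)
        if "synergy" in d:
            d["synergy"] = SynergySettings(**d["synergy"])
        if "online" in d:
            d["online"] = OnlineConfig(**d["online"])
        if "pathways" in d:
            d["pathways"] = tuple(d["pathways"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert to YAML/JSON-native types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _seed_for(config: RunConfig, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    offsets = {"nmf": 10, "elm": 11, "cv": 12, "split": 13}
    ss = np.random.SeedSequence([config.synth.seed, offsets[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------


def prepare_sessions(config: RunConfig):
    """(ground truth, training session, testing session)."""
    truth = make_ground_truth(config.synth, separation=config.separation)
    train = generate_session(config.synth, truth, "training")
    test = generate_session(config.synth, truth, "testing")
    return truth, train, test


def train_pathway(config: RunConfig, pathway: str, train_env: EmgSession
                  ) -> dict:
    """Train one feature pathway on offline training envelopes.

    Returns a dict with the feature matrix, fitted ELM (refit on all
    windows), the offline accuracy on the held-out window split, the CV
    trace, and the synergy model where applicable.
    """
    syn_model = None
    if pathway == "synergy":
        X = motion_envelope_matrix(train_env, rest_label=REST_LABEL)
        dec = max(1, int(config.synergy.fit_decimate))
        syn_model = SynergyModel.fit(
            X[:, ::dec], k=config.synergy.k_override,
            variance_threshold=config.synergy.variance_threshold,
            slope_threshold=config.synergy.slope_threshold,
            seed=_seed_for(config, "nmf"),
            centered=config.synergy.centered_variance,
            max_iter=config.synergy.max_iter, tol=config.synergy.tol)
        feats = extract_synergy_features(train_env, syn_model, config.window)
    else:
        feats = extract_emg_features(train_env, config.window)

    Xw = feats.values.T
    yw = feats.labels
    # trial-level stratified split: all windows of one repetition stay on the
    # same side, otherwise per-repetition amplitude leaks across the split
    tids = feats.trial_ids
    uniq, first = np.unique(tids, return_index=True)
    trial_labels = yw[first]
    tr_trials, te_trials = train_test_split(
        uniq, test_size=config.offline_split,
        random_state=_seed_for(config, "split"), stratify=trial_labels)
    idx_train = np.nonzero(np.isin(tids, tr_trials))[0]
    idx_test = np.nonzero(np.isin(tids, te_trials))[0]

    es = config.elm
    if es.n_hidden is not None:
        n_hidden = int(es.n_hidden)
        cv_acc: dict[int, float] = {}
    else:
        n_hidden, cv_acc = elm_mod.cv_select_hidden(
            Xw[idx_train], grid=es.hidden_grid, labels=yw[idx_train],
            lam=es.lam, folds=es.cv_folds, activation=es.activation,
            seed=_seed_for(config, "cv"))

    model_half = elm_mod.fit(Xw[idx_train], n_hidden, labels=yw[idx_train],
                             lam=es.lam, activation=es.activation,
                             seed=_seed_for(config, "elm"))
    pred, _ = elm_mod.predict(model_half, Xw[idx_test])
    # offline accuracy is reported over the five motion classes (rest windows
    # are trained and decoded but not part of the accuracy figure, matching
    # how motion-decoding accuracy is conventionally tabulated)
    motion_mask = yw[idx_test] != REST_LABEL
    off_acc = metrics_mod.offline_accuracy(pred[motion_mask],
                                           yw[idx_test][motion_mask])
    confusion = metrics_mod.confusion_matrix(yw[idx_test][motion_mask],
                                             pred[motion_mask],
                                             model_half.class_order)

    model_full = elm_mod.fit(Xw, n_hidden, labels=yw, lam=es.lam,
                             activation=es.activation,
                             seed=_seed_for(config, "elm"))
    return {"features": feats, "elm": model_full, "n_hidden": n_hidden,
            "cv_accuracy": cv_acc, "offline_accuracy": off_acc,
            "confusion": confusion, "synergy_model": syn_model}


def evaluate_online(config: RunConfig, pathway: str, trained: dict,
                    test_session: EmgSession) -> dict:
    """Causal envelopes -> simulated testing phase -> online metrics."""
    test_env = envelope(test_session, mode="causal")
    decoder = OnlineDecoder(trained["elm"], config.window, pathway=pathway,
                            synergy_model=trained["synergy_model"])
    records = run_testing_phase(decoder, test_env, config.online)

    per_class: dict[str, dict] = {}
    for label in config.synth.motion_labels:
        cls_records = [r for r in records if r.target_class == label]
        sel_mean, sel_sd = metrics_mod.time_summary(records, label,
                                                    "selection_time")
        comp_mean, comp_sd = metrics_mod.time_summary(records, label,
                                                      "completion_time")
        comp_times = [r.completion_time for r in cls_records
                      if r.completed and r.completion_time is not None]
        trend = None
        if len(comp_times) >= 4:
            t = metrics_mod.fit_learning_trend(np.asarray(comp_times))
            trend = {"a": t.a, "b": t.b, "c": t.c,
                     "residual_norm": t.residual_norm,
                     "converged": t.converged, "degenerate": t.degenerate}
        # variability over the commanded-motion portion of each repetition
        traces = []
        for trial, rec in zip(
                [t for t in test_env.trials if t.label != REST_LABEL],
                records):
            if rec.target_class != label:
                continue
            if rec.completed and rec.completion_time is not None:
                stop = trial.start + int(
                    (rec.movement_onset_time + rec.completion_time)
                    * test_env.sample_rate)
            else:
                stop = trial.end
            stop = min(max(stop, trial.start + 2), test_env.n_samples)
            traces.append(test_env.signal[:, trial.start:stop])
        var = metrics_mod.variability(traces) if len(traces) >= 2 else None

        per_class[label] = {
            "online_accuracy_pct": metrics_mod.online_accuracy(records, label),
            "selection_time_mean_s": sel_mean, "selection_time_sd_s": sel_sd,
            "completion_time_mean_s": comp_mean,
            "completion_time_sd_s": comp_sd,
            "completion_rate_pct": metrics_mod.completion_rate(records, label),
            "learning_trend": trend,
            "variability": var,
            "n_trials": len(cls_records),
        }

    # online confusion over all decoder outputs between onset and completion
    actual, predicted = [], []
    for r in records:
        if r.movement_onset_time is None:
            continue
        hi = (r.movement_onset_time + r.completion_time
              if r.completed and r.completion_time is not None
              else np.inf)
        mask = (r.times >= r.movement_onset_time) & (r.times <= hi)
        predicted.extend(r.predictions[mask])
        actual.extend([r.target_class] * int(mask.sum()))
    confusion = (metrics_mod.confusion_matrix(actual, predicted,
                                              trained["elm"].class_order)
                 if actual else None)

    acc_vals = [v["online_accuracy_pct"] for v in per_class.values()
                if v["online_accuracy_pct"] is not None]
    sel_vals = [r.selection_time for r in records
                if r.completed and r.selection_time is not None]
    comp_vals = [r.completion_time for r in records
                 if r.completed and r.completion_time is not None]
    overall = {
        "online_accuracy_pct": float(np.mean(acc_vals)) if acc_vals else None,
        "selection_time_mean_s": float(np.mean(sel_vals)) if sel_vals else None,
        "completion_time_mean_s": float(np.mean(comp_vals)) if comp_vals else None,
        "completion_rate_pct": metrics_mod.completion_rate(records),
        "n_trials": len(records),
    }
    return {"records": records, "per_class": per_class, "overall": overall,
            "confusion": confusion}


def run_experiment(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured pathways end to end; return (and optionally write)
    the performance report.

    The report contains no timestamps or paths, so identical (config, seed)
    runs serialize to byte-identical JSON.
    """
    config.validate()
    truth, train_session, test_session = prepare_sessions(config)
    train_env = envelope(train_session, mode="offline")

    report: dict = {"seed": config.synth.seed,
                    "config": _plain(config.to_dict()),
                    "pathways": {}}
    artifacts: dict = {}
    for pathway in config.pathways:
        logger.info("training pathway %s", pathway)
        trained = train_pathway(config, pathway, train_env)
        online = evaluate_online(config, pathway, trained, test_session)
        entry = {
            "feature_dim": trained["features"].dim,
            "n_hidden": trained["n_hidden"],
            "cv_accuracy": {str(k): v for k, v in trained["cv_accuracy"].items()},
            "offline_accuracy_pct": trained["offline_accuracy"],
            "confusion_offline_pct": _plain(trained["confusion"].to_numpy()),
            "online": {
                "per_class": _plain(online["per_class"]),
                "overall": _plain(online["overall"]),
                "confusion_pct": (_plain(online["confusion"].to_numpy())
                                  if online["confusion"] is not None else None),
            },
        }
        if pathway == "synergy":
            sm = trained["synergy_model"]
            entry["chosen_k"] = sm.chosen_k
            entry["explained_variance_profile"] = _plain(
                sm.explained_variance_profile)
            entry["residual_r2"] = sm.residual_r2
        report["pathways"][pathway] = entry
        artifacts[pathway] = {"trained": trained, "online": online}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir)
        for pathway in config.pathways:
            trained = artifacts[pathway]["trained"]
            trained["elm"].save(outdir / f"elm_{pathway}.npz")
            if trained["synergy_model"] is not None:
                trained["synergy_model"].save(outdir / "synergy_model.npz")
            trained["confusion"].to_csv(outdir / f"confusion_offline_{pathway}.csv")
    report["_artifacts"] = artifacts
    return report


def report_json(report: dict) -> str:
    """Deterministic JSON serialization (artifacts stripped)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(_plain(clean), sort_keys=True, indent=2)


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write report.json plus per-class polar-plot-ready metric tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(report_json(report) + "\n")

    import pandas as pd

    rows = []
    for pathway, entry in report["pathways"].items():
        for label, m in entry["online"]["per_class"].items():
            rows.append({"pathway": pathway, "class": label,
                         "online_accuracy_pct": m["online_accuracy_pct"],
                         "selection_time_mean_s": m["selection_time_mean_s"],
                         "selection_time_sd_s": m["selection_time_sd_s"],
                         "completion_time_mean_s": m["completion_time_mean_s"],
                         "completion_time_sd_s": m["completion_time_sd_s"],
                         "completion_rate_pct": m["completion_rate_pct"],
                         "variability": m["variability"]})
    pd.DataFrame(rows).to_csv(outdir / "per_class_metrics.csv", index=False)
    return path
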