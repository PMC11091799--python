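"""End-to-end orchestration: audio (or synthetic cohort) to report bundle.

A run walks the full chain: ingest or simulate recordings, extract the 23
per-segment features at the three time scales, pool to recording values,
aggregate to 138-entry participant vectors, run the group statistics, and
fit the nested-CV soft-voting ensembles for the requested classification
tasks and families.  Every numeric output is reproducible from the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import classify as clf
from . import group_stats as gs
from .features import FeatureConfig, extract_all, FEATURE_CODES
from .io_audio import Waveform, preprocess, read_wav, segment, TASKS

log = logging.getLogger(__name__)

CLASS_TASKS = ("multiclass", "g1_vs_g2", "g1_vs_g3")


@dataclass
class RunConfig:
    source: str = "synth_cohort"     # synth_cohort | synth_audio | <manifest.csv>
    segment_lengths: tuple[int, ...] = (5, 10, 15)
    alpha: float = 0.05
    seed: int = 0
    tasks: tuple[str, ...] = ("multiclass",)
    families: tuple[str, ...] = ("logreg",)
    n_per_group: tuple[int, int, int] = (20, 20, 20)
    recording_duration: float = 45.0  # synth_audio only
    n_draws: int = 30                 # randomized-search draws (tree family)
    n_outer: int = 10
    n_inner: int = 10

    def __post_init__(self) -> None:
        if not self.segment_lengths:
            raise ValueError("segment_lengths must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        for t in self.tasks:
            if t not in CLASS_TASKS:
                raise ValueError(f"unknown task {t!r}")


def extract_participant(recordings: dict[str, np.ndarray], participant_id: str,
                        rate: int = 16_000,
                        lengths: tuple[int, ...] = (5, 10, 15),
                        cfg: FeatureConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract all per-segment features for one participant's recordings.

    Returns ``(long, wide)``: the long table has one row per
    (task, length, segment, feature code); the wide table has one row per
    task with the pooled recording values ``F{code}_L{length}``.
    """
    cfg = cfg or FeatureConfig()
    long_rows, wide_rows = [], []
    for task, samples in recordings.items():
        w = preprocess(Waveform(samples, rate, participant_id, task))
        wide: dict[str, object] = {"participant_id": participant_id, "task": task}
        for L in lengths:
            segs = segment(w, L)
            per_code: dict[str, list[float]] = {c: [] for c in FEATURE_CODES}
            for s in segs:
                feats = extract_all(s, cfg)
                for code, val in feats.items():
                    per_code[code].append(val)
                    long_rows.append({"participant_id": participant_id,
                                      "task": task, "length_s": L,
                                      "segment_index": s.origin[2],
                                      "feature_code": code, "value": val})
            for code in FEATURE_CODES:
                wide[f"{code}_L{L}"] = agg.recording_value(per_code[code])
        wide_rows.append(wide)
    return pd.DataFrame(long_rows), pd.DataFrame(wide_rows)


def extract_manifest(manifest: pd.DataFrame,
                     lengths: tuple[int, ...] = (5, 10, 15),
                     cfg: FeatureConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run extraction for a manifest (columns: participant_id, task, path,
    mmse, age, gender, education_years, language).  Missing files are
    collected and reported together."""
    missing = [p for p in manifest["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    longs, wides = [], []
    for pid, grp in manifest.groupby("participant_id", sort=True):
        recs = {row.task: read_wav(row.path, pid, row.task).samples
                for row in grp.itertuples()}
        lo, wi = extract_participant(recs, pid, lengths=lengths, cfg=cfg)
        longs.append(lo)
        wides.append(wi)
    meta_cols = [c for c in ("participant_id", "mmse", "age", "gender",
                             "education_years", "language")
                 if c in manifest.columns]
    meta = manifest[meta_cols].drop_duplicates("participant_id")
    return pd.concat(longs, ignore_index=True), pd.concat(wides, ignore_index=True), meta


def _synth_audio_cohort(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    from .synth import gen_participant_audio, MMSE_RANGES

    rng = np.random.default_rng(config.seed)
    longs, wides, meta_rows = [], [], []
    pid = 0
    for g, n_g in zip((1, 2, 3), config.n_per_group):
        for _ in range(n_g):
            name = f"S{pid:03d}"
            recs = gen_participant_audio(int(rng.integers(2 ** 31)),
                                         duration=config.recording_duration,
                                         group=g)
            lo, wi = extract_participant(
                {t: x for t, (x, _) in recs.items()}, name,
                lengths=config.segment_lengths)
            longs.append(lo)
            wides.append(wi)
            lo_m, hi_m = MMSE_RANGES[g]
            meta_rows.append({"participant_id": name,
                              "mmse": int(rng.integers(lo_m, hi_m + 1)),
                              "age": float(rng.normal(78 + 3 * g, 5)),
                              "gender": "F" if rng.random() < 0.7 else "M",
                              "education_years": int(rng.integers(3, 18)),
                              "language": "italian"})
            pid += 1
    return (pd.concat(longs, ignore_index=True),
            pd.concat(wides, ignore_index=True), pd.DataFrame(meta_rows))


def _task_subset(cohort: pd.DataFrame, task: str) -> pd.DataFrame:
    if task == "multiclass":
        return cohort
    keep = {"g1_vs_g2": (1, 2), "g1_vs_g3": (1, 3)}[task]
    return cohort[cohort["group"].isin(keep)].reset_index(drop=True)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured run and write the report bundle to *outdir*.

    Returns a summary dict with the main computed quantities.  Outputs:
    feature CSVs, aggregation decisions, demographic and per-feature
    statistics CSVs, per task/family evaluation JSONs with confusion and
    ROC tables, and a provenance log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}
    decisions: dict[str, str] = {}
    recording_table = None

    if config.source == "synth_cohort":
        from .synth import CohortSpec, gen_cohort

        cohort, truth = gen_cohort(CohortSpec(n_per_group=config.n_per_group,
                                              seed=config.seed))
    else:
        if config.source == "synth_audio":
            long_df, wide_df, meta = _synth_audio_cohort(config)
        else:
            manifest = pd.read_csv(config.source)
            long_df, wide_df, meta = extract_manifest(
                manifest, lengths=config.segment_lengths)
        long_df.to_csv(outdir / "segment_features.csv", index=False)
        wide_df.to_csv(outdir / "recording_features.csv", index=False)
        recording_table = wide_df
        agg_df, decisions = agg.aggregate_cohort(wide_df, alpha=config.alpha)
        cohort = agg.attach_groups(agg_df, meta)
        (outdir / "aggregation_decisions.json").write_text(
            json.dumps(decisions, indent=1))
    cohort.to_csv(outdir / "cohort.csv", index=False)
    feat_names = [c for c in agg.feature_names() if c in cohort.columns]
    summary["n_participants"] = int(len(cohort))
    summary["n_features"] = len(feat_names)

    demo = gs.demographic_tests(cohort)
    pd.DataFrame([{"variable": r.name, "test": r.test_kind,
                   "statistic": r.statistic, "p": r.omnibus_p}
                  for r in demo]).to_csv(outdir / "demographics.csv", index=False)
    # per-feature gamma comparison on the 15-s location statistics
    loc15 = [f"{c}_L15_loc" for c in FEATURE_CODES if f"{c}_L15_loc" in cohort.columns]
    stats_df = gs.feature_table(cohort, loc15, alpha=config.alpha)
    stats_df.to_csv(outdir / "feature_stats.csv", index=False)
    summary["n_significant_features"] = int((stats_df["omnibus_p"] < config.alpha).sum())

    summary["tasks"] = {}
    for task in config.tasks:
        sub = _task_subset(cohort, task)
        X = sub.set_index("participant_id")[feat_names]
        y = sub["group"].to_numpy()
        fold_accs: dict[str, np.ndarray] = {}
        task_out: dict = {}
        for family in config.families:
            spec = clf.ModelSpec(family=family, seed=config.seed)
            ens, rep = clf.nested_cv(
                X, y, spec, n_outer=config.n_outer, n_inner=config.n_inner,
                n_draws=config.n_draws, recording_table=recording_table,
                alpha=config.alpha)
            fold_accs[family] = rep.val_accuracies
            _write_report(outdir, task, family, rep)
            task_out[family] = {
                "validation": [rep.val_mean, rep.val_sd],
                "test": [rep.test_mean, rep.test_sd],
                "n_members": len(ens.members),
            }
        if len(config.families) > 1:
            comp = clf.compare_classifiers(fold_accs)
            (outdir / f"{task}_classifier_comparison.json").write_text(
                json.dumps(comp, indent=1))
            task_out["comparison"] = comp
        summary["tasks"][task] = task_out

    prov = {"config": asdict(config),
            "config_sha256": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
            "versions": _versions()}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _write_report(outdir: Path, task: str, family: str,
                  rep: "clf.EvalReport") -> None:
    base = f"{task}_{family}"
    payload = {
        "validation_accuracy": {"mean": rep.val_mean, "sd": rep.val_sd,
                                "folds": rep.val_accuracies.tolist()},
        "test_accuracy": {"mean": rep.test_mean, "sd": rep.test_sd,
                          "folds": rep.test_accuracies.tolist()},
        "pooled_accuracy": rep.accuracy,
        "micro_auc": rep.roc["micro_auc"] if rep.roc else None,
        "macro_auc": rep.roc["macro_auc"] if rep.roc else None,
        "top_features": rep.ranking.head(10).to_dict(),
    }
    (outdir / f"{base}_report.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(rep.confusion,
                 index=[f"true_{c}" for c in rep.classes],
                 columns=[f"pred_{c}" for c in rep.classes]
                 ).to_csv(outdir / f"{base}_confusion.csv")
    if rep.roc:
        rows = []
        for c, d in rep.roc["per_class"].items():
            rows += [{"curve": f"class_{c}", "fpr": f, "tpr": t}
                     for f, t in zip(d["fpr"], d["tpr"])]
        fpr_mi, tpr_mi = rep.roc["micro_curve"]
        rows += [{"curve": "micro", "fpr": f, "tpr": t}
                 for f, t in zip(fpr_mi, tpr_mi)]
        pd.DataFrame(rows).to_csv(outdir / f"{base}_roc.csv", index=False)
    rep.ranking.rename("importance").to_csv(outdir / f"{base}_ranking.csv")


def _versions() -> dict:
    import sklearn
    import scipy
    import statsmodels

    from . import __version__

    return {"voicescreen": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "scipy": scipy.__version__, "statsmodels": statsmodels.__version__}
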