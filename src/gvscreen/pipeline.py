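"""End-to-end orchestration: cohort -> features -> model -> SES -> statistics.

These functions are the programmatic core behind the CLI; they work both on
in-memory :class:`~gvscreen.simulate.Cohort` objects and on session
directories read back from disk.
"""
from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import features as feat
from . import model as mdl
from . import ranking, stats
from .features import (BIOMARKER_ABBREV, BiomarkerConfig, CENTRAL_CHANNELS,
                       DEFAULT_CONFIG, N_BIOMARKERS)
from .simulate import Cohort
from .stimuli import StimulusSpec, sham_spec

INTERVALS = ("pre", "stim", "post")


def _subject_groups(source) -> dict[str, str]:
    if isinstance(source, Cohort):
        return {p.subject_id: p.group for p in source.profiles}
    return dict(zip(source.subjects["subject_id"], source.subjects["group"]))


def subject_burst_thresholds(source, subject_id: str,
                             central_channels=CENTRAL_CHANNELS,
                             cfg: BiomarkerConfig = DEFAULT_CONFIG
                             ) -> dict[str, float]:
    """Per-channel burst thresholds from the subject's pooled pre windows."""
    chans = list(central_channels)
    if isinstance(source, Cohort):
        n_trials = len(source.trial_order(subject_id))
        pre = np.stack([source.pre_window(subject_id, t, chans)
                        for t in range(n_trials)])
        fs = source.config.fs
    else:
        wins, fs = [], None
        for trial in source.iter_trials(subject_id):
            idx = [trial.channel_names.index(c) for c in chans]
            wins.append(feat.segment_trial(trial.data, trial.fs)["pre"][0][idx])
            fs = trial.fs
        pre = np.stack(wins)
    thr = feat.burst_thresholds_from_pre_windows(pre, fs, cfg)
    return dict(zip(chans, thr))


def extract_features_table(source, central_channels=CENTRAL_CHANNELS,
                           cfg: BiomarkerConfig = DEFAULT_CONFIG,
                           subject_ids: Iterable[str] | None = None
                           ) -> pd.DataFrame:
    """Long-format feature table: one row per (subject, stimulus, interval).

    Columns: subject_id, group, stim_id, interval, then the 16 biomarkers
    under their standard abbreviations.
    """
    groups = _subject_groups(source)
    ids = list(subject_ids) if subject_ids is not None else list(groups)
    rows = []
    for subject_id in ids:
        thr = subject_burst_thresholds(source, subject_id, central_channels, cfg)
        for trial in source.iter_trials(subject_id):
            tf = feat.extract_features(trial, thr, central_channels, cfg)
            for interval in INTERVALS:
                vec = getattr(tf, interval).to_array()
                rows.append([subject_id, groups[subject_id], trial.stim_id,
                             interval, *vec])
    cols = ["subject_id", "group", "stim_id", "interval", *BIOMARKER_ABBREV]
    return pd.DataFrame(rows, columns=cols)


def prestim_feature_table(cohort: Cohort, central_channels=CENTRAL_CHANNELS,
                          cfg: BiomarkerConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Pre-stimulation-interval features only, without materializing full
    trials.  Pre segments are regenerated from their own child seeds, so the
    values are bit-identical to what full-trial extraction would produce."""
    chans = list(central_channels)
    groups = _subject_groups(cohort)
    rows = []
    fs = cohort.config.fs
    for subject_id in cohort.subject_ids:
        order = cohort.trial_order(subject_id)
        pre = np.stack([cohort.pre_window(subject_id, t, chans)
                        for t in range(len(order))])
        thr = feat.burst_thresholds_from_pre_windows(pre, fs, cfg)
        n_tr, n_ch, n = pre.shape
        block = feat.compute_block(pre.reshape(n_tr * n_ch, n), fs,
                                   np.tile(thr, n_tr), cfg)
        vecs = block.reshape(n_tr, n_ch, N_BIOMARKERS).mean(axis=1)
        for stim_id, vec in zip(order, vecs):
            rows.append([subject_id, groups[subject_id], stim_id, "pre", *vec])
    cols = ["subject_id", "group", "stim_id", "interval", *BIOMARKER_ABBREV]
    return pd.DataFrame(rows, columns=cols)


def prestim_feature_arrays(table: pd.DataFrame, interval: str = "pre"
                           ) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """(subject_ids, groups, stim_ids, features (n_subj, n_trials, 16)) for
    one interval, trials ordered by stim_id within each subject."""
    sub = table[table["interval"] == interval].sort_values(
        ["subject_id", "stim_id"], kind="stable")
    subject_ids = sorted(sub["subject_id"].unique())
    stim_ids = np.sort(sub["stim_id"].unique())
    groups, mats = [], []
    for s in subject_ids:
        block = sub[sub["subject_id"] == s]
        if not np.array_equal(block["stim_id"].to_numpy(), stim_ids):
            raise ValueError(f"subject {s} is missing trials")
        groups.append(str(block["group"].iloc[0]))
        mats.append(block[list(BIOMARKER_ABBREV)].to_numpy(dtype=float))
    return subject_ids, groups, stim_ids, np.stack(mats)


def train_composite(table: pd.DataFrame, **kwargs) -> mdl.CompositeModel:
    subject_ids, groups, _, F = prestim_feature_arrays(table, "pre")
    return mdl.train_loso_lasso(F, subject_ids, groups, **kwargs)


def score_table(model: mdl.CompositeModel, table: pd.DataFrame) -> pd.DataFrame:
    """Composite score per (subject, stimulus, interval)."""
    X = table[list(BIOMARKER_ABBREV)].to_numpy(dtype=float)
    out = table[["subject_id", "group", "stim_id", "interval"]].copy()
    out["score"] = model.score(X)
    return out


def interval_accuracies(model: mdl.CompositeModel,
                        table: pd.DataFrame) -> dict[str, float]:
    by_interval = {}
    subject_ids = groups = None
    for interval in INTERVALS:
        subject_ids, groups, _, F = prestim_feature_arrays(table, interval)
        by_interval[interval] = F
    return mdl.interval_accuracy(model, by_interval, subject_ids, groups)


def distance_matrix(scores: pd.DataFrame, reference: float,
                    interval: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(dist (n_stim, n_pd), stim_ids, pd_subject_ids) for one interval."""
    sub = scores[(scores["interval"] == interval) & (scores["group"] == "PD")]
    pivot = sub.pivot(index="stim_id", columns="subject_id", values="score")
    if pivot.isna().any().any():
        raise ValueError("missing PD trial scores")
    dist = mdl.distances(pivot.to_numpy(), reference)
    return dist, pivot.index.to_numpy(), list(pivot.columns)


def analyze(table: pd.DataFrame, library: list[StimulusSpec],
            q_threshold: float = 0.1, epsilon: float = ranking.EPSILON,
            normalization: str = "vector") -> dict:
    """Full analysis from a feature table: model, scores, SES and group stats
    for the stimulation interval plus the post-stimulation control run."""
    model = train_composite(table)
    scores = score_table(model, table)
    hc_pre = scores[(scores["group"] == "HC") & (scores["interval"] == "pre")]
    reference = mdl.healthy_reference(hc_pre["score"].to_numpy())

    results: dict = {
        "model": model,
        "scores": scores,
        "reference": reference,
        "accuracy": interval_accuracies(model, table),
        "intervals": {},
    }
    present = set(scores["stim_id"].astype(int))
    lib_used = [s for s in library if s.stim_id in present]
    for interval in ("stim", "post"):
        dist, stim_ids, pd_subjects = distance_matrix(scores, reference,
                                                      interval)
        ses = ranking.ses_table(dist, stim_ids, pd_subjects, epsilon,
                                normalization)
        ranks = stats.subject_ranks(dist)
        medians = stats.median_ranks_by_category(ranks, stim_ids, lib_used)
        w, chi2, w_p = stats.kendalls_w(medians.to_numpy())
        global_rank = ses["rank"].to_numpy()
        cats = stats.category_wilcoxon(global_rank, stim_ids, lib_used,
                                       q_threshold)
        results["intervals"][interval] = {
            "distances": dist,
            "stim_ids": stim_ids,
            "pd_subjects": pd_subjects,
            "ses": ses,
            "subject_ranks": ranks,
            "median_ranks": medians,
            "kendall_w": w, "kendall_chi2": chi2, "kendall_p": w_p,
            "categories": cats,
        }
    stim_ses = results["intervals"]["stim"]["ses"]
    post_ses = results["intervals"]["post"]["ses"]
    merged = stim_ses.merge(post_ses, on="stim_id", suffixes=("_stim", "_post"))
    rho, p = stats.spearman_ses(merged["ses_stim"].to_numpy(),
                                merged["ses_post"].to_numpy())
    results["spearman_rho"] = rho
    results["spearman_p"] = p
    try:
        sham_id = sham_spec(library).stim_id
        ses = results["intervals"]["stim"]["ses"]
        row = ses[ses["stim_id"] == sham_id]
        results["sham_rank"] = float(row["rank"].iloc[0]) if not row.empty else None
    except ValueError:
        results["sham_rank"] = None
    return results


def channel_map_values(cohort: Cohort, categories: set[int],
                       intervals=("pre", "stim", "post"),
                       cfg: BiomarkerConfig = DEFAULT_CONFIG) -> dict:
    """Per-channel RelBetaPower/PTAsym values on trials of the selected
    stimulus categories, paired by trial and pooled within group.

    Returns {group: {biomarker: {interval: (n_trials, n_channels)}}}.
    """
    cat_by_stim = {s.stim_id: s.category_id for s in cohort.library}
    groups = _subject_groups(cohort)
    out: dict = {}
    for subject_id in cohort.subject_ids:
        order = cohort.trial_order(subject_id)
        for trial_idx, stim_id in enumerate(order):
            if cat_by_stim[stim_id] not in categories:
                continue
            trial = cohort.trial_at(subject_id, trial_idx)
            metrics = feat.channelwise_metrics(trial, cfg, intervals)
            g = out.setdefault(groups[subject_id], {})
            for bm in ("RelBetaPower", "PTAsym"):
                b = g.setdefault(bm, {iv: [] for iv in intervals})
                for iv in intervals:
                    b[iv].append(metrics[iv][bm])
    return {
        grp: {bm: {iv: np.stack(rows) for iv, rows in per_iv.items()}
              for bm, per_iv in per_bm.items()}
        for grp, per_bm in out.items()
    }


def channel_maps(cohort: Cohort, categories: set[int],
                 intervals=("pre", "stim", "post"),
                 cfg: BiomarkerConfig = DEFAULT_CONFIG) -> list:
    """Paired-t q-value channel maps (one per biomarker/group/comparison)."""
    values = channel_map_values(cohort, categories, intervals, cfg)
    pairs = [(a, b) for a, b in (("pre", "stim"), ("stim", "post"),
                                 ("pre", "post"))
             if a in intervals and b in intervals]
    maps = []
    for grp, per_bm in sorted(values.items()):
        for bm, per_iv in sorted(per_bm.items()):
            maps.extend(stats.interval_ttest_maps(
                per_iv, list(cohort.config.channel_names), bm, grp, pairs))
    return maps


def summarize(results: dict, library: list[StimulusSpec],
              truth: pd.DataFrame | None = None) -> dict:
    """JSON-serializable run summary (the CLI report)."""
    stim_res = results["intervals"]["stim"]
    post_res = results["intervals"]["post"]
    sig = stim_res["categories"]
    summary = {
        "accuracy": results["accuracy"],
        "reference": results["reference"],
        "kendall_w": {"stim": stim_res["kendall_w"],
                      "post": post_res["kendall_w"]},
        "kendall_p": {"stim": stim_res["kendall_p"],
                      "post": post_res["kendall_p"]},
        "spearman_rho": results["spearman_rho"],
        "spearman_p": results["spearman_p"],
        "sham_rank": results["sham_rank"],
        "significant_categories": {
            "stim": sig[sig["significant"]]["category_id"].tolist(),
            "post": post_res["categories"][
                post_res["categories"]["significant"]]["category_id"].tolist(),
        },
        "top_50": stim_res["ses"].sort_values("rank").head(50)
                  ["stim_id"].astype(int).tolist(),
    }
    if truth is not None:
        planted = sorted(truth[truth["delta"] > 0]["category_id"].unique()
                         .tolist())
        found = summary["significant_categories"]["stim"]
        summary["planted_categories"] = planted
        summary["planted_recovered"] = sorted(found) == planted
    return summary
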