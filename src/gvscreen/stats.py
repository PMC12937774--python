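"""Category-level inference: per-subject ranks, Kendall's W, one-tailed
rank-sum tests with BH-FDR, Spearman interval check, and per-channel paired-t
q-value maps."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .stimuli import StimulusSpec, nonsingleton_categories


def subject_ranks(dist: np.ndarray) -> np.ndarray:
    """Per-subject (column) ranks of the distance matrix; rank 1 = smallest
    distance, ties averaged."""
    d = np.asarray(dist, dtype=float)
    return np.column_stack([rankdata(d[:, j]) for j in range(d.shape[1])])


def median_ranks_by_category(ranks: np.ndarray, stim_ids: np.ndarray,
                             library: list[StimulusSpec]) -> pd.DataFrame:
    """Median rank per (category, subject); singleton categories excluded.

    Returns a DataFrame indexed by category_id with one column per subject
    position (0..n_subj-1).
    """
    cat_by_stim = {s.stim_id: s.category_id for s in library}
    cats = nonsingleton_categories(library)
    stim_ids = np.asarray(stim_ids)
    rows = {}
    for cat in cats:
        mask = np.array([cat_by_stim[int(s)] == cat for s in stim_ids])
        if not mask.any():
            raise ValueError(f"category {cat} has no member stimuli")
        rows[cat] = np.median(ranks[mask], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(range(ranks.shape[1])))


def kendalls_w(medians: np.ndarray) -> tuple[float, float, float]:
    """Tie-corrected Kendall's coefficient of concordance.

    ``medians`` is (k items, m raters); each rater's values are ranked
    internally (ties averaged).  Returns (W, chi2, p) with the chi-square
    approximation on k-1 degrees of freedom.
    """
    x = np.asarray(medians, dtype=float)
    k, m = x.shape
    if k < 3:
        raise ValueError("Kendall's W needs at least 3 items")
    if m < 2:
        raise ValueError("Kendall's W needs at least 2 raters")
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(m)])
    rank_sums = ranks.sum(axis=1)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    tie_term = 0.0
    for j in range(m):
        _, counts = np.unique(ranks[:, j], return_counts=True)
        tie_term += float(np.sum(counts.astype(float) ** 3 - counts))
    denom = m * m * (k ** 3 - k) - m * tie_term
    if denom <= 0:
        return 0.0, 0.0, 1.0
    w = 12.0 * s / denom
    chi2 = m * (k - 1) * w
    p = float(sps.chi2.sf(chi2, k - 1))
    return float(w), float(chi2), p


def bh_fdr(p_values: np.ndarray, q_threshold: float = 0.1
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q values, rejection mask at q_threshold)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # <= so the rejection set coincides with the classic step-up rule
    return q, q <= q_threshold


def category_wilcoxon(stim_ranks: np.ndarray, stim_ids: np.ndarray,
                      library: list[StimulusSpec],
                      q_threshold: float = 0.1) -> pd.DataFrame:
    """One-tailed (less) rank-sum test of each retained category's global
    SES-derived ranks against the pooled ranks of all other stimuli, with
    BH-FDR across categories."""
    cat_by_stim = {s.stim_id: s.category_id for s in library}
    label_by_cat = {s.category_id: s.category_label for s in library}
    cats = nonsingleton_categories(library)
    stim_ids = np.asarray(stim_ids)
    ranks = np.asarray(stim_ranks, dtype=float)
    rows = []
    for cat in cats:
        mask = np.array([cat_by_stim[int(s)] == cat for s in stim_ids])
        member, rest = ranks[mask], ranks[~mask]
        if rest.size == 0:
            raise ValueError("cannot test a category against an empty pool")
        # exact when feasible, otherwise normal approximation with tie and
        # continuity corrections
        res = sps.mannwhitneyu(member, rest, alternative="less",
                               method="auto")
        rows.append((cat, label_by_cat[cat], int(mask.sum()),
                     float(np.median(member)), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["category_id", "category_label", "size",
                                     "median_rank", "p"])
    q, sig = bh_fdr(df["p"].to_numpy(), q_threshold)
    df["q"] = q
    df["significant"] = sig
    return df


def spearman_ses(ses_a: np.ndarray, ses_b: np.ndarray) -> tuple[float, float]:
    """Spearman correlation between two SES vectors (two-sided p)."""
    a = np.asarray(ses_a, dtype=float)
    b = np.asarray(ses_b, dtype=float)
    if a.size != b.size:
        raise ValueError("SES vectors must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


@dataclass
class ChannelMap:
    biomarker: str
    group: str
    comparison: str  # e.g. "pre-vs-stim"
    channels: list[str]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray

    @property
    def neglog10_q(self) -> np.ndarray:
        return -np.log10(np.maximum(self.q, 1e-300))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "biomarker": self.biomarker, "group": self.group,
            "comparison": self.comparison, "channel": self.channels,
            "t": self.t, "p": self.p, "q": self.q,
            "neglog10_q": self.neglog10_q,
        })


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def interval_ttest_maps(values: dict[str, np.ndarray], channels: list[str],
                        biomarker: str, group: str,
                        comparisons=(("pre", "stim"), ("stim", "post"),
                                     ("pre", "post"))) -> list[ChannelMap]:
    """Per-channel paired t-tests between interval pairs.

    ``values`` maps interval -> (n_trials, n_channels) biomarker values,
    paired by trial.  BH-FDR is applied within each 36-channel map.
    """
    n_trials = next(iter(values.values())).shape[0]
    if n_trials < 3:
        raise ValueError("paired t maps need at least 3 trials")
    maps = []
    for ia, ib in comparisons:
        a, b = np.asarray(values[ia]), np.asarray(values[ib])
        tp = [_paired_t(a[:, c], b[:, c]) for c in range(len(channels))]
        t = np.array([x[0] for x in tp])
        p = np.array([x[1] for x in tp])
        q, _ = bh_fdr(p, 0.05)
        maps.append(ChannelMap(biomarker=biomarker, group=group,
                               comparison=f"{ia}-vs-{ib}",
                               channels=list(channels), t=t, p=p, q=q))
    return maps
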