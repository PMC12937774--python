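"""TOPSIS-style Stimulus Evaluation Score (SES) over the inverse-distance
decision matrix, and the global stimulus ranking."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EPSILON = 1e-9


def decision_matrix(dist: np.ndarray, epsilon: float = EPSILON) -> np.ndarray:
    """Inverse distances 1/(dist + epsilon); larger is better."""
    dist = np.asarray(dist, dtype=float)
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")
    return 1.0 / (dist + epsilon)


def normalize_columns(matrix: np.ndarray, method: str = "vector") -> np.ndarray:
    """Per-subject (column) normalization of the decision matrix."""
    m = np.asarray(matrix, dtype=float)
    if method == "vector":
        norms = np.linalg.norm(m, axis=0)
        if (norms == 0).any():
            raise ValueError("cannot normalize an all-zero column")
        return m / norms
    if method == "minmax":
        lo, hi = m.min(axis=0), m.max(axis=0)
        span = hi - lo
        if (span == 0).any():
            raise ValueError("cannot min-max normalize a constant column")
        return (m - lo) / span
    if method == "sum":
        s = m.sum(axis=0)
        if (s == 0).any():
            raise ValueError("cannot sum-normalize an all-zero column")
        return m / s
    raise ValueError(f"unknown normalization method: {method!r}")


def topsis_ses(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ses, d_ideal, d_anti): relative closeness to the per-column ideal
    (max) vs anti-ideal (min) under equal criterion weights."""
    m = np.asarray(normalized, dtype=float)
    ideal = m.max(axis=0)
    anti = m.min(axis=0)
    d_ideal = np.linalg.norm(m - ideal, axis=1)
    d_anti = np.linalg.norm(m - anti, axis=1)
    denom = d_ideal + d_anti
    ses = np.divide(d_anti, denom, out=np.full(m.shape[0], 0.5),
                    where=denom > 0)
    return ses, d_ideal, d_anti


def rank_stimuli(ses: np.ndarray) -> np.ndarray:
    """Rank 1 = highest SES; ties get averaged ranks."""
    ses = np.asarray(ses, dtype=float)
    return rankdata(-ses, method="average")


def ses_table(dist: np.ndarray, stim_ids: np.ndarray,
              subject_ids: list[str], epsilon: float = EPSILON,
              normalization: str = "vector") -> pd.DataFrame:
    """Full SES pipeline: (n_stim, n_subj) distances -> SES table."""
    inv = decision_matrix(dist, epsilon)
    norm = normalize_columns(inv, normalization)
    ses, d_ideal, d_anti = topsis_ses(norm)
    df = pd.DataFrame({"stim_id": np.asarray(stim_ids),
                       "ses": ses, "rank": rank_stimuli(ses),
                       "d_ideal": d_ideal, "d_anti": d_anti})
    for j, subj in enumerate(subject_ids):
        df[f"norm_{subj}"] = norm[:, j]
    return df


def top_ranked_report(df: pd.DataFrame, n: int = 50) -> str:
    """Plain-text ranked list of the top-n stimuli."""
    top = df.sort_values("rank").head(n)
    lines = [f"{'rank':>5}  {'stim_id':>7}  {'SES':>8}"]
    lines += [f"{int(r['rank']):>5}  {int(r['stim_id']):>7}  {r['ses']:8.4f}"
              for _, r in top.iterrows()]
    return "\n".join(lines)
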