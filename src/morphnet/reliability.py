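"""Test-retest reliability via one-way random-effects intraclass correlation.

For each measured quantity (a connection's KLS value, a global metric AUC,
a nodal centrality AUC) the subjects x sessions table is decomposed by
one-way ANOVA into between-subject (MS_b) and within-subject (MS_w) mean
squares, and

    ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w)

with k repeated sessions per subject. ICC approaches 1 when within-subject
variance is small relative to between-subject variance. Values are binned
into poor / low / fair / good / excellent reliability categories; negative
estimates are reported as computed but labeled "nonpositive" since the
categories start at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError, UndefinedICCError
from .graph import hub_score
from .similarity import SimilarityMatrix

#: category lower bounds; a boundary value falls in the upper category
CATEGORY_BINS = (
    (0.75, "excellent"),
    (0.60, "good"),
    (0.40, "fair"),
    (0.25, "low"),
    (0.00, "poor"),
)

CATEGORY_NAMES = ("nonpositive", "poor", "low", "fair", "good", "excellent")


def icc_category(icc: float) -> str:
    if not np.isfinite(icc) or icc <= 0:
        return "nonpositive"
    for lower, name in CATEGORY_BINS:
        if icc >= lower:
            return name
    return "nonpositive"  # pragma: no cover


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_between: float
    ms_within: float
    k: int
    category: str


def icc_oneway(table: np.ndarray) -> ICCResult:
    """One-way random-effects ICC of a subjects x sessions table.

    Requires at least 2 subjects, k >= 2 sessions and finite values; a
    table with zero total variance raises :class:`UndefinedICCError`.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x sessions)")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {table.shape}")
    if not np.all(np.isfinite(table)):
        raise ValueError("table contains non-finite values")
    grand = table.mean()
    subj_means = table.mean(axis=1)
    ss_between = k * np.sum((subj_means - grand) ** 2)
    ss_within = np.sum((table - subj_means[:, None]) ** 2)
    if ss_between + ss_within <= 0:
        raise UndefinedICCError("total variance is zero; ICC undefined")
    ms_b = ss_between / (n - 1)
    ms_w = ss_within / (n * (k - 1))
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    return ICCResult(
        icc=float(icc),
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        k=k,
        category=icc_category(float(icc)),
    )


def elementwise_icc(
    matrices: dict[tuple[str, str], SimilarityMatrix | np.ndarray],
) -> tuple[np.ndarray, dict]:
    """ICC of every connection across subjects and sessions.

    ``matrices`` maps (subject_id, session_id) to an N x N similarity
    matrix; every subject must have the same sessions. Returns a symmetric
    ICC matrix (NaN diagonal; NaN where the ICC is undefined) and a summary
    with mean, SD, and the fraction of connections per reliability
    category.
    """
    subjects = sorted({s for s, _ in matrices})
    sessions = sorted({t for _, t in matrices})
    if len(subjects) < 2 or len(sessions) < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    arrays = {}
    for key, m in matrices.items():
        arrays[key] = m.kls if isinstance(m, SimilarityMatrix) else np.asarray(m, dtype=float)
    n = next(iter(arrays.values())).shape[0]
    stack = np.empty((len(subjects), len(sessions), n, n))
    for si, s in enumerate(subjects):
        for ti, t in enumerate(sessions):
            if (s, t) not in arrays:
                raise ValueError(f"missing matrix for subject {s}, session {t}")
            stack[si, ti] = arrays[(s, t)]

    icc_mat = np.full((n, n), np.nan)
    iu = np.triu_indices(n, k=1)
    for i, j in zip(iu[0], iu[1], strict=True):
        try:
            icc_mat[i, j] = icc_mat[j, i] = icc_oneway(stack[:, :, i, j]).icc
        except UndefinedICCError:
            pass
    vals = icc_mat[iu]
    valid = vals[np.isfinite(vals)]
    categories = [icc_category(v) for v in valid]
    summary = {
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
        "n_connections": int(vals.size),
        "fraction_per_category": {
            name: categories.count(name) / max(len(categories), 1) for name in CATEGORY_NAMES
        },
    }
    return icc_mat, summary


def metric_icc(values: dict[tuple[str, str], float]) -> ICCResult:
    """ICC of one scalar metric given per-(subject, session) values."""
    subjects = sorted({s for s, _ in values})
    sessions = sorted({t for _, t in values})
    table = np.array([[values[(s, t)] for t in sessions] for s in subjects])
    return icc_oneway(table)


def centrality_reliability_correlation(
    centrality: np.ndarray, icc_values: np.ndarray
) -> dict[str, float]:
    """Pearson correlation between nodal centrality and its reliability."""
    x = np.asarray(centrality, dtype=float)
    y = np.asarray(icc_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite node values")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("a vector has zero variance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}


def reliability_hub_score(
    icc_maps: list[np.ndarray] | dict[str, np.ndarray],
    top_fraction: float = 0.10,
    score_threshold: int = 3,
) -> dict:
    """Hub-score mechanics applied to nodal ICC maps.

    Flags, per map, the top-10% most reliable nodes and counts per node
    how many maps flag it; nodes scoring above ``score_threshold`` are the
    consistently reliable regions.
    """
    return hub_score(icc_maps, top_fraction=top_fraction, score_threshold=score_threshold)
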