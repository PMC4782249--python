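"""Symmetric KL divergence similarity (KLS) and connectivity matrices.

Morphological connectivity between two regions of one subject is the
similarity of their gray-matter value distributions:

    D(P, Q) = sum_i P(i) log(P(i)/Q(i)) + Q(i) log(Q(i)/P(i))
    KLS(P, Q) = exp(-D(P, Q))

with natural logarithms, so KLS lies in (0, 1] and equals 1 exactly when
the two discretized distributions coincide. Self-connections are set to 0
in the assembled matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .density import DEFAULT_N_GRID, RegionalDistribution, estimate_pmf, select_bandwidth
from .errors import DegenerateRegionError, GridAlignmentError, MorphnetError
from .image_io import AtlasParcellation, GMVolumeMap, extract_all_regions

logger = logging.getLogger(__name__)

#: probability floor applied before taking log ratios; log(p/q) is undefined
#: at exact zeros, so both pmfs are floored here and renormalized
DEFAULT_PMF_FLOOR = 1e-12


@dataclass
class SimilarityMatrix:
    """N x N symmetric KLS matrix with zero diagonal."""

    kls: np.ndarray
    region_ids: list[int]
    subject_id: str = ""
    session_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.kls, dtype=float)
        n = len(self.region_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} region ids")
        if not np.array_equal(m, m.T):
            raise ValueError("KLS matrix must be exactly symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("self-connections must be 0")
        off = m[~np.eye(n, dtype=bool)]
        if off.size and (np.any(off <= 0) or np.any(off > 1.0 + 1e-12)):
            raise ValueError("off-diagonal KLS entries must lie in (0, 1]")
        self.kls = m

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.kls[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.kls, index=self.region_ids, columns=self.region_ids)


# ---------------------------------------------------------------------------
# divergence kernel
# ---------------------------------------------------------------------------


def _prepare_pair(
    p: RegionalDistribution | np.ndarray,
    q: RegionalDistribution | np.ndarray,
    floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, RegionalDistribution) and isinstance(q, RegionalDistribution):
        if p.n != q.n or not np.allclose(p.grid, q.grid, rtol=0, atol=1e-9):
            raise GridAlignmentError("distributions are not on a common grid")
        pv, qv = p.pmf, q.pmf
    else:
        pv = np.asarray(p, dtype=float)
        qv = np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise GridAlignmentError("pmf vectors have different lengths")
    pv = np.clip(pv, floor, None)
    qv = np.clip(qv, floor, None)
    return pv / pv.sum(), qv / qv.sum()


def kl_symmetric(
    p: RegionalDistribution | np.ndarray,
    q: RegionalDistribution | np.ndarray,
    floor: float = DEFAULT_PMF_FLOOR,
) -> float:
    """Symmetrized KL divergence D(P,Q) = D_KL(P||Q) + D_KL(Q||P).

    Nonnegative, symmetric in its arguments, and zero iff the two pmfs are
    equal. Both pmfs are floored at ``floor`` and renormalized first.
    """
    pv, qv = _prepare_pair(p, q, floor)
    log_ratio = np.log(pv) - np.log(qv)
    return float(np.sum(pv * log_ratio) - np.sum(qv * log_ratio))


def kls(
    p: RegionalDistribution | np.ndarray,
    q: RegionalDistribution | np.ndarray,
    floor: float = DEFAULT_PMF_FLOOR,
) -> float:
    """KL-divergence-based similarity exp(-D(P,Q)) in (0, 1]."""
    return float(np.exp(-kl_symmetric(p, q, floor=floor)))


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------


def similarity_matrix_from_values(
    values_by_region: dict[int, np.ndarray],
    n_grid: int = DEFAULT_N_GRID,
    common_support_policy: str = "pairwise",
    floor: float = DEFAULT_PMF_FLOOR,
    subject_id: str = "",
    session_id: str = "",
    provenance: dict | None = None,
) -> SimilarityMatrix:
    """Assemble the KLS matrix from per-region value vectors.

    For each unordered region pair both densities are (re-)evaluated on one
    shared uniform grid before the divergence is taken:

    * ``pairwise`` (default) — the grid spans the union of the two regions'
      value ranges, each extended by 3 bandwidths;
    * ``global`` — a single grid spanning all regions' ranges is used for
      every pair (each region's density then needs evaluating only once).

    Each region keeps its own automatically selected bandwidth in either
    policy. The diagonal is set to 0.
    """
    if common_support_policy not in ("pairwise", "global"):
        raise ValueError(f"unknown common_support_policy {common_support_policy!r}")
    region_ids = sorted(int(r) for r in values_by_region)
    n = len(region_ids)
    bw: dict[int, float] = {}
    rng_lo: dict[int, float] = {}
    rng_hi: dict[int, float] = {}
    for rid in region_ids:
        vals = np.asarray(values_by_region[rid], dtype=float)
        try:
            bw[rid] = select_bandwidth(vals, n_grid)
        except MorphnetError as exc:
            raise DegenerateRegionError(f"region {rid}: {exc}") from exc
        rng_lo[rid] = vals.min() - 3.0 * bw[rid]
        rng_hi[rid] = vals.max() + 3.0 * bw[rid]

    m = np.zeros((n, n), dtype=float)
    if common_support_policy == "global":
        lo = min(rng_lo.values())
        hi = max(rng_hi.values())
        dists = {
            rid: estimate_pmf(
                values_by_region[rid], n_grid, support=(lo, hi),
                bandwidth=bw[rid], region_id=rid,
            )
            for rid in region_ids
        }
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = kls(dists[region_ids[i]], dists[region_ids[j]], floor=floor)
    else:
        for i in range(n):
            ri = region_ids[i]
            for j in range(i + 1, n):
                rj = region_ids[j]
                support = (min(rng_lo[ri], rng_lo[rj]), max(rng_hi[ri], rng_hi[rj]))
                p = estimate_pmf(
                    values_by_region[ri], n_grid, support=support,
                    bandwidth=bw[ri], region_id=ri,
                )
                q = estimate_pmf(
                    values_by_region[rj], n_grid, support=support,
                    bandwidth=bw[rj], region_id=rj,
                )
                m[i, j] = m[j, i] = kls(p, q, floor=floor)

    prov = dict(provenance or {})
    prov.setdefault("n_grid", n_grid)
    prov.setdefault("common_support_policy", common_support_policy)
    return SimilarityMatrix(
        kls=m,
        region_ids=region_ids,
        subject_id=subject_id,
        session_id=session_id,
        provenance=prov,
    )


def build_similarity_matrix(
    gm_map: GMVolumeMap,
    atlas: AtlasParcellation,
    n_grid: int = DEFAULT_N_GRID,
    common_support_policy: str = "pairwise",
    positive_only: bool = True,
    min_voxels: int = 10,
    smoothed: bool = False,
) -> SimilarityMatrix:
    """KLS connectivity matrix of one GM map under one parcellation."""
    values = extract_all_regions(
        gm_map, atlas, positive_only=positive_only, min_voxels=min_voxels
    )
    return similarity_matrix_from_values(
        values,
        n_grid=n_grid,
        common_support_policy=common_support_policy,
        subject_id=gm_map.subject_id,
        session_id=gm_map.session_id,
        provenance={"atlas": atlas.name, "smoothed": smoothed},
    )


# ---------------------------------------------------------------------------
# matrix-level analyses
# ---------------------------------------------------------------------------


def homotopic_contrast(
    m: SimilarityMatrix,
    atlas: AtlasParcellation,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Are homotopic (mirror-pair) connections stronger than the rest?

    Compares the KLS entries of homotopic pairs against all remaining
    off-diagonal entries with a Welch t statistic; the p-value comes from a
    label-shuffling permutation test (two-sided) on the same statistic.
    """
    pairs = atlas.homotopic_pairs
    if len(pairs) < 1:
        raise ValueError("atlas defines no homotopic pairs")
    index = {rid: i for i, rid in enumerate(m.region_ids)}
    iu = np.triu_indices(m.n_regions, k=1)
    values = m.kls[iu]
    pair_set = {(min(index[a], index[b]), max(index[a], index[b])) for a, b in pairs}
    is_homotopic = np.array(
        [(i, j) in pair_set for i, j in zip(iu[0], iu[1], strict=True)]
    )
    homo = values[is_homotopic]
    other = values[~is_homotopic]
    if other.size == 0:
        raise ValueError("no non-homotopic connections to compare against")

    def welch(x: np.ndarray, y: np.ndarray) -> float:
        vx = x.var(ddof=1) if x.size > 1 else 0.0
        vy = y.var(ddof=1) if y.size > 1 else 0.0
        denom = np.sqrt(vx / x.size + vy / y.size)
        if denom == 0:
            return 0.0
        return float((x.mean() - y.mean()) / denom)

    t_obs = welch(homo, other)
    rng = np.random.default_rng(seed)
    count = 0
    n_h = homo.size
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if abs(welch(perm[:n_h], perm[n_h:])) >= abs(t_obs) - 1e-15:
            count += 1
    return {
        "mean_homotopic": float(homo.mean()),
        "mean_other": float(other.mean()),
        "statistic": t_obs,
        "p": count / n_perm,
        "n_homotopic": int(n_h),
    }


def matrix_correlation(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Pearson correlation of the two matrices' upper-triangle entries."""
    if a.region_ids != b.region_ids:
        raise ValueError("matrices have different region orderings")
    x, y = a.upper_values(), b.upper_values()
    if x.size < 2:
        raise ValueError("need at least two off-diagonal entries")
    return float(stats.pearsonr(x, y)[0])
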