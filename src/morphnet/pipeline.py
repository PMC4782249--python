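"""Full factorial study driver: {smoothing} x {atlas} x {network type}.

``run_study`` walks every subject/session map through smoothing (on and
off), similarity-matrix construction under each atlas, metric curves and
AUCs for binary and weighted networks, hub scoring, and — when two or more
sessions are present — intersession matrix correlations, elementwise and
metric-level ICC, and reliability hub scores. Every tabular output carries
the configuration hash and master seed so a run can be reproduced bit for
bit; a failing subject is logged and skipped without aborting the study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph, reliability, similarity
from .image_io import AtlasParcellation, GMVolumeMap, smooth_gm_map

logger = logging.getLogger(__name__)

SMOOTHING_LEVELS = ("nosmo", "smo")


@dataclass
class RunConfig:
    """Everything a study run depends on."""

    maps: dict[tuple[str, str], GMVolumeMap]
    atlases: dict[str, AtlasParcellation]
    smoothing: tuple[str, ...] = SMOOTHING_LEVELS
    fwhm_mm: float = 6.0
    n_grid: int = 128
    sparsities: tuple[float, ...] = graph.DEFAULT_SPARSITIES
    network_types: tuple[str, ...] = graph.NETWORK_TYPES
    n_null: int = 0
    normalize_at: float | None = None
    n_perm: int = 10000
    seed: int = 0
    out_dir: Path | None = None
    resume: bool = False

    def __post_init__(self) -> None:
        if not self.atlases:
            raise ValueError("at least one atlas is required")
        if any(not (0 < s < 1) for s in self.sparsities):
            raise ValueError("sparsity grid must lie within (0, 1)")
        for level in self.smoothing:
            if level not in SMOOTHING_LEVELS:
                raise ValueError(f"unknown smoothing level {level!r}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def config_hash(self) -> str:
        payload = {
            "subjects": sorted(map(list, self.maps)),
            "atlases": sorted(self.atlases),
            "smoothing": list(self.smoothing),
            "fwhm_mm": self.fwhm_mm,
            "n_grid": self.n_grid,
            "sparsities": [float(s) for s in self.sparsities],
            "network_types": list(self.network_types),
            "n_null": self.n_null,
            "normalize_at": self.normalize_at,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:16]


@dataclass
class StudyResult:
    """Tidy tables plus bookkeeping from one study run."""

    config_hash: str
    seed: int
    global_curves: pd.DataFrame
    global_auc: pd.DataFrame
    nodal_auc: pd.DataFrame
    hub_scores: pd.DataFrame
    matrix_correlations: pd.DataFrame
    elementwise_icc_summary: pd.DataFrame
    metric_icc: pd.DataFrame
    nodal_icc: pd.DataFrame
    reliability_scores: pd.DataFrame
    normalized_global: pd.DataFrame
    failures: list[tuple] = field(default_factory=list)

    @property
    def network_configurations_per_subject(self) -> int:
        """Distinct (smoothing, atlas, type) networks per subject per sparsity."""
        cols = ["smoothing", "atlas", "network_type"]
        return int(self.global_curves[cols].drop_duplicates().shape[0])

    def nodal_maps_per_subject(self, atlas: str) -> int:
        """Distinct (smoothing, type, metric) nodal AUC maps per subject."""
        sub = self.nodal_auc[self.nodal_auc["atlas"] == atlas]
        return int(sub[["smoothing", "network_type", "metric"]].drop_duplicates().shape[0])


def _stage_seed(master: int, *tags: str) -> int:
    """Stable per-stage seed derived from the master seed and stage tags."""
    h = hashlib.sha256(("|".join(map(str, (master, *tags)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _matrix_cache_path(out_dir: Path, cfg_hash: str, atlas: str, smoothing: str,
                       subject: str, session: str) -> Path:
    return out_dir / "matrices" / f"{cfg_hash}_{atlas}_{smoothing}_{subject}_{session}.tsv"


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_study(config: RunConfig) -> StudyResult:
    cfg_hash = config.config_hash()
    subjects = sorted({s for s, _ in config.maps})
    sessions = sorted({t for _, t in config.maps})
    failures: list[tuple] = []

    matrices: dict[tuple[str, str, str, str], similarity.SimilarityMatrix] = {}
    for atlas_name, atlas in sorted(config.atlases.items()):
        for smoothing in config.smoothing:
            for (subj, ses), gm_map in sorted(config.maps.items()):
                key = (atlas_name, smoothing, subj, ses)
                cache = None
                if config.out_dir is not None:
                    cache = _matrix_cache_path(config.out_dir, cfg_hash, *key)
                if config.resume and cache is not None and cache.exists():
                    df = pd.read_csv(cache, sep="\t", comment="#", index_col=0)
                    matrices[key] = similarity.SimilarityMatrix(
                        kls=df.to_numpy(),
                        region_ids=[int(c) for c in df.columns],
                        subject_id=subj,
                        session_id=ses,
                    )
                    continue
                t0 = time.perf_counter()
                try:
                    this_map = (
                        smooth_gm_map(gm_map, config.fwhm_mm)
                        if smoothing == "smo"
                        else gm_map
                    )
                    m = similarity.build_similarity_matrix(
                        this_map, atlas, n_grid=config.n_grid, smoothed=smoothing == "smo"
                    )
                except Exception as exc:  # noqa: BLE001 - isolate subject failures
                    logger.error("stage=similarity subject=%s session=%s atlas=%s "
                                 "smoothing=%s failed: %s", subj, ses, atlas_name, smoothing, exc)
                    failures.append((subj, ses, atlas_name, smoothing, str(exc)))
                    continue
                logger.info("stage=similarity subject=%s session=%s atlas=%s smoothing=%s "
                            "wall=%.2fs", subj, ses, atlas_name, smoothing,
                            time.perf_counter() - t0)
                matrices[key] = m
                if cache is not None:
                    cache.parent.mkdir(parents=True, exist_ok=True)
                    with open(cache, "w") as fh:
                        fh.write(f"# config_hash={cfg_hash} seed={config.seed}\n")
                        m.to_frame().to_csv(fh, sep="\t")

    ok_subjects = [
        s for s in subjects
        if all(
            (a, sm, s, t) in matrices
            for a in config.atlases for sm in config.smoothing for t in sessions
        )
    ]

    gc_rows, ga_rows, na_rows, norm_rows = [], [], [], []
    nodal_auc_store: dict[tuple, np.ndarray] = {}
    for (atlas_name, smoothing, subj, ses), m in sorted(matrices.items()):
        if subj not in ok_subjects:
            continue
        for kind in config.network_types:
            for metric in ("cp", "lp", "eloc", "eglob"):
                curve = graph.metric_over_sparsity(m, metric, config.sparsities, kind=kind)
                for s, v in zip(curve.sparsities, curve.values, strict=True):
                    gc_rows.append((subj, ses, atlas_name, smoothing, kind, metric, s, v))
                ga_rows.append((subj, ses, atlas_name, smoothing, kind, metric, curve.auc))
            for metric in graph.NODAL_METRICS:
                curve = graph.metric_over_sparsity(m, metric, config.sparsities, kind=kind)
                nodal_auc_store[(atlas_name, smoothing, subj, ses, kind, metric)] = curve.auc
                for rid, v in zip(m.region_ids, curve.auc, strict=True):
                    na_rows.append((subj, ses, atlas_name, smoothing, kind, metric, rid, v))
            if config.n_null > 0 and config.normalize_at is not None:
                net = graph.threshold_by_sparsity(m, config.normalize_at)
                seed = _stage_seed(config.seed, "null", atlas_name, smoothing, subj, ses, kind)
                nulls = graph.rewire_null(net, n_nulls=config.n_null, seed=seed)
                real = graph.global_metrics(net, kind=kind, with_modularity=True, seed=seed)
                null_metrics = [
                    graph.global_metrics(nu, kind=kind, with_modularity=True,
                                         seed=seed + i + 1, n_restarts=10)
                    for i, nu in enumerate(nulls)
                ]
                for name, entry in graph.normalize_metrics(real, null_metrics).items():
                    norm_rows.append(
                        (subj, ses, atlas_name, smoothing, kind, name,
                         entry["real"], entry["null_mean"], entry["normalized"])
                    )

    global_curves = pd.DataFrame(
        gc_rows, columns=["subject", "session", "atlas", "smoothing", "network_type",
                          "metric", "sparsity", "value"]
    )
    global_auc = pd.DataFrame(
        ga_rows, columns=["subject", "session", "atlas", "smoothing", "network_type",
                          "metric", "auc"]
    )
    nodal_auc = pd.DataFrame(
        na_rows, columns=["subject", "session", "atlas", "smoothing", "network_type",
                          "metric", "region", "auc"]
    )
    normalized_global = pd.DataFrame(
        norm_rows, columns=["subject", "session", "atlas", "smoothing", "network_type",
                            "metric", "real", "null_mean", "normalized"]
    )

    # hub scores: 3 centrality metrics x network types, group-mean session-1 maps
    hub_rows = []
    first_ses = sessions[0] if sessions else None
    for atlas_name, atlas in sorted(config.atlases.items()):
        for smoothing in config.smoothing:
            maps = {}
            for kind in config.network_types:
                for metric in graph.NODAL_METRICS:
                    per_subj = [
                        nodal_auc_store[(atlas_name, smoothing, s, first_ses, kind, metric)]
                        for s in ok_subjects
                        if (atlas_name, smoothing, s, first_ses, kind, metric) in nodal_auc_store
                    ]
                    if per_subj:
                        maps[f"{kind}_{metric}"] = np.mean(per_subj, axis=0)
            if not maps:
                continue
            hs = graph.hub_score(maps)
            for rid, score in zip(atlas.region_ids, hs["scores"], strict=True):
                hub_rows.append((atlas_name, smoothing, int(rid), int(score)))
    hub_scores = pd.DataFrame(hub_rows, columns=["atlas", "smoothing", "region", "hub_score"])

    # reliability (needs >= 2 sessions and >= 2 subjects)
    mc_rows, ei_rows, mi_rows, ni_rows, rs_rows = [], [], [], [], []
    if len(sessions) >= 2 and len(ok_subjects) >= 2:
        for atlas_name, atlas in sorted(config.atlases.items()):
            for smoothing in config.smoothing:
                for subj in ok_subjects:
                    for t1, t2 in zip(sessions[:-1], sessions[1:], strict=False):
                        r = similarity.matrix_correlation(
                            matrices[(atlas_name, smoothing, subj, t1)],
                            matrices[(atlas_name, smoothing, subj, t2)],
                        )
                        mc_rows.append((subj, atlas_name, smoothing, t1, t2, r))
                sub_mats = {
                    (s, t): matrices[(atlas_name, smoothing, s, t)]
                    for s in ok_subjects for t in sessions
                }
                _, summary = reliability.elementwise_icc(sub_mats)
                ei_rows.append(
                    (atlas_name, smoothing, summary["mean"], summary["sd"],
                     summary["fraction_per_category"]["excellent"])
                )
                ga_sub = global_auc[
                    (global_auc["atlas"] == atlas_name)
                    & (global_auc["smoothing"] == smoothing)
                ]
                for kind in config.network_types:
                    for metric in ("cp", "lp", "eloc", "eglob"):
                        sel = ga_sub[
                            (ga_sub["network_type"] == kind) & (ga_sub["metric"] == metric)
                        ].set_index(["subject", "session"])["auc"]
                        vals = {
                            (s, t): float(sel.loc[(s, t)])
                            for s in ok_subjects for t in sessions
                        }
                        res = reliability.metric_icc(vals)
                        mi_rows.append((atlas_name, smoothing, kind, metric, res.icc, res.category))
                icc_maps = {}
                for kind in config.network_types:
                    for metric in graph.NODAL_METRICS:
                        table = np.array(
                            [
                                [
                                    nodal_auc_store[(atlas_name, smoothing, s, t, kind, metric)]
                                    for t in sessions
                                ]
                                for s in ok_subjects
                            ]
                        )  # (subjects, sessions, regions)
                        n_regions = table.shape[2]
                        iccs = np.full(n_regions, np.nan)
                        for ri in range(n_regions):
                            try:
                                iccs[ri] = reliability.icc_oneway(table[:, :, ri]).icc
                            except reliability.UndefinedICCError:
                                pass
                        icc_maps[f"{kind}_{metric}"] = iccs
                        for rid, v in zip(atlas.region_ids, iccs, strict=True):
                            ni_rows.append((atlas_name, smoothing, kind, metric, int(rid), v))
                finite_maps = {
                    k: np.nan_to_num(v, nan=-np.inf) for k, v in icc_maps.items()
                }
                rs = reliability.reliability_hub_score(finite_maps)
                for rid, score in zip(atlas.region_ids, rs["scores"], strict=True):
                    rs_rows.append((atlas_name, smoothing, int(rid), int(score)))

    result = StudyResult(
        config_hash=cfg_hash,
        seed=config.seed,
        global_curves=global_curves,
        global_auc=global_auc,
        nodal_auc=nodal_auc,
        hub_scores=hub_scores,
        matrix_correlations=pd.DataFrame(
            mc_rows, columns=["subject", "atlas", "smoothing", "session_a", "session_b", "r"]
        ),
        elementwise_icc_summary=pd.DataFrame(
            ei_rows, columns=["atlas", "smoothing", "icc_mean", "icc_sd", "fraction_excellent"]
        ),
        metric_icc=pd.DataFrame(
            mi_rows, columns=["atlas", "smoothing", "network_type", "metric", "icc", "category"]
        ),
        nodal_icc=pd.DataFrame(
            ni_rows, columns=["atlas", "smoothing", "network_type", "metric", "region", "icc"]
        ),
        reliability_scores=pd.DataFrame(
            rs_rows, columns=["atlas", "smoothing", "region", "reliability_score"]
        ),
        normalized_global=normalized_global,
        failures=failures,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        for name in (
            "global_curves", "global_auc", "nodal_auc", "hub_scores",
            "matrix_correlations", "elementwise_icc_summary", "metric_icc",
            "nodal_icc", "reliability_scores", "normalized_global",
        ):
            _write_tsv(getattr(result, name), out / f"{name}.tsv", cfg_hash, config.seed)
    return result
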