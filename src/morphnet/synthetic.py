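"""Synthetic atlases and multi-subject, multi-session GM volume cohorts.

The generator plants every structure the downstream pipeline is supposed to
recover, so each stage can be tested against a known ground truth:

* **families** — groups of regions sharing a base value distribution, which
  induce modular block structure in the similarity matrix;
* **subject and session random effects** — location shifts of the family
  distribution drawn per (subject, family) and per (subject, session,
  family), giving a controllable between/within variance ratio and hence a
  known intraclass-correlation regime;
* **homotopic pairs** — mirror-placed parcels across the mid-sagittal voxel
  plane that share a family (and therefore its random effects), so their
  similarity is elevated above ordinary region pairs.

Base family distributions are two-component Gaussian mixtures, a reasonable
stand-in for the skewed histograms of real regional gray-matter volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SizingError
from .image_io import AtlasParcellation, GMVolumeMap

_CATEGORIES = ("primary", "association", "paralimbic", "limbic", "subcortical")

#: default parcel edge length in voxels; 3**3 = 27 voxels is the minimum
PARCEL_EDGE = 3
_MARGIN = 1


@dataclass(frozen=True)
class MixtureParams:
    """Two-component Gaussian mixture in GM-volume units."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float] = (0.6, 0.4)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weights[0]
        out = np.where(
            comp,
            rng.normal(self.means[0], self.sds[0], size=n),
            rng.normal(self.means[1], self.sds[1], size=n),
        )
        return out


def default_family_params(n_families: int) -> dict[int, MixtureParams]:
    """Overlapping mixtures emulating regional GM-volume histograms.

    Every family shares a broad component near 0.45 (partial-volume mass
    common to all of gray matter) and adds a family-specific component
    whose location and weight vary non-monotonically with the family
    label, so cross-family similarity is not a simple 1-D gradient.
    """
    out = {}
    for f in range(n_families):
        loc = 0.25 + 0.05 * ((f * 3) % max(n_families, 1))
        w_shared = 0.60 + 0.10 * (f % 3) / 2.0
        out[f] = MixtureParams(
            means=(0.45, loc),
            sds=(0.10, 0.06),
            weights=(w_shared, 1.0 - w_shared),
        )
    return out


def separated_family_params(n_families: int, step: float = 0.09) -> dict[int, MixtureParams]:
    """Well-separated mixtures (family f centred ~step*f above family f-1);
    use these to plant unambiguous modular structure."""
    return {
        f: MixtureParams(means=(0.15 + step * f, 0.40 + step * f), sds=(0.04, 0.06))
        for f in range(n_families)
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full description of a synthetic test-retest cohort.

    ``family_assignment`` maps region id (1-based) to a family label; by
    default regions are dealt round-robin over ``n_families`` families.
    ``subject_sd`` and ``session_sd`` are the standard deviations of the
    between-subject and within-subject (session) location shifts, in the
    same units as the GM values; their squared ratio sets the intraclass
    correlation the cohort plants.
    """

    n_regions: int = 28
    image_shape: tuple[int, int, int] = (40, 40, 40)
    parcel_edge: int = PARCEL_EDGE
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 10
    n_sessions: int = 2
    n_families: int = 7
    family_assignment: tuple[int, ...] | None = None
    family_params: dict[int, MixtureParams] | None = None
    subject_sd: float = 0.05
    session_sd: float = 0.01
    region_jitter_sd: float = 0.03
    homotopic_pairs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.subject_sd < 0 or self.session_sd < 0:
            raise ValueError("effect standard deviations must be >= 0")
        fa = self.resolved_family_assignment()
        if len(fa) != self.n_regions:
            raise ValueError("family_assignment must cover every region exactly once")
        seen: set[int] = set()
        for a, b in self.homotopic_pairs:
            if a in seen or b in seen or a == b:
                raise ValueError("homotopic pairs must be disjoint")
            seen.update((a, b))
            if not (1 <= a <= self.n_regions and 1 <= b <= self.n_regions):
                raise ValueError(f"homotopic pair ({a}, {b}) outside region range")

    def resolved_family_assignment(self) -> dict[int, int]:
        """Region id -> family label. Homotopic partners share a family."""
        if self.family_assignment is not None:
            fa = {rid: int(f) for rid, f in zip(range(1, self.n_regions + 1), self.family_assignment)}
        else:
            fa = {rid: (rid - 1) % self.n_families for rid in range(1, self.n_regions + 1)}
        for a, b in self.homotopic_pairs:
            fa[b] = fa[a]
        return fa

    def resolved_family_params(self) -> dict[int, MixtureParams]:
        if self.family_params is not None:
            return dict(self.family_params)
        n_fam = len(set(self.resolved_family_assignment().values()))
        return default_family_params(max(n_fam, self.n_families))


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def _left_half_slots(shape: tuple[int, int, int], edge: int) -> list[tuple[int, int, int]]:
    """Parcel corner positions strictly left of the mid-sagittal plane."""
    nx, ny, nz = shape
    cx = nx // 2
    stride = edge + 1  # one-voxel gap between parcels
    xs = range(_MARGIN, cx - edge + 1, stride)
    ys = range(_MARGIN, ny - edge - _MARGIN + 1, stride)
    zs = range(_MARGIN, nz - edge - _MARGIN + 1, stride)
    return [(x, y, z) for x in xs for y in ys for z in zs]


def generate_atlas(spec: SyntheticCohortSpec) -> AtlasParcellation:
    """Lay out cubic parcels; homotopic partners are mirror images.

    Every parcel is a cube of ``parcel_edge`` voxels per side (>= 27 voxels
    at the default edge of 3). Parcels are placed on a lattice in the left
    half-volume; the second member of each homotopic pair is the reflection
    of the first across the mid-sagittal voxel plane (for odd widths, the
    reflection about the centre column).
    """
    shape = spec.image_shape
    edge = spec.parcel_edge
    slots = _left_half_slots(shape, edge)
    paired_first = {a for a, _ in spec.homotopic_pairs}
    paired_second = {b for _, b in spec.homotopic_pairs}
    partner_of = {a: b for a, b in spec.homotopic_pairs}
    n_slots_needed = spec.n_regions - len(paired_second)
    if len(slots) < n_slots_needed:
        raise SizingError(
            f"image shape {shape} hosts only {len(slots)} parcels; "
            f"{n_slots_needed} needed for {spec.n_regions} regions"
        )

    labels = np.zeros(shape, dtype=np.int64)
    nx = shape[0]
    slot_iter = iter(slots)
    placed: dict[int, tuple[slice, slice, slice]] = {}
    for rid in range(1, spec.n_regions + 1):
        if rid in paired_second:
            continue  # placed by mirroring below
        x, y, z = next(slot_iter)
        sl = (slice(x, x + edge), slice(y, y + edge), slice(z, z + edge))
        labels[sl] = rid
        placed[rid] = sl
        if rid in paired_first:
            pid = partner_of[rid]
            xs = sl[0]
            mx = slice(nx - xs.stop, nx - xs.start)  # mirror across midline
            labels[mx, sl[1], sl[2]] = pid
            placed[pid] = (mx, sl[1], sl[2])

    fa = spec.resolved_family_assignment()
    rows = []
    for rid in range(1, spec.n_regions + 1):
        sl = placed[rid]
        cx_region = (sl[0].start + sl[0].stop - 1) / 2
        mid = (nx - 1) / 2
        hemi = "L" if cx_region < mid else ("R" if cx_region > mid else "M")
        partner = None
        for a, b in spec.homotopic_pairs:
            if rid == a:
                partner = b
            elif rid == b:
                partner = a
        rows.append(
            {
                "id": rid,
                "name": f"region_{rid:03d}",
                "hemisphere": hemi,
                "category": _CATEGORIES[fa[rid] % len(_CATEGORIES)],
                "homotopic_partner_id": partner,
            }
        )
    regions = pd.DataFrame(rows)
    regions["homotopic_partner_id"] = regions["homotopic_partner_id"].astype("Int64")
    return AtlasParcellation(
        labels=labels,
        regions=regions,
        voxel_size_mm=spec.voxel_size_mm,
        name="synthetic",
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    spec: SyntheticCohortSpec, atlas: AtlasParcellation
) -> dict[tuple[str, str], GMVolumeMap]:
    """Generate GM maps keyed by (subject_id, session_id).

    Per subject and region, a base sample is drawn once from the region's
    family mixture and reused across sessions; the subject's family shift
    and the session's family shift are then added and the result clipped at
    zero. With ``session_sd == 0`` the two sessions of a subject are
    therefore voxelwise identical. Identical spec + seed reproduces the
    cohort bit for bit.
    """
    if atlas.labels.shape != spec.image_shape:
        raise AlignmentError(
            f"atlas shape {atlas.labels.shape} != spec image shape {spec.image_shape}"
        )
    rng = np.random.default_rng(spec.seed)
    fa = spec.resolved_family_assignment()
    fparams = spec.resolved_family_params()
    families = sorted(set(fa.values()))
    region_ids = [int(r) for r in atlas.region_ids]
    masks = {rid: atlas.labels == rid for rid in region_ids}
    n_vox = {rid: int(masks[rid].sum()) for rid in region_ids}

    # fixed per-region idiosyncratic offset ("region-specific shape"),
    # shared by homotopic partners and identical for every subject/session
    region_offset = {
        rid: rng.normal(0.0, spec.region_jitter_sd) if spec.region_jitter_sd > 0 else 0.0
        for rid in region_ids
    }
    for a, b in spec.homotopic_pairs:
        region_offset[b] = region_offset[a]

    # fixed draw order: subjects, then (families), then regions, then sessions
    cohort: dict[tuple[str, str], GMVolumeMap] = {}
    for s in range(spec.n_subjects):
        subj = f"sub{s + 1:02d}"
        subj_shift = {
            f: rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
            for f in families
        }
        base = {rid: fparams[fa[rid]].sample(n_vox[rid], rng) for rid in region_ids}
        for t in range(spec.n_sessions):
            ses = f"ses{t + 1}"
            sess_shift = {
                f: rng.normal(0.0, spec.session_sd) if spec.session_sd > 0 else 0.0
                for f in families
            }
            vol = np.zeros(spec.image_shape, dtype=float)
            for rid in region_ids:
                fam = fa[rid]
                vals = base[rid] + region_offset[rid] + subj_shift[fam] + sess_shift[fam]
                vol[masks[rid]] = np.clip(vals, 0.0, None)
            cohort[(subj, ses)] = GMVolumeMap(
                values=vol,
                voxel_size_mm=spec.voxel_size_mm,
                affine=atlas.affine.copy(),
                subject_id=subj,
                session_id=ses,
            )
    return cohort


def generate_icc_table(
    n_subjects: int,
    n_sessions: int,
    subject_sd: float,
    session_sd: float,
    seed: int | np.random.Generator = 0,
    mean: float = 0.0,
) -> np.ndarray:
    """Direct variance-components table ``y[s, t] = mean + b_s + w_st``.

    The population intraclass correlation of this table is
    ``subject_sd**2 / (subject_sd**2 + session_sd**2)``, which makes it the
    ground truth for ICC parameter-recovery checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.normal(0.0, subject_sd, size=(n_subjects, 1))
    w = rng.normal(0.0, session_sd, size=(n_subjects, n_sessions))
    return mean + b + w
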