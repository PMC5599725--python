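"""Synthetic resting-state cohorts with planted connectivity deficits.

This module generates everything the downstream analysis consumes: a set of
spatial network templates (stand-ins for canonical intrinsic connectivity
network maps), per-subject 4-D scans produced by a linear mixing model, and a
clinical table whose scores are coupled to the planted connectivity effect.

The mixing model is the one dual regression assumes: the signal at voxel v and
time t is the sum over networks k of ``loadings(t, k) * map_k(v) * gain_k(v)``
plus i.i.d. Gaussian noise. A group deficit is planted multiplicatively on the
spatial gain of one or more networks, so it propagates to the dual-regression
betas (and hence z-maps) exactly as a loss of within-network connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ICNTemplateSet",
    "SubjectRecord",
    "Scan4D",
    "PlantedEffect",
    "ClinicalCoupling",
    "SimulationConfig",
    "make_template_set",
    "simulate_subject_scan",
    "simulate_clinical",
    "simulate_cohort",
    "generate_scans",
]

MHE = "MHE"
NMHE = "NMHE"

#: Group means/SDs of the neuropsychological and hepatic scores used to seed the
#: clinical generator (NMHE, MHE). Units: TMT in seconds, DST/BDT raw scores,
#: Child-Pugh points.
CLINICAL_NORMS = {
    "tmt_a": ((47.3, 16.9), (75.2, 19.8)),
    "tmt_b": ((124.1, 41.9), (175.4, 47.6)),
    "dst": ((40.0, 11.0), (25.1, 7.6)),
    "bdt": ((28.5, 9.6), (18.5, 7.2)),
    "child_pugh": ((7.0, 2.0), (8.2, 2.2)),
}


class SizingError(ValueError):
    """Grid too small to host the requested number of well-separated templates."""


@dataclass(frozen=True)
class ICNTemplateSet:
    """A set of K spatial network templates on a common 3-D grid."""

    names: list[str]
    maps: np.ndarray  # (K, X, Y, Z), non-negative weights
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.maps.ndim != 4 or self.maps.shape[0] != len(self.names):
            raise ValueError("maps must be (K, X, Y, Z) with one name per map")
        if len(set(self.names)) != len(self.names):
            raise ValueError("template names must be unique")
        if self.n_templates < 1:
            raise ValueError("need at least one template")
        for k, m in enumerate(self.maps):
            if not (m > 0).any():
                raise ValueError(f"template {self.names[k]} has empty support")

    @property
    def n_templates(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    @property
    def supports(self) -> np.ndarray:
        """Boolean (K, X, Y, Z) array of strictly positive template weights."""
        return self.maps > 0


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # MHE | NMHE
    tmt_a: float  # seconds
    tmt_b: float  # seconds
    dst: float  # raw score
    bdt: float  # raw score
    child_pugh: float
    age: float  # years
    gender: str  # M | F
    education: float  # years
    movement: float  # mean framewise displacement, mm

    def __post_init__(self) -> None:
        if self.group not in (MHE, NMHE):
            raise ValueError(f"group must be {MHE!r} or {NMHE!r}, got {self.group!r}")
        for name in ("tmt_a", "tmt_b", "dst", "bdt", "child_pugh", "age", "education", "movement"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class Scan4D:
    """A 4-D functional volume (X, Y, Z, T)."""

    data: np.ndarray
    tr_seconds: float = 2.5

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("scan data must be 4-D (X, Y, Z, T)")
        if not np.isfinite(self.data).all():
            raise ValueError("scan contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class PlantedEffect:
    """A discriminative sub-region: MHE spatial gain is reduced by ``delta`` on it."""

    icn: int
    voxels: np.ndarray  # (m, 3) integer voxel indices
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta:
            raise ValueError("delta must be >= 0")


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear coefficients linking a subject's planted integration (mean spatial
    gain over the planted region; 1 = intact) to each clinical score.

    Scores are generated as ``group_base + coef * (integration - 1) + noise``, so
    a negative coefficient makes the score rise as connectivity is lost.
    """

    tmt_a: float = -13.95
    tmt_b: float = -25.65
    dst: float = 7.45
    bdt: float = 5.0
    child_pugh: float = -0.6

    def as_dict(self) -> dict[str, float]:
        return {
            "tmt_a": self.tmt_a,
            "tmt_b": self.tmt_b,
            "dst": self.dst,
            "bdt": self.bdt,
            "child_pugh": self.child_pugh,
        }

    @classmethod
    def zero(cls) -> "ClinicalCoupling":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    n_mhe: int = 32
    n_nmhe: int = 42
    grid_shape: tuple[int, int, int] = (30, 36, 30)
    n_templates: int = 20
    n_timepoints: int = 115
    tr_seconds: float = 2.5
    planted: list[PlantedEffect] | None = None  # None -> one default effect in ICN 0
    delta: float = 1.0  # used when planted is None
    noise_sd: float = 0.2
    coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mhe < 2 or self.n_nmhe < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_timepoints < self.n_templates + 2:
            raise ValueError("need T >= K + 2 for overdetermined regressions")

    @property
    def n_subjects(self) -> int:
        return self.n_mhe + self.n_nmhe


def make_template_set(
    n_templates: int,
    grid_shape: tuple[int, int, int],
    seed: int,
    *,
    sigma: float = 1.8,
    support_level: float = 0.1,
    names: Sequence[str] | None = None,
) -> ICNTemplateSet:
    """Place ``n_templates`` compact Gaussian blobs with low mutual overlap.

    Each template is a Gaussian kernel around a random centre, truncated at
    ``support_level`` of its peak (binarized support, Gaussian weights kept
    inside it). Centres are rejection-sampled with a minimum separation of
    1.5 support radii, which bounds pairwise support overlap well below 20%.
    Deterministic given ``seed``.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    rng = np.random.default_rng(seed)
    radius = sigma * math.sqrt(2.0 * math.log(1.0 / support_level))
    min_sep = 1.5 * radius
    margin = int(math.ceil(radius))
    lo = np.full(3, margin)
    hi = np.asarray(grid_shape) - margin
    if (hi <= lo).any():
        raise SizingError(
            f"grid {grid_shape} too small for blobs of radius {radius:.1f}"
        )
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_templates:
        if tries > 20000:
            raise SizingError(
                f"could not place {n_templates} blobs with separation "
                f"{min_sep:.1f} on grid {grid_shape}"
            )
        tries += 1
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)

    grids = np.indices(grid_shape).astype(float)  # (3, X, Y, Z)
    maps = np.zeros((n_templates,) + tuple(grid_shape))
    for k, c in enumerate(centers):
        d2 = sum((grids[a] - c[a]) ** 2 for a in range(3))
        w = np.exp(-d2 / (2.0 * sigma**2))
        w[w < support_level] = 0.0
        maps[k] = w
    if names is None:
        names = [f"ICN{k:02d}" for k in range(n_templates)]
    return ICNTemplateSet(names=list(names), maps=maps)


def simulate_subject_scan(
    templates: ICNTemplateSet,
    loadings: np.ndarray,
    spatial_gain: np.ndarray | None,
    noise_sd: float,
    seed: int,
    *,
    tr_seconds: float = 2.5,
    dtype=np.float64,
) -> Scan4D:
    """Mix templates with per-network time courses and spatial gains plus noise.

    data(v, t) = sum_k loadings(t, k) * map_k(v) * gain_k(v) + N(0, noise_sd^2)
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[1] != templates.n_templates:
        raise ValueError("loadings must be (T, K) matching the template set")
    if not np.isfinite(loadings).all():
        raise ValueError("loadings must be finite")
    t_len, k = loadings.shape
    if t_len < k + 2:
        raise ValueError("need T >= K + 2")
    if spatial_gain is None:
        effective = templates.maps
    else:
        spatial_gain = np.asarray(spatial_gain, dtype=float)
        if spatial_gain.shape != templates.maps.shape:
            raise ValueError(
                f"spatial_gain shape {spatial_gain.shape} does not match "
                f"templates {templates.maps.shape}"
            )
        effective = templates.maps * spatial_gain
    data = np.einsum("tk,kxyz->xyzt", loadings, effective).astype(dtype)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(dtype)
    return Scan4D(data=data, tr_seconds=tr_seconds)


def simulate_clinical(
    group: str,
    planted_integration: float,
    coupling: ClinicalCoupling,
    seed: int,
    *,
    subject_id: str = "S000",
) -> SubjectRecord:
    """Draw one subject's clinical record.

    Cognitive scores combine a group base level (TMT higher, DST/BDT lower in
    MHE), a coupling term proportional to the lost planted connectivity
    (``planted_integration - 1``; zero for an intact subject), and Gaussian
    noise. Age, gender, education and movement are drawn independently of group.
    """
    rng = np.random.default_rng(seed)
    gi = 1 if group == MHE else 0
    coefs = coupling.as_dict()
    scores = {}
    for name, ((m_n, s_n), (m_m, _s_m)) in CLINICAL_NORMS.items():
        # half the group gap in the base mean, the rest carried by the coupling
        base = m_n + gi * 0.5 * (m_m - m_n)
        val = base + coefs[name] * (planted_integration - 1.0) + rng.normal(0.0, s_n)
        scores[name] = float(val)
    scores["dst"] = max(scores["dst"], 0.0)
    scores["bdt"] = max(scores["bdt"], 0.0)
    scores["tmt_a"] = max(scores["tmt_a"], 5.0)
    scores["tmt_b"] = max(scores["tmt_b"], 10.0)
    scores["child_pugh"] = float(np.clip(scores["child_pugh"], 5.0, 15.0))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=float(rng.normal(51.0, 9.0)),
        gender="M" if rng.random() < 0.8 else "F",
        education=float(np.clip(rng.normal(8.0, 2.5), 0.0, 20.0)),
        movement=float(np.exp(rng.normal(math.log(0.12), 0.4))),
        **scores,
    )


def default_planted_effect(
    templates: ICNTemplateSet, icn: int = 0, delta: float = 1.0, core_level: float = 0.5
) -> PlantedEffect:
    """Plant the deficit on the core of a template: voxels at >= ``core_level``
    of the peak weight."""
    m = templates.maps[icn]
    voxels = np.argwhere(m >= core_level * m.max())
    return PlantedEffect(icn=icn, voxels=voxels, delta=delta)


def _subject_gain(
    cfg: SimulationConfig, templates: ICNTemplateSet, planted: list[PlantedEffect], group: str
) -> tuple[np.ndarray | None, float]:
    """Spatial gain volume for one subject and the planted-integration scalar."""
    integrations = []
    if group == NMHE:
        return None, 1.0
    gain = np.ones_like(templates.maps)
    for eff in planted:
        idx = tuple(eff.voxels.T)
        gain[eff.icn][idx] = 1.0 - eff.delta
        integrations.append(1.0 - eff.delta)
    return gain, float(np.mean(integrations)) if integrations else 1.0


def _cohort_plan(cfg: SimulationConfig, templates: ICNTemplateSet):
    planted = cfg.planted
    if planted is None:
        planted = [default_planted_effect(templates, icn=0, delta=cfg.delta)]
    for eff in planted:
        support = templates.supports[eff.icn]
        if not support[tuple(eff.voxels.T)].all():
            raise ValueError(
                f"planted voxels for ICN {eff.icn} fall outside template support"
            )
    groups = [NMHE] * cfg.n_nmhe + [MHE] * cfg.n_mhe
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * len(groups))
    plan = []
    for i, group in enumerate(groups):
        gain, integration = _subject_gain(cfg, templates, planted, group)
        plan.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "group": group,
                "gain": gain,
                "integration": integration,
                "scan_seed": children[2 * i],
                "clin_seed": children[2 * i + 1],
            }
        )
    return plan


def generate_scans(
    cfg: SimulationConfig, templates: ICNTemplateSet | None = None, *, dtype=np.float32
) -> Iterator[tuple[SubjectRecord, Scan4D]]:
    """Yield (record, scan) pairs one subject at a time (memory-friendly).

    The stream is identical to what :func:`simulate_cohort` materializes.
    """
    if templates is None:
        templates = make_template_set(cfg.n_templates, cfg.grid_shape, cfg.seed)
    for item in _cohort_plan(cfg, templates):
        loadings_rng = np.random.default_rng(item["scan_seed"])
        loadings = loadings_rng.standard_normal((cfg.n_timepoints, cfg.n_templates))
        scan = simulate_subject_scan(
            templates,
            loadings,
            item["gain"],
            cfg.noise_sd,
            loadings_rng.integers(0, 2**31),
            tr_seconds=cfg.tr_seconds,
            dtype=dtype,
        )
        record = simulate_clinical(
            item["group"],
            item["integration"],
            cfg.coupling,
            item["clin_seed"],
            subject_id=item["subject_id"],
        )
        yield record, scan


def simulate_cohort(
    cfg: SimulationConfig, *, dtype=np.float32
) -> tuple[ICNTemplateSet, list[Scan4D], list[SubjectRecord]]:
    """Simulate the full cohort: templates, one scan per subject, clinical table.

    MHE subjects have their spatial gain reduced by delta on every planted
    region; NMHE subjects have gain 1 everywhere. Fully reproducible from
    ``cfg.seed``.
    """
    templates = make_template_set(cfg.n_templates, cfg.grid_shape, cfg.seed)
    scans: list[Scan4D] = []
    records: list[SubjectRecord] = []
    for record, scan in generate_scans(cfg, templates, dtype=dtype):
        records.append(record)
        scans.append(scan)
    return templates, scans, records


def planted_integrations(cfg: SimulationConfig, templates: ICNTemplateSet | None = None) -> np.ndarray:
    """Per-subject planted-integration scalars (mean spatial gain over R*)."""
    if templates is None:
        templates = make_template_set(cfg.n_templates, cfg.grid_shape, cfg.seed)
    return np.array([item["integration"] for item in _cohort_plan(cfg, templates)])
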