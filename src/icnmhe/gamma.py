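"""Bayesian discriminative-ROI discovery on binarized connectivity maps.

Given one binary high-connectivity map per subject (a z-map thresholded at a
fixed cut) and a binary clinical label, the procedure:

1. scores every in-mask voxel by the log Bayesian-Dirichlet (BD) marginal
   likelihood of the label column given the voxel's on/off state across
   subjects;
2. takes the best-scoring voxel as a representative voxel, and grows an ROI
   around it: the 26-connected component (through the representative voxel) of
   all voxels whose across-subject binary vector agrees with the
   representative's in at least ``kappa_sim`` of subjects;
3. summarizes each subject's ROI state by majority vote (mean >= tau), rescores
   at the ROI level, and keeps the ROI only if a label-permutation test finds
   the score unlikely under exchangeability;
4. masks out the accepted ROI and repeats, until a candidate fails validation
   or ``max_rois`` ROIs are found.

The output is the ordered ROI list with a smoothed conditional probability
table P(class | ROI state) per ROI.

The BD score uses a Dirichlet prior of equivalent sample size ``alpha_ess``
per parent state over the two classes (``alpha_ess / 2`` per cell), i.e. the
classic K2 metric when ``alpha_ess = 2``. It equals the log product of
sequential predictive probabilities (Polya urn), which the test suite uses as
an independent oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import gammaln

__all__ = [
    "DEFAULT_THRESHOLDS",
    "threshold_grid",
    "GammaParams",
    "BinaryMap",
    "GammaModel",
    "DegenerateLabelsError",
    "discretize_zmap",
    "log_bd_score",
    "grow_roi",
    "roi_state",
    "roi_states",
    "build_cpt",
    "validate_model",
    "fit_gamma",
]

#: The 9 z thresholds used throughout: 1.00 to 3.00 in steps of 0.25.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(1.0, 3.01, 0.25), 2))

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def threshold_grid() -> tuple[float, ...]:
    """The default strictly-increasing 9-value z-threshold grid."""
    return DEFAULT_THRESHOLDS


class DegenerateLabelsError(ValueError):
    """Label vector contains a single class."""


@dataclass(frozen=True)
class BinaryMap:
    """A subject's thresholded high-connectivity map for one network."""

    subject_id: str
    icn: str
    threshold: float
    data: np.ndarray  # boolean (X, Y, Z)

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            raise ValueError("binary map data must be boolean")


@dataclass
class GammaParams:
    alpha_ess: float = 2.0  # Dirichlet equivalent sample size
    kappa_sim: float = 0.9  # Hamming-similarity cut for region growing
    tau: float = 0.5  # majority fraction for the ROI state
    n_permutations: int = 199
    alpha: float = 0.05  # validation level
    max_rois: int = 5
    cpt_smoothing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_ess <= 0:
            raise ValueError("alpha_ess must be > 0")
        if not 0.5 < self.kappa_sim <= 1.0:
            raise ValueError("kappa_sim must be in (0.5, 1]")
        if self.n_permutations < 99:
            raise ValueError("need at least 99 permutations")


@dataclass
class GammaModel:
    """Discriminative ROIs with conditional probability tables for one
    (network, threshold) pair."""

    icn: str
    threshold: float
    rois: list[np.ndarray]  # each (m, 3) sorted voxel-index triples
    representative_voxels: list[tuple[int, int, int]]
    cpt: list[np.ndarray]  # each 2x2: rows = state 0/1, cols = P(NMHE), P(MHE)
    scores: list[float]  # ROI-level log BD score
    p_values: list[float]  # permutation p per ROI
    params: GammaParams

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def log_bd(self) -> float:
        """Score of the leading ROI (NaN when no ROI was validated)."""
        return self.scores[0] if self.scores else float("nan")

    @property
    def validation_p(self) -> float:
        return self.p_values[0] if self.p_values else float("nan")

    def to_json(self) -> str:
        payload = {
            "icn": self.icn,
            "threshold": self.threshold,
            "rois": [r.tolist() for r in self.rois],
            "representative_voxels": [list(v) for v in self.representative_voxels],
            "cpt": [c.tolist() for c in self.cpt],
            "scores": self.scores,
            "p_values": self.p_values,
            "params": asdict(self.params),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GammaModel":
        d = json.loads(text)
        return cls(
            icn=d["icn"],
            threshold=d["threshold"],
            rois=[np.asarray(r, dtype=int) for r in d["rois"]],
            representative_voxels=[tuple(v) for v in d["representative_voxels"]],
            cpt=[np.asarray(c, dtype=float) for c in d["cpt"]],
            scores=list(d["scores"]),
            p_values=list(d["p_values"]),
            params=GammaParams(**d["params"]),
        )


def discretize_zmap(
    z: np.ndarray, thr: float, *, subject_id: str = "S000", icn: str = "ICN00"
) -> BinaryMap:
    """Label a voxel 1 iff its z-score is strictly larger than the threshold."""
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    return BinaryMap(subject_id=subject_id, icn=icn, threshold=float(thr), data=z > thr)


def _bd_terms(n_j: np.ndarray, n_jm: np.ndarray, alpha_ess: float) -> np.ndarray:
    """BD contribution of one parent-state cell with n_j subjects, n_jm of class MHE."""
    a_j = alpha_ess
    a_jc = alpha_ess / 2.0
    return (
        gammaln(a_j)
        - gammaln(a_j + n_j)
        + gammaln(a_jc + n_jm)
        - gammaln(a_jc)
        + gammaln(a_jc + (n_j - n_jm))
        - gammaln(a_jc)
    )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.size < 2:
        raise ValueError("need at least two subjects")
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("labels contain a single class")
    return labels


def log_bd_score(states: Sequence[int], labels: Sequence[int], alpha_ess: float = 2.0) -> float:
    """Log marginal likelihood of the class column given the binary state.

    ``labels`` is boolean with True = MHE. Depends on the data only through the
    2x2 (state, class) counts, hence invariant to subject order.
    """
    if alpha_ess <= 0:
        raise ValueError("alpha_ess must be > 0")
    states = np.asarray(states).astype(bool)
    labels = _check_labels(labels)
    if states.shape != labels.shape:
        raise ValueError("states and labels must have the same length")
    total = 0.0
    for j in (False, True):
        sel = states == j
        total += float(_bd_terms(sel.sum(), (labels & sel).sum(), alpha_ess))
    return total


def _log_bd_many(states: np.ndarray, labels: np.ndarray, alpha_ess: float) -> np.ndarray:
    """Vectorized BD score: ``states`` (n, V) uint8, ``labels`` (n,) bool -> (V,)."""
    n = states.shape[0]
    n1 = states.sum(axis=0)
    n1m = labels.astype(np.int64) @ states
    n0 = n - n1
    n0m = labels.sum() - n1m
    return _bd_terms(n1, n1m, alpha_ess) + _bd_terms(n0, n0m, alpha_ess)


def _perm_bd_many(states: np.ndarray, perm_labels: np.ndarray, alpha_ess: float) -> np.ndarray:
    """BD scores for B permuted label vectors at once: (B, n) x (n, V) -> (B, V)."""
    n = states.shape[0]
    n1 = states.sum(axis=0)[None, :]
    n1m = perm_labels.astype(np.int64) @ states
    n0 = n - n1
    n0m = perm_labels.sum(axis=1)[:, None] - n1m
    return _bd_terms(n1, n1m, alpha_ess) + _bd_terms(n0, n0m, alpha_ess)


def _stack(maps: Sequence[BinaryMap] | np.ndarray) -> np.ndarray:
    """Stack binary maps into an (n, X, Y, Z) boolean array."""
    if isinstance(maps, np.ndarray):
        if maps.ndim != 4:
            raise ValueError("stacked maps must be (n, X, Y, Z)")
        return maps.astype(bool)
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("all maps must share the same grid")
    return np.stack([m.data for m in maps])


def grow_roi(
    rep_voxel: tuple[int, int, int],
    maps: Sequence[BinaryMap] | np.ndarray,
    kappa_sim: float = 0.9,
) -> np.ndarray:
    """Grow an ROI around a representative voxel by subject-vector similarity.

    Returns the boolean volume of the 26-connected component containing
    ``rep_voxel`` within the set of voxels whose across-subject binary vector
    has Hamming similarity >= ``kappa_sim`` with the representative voxel's.
    """
    if not 0.5 < kappa_sim <= 1.0:
        raise ValueError("kappa_sim must be in (0.5, 1]")
    stack = _stack(maps)  # (n, X, Y, Z)
    rep_voxel = tuple(int(c) for c in rep_voxel)
    rep_vec = stack[(slice(None),) + rep_voxel]  # (n,)
    agree = (stack == rep_vec.reshape((-1,) + (1, 1, 1))).mean(axis=0)
    candidate = agree >= kappa_sim
    labeled, _ = ndimage.label(candidate, structure=_CONN26)
    comp = labeled[rep_voxel]
    if comp == 0:  # rep itself always satisfies similarity 1; defensive
        out = np.zeros(stack.shape[1:], dtype=bool)
        out[rep_voxel] = True
        return out
    return labeled == comp


def roi_state(dmap: BinaryMap | np.ndarray, roi: np.ndarray, tau: float = 0.5) -> int:
    """Majority ROI state: 1 iff the mean of the binary map over the ROI >= tau."""
    data = dmap.data if isinstance(dmap, BinaryMap) else np.asarray(dmap)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    return int(data[roi].mean() >= tau)


def roi_states(stack: np.ndarray, roi: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Vector of per-subject ROI states from an (n, X, Y, Z) stack."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    return (stack[:, roi].mean(axis=1) >= tau).astype(np.uint8)


def build_cpt(
    states: Sequence[int], labels: Sequence[int], smoothing: float = 1.0
) -> np.ndarray:
    """Smoothed conditional probability table P(class | ROI state).

    Rows index the ROI state (0, 1); columns are P(NMHE), P(MHE).
    P(c | j) = (N_jc + s) / (N_j + 2 s). Rows sum to 1.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    states = np.asarray(states).astype(bool)
    labels = np.asarray(labels).astype(bool)
    cpt = np.empty((2, 2))
    for j in (0, 1):
        sel = states == bool(j)
        n_j = sel.sum()
        n_mhe = (labels & sel).sum()
        denom = n_j + 2 * smoothing
        if denom == 0:  # unsmoothed empty cell: fall back to uniform
            cpt[j] = (0.5, 0.5)
        else:
            cpt[j] = ((n_j - n_mhe + smoothing) / denom, (n_mhe + smoothing) / denom)
    return cpt


class _RoiCache:
    """Caches grown ROIs and their state vectors per representative voxel.

    Both depend only on the binary maps (never on labels), so permutation
    replicates can reuse them.
    """

    def __init__(self, stack: np.ndarray, kappa_sim: float, tau: float):
        self.stack = stack
        self.kappa = kappa_sim
        self.tau = tau
        self._cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def get(self, voxel: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        if voxel not in self._cache:
            roi = grow_roi(voxel, self.stack, self.kappa)
            self._cache[voxel] = (roi, roi_states(self.stack, roi, self.tau))
        return self._cache[voxel]


def _selection_statistic(
    cache: _RoiCache,
    voxel_scores: np.ndarray,
    mask_idx: np.ndarray,
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    labels: np.ndarray,
    alpha_ess: float,
) -> tuple[float, tuple[int, int, int], np.ndarray, np.ndarray]:
    """Best voxel -> grown ROI (clipped to mask) -> ROI-level score.

    Tie-break on the representative voxel: smallest linear (row-major) index.
    Returns (roi_score, rep_voxel, roi_volume, roi_state_vector).
    """
    best = int(np.argmax(voxel_scores))  # first max = smallest linear index
    rep = tuple(int(c) for c in np.unravel_index(mask_idx[best], grid_shape))
    roi, states = cache.get(rep)
    roi = roi & mask
    if not roi[rep]:  # clipping never removes rep (rep is in mask), defensive
        roi = roi.copy()
        roi[rep] = True
    states = roi_states(cache.stack, roi, cache.tau)
    score = float(log_bd_score(states, labels, alpha_ess))
    return score, rep, roi, states


def _permutation_pvalue(
    cache: _RoiCache,
    states_flat: np.ndarray,
    mask_idx: np.ndarray,
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    labels: np.ndarray,
    observed: float,
    params: GammaParams,
    rng: np.random.Generator,
) -> float:
    """p = (1 + #{permuted selection statistic >= observed}) / (B + 1).

    Each permutation reruns the full representative-voxel search and ROI
    scoring on the permuted labels.
    """
    b = params.n_permutations
    perms = np.stack([rng.permutation(labels) for _ in range(b)])
    all_scores = _perm_bd_many(states_flat, perms, params.alpha_ess)  # (B, V)
    count = 0
    for bi in range(b):
        score, *_ = _selection_statistic(
            cache, all_scores[bi], mask_idx, grid_shape, mask, perms[bi], params.alpha_ess
        )
        if score >= observed - 1e-12:
            count += 1
    return (1 + count) / (b + 1)


def validate_model(
    observed_score: float,
    maps: Sequence[BinaryMap] | np.ndarray,
    labels: Sequence[int],
    params: GammaParams | None = None,
    mask: np.ndarray | None = None,
    seed: int | None = None,
) -> float:
    """Permutation p-value for an observed ROI-level score.

    The null statistic is the score the selection procedure itself attains on
    label-permuted data (best voxel, grown and clipped ROI, majority state),
    which makes the test exchangeable with respect to the selection step.
    """
    params = params or GammaParams()
    labels = _check_labels(np.asarray(labels))
    stack = _stack(maps)
    if mask is None:
        mask = np.ones(stack.shape[1:], dtype=bool)
    mask_idx = np.flatnonzero(mask.ravel())
    states_flat = stack.reshape(stack.shape[0], -1)[:, mask_idx].astype(np.uint8)
    cache = _RoiCache(stack, params.kappa_sim, params.tau)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    return _permutation_pvalue(
        cache, states_flat, mask_idx, stack.shape[1:], mask, labels, observed_score, params, rng
    )


def fit_gamma(
    maps: Sequence[BinaryMap] | np.ndarray,
    labels: Sequence[int],
    params: GammaParams | None = None,
    *,
    mask: np.ndarray | None = None,
    icn: str = "ICN00",
    threshold: float = float("nan"),
) -> GammaModel:
    """Discover validated discriminative ROIs.

    ``labels`` is boolean (True = MHE) aligned with ``maps``. Iterates
    score -> representative voxel -> region growing -> ROI-level rescoring ->
    permutation validation, removing each accepted ROI from the mask, until a
    candidate fails validation or ``max_rois`` ROIs are found.
    """
    params = params or GammaParams()
    labels = _check_labels(np.asarray(labels))
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    stack = _stack(maps)
    if stack.shape[0] != labels.size:
        raise ValueError("number of maps and labels differ")
    grid_shape = stack.shape[1:]
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    mask = mask.copy()
    flat = stack.reshape(stack.shape[0], -1)
    cache = _RoiCache(stack, params.kappa_sim, params.tau)
    rng = np.random.default_rng(params.seed)

    model = GammaModel(
        icn=icn, threshold=float(threshold), rois=[], representative_voxels=[],
        cpt=[], scores=[], p_values=[], params=params,
    )
    for _ in range(params.max_rois):
        if not mask.any():
            break
        mask_idx = np.flatnonzero(mask.ravel())
        states_flat = flat[:, mask_idx].astype(np.uint8)
        voxel_scores = _log_bd_many(states_flat, labels, params.alpha_ess)
        score, rep, roi, states = _selection_statistic(
            cache, voxel_scores, mask_idx, grid_shape, mask, labels, params.alpha_ess
        )
        p = _permutation_pvalue(
            cache, states_flat, mask_idx, grid_shape, mask, labels, score, params, rng
        )
        if p >= params.alpha:
            break
        model.rois.append(np.argwhere(roi))
        model.representative_voxels.append(rep)
        model.cpt.append(build_cpt(states, labels, params.cpt_smoothing))
        model.scores.append(score)
        model.p_values.append(p)
        mask &= ~roi
    return model


def roi_volume(roi_voxels: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean volume from an (m, 3) voxel-index array."""
    vol = np.zeros(grid_shape, dtype=bool)
    vol[tuple(np.asarray(roi_voxels).T)] = True
    return vol
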