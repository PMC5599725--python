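"""Two-stage dual regression: subject-specific network time courses and z-maps.

Stage 1 (spatial regression) regresses each time point's volume, flattened over
the analysis mask, on the K template maps (plus intercept), giving a T x K
matrix of per-network time courses. Stage 2 (temporal regression) regresses
each in-mask voxel's time series on those K time courses (plus intercept),
giving K beta maps and per-voxel, per-regressor standard errors. The z-map is
the t-like statistic beta / SE, capped at +/- ``z_cap`` where the residual is
exactly zero; voxels outside the mask get z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import ICNTemplateSet, Scan4D

__all__ = [
    "TimeCourses",
    "SubjectICNMaps",
    "CollinearityError",
    "analysis_mask",
    "spatial_regression",
    "temporal_regression",
    "zscore_map",
    "dual_regress",
]

DEFAULT_Z_CAP = 10.0


class CollinearityError(ValueError):
    """Rank-deficient regressor matrix."""


@dataclass(frozen=True)
class TimeCourses:
    """Per-network time courses (T x K) from the spatial regression stage."""

    values: np.ndarray
    tr_seconds: float = 2.5

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("time courses must be T x K")
        if not np.isfinite(self.values).all():
            raise ValueError("time courses contain non-finite values")


@dataclass
class SubjectICNMaps:
    """Per-subject network maps: betas and z-scores, one volume per network."""

    subject_id: str
    names: list[str]
    beta: np.ndarray  # (K, X, Y, Z)
    z: np.ndarray  # (K, X, Y, Z)


def analysis_mask(templates: ICNTemplateSet, dilate: int = 1) -> np.ndarray:
    """Union of template supports, binary-dilated by ``dilate`` voxels."""
    mask = templates.supports.any(axis=0)
    if dilate > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


def _check_collinear(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the offenders: zero-variance or duplicated columns
        bad = []
        cols = design - design.mean(axis=0)
        sd = cols.std(axis=0)
        # skip the intercept (column 0): centering always zeroes it out
        for j, name in list(enumerate(names))[1:]:
            if sd[j] == 0:
                bad.append(name)
        live_idx = [j for j in range(1, design.shape[1]) if sd[j] > 0]
        if len(live_idx) > 1:
            corr = np.corrcoef(cols[:, live_idx].T)
            for a in range(len(live_idx)):
                for b in range(a + 1, len(live_idx)):
                    if abs(corr[a, b]) > 1 - 1e-10:
                        bad.extend([names[live_idx[a]], names[live_idx[b]]])
        raise CollinearityError(
            f"regressor matrix is rank deficient (rank {rank} < {design.shape[1]});"
            f" offending regressors: {sorted(set(bad)) or 'unidentified'}"
        )


def spatial_regression(
    scan: Scan4D, templates: ICNTemplateSet, mask: np.ndarray | None = None
) -> TimeCourses:
    """OLS of each time point's in-mask volume on the K templates (+ intercept)."""
    if scan.grid_shape != templates.grid_shape:
        raise ValueError(
            f"scan grid {scan.grid_shape} != template grid {templates.grid_shape}"
        )
    k = templates.n_templates
    if scan.n_timepoints <= k + 1:
        raise ValueError("need T > K + 1 time points")
    if mask is None:
        mask = analysis_mask(templates)
    x = np.column_stack(
        [np.ones(int(mask.sum()))] + [templates.maps[j][mask] for j in range(k)]
    )
    _check_collinear(x, ["intercept"] + list(templates.names))
    y = scan.data[mask, :].astype(float)  # (V, T)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)  # (K+1, T)
    return TimeCourses(values=beta[1:].T.copy(), tr_seconds=scan.tr_seconds)


def temporal_regression(
    scan: Scan4D, tc: TimeCourses, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS of the time series on the K time courses (+ intercept).

    Returns ``(beta, se)``, each (K, X, Y, Z): coefficient and standard-error
    volumes. Outside the mask both are zero. A zero residual yields SE = 0 at
    that voxel (downstream z-guarding applies, not an error).
    """
    t_len, k = tc.values.shape
    if scan.n_timepoints != t_len:
        raise ValueError("scan and time courses disagree on T")
    if t_len <= k + 1:
        raise ValueError("need T > K + 1")
    x = np.column_stack([np.ones(t_len), tc.values])
    _check_collinear(x, ["intercept"] + [f"tc{j}" for j in range(k)])
    y = scan.data[mask, :].astype(float).T  # (T, V)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta_all = xtx_inv @ (x.T @ y)  # (K+1, V)
    resid = y - x @ beta_all
    dof = t_len - (k + 1)
    sigma2 = (resid**2).sum(axis=0) / dof  # (V,)
    se_all = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (K+1, V)

    grid = scan.grid_shape
    beta = np.zeros((k,) + grid)
    se = np.zeros((k,) + grid)
    beta[:, mask] = beta_all[1:]
    se[:, mask] = se_all[1:]
    return beta, se


def zscore_map(beta: np.ndarray, se: np.ndarray, z_cap: float = DEFAULT_Z_CAP) -> np.ndarray:
    """z = beta / se, with sign(beta) * z_cap where se == 0."""
    if beta.shape != se.shape:
        raise ValueError("beta and se grids differ")
    z = np.zeros_like(beta, dtype=float)
    ok = se > 0
    z[ok] = beta[ok] / se[ok]
    z[~ok] = np.sign(beta[~ok]) * z_cap
    return z


def dual_regress(
    scan: Scan4D,
    templates: ICNTemplateSet,
    *,
    subject_id: str = "S000",
    mask: np.ndarray | None = None,
    z_cap: float = DEFAULT_Z_CAP,
) -> SubjectICNMaps:
    """Run both stages and return beta and z volumes for every network."""
    if mask is None:
        mask = analysis_mask(templates)
    tc = spatial_regression(scan, templates, mask=mask)
    beta, se = temporal_regression(scan, tc, mask)
    z = zscore_map(beta, se, z_cap=z_cap)
    z[:, ~mask] = 0.0
    return SubjectICNMaps(subject_id=subject_id, names=list(templates.names), beta=beta, z=z)
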