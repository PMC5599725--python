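"""Evaluation of discovered ROIs against group labels and clinical variables.

Two functional-integration patterns summarize a subject's relationship to a
discriminative ROI: the number of suprathreshold ROI voxels in the subject's
binary map (ROI size, N_{D cap ROI}) and the mean connectivity (z) over the ROI
in the unthresholded map (mean FC, FC_{F cap ROI}). Group differences use
pooled-variance two-sample t-tests; associations with clinical scores use
partial correlations controlling for movement, age, gender and education, with
Bonferroni correction across the representative networks.

The module also implements the clinical-side computations: the neuropsychological
MHE diagnostic rule (impairment on at least two of four tests at fixed cutoffs)
and the demographics-table tests (chi-square for categorical rows, summary-based
t-tests for continuous ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MHE, NMHE, SubjectRecord

__all__ = [
    "ClinicalCutoffs",
    "TestResult",
    "roi_size_metric",
    "roi_meanfc_metric",
    "integration_patterns",
    "group_difference_tests",
    "partial_correlation",
    "bonferroni_flags",
    "diagnose_mhe",
    "chi_square_2x2",
    "ttest_from_summary",
    "demographics_table",
]


@dataclass(frozen=True)
class ClinicalCutoffs:
    """Impairment cutoffs (two SD beyond normative performance per test)."""

    tmt_a_max: float = 68.0  # seconds
    tmt_b_max: float = 156.0  # seconds
    dst_min: float = 23.0  # raw score
    bdt_min: float = 16.0  # raw score
    n_required: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.n_required <= 4:
            raise ValueError("n_required must be in 1..4")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    degenerate: bool = False


def roi_size_metric(dmap: np.ndarray, roi: np.ndarray) -> int:
    """Number of voxels suprathreshold in the binary map within the ROI."""
    dmap = np.asarray(dmap).astype(bool)
    roi = np.asarray(roi, dtype=bool)
    if dmap.shape != roi.shape:
        raise ValueError("binary map and ROI grids differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    return int(dmap[roi].sum())


def roi_meanfc_metric(fmap: np.ndarray, roi: np.ndarray) -> float:
    """Mean connectivity (z) over the ROI in the unthresholded map."""
    fmap = np.asarray(fmap, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if fmap.shape != roi.shape:
        raise ValueError("map and ROI grids differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(fmap[roi].mean())


def integration_patterns(
    zstack: np.ndarray,
    roi: np.ndarray,
    threshold: float,
    subject_ids: list[str] | None = None,
    icn: str = "ICN00",
    roi_index: int = 0,
) -> pd.DataFrame:
    """Both integration patterns for every subject over one ROI.

    ``zstack`` is the (n, X, Y, Z) stack of unthresholded z-maps; the binary
    map of each subject is recomputed at ``threshold`` (strict inequality).
    """
    zstack = np.asarray(zstack, dtype=float)
    n = zstack.shape[0]
    if subject_ids is None:
        subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    rows = [
        {
            "subject_id": subject_ids[i],
            "icn": icn,
            "roi": roi_index,
            "n_overlap": roi_size_metric(zstack[i] > threshold, roi),
            "mean_fc": roi_meanfc_metric(zstack[i], roi),
        }
        for i in range(n)
    ]
    return pd.DataFrame(rows)


def group_difference_tests(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """Two-sided pooled-variance two-sample t-test (MHE vs NMHE)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == MHE]
    b = values[groups == NMHE]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p))


def _residuals(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> TestResult:
    """Pearson correlation of x and y after removing covariates by OLS.

    With no covariates this is the plain Pearson correlation. The p-value uses
    t = r sqrt(df / (1 - r^2)) with df = n - n_covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        if n <= k + 2:
            raise ValueError("need n > n_covariates + 2")
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        rx, ry = _residuals(x, design), _residuals(y, design)
    sx = float(np.sqrt((rx**2).sum()))
    sy = float(np.sqrt((ry**2).sum()))
    # residuals that vanish to rounding error (e.g. y lies in the covariate
    # span) carry no information: report r = 0 rather than numerical noise
    tol_x = 1e-10 * max(np.abs(x).max(), 1.0) * np.sqrt(n)
    tol_y = 1e-10 * max(np.abs(y).max(), 1.0) * np.sqrt(n)
    if sx <= tol_x or sy <= tol_y:
        return TestResult(0.0, 1.0, degenerate=True)
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return TestResult(r, 0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(r, float(p))


def bonferroni_flags(pvals, family_size: int, alpha: float = 0.05) -> np.ndarray:
    """Significance flags under Bonferroni correction: p <= alpha / m."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return np.asarray(pvals, dtype=float) <= alpha / family_size


def diagnose_mhe(record: SubjectRecord, cutoffs: ClinicalCutoffs | None = None) -> str:
    """Apply the neuropsychological rule: MHE iff impaired on >= n_required of
    the four tests (TMT-A/TMT-B too slow, DST/BDT too low)."""
    cutoffs = cutoffs or ClinicalCutoffs()
    for name in ("tmt_a", "tmt_b", "dst", "bdt"):
        v = getattr(record, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing score {name} for {record.subject_id}")
    impaired = sum(
        [
            record.tmt_a > cutoffs.tmt_a_max,
            record.tmt_b > cutoffs.tmt_b_max,
            record.dst < cutoffs.dst_min,
            record.bdt < cutoffs.bdt_min,
        ]
    )
    return MHE if impaired >= cutoffs.n_required else NMHE


def chi_square_2x2(table: np.ndarray) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p))


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t-test from group summary statistics."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(np.inf if m1 > m2 else -np.inf, 0.0, degenerate=True)
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestResult(float(t), float(p))


_CONTINUOUS_ROWS = [
    ("age", "Age (years)"),
    ("education", "Education (years)"),
    ("child_pugh", "Child-Pugh score"),
    ("tmt_a", "TMT-A (seconds)"),
    ("tmt_b", "TMT-B (seconds)"),
    ("dst", "DST (raw score)"),
    ("bdt", "BDT (raw score)"),
]


def demographics_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Demographics/clinical comparison of the two groups.

    Continuous characteristics: mean +/- SD per group with a pooled-variance
    t-test. Gender: counts with an (uncorrected) chi-square test.
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    nmhe = df[df["group"] == NMHE]
    mhe = df[df["group"] == MHE]
    rows = []
    for col, label in _CONTINUOUS_ROWS:
        res = group_difference_tests(df[col].to_numpy(), df["group"].to_numpy())
        rows.append(
            {
                "characteristic": label,
                "nmhe": f"{nmhe[col].mean():.1f} ± {nmhe[col].std(ddof=1):.1f}",
                "mhe": f"{mhe[col].mean():.1f} ± {mhe[col].std(ddof=1):.1f}",
                "p": res.p,
                "test": "t",
            }
        )
    table = np.array(
        [
            [(nmhe["gender"] == "M").sum(), (nmhe["gender"] == "F").sum()],
            [(mhe["gender"] == "M").sum(), (mhe["gender"] == "F").sum()],
        ]
    )
    try:
        gender = chi_square_2x2(table)
        rows.append(
            {
                "characteristic": "Gender (M/F)",
                "nmhe": f"{table[0, 0]}/{table[0, 1]}",
                "mhe": f"{table[1, 0]}/{table[1, 1]}",
                "p": gender.p,
                "test": "chi2",
            }
        )
    except ValueError:  # single-gender cohort: no test
        pass
    return pd.DataFrame(rows)
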