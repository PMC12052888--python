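"""Empirical fold-change threshold calibration from control comparisons.

Two vectors of mean N-SC from comparable (null) conditions — e.g. two
halves of the control group — are compared on the natural-log scale.
Proteins in the inner quartile of mean ln-abundance define the
calibration set; the Pearson correlation of their (ln a, ln b) pairs
summarizes reproducibility, and the fold-change threshold is the
smallest candidate t on a grid in [1.5, 2.0] such that the fraction of
inner-quartile proteins with |ln(a/b)| <= ln t reaches the target
coverage (default 99%). If no grid value reaches coverage the threshold
clamps at 2.0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import SpectralCountMatrix
from .quantify import normalize_counts

DEFAULT_GRID = tuple(np.round(np.arange(1.5, 2.0001, 0.05), 2))


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    pearson_r: float
    coverage: float
    fc_threshold: float
    n_inner_quartile: int
    n_zero_excluded: int
    clamped: bool

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "coverage": self.coverage,
            "fc_threshold": self.fc_threshold,
            "n_inner_quartile": self.n_inner_quartile,
            "n_zero_excluded": self.n_zero_excluded,
            "clamped": self.clamped,
        }


def calibrate_fc_threshold(
    control_a,
    control_b,
    grid=DEFAULT_GRID,
    target_coverage: float = 0.99,
    trim: str = "abundance",
) -> CalibrationResult:
    """Pick the smallest grid threshold covering the inner-quartile ratios.

    ``trim="abundance"`` (default) selects proteins whose mean
    ln-abundance, (ln a + ln b)/2, lies within [Q1, Q3] of that
    distribution; ``trim="ratio"`` trims by the ln-ratio instead.
    Zeros are excluded (ln undefined) and counted.
    """
    a = np.asarray(control_a, dtype=float)
    b = np.asarray(control_b, dtype=float)
    if a.shape != b.shape:
        raise CalibrationError("control vectors must share a protein list")
    grid = sorted(float(t) for t in grid)
    if not grid or grid[0] < 1.5 - 1e-9 or grid[-1] > 2.0 + 1e-9:
        raise CalibrationError("grid must be non-empty and lie within [1.5, 2.0]")
    if not 0 < target_coverage <= 1:
        raise CalibrationError("target_coverage must lie in (0, 1]")
    if trim not in ("abundance", "ratio"):
        raise CalibrationError("trim must be 'abundance' or 'ratio'")

    positive = (a > 0) & (b > 0)
    n_zero = int((~positive).sum())
    a, b = a[positive], b[positive]
    if a.size < 8:
        raise CalibrationError(f"only {a.size} positive proteins; quartile trimming needs >= 8")

    la, lb = np.log(a), np.log(b)
    key = (la + lb) / 2 if trim == "abundance" else la - lb
    q1, q3 = np.percentile(key, [25, 75])
    inner = (key >= q1) & (key <= q3)
    la_i, lb_i = la[inner], lb[inner]

    if np.allclose(la_i, lb_i):
        r = 1.0
    elif np.std(la_i) == 0 or np.std(lb_i) == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(la_i, lb_i)[0])

    ratios = np.abs(la_i - lb_i)
    threshold, coverage, clamped = None, None, False
    for t in grid:
        cov = float(np.mean(ratios <= np.log(t) + 1e-12))
        if cov >= target_coverage:
            threshold, coverage = t, cov
            break
    if threshold is None:
        threshold = 2.0
        coverage = float(np.mean(ratios <= np.log(2.0) + 1e-12))
        clamped = True
        warnings.warn(
            f"control ratio spread exceeds the 2.0-fold cap (coverage {coverage:.3f} "
            f"< target {target_coverage}); threshold clamped at 2.0",
            RuntimeWarning,
            stacklevel=2,
        )
    return CalibrationResult(
        pearson_r=r,
        coverage=coverage,
        fc_threshold=float(threshold),
        n_inner_quartile=int(inner.sum()),
        n_zero_excluded=n_zero,
        clamped=clamped,
    )


def split_control_pairs(matrix: SpectralCountMatrix, group: str, seed: int) -> tuple[pd.Series, pd.Series]:
    """Seeded half-split of one group into a control pair.

    Normalizes first if given a raw matrix, randomly halves the group's
    samples, and returns the per-protein mean N-SC of each half over the
    proteins detected (nonzero somewhere) in both halves.
    """
    samples = matrix.samples_in(group)
    if len(samples) < 4:
        raise CalibrationError(f"group {group} has {len(samples)} samples; splitting needs >= 4")
    if matrix.flavor == "raw":
        matrix = normalize_counts(matrix)
    rng = np.random.default_rng(seed)
    perm = [samples[i] for i in rng.permutation(len(samples))]
    half = len(perm) // 2
    h1, h2 = perm[:half], perm[half:]
    v1, v2 = matrix.values[h1], matrix.values[h2]
    present = (v1.sum(axis=1) > 0) & (v2.sum(axis=1) > 0)
    return v1.loc[present].mean(axis=1), v2.loc[present].mean(axis=1)
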