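"""Between-sample normalization and per-group summaries.

Normalized spectral counts (N-SC) rescale each sample column so all
column totals equal the mean library size; the matrix grand total is
preserved. Group summaries are per-protein means and sample standard
deviations (n-1 denominator) of N-SC in each group — the ingredients
of the SAM-style weight statistic and the fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GROUP_A, GROUP_B, SpectralCountMatrix


class QuantifyError(ValueError):
    pass


def normalize_counts(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Scale each sample to the mean column total (total-count N-SC).

    Column j is multiplied by ``mean(column totals) / total_j``, making
    all column totals equal while preserving the grand total.
    """
    totals = matrix.values.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise QuantifyError(f"all-zero sample column(s): {zero}")
    factors = totals.mean() / totals
    nsc = matrix.values * factors
    return matrix.with_values(nsc.astype(float), flavor="normalized")


@dataclass
class GroupSummary:
    """Per-protein group means (mu) and sample SDs (delta) of N-SC."""

    table: pd.DataFrame  # columns: mu_a, mu_b, delta_a, delta_b

    def __getitem__(self, protein_id: str) -> pd.Series:
        return self.table.loc[protein_id]


def group_summary(matrix: SpectralCountMatrix) -> GroupSummary:
    """Means and sample SDs per group; each group needs >= 2 samples."""
    parts = {}
    for group, mu_col, sd_col in ((GROUP_A, "mu_a", "delta_a"), (GROUP_B, "mu_b", "delta_b")):
        vals = matrix.group_values(group)
        if vals.shape[1] < 2:
            raise QuantifyError(f"group {group} has {vals.shape[1]} sample(s); need >= 2")
        parts[mu_col] = vals.mean(axis=1)
        parts[sd_col] = vals.std(axis=1, ddof=1)
    table = pd.DataFrame(parts)[["mu_a", "mu_b", "delta_a", "delta_b"]]
    table.index.name = "protein_id"
    return GroupSummary(table)


@dataclass
class PresenceFlags:
    """Per-protein detection flags under a min-nonzero-samples rule."""

    table: pd.DataFrame  # boolean columns: present_a, present_b
    min_samples: int = 1


def detect_presence(matrix: SpectralCountMatrix, min_samples: int = 1) -> PresenceFlags:
    """Flag a protein present in a group iff >= ``min_samples`` samples
    of that group have a nonzero count."""
    if min_samples < 1:
        raise QuantifyError("min_samples must be >= 1")
    smaller = min(len(matrix.samples_in(GROUP_A)), len(matrix.samples_in(GROUP_B)))
    if min_samples > smaller:
        raise QuantifyError(f"min_samples={min_samples} exceeds the smaller group size ({smaller})")
    nz_a = (matrix.group_values(GROUP_A) > 0).sum(axis=1)
    nz_b = (matrix.group_values(GROUP_B) > 0).sum(axis=1)
    table = pd.DataFrame({"present_a": nz_a >= min_samples, "present_b": nz_b >= min_samples})
    table.index.name = "protein_id"
    return PresenceFlags(table, min_samples=min_samples)
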