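"""Differential expression of spectral counts via a three-test conjunction.

The procedure computes, per protein, on normalized spectral counts (N-SC):

* a SAM-style weight ``W = (mu1 - mu2) / (delta1 - delta2)`` — group
  mean separation scaled by the (as-printed, difference-of-SDs) spread
  term; an alternative ``sum`` denominator ``delta1 + delta2`` is
  available because the difference form is sign-unstable;
* a one-tailed Welch (unequal-variance) t-test p-value, taken in the
  direction of the observed mean difference, so p <= 0.5;
* a signed fold change ``FC = mu_a / mu_b`` reported as ``-mu_b / mu_a``
  when the ratio is below 1, so |FC| >= 1 and depletion is negative.

A protein is called ``up`` iff |W| > w_cut AND p < p_cut AND
FC >= +fc_cut, ``down`` symmetrically — all three tests must pass.
Proteins detected in only one group are classed ``unique_a``/``unique_b``
and bypass the gate (and the BH family). Benjamini-Hochberg adjusted
p-values (q) are reported across the tested proteins for the volcano
display; the gate itself uses the raw p.

The statsmodels-style entry point is :class:`DifferentialSpectralCounts`
(model) / :class:`DifferentialExpressionResults` (results).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import bh_adjust, venn_partition, VennCounts
from .matrix import GROUP_A, GROUP_B, SpectralCountMatrix, make_group_map
from .quantify import GroupSummary, detect_presence, group_summary, normalize_counts

_DEGENERATE_DENOM = 1e-12

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_UNIQUE_A = "unique_a"
STATUS_UNIQUE_B = "unique_b"


@dataclass(frozen=True)
class GateThresholds:
    """The three cutoffs of the conjunction gate.

    w_cut
        SAM-weight cutoff; the gate tests ``|W| > w_cut``. Default 0.8.
    p_cut
        One-tailed Welch p cutoff, strict ``<``. Default 0.05.
    fc_cut
        Fold-change magnitude cutoff (>= 1); calibratable on [1.5, 2.0].
        The gate tests ``FC >= +fc_cut`` / ``FC <= -fc_cut``. Default 1.5.
    w_variant
        ``"difference"`` uses the as-printed denominator delta1 - delta2;
        ``"sum"`` uses delta1 + delta2.
    """

    w_cut: float = 0.8
    p_cut: float = 0.05
    fc_cut: float = 1.5
    w_variant: str = "difference"

    def __post_init__(self) -> None:
        if self.w_cut <= 0:
            raise ValueError("w_cut must be positive")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if self.w_variant not in ("difference", "sum"):
            raise ValueError("w_variant must be 'difference' or 'sum'")

    def to_dict(self) -> dict:
        return asdict(self)


def sam_weight(mu1, mu2, delta1, delta2, variant: str = "difference"):
    """SAM-style weight; NaN (flagged) when the denominator degenerates.

    ``difference`` -> (mu1 - mu2)/(delta1 - delta2) as printed;
    ``sum`` -> (mu1 - mu2)/(delta1 + delta2). A |denominator| below
    1e-12 yields NaN with a warning, and the W gate treats it as failed.
    """
    mu1, mu2, delta1, delta2 = (np.asarray(x, dtype=float) for x in (mu1, mu2, delta1, delta2))
    if variant == "difference":
        denom = delta1 - delta2
    elif variant == "sum":
        denom = delta1 + delta2
    else:
        raise ValueError("variant must be 'difference' or 'sum'")
    degenerate = np.abs(denom) < _DEGENERATE_DENOM
    n_degen = int(np.count_nonzero(degenerate))
    if n_degen:
        warnings.warn(
            f"SAM weight denominator degenerate for {n_degen} protein(s); W flagged non-finite",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(degenerate, np.nan, (mu1 - mu2) / np.where(degenerate, 1.0, denom))
    if w.ndim == 0:
        return float(w)
    return w


def welch_one_tailed_p(values_a, values_b):
    """One-tailed Welch p in the direction of the observed difference.

    Uses the unequal-variance t statistic with Welch-Satterthwaite
    degrees of freedom; p = P[T >= |t|] <= 0.5. When both groups are
    constant with equal means, t = 0 and p = 0.5 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("each group needs at least 2 values")
    return _welch_p_from_moments(
        a.mean(axis=-1), b.mean(axis=-1), a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1), a.shape[-1], b.shape[-1]
    )


def _welch_p_from_moments(ma, mb, va, vb, na, nb):
    ma, mb, va, vb = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (ma, mb, va, vb))
    se2 = va / na + vb / nb
    zero_se = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(np.where(zero_se, 1.0, se2))
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = sps.t.sf(np.abs(t), df)
    # zero pooled SE: equal constant groups -> t = 0 convention (p = .5);
    # distinct constant groups -> infinitely separated (p -> 0)
    p = np.where(zero_se, np.where(ma == mb, 0.5, 0.0), p)
    if p.shape == (1,):
        return float(p[0])
    return p


_UNIQUE_MARKER = np.nan  # FC is undefined (presence semantics), not a number


def signed_fold_change(mu_a, mu_b, pseudocount: float = 0.0):
    """Signed ratio with |FC| >= 1; depletion as negative reciprocal.

    r = (mu_a + c)/(mu_b + c); returns +r when r >= 1, else -1/r, so
    fc(A,B) = -fc(B,A) whenever r != 1. With pseudocount 0 and exactly
    one zero mean the ratio is undefined and NaN (the unique marker) is
    returned; both means zero is an error.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    if np.any((mu_a < 0) | (mu_b < 0)):
        raise ValueError("means must be non-negative")
    if np.any((mu_a == 0) & (mu_b == 0)):
        raise ValueError("fold change undefined: both group means are zero")
    c = float(pseudocount)
    if c < 0:
        raise ValueError("pseudocount must be >= 0")
    num, den = mu_a + c, mu_b + c
    undefined = (num == 0) | (den == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(undefined, np.nan, num / np.where(den == 0, 1.0, den))
        fc = np.where(r >= 1, r, -1.0 / r)
    fc = np.where(undefined, _UNIQUE_MARKER, fc)
    if fc.ndim == 0:
        return float(fc)
    return fc


def gate_call(w, p, fc, thresholds: GateThresholds = GateThresholds()) -> str:
    """Conjunction call for one protein: all three tests must pass."""
    if not np.isfinite(w) or not np.isfinite(fc) or not np.isfinite(p):
        return STATUS_NS
    if abs(w) > thresholds.w_cut and p < thresholds.p_cut:
        if fc >= thresholds.fc_cut:
            return STATUS_UP
        if fc <= -thresholds.fc_cut:
            return STATUS_DOWN
    return STATUS_NS


class DifferentialSpectralCounts:
    """Two-group differential-expression model for spectral counts.

    Parameters
    ----------
    counts
        Raw :class:`SpectralCountMatrix` (protein x sample, integer
        counts, with a sample -> {A, B} group map).
    thresholds
        :class:`GateThresholds` for the conjunction gate.
    pseudocount
        Added to both group means before the fold-change ratio; default
        0 (group-unique proteins are handled structurally instead).
    min_presence_samples
        Minimum nonzero samples per group for a protein to count as
        detected in that group (default 1).

    Examples
    --------
    >>> model = DifferentialSpectralCounts.from_dataframe(counts_df, groups)
    >>> res = model.fit()
    >>> res.table.head(); print(res.summary())
    """

    def __init__(
        self,
        counts: SpectralCountMatrix,
        thresholds: GateThresholds = GateThresholds(),
        pseudocount: float = 0.0,
        min_presence_samples: int = 1,
    ):
        if counts.flavor != "raw":
            raise ValueError("the model expects a raw count matrix; it normalizes internally")
        self.counts = counts
        self.thresholds = thresholds
        self.pseudocount = float(pseudocount)
        self.min_presence_samples = int(min_presence_samples)

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, groups, **kwargs) -> "DifferentialSpectralCounts":
        """Build from a protein x sample DataFrame and a group mapping.

        ``groups`` may be a dict/Series ``sample -> 'A'|'B'`` or a pair
        ``(samples_a, samples_b)`` of column-name lists.
        """
        if isinstance(groups, tuple) and len(groups) == 2:
            gm = make_group_map(*groups)
        elif isinstance(groups, pd.Series):
            gm = groups.to_dict()
        else:
            gm = dict(groups)
        return cls(SpectralCountMatrix(counts, gm, flavor="raw"), **kwargs)

    def fit(self) -> "DifferentialExpressionResults":
        """Normalize, summarize, test, gate; return the results object."""
        nsc = normalize_counts(self.counts)
        presence = detect_presence(self.counts, min_samples=self.min_presence_samples)
        summ = group_summary(nsc)

        flags = presence.table
        unique_a = flags.present_a & ~flags.present_b
        unique_b = flags.present_b & ~flags.present_a
        tested = ~(unique_a | unique_b)

        t = summ.table
        w = sam_weight(t.mu_a, t.mu_b, t.delta_a, t.delta_b, variant=self.thresholds.w_variant)

        a_vals = nsc.group_values(GROUP_A).to_numpy()
        b_vals = nsc.group_values(GROUP_B).to_numpy()
        p = np.atleast_1d(welch_one_tailed_p(a_vals, b_vals))

        fc = np.full(len(t), np.nan)
        mu_a = t.mu_a.to_numpy()
        mu_b = t.mu_b.to_numpy()
        tm = tested.to_numpy()
        if tm.any():
            fc[tm] = signed_fold_change(mu_a[tm], mu_b[tm], pseudocount=self.pseudocount)

        q = np.full(len(t), np.nan)
        if tm.any():
            q[tm] = bh_adjust(p[tm])

        with np.errstate(invalid="ignore"):
            log2fc = np.where(np.isfinite(fc), np.sign(fc) * np.log2(np.abs(fc)), np.nan)

        th = self.thresholds
        with np.errstate(invalid="ignore"):
            pass_w = np.isfinite(w) & (np.abs(w) > th.w_cut)
            pass_p = p < th.p_cut
            up = pass_w & pass_p & np.isfinite(fc) & (fc >= th.fc_cut)
            down = pass_w & pass_p & np.isfinite(fc) & (fc <= -th.fc_cut)
        status = np.full(len(t), STATUS_NS, dtype=object)
        status[up & tm] = STATUS_UP
        status[down & tm] = STATUS_DOWN
        status[unique_a.to_numpy()] = STATUS_UNIQUE_A
        status[unique_b.to_numpy()] = STATUS_UNIQUE_B

        table = t.copy()
        table["w"] = w
        table["p"] = p
        table["q"] = q
        table["fc"] = fc
        table["log2fc"] = log2fc
        table["status"] = status
        return DifferentialExpressionResults(self, table, nsc, presence, GroupSummary(t))

    # statsmodels spelling
    def fit_table(self) -> pd.DataFrame:
        return self.fit().table


class DifferentialExpressionResults:
    """Fit results: the per-protein DEP table plus derived views.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``mu_a, mu_b, delta_a, delta_b, w, p, q, fc, log2fc,
        status`` indexed by protein id.
    nsc : SpectralCountMatrix
        The normalized matrix the statistics were computed on.
    """

    def __init__(self, model, table, nsc, presence, summary_):
        self.model = model
        self.table = table
        self.nsc = nsc
        self.presence = presence
        self.group_summary = summary_
        self.thresholds = model.thresholds

    @property
    def status_counts(self) -> dict[str, int]:
        vc = self.table["status"].value_counts()
        return {s: int(vc.get(s, 0)) for s in (STATUS_UP, STATUS_DOWN, STATUS_NS, STATUS_UNIQUE_A, STATUS_UNIQUE_B)}

    def venn(self) -> VennCounts:
        counts, _ = venn_partition(self.presence)
        return counts

    # -- report views ----------------------------------------------------------

    def volcano_table(self) -> pd.DataFrame:
        from .report import volcano_table

        return volcano_table(self.table, self.thresholds)

    def pca_scores(self, k: int = 3):
        from .report import pca_scores

        return pca_scores(self.nsc, k=k)

    def heatmap_order(self, proteins=None, metric: str = "euclidean"):
        from .report import heatmap_order

        sel = self.nsc.values if proteins is None else self.nsc.values.loc[list(proteins)]
        return heatmap_order(sel, metric=metric)

    def summary(self) -> str:
        """Human-readable run summary (thresholds and status tallies)."""
        th = self.thresholds
        sc = self.status_counts
        na = len(self.nsc.samples_in(GROUP_A))
        nb = len(self.nsc.samples_in(GROUP_B))
        lines = [
            "Differential spectral-count analysis (three-test conjunction)",
            "=" * 62,
            f"proteins: {len(self.table):5d}    samples: {na} (A) vs {nb} (B)",
            f"gate: |W| > {th.w_cut}  AND  one-tailed Welch p < {th.p_cut}  AND  |FC| >= {th.fc_cut}",
            f"W variant: {th.w_variant}   pseudocount: {self.model.pseudocount}",
            "-" * 62,
            f"up: {sc['up']:5d}   down: {sc['down']:5d}   ns: {sc['ns']:5d}   "
            f"unique A: {sc['unique_a']:4d}   unique B: {sc['unique_b']:4d}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def run_metadata(self) -> dict:
        return {
            "thresholds": self.thresholds.to_dict(),
            "pseudocount": self.model.pseudocount,
            "min_presence_samples": self.model.min_presence_samples,
            "one_tailed_direction": "observed mean difference",
            "status_counts": self.status_counts,
        }

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def run_dep(
    matrix: SpectralCountMatrix,
    thresholds: GateThresholds = GateThresholds(),
    pseudocount: float = 0.0,
    min_presence_samples: int = 1,
) -> pd.DataFrame:
    """Full per-protein differential-expression table (function form)."""
    return (
        DifferentialSpectralCounts(
            matrix, thresholds=thresholds, pseudocount=pseudocount, min_presence_samples=min_presence_samples
        )
        .fit()
        .table
    )
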