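"""Volcano, PCA and heatmap-ordering views of a DEP table.

The canonical outputs are plain tables (TSV-writable DataFrames); figure
rendering is an optional convenience on top of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .matrix import GROUP_A, SpectralCountMatrix
from .model import GateThresholds, STATUS_DOWN, STATUS_NS, STATUS_UP


class ReportError(ValueError):
    pass


def volcano_table(dep_table: pd.DataFrame, thresholds: GateThresholds = GateThresholds()) -> pd.DataFrame:
    """log2 FC vs -log10 q per tested protein (uniques excluded).

    The returned frame carries the reference lines as attrs:
    ``x_lines`` at +/- log2(fc_cut) and ``y_line`` at -log10(0.05).
    """
    tested = dep_table[dep_table["status"].isin([STATUS_UP, STATUS_DOWN, STATUS_NS])].copy()
    tested = tested[np.isfinite(tested["fc"])]
    out = pd.DataFrame(
        {
            "log2fc": np.sign(tested["fc"]) * np.log2(np.abs(tested["fc"])),
            "neg_log10_q": -np.log10(tested["q"]),
            "category": tested["status"],
        },
        index=tested.index,
    )
    out.index.name = "protein_id"
    out.attrs["x_lines"] = (-np.log2(thresholds.fc_cut), np.log2(thresholds.fc_cut))
    out.attrs["y_line"] = -np.log10(0.05)
    return out


@dataclass
class PcaScores:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # proteins x components


def pca_scores(matrix: SpectralCountMatrix, k: int = 3) -> PcaScores:
    """Sample scores from an exact SVD of log2(N-SC + 1), centered per protein.

    Deterministic up to sign; each component's sign is fixed so its
    largest-magnitude protein loading is positive.
    """
    n_samples = len(matrix.sample_ids)
    n_proteins = len(matrix.protein_ids)
    if not 1 <= k <= min(n_samples - 1, n_proteins):
        raise ReportError(f"k={k} must lie in [1, min(n_samples - 1, n_proteins)]")
    x = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each protein across samples
    # samples as observations: SVD of the samples x proteins matrix
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :k] * s[:k]
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaScores(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        explained_variance_ratio=evr[:k],
        loadings=pd.DataFrame(vt[:k].T, index=matrix.protein_ids, columns=cols),
    )


@dataclass
class HeatmapOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    zscores: pd.DataFrame


def heatmap_order(values: pd.DataFrame, metric: str = "euclidean", linkage: str = "average") -> HeatmapOrder:
    """Average-linkage orderings of z-scored rows and of columns.

    Rows (proteins) are z-scored before clustering; zero-variance rows
    z-score to 0 under the euclidean metric and are an error under the
    correlation metric (correlation undefined). Ordering is
    deterministic given the scipy tie-breaking (lower index first).
    """
    if values.shape[0] < 2:
        raise ReportError("heatmap ordering needs >= 2 rows")
    if metric not in ("euclidean", "correlation"):
        raise ReportError("metric must be 'euclidean' or 'correlation'")
    if linkage != "average":
        raise ReportError("only average linkage is supported")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if metric == "correlation" and (sd == 0).any():
        flat = values.index[sd == 0].tolist()
        raise ReportError(f"zero-variance row(s) under the correlation metric: {flat[:5]}")
    mean = x.mean(axis=1, keepdims=True)
    z = np.where(sd[:, None] > 0, (x - mean) / np.where(sd[:, None] == 0, 1.0, sd[:, None]), 0.0)
    row_link = hierarchy.linkage(pdist(z, metric=metric), method="average")
    col_link = hierarchy.linkage(pdist(z.T, metric="euclidean"), method="average")
    row_order = [values.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [values.columns[i] for i in hierarchy.leaves_list(col_link)]
    return HeatmapOrder(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        zscores=pd.DataFrame(z, index=values.index, columns=values.columns),
    )


def render_volcano(volcano: pd.DataFrame, path) -> None:
    """Optional PNG/SVG rendering of the volcano table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {STATUS_UP: "tab:red", STATUS_DOWN: "tab:green", STATUS_NS: "0.7"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, sub in volcano.groupby("category"):
        ax.scatter(sub["log2fc"], sub["neg_log10_q"], s=8, c=colors.get(cat, "0.7"), label=cat)
    for xl in volcano.attrs.get("x_lines", ()):
        ax.axvline(xl, ls="--", lw=0.8, c="k")
    if "y_line" in volcano.attrs:
        ax.axhline(volcano.attrs["y_line"], ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (A / B)")
    ax.set_ylabel("-log10 BH-adjusted p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_pca(pca: PcaScores, group_map, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for sample in pca.scores.index:
        g = group_map[sample]
        ax.scatter(
            pca.scores.loc[sample, "PC1"],
            pca.scores.loc[sample, "PC2"] if pca.scores.shape[1] > 1 else 0.0,
            c="tab:red" if g == GROUP_A else "tab:blue",
        )
        ax.annotate(sample, (pca.scores.loc[sample, "PC1"], pca.scores.loc[sample].get("PC2", 0.0)), fontsize=6)
    ax.set_xlabel(f"PC1 ({pca.explained_variance_ratio[0]:.0%})")
    if pca.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({pca.explained_variance_ratio[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
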