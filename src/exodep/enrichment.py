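"""Presence/absence Venn partition and over-representation analysis.

The Venn partition splits the identified inventory into proteins common
to both groups and proteins unique to either. Over-representation
analysis (ORA) tests each annotation term for enrichment in a query set
against a background using the one-sided hypergeometric upper tail
(identical to a one-sided Fisher exact test on the 2x2 table), with
Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import PresenceFlags


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class VennCounts:
    n_common: int
    n_only_a: int
    n_only_b: int

    @property
    def n_total(self) -> int:
        return self.n_common + self.n_only_a + self.n_only_b


def venn_partition(flags: PresenceFlags) -> tuple[VennCounts, pd.Series]:
    """Partition proteins into common / only-A / only-B classes.

    Returns the counts and a per-protein class label series
    (``common``, ``only_a``, ``only_b``; ``absent`` should not occur in
    matrices produced by evidence assembly but is labelled if present).
    """
    t = flags.table
    if t.empty:
        raise EnrichmentError("presence flags are empty")
    labels = pd.Series(
        np.select(
            [t.present_a & t.present_b, t.present_a & ~t.present_b, ~t.present_a & t.present_b],
            ["common", "only_a", "only_b"],
            default="absent",
        ),
        index=t.index,
        name="venn_class",
    )
    counts = VennCounts(
        n_common=int((labels == "common").sum()),
        n_only_a=int((labels == "only_a").sum()),
        n_only_b=int((labels == "only_b").sum()),
    )
    return counts, labels


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(f"{path}:{ln}: GMT lines need term, description and >=1 member")
            term, desc, members = parts[0], parts[1], frozenset(parts[2:])
            out[term] = (desc, members)
    return out


def write_gmt(annotations: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in annotations:
            desc, members = annotations[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def ora(
    query: Iterable[str],
    annotations: Mapping[str, tuple[str, frozenset[str]]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    For a term covering K of the N background identifiers and a query of
    size n with k overlaps, p = P[X >= k] for X ~ Hypergeom(N, K, n).
    Terms are intersected with the background; terms with no background
    members are dropped. Results are BH-adjusted and sorted by p (ties
    by term id); ``significant`` flags q <= alpha.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise EnrichmentError(f"query identifiers outside the background: {sorted(stray)[:10]}")
    n, N = len(query), len(background)
    columns = ["term_id", "term_name", "k", "K", "n", "N", "p", "q", "significant"]
    if n == 0:
        return pd.DataFrame(columns=columns)
    rows = []
    for term in sorted(annotations):
        desc, members = annotations[term]
        members = frozenset(members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # upper tail P[X >= k]; k = 0 gives the certain event, p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, desc, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=columns[:7])
    if df.empty:
        return pd.DataFrame(columns=columns)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] <= alpha
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
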