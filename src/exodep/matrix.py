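"""Spectral-count matrices and their on-disk TSV representation.

A :class:`SpectralCountMatrix` is a protein x sample table of spectral
counts (raw integers straight from evidence assembly, or real-valued
normalized spectral counts, N-SC) together with a mapping of each sample
to one of two experimental groups, conventionally ``A`` (e.g. treated /
myopic) and ``B`` (control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUP_A = "A"
GROUP_B = "B"
_VALID_GROUPS = (GROUP_A, GROUP_B)


class MatrixError(ValueError):
    """Raised for structurally invalid count matrices or group maps."""


@dataclass
class SpectralCountMatrix:
    """Protein x sample count table with a two-group sample map.

    Parameters
    ----------
    values
        DataFrame indexed by protein identifier with one column per
        sample. Raw matrices must hold non-negative integers.
    group_map
        Mapping ``sample_id -> group``, groups drawn from ``{"A", "B"}``.
        Every sample column must be mapped and both groups must be
        non-empty.
    flavor
        ``"raw"`` for integer spectral counts, ``"normalized"`` for N-SC.
    """

    values: pd.DataFrame
    group_map: Mapping[str, str]
    flavor: str = "raw"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.group_map = dict(self.group_map)
        if self.flavor not in ("raw", "normalized"):
            raise MatrixError(f"unknown flavor {self.flavor!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixError(f"duplicate protein identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise MatrixError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if arr.size and (np.asarray(arr, dtype=float) < 0).any():
            raise MatrixError("negative counts are not allowed")
        if self.flavor == "raw" and arr.size:
            if not np.allclose(np.asarray(arr, float) % 1, 0):
                raise MatrixError("raw matrices must contain integer counts")
        missing = [s for s in self.values.columns if s not in self.group_map]
        if missing:
            raise MatrixError(f"samples missing from group map: {missing}")
        bad = {s: g for s, g in self.group_map.items() if g not in _VALID_GROUPS}
        if bad:
            raise MatrixError(f"groups must be one of {_VALID_GROUPS}: {bad}")
        groups = {self.group_map[s] for s in self.values.columns}
        if self.values.shape[1] and groups != set(_VALID_GROUPS):
            raise MatrixError("both groups A and B must be present among samples")

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_map[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def with_values(self, values: pd.DataFrame, flavor: str) -> "SpectralCountMatrix":
        return SpectralCountMatrix(values, self.group_map, flavor=flavor)

    def swap_groups(self) -> "SpectralCountMatrix":
        """Relabel A<->B (useful for symmetry checks)."""
        swapped = {s: (GROUP_B if g == GROUP_A else GROUP_A) for s, g in self.group_map.items()}
        return SpectralCountMatrix(self.values.copy(), swapped, flavor=self.flavor)

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "protein_id"
        out.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            write_group_map(self.group_map, samples_path)


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": list(group_map), "group": [group_map[s] for s in group_map]})
    df.to_csv(path, sep="\t", index=False)


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise MatrixError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    return dict(zip(df["sample_id"], df["group"]))


def read_counts(
    counts_path: str | Path,
    samples_path: str | Path | None = None,
    group_map: Mapping[str, str] | None = None,
    flavor: str = "raw",
) -> SpectralCountMatrix:
    """Read a counts TSV (``protein_id`` first column, one column per sample)."""
    df = pd.read_csv(counts_path, sep="\t", index_col="protein_id")
    if group_map is None:
        if samples_path is None:
            raise MatrixError("either samples_path or group_map is required")
        group_map = read_group_map(samples_path)
    return SpectralCountMatrix(df, group_map, flavor=flavor)


def make_group_map(samples_a: Iterable[str], samples_b: Iterable[str]) -> dict[str, str]:
    gm = {s: GROUP_A for s in samples_a}
    gm.update({s: GROUP_B for s in samples_b})
    return gm
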