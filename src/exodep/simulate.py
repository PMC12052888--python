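"""Synthetic two-group spectral-count studies with known ground truth.

The generator emulates a label-free spectral-counting comparison of a
small treated group against a larger control group (defaults: 4 vs 7
samples over 506 proteins, with 48 proteins structurally unique to group
A and 41 to group B). Counts are negative-binomial around log-normal
per-protein baselines with per-sample library-size factors; a subset of
proteins carries planted multiplicative fold changes on the group-A
mean. Presence classes are enforced structurally: any protein whose
sampled row would violate its class (e.g. a "common" protein with an
all-zero group) is resampled from its own RNG stream, so the Venn
partition of the output is deterministic given the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import GROUP_A, GROUP_B, SpectralCountMatrix, make_group_map

LABEL_NULL = "null"
LABEL_UP = "up"
LABEL_DOWN = "down"
LABEL_UNIQUE_A = "unique_a"
LABEL_UNIQUE_B = "unique_b"

_MAX_RESAMPLE = 100


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for one simulated experiment.

    The defaults mirror the emulated study: 506 proteins, 48 unique to
    the treated group (A) and 41 to the control group (B), 79 planted up
    and 70 down, 4 vs 7 samples. Baseline expected counts are log-normal
    (ln-mean 1.5, ln-sd 1.0, i.e. median ~4.5 spectra per sample);
    counts are negative binomial with dispersion 0.1 (variance
    m + 0.1 m^2); per-sample size factors are log-normal with ln-sd
    0.15; planted |log2 FC| is uniform on [0.8, 2.0] so some effects
    straddle a 1.5-fold gate.
    """

    total_proteins: int = 506
    n_unique_a: int = 48
    n_unique_b: int = 41
    n_up: int = 79
    n_down: int = 70
    n_a: int = 4
    n_b: int = 7
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    effect_log2fc_range: tuple[float, float] = (0.8, 2.0)
    size_factor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        ints = ("total_proteins", "n_unique_a", "n_unique_b", "n_up", "n_down", "n_a", "n_b")
        for name in ints:
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if self.total_proteins < 1:
            raise SimulationError("total_proteins must be positive")
        planted = self.n_unique_a + self.n_unique_b + self.n_up + self.n_down
        if planted > self.total_proteins:
            raise SimulationError(
                f"class counts ({planted}) exceed total_proteins ({self.total_proteins})"
            )
        if self.n_a < 2 or self.n_b < 2:
            raise SimulationError("each group needs >= 2 samples")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be positive")
        lo, hi = self.effect_log2fc_range
        if not (0 < lo <= hi):
            raise SimulationError("effect_log2fc_range must be an interval of positive reals")
        if self.size_factor_sd < 0:
            raise SimulationError("size_factor_sd must be >= 0")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "effect_log2fc_range" in data:
            data["effect_log2fc_range"] = tuple(data["effect_log2fc_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-protein class label and true log2 fold change (A over B)."""

    table: pd.DataFrame  # columns: label, true_log2fc

    def label_counts(self) -> dict[str, int]:
        vc = self.table["label"].value_counts()
        return {k: int(vc.get(k, 0)) for k in (LABEL_NULL, LABEL_UP, LABEL_DOWN, LABEL_UNIQUE_A, LABEL_UNIQUE_B)}


@dataclass
class SimulatedStudy:
    counts: SpectralCountMatrix
    truth: GroundTruth
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write counts/samples/truth TSVs and the config JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": str(out / "counts.tsv"),
            "samples": str(out / "samples.tsv"),
            "truth": str(out / "truth.tsv"),
            "config": str(out / "config.json"),
        }
        self.counts.to_tsv(paths["counts"], paths["samples"])
        t = self.truth.table.copy()
        t.index.name = "protein_id"
        t.to_csv(paths["truth"], sep="\t")
        self.config.to_json(paths["config"])
        return paths


def _nb_row(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and variance mu + dispersion*mu^2."""
    r = 1.0 / dispersion
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _row_ok(label: str, row: np.ndarray, n_a: int) -> bool:
    a_nonzero = (row[:n_a] > 0).any()
    b_nonzero = (row[n_a:] > 0).any()
    if label == LABEL_UNIQUE_A:
        return a_nonzero
    if label == LABEL_UNIQUE_B:
        return b_nonzero
    return a_nonzero and b_nonzero  # null/up/down must be detected in both


def simulate_counts(config: SimulationConfig) -> SimulatedStudy:
    """Draw one study; bit-identical for identical config (incl. seed).

    One study-level RNG stream (baselines, size factors, label
    placement, effect sizes) plus one spawned sub-stream per protein for
    its count row, so resampling a violating row never perturbs other
    proteins.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.total_proteins + 1)
    study_rng = np.random.default_rng(children[0])

    n = config.total_proteins
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    sample_ids = [f"A{i + 1}" for i in range(config.n_a)] + [f"B{i + 1}" for i in range(config.n_b)]
    group_map = make_group_map(sample_ids[: config.n_a], sample_ids[config.n_a :])

    # class labels placed at random protein positions
    labels = np.array([LABEL_NULL] * n, dtype=object)
    order = study_rng.permutation(n)
    pos = 0
    for label, count in (
        (LABEL_UNIQUE_A, config.n_unique_a),
        (LABEL_UNIQUE_B, config.n_unique_b),
        (LABEL_UP, config.n_up),
        (LABEL_DOWN, config.n_down),
    ):
        labels[order[pos : pos + count]] = label
        pos += count

    baselines = study_rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    lo, hi = config.effect_log2fc_range
    magnitudes = study_rng.uniform(lo, hi, size=n)
    true_log2fc = np.where(labels == LABEL_UP, magnitudes, np.where(labels == LABEL_DOWN, -magnitudes, 0.0))

    size_factors = study_rng.lognormal(0.0, config.size_factor_sd, size=config.n_a + config.n_b)
    size_factors = size_factors / size_factors.mean()

    in_a = np.array([group_map[s] == GROUP_A for s in sample_ids])
    rows = np.zeros((n, len(sample_ids)), dtype=np.int64)
    for i in range(n):
        label = labels[i]
        mu = baselines[i] * size_factors.copy()
        mu[in_a] *= 2.0 ** true_log2fc[i]
        if label == LABEL_UNIQUE_A:
            mu[~in_a] = 0.0
        elif label == LABEL_UNIQUE_B:
            mu[in_a] = 0.0
        rng_i = np.random.default_rng(children[i + 1])
        for attempt in range(_MAX_RESAMPLE):
            row = _nb_row(rng_i, mu, config.dispersion)
            if _row_ok(label, row, config.n_a):
                break
        else:
            raise SimulationError(
                f"protein {protein_ids[i]} ({label}) violated its presence class "
                f"after {_MAX_RESAMPLE} resampling attempts (baseline {baselines[i]:.3g})"
            )
        rows[i] = row

    counts = pd.DataFrame(rows, index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids)
    truth = pd.DataFrame({"label": labels, "true_log2fc": true_log2fc}, index=counts.index)
    return SimulatedStudy(
        counts=SpectralCountMatrix(counts, group_map, flavor="raw"),
        truth=GroundTruth(truth),
        config=config,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    tpr: float
    fdr: float
    venn_exact: bool
    fc_bias: float
    fc_rmse: float
    n_called: int
    n_true_de: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_recovery(study: SimulatedStudy, dep_table: pd.DataFrame) -> RecoveryMetrics:
    """Score a DEP table against the study's ground truth.

    TPR = called-DE among truly-DE / truly-DE; FDR = truly-null among
    called-DE / called-DE (0 when nothing is called). ``venn_exact``
    requires the unique_a/unique_b/common assignments to match truth
    exactly. fc_bias / fc_rmse compare estimated to true log2 FC over
    truly-DE proteins with finite estimates.
    """
    truth = study.truth.table
    if set(dep_table.index) != set(truth.index):
        missing = set(truth.index) ^ set(dep_table.index)
        raise SimulationError(f"protein identifiers mismatch between truth and DEP table: {sorted(missing)[:5]}")
    dep = dep_table.reindex(truth.index)

    called = dep["status"].isin([LABEL_UP, LABEL_DOWN])
    truly_de = truth["label"].isin([LABEL_UP, LABEL_DOWN])
    truly_null = truth["label"] == LABEL_NULL

    n_called = int(called.sum())
    tpr = float((called & truly_de).sum() / truly_de.sum()) if truly_de.any() else 0.0
    fdr = float((called & truly_null).sum() / n_called) if n_called else 0.0

    venn_exact = bool(
        ((dep["status"] == LABEL_UNIQUE_A) == (truth["label"] == LABEL_UNIQUE_A)).all()
        and ((dep["status"] == LABEL_UNIQUE_B) == (truth["label"] == LABEL_UNIQUE_B)).all()
    )

    de_mask = truly_de & np.isfinite(dep["log2fc"])
    if de_mask.any():
        err = dep.loc[de_mask, "log2fc"] - truth.loc[de_mask, "true_log2fc"]
        fc_bias = float(err.mean())
        fc_rmse = float(np.sqrt((err**2).mean()))
    else:
        fc_bias = fc_rmse = float("nan")
    return RecoveryMetrics(
        tpr=tpr,
        fdr=fdr,
        venn_exact=venn_exact,
        fc_bias=fc_bias,
        fc_rmse=fc_rmse,
        n_called=n_called,
        n_true_de=int(truly_de.sum()),
    )


def simulate_evidence(
    counts: SpectralCountMatrix,
    seed: int = 0,
    peptides_per_protein: int = 3,
):
    """Expand a count matrix into clean peptide-spectrum records.

    A light-weight evidence-table generator for exercising the filter
    stage: each protein gets ``peptides_per_protein`` synthetic tryptic
    peptide sequences, and each spectral count becomes one record cycling
    through them (across samples), with charge >= 2 and probabilities
    above the default retention cutoffs. Filtering these records at the
    default thresholds reassembles every input row whose protein carries
    at least two spectra in total (a single-spectrum protein cannot meet
    the two-distinct-peptides rule).
    """
    from .filtering import PeptideRecord

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHILMNPSTVWY"))
    records = []
    for pid in counts.protein_ids:
        peptides = ["".join(rng.choice(alphabet, size=int(rng.integers(7, 15)))) + "K" for _ in range(peptides_per_protein)]
        spectrum_no = 0
        for sample in counts.sample_ids:
            c = int(counts.values.loc[pid, sample])
            for _ in range(c):
                k = spectrum_no
                spectrum_no += 1
                records.append(
                    PeptideRecord(
                        sample_id=sample,
                        protein_id=pid,
                        peptide_seq=peptides[k % peptides_per_protein],
                        charge_state=int(rng.integers(2, 4)),
                        peptide_prob=float(rng.uniform(0.9, 1.0)),
                        protein_prob=0.999,
                        protein_fdr=0.001,
                    )
                )
    return records


def random_gmt(protein_ids: Iterable[str], n_terms: int = 20, term_size: tuple[int, int] = (10, 40), seed: int = 0):
    """Random annotation terms over the given identifiers (demo plumbing)."""
    ids = list(protein_ids)
    rng = np.random.default_rng(seed)
    out = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        size = min(size, len(ids))
        members = rng.choice(ids, size=size, replace=False)
        out[f"T{t + 1:04d}"] = (f"synthetic term {t + 1}", frozenset(members.tolist()))
    return out
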