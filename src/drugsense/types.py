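"""Shared in-memory containers.

Expression matrices and drug-response tables are plain :class:`pandas.DataFrame`
objects with a fixed orientation (genes x samples, drugs x cell lines) validated
by the helpers below; the richer domain objects (DGCPs, gold standards, PPV
curves, consensus lists) are lightweight dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "validate_expression",
    "validate_response",
    "DGCP",
    "DGCPLibrary",
    "BiomarkerSet",
    "MannWhitneyResult",
    "RankedProfile",
    "ScoringParams",
    "GoldStandard",
    "PPVCurve",
    "CEParams",
    "ConsensusList",
    "SyntheticBenchmark",
    "SyntheticCohort",
]


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression matrix (log-scale, NaN allowed)."""
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("expression matrix has zero genes or zero samples")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    return expr.astype(float)


def validate_response(response: pd.DataFrame) -> pd.DataFrame:
    """Validate a drugs x cell-lines AUC table (non-negative, NaN allowed)."""
    if response.index.has_duplicates:
        raise ValueError("duplicate drug ids in response table")
    if response.columns.has_duplicates:
        raise ValueError("duplicate cell-line ids in response table")
    response = response.astype(float)
    vals = response.to_numpy()
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("AUC values must be non-negative")
    return response


@dataclass
class DGCP:
    """A drug-gene correlation profile.

    Genes ordered by Pearson correlation with the drug's AUC, descending:
    the top of the list holds resistance biomarkers (positive correlation),
    the bottom sensitivity biomarkers (negative correlation).
    """

    drug_id: str
    genes: np.ndarray  # ordered gene ids
    pcc: np.ndarray  # matching correlations, non-increasing
    n_cell_lines: int

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.pcc = np.asarray(self.pcc, dtype=float)
        if len(self.genes) != len(self.pcc):
            raise ValueError("genes and pcc must have equal length")
        if len(self.pcc) and (np.nanmax(self.pcc) > 1 + 1e-9 or np.nanmin(self.pcc) < -1 - 1e-9):
            raise ValueError("PCC values outside [-1, 1]")
        if np.any(np.diff(self.pcc) > 1e-12):
            raise ValueError("pcc must be non-increasing (descending DGCP order)")

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, genes: Sequence[str]) -> "DGCP":
        """Restrict to a gene subset, preserving the descending-PCC order."""
        keep = set(genes)
        mask = np.fromiter((g in keep for g in self.genes), bool, len(self.genes))
        return DGCP(self.drug_id, self.genes[mask], self.pcc[mask], self.n_cell_lines)


@dataclass
class DGCPLibrary:
    """A collection of DGCPs trained on one lineage panel.

    Every DGCP covers exactly ``gene_universe`` (the genes retained by all
    drugs), in its own correlation order.
    """

    lineage_label: str
    dgcps: dict[str, DGCP]
    gene_universe: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.dgcps)

    def __len__(self) -> int:
        return len(self.dgcps)


@dataclass
class BiomarkerSet:
    drug_id: str
    direction: str  # "sensitivity" | "resistance"
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class MannWhitneyResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    direction_tested: str


@dataclass
class RankedProfile:
    """One sample's genes ordered from most to least expressed."""

    sample_id: str
    genes: np.ndarray
    expression_values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.expression_values = np.asarray(self.expression_values, dtype=float)
        if np.any(np.diff(self.expression_values) > 1e-12):
            raise ValueError("expression_values must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoringParams:
    """Tuning knobs for the four-way GSEA scoring.

    set_size: biomarker / expression-extreme set size (250 in the reference
        protocol); n_perm: permutations for the empirical null; shuffle_fraction:
        fraction of gene labels shuffled per randomized profile; es_weight:
        exponent on the ranking metric for hit increments (0 = classic
        Kolmogorov-Smirnov statistic); combine_method: "gmean" or "brown".
    """

    set_size: int = 250
    n_perm: int = 10_000
    shuffle_fraction: float = 0.25
    es_weight: float = 0.0
    combine_method: str = "gmean"
    chunk_size: int = 512

    def __post_init__(self) -> None:
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.shuffle_fraction <= 1):
            raise ValueError("shuffle_fraction must be in (0, 1]")
        if self.combine_method not in ("gmean", "brown"):
            raise ValueError(f"unknown combine_method {self.combine_method!r}")


@dataclass
class GoldStandard:
    """Binary sensitivity labels for (sample, drug) pairs.

    ``labels`` maps (sample_id, drug_id) -> "sensitive" | "resistant" |
    "unknown". Unknown pairs are excluded from precision metrics.
    """

    labels: dict[tuple[str, str], str]
    rule_provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, d, lab) for (s, d), lab in self.labels.items()]
        return pd.DataFrame(rows, columns=["sample_id", "drug_id", "label"])


@dataclass
class PPVCurve:
    """Cumulative positive predictive value per score percentile."""

    percentiles: np.ndarray
    ppv: np.ndarray
    random_ppv: float
    normalized_ppv: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "ppv": self.ppv,
                "random_ppv": self.random_ppv,
                "normalized_ppv": self.normalized_ppv,
            }
        )

    def at_percentile(self, pct: float) -> float:
        """Normalized PPV at the smallest grid point >= pct."""
        idx = int(np.searchsorted(self.percentiles, pct - 1e-9))
        idx = min(idx, len(self.percentiles) - 1)
        return float(self.normalized_ppv[idx])


@dataclass
class CEParams:
    """Cross-Entropy Monte Carlo settings for rank aggregation."""

    k: int = 20
    n_samples: int | None = None  # default 10 * |universe|
    elite_fraction: float = 0.1
    smoothing: float = 0.7
    max_iterations: int = 200
    tolerance: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.elite_fraction < 1):
            raise ValueError("elite_fraction must be in (0, 1)")
        if not (0 < self.smoothing <= 1):
            raise ValueError("smoothing must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ConsensusList:
    items: list[str]
    objective: float
    k: int
    converged: bool
    n_iterations: int


@dataclass
class SyntheticBenchmark:
    """A simulated training panel with planted biomarkers and implied truth."""

    expression: pd.DataFrame  # genes x cell lines
    response: pd.DataFrame  # drugs x cell lines
    truth_biomarkers: dict[str, dict[str, list[str]]]  # drug -> direction -> genes
    truth_sensitivity: GoldStandard
    params: dict
    seed: int


@dataclass
class SyntheticCohort:
    """Simulated tumor profiles with subtype structure."""

    expression: pd.DataFrame  # genes x patients
    subtype_labels: pd.Series  # patient -> subtype
    truth_effective_drugs: dict[str, list[str]]  # subtype -> drugs
    params: dict = field(default_factory=dict)
    seed: int = 0
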