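"""scikit-learn-style estimators wrapping the training/scoring/aggregation
pipeline, so the method composes with sklearn model selection and pipelines.

`DrugSensitivityScorer` follows the sklearn sample-orientation convention:
``fit(X, Y)`` takes cell lines as rows (X: cell lines x genes, Y: cell lines
x drugs AUC) and ``transform`` maps tumors x genes to tumors x drugs
G-scores. The functional modules (:mod:`drugsense.training`,
:mod:`drugsense.scoring`, :mod:`drugsense.aggregation`) remain the primary
API; these classes delegate to them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import aggregation, scoring, training
from .types import CEParams, ScoringParams

__all__ = ["DrugSensitivityScorer", "ConsensusRankAggregator"]


class DrugSensitivityScorer(TransformerMixin, BaseEstimator):
    """Predict per-drug sensitivity scores for tumors from a cell-line panel.

    Fitting correlates every gene with every drug's AUC across cell lines
    (pairwise-complete Pearson) and stores one descending drug-gene
    correlation profile (DGCP) per drug. Transforming scores each tumor
    profile against every DGCP with four directional permutation-null GSEA
    tests and returns the geometric-mean G-score matrix (smaller = predicted
    more sensitive).

    Parameters
    ----------
    set_size : biomarker / expression-extreme set size per test.
    n_perm : permutations for the empirical null.
    shuffle_fraction : fraction of tumor gene labels shuffled per permutation.
    es_weight : running-sum hit-weight exponent (0 = classic KS statistic).
    combine_method : "gmean", or "brown" to also compute Brown-combined p.
    min_pairs : minimum complete (expression, AUC) pairs to train a drug.
    lineage_label : free-text label recorded in the fitted library.
    random_state : seed for the permutation null at transform time.

    Attributes
    ----------
    library_ : fitted :class:`~drugsense.types.DGCPLibrary`.
    drugs_ : list of trained drug ids.
    gene_universe_ : genes covered by every DGCP.
    """

    def __init__(
        self,
        set_size: int = 250,
        n_perm: int = 10_000,
        shuffle_fraction: float = 0.25,
        es_weight: float = 0.0,
        combine_method: str = "gmean",
        min_pairs: int = 10,
        lineage_label: str = "all",
        chunk_size: int = 512,
        random_state: int | None = None,
    ) -> None:
        self.set_size = set_size
        self.n_perm = n_perm
        self.shuffle_fraction = shuffle_fraction
        self.es_weight = es_weight
        self.combine_method = combine_method
        self.min_pairs = min_pairs
        self.lineage_label = lineage_label
        self.chunk_size = chunk_size
        self.random_state = random_state

    def _scoring_params(self) -> ScoringParams:
        return ScoringParams(
            set_size=self.set_size,
            n_perm=self.n_perm,
            shuffle_fraction=self.shuffle_fraction,
            es_weight=self.es_weight,
            combine_method=self.combine_method,
            chunk_size=self.chunk_size,
        )

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Train DGCPs. X: cell lines x genes expression; y: cell lines x drugs AUC."""
        X = self._as_frame(X, "X")
        y = self._as_frame(y, "y")
        self.library_ = training.build_library(
            X.T, y.T, lineage_label=self.lineage_label, min_pairs=self.min_pairs
        )
        self.drugs_ = self.library_.drug_ids
        self.gene_universe_ = list(self.library_.gene_universe)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """G-score matrix (tumors x drugs) for tumor profiles X (tumors x genes)."""
        scored = self.score_table(X)
        return scored.pivot(index="sample_id", columns="drug_id", values="g_score").loc[
            [str(s) for s in self._as_frame(X, "X").index]
        ]

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full long-format scoring table (four p-values, ES, G-score, rank)."""
        check_is_fitted(self, "library_")
        X = self._as_frame(X, "X")
        seed = 0 if self.random_state is None else int(self.random_state)
        return scoring.score_cohort(X.T, self.library_, self._scoring_params(), seed=seed)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-tumor drug ranks (1 = predicted most sensitive), tumors x drugs."""
        scored = self.score_table(X)
        return scored.pivot(index="sample_id", columns="drug_id", values="rank").loc[
            [str(s) for s in self._as_frame(X, "X").index]
        ]

    @staticmethod
    def _as_frame(X, name: str) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(f"{name} must be a pandas DataFrame with gene ids as columns")
        return X


class ConsensusRankAggregator(BaseEstimator):
    """Aggregate per-patient ranked drug lists into one consensus top-k list.

    Cross-Entropy Monte Carlo minimization of the mean Spearman footrule
    distance between the consensus k-list and the input rankings. With
    ``direction="bottom"`` the input lists are reversed first, yielding the
    consensus of worst-ranked drugs.

    Attributes
    ----------
    consensus_ : ordered consensus item list (length k).
    objective_ : achieved mean footrule distance.
    converged_ : whether the stop came from the stall tolerance (or exact 0).
    n_iterations_ : CE iterations run.
    """

    def __init__(
        self,
        k: int = 20,
        direction: str = "top",
        n_samples: int | None = None,
        elite_fraction: float = 0.1,
        smoothing: float = 0.7,
        max_iterations: int = 200,
        tolerance: int = 15,
        random_state: int | None = None,
    ) -> None:
        self.k = k
        self.direction = direction
        self.n_samples = n_samples
        self.elite_fraction = elite_fraction
        self.smoothing = smoothing
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: sequence of ranked item lists (best first), one per patient."""
        if self.direction not in ("top", "bottom"):
            raise ValueError(f"direction must be 'top' or 'bottom', got {self.direction!r}")
        params = CEParams(
            k=self.k,
            n_samples=self.n_samples,
            elite_fraction=self.elite_fraction,
            smoothing=self.smoothing,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
        )
        rng = np.random.default_rng(self.random_state)
        lists = [list(lst) for lst in X]
        if self.direction == "bottom":
            result = aggregation.aggregate_bottom(lists, params, rng)
        else:
            result = aggregation.ce_aggregate(lists, params, rng)
        self.consensus_ = list(result.items)
        self.objective_ = result.objective
        self.converged_ = result.converged
        self.n_iterations_ = result.n_iterations
        self.result_ = result
        return self
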