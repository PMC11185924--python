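"""Scoring: compare one tumor expression profile against every DGCP.

For each drug, four directional gene-set enrichment tests are run:

1. the ``set_size`` most expressed tumor genes should sit at the *bottom*
   of the DGCP (they should be sensitivity biomarkers) — ES toward -1;
2. the ``set_size`` least expressed tumor genes should sit at the *top*
   of the DGCP (resistance biomarkers) — ES toward +1;
3. the DGCP's bottom ``set_size`` genes (sensitivity biomarkers) should be
   up-regulated in the tumor — ES toward +1 on the expression ranking;
4. the DGCP's top ``set_size`` genes (resistance biomarkers) should be
   down-regulated in the tumor — ES toward -1 on the expression ranking.

Each enrichment score gets a one-sided empirical p-value against a null of
randomized tumor profiles obtained by shuffling a fraction (default 25%) of
the tumor's gene labels; the same randomized profiles drive all four tests,
which also yields the covariance needed for Brown's combination. The G-score
is the geometric mean of the four p-values; smaller means predicted more
sensitive. Drugs are ranked by ascending G-score.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DGCP, DGCPLibrary, RankedProfile, ScoringParams

logger = logging.getLogger(__name__)

__all__ = [
    "FourPValues",
    "rank_profile",
    "enrichment_score",
    "null_es_distribution",
    "empirical_p",
    "four_way_gsea",
    "combine_g_score",
    "combine_fisher",
    "combine_brown",
    "score_sample",
    "score_cohort",
    "ShuffleEnsemble",
]


@dataclass
class FourPValues:
    """The four one-sided empirical p-values and their observed ES."""

    p_top_expr_vs_sensitivity: float
    p_bottom_expr_vs_resistance: float
    p_sens_biomarkers_up: float
    p_res_biomarkers_down: float
    es: tuple[float, float, float, float]
    brown_p: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.p_top_expr_vs_sensitivity,
                self.p_bottom_expr_vs_resistance,
                self.p_sens_biomarkers_up,
                self.p_res_biomarkers_down,
            ]
        )


def rank_profile(
    values: pd.Series,
    universe: list[str] | pd.Index,
    min_genes: int | None = None,
) -> RankedProfile:
    """Order a sample's genes from most to least expressed within a universe.

    Genes outside ``universe`` or with missing expression are dropped
    (warned); ties are broken by gene id so the ranking is deterministic.
    """
    sample_id = str(values.name) if values.name is not None else ""
    vals = values.reindex(pd.Index(universe))
    missing = int(vals.isna().sum())
    if missing:
        logger.warning("sample %s: dropping %d universe genes without expression", sample_id, missing)
        vals = vals.dropna()
    if min_genes is not None and len(vals) < min_genes:
        raise ValueError(
            f"sample {sample_id}: only {len(vals)} genes overlap the universe; need >= {min_genes}"
        )
    genes = vals.index.to_numpy(object)
    v = vals.to_numpy(float)
    if len(v) and v.max() == v.min():
        logger.warning("sample %s: all expression values equal; order is lexicographic", sample_id)
    order = np.lexsort((genes.astype(str), -v))
    return RankedProfile(sample_id, genes[order], v[order])


def _es_rows(H: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Signed maximum running-sum deviation per row of a hit matrix.

    ``H`` is (n_rows, N) boolean hit indicators along a ranking; ``w`` an
    optional (N,) non-negative weight vector (|metric|^weight) attached to
    positions. The running sum increments at hits by the (normalized) weight
    and decrements at misses by 1/(N - n_hits); the ES is the cumulative-sum
    value of largest magnitude (first occurrence on exact ties).
    """
    H = np.atleast_2d(H)
    B, N = H.shape
    m = H.sum(axis=1)
    if np.any(m == 0):
        raise ValueError("gene set has no overlap with the ranked list")
    if np.any(m == N):
        raise ValueError("gene set covers the whole ranked list (no misses)")
    dec = 1.0 / (N - m)
    if w is None:
        steps = np.where(H, (1.0 / m)[:, None], -dec[:, None])
    else:
        w = np.asarray(w, float)
        Wh = (H * w).sum(axis=1)
        if np.any(Wh <= 0):
            raise ValueError("all hit weights are zero; cannot form weighted ES")
        steps = np.where(H, w[None, :] / Wh[:, None], -dec[:, None])
    c = np.cumsum(steps, axis=1)
    idx = np.abs(c).argmax(axis=1)
    return c[np.arange(B), idx]


def enrichment_score(
    ranked_genes,
    gene_set,
    weight: float = 0.0,
    ranking_values=None,
) -> float:
    """Kolmogorov-Smirnov-style enrichment score of a gene set in a ranking.

    With ``weight`` 0 this is the classic unweighted statistic; a positive
    weight requires ``ranking_values`` (the ranking metric) and increments
    hits proportionally to |value|^weight. ES lies in [-1, 1]: +1 when the
    set occupies the top of the list, -1 when it occupies the bottom.
    """
    genes = np.asarray(list(ranked_genes), dtype=object)
    members = set(gene_set)
    hits = np.fromiter((g in members for g in genes), bool, len(genes))
    w = None
    if weight != 0:
        if ranking_values is None:
            raise ValueError("ranking_values required when weight != 0")
        w = np.abs(np.asarray(ranking_values, float)) ** weight
    return float(_es_rows(hits[None, :], w)[0])


class ShuffleEnsemble:
    """A seeded ensemble of partial label shuffles of a ranked profile.

    Each permutation selects ``ceil(shuffle_fraction * N)`` positions of the
    ranked gene-label vector uniformly at random and cyclically deranges the
    labels among them (so every selected label actually moves); values and
    their ordering are untouched. The ensemble depends only on (N, fraction,
    n_perm, seed) and is therefore shared across drugs — and across samples
    with equal universe size — mirroring a single set of randomized tumor
    profiles driving all tests.
    """

    def __init__(
        self,
        n_genes: int,
        n_perm: int,
        shuffle_fraction: float,
        rng: np.random.Generator,
        chunk_size: int = 512,
    ) -> None:
        N = int(n_genes)
        s = min(N, max(2, math.ceil(shuffle_fraction * N)))
        self.n_genes = N
        self.n_perm = int(n_perm)
        self.n_shuffled = s
        self.chunk_size = int(chunk_size)
        self.sel = np.empty((self.n_perm, s), dtype=np.int32)
        base = np.arange(N, dtype=np.int32)
        for start in range(0, self.n_perm, self.chunk_size):
            stop = min(start + self.chunk_size, self.n_perm)
            block = np.tile(base, (stop - start, 1))
            rng.permuted(block, axis=1, out=block)
            self.sel[start:stop] = block[:, :s]


def null_es_distribution(
    profile: RankedProfile,
    gene_set,
    params: ScoringParams,
    rng: np.random.Generator,
    ensemble: ShuffleEnsemble | None = None,
) -> np.ndarray:
    """Null ES values for one gene set under partial label shuffling."""
    N = len(profile)
    if ensemble is None:
        ensemble = ShuffleEnsemble(N, params.n_perm, params.shuffle_fraction, rng, params.chunk_size)
    members = set(gene_set)
    b = np.fromiter((g in members for g in profile.genes), bool, N)
    w = None
    if params.es_weight != 0:
        w = np.abs(profile.expression_values) ** params.es_weight
    out = np.empty(ensemble.n_perm)
    for start in range(0, ensemble.n_perm, ensemble.chunk_size):
        stop = min(start + ensemble.chunk_size, ensemble.n_perm)
        sel = ensemble.sel[start:stop]
        src = np.roll(sel, -1, axis=1)
        B = np.repeat(b[None, :], stop - start, axis=0)
        B[np.arange(stop - start)[:, None], sel] = b[src]
        out[start:stop] = _es_rows(B, w)
    return out


def empirical_p(es_observed: float, null: np.ndarray, direction: str) -> float:
    """One-sided empirical p with an add-one floor: p >= 1/(n_perm + 1)."""
    null = np.asarray(null, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "greater":
        extreme = int((null >= es_observed).sum())
    elif direction == "less":
        extreme = int((null <= es_observed).sum())
    else:
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    return (1 + extreme) / (1 + null.size)


_DIRECTIONS = ("less", "greater", "greater", "less")


def four_way_gsea(
    profile: RankedProfile,
    dgcp: DGCP,
    params: ScoringParams | None = None,
    rng: np.random.Generator | None = None,
    ensemble: ShuffleEnsemble | None = None,
) -> FourPValues:
    """Run the four directional enrichment tests for one (sample, drug) pair.

    Tests 1-2 rank genes by the DGCP and use tumor-derived extreme-expression
    sets; tests 3-4 rank genes by tumor expression and use DGCP-derived
    biomarker sets. All four nulls come from the same ensemble of randomized
    tumor profiles.
    """
    params = params or ScoringParams()
    dg = dgcp.restrict(profile.genes)
    N = len(profile)
    if len(dg) != N:
        # genes in the profile but absent from this DGCP: restrict both sides
        profile = rank_profile(
            pd.Series(profile.expression_values, index=list(profile.genes), name=profile.sample_id),
            list(dg.genes),
        )
        N = len(profile)
    m = params.set_size
    if 2 * m > N:
        raise ValueError(f"set_size {m} too large for a {N}-gene shared universe (need >= 2*set_size)")
    if ensemble is None:
        if rng is None:
            rng = np.random.default_rng(0)
        ensemble = ShuffleEnsemble(N, params.n_perm, params.shuffle_fraction, rng, params.chunk_size)
    if ensemble.n_genes != N:
        raise ValueError("ensemble was built for a different universe size")

    tumor_index = pd.Index(profile.genes)
    dord = tumor_index.get_indexer(dg.genes)  # tumor position of each DGCP-ranked gene
    posD = np.empty(N, dtype=np.int64)
    posD[dord] = np.arange(N)  # DGCP rank of the gene at each tumor position
    # hit indicators: b1/b2 along the DGCP ranking, b3/b4 along the tumor ranking
    b1 = dord < m  # tumor top-m expressed, located on the DGCP
    b2 = dord >= N - m  # tumor bottom-m expressed
    b3 = posD >= N - m  # DGCP bottom-m (sensitivity biomarkers), located on the tumor
    b4 = posD < m  # DGCP top-m (resistance biomarkers)

    wD = wT = None
    if params.es_weight != 0:
        wD = np.abs(dg.pcc) ** params.es_weight
        wT = np.abs(profile.expression_values) ** params.es_weight

    es_obs = (
        float(_es_rows(b1[None, :], wD)[0]),
        float(_es_rows(b2[None, :], wD)[0]),
        float(_es_rows(b3[None, :], wT)[0]),
        float(_es_rows(b4[None, :], wT)[0]),
    )

    nulls = np.empty((4, ensemble.n_perm))
    for start in range(0, ensemble.n_perm, ensemble.chunk_size):
        stop = min(start + ensemble.chunk_size, ensemble.n_perm)
        sel = ensemble.sel[start:stop]
        B = stop - start
        rows = np.arange(B)[:, None]
        src = np.roll(sel, -1, axis=1)  # position whose label moves to `sel`
        dest = np.roll(sel, 1, axis=1)  # position each selected gene moves to
        B3 = np.repeat(b3[None, :], B, axis=0)
        B3[rows, sel] = b3[src]
        B4 = np.repeat(b4[None, :], B, axis=0)
        B4[rows, sel] = b4[src]
        D = posD[sel]  # DGCP positions of the selected (moving) genes
        B1 = np.repeat(b1[None, :], B, axis=0)
        B1[rows, D] = dest < m
        B2 = np.repeat(b2[None, :], B, axis=0)
        B2[rows, D] = dest >= N - m
        nulls[0, start:stop] = _es_rows(B1, wD)
        nulls[1, start:stop] = _es_rows(B2, wD)
        nulls[2, start:stop] = _es_rows(B3, wT)
        nulls[3, start:stop] = _es_rows(B4, wT)

    p = [empirical_p(es_obs[i], nulls[i], _DIRECTIONS[i]) for i in range(4)]
    brown_p = None
    if params.combine_method == "brown":
        cov = _brown_covariance(nulls, _DIRECTIONS)
        brown_p = combine_brown(p, cov)
    return FourPValues(p[0], p[1], p[2], p[3], es=es_obs, brown_p=brown_p)


def combine_g_score(four_p) -> float:
    """Geometric mean of the four p-values; smaller = predicted more sensitive."""
    if isinstance(four_p, FourPValues):
        four_p = four_p.as_array()
    p = np.asarray(four_p, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(p))))


def combine_fisher(four_p) -> float:
    """Fisher's combination (independence assumed): chi-square with 2k df."""
    p = np.asarray(four_p, float)
    X = float(-2.0 * np.log(p).sum())
    return float(stats.chi2.sf(X, 2 * len(p)))


def combine_brown(four_p, covariance) -> float:
    """Brown's extension of Fisher's method for dependent p-values.

    ``covariance`` is the k x k covariance matrix of the -2 ln p statistics
    (here estimated from the shared permutation ensemble). X = -2 sum ln p is
    fitted with a scaled chi-square: c = var(X) / (2 E[X]),
    df = 2 E[X]^2 / var(X), with E[X] = 2k and
    var(X) = 4k + 2 sum_{i<j} cov_ij. Degenerate covariance falls back to
    Fisher's method with a warning.
    """
    if isinstance(four_p, FourPValues):
        four_p = four_p.as_array()
    p = np.asarray(four_p, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = len(p)
    cov = np.asarray(covariance, float)
    ok = cov.shape == (k, k) and np.allclose(cov, cov.T, atol=1e-8)
    if ok:
        ok = float(np.linalg.eigvalsh((cov + cov.T) / 2).min()) > -1e-8
    e_x = 2.0 * k
    var_x = 4.0 * k + 2.0 * float(np.triu(cov, 1).sum()) if ok else 0.0
    if not ok or var_x <= 0:
        warnings.warn("degenerate covariance; falling back to Fisher's method", stacklevel=2)
        return combine_fisher(p)
    c = var_x / (2.0 * e_x)
    df = 2.0 * e_x * e_x / var_x
    X = float(-2.0 * np.log(p).sum())
    return float(stats.chi2.sf(X / c, df))


def _brown_covariance(nulls: np.ndarray, directions) -> np.ndarray:
    """Covariance of -2 ln p across the four tests, from the joint null."""
    n = nulls.shape[1]
    T = np.empty_like(nulls)
    for i, direction in enumerate(directions):
        x = nulls[i]
        ranks = stats.rankdata(-x if direction == "greater" else x, method="max")
        T[i] = -2.0 * np.log(ranks / n)
    return np.cov(T)


def score_sample(
    sample: pd.Series,
    library: DGCPLibrary,
    params: ScoringParams | None = None,
    seed: int | np.random.Generator = 0,
    ensemble: ShuffleEnsemble | None = None,
) -> pd.DataFrame:
    """Score one sample against every drug in the library.

    Returns one row per drug with the four p-values, observed ES values,
    G-score (and Brown p when requested) and the 1-based ascending-G-score
    rank (ties broken by drug id).
    """
    params = params or ScoringParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = rank_profile(sample, library.gene_universe, min_genes=2 * params.set_size)
    if ensemble is None:
        ensemble = ShuffleEnsemble(
            len(profile), params.n_perm, params.shuffle_fraction, rng, params.chunk_size
        )
    rows = []
    for drug_id in library.drug_ids:
        fp = four_way_gsea(profile, library.dgcps[drug_id], params, ensemble=ensemble)
        rows.append(
            {
                "sample_id": profile.sample_id,
                "drug_id": drug_id,
                "p_top_expr_vs_sensitivity": fp.p_top_expr_vs_sensitivity,
                "p_bottom_expr_vs_resistance": fp.p_bottom_expr_vs_resistance,
                "p_sens_biomarkers_up": fp.p_sens_biomarkers_up,
                "p_res_biomarkers_down": fp.p_res_biomarkers_down,
                "es1": fp.es[0],
                "es2": fp.es[1],
                "es3": fp.es[2],
                "es4": fp.es[3],
                "g_score": combine_g_score(fp),
                "brown_p": fp.brown_p,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(["g_score", "drug_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_cohort(
    expr: pd.DataFrame,
    library: DGCPLibrary,
    params: ScoringParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every sample (column) of a tumor expression matrix.

    One shuffle ensemble per distinct universe size is generated from the
    seed and shared across samples, so scoring is reproducible and identical
    expression columns receive identical results.
    """
    params = params or ScoringParams()
    rng = np.random.default_rng(seed)
    ensembles: dict[int, ShuffleEnsemble] = {}
    results = []
    for sample_id in expr.columns:
        profile = rank_profile(expr[sample_id], library.gene_universe, min_genes=2 * params.set_size)
        N = len(profile)
        if N not in ensembles:
            ensembles[N] = ShuffleEnsemble(N, params.n_perm, params.shuffle_fraction, rng, params.chunk_size)
        results.append(
            score_sample(expr[sample_id], library, params, seed=rng, ensemble=ensembles[N])
        )
    return pd.concat(results, ignore_index=True)
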