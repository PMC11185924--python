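"""Training: build drug-gene correlation profiles (DGCPs) from a cell-line
expression panel and an AUC response table.

For each (gene, drug) pair the Pearson correlation between the gene's
expression and the drug's AUC is computed across cell lines with a
pairwise-complete-observation policy; genes are then ranked by correlation in
descending order, so the top of each DGCP carries resistance biomarkers
(expression rises with AUC, i.e. with resistance) and the bottom carries
sensitivity biomarkers. Lineage splits (e.g. solid vs liquid panels) are the
caller's responsibility: pass the already-restricted cell-line subset.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DGCP, BiomarkerSet, DGCPLibrary, MannWhitneyResult

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 10


def _pairwise_pearson(values: np.ndarray, auc: np.ndarray, min_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation of each row of ``values`` with ``auc``.

    Returns (pcc, n_pairs) per row; rows with fewer than ``min_pairs`` complete
    pairs or zero variance on either side get NaN.
    """
    finite_auc = np.isfinite(auc)
    X = np.where(np.isfinite(values), values, 0.0)
    M = np.isfinite(values) & finite_auc  # complete pairs per row
    Xm = np.where(M, X, 0.0)
    Ym = np.where(M, auc, 0.0)
    n = M.sum(axis=1)
    sx = Xm.sum(axis=1)
    sy = Ym.sum(axis=1)
    sxx = (Xm * Xm).sum(axis=1)
    syy = (Ym * Ym).sum(axis=1)
    sxy = (Xm * Ym).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        pcc = cov / np.sqrt(varx * vary)
    bad = (n < min_pairs) | (varx <= 0) | (vary <= 0)
    pcc = np.where(bad, np.nan, pcc)
    # guard rounding just past +/-1
    return np.clip(pcc, -1.0, 1.0), n


def compute_dgcp(
    expr: pd.DataFrame,
    auc_row: pd.Series,
    drug_id: str = "",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> DGCP | None:
    """Correlate every gene with one drug's AUC vector and rank descending.

    ``expr`` is genes x cell lines; ``auc_row`` indexed by cell-line id.
    Genes with fewer than ``min_pairs`` complete pairs or zero variance are
    dropped (logged). Returns None (with a warning) when fewer than
    ``min_pairs`` cell lines are shared overall.
    """
    drug_id = drug_id or str(auc_row.name or "")
    shared = expr.columns.intersection(auc_row.index)
    if len(shared) < min_pairs:
        logger.warning(
            "drug %s: only %d shared cell lines (< min_pairs=%d); skipped",
            drug_id, len(shared), min_pairs,
        )
        return None
    auc = auc_row.loc[shared].to_numpy(float)
    if np.isfinite(auc).sum() < min_pairs:
        logger.warning("drug %s: fewer than %d finite AUC values; skipped", drug_id, min_pairs)
        return None
    values = expr.loc[:, shared].to_numpy(float)
    pcc, n = _pairwise_pearson(values, auc, min_pairs)
    keep = np.isfinite(pcc)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drug %s: dropped %d genes (insufficient pairs or zero variance)", drug_id, n_dropped)
    if not keep.any():
        logger.warning("drug %s: no gene passed the correlation filter; skipped", drug_id)
        return None
    genes = expr.index.to_numpy(object)[keep]
    pcc = pcc[keep]
    # descending PCC; ties broken by gene id for determinism
    order = np.lexsort((genes.astype(str), -pcc))
    return DGCP(drug_id, genes[order], pcc[order], int(np.isfinite(auc).sum()))


def build_library(
    expr: pd.DataFrame,
    response: pd.DataFrame,
    lineage_label: str = "all",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> DGCPLibrary:
    """Train one DGCP per drug and assemble them into a library.

    The library's gene universe is the intersection of genes retained by every
    surviving DGCP; each DGCP is restricted to it (order preserved).
    """
    shared = expr.columns.intersection(response.columns)
    if len(shared) == 0:
        raise ValueError(
            f"no shared cell-line ids between expression ({expr.shape[1]} lines) "
            f"and response ({response.shape[1]} lines)"
        )
    dgcps: dict[str, DGCP] = {}
    for drug_id, auc_row in response.iterrows():
        d = compute_dgcp(expr, auc_row, str(drug_id), min_pairs=min_pairs)
        if d is not None:
            dgcps[str(drug_id)] = d
            logger.info("drug %s: DGCP over %d genes, %d cell lines", drug_id, len(d), d.n_cell_lines)
    if not dgcps:
        raise ValueError("no drug passed training; library would be empty")
    universe_set = set(next(iter(dgcps.values())).genes)
    for d in dgcps.values():
        universe_set &= set(d.genes)
    if not universe_set:
        raise ValueError("gene universe is empty after intersecting DGCPs")
    dgcps = {drug: d.restrict(universe_set) for drug, d in dgcps.items()}
    universe = [g for g in expr.index if g in universe_set]
    provenance = {
        "min_pairs": min_pairs,
        "n_training_cell_lines": int(len(shared)),
        "n_drugs_in": int(response.shape[0]),
        "n_drugs_trained": len(dgcps),
    }
    return DGCPLibrary(lineage_label, dgcps, universe, provenance)


def extract_biomarkers(dgcp: DGCP, direction: str, size: int = 250) -> BiomarkerSet:
    """Top-of-list (resistance) or bottom-of-list (sensitivity) biomarker set."""
    if direction not in ("sensitivity", "resistance"):
        raise ValueError(f"direction must be 'sensitivity' or 'resistance', got {direction!r}")
    n = len(dgcp)
    if size > n:
        logger.warning("drug %s: requested %d biomarkers, only %d genes; clamped", dgcp.drug_id, size, n)
        size = n
    if direction == "resistance":
        genes = dgcp.genes[:size]
    else:
        genes = dgcp.genes[n - size:]
    return BiomarkerSet(dgcp.drug_id, direction, list(genes))


def pathway_anticorrelation_check(
    dgcp: DGCP,
    target_pathway_genes: Sequence[str],
    background_genes: Sequence[str],
) -> MannWhitneyResult:
    """One-sided Mann-Whitney U: are target-pathway PCCs smaller (more
    anticorrelated with AUC) than background-pathway PCCs?"""
    pcc_by_gene = dict(zip(dgcp.genes, dgcp.pcc))
    target = np.array([pcc_by_gene[g] for g in dict.fromkeys(target_pathway_genes) if g in pcc_by_gene])
    background = np.array([pcc_by_gene[g] for g in dict.fromkeys(background_genes) if g in pcc_by_gene])
    if len(target) == 0 or len(background) == 0:
        raise ValueError(
            f"empty group after intersecting with the DGCP universe "
            f"(target n={len(target)}, background n={len(background)})"
        )
    res = stats.mannwhitneyu(target, background, alternative="less")
    return MannWhitneyResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(target),
        n2=len(background),
        direction_tested="target PCCs less than background",
    )


def biomarker_overlap_enrichment(
    genes: Sequence[str],
    sets: dict[str, Sequence[str]],
    universe: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each gene set.

    Returns one row per set: overlap count, one-sided hypergeometric p,
    Benjamini-Hochberg q, and a significance flag at q < ``fdr_threshold``.
    """
    universe_list = list(dict.fromkeys(universe))
    if not universe_list:
        raise ValueError("empty gene universe")
    universe_set = set(universe_list)
    query = [g for g in dict.fromkeys(genes) if g in universe_set]
    M, n = len(universe_set), len(query)
    rows = []
    for name, members in sets.items():
        members_in = set(members) & universe_set
        K = len(members_in)
        k = len(members_in.intersection(query))
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size_in_universe", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < fdr_threshold
        out = out.sort_values(["p_value", "set"], kind="mergesort").reset_index(drop=True)
    return out


def shuffle_gene_labels(lib: DGCPLibrary, seed: int | np.random.Generator = 0) -> DGCPLibrary:
    """Relabel the library's gene universe with one random permutation.

    Destroys the gene-to-biomarker correspondence while keeping every
    correlation profile's shape; used as a mismatched-library negative control.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = np.array(lib.gene_universe, dtype=object)
    relabel = dict(zip(universe, rng.permutation(universe)))
    dgcps = {
        drug: DGCP(drug, np.array([relabel[g] for g in d.genes], object), d.pcc.copy(), d.n_cell_lines)
        for drug, d in lib.dgcps.items()
    }
    prov = dict(lib.provenance)
    prov["gene_labels_shuffled"] = True
    return DGCPLibrary(lib.lineage_label + "+shuffled", dgcps, list(lib.gene_universe), prov)
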