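"""Validation: gold standards of drug sensitivity and normalized PPV curves.

A gold standard labels (sample, drug) pairs sensitive or resistant, either
from AUC values (per-drug quantile or absolute threshold) or from categorical
response calls (CR/PR = sensitive, SD/PD = resistant). Scored pairs are
ranked by ascending G-score, binned into score percentiles, and the
cumulative positive predictive value PPV = TP / (TP + FP) at each percentile
is normalized against the precision of a random ordering (the sensitive-pair
prevalence). A curve above 1 at early percentiles means the scorer
concentrates truly sensitive pairs at the top.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import DGCPLibrary, GoldStandard, PPVCurve, ScoringParams

logger = logging.getLogger(__name__)

__all__ = [
    "call_sensitive_from_auc",
    "call_sensitive_from_labels",
    "ppv_curve",
    "cross_control_evaluation",
]

_LABEL_MAP = {"CR": "sensitive", "PR": "sensitive", "SD": "resistant", "PD": "resistant"}


def call_sensitive_from_auc(
    response: pd.DataFrame,
    rule: str = "per_drug_quantile",
    q: float = 0.05,
    threshold: float | None = None,
) -> GoldStandard:
    """Call (cell line, drug) pairs sensitive from an AUC table.

    ``per_drug_quantile``: sensitive iff AUC <= the q-quantile of that drug's
    AUC values (default q = 0.05, i.e. the most-inhibited tail);
    ``absolute_threshold``: sensitive iff AUC <= ``threshold``. Missing AUC
    entries become "unknown".
    """
    labels: dict[tuple[str, str], str] = {}
    if rule == "per_drug_quantile":
        if not (0 < q < 1):
            raise ValueError(f"quantile q must lie in (0, 1), got {q}")
        for drug_id, row in response.iterrows():
            vals = row.dropna()
            if len(vals) < 2:
                logger.warning("drug %s: fewer than 2 AUC values; pairs left unknown", drug_id)
                for cl in row.index:
                    labels[(str(cl), str(drug_id))] = "unknown"
                continue
            cutoff = float(np.quantile(vals.to_numpy(), q))
            for cl, v in row.items():
                if pd.isna(v):
                    labels[(str(cl), str(drug_id))] = "unknown"
                else:
                    labels[(str(cl), str(drug_id))] = "sensitive" if v <= cutoff else "resistant"
        provenance = f"per_drug_quantile(q={q})"
    elif rule == "absolute_threshold":
        if threshold is None:
            raise ValueError("absolute_threshold rule requires `threshold`")
        for drug_id, row in response.iterrows():
            for cl, v in row.items():
                if pd.isna(v):
                    labels[(str(cl), str(drug_id))] = "unknown"
                else:
                    labels[(str(cl), str(drug_id))] = "sensitive" if v <= threshold else "resistant"
        provenance = f"absolute_threshold(t={threshold})"
    else:
        raise ValueError(f"unknown gold-standard rule {rule!r}")
    return GoldStandard(labels, provenance)


def call_sensitive_from_labels(labels: pd.DataFrame) -> GoldStandard:
    """Map categorical response calls to a gold standard.

    Expects columns (model_id, drug_id, response); complete or partial
    response is sensitive, stable or progressive disease resistant, anything
    else unknown (warned).
    """
    cols = list(labels.columns[:3])
    out: dict[tuple[str, str], str] = {}
    for _, row in labels.iterrows():
        resp = str(row[cols[2]]).strip().upper()
        call = _LABEL_MAP.get(resp)
        if call is None:
            logger.warning(
                "model %s drug %s: unrecognized response %r; labeled unknown",
                row[cols[0]], row[cols[1]], row[cols[2]],
            )
            call = "unknown"
        out[(str(row[cols[0]]), str(row[cols[1]]))] = call
    return GoldStandard(out, "categorical CR/PR vs SD/PD")


def ppv_curve(
    scores: pd.DataFrame,
    gold: GoldStandard,
    n_bins: int = 100,
    per_bin: bool = False,
) -> PPVCurve:
    """Cumulative precision per score percentile, normalized against random.

    ``scores`` needs columns (sample_id, drug_id, g_score). Pairs without a
    sensitive/resistant label are excluded. The random-ordering baseline is
    the sensitive prevalence among labeled pairs, so the cumulative curve
    terminates at normalized PPV = 1. With ``per_bin`` the precision is
    computed within each percentile bin instead of cumulatively.
    """
    df = scores[["sample_id", "drug_id", "g_score"]].copy()
    df["label"] = [
        gold.labels.get((s, d), "unknown") for s, d in zip(df["sample_id"], df["drug_id"])
    ]
    df = df[df["label"].isin(["sensitive", "resistant"])]
    if df.empty or not (df["label"] == "sensitive").any():
        raise ValueError("no labeled sensitive pair among the scored pairs")
    df = df.sort_values(["g_score", "sample_id", "drug_id"], kind="mergesort")
    hits = (df["label"] == "sensitive").to_numpy()
    n = len(hits)
    prevalence = float(hits.mean())
    percentiles = 100.0 * np.arange(1, n_bins + 1) / n_bins
    cum = np.cumsum(hits)
    edges = np.ceil(percentiles / 100.0 * n).astype(int)
    edges = np.clip(edges, 1, n)
    if per_bin:
        lo = np.concatenate([[0], edges[:-1]])
        width = np.maximum(edges - lo, 1)
        ppv = (cum[edges - 1] - np.concatenate([[0], cum[edges[:-1] - 1]])) / width
    else:
        ppv = cum[edges - 1] / edges
    return PPVCurve(percentiles, ppv, prevalence, ppv / prevalence)


def cross_control_evaluation(
    samples: pd.DataFrame,
    library_matched: DGCPLibrary,
    library_mismatched: DGCPLibrary,
    gold: GoldStandard,
    params: ScoringParams | None = None,
    seed: int = 0,
    n_bins: int = 100,
) -> tuple[PPVCurve, PPVCurve]:
    """Score a cohort with a matched and a mismatched library; return both curves.

    The mismatched library (e.g. wrong lineage, or gene-label-shuffled) is the
    negative control: its normalized PPV should hover around 1.
    """
    from .scoring import score_cohort

    gold_drugs = {d for (_, d) in gold.labels}
    for name, lib in (("matched", library_matched), ("mismatched", library_mismatched)):
        if not gold_drugs.intersection(lib.drug_ids):
            raise ValueError(f"{name} library shares no drugs with the gold standard")
    curves = []
    for lib in (library_matched, library_mismatched):
        scored = score_cohort(samples, lib, params, seed=seed)
        curves.append(ppv_curve(scored, gold, n_bins=n_bins))
    return curves[0], curves[1]
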