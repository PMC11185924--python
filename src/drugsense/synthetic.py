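"""Seed-reproducible synthetic training panels and tumor cohorts.

The benchmark emulates the statistical premise of correlation-based biomarker
discovery: each drug has planted sensitivity and resistance biomarker genes
whose (standard-normal) expression is linearly correlated with that drug's
AUC across cell lines — negatively for sensitivity, positively for
resistance. A per-drug latent factor ``t_c ~ N(0, 1)`` per cell line drives
both sides:

    AUC_{d,c} = mu + effect_beta * t_c + eps,        eps ~ N(0, noise_sd^2)
    z_{g,c}   = (-t_c + eta) / sqrt(2)  (sensitivity biomarker g)
    z_{g,c}   = (+t_c + eta) / sqrt(2)  (resistance biomarker g),  eta ~ N(0, 1)

so every planted gene keeps a standard-normal marginal and carries a per-gene
expected Pearson correlation of ∓ effect_beta / sqrt(2 (effect_beta^2 +
noise_sd^2)) with the AUC (≈ ∓0.63 at effect/noise = 2), strong enough for
the DGCP extremes to recover the planted sets. When planted sets overlap
across drugs (the default when the gene pool is too small for disjoint
planting), a gene serving k drugs sums its k factors and is renormalized to
unit variance, diluting each per-drug correlation by sqrt((1 + k) / 2). Non-biomarker expression is
i.i.d. standard normal; marginal distribution shape is immaterial to the
rank/correlation-based method.

Cohort tumors are i.i.d. normal background profiles with the sensitivity
biomarkers of their subtype's designated drugs shifted up (and resistance
biomarkers shifted down), emulating a cohort whose subtypes respond to
different drugs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GoldStandard, SyntheticBenchmark, SyntheticCohort
from .validation import call_sensitive_from_auc

__all__ = ["simulate_benchmark", "simulate_cohort", "cohort_gold_standard"]


def simulate_benchmark(
    n_genes: int = 2000,
    n_cell_lines: int = 60,
    n_drugs: int = 30,
    n_biomarkers_per_direction: int = 50,
    effect_beta: float = 2.0,
    noise_sd: float = 1.0,
    mu_auc: float = 10.0,
    sensitivity_quantile: float = 0.05,
    cross_drug_disjoint: bool = False,
    seed: int = 0,
) -> SyntheticBenchmark:
    """Simulate a training panel with planted per-drug biomarkers.

    Each drug's sensitivity and resistance sets are disjoint within the drug;
    with ``cross_drug_disjoint`` the sets are disjoint across drugs too,
    which requires ``2 * n_biomarkers_per_direction * n_drugs <= n_genes``.
    The implied gold standard calls a (cell line, drug) pair sensitive below
    the per-drug ``sensitivity_quantile`` AUC quantile.
    """
    n_bio = n_biomarkers_per_direction
    if 2 * n_bio > n_genes:
        raise ValueError("2 * n_biomarkers_per_direction exceeds n_genes; planting infeasible")
    if cross_drug_disjoint and 2 * n_bio * n_drugs > n_genes:
        raise ValueError(
            f"cross-drug disjoint planting needs 2*{n_bio}*{n_drugs} <= {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cell_lines = [f"CL{j:03d}" for j in range(n_cell_lines)]
    drugs = [f"D{d:03d}" for d in range(n_drugs)]

    noise = rng.standard_normal((n_genes, n_cell_lines))  # eta: per-gene noise
    contrib = np.zeros((n_genes, n_cell_lines))  # summed latent-factor loadings
    n_roles = np.zeros(n_genes, dtype=np.int64)  # how many drugs plant each gene
    auc = np.empty((n_drugs, n_cell_lines))
    truth: dict[str, dict[str, list[str]]] = {}
    gene_idx = np.arange(n_genes)
    if cross_drug_disjoint:
        planted_pool = rng.permutation(gene_idx)
    for d, drug in enumerate(drugs):
        if cross_drug_disjoint:
            block = planted_pool[2 * n_bio * d : 2 * n_bio * (d + 1)]
        else:
            block = rng.choice(gene_idx, size=2 * n_bio, replace=False)
        sens, res = block[:n_bio], block[n_bio:]
        t = rng.standard_normal(n_cell_lines)
        contrib[sens, :] += -t[None, :]
        contrib[res, :] += t[None, :]
        n_roles[block] += 1
        auc[d] = mu_auc + effect_beta * t + noise_sd * rng.standard_normal(n_cell_lines)
        truth[drug] = {
            "sensitivity": [genes[i] for i in sorted(sens)],
            "resistance": [genes[i] for i in sorted(res)],
        }
    # gene expression: shared factors + private noise, unit marginal variance;
    # a gene planted for k drugs carries each factor diluted by sqrt(1 + k)
    Z = (noise + contrib) / np.sqrt(1.0 + n_roles)[:, None]
    auc = np.clip(auc, 0.0, None)  # AUC is non-negative by definition
    expression = pd.DataFrame(Z, index=genes, columns=cell_lines)
    response = pd.DataFrame(auc, index=drugs, columns=cell_lines)
    gold = call_sensitive_from_auc(response, rule="per_drug_quantile", q=sensitivity_quantile)
    params = {
        "n_genes": n_genes,
        "n_cell_lines": n_cell_lines,
        "n_drugs": n_drugs,
        "n_biomarkers_per_direction": n_bio,
        "effect_beta": effect_beta,
        "noise_sd": noise_sd,
        "mu_auc": mu_auc,
        "sensitivity_quantile": sensitivity_quantile,
        "cross_drug_disjoint": cross_drug_disjoint,
    }
    return SyntheticBenchmark(expression, response, truth, gold, params, seed)


def simulate_cohort(
    benchmark: SyntheticBenchmark,
    n_patients_per_subtype: int = 12,
    drugs_per_subtype: dict[str, list[str]] | int = 5,
    shift: float = 2.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate tumor profiles whose subtypes respond to designated drugs.

    ``drugs_per_subtype`` is either a mapping subtype -> drug ids, or an
    integer n: two subtypes ("C1", "C2") each get n distinct benchmark drugs.
    Each patient profile is i.i.d. N(0, 1) background plus ``+shift`` on the
    planted sensitivity biomarkers (and ``-shift`` on the resistance
    biomarkers) of the subtype's designated drugs.
    """
    rng = np.random.default_rng(seed)
    bench_drugs = list(benchmark.response.index)
    if isinstance(drugs_per_subtype, int):
        n_eff = drugs_per_subtype
        if 2 * n_eff > len(bench_drugs):
            raise ValueError("not enough benchmark drugs for two disjoint subtype sets")
        chosen = rng.choice(bench_drugs, size=2 * n_eff, replace=False)
        designated = {"C1": list(chosen[:n_eff]), "C2": list(chosen[n_eff:])}
    else:
        designated = {k: list(v) for k, v in drugs_per_subtype.items()}
    for subtype, drug_list in designated.items():
        if not drug_list:
            raise ValueError(f"subtype {subtype}: empty effective-drug set")
        unknown = [d for d in drug_list if d not in benchmark.truth_biomarkers]
        if unknown:
            raise ValueError(f"subtype {subtype}: unknown drug ids {unknown}")

    genes = list(benchmark.expression.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    profiles = {}
    labels = {}
    for subtype, drug_list in designated.items():
        up = sorted({gene_pos[g] for d in drug_list for g in benchmark.truth_biomarkers[d]["sensitivity"]})
        down = sorted({gene_pos[g] for d in drug_list for g in benchmark.truth_biomarkers[d]["resistance"]})
        for i in range(n_patients_per_subtype):
            pid = f"{subtype}_P{i:03d}"
            profile = rng.standard_normal(len(genes))
            profile[up] += shift
            profile[down] -= shift
            profiles[pid] = profile
            labels[pid] = subtype
    expression = pd.DataFrame(profiles, index=genes)
    params = {
        "n_patients_per_subtype": n_patients_per_subtype,
        "shift": shift,
        "designated": designated,
    }
    return SyntheticCohort(expression, pd.Series(labels), designated, params, seed)


def cohort_gold_standard(cohort: SyntheticCohort, drugs: list[str] | None = None) -> GoldStandard:
    """Gold standard implied by a synthetic cohort: a (patient, drug) pair is
    sensitive iff the drug is designated effective for the patient's subtype."""
    if drugs is None:
        drugs = sorted({d for ds in cohort.truth_effective_drugs.values() for d in ds})
        # include every drug id seen in params' designated sets only if no
        # explicit drug universe is given; callers scoring a library should
        # pass that library's drugs for resistant labels to exist
    labels: dict[tuple[str, str], str] = {}
    for patient, subtype in cohort.subtype_labels.items():
        effective = set(cohort.truth_effective_drugs[subtype])
        for drug in drugs:
            labels[(str(patient), str(drug))] = "sensitive" if drug in effective else "resistant"
    return GoldStandard(labels, "synthetic cohort designation")
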