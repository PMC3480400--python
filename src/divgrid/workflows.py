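"""End-to-end pipelines tying the modules together.

These are the computations the analysis drivers and the acceptance checks
run: the bootstrap-vs-rarefaction method validation on a synthetic grid, and
cluster recovery on the full synthetic scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .bootstrap import (BootstrapConfig, cell_rarefaction_expectation,
                        gridwide_bootstrap, unit_bootstrap_table,
                        validate_against_rarefaction)
from .grid import GridSpec, filter_cells, replicate_samples
from .simulate import cacao_like_scenario
from .structure import (build_allele_matrix, cluster_members, dapc_membership,
                        fit_kmeans, kmeans_bic_scan)


def bootstrap_rarefaction_validation(seed: int = 42, n_trees: int = 8,
                                     B: int = 1000, diameter: float = 1.0):
    """Regress per-cell bootstrap richness on the analytic rarefaction value.

    Generates the full synthetic scenario, replicates individuals on the
    10-arcminute grid with circular neighborhoods, retains cells with at
    least ``n_trees`` individuals, and compares the bootstrap mean allelic
    richness (subsamples of ``n_trees`` trees, B replicates) with the exact
    hypergeometric expectation at g = 2*n_trees on the same locus sets.
    Returns a dict with the regression slope, Pearson r and problem sizes.
    """
    genotypes, passports, _, _ = cacao_like_scenario(seed)
    grid = GridSpec()
    assignment = replicate_samples(passports, grid, diameter)
    retained, stats = filter_cells(assignment, min_trees=n_trees)
    config = BootstrapConfig(n_trees=n_trees, B=B, seed=seed,
                             statistics=("allelic_richness",))
    table = gridwide_bootstrap(retained, genotypes, config,
                               locus_min_copies=2 * n_trees)
    analytic = cell_rarefaction_expectation(genotypes, retained.cells, 2 * n_trees)
    analytic.index = pd.MultiIndex.from_tuples(analytic.index,
                                               names=["cell_col", "cell_row"])
    slope, r = validate_against_rarefaction(table, analytic)
    return {
        "slope": slope, "pearson_r": r,
        "n_cells": int(len(table)),
        "n_cells_before_filter": stats.n_cells_before,
        "n_placements": stats.n_placements_before,
        "n_individuals": genotypes.n_individuals,
        "table": table, "analytic": analytic,
    }


def cluster_recovery(seed: int = 42, k_range=range(1, 16), true_k: int = 10,
                     B: int = 1000, membership_threshold: float = 0.7):
    """Recover the planted population structure from the synthetic scenario.

    Runs the BIC scan for the number of clusters, fits k-means at the true
    k, derives DAPC memberships, and computes bootstrap-corrected cluster
    statistics with the subsample size set to the smallest cluster. Returns
    truth-comparison summaries (elbow k, adjusted Rand index, share of
    confident memberships, per-cluster richness with the truth mapping).
    """
    genotypes, passports, truth, config = cacao_like_scenario(seed)
    matrix = build_allele_matrix(genotypes)
    curve = kmeans_bic_scan(matrix, k_range=k_range, seed=seed)
    labels = fit_kmeans(matrix, true_k, seed=seed)
    model = dapc_membership(matrix, labels)
    ari = adjusted_rand_score(truth.pop, model.labels)
    frac_confident = float((model.membership.max(axis=1) > membership_threshold).mean())

    members = {j: ids for j, ids in cluster_members(model, membership_threshold).items()
               if ids}
    n_trees = min(len(v) for v in members.values())
    cfg = BootstrapConfig(n_trees=n_trees, B=B, seed=seed)
    table = unit_bootstrap_table(
        genotypes, members, cfg, include_private=True,
        locally_common={"occupancy_max_units": 2, "freq_min": 0.05, "strict": True})

    id_row = {i: r for r, i in enumerate(genotypes.ids)}
    cluster_to_pop = {}
    for j, ids in members.items():
        pops = truth.pop[[id_row[i] for i in ids]]
        cluster_to_pop[j] = int(np.bincount(pops).argmax())
    table = table.assign(true_pop=[cluster_to_pop[j] for j in table.index])

    return {
        "bic_curve": curve, "chosen_k": curve.chosen_k,
        "model": model, "ari": float(ari),
        "frac_confident": frac_confident,
        "cluster_table": table, "n_trees": n_trees,
        "truth": truth, "genotypes": genotypes, "passports": passports,
        "config": config,
    }
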