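"""Simulation-based validation experiments with planted ground truth.

Each experiment builds synthetic inputs with a known planted quantity, runs
the estimator under test end to end, and reports the recovered value; used by
the acceptance report script and the acceptance test suite.
"""
from __future__ import annotations

import numpy as np

from .enrichment import EnrichmentParams, enrichment_test, scan_categories
from .pgls import pgls_fit, tree_vcv
from .synthetic import (
    PlantedEnrichment,
    SimulationConfig,
    plant_genome,
    random_ultrametric_tree,
    simulate_bm_traits,
)

__all__ = [
    "p_floor_experiment",
    "fold_recovery_experiment",
    "fdr_experiment",
    "pgls_recovery_experiment",
]


def p_floor_experiment(seed: int, n_resamples: int = 499) -> dict:
    """Plant extreme enrichment so the observed density tops every null draw.

    Returns the one-sided empirical p, which must sit at the add-one floor
    1/(N+1).
    """
    config = SimulationConfig(
        seed=seed,
        seq_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        classes={"LINE/BovB": 0.005, "DNA/TcMar-Tc1": 0.01, "Unknown": 0.01},
        n_genes=200,
        family_length_range=(150, 400),
        enrichments=[PlantedEnrichment("fs", 6, "LINE/BovB", 40.0)],
    )
    sim = plant_genome(config)
    params = EnrichmentParams(n_resamples=n_resamples, seed=seed + 1)
    res = enrichment_test(
        sim.focal_genes("fs"), sim.hits, sim.genes, "LINE/BovB", sim.index, params
    )
    return {
        "p_emp": res.p_emp,
        "observed_exceeds_all_nulls": bool(
            (res.null_densities < res.observed_density).all()
        ),
        "n": n_resamples,
    }


def fold_recovery_experiment(
    seed: int,
    planted_fold: float,
    m: int,
    category: str = "LINE/BovB",
    n_resamples: int = 499,
    background_density: float = 0.05,
) -> dict:
    """Plant ``planted_fold`` around an m-gene family; re-estimate it.

    The genome is sized so enough repeat copies overlap gene neighbourhoods
    to keep the null-mean realization noise well under the recovery
    tolerance.
    """
    config = SimulationConfig(
        seed=seed,
        seq_lengths={"chr1": 8_000_000, "chr2": 8_000_000},
        classes={
            category: background_density,
            "DNA/TcMar-Tigger": 0.02,
            "Unknown": 0.02,
        },
        families_per_class=3,
        family_length_range=(150, 400),
        n_genes=800,
        gene_length_range=(1000, 2000),
        enrichments=[PlantedEnrichment("fs", m, category, planted_fold)],
    )
    sim = plant_genome(config)
    params = EnrichmentParams(flank=1000, n_resamples=n_resamples, seed=seed + 1)
    res = enrichment_test(
        sim.focal_genes("fs"), sim.hits, sim.genes, category, sim.index, params
    )
    truth = sim.truth["enrichments"][0]
    return {
        "estimated_fold": res.fold_enrichment,
        "planted_fold": planted_fold,
        "realized_fold": truth["realized_fold"],
        "p_emp": res.p_emp,
        "m": m,
        "n": n_resamples,
    }


def fdr_experiment(
    seed: int,
    n_replicates: int = 200,
    n_categories: int = 20,
    n_enriched: int = 2,
    enriched_fold: float = 3.0,
    fdr_level: float = 0.1,
    n_resamples: int = 499,
) -> dict:
    """Mean realized false-discovery proportion of the BH-controlled scan.

    Each replicate plants ``n_enriched`` truly enriched categories (same
    focal set) among nulls, scans all categories with shared null draws, and
    scores the discovery list against the planted truth.
    """
    classes = {f"SIM/cat{i:02d}": 0.02 for i in range(n_categories)}
    enriched = [f"SIM/cat{i:02d}" for i in range(n_enriched)]
    rng = np.random.default_rng(seed)
    fdps = []
    n_discoveries = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        config = SimulationConfig(
            seed=rep_seed,
            seq_lengths={"chr1": 2_000_000},
            classes=classes,
            families_per_class=2,
            family_length_range=(100, 250),  # short copies: low per-region noise
            n_genes=250,
            gene_length_range=(800, 1500),
            enrichments=[
                PlantedEnrichment("fs", 15, cat, enriched_fold) for cat in enriched
            ],
        )
        sim = plant_genome(config)
        params = EnrichmentParams(
            n_resamples=n_resamples, fdr_level=fdr_level, seed=rep_seed + 1
        )
        results = scan_categories(
            sim.focal_genes("fs"), sim.hits, sim.genes, list(classes),
            sim.index, params,
        )
        discoveries = [r.category for r in results if r.q_bh <= fdr_level]
        false = [c for c in discoveries if c not in enriched]
        fdps.append(len(false) / max(1, len(discoveries)))
        n_discoveries += len(discoveries)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "fdr_level": fdr_level,
        "mean_discoveries": n_discoveries / n_replicates,
        "n": n_replicates,
    }


def pgls_recovery_experiment(
    seed: int,
    planted_slope: float = 4.8e-4,
    planted_intercept: float = 0.15,
    n_tips: int = 16,
    n_replicates: int = 500,
    sigma2: float = 0.017,  # gives R^2 ~= 0.6 for x ~ U(300, 1400)
) -> dict:
    """Mean recovered PGLS slope over BM-simulated trait replicates."""
    tree = random_ultrametric_tree(n_tips, seed=seed)
    labels, _ = tree_vcv(tree)
    rng = np.random.default_rng(seed + 1)
    x = {l: float(v) for l, v in zip(labels, rng.uniform(300, 1400, n_tips))}
    slopes = []
    for i in range(n_replicates):
        traits = simulate_bm_traits(
            tree, planted_intercept, planted_slope, sigma2, x,
            seed=int(rng.integers(2**31)),
        )
        slopes.append(pgls_fit(traits, tree).slope)
    return {
        "mean_slope": float(np.mean(slopes)),
        "planted_slope": planted_slope,
        "sd_slope": float(np.std(slopes)),
        "n": n_replicates,
    }
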