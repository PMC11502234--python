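"""End-to-end validation experiments on synthetic data with known truth.

Each function runs one self-contained study — simulate, analyze, measure —
and returns a flat dict of summary numbers. They back both the validation
part of the test suite and the ``scripts/acceptance.py`` report.

Problem sizes are scaled for a single CPU: the differential-expression
studies use 2,000-gene cohorts; module recovery runs on the 1,000-gene
two-module benchmark (where the full correlation network fits comfortably);
the permutation-envelope study keeps the full ~15,000-gene transcriptome
scale because its outcome depends on trait-linked genes being a small
minority, as they are in real cohorts (eigengenes of permuted gene sets
pick up the trait axis whenever trait-linked genes are a sizable share of
the matrix).
"""

from __future__ import annotations

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import graphtop, modulenet, startle, synthio
from .degflow import run_deg_pipeline
from .synthio import ModuleSpec, SimConfig

__all__ = [
    "mcc_oracle_agreement",
    "deg_calibration_and_power",
    "module_recovery",
    "permutation_envelope",
    "driver_deletion",
    "hub_fragmentation",
    "deterministic_toys",
    "ppi_examples",
]


def _mcc_bitmask_oracle(graph: nx.Graph) -> dict:
    """Exhaustive MCC by subset filtering with adjacency bitmasks.

    Independent of the Bron-Kerbosch path: every vertex subset is tested
    for cliqueness and maximality directly.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    score = [0] * n
    for subset in range(1, 1 << n):
        members = [i for i in range(n) if subset >> i & 1]
        rest = subset
        if any((adj[i] | 1 << i) & subset != subset for i in members):
            continue  # not a clique
        # maximal iff no outside vertex is adjacent to every member
        closure = ~subset
        if any(
            (adj[w] & subset) == subset
            for w in range(n)
            if closure >> w & 1
        ):
            continue
        contrib = math.factorial(len(members) - 1)
        for i in members:
            score[i] += contrib
    return {nodes[i]: score[i] for i in range(n)}


def mcc_oracle_agreement(seed: int, n_graphs: int = 100) -> dict:
    """MCC vs exhaustive oracle on random graphs, plus closed forms."""
    rng = np.random.default_rng(seed)
    matches = 0
    for g_idx in range(n_graphs):
        n = int(rng.integers(4, 16))
        p = float(rng.uniform(0.1, 0.5))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        ours = graphtop.mcc_scores(g)["mcc"].to_dict()
        matches += ours == _mcc_bitmask_oracle(g)
    complete_ok = all(
        (graphtop.mcc_scores(nx.complete_graph(k))["mcc"] == math.factorial(k - 1)).all()
        for k in (3, 4, 5, 6, 7)
    )
    star = graphtop.mcc_scores(nx.star_graph(5))
    star_ok = star.loc[0, "mcc"] == 5 and (star.drop(index=0)["mcc"] == 1).all()
    return {
        "mcc_oracle_match_pct": 100.0 * matches / n_graphs,
        "mcc_closed_forms_ok": float(complete_ok and star_ok),
        "n": n_graphs,
    }


def deg_calibration_and_power(seed: int, n_genes: int = 2000) -> dict:
    """Type-I calibration under the null and power on planted fold changes."""
    null_cfg = SimConfig(n_genes=n_genes, de_fraction=0.0, seed=seed)
    counts, meta, _ = synthio.simulate_bulk_counts(null_cfg)
    res, _, _ = run_deg_pipeline(counts, meta, drop_outliers=False)
    null_frac = float((res.table["p_trait"] < 0.05).mean())

    alt_cfg = SimConfig(
        n_genes=n_genes, de_fraction=0.05, de_log2fc=1.0, nb_dispersion=0.1,
        seed=seed + 1,
    )
    counts, meta, truth = synthio.simulate_bulk_counts(alt_cfg)
    res, _, _ = run_deg_pipeline(counts, meta, drop_outliers=False)
    planted = [g for g, _ in truth.de_genes if g in res.table.index]
    power = float(res.table.loc[planted, "called_05"].mean())
    return {
        "deg_null_p05_fraction": null_frac,
        "deg_power_pct": 100.0 * power,
        "n": n_genes,
    }


def _module_chain(cfg: SimConfig):
    counts, meta, truth = synthio.simulate_bulk_counts(cfg)
    _, expr, _ = run_deg_pipeline(counts, meta, drop_outliers=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, _ = modulenet.pick_soft_power(expr.values)
    network = modulenet.build_tom(expr.values, beta)
    assignment, eig = modulenet.detect_modules(network)
    return meta, truth, expr, network, assignment, eig


def module_recovery(seed: int, n_seeds: int = 20, n_genes: int = 1000) -> dict:
    """Adjusted Rand index of detected vs planted modules (two planted
    modules of 150 genes, trait correlations +0.9 / -0.75, 12 samples)."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes, de_fraction=0.0, seed=seed + k,
            modules=(ModuleSpec(150, 0.9), ModuleSpec(150, -0.75)),
        )
        _, truth, _, _, assignment, _ = _module_chain(cfg)
        truth_labels = (
            pd.Series(truth.module_map).reindex(assignment.index).fillna("none")
        )
        aris.append(adjusted_rand_score(truth_labels, assignment))
    return {
        "module_recovery_mean_ari": float(np.mean(aris)),
        "module_recovery_min_ari": float(np.min(aris)),
        "n": n_seeds,
    }


def permutation_envelope(
    seed: int, n_seeds: int = 20, n_genes: int = 15000, n_perm: int = 40
) -> dict:
    """Permutation-envelope behavior of planted vs trait-independent modules.

    Planted memberships (150-gene modules at trait correlations +0.9,
    -0.75 and 0.0) are validated against ``n_perm`` membership
    permutations on a full-transcriptome-scale matrix; a seed succeeds when
    both trait-linked modules beat every permutation and the independent
    module does not.
    """
    joint = pm1 = pm2 = null_ok = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes, de_fraction=0.0, seed=seed + k,
            modules=(
                ModuleSpec(150, 0.9), ModuleSpec(150, -0.75), ModuleSpec(150, 0.0),
            ),
        )
        counts, meta, truth = synthio.simulate_bulk_counts(cfg)
        _, expr, _ = run_deg_pipeline(counts, meta, drop_outliers=False)
        assignment = (
            pd.Series(truth.module_map)
            .reindex(expr.values.index)
            .fillna(modulenet.UNASSIGNED)
        )
        summary = modulenet.permute_module_validation(
            expr.values, assignment, meta, n_perm=n_perm, seed=seed + k
        )
        ex = summary.exceeds_all
        pm1 += bool(ex.get("pm1", False))
        pm2 += bool(ex.get("pm2", False))
        null_ok += not ex.get("pm3", True)
        joint += bool(ex.get("pm1", False) and ex.get("pm2", False)
                      and not ex.get("pm3", True))
    return {
        "envelope_joint_pct": 100.0 * joint / n_seeds,
        "envelope_planted_up_pct": 100.0 * pm1 / n_seeds,
        "envelope_planted_down_pct": 100.0 * pm2 / n_seeds,
        "envelope_null_within_pct": 100.0 * null_ok / n_seeds,
        "n": n_seeds,
    }


def driver_deletion(seed: int, n_random: int = 20) -> dict:
    """KS shift from deleting top-MM drivers vs matched random deletions."""
    cfg = SimConfig(
        n_genes=1000, de_fraction=0.0, seed=seed, modules=(ModuleSpec(150, 0.9),),
    )
    meta, truth, expr, network, assignment, eig = _module_chain(cfg)
    per_gene, _ = modulenet.gene_module_stats(expr.values, eig, assignment, meta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        drivers = modulenet.select_drivers(per_gene)
    module = max(drivers, key=lambda m: int((assignment == m).sum()))
    shift = modulenet.driver_deletion_shift(
        network, assignment, drivers[module], module
    )
    members = [
        g for g in assignment.index
        if assignment[g] == module and g not in set(drivers[module])
    ]
    rng = np.random.default_rng(seed)
    random_d = [
        modulenet.driver_deletion_shift(
            network, assignment,
            list(rng.choice(members, size=len(drivers[module]), replace=False)),
            module,
        ).statistic
        for _ in range(n_random)
    ]
    return {
        "driver_ks_d": shift.statistic,
        "driver_ks_p": shift.pvalue,
        "driver_shift_left": float(shift.direction == "left"),
        "random_deletion_median_d": float(np.median(random_d)),
        "n": n_random,
    }


def hub_fragmentation(seed: int, n_seeds: int = 20, n_nodes: int = 500) -> dict:
    """Deleting MCC hubs vs random non-hubs in scale-free interactomes."""
    wins = 0
    for k in range(n_seeds):
        g, _ = synthio.simulate_interactome(n_nodes, attach_m=1, planted_clique=0,
                                            seed=seed + k)
        ranking = graphtop.mcc_scores(g)
        hubs = graphtop.top_hubs(ranking, 10)[:10]
        nonhub_pool = [v for v in g.nodes if v not in set(graphtop.top_hubs(ranking, 50))]
        rng = np.random.default_rng(seed + k)
        random_nodes = list(rng.choice(nonhub_pool, 10, replace=False))
        _, _, hub_after = graphtop.delete_nodes_stats(g, hubs)
        _, _, rnd_after = graphtop.delete_nodes_stats(g, random_nodes)
        wins += (hub_after.n_components > rnd_after.n_components
                 and hub_after.n_edges < rnd_after.n_edges)
    g, _ = synthio.simulate_interactome(n_nodes, attach_m=2, planted_clique=0, seed=seed)
    tc = graphtop.topological_coefficients(g)
    deg = pd.Series(dict(g.degree)).reindex(tc.index)
    keep = tc > 0
    rho = float(spearmanr(deg[keep], tc[keep]).statistic)
    return {
        "hub_deletion_win_pct": 100.0 * wins / n_seeds,
        "degree_tc_spearman": rho,
        "n": n_seeds,
    }


def deterministic_toys(tmp_dir) -> dict:
    """Hand-enumerated STRING filtering, seeded growth, and enrichment."""
    from pathlib import Path

    tmp_dir = Path(tmp_dir)
    rows = []
    channels = synthio.STRING_CHANNELS

    def row(p1, p2, **scores):
        base = dict.fromkeys(channels, 0)
        base.update(scores)
        return [p1, p2, *(base[c] for c in channels), max(base.values())]

    rows = [
        row("A", "B", experimental=950),
        row("B", "C", textmining=990),
        row("C", "D", experimental=500),
        row("D", "E", database=920, fusion=910),
    ]
    path = tmp_dir / "toy_edges.tsv"
    pd.DataFrame(
        rows, columns=["protein1", "protein2", *channels, "combined_score"]
    ).to_csv(path, sep="\t", index=False)
    g = graphtop.load_interactions(path)
    filter_ok = set(map(tuple, map(sorted, g.edges))) == {("A", "B"), ("D", "E")}

    interactome = nx.Graph(
        [("A", "B"), ("A", "C"), ("C", "F"), ("D", "E"), ("B", "G"), ("G", "H")]
    )
    grown = graphtop.grow_seeded_network(
        ["A", "B"], ["C", "D", "E", "F", "G", "H"], interactome
    )
    growth_ok = set(grown.nodes) == {"A", "B", "C", "F", "G", "H"}

    universe = [f"g{i}" for i in range(20)]
    full = graphtop.hypergeom_enrichment(universe[:5], {"s": universe[:5]}, universe)
    table = graphtop.hypergeom_enrichment(
        universe[:5], {"s": universe[:3] + universe[5:7]}, universe
    )
    return {
        "toy_filter_ok": float(filter_ok),
        "toy_growth_ok": float(growth_ok),
        "toy_hypergeom_p": float(full.loc["s", "p"]),
        "toy_odds_ratio": float(table.loc["s", "odds_ratio"]),
        "n": len(rows),
    }


def ppi_examples() -> dict:
    """%PPI worked examples and scale invariance."""
    def session(baseline, pp):
        return startle.StartleSession(
            pd.DataFrame(
                [("startle_alone", b) for b in baseline] + [("pp", a) for a in pp],
                columns=["trial_type", "amplitude"],
            )
        )

    sixty = startle.percent_ppi(session([100.0], [40.0])).loc["pp", "ppi_pct"]
    capped = startle.percent_ppi(session([100.0], [120.0])).loc["pp", "ppi_pct"]
    base = startle.percent_ppi(session([100.0, 80.0], [55.0])).loc["pp", "ppi_pct"]
    scaled = startle.percent_ppi(
        session([1000.0, 800.0], [550.0])
    ).loc["pp", "ppi_pct"]
    return {
        "ppi_sixty_example_pct": float(sixty),
        "ppi_capped_example_pct": float(capped),
        "ppi_scale_invariance_gap": abs(float(base) - float(scaled)),
        "n": 3,
    }
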