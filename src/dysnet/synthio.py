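"""Synthetic-data generators with ground truth for every downstream stage.

The bulk-count generator emulates a small two-genotype mouse RNA-seq design
(by default 6 animals per genotype, 3 of each sex, two sequencing batches):
negative-binomial counts around log-normal per-gene baselines scaled by
log-normal library sizes, planted fold changes on a fraction of genes,
latent-factor coexpression modules with a configured genotype correlation,
and an additive log-scale batch effect. The interactome generator plants a
clique inside a preferential-attachment backbone; the gene-set generator
plants a known query overlap; the startle generator produces trial tables
with a known prepulse-inhibition effect.

Every generator is driven by a single root seed with per-purpose child
streams, so identical configuration yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .startle import StartleSession

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "SynthTruth",
    "simulate_bulk_counts",
    "simulate_interactome",
    "simulate_gene_sets",
    "simulate_startle_session",
    "write_counts_tsv",
    "write_metadata_tsv",
    "write_edges_tsv",
    "write_gmt",
    "write_trials_csv",
    "write_truth_json",
]

STRING_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted coexpression module.

    ``trait_correlation`` is the Pearson correlation, in expectation,
    between the module's latent factor and the numeric (0/1) trait;
    ``loading_range`` bounds the per-gene log2-scale loadings on the factor.
    """

    size: int
    trait_correlation: float
    loading_range: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be positive")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ValueError("|trait_correlation| must be <= 1")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the bulk RNA-seq simulation.

    Defaults reproduce the emulated study design: 6 samples per genotype
    split 3/3 by sex over two sequencing batches, library sizes around
    33.3 M reads, NB dispersion 0.1, and gene baselines log-normal on the
    CPM scale.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 6
    groups: tuple[str, str] = ("WT", "LL")
    batches: tuple[str, ...] = ("b1", "b2")
    sexes: tuple[str, ...] = ("M", "F")
    lib_size_log_mean: float = float(np.log(33.33e6))
    lib_size_log_sd: float = 0.1
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    batch_sd: float = 0.2
    modules: tuple[ModuleSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if len(self.groups) < 2:
            raise ValueError("at least 2 trait groups are required")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("module sizes sum above n_genes")


@dataclass
class SynthTruth:
    """Ground truth of a simulation, for recovery testing."""

    de_genes: list[tuple[str, float]] = field(default_factory=list)
    module_map: dict[str, str] = field(default_factory=dict)
    hub_nodes: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": self.de_genes,
                "module_map": self.module_map,
                "hub_nodes": self.hub_nodes,
                "enriched_sets": self.enriched_sets,
            },
            indent=1,
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mu + dispersion*mu^2 (gamma-Poisson).

    dispersion -> 0 degenerates to Poisson.
    """
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_bulk_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Simulate a gene x sample count matrix, sample table, and truth record.

    Counts are NB around ``baseline_cpm * lib_size/1e6`` modified on the
    log2 scale by (i) the planted group effect of ``de_log2fc`` on a
    ``de_fraction`` of genes, half up / half down in the test group; (ii)
    module latent factors built as ``rho*z_trait + sqrt(1-rho^2)*noise`` so
    the factor-trait Pearson correlation is ``rho`` in expectation, entering
    each member gene through its loading; and (iii) a gene-wise additive
    N(0, batch_sd) batch offset.
    """
    root = np.random.default_rng(config.seed)
    streams = root.spawn(5)
    rng_design, rng_base, rng_de, rng_mod, rng_counts = streams

    n_grp = config.n_samples_per_group
    groups = list(config.groups)
    n_samples = n_grp * len(groups)
    sample_ids = [f"{g}{i + 1}" for g in groups for i in range(n_grp)]
    trait = np.repeat(groups, n_grp)
    # sex alternates within group; batch splits each group into blocks, so
    # neither is aliased with trait nor with the other
    sexes = np.array(
        [config.sexes[i % len(config.sexes)] for _ in groups for i in range(n_grp)]
    )
    n_batch = len(config.batches)
    batches = np.array(
        [config.batches[min(i * n_batch // n_grp, n_batch - 1)]
         for _ in groups for i in range(n_grp)]
    )
    meta = pd.DataFrame(
        {"sample": sample_ids, "trait": trait, "batch": batches, "sex": sexes}
    ).set_index("sample")

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    baseline_cpm = np.power(
        2.0,
        rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes),
    )
    lib_sizes = rng_base.lognormal(
        config.lib_size_log_mean, config.lib_size_log_sd, n_samples
    )

    log2_shift = np.zeros((config.n_genes, n_samples))
    truth = SynthTruth()

    is_test = (trait == groups[1]).astype(float)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = set()
    if n_de:
        chosen = rng_de.choice(config.n_genes, size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        for idx, sign in zip(chosen, signs):
            lfc = sign * config.de_log2fc
            log2_shift[idx] += lfc * is_test
            truth.de_genes.append((genes[idx], float(lfc)))
        de_idx = set(chosen.tolist())

    z_trait = (is_test - is_test.mean()) / is_test.std()
    cursor = 0
    free = [i for i in range(config.n_genes) if i not in de_idx]
    for m, spec in enumerate(config.modules):
        label = f"pm{m + 1}"
        members = free[cursor : cursor + spec.size]
        if len(members) < spec.size:
            raise ValueError("not enough non-DE genes left to plant modules")
        cursor += spec.size
        rho = spec.trait_correlation
        factor = rho * z_trait + np.sqrt(1 - rho**2) * rng_mod.standard_normal(n_samples)
        lo, hi = spec.loading_range
        loadings = rng_mod.uniform(lo, hi, spec.size)
        log2_shift[members] += np.outer(loadings, factor)
        for i in members:
            truth.module_map[genes[i]] = label

    batch_levels = list(dict.fromkeys(batches))
    if len(batch_levels) > 1 and config.batch_sd > 0:
        offsets = rng_mod.normal(0.0, config.batch_sd, (config.n_genes, len(batch_levels)))
        batch_idx = np.array([batch_levels.index(b) for b in batches])
        log2_shift += offsets[:, batch_idx]

    mu = (
        baseline_cpm[:, None]
        * (lib_sizes[None, :] / 1e6)
        * np.power(2.0, log2_shift)
    )
    counts = _nb_draw(rng_counts, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    return counts_df, meta.reset_index(), truth


def _string_scores(rng: np.random.Generator, strong: bool) -> dict[str, int]:
    """Per-channel evidence scores (0-1000) for one edge.

    Planted/strong edges get high experimental support; background edges get
    moderate mixed support.
    """
    scores = dict.fromkeys(STRING_CHANNELS, 0)
    if strong:
        scores["experimental"] = int(rng.integers(900, 1000))
        scores["database"] = int(rng.integers(700, 1000))
    else:
        scores["experimental"] = int(rng.integers(400, 950))
        scores["textmining"] = int(rng.integers(0, 800))
        scores["coexpression"] = int(rng.integers(0, 600))
    return scores


def simulate_interactome(
    n_nodes: int,
    attach_m: int = 2,
    planted_clique: int = 0,
    seed: int = 0,
) -> tuple[nx.Graph, SynthTruth]:
    """Scale-free interactome with an optional planted clique.

    A Barabasi-Albert preferential-attachment backbone (heavy-tailed degree
    distribution) is decorated with per-channel evidence scores; the clique
    is planted on the ``planted_clique`` lowest-degree backbone nodes, so
    its members are otherwise peripheral. Clique edges carry strong
    experimental evidence. Node ids are ``n0000``-style strings.
    """
    if planted_clique > n_nodes:
        raise ValueError("planted_clique cannot exceed n_nodes")
    if attach_m >= n_nodes:
        raise ValueError("attach_m must be below n_nodes")
    rng = np.random.default_rng(seed)
    backbone = nx.barabasi_albert_graph(
        n_nodes, attach_m, seed=int(rng.integers(2**31))
    )
    relabel = {i: f"n{i:04d}" for i in backbone.nodes}
    g = nx.relabel_nodes(backbone, relabel)
    truth = SynthTruth()
    clique_nodes: set[str] = set()
    if planted_clique >= 2:
        by_degree = sorted(g.nodes, key=lambda v: (g.degree(v), v))
        members = by_degree[:planted_clique]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
        clique_nodes = set(members)
        truth.hub_nodes = sorted(clique_nodes)
    for u, v, data in g.edges(data=True):
        strong = u in clique_nodes and v in clique_nodes
        data.update(_string_scores(rng, strong))
        data["combined_score"] = max(data[c] for c in STRING_CHANNELS)
    return g, truth


def simulate_gene_sets(
    universe: list[str],
    n_sets: int,
    planted: tuple[str, int] | None = None,
    query: list[str] | None = None,
    set_size: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> tuple[dict[str, list[str]], SynthTruth]:
    """Random gene-set collection with an optional planted query overlap.

    Non-planted sets are uniform draws from the universe. When ``planted``
    is ``(set_id, k)``, that set is forced to contain exactly ``k`` genes
    of ``query`` (plus off-query filler up to its size).
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    collection: dict[str, list[str]] = {}
    truth = SynthTruth()
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        size = min(size, len(universe))
        collection[f"set{i:03d}"] = sorted(
            rng.choice(universe, size=size, replace=False).tolist()
        )
    if planted is not None:
        set_id, overlap = planted
        if set_id in collection:
            raise ValueError(f"duplicate set id: {set_id}")
        if query is None:
            raise ValueError("planted overlap requires a query gene list")
        if overlap > len(query):
            raise ValueError("planted overlap exceeds query size")
        size = max(overlap, int(rng.integers(set_size[0], set_size[1] + 1)))
        size = min(size, len(universe))
        if overlap > size:
            raise ValueError("planted overlap exceeds set size")
        inside = rng.choice(query, size=overlap, replace=False).tolist()
        off_query = [g for g in universe if g not in set(query)]
        filler = rng.choice(off_query, size=size - overlap, replace=False).tolist()
        collection[set_id] = sorted(inside + filler)
        truth.enriched_sets = [set_id]
    return collection, truth


def simulate_startle_session(
    baseline_mean: float = 100.0,
    ppi_effect: dict[str, float] | None = None,
    noise_sd: float = 10.0,
    n_trials: int = 20,
    seed: int = 0,
) -> StartleSession:
    """Startle-trial table with known per-trial-type inhibition.

    Startle-alone amplitudes are Normal(baseline_mean, noise_sd); each
    prepulse trial type with effect ``e`` is Normal(baseline*(1-e),
    noise_sd). Amplitudes are truncated at 0.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if ppi_effect is None:
        ppi_effect = {"75dB-30ms": 0.5, "85dB-30ms": 0.7}
    for t, e in ppi_effect.items():
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"ppi_effect for {t!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trials):
        rows.append(("startle_alone", max(0.0, rng.normal(baseline_mean, noise_sd))))
    for trial_type, effect in ppi_effect.items():
        mean = baseline_mean * (1.0 - effect)
        for _ in range(n_trials):
            rows.append((trial_type, max(0.0, rng.normal(mean, noise_sd))))
    trials = pd.DataFrame(rows, columns=["trial_type", "amplitude"])
    return StartleSession(trials)


# ---------------------------------------------------------------------------
# plain-text writers (TSV/CSV/GMT/JSON), matching the downstream readers

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_edges_tsv(graph: nx.Graph, path: str | Path) -> None:
    """STRING-dialect edge list: protein1 protein2 channels combined_score."""
    cols = ["protein1", "protein2", *STRING_CHANNELS, "combined_score"]
    rows = [
        [u, v, *(data.get(c, 0) for c in STRING_CHANNELS), data.get("combined_score", 0)]
        for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_gmt(collection: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, genes in collection.items():
            fh.write("\t".join([set_id, "synthetic", *genes]) + "\n")


def write_trials_csv(session: StartleSession, path: str | Path) -> None:
    session.trials.to_csv(path, index=False)


def write_truth_json(truth: SynthTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())
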