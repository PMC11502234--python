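"""Weighted coexpression-module discovery and driver-gene analysis.

The workflow is the WGCNA family of methods: soft-threshold the gene-gene
correlation matrix into an adjacency (``|r|**beta`` unsigned by default),
blend it with shared-neighbor structure into the topological overlap matrix
(TOM), cluster genes by average linkage on ``1 - TOM``, and cut the
dendrogram adaptively into modules. Each module is summarized by its
eigengene (first principal component across samples), correlated with the
trait and technical covariates, and validated against a permutation null in
which gene-module memberships are reshuffled while module sizes are kept.
Putative driver genes are the top tail of module membership (MM); their
importance is quantified by deleting them and testing for a leftward shift
of the module's intra-module edge-weight distribution (two-sample KS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoexprNetwork",
    "PermutationSummary",
    "DeletionShift",
    "pick_soft_power",
    "build_tom",
    "detect_modules",
    "module_eigengenes",
    "module_trait_stats",
    "gene_module_stats",
    "permute_module_validation",
    "select_drivers",
    "driver_deletion_shift",
]

UNASSIGNED = "unassigned"

# WGCNA's conventional module color sequence, assigned by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)



@dataclass(frozen=True)
class CoexprNetwork:
    """Soft-thresholded coexpression network with its TOM.

    ``expr`` is the (genes x samples) log2 expression the network was built
    from; ``adjacency`` and ``tom`` are symmetric gene x gene arrays in
    [0, 1] with unit diagonal.
    """

    expr: pd.DataFrame
    beta: int
    mode: str
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def genes(self) -> pd.Index:
        return self.expr.index


@dataclass(frozen=True)
class PermutationSummary:
    """Observed module-trait correlations against the permutation cloud."""

    observed: pd.DataFrame  # index module, columns r, p
    permuted: pd.DataFrame  # columns perm, module, r, p
    exceeds_all: pd.Series  # per module: observed beyond every permutation
    n_perm: int


@dataclass(frozen=True)
class DeletionShift:
    """KS comparison of intact vs driver-deleted module edge weights."""

    statistic: float
    pvalue: float
    direction: str  # "left", "right" or "none"
    median_intact: float
    median_deleted: float
    note: str = ""


def _correlation(x: np.ndarray, method: str = "pearson") -> np.ndarray:
    if method == "pearson":
        return np.corrcoef(x)
    if method == "bicor":  # biweight midcorrelation, 9-MAD outlier weighting
        med = np.median(x, axis=1, keepdims=True)
        mad = np.median(np.abs(x - med), axis=1, keepdims=True)
        mad[mad == 0] = np.finfo(float).eps
        u = (x - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        xw = (x - med) * w
        norm = np.sqrt((xw**2).sum(axis=1, keepdims=True))
        return np.clip((xw / norm) @ (xw / norm).T, -1.0, 1.0)
    raise ValueError(f"unknown correlation method: {method!r}")


def _adjacency(cor: np.ndarray, beta: int, mode: str) -> np.ndarray:
    if mode == "unsigned":
        a = np.abs(cor) ** beta
    elif mode == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError(f"mode must be 'unsigned' or 'signed', got {mode!r}")
    np.fill_diagonal(a, 1.0)
    return a


def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"dropping {int((sd == 0).sum())} zero-variance gene(s)", stacklevel=3
        )
        expr = expr.loc[sd > 0]
    return expr


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) on log10 k over connectivity bins.

    Positive-slope fits score 0: scale-free topology requires a decreasing
    degree distribution.
    """
    k = k[k > 0]
    if len(k) < n_bins or k.min() == k.max():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    occupied = [b for b in range(n_bins) if (which == b).any()]
    if len(occupied) < 3:
        return 0.0
    kmean = np.array([k[which == b].mean() for b in occupied])
    freq = np.array([(which == b).mean() for b in occupied])
    lx, ly = np.log10(kmean), np.log10(freq)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(r**2) if slope < 0 else 0.0


def pick_soft_power(
    expr: pd.DataFrame,
    candidates: range = range(1, 21),
    fit_target: float = 0.8,
    mode: str = "unsigned",
    method: str = "pearson",
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power by the scale-free topology criterion.

    Returns the smallest candidate power whose scale-free model fit R^2
    reaches ``fit_target``; if none does, the power where the fit curve
    plateaus (successive change < 0.01), with a warning. Also returns the
    per-candidate diagnostics (fit R^2 and mean connectivity).
    """
    if expr.shape[1] < 4:
        raise ValueError("soft-power selection requires at least 4 samples")
    if expr.shape[1] < 8:
        warnings.warn("fewer than 8 samples; soft-power fit is unreliable", stacklevel=2)
    expr = _drop_constant(expr)
    cor = _correlation(expr.to_numpy(dtype=float), method)
    base = np.abs(cor) if mode == "unsigned" else (1.0 + cor) / 2.0
    np.fill_diagonal(base, 1.0)
    rows = []
    acc, acc_power = np.ones_like(base), 0
    for beta in candidates:
        # consecutive integer powers build up by multiplication
        while acc_power < beta:
            acc *= base
            acc_power += 1
        k = acc.sum(axis=1) - 1.0
        rows.append({"power": beta, "fit_r2": _scale_free_fit(k), "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows).set_index("power")
    reaching = diag.index[diag["fit_r2"] >= fit_target]
    if len(reaching):
        return int(reaching[0]), diag
    # plateau = sustained flatness: every later step changes by < 0.01
    fits = diag["fit_r2"].to_numpy()
    small = np.abs(np.diff(fits)) < 0.01
    plateau = [i for i in range(len(small)) if small[i:].all()]
    chosen = int(diag.index[plateau[0] + 1]) if plateau else int(diag.index[-1])
    warnings.warn(
        f"no candidate power reached scale-free fit {fit_target}; "
        f"using plateau power {chosen}",
        stacklevel=2,
    )
    return chosen, diag


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k the connectivity (row sum minus the diagonal); diagonal is 1.
    """
    k = a.sum(axis=1) - 1.0
    numerator = a @ a - a  # (A@A)_ij counts u=i and u=j, each worth a_ij
    tom = numerator / (np.minimum.outer(k, k) + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def build_tom(
    expr: pd.DataFrame,
    beta: int,
    mode: str = "unsigned",
    method: str = "pearson",
) -> CoexprNetwork:
    """Adjacency and topological overlap matrix from expression.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and k the connectivity (row sum minus the diagonal);
    TOM blends direct adjacency with shared-neighbor support and equals 1
    for identical genes.
    """
    expr = _drop_constant(expr)
    x = expr.to_numpy(dtype=float)
    cor = _correlation(x, method)
    if not np.isfinite(cor).all():
        raise ValueError("non-finite correlations in expression data")
    a = _adjacency(cor, beta, mode)
    return CoexprNetwork(
        expr=expr, beta=int(beta), mode=mode, adjacency=a, tom=tom_from_adjacency(a)
    )


def module_eigengenes(
    expr: pd.DataFrame, assignment: pd.Series
) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Rows are modules, columns samples; each eigengene has unit norm and is
    oriented so its mean correlation with the module's genes is >= 0.
    """
    eigs = {}
    for label in assignment.unique():
        if label == UNASSIGNED:
            continue
        genes = assignment.index[assignment == label]
        x = expr.loc[genes].to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x /= sd
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        me = vt[0]
        cors = _row_cor(x, me)
        if np.nanmean(cors) < 0:
            me = -me
        eigs[label] = me
    return pd.DataFrame(eigs, index=expr.columns).T


def _row_cor(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with vector v."""
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    denom[denom == 0] = np.nan
    return (xc @ vc) / denom


def detect_modules(
    network: CoexprNetwork,
    min_size: int = 30,
    core_quantile: float = 0.5,
    kme_alpha: float = 0.05,
    merge_cut_height: float = 0.25,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cut the 1-TOM average-linkage dendrogram into modules.

    The cut adapts to the tree instead of using a fixed height. Module
    *cores* are the dendrogram's birth nodes: branches that first reach
    ``min_size`` genes (both children smaller), found below the
    ``core_quantile`` quantile of all merge heights (default the median) —
    coherent modules coalesce before the bulk of the tree agglomerates,
    while unstructured genes only clump in the top of the tree and so
    never seed a core.
    Remaining genes then join the core whose eigengene they correlate with
    most strongly, when that correlation is significant under BH control at
    ``kme_alpha`` (so admission adapts to sample count and background
    size); fragments of
    one underlying module are reunited by merging modules whose eigengenes
    correlate above ``1 - merge_cut_height``; modules below ``min_size``
    after merging are dissolved into ``unassigned``.

    Modules are labeled by the conventional color sequence in order of
    decreasing size. Returns (gene -> label assignment, eigengene matrix).
    """
    n = network.tom.shape[0]
    if n < min_size:
        raise ValueError(f"need at least min_size={min_size} genes, got {n}")
    dissim = 1.0 - network.tom
    condensed = squareform(dissim, checks=False)
    if np.allclose(condensed, condensed[0]):
        raise ValueError("degenerate dissimilarity: all gene pairs equidistant")
    Z = linkage(condensed, method="average")
    heights = Z[:, 2]
    ceiling = float(np.quantile(heights, core_quantile))

    sizes = np.concatenate([np.ones(n, dtype=int), Z[:, 3].astype(int)])
    labels = np.full(n, UNASSIGNED, dtype=object)

    def leaves_of(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b = Z[v - n, 0], Z[v - n, 1]
                stack.extend((int(a), int(b)))
        return out

    for k, (a, b, h, _) in enumerate(Z):
        node = n + k
        if h > ceiling or sizes[node] < min_size:
            continue
        if sizes[int(a)] < min_size and sizes[int(b)] < min_size:
            labels[leaves_of(node)] = f"b{node}"  # birth node: a new core
    assignment = pd.Series(labels, index=network.genes, name="module")

    if (assignment != UNASSIGNED).any():
        assignment = _assign_by_kme(network.expr, assignment, kme_alpha)
        assignment = _merge_close_modules(network.expr, assignment, merge_cut_height)

    sizes = assignment.value_counts()
    for label, sz in sizes.items():
        if label != UNASSIGNED and sz < min_size:
            assignment[assignment == label] = UNASSIGNED

    # relabel by decreasing size with the conventional colors
    ordered = [
        l for l in assignment.value_counts().index if l != UNASSIGNED
    ]
    rename = {
        l: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, l in enumerate(ordered)
    }
    assignment = assignment.map(lambda l: rename.get(l, UNASSIGNED))
    eig = module_eigengenes(network.expr, assignment)
    return assignment, eig


def _assign_by_kme(
    expr: pd.DataFrame, assignment: pd.Series, kme_alpha: float
) -> pd.Series:
    """Pull unassigned genes into the core module they correlate with most.

    Admission is significance-based so it adapts to both the sample count
    and the background size: each free gene's best |kME| (correlation with
    a core eigengene) is converted to its t-test p-value, Bonferroni-scaled
    by the number of candidate modules, and the gene joins only if it
    survives BH control at ``kme_alpha`` across all free genes.
    """
    eig = module_eigengenes(expr, assignment)
    free = assignment == UNASSIGNED
    if not free.any() or eig.empty:
        return assignment
    x = expr.loc[free].to_numpy(dtype=float)
    kme = np.column_stack(
        [_row_cor(x, eig.loc[label].to_numpy()) for label in eig.index]
    )
    kme = np.abs(np.nan_to_num(kme))
    best = kme.argmax(axis=1)
    r = np.clip(kme.max(axis=1), 0.0, 1.0 - 1e-12)
    dof = expr.shape[1] - 2
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = np.minimum(2.0 * stats.t.sf(t, dof) * len(eig.index), 1.0)
    accept = multipletests(p, alpha=kme_alpha, method="fdr_bh")[0]
    assignment = assignment.copy()
    joined = np.asarray(eig.index)[best]
    assignment.loc[assignment.index[free][accept]] = joined[accept]
    return assignment


def _merge_close_modules(
    expr: pd.DataFrame, assignment: pd.Series, merge_cut_height: float
) -> pd.Series:
    """Iteratively merge the closest module pair while ME dissimilarity
    (1 - signed correlation) is below the merge height."""
    assignment = assignment.copy()
    while True:
        labels = [l for l in assignment.unique() if l != UNASSIGNED]
        if len(labels) < 2:
            return assignment
        eig = module_eigengenes(expr, assignment)
        cor = np.corrcoef(eig.loc[labels].to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            return assignment
        assignment[assignment == labels[j]] = labels[i]


def _encode(col: pd.Series) -> np.ndarray:
    """Binary/ordinal 0,1,... encoding of a categorical covariate, by first
    appearance; numeric columns pass through."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    codes = pd.Categorical(col.astype(str), categories=pd.unique(col.astype(str)))
    return codes.codes.astype(float)


def module_trait_stats(
    eig: pd.DataFrame, design: pd.DataFrame, covariates: tuple[str, ...] = ("trait", "batch", "sex")
) -> pd.DataFrame:
    """Pearson correlation (and its exact t-based p, n-2 df) of each module
    eigengene with each covariate, covariates encoded 0/1 by first level."""
    design = design.set_index("sample") if "sample" in design.columns else design
    design = design.loc[list(eig.columns)]
    rows = []
    for cov in covariates:
        if cov not in design.columns:
            continue
        y = _encode(design[cov])
        if np.std(y) == 0:
            raise ValueError(f"covariate {cov!r} has zero variance")
        for module in eig.index:
            r, p = stats.pearsonr(eig.loc[module].to_numpy(), y)
            rows.append({"module": module, "covariate": cov, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def gene_module_stats(
    expr: pd.DataFrame,
    eig: pd.DataFrame,
    assignment: pd.Series,
    design: pd.DataFrame,
    signed_gs: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module membership (MM), gene significance (GS) and the GS~MM statistic.

    MM is each gene's correlation with its own module eigengene; GS is its
    correlation with the 0/1-encoded trait (absolute value when
    ``signed_gs`` is False). The second frame carries the per-module
    Pearson correlation between |GS| and |MM| with its p-value — the usual
    summary of whether trait-associated genes are central to their module.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    design = design.loc[list(expr.columns)]
    y = _encode(design["trait"])
    x = expr.to_numpy(dtype=float)
    gs = _row_cor(x, y)
    if not signed_gs:
        gs = np.abs(gs)
    mm = np.full(len(expr), np.nan)
    for label in eig.index:
        members = assignment.to_numpy() == label
        mm[members] = _row_cor(x[members], eig.loc[label].to_numpy())
    per_gene = pd.DataFrame(
        {"module": assignment.to_numpy(), "MM": mm, "GS": gs}, index=expr.index
    )
    rows = []
    for label in eig.index:
        sub = per_gene[per_gene["module"] == label].dropna()
        if len(sub) < 3:
            continue
        r, p = stats.pearsonr(np.abs(sub["GS"]), np.abs(sub["MM"]))
        rows.append({"module": label, "gs_mm_r": float(r), "gs_mm_p": float(p), "n_genes": len(sub)})
    return per_gene, pd.DataFrame(rows)


def permute_module_validation(
    expr: pd.DataFrame,
    assignment: pd.Series,
    design: pd.DataFrame,
    n_perm: int = 40,
    seed: int = 0,
) -> PermutationSummary:
    """Permutation null for module-trait correlations.

    Gene-module memberships are reshuffled ``n_perm`` times (module sizes
    preserved), eigengenes and module-trait correlations recomputed each
    time. A module passes the envelope criterion when its observed |r|
    exceeds every permuted |r| and its observed p undercuts every permuted
    p for that module — no permuted module is as correlated or as
    significant as the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    eig = module_eigengenes(expr, assignment)
    obs = (
        module_trait_stats(eig, design, covariates=("trait",))
        .set_index("module")[["r", "p"]]
    )
    perm_rows = []
    labels = assignment.to_numpy()
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(labels), index=assignment.index)
        eig_b = module_eigengenes(expr, perm)
        stats_b = module_trait_stats(eig_b, design, covariates=("trait",))
        for _, row in stats_b.iterrows():
            perm_rows.append(
                {"perm": b, "module": row["module"], "r": row["r"], "p": row["p"]}
            )
    permuted = pd.DataFrame(perm_rows)
    exceeds = {}
    for module in obs.index:
        cloud = permuted[permuted["module"] == module]
        exceeds[module] = bool(
            (np.abs(obs.loc[module, "r"]) > np.abs(cloud["r"]).max())
            and (obs.loc[module, "p"] < cloud["p"].min())
        )
    return PermutationSummary(
        observed=obs,
        permuted=permuted,
        exceeds_all=pd.Series(exceeds, name="exceeds_all"),
        n_perm=n_perm,
    )


def select_drivers(
    per_gene: pd.DataFrame, percentile: float = 95.0
) -> dict[str, list[str]]:
    """Putative driver genes: MM at or above the module's percentile cutoff.

    Ties at the cutoff are all included. Warns for modules below 20 genes,
    where a 95th percentile rests on very few observations.
    """
    drivers: dict[str, list[str]] = {}
    for label, sub in per_gene.groupby("module"):
        if label == UNASSIGNED:
            continue
        sub = sub.dropna(subset=["MM"])
        if sub.empty:
            raise ValueError(f"module {label!r} has no scored genes")
        if len(sub) < 20:
            warnings.warn(
                f"module {label!r} has {len(sub)} genes; percentile cutoff is coarse",
                stacklevel=2,
            )
        cutoff = np.percentile(sub["MM"], percentile)
        drivers[label] = list(sub.index[sub["MM"] >= cutoff])
    return drivers


def driver_deletion_shift(
    network: CoexprNetwork,
    assignment: pd.Series,
    drivers: list[str],
    module: str,
    weights: str = "tom",
) -> DeletionShift:
    """KS test for the weight shift caused by deleting a module's drivers.

    The intact distribution is the module's intra-module edge weights
    (upper triangle of the TOM restricted to module genes). The deleted
    distribution is the same set of edges after the driver rows/columns are
    removed from the network and, for TOM weights, the topological overlap
    is recomputed on the reduced adjacency — deleting high-connectivity
    drivers removes their shared-neighbor support, so every remaining
    weight can drop, not only the edges incident to drivers. A leftward
    shift (deleted median below intact median) means the drivers carried
    the module's cohesion. With ``weights="adjacency"`` the pairwise
    weights are unchanged by deletion and only the driver-incident edges
    leave the comparison.
    """
    if weights not in ("tom", "adjacency"):
        raise ValueError(f"weights must be 'tom' or 'adjacency', got {weights!r}")
    members = [g for g in network.genes if assignment.get(g) == module]
    if not members:
        raise ValueError(f"module {module!r} is empty")
    drivers_in = [g for g in drivers if g in set(members)]
    remaining = [g for g in members if g not in set(drivers_in)]
    if len(remaining) < 2:
        raise ValueError("module needs at least 2 non-driver genes")
    pos = {g: i for i, g in enumerate(network.genes)}
    w = network.tom if weights == "tom" else network.adjacency

    def upper(mat: np.ndarray, genes: list[str], index: dict[str, int]) -> np.ndarray:
        idx = np.array([index[g] for g in genes])
        sub = mat[np.ix_(idx, idx)]
        return sub[np.triu_indices(len(idx), k=1)]

    intact = upper(w, members, pos)
    if not drivers_in:
        med = float(np.median(intact))
        return DeletionShift(0.0, 1.0, "none", med, med, note="no drivers supplied")
    if weights == "tom":
        keep = [g for g in network.genes if g not in set(drivers_in)]
        idx = np.array([pos[g] for g in keep])
        tom = tom_from_adjacency(network.adjacency[np.ix_(idx, idx)])
        deleted = upper(tom, remaining, {g: i for i, g in enumerate(keep)})
    else:
        deleted = upper(w, remaining, pos)
    res = stats.ks_2samp(deleted, intact)
    med_i, med_d = float(np.median(intact)), float(np.median(deleted))
    direction = "left" if med_d < med_i else ("right" if med_d > med_i else "none")
    return DeletionShift(float(res.statistic), float(res.pvalue), direction, med_i, med_d)
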