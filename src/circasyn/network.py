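"""Weighted co-expression networks, module differential connectivity, hubs.

A soft-thresholded adjacency ``a_ij = |cor(x_i, x_j)|**beta`` is built per
group.  Modules come from average-linkage clustering of the topological
overlap dissimilarity with a height cut, a minimum size, a module-quality
filter, and eigenprotein-based merging.  Module differential connectivity
(MDC) is the ratio of mean within-module adjacency in OUD over unaffected
subjects, with significance from two permutation nulls (sample labels and
module membership).  Hubs are proteins whose N-hop neighborhood in the
90th-quantile-thresholded module graph exceeds the module average (NHNN
rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .data import Dataset

logger = logging.getLogger(__name__)

_STREAM_MDC = 13

#: module label palette, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
)


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-thresholded adjacency with unit diagonal."""

    protein_ids: list
    values: np.ndarray
    beta: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.protein_ids)
        if self.values.shape != (n, n):
            raise ValueError("adjacency shape does not match protein ids")

    def submatrix(self, members) -> "AdjacencyMatrix":
        pos = {p: i for i, p in enumerate(self.protein_ids)}
        idx = [pos[m] for m in members]
        return AdjacencyMatrix(list(members), self.values[np.ix_(idx, idx)], self.beta)


def _correlation(values: np.ndarray) -> np.ndarray:
    Z = values - values.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=0)
    Z = Z / sd[:, None]
    n = values.shape[1]
    return np.clip(Z @ Z.T / n, -1.0, 1.0)


def build_adjacency(ds_or_values, beta: float = 6.0, method: str = "unsigned",
                    protein_ids=None) -> AdjacencyMatrix:
    """Pairwise-correlation adjacency ``|cor|**beta`` (or signed variant).

    Accepts a :class:`~circasyn.data.Dataset` or a proteins-by-samples
    array.  Constant protein rows have undefined correlation and are
    dropped with a log entry.
    """
    if isinstance(ds_or_values, Dataset):
        values = ds_or_values.expr.values
        protein_ids = ds_or_values.protein_ids
    else:
        values = np.asarray(ds_or_values, dtype=float)
        if protein_ids is None:
            protein_ids = [f"P{i}" for i in range(values.shape[0])]
    if values.shape[1] < 4:
        raise ValueError("adjacency requires at least 4 samples")
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d constant protein row(s) from adjacency", int((~keep).sum()))
        values = values[keep]
        protein_ids = [p for p, k in zip(protein_ids, keep) if k]
    r = _correlation(values)
    if method == "unsigned":
        a = np.abs(r) ** beta
    elif method == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(list(protein_ids), a, beta)


def pick_soft_power(values: np.ndarray, powers=range(1, 21), target_r2: float = 0.8,
                    n_bins: int = 10, default: float = 6.0) -> float:
    """Smallest power whose connectivity distribution fits a scale-free law.

    Fits log10 p(k) on log10 k over binned connectivities; returns the
    first power with fit R^2 >= ``target_r2``, else ``default``.
    """
    r = np.abs(_correlation(np.asarray(values, dtype=float)))
    np.fill_diagonal(r, 0.0)
    for beta in powers:
        k = (r ** beta).sum(axis=1)
        if np.allclose(k, 0):
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            continue
        x, y = np.log10(centers[ok]), np.log10(hist[ok])
        slope, intercept, rval, *_ = stats.linregress(x, y)
        if rval ** 2 >= target_r2 and slope < 0:
            return float(beta)
    return float(default)


def tom_similarity(adj: AdjacencyMatrix) -> np.ndarray:
    """Unsigned topological overlap matrix of a unit-diagonal adjacency."""
    A = adj.values
    n = A.shape[0]
    L = A @ A - 2.0 * A              # shared-neighbor sums, diagonal irrelevant
    k = A.sum(axis=0) - 1.0
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.where(kmin + 1.0 - A > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _eigenprotein(values: np.ndarray) -> np.ndarray:
    """First principal component of standardized member expression."""
    Z = values - values.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Z = Z / sd[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc = vt[0]
    # orient with the average profile for determinism
    if np.corrcoef(pc, Z.mean(axis=0))[0, 1] < 0:
        pc = -pc
    return pc


def detect_modules(adj: AdjacencyMatrix, min_size: int = 30, merge_cut: float = 0.25,
                   cut_height: float | None = None, expr: np.ndarray | None = None,
                   quality_factor: float = 1.5) -> pd.Series:
    """Assign proteins to co-expression modules (grey = unassigned).

    Average-linkage hierarchical clustering on 1 - TOM, cut at
    ``cut_height`` (default: 98% of the tallest merge), clusters below
    ``min_size`` -> grey.  A candidate module is kept only if its mean
    within-module TOM exceeds ``quality_factor`` times the global mean TOM,
    which discards spurious clusters on unstructured data.  Modules whose
    eigenproteins correlate above ``1 - merge_cut`` are merged
    (requires ``expr``; skipped otherwise).  Labels are color names ordered
    by decreasing module size.
    """
    n = len(adj.protein_ids)
    if n < min_size:
        logger.warning("fewer proteins (%d) than min_size (%d): all grey", n, min_size)
        return pd.Series(["grey"] * n, index=adj.protein_ids)
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = average(condensed)
    heights = linkage[:, 2]
    if cut_height is None:
        cut_height = 0.98 * float(heights.max())
    labels = fcluster(linkage, t=cut_height, criterion="distance")

    offdiag = ~np.eye(n, dtype=bool)
    background_tom = float(tom[offdiag].mean())
    assignment = np.array(["grey"] * n, dtype=object)
    kept = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_size:
            continue
        block = tom[np.ix_(idx, idx)]
        within = float(block[~np.eye(len(idx), dtype=bool)].mean())
        if within <= quality_factor * background_tom:
            continue
        kept.append(idx)

    # merge modules with highly correlated eigenproteins
    if expr is not None and len(kept) > 1:
        merged = True
        while merged and len(kept) > 1:
            merged = False
            eigs = [_eigenprotein(expr[idx]) for idx in kept]
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    if np.corrcoef(eigs[i], eigs[j])[0, 1] > 1.0 - merge_cut:
                        kept[i] = np.sort(np.concatenate([kept[i], kept[j]]))
                        del kept[j]
                        merged = True
                        break
                if merged:
                    break

    kept.sort(key=lambda idx: (-len(idx), idx[0]))
    for color, idx in zip(MODULE_COLORS, kept):
        assignment[idx] = color
    if len(kept) > len(MODULE_COLORS):
        for extra, idx in enumerate(kept[len(MODULE_COLORS):]):
            assignment[idx] = f"module{len(MODULE_COLORS) + extra + 1}"
    return pd.Series(assignment, index=adj.protein_ids, name="module")


# ---------------------------------------------------------------------------
# module differential connectivity
# ---------------------------------------------------------------------------

def _standardize_cols(X: np.ndarray) -> np.ndarray:
    Z = X - X.mean(axis=-2, keepdims=True)
    sd = Z.std(axis=-2, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return Z / sd


def _mean_adjacency(X: np.ndarray, beta: float, statistic: str = "mean") -> float:
    """Connectivity of one sample-by-member block: mean off-diagonal |cor|^beta."""
    Z = _standardize_cols(X)
    n, m = X.shape
    C = np.clip(Z.T @ Z / n, -1.0, 1.0)
    A = np.abs(C) ** beta
    off = A[~np.eye(m, dtype=bool)]
    return float(off.sum() if statistic == "sum" else off.mean())


def _batched_connectivity(blocks: np.ndarray, beta: float) -> np.ndarray:
    """Mean off-diagonal adjacency for a (P, n, m) batch of sample blocks."""
    Z = _standardize_cols(blocks)
    n = blocks.shape[1]
    m = blocks.shape[2]
    C = np.clip(np.swapaxes(Z, 1, 2) @ Z / n, -1.0, 1.0)
    A = np.abs(C) ** beta
    mask = ~np.eye(m, dtype=bool)
    return A[:, mask].mean(axis=1)


def _two_sided_perm_p(null: np.ndarray, observed: float, n_perm: int) -> float:
    p_low = (1 + np.sum(null <= observed)) / (n_perm + 1)
    p_high = (1 + np.sum(null >= observed)) / (n_perm + 1)
    return min(1.0, 2.0 * min(p_low, p_high))


@dataclass
class MDCResult:
    mdc: float
    p_mdc: float
    direction: str
    connectivity_unaffected: float
    connectivity_oud: float
    p_sample_perm: float
    p_member_perm: float


def mdc_test(ds_u: Dataset, ds_o: Dataset, members, beta: float = 6.0,
             n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
             statistic: str = "mean", module_index: int = 0) -> MDCResult:
    """Module differential connectivity with two permutation nulls.

    Connectivity per group is the size-normalized mean off-diagonal
    adjacency among ``members``; MDC = connectivity(OUD) / connectivity
    (unaffected).  Null 1 permutes sample-group labels; null 2 replaces the
    membership by random equal-size protein sets.  Each scheme yields a
    two-sided permutation p (add-one estimator) for MDC differing from 1;
    the reported p is the more conservative (max) of the two, and the
    gain/loss direction comes from the sign of ``MDC - 1`` when
    significant.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError("module must have at least 3 members")
    prot_u, prot_o = set(ds_u.protein_ids), set(ds_o.protein_ids)
    missing = [m for m in members if m not in prot_u or m not in prot_o]
    if missing:
        raise ValueError(f"member(s) absent from a dataset: {missing[:5]}")
    shared = [p for p in ds_u.protein_ids if p in prot_o]
    Xu_full = ds_u.expr.select_proteins(shared).values.T   # samples x proteins
    Xo_full = ds_o.expr.select_proteins(shared).values.T
    pos = {p: i for i, p in enumerate(shared)}
    midx = np.array([pos[m] for m in members])
    Xu = Xu_full[:, midx]
    Xo = Xo_full[:, midx]
    conn_u = _mean_adjacency(Xu, beta, statistic)
    conn_o = _mean_adjacency(Xo, beta, statistic)
    if conn_u == 0:
        raise ValueError("zero connectivity in the reference (unaffected) group")
    mdc = conn_o / conn_u

    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_MDC, module_index))
    )
    n_u, n_o = Xu.shape[0], Xo.shape[0]
    combined = np.vstack([Xu, Xo])

    # null 1: permute sample-group labels
    perm = rng.permuted(np.tile(np.arange(n_u + n_o), (n_perm, 1)), axis=1)
    blocks = combined[perm]                                  # (P, n, m)
    cu = _batched_connectivity(blocks[:, :n_u, :], beta)
    co = _batched_connectivity(blocks[:, n_u:, :], beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        null1 = np.where(cu > 0, co / cu, np.inf)

    # null 2: random member sets of equal size
    m = len(members)
    rand_members = np.argsort(rng.random((n_perm, len(shared))), axis=1)[:, :m]
    gu = np.swapaxes(Xu_full.T[rand_members], 1, 2)          # (P, n_u, m)
    go = np.swapaxes(Xo_full.T[rand_members], 1, 2)
    cu2 = _batched_connectivity(gu, beta)
    co2 = _batched_connectivity(go, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        null2 = np.where(cu2 > 0, co2 / cu2, np.inf)

    if mdc != 1.0:
        # two-sided permutation p: is MDC significantly different from 1?
        # (the direction label then comes from the sign; a sign-selected
        # one-sided tail would double the direction-call rate under the null)
        p1 = _two_sided_perm_p(null1, mdc, n_perm)
        p2 = _two_sided_perm_p(null2, mdc, n_perm)
        candidate = "loss" if mdc < 1.0 else "gain"
    else:
        p1 = p2 = 1.0
        candidate = "unchanged"
    p_mdc = max(p1, p2)
    direction = candidate if (p_mdc < alpha and candidate != "unchanged") else "unchanged"
    return MDCResult(
        mdc=float(mdc), p_mdc=float(p_mdc), direction=direction,
        connectivity_unaffected=conn_u, connectivity_oud=conn_o,
        p_sample_perm=float(p1), p_member_perm=float(p2),
    )


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def identify_hubs(adj: AdjacencyMatrix, members, quantile: float = 0.90,
                  n_hops: int = 1):
    """NHNN hub identification within one module.

    An edge i-j exists iff ``a_ij`` strictly exceeds the ``quantile`` of
    off-diagonal within-module adjacency.  NHNN_i counts distinct nodes
    within ``n_hops`` of i; hubs are nodes with NHNN above the module mean.

    Returns ``(hub set, nhnn Series)``.
    """
    members = list(members)
    if len(members) < 3:
        logger.warning("module of size %d: no hubs defined", len(members))
        return set(), pd.Series(dtype=float)
    sub = adj.submatrix(members)
    A = sub.values
    m = len(members)
    off = A[~np.eye(m, dtype=bool)]
    thr = float(np.quantile(off, quantile))
    edges = (A > thr) & ~np.eye(m, dtype=bool)
    g = nx.from_numpy_array(edges.astype(int))
    nhnn = np.array([
        len(nx.single_source_shortest_path_length(g, i, cutoff=n_hops)) - 1
        for i in range(m)
    ], dtype=float)
    mean_nhnn = nhnn.mean()
    hubs = {members[i] for i in range(m) if nhnn[i] > mean_nhnn}
    return hubs, pd.Series(nhnn, index=members, name="nhnn")


def disease_specific_hubs(hubs_u, hubs_o) -> tuple:
    """(unaffected-only, OUD-only, shared) hub sets."""
    hubs_u, hubs_o = set(hubs_u), set(hubs_o)
    return hubs_u - hubs_o, hubs_o - hubs_u, hubs_u & hubs_o


def module_flag_enrichment(members, flagged, background) -> tuple:
    """Hypergeometric enrichment of a flagged set (DE/rhythmic) in a module.

    Returns ``(p_hyper, fold)`` where fold is observed/expected overlap.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    members = set(members) & background
    flagged = set(flagged) & background
    N, K, n = len(background), len(flagged), len(members)
    k = len(members & flagged)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    fold = k / expected if expected > 0 else np.nan
    return p, fold


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ModuleResult:
    """One module's connectivity comparison and hub calls."""

    label: str
    members: list
    connectivity_unaffected: float
    connectivity_oud: float
    mdc: float
    p_mdc: float
    direction: str
    hubs_unaffected: set
    hubs_oud: set
    nhnn_unaffected: pd.Series
    nhnn_oud: pd.Series


class ModuleConnectivityModel:
    """Build modules on the reference group and test differential connectivity.

    Modules are constructed on unaffected subjects by default (set
    ``reference='OUD'`` to build symmetrically on the other group); MDC is
    the OUD/unaffected connectivity ratio for either choice.
    """

    def __init__(self, dataset: Dataset, beta: float | None = None,
                 min_size: int = 30, merge_cut: float = 0.25,
                 reference: str = "unaffected"):
        self.dataset = dataset
        self.reference = reference
        self.ds_u = dataset.select_group("unaffected")
        self.ds_o = dataset.select_group("OUD")
        ref = self.ds_u if reference == "unaffected" else self.ds_o
        if beta is None:
            beta = pick_soft_power(ref.expr.values)
            logger.info("selected soft power beta=%g", beta)
        self.beta = float(beta)
        self.min_size = min_size
        self.merge_cut = merge_cut
        self._ref = ref

    def fit(self, n_perm: int = 1000, seed: int = 0,
            hub_quantile: float = 0.90, n_hops: int = 1) -> "ModuleConnectivityResults":
        adj_ref = build_adjacency(self._ref, beta=self.beta)
        assignment = detect_modules(
            adj_ref, min_size=self.min_size, merge_cut=self.merge_cut,
            expr=self._ref.expr.select_proteins(adj_ref.protein_ids).values,
        )
        adj_u = build_adjacency(self.ds_u, beta=self.beta)
        adj_o = build_adjacency(self.ds_o, beta=self.beta)
        modules = []
        labels = [m for m in assignment.unique() if m != "grey"]
        for mi, label in enumerate(sorted(labels)):
            members = list(assignment.index[assignment == label])
            res = mdc_test(self.ds_u, self.ds_o, members, beta=self.beta,
                           n_perm=n_perm, seed=seed, module_index=mi)
            hubs_u, nhnn_u = identify_hubs(adj_u, members, hub_quantile, n_hops)
            hubs_o, nhnn_o = identify_hubs(adj_o, members, hub_quantile, n_hops)
            modules.append(ModuleResult(
                label=label, members=members,
                connectivity_unaffected=res.connectivity_unaffected,
                connectivity_oud=res.connectivity_oud, mdc=res.mdc,
                p_mdc=res.p_mdc, direction=res.direction,
                hubs_unaffected=hubs_u, hubs_oud=hubs_o,
                nhnn_unaffected=nhnn_u, nhnn_oud=nhnn_o,
            ))
        return ModuleConnectivityResults(assignment=assignment, modules=modules,
                                         beta=self.beta)


@dataclass
class ModuleConnectivityResults:
    assignment: pd.Series
    modules: list
    beta: float

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            rows.append(dict(
                label=m.label, size=len(m.members),
                connectivity_unaffected=m.connectivity_unaffected,
                connectivity_oud=m.connectivity_oud,
                mdc=m.mdc, p_mdc=m.p_mdc, direction=m.direction,
                n_hubs_unaffected=len(m.hubs_unaffected),
                n_hubs_oud=len(m.hubs_oud),
            ))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.summary_table()
        n_loss = int((t["direction"] == "loss").sum()) if len(t) else 0
        n_gain = int((t["direction"] == "gain").sum()) if len(t) else 0
        lines = [
            f"Co-expression modules (beta={self.beta:g}): {len(self.modules)} modules",
            f"  connectivity loss / gain / unchanged: "
            f"{n_loss} / {n_gain} / {len(self.modules) - n_loss - n_gain}",
        ]
        return "\n".join(lines)
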