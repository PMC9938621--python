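"""Weighted co-expression modules, eigengenes and hub genes.

A soft-thresholded correlation network is built over the stage-associated
genes (unsigned adjacency |cor|^beta by default), converted to the
topological overlap matrix (TOM), and clustered by average-linkage
hierarchical clustering of the TOM dissimilarity with a static cut.  Each
module is summarised by its eigengene (first principal component of the
standardized member expression), correlated with the ordinal receptivity
axis PR=1 < RE=2 < PO=3, and assigned a hub gene: the member with maximal
intramodular connectivity kWithin (summed adjacency to co-members).

Module labels follow the size-ranked colour naming convention of weighted
co-expression analysis (turquoise, blue, ...); genes in clusters below the
minimum size are labelled grey and excluded from hub/panel use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exprio import ExpressionDataset, STAGES

GREY = "grey"
_COLOR_ORDER = ("turquoise", "blue", "brown", "yellow", "green", "red", "black",
                "pink", "magenta", "purple", "greenyellow", "tan", "salmon",
                "cyan", "midnightblue", "lightcyan")
STAGE_CODE = {"PR": 1.0, "RE": 2.0, "PO": 3.0}


class NetworkError(ValueError):
    """Invalid input to a network-construction step."""


@dataclass
class NetworkParams:
    """Soft power, sign convention and tree-cut settings."""

    soft_power: float = 6.0
    sign: str = "unsigned"
    cut_height: float = 0.25
    min_module_size: int = 30

    def validate(self) -> None:
        if self.soft_power < 1:
            raise NetworkError("soft_power must be >= 1")
        if self.sign not in ("unsigned", "signed"):
            raise NetworkError("sign must be 'unsigned' or 'signed'")
        if not (0 < self.cut_height < 1):
            raise NetworkError("cut_height must lie in (0, 1)")
        if self.min_module_size < 3:
            raise NetworkError("min_module_size must be >= 3")


@dataclass
class ModuleAssignment:
    """Gene->module labels plus module summaries."""

    labels: pd.Series  # gene -> module colour ("grey" = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    stage_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)  # module: r, p
    k_within: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    hub_genes: dict[str, str] = field(default_factory=dict)

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]


def build_adjacency(dataset: ExpressionDataset, params: NetworkParams) -> pd.DataFrame:
    """Soft-thresholded adjacency over the dataset's genes.

    Unsigned: ``a_ij = |cor(g_i, g_j)|**beta``; signed:
    ``a_ij = ((1 + cor)/2)**beta``; unit diagonal.
    """
    params.validate()
    if dataset.n_samples < 3:
        raise NetworkError("need >= 3 samples to estimate correlations")
    Y = dataset.values.to_numpy(dtype=float)
    sd = Y.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        names = [dataset.gene_ids[i] for i in zero[:5]]
        raise NetworkError(f"zero-variance genes present: {names}")
    cor = np.corrcoef(Y)
    cor = np.clip(cor, -1.0, 1.0)
    if params.sign == "unsigned":
        adj = np.abs(cor) ** params.soft_power
    else:
        adj = ((1.0 + cor) / 2.0) ** params.soft_power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=dataset.values.index, columns=dataset.values.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap ``w_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)``.

    ``l_ij`` counts shared neighbours (sum over u != i,j of a_iu * a_uj) and
    ``k_i`` is the node connectivity excluding the diagonal.
    """
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-12):
        raise NetworkError("adjacency must be symmetric")
    if (A < 0).any() or (A > 1 + 1e-12).any():
        raise NetworkError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=0) - np.diag(A)
    # (A @ A)_ij includes u=i and u=j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij
    L = A @ A - 2.0 * A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, params: NetworkParams) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` become grey; surviving modules
    are named by decreasing size with the canonical colour sequence.
    Deterministic given its inputs.
    """
    params.validate()
    genes = list(tom.index)
    if len(genes) < params.min_module_size:
        return ModuleAssignment(pd.Series(GREY, index=tom.index, name="module"))
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    flat = fcluster(Z, t=params.cut_height, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    # stable size ranking: ties broken by smallest member gene id
    def rank_key(c):
        members = [genes[i] for i in np.flatnonzero(flat == c)]
        return (-len(members), min(members))
    keep.sort(key=rank_key)
    if len(keep) > len(_COLOR_ORDER):
        names = list(_COLOR_ORDER) + [f"module{i}" for i in range(len(_COLOR_ORDER), len(keep))]
    else:
        names = list(_COLOR_ORDER[:len(keep)])
    mapping = dict(zip(keep, names))
    labels = pd.Series([mapping.get(c, GREY) for c in flat], index=tom.index, name="module")
    return ModuleAssignment(labels)


def module_eigengene_and_correlation(dataset: ExpressionDataset,
                                     assignment: ModuleAssignment) -> ModuleAssignment:
    """Attach eigengenes and module-stage correlations to an assignment.

    The eigengene is the first right singular vector of the standardized
    (per-gene z-scored) module submatrix over samples, unit norm, oriented so
    its mean correlation with member profiles is positive.  Stage correlation
    is Pearson r of the eigengene against the ordinal code PR=1/RE=2/PO=3
    with the usual t-approximation p-value.
    """
    stages = dataset.stages()
    code = stages.map(STAGE_CODE)
    eig = {}
    rows = {}
    for module in assignment.modules + ([GREY] if GREY in set(assignment.labels) else []):
        genes = assignment.module_genes(module)
        sub = dataset.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if z.shape[0] == 1:
            v = z[0] / np.linalg.norm(z[0])
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            v = vt[0]
        member_cor = np.array([np.corrcoef(v, row)[0, 1] for row in z])
        if np.nanmean(member_cor) < 0:
            v = -v
        eig[module] = v
        if code.notna().all():
            r, p = stats.pearsonr(v, code.to_numpy(dtype=float))
        else:
            r, p = np.nan, np.nan
        rows[module] = {"r": r, "p": p, "size": len(genes)}
    assignment.eigengenes = pd.DataFrame(eig, index=dataset.values.columns)
    assignment.stage_correlation = pd.DataFrame(rows).T
    return assignment


def hub_genes(adjacency: pd.DataFrame, assignment: ModuleAssignment) -> ModuleAssignment:
    """Intramodular connectivity and per-module hubs.

    ``kWithin_i`` sums a gene's adjacency to co-members; the hub is the
    argmax per module with lexicographic tie-break.  The grey pseudo-module's
    hub is reported but excluded from panel use downstream.
    """
    labels = assignment.labels
    k_within = pd.Series(0.0, index=labels.index, name="k_within")
    hubs: dict[str, str] = {}
    for module in sorted(set(labels)):
        genes = list(labels.index[labels == module])
        if not genes:
            continue
        sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
        kw = sub.sum(axis=0) - np.diag(sub)
        k_within.loc[genes] = kw
        order = sorted(range(len(genes)), key=lambda i: (-kw[i], genes[i]))
        hubs[module] = genes[order[0]]
    assignment.k_within = k_within
    assignment.hub_genes = hubs
    return assignment


def analyze_network(dataset: ExpressionDataset, gene_set=None,
                    params: NetworkParams | None = None) -> ModuleAssignment:
    """Full network pass: adjacency -> TOM -> modules -> eigengenes -> hubs."""
    params = params or NetworkParams()
    sub = dataset.subset_genes(gene_set) if gene_set is not None else dataset
    sd = sub.values.std(axis=1)
    sub = sub.subset_genes(list(sd.index[sd > 0]))
    adj = build_adjacency(sub, params)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, params)
    assignment = module_eigengene_and_correlation(sub, assignment)
    assignment = hub_genes(adj, assignment)
    return assignment


def panel_hubs(assignment: ModuleAssignment) -> list[str]:
    """Hub genes eligible for the marker panel (grey module excluded)."""
    return [assignment.hub_genes[m] for m in sorted(assignment.hub_genes)
            if m != GREY]
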