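"""Weighted co-expression module analysis (WGCNA-style, signed hybrid).

From a normalized expression matrix (genes x samples) the pipeline builds a
signed-hybrid adjacency ``a_ij = max(cor(x_i, x_j), 0)^beta`` (Pearson,
negative correlations clipped to zero), converts it to the topological
overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

clusters genes by average-linkage hierarchical clustering on ``1 - TOM``
with a flat cut, discards clusters below a minimum size (50 genes for an
all-sample network, 100 when only reorganized animals are analysed), and
summarises each module by its eigengene (first principal component of the
standardized within-module expression, sign-oriented so genes correlate
positively with it on average).  Module membership (MM) is the Pearson
correlation of a gene with a module eigengene; genes with own-module
MM > 0.8 are hub genes.  Module-condition association uses a linear model
of the eigengene on social condition with group id as a fixed blocking
covariate.

The soft-threshold power defaults to 4; :func:`soft_threshold_scan`
implements the scale-free topology criterion for choosing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkConfig",
    "soft_threshold_scan",
    "pick_soft_threshold",
    "adjacency_signed_hybrid",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_membership",
    "me_association",
    "CoexpressionNetwork",
    "ModuleSet",
]

UNASSIGNED = "unassigned"


@dataclass
class NetworkConfig:
    """Parameters of the signed-hybrid co-expression network.

    ``min_kme`` is the minimum own-module eigengene correlation a gene must
    retain to stay in its module after clustering (the canonical membership
    refinement step); genes below it are returned to the unassigned pool.
    """

    power: int = 4
    min_module_size: int = 50
    cut_height: float = 0.99
    min_kme: float = 0.3
    hub_mm: float = 0.8

    def validate(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must lie in (0, 1]")


def _gene_corr(expr: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Pearson correlation between genes; constant genes dropped with warning."""
    X = expr.to_numpy(dtype=float)
    keep = X.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} constant genes before correlation")
        X = X[keep]
    corr = np.corrcoef(X)
    return corr, expr.index[keep]


def adjacency_signed_hybrid(expr: pd.DataFrame, beta: int = 4) -> pd.DataFrame:
    """Signed-hybrid adjacency: ``max(cor, 0)^beta`` with a zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    corr, index = _gene_corr(expr)
    A = np.clip(corr, 0.0, None) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=index, columns=index)


def soft_threshold_scan(expr: pd.DataFrame, powers=(1, 2, 3, 4, 5, 6, 8, 10),
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free fit R^2 and mean connectivity for candidate powers.

    For each power the connectivity ``k_i = sum_j a_ij`` is binned on a log
    scale and ``log10 p(k)`` is regressed on ``log10 k``; the reported R^2
    is signed by the slope (scale-free networks have a negative slope).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if not len(powers):
        raise ValueError("powers must be non-empty")
    corr, _ = _gene_corr(expr)
    pos = np.clip(corr, 0.0, None)
    rows = []
    for beta in powers:
        A = pos ** beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        k_pos = k[k > 0]
        if k_pos.size < n_bins:
            rows.append({"power": beta, "r2": np.nan, "mean_k": float(k.mean())})
            continue
        # equal-width bins on k, as in the scale-free topology criterion
        edges = np.linspace(k_pos.min(), k_pos.max(), n_bins + 1)
        which = np.clip(np.digitize(k_pos, edges[1:-1]), 0, n_bins - 1)
        log_k, log_p = [], []
        for b in range(n_bins):
            in_bin = which == b
            if in_bin.sum() == 0:
                continue
            log_k.append(np.log10(k_pos[in_bin].mean()))
            log_p.append(np.log10(in_bin.mean()))
        if len(log_k) < 3:
            rows.append({"power": beta, "r2": np.nan, "mean_k": float(k.mean())})
            continue
        fit = stats.linregress(log_k, log_p)
        r2 = 0.0 if np.isnan(fit.rvalue) else float(
            -np.sign(fit.slope) * fit.rvalue ** 2)
        rows.append({"power": beta, "r2": r2, "mean_k": float(k.mean())})
    return pd.DataFrame(rows)


def pick_soft_threshold(scan: pd.DataFrame, r2_min: float = 0.8,
                        fallback: int = 4) -> int:
    """Smallest power reaching the scale-free R^2 threshold, else fallback."""
    ok = scan[(scan["r2"].notna()) & (scan["r2"] >= r2_min)]
    if len(ok):
        return int(ok["power"].iloc[0])
    return int(fallback)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric [0, 1] adjacency."""
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return pd.DataFrame(T, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 50,
                   cut_height: float = 0.99) -> pd.Series:
    """Flat-cut average-linkage module labels from a TOM matrix.

    Genes are clustered on the dissimilarity ``1 - TOM``; the dendrogram is
    cut at ``cut_height`` and clusters smaller than ``min_module_size`` are
    relabeled ``unassigned``.  Surviving modules are named ``M1, M2, ...``
    in decreasing size order (deterministic given the input).
    """
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=tom.index, dtype=object, name="module")
    sizes = pd.Series(flat).value_counts()
    big = sizes[sizes >= min_module_size]
    if big.empty:
        warnings.warn("no cluster reached the minimum module size; all genes unassigned")
        return labels
    order = sorted(big.index, key=lambda c: (-big[c], c))
    for m, cluster_id in enumerate(order, start=1):
        labels.iloc[np.flatnonzero(flat == cluster_id)] = f"M{m}"
    return labels


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene of each module (samples x modules).

    Within-module expression is standardized gene-wise before the SVD; each
    eigengene has unit norm and is sign-oriented so the average gene-ME
    correlation is positive.
    """
    modules = sorted(m for m in labels.unique() if m != UNASSIGNED)
    me = {}
    for m in modules:
        genes = labels.index[labels == m]
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        X = expr.loc[genes].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise ValueError(f"module {m} contains a constant gene")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        v = vt[0]
        corr_sign = np.sign(np.mean(Z @ v))
        if corr_sign < 0:
            v = -v
        me[m] = v
    return pd.DataFrame(me, index=expr.columns)


def module_membership(expr: pd.DataFrame, me: pd.DataFrame,
                      labels: pd.Series | None = None,
                      hub_mm: float = 0.8):
    """Gene-ME Pearson correlations and (optionally) the hub-gene set.

    Returns ``(mm, hubs)``: ``mm`` is genes x modules; ``hubs`` is the set
    of genes whose *own-module* MM strictly exceeds ``hub_mm`` (empty when
    ``labels`` is not given).
    """
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    M = me.to_numpy(dtype=float)
    Mc = M - M.mean(axis=0, keepdims=True)
    mn = np.linalg.norm(Mc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Xc @ Mc) / np.outer(xn, mn)
    mm = pd.DataFrame(np.clip(corr, -1, 1), index=expr.index, columns=me.columns)
    hubs: set = set()
    if labels is not None:
        for g in mm.index:
            m = labels.get(g, UNASSIGNED)
            if m != UNASSIGNED and m in mm.columns and mm.at[g, m] > hub_mm:
                hubs.add(g)
    return mm, hubs


def refine_membership(expr: pd.DataFrame, labels: pd.Series,
                      min_kme: float = 0.3,
                      min_module_size: int = 2) -> pd.Series:
    """Return clustered genes with weak eigengene correlation to unassigned.

    After hierarchical clustering, a gene stays in its module only if its
    correlation with the module eigengene is at least ``min_kme``; modules
    falling below ``min_module_size`` afterwards are dissolved.  One round
    of refinement is applied (eigengenes are recomputed by the caller).
    """
    labels = labels.copy()
    assigned = labels[labels != UNASSIGNED]
    if assigned.empty:
        return labels
    me = module_eigengene(expr.loc[labels.index], labels)
    mm, _ = module_membership(expr.loc[labels.index], me)
    for g in assigned.index:
        if mm.at[g, labels[g]] < min_kme:
            labels[g] = UNASSIGNED
    sizes = labels.value_counts()
    for m in sizes.index:
        if m != UNASSIGNED and sizes[m] < min_module_size:
            labels[labels == m] = UNASSIGNED
    return labels


def me_association(me: pd.DataFrame, metadata: pd.DataFrame,
                   contrasts=None) -> pd.DataFrame:
    """Module eigengene vs social condition, blocking on group id.

    Fits, per module, an OLS of the eigengene on condition with group id as
    a fixed blocking covariate, and reports each requested pairwise
    condition contrast as ``(estimate, se, p)`` from the model's t tests.
    ``contrasts`` defaults to every ordered condition pair.  A design in
    which condition is confounded with group raises.
    """
    import statsmodels.api as sm

    meta = metadata.set_index("sample_id").loc[me.index]
    cond = pd.get_dummies(meta["condition"], dtype=float)
    conditions = list(cond.columns)
    use_groups = "group_id" in meta.columns and meta["group_id"].nunique() > 1
    if use_groups and len(conditions) > 1:
        per_group = meta.groupby("group_id")["condition"].nunique()
        if (per_group == 1).all():
            raise ValueError("condition is nested in group id; association "
                             "model is not identifiable")
    blocks = (pd.get_dummies(meta["group_id"], dtype=float).iloc[:, 1:]
              if use_groups else pd.DataFrame(index=me.index))
    # drop block columns that are linearly dependent on the condition means
    # (paired designs alias one block-sum per condition pair)
    X = cond.copy()
    rank = np.linalg.matrix_rank(X.to_numpy())
    for col in blocks.columns:
        cand = pd.concat([X, blocks[col]], axis=1)
        new_rank = np.linalg.matrix_rank(cand.to_numpy())
        if new_rank > rank:
            X, rank = cand, new_rank
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(conditions)
                     for b in conditions[i + 1:]]
    else:
        contrasts = [tuple(c.replace("_vs_", ":").split(":")) if isinstance(c, str)
                     else tuple(c) for c in contrasts]
    rows = []
    for module in me.columns:
        fit = sm.OLS(me[module].to_numpy(dtype=float), X.to_numpy()).fit()
        for a, b in contrasts:
            L = np.zeros(X.shape[1])
            L[conditions.index(a)] = 1.0
            L[conditions.index(b)] = -1.0
            tt = fit.t_test(L)
            rows.append({
                "module": module, "contrast": f"{a}:{b}",
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "p": float(np.squeeze(tt.pvalue)),
            })
    return pd.DataFrame(rows)


class CoexpressionNetwork:
    """Signed-hybrid co-expression network over normalized expression.

    Parameters
    ----------
    expr : genes x samples DataFrame of normalized (log-CPM) expression.
    config : :class:`NetworkConfig`; defaults follow the all-sample network
        (power 4, minimum module size 50, flat cut at 0.99).
    """

    def __init__(self, expr: pd.DataFrame, config: NetworkConfig | None = None):
        self.expr = expr
        self.config = config or NetworkConfig()
        self.config.validate()

    def scan_powers(self, powers=(1, 2, 3, 4, 5, 6, 8, 10)) -> pd.DataFrame:
        return soft_threshold_scan(self.expr, powers)

    def fit(self) -> "ModuleSet":
        cfg = self.config
        A = adjacency_signed_hybrid(self.expr, beta=cfg.power)
        tom = tom_similarity(A)
        labels = detect_modules(tom, min_module_size=cfg.min_module_size,
                                cut_height=cfg.cut_height)
        expr = self.expr.loc[labels.index]
        labels = refine_membership(expr, labels, min_kme=cfg.min_kme,
                                   min_module_size=cfg.min_module_size)
        assigned = labels[labels != UNASSIGNED]
        if assigned.empty:
            me = pd.DataFrame(index=expr.columns)
            mm = pd.DataFrame(index=expr.index)
            hubs: set = set()
        else:
            me = module_eigengene(expr, labels)
            mm, hubs = module_membership(expr, me, labels=labels, hub_mm=cfg.hub_mm)
        return ModuleSet(self, labels=labels, me=me, mm=mm, hubs=hubs)


class ModuleSet:
    """Detected modules: labels, eigengenes, memberships and hub genes."""

    def __init__(self, network, labels, me, mm, hubs):
        self.network = network
        self.labels = labels
        self.me = me
        self.mm = mm
        self.hubs = hubs

    @property
    def modules(self) -> list:
        return list(self.me.columns)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def association(self, metadata: pd.DataFrame, contrasts=None) -> pd.DataFrame:
        return me_association(self.me, metadata, contrasts=contrasts)

    def to_frame(self) -> pd.DataFrame:
        own_mm = [
            self.mm.at[g, m] if (m := self.labels[g]) != UNASSIGNED and m in self.mm.columns
            else np.nan
            for g in self.labels.index
        ]
        return pd.DataFrame({
            "gene_id": self.labels.index,
            "module": self.labels.to_numpy(),
            "mm": own_mm,
            "hub": [g in self.hubs for g in self.labels.index],
        })

    def plot_eigengenes(self, metadata=None, ax=None):
        """Heat-strip of module eigengene values per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.me.T.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(len(self.me.columns)), self.me.columns)
        ax.set_xticks(range(len(self.me.index)), self.me.index, rotation=90, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="eigengene")
        return ax

    def summary(self) -> str:
        sizes = self.sizes()
        lines = ["Co-expression modules", "=" * 30]
        lines.append(f"genes: {len(self.labels)}   modules: {len(self.modules)}   "
                     f"unassigned: {int(sizes.get(UNASSIGNED, 0))}")
        lines.append(f"hub genes (own-module MM > {self.network.config.hub_mm}): "
                     f"{len(self.hubs)}")
        lines.append("")
        lines.append(f"{'module':<10}{'genes':>7}{'hubs':>7}")
        for m in self.modules:
            n_hub = sum(1 for g in self.hubs if self.labels[g] == m)
            lines.append(f"{m:<10}{int(sizes[m]):>7}{n_hub:>7}")
        return "\n".join(lines)
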