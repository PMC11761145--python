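"""Differential expression with a permutation-based empirical FDR.

The pipeline mirrors the standard tag-seq workflow for small multi-group
designs:

1. **Low-count filtering** — genes with fewer than 10 summed counts across
   all samples are dropped.
2. **TMM normalization** — per-sample scale factors from the trimmed mean
   of M-values (doubly trimmed weighted mean of gene-wise log-ratios to an
   upper-quartile-matched reference sample), rescaled to geometric mean 1.
3. **log-CPM transform** — ``log2((count + prior) / (eff.lib + 2*prior) * 1e6)``
   with a prior count of 0.5.
4. **Per-gene contrasts** — a cell-means linear model across all social
   conditions; the contrast estimate is the difference of fitted condition
   means (the log2 fold change) and the t statistic uses the residual
   variance pooled across all conditions.  No precision weights are used:
   error control is delegated entirely to the permutation null below, which
   is valid under the implemented model.
5. **Empirical FDR** — condition labels are permuted across all samples
   (5000 times by default), the same model is refit, and the null p-values
   are pooled across genes and permutations:
   ``eFDR(p) = E_perm #{null p <= p} / #{observed p <= p}``, clipped to
   [0, 1] and made monotone non-decreasing in p.
6. **DEG calls** — a gene is called up/down when ``|log2FC| >= 0.2`` (a 15%
   expression change) at eFDR < 0.05, with counts reported in the
   |log2FC| bins >=0.20, 0.20-0.75, 0.75-1.50, >1.50.

:class:`DifferentialExpressionModel` wires the stages together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedMatrix",
    "filter_low_counts",
    "tmm_normalize",
    "log_cpm",
    "contrast_fit",
    "permutation_null_pvalues",
    "empirical_fdr",
    "call_degs",
    "deg_asymmetry_ratio",
    "DifferentialExpressionModel",
    "DGEResults",
]

#: |log2FC| bins used in the DEG inventory tables
LFC_BINS = [(0.20, 0.75), (0.75, 1.50), (1.50, np.inf)]
LFC_BIN_LABELS = ["0.20-0.75", "0.75-1.50", ">1.50"]


@dataclass
class NormalizedMatrix:
    """TMM scale factors, effective library sizes and log-CPM values."""

    factors: pd.Series
    lib_sizes: pd.Series
    logcpm: pd.DataFrame | None = None
    prior: float = 0.5


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose summed count over all samples is below ``min_total``."""
    kept = counts.loc[counts.sum(axis=1) >= min_total]
    if kept.empty:
        raise ValueError("low-count filter removed every gene")
    return kept


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    """Trimmed weighted mean of M-values of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size < 10:
        warnings.warn("degenerate sample in TMM: too few shared expressed genes; factor set to 1")
        return 1.0
    po, pr = obs / n_obs, ref / n_ref
    M = np.log2(po / pr)
    A = 0.5 * (np.log2(po) + np.log2(pr))
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("TMM trimming removed all genes; factor set to 1")
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_normalize(counts: pd.DataFrame, trim_m: float = 0.30,
                  trim_a: float = 0.05) -> NormalizedMatrix:
    """TMM scale factors with the upper-quartile reference rule.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the across-sample mean; each remaining sample's factor is the
    doubly trimmed (``trim_m`` on M, ``trim_a`` on A), inverse-variance
    weighted mean of its gene-wise log2 ratios to the reference.  Factors
    are rescaled so their geometric mean is 1.
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive library size")
    f75 = _quantile_factor(X, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = X[:, ref_idx]
    factors = np.ones(X.shape[1])
    for s in range(X.shape[1]):
        if s == ref_idx:
            continue
        factors[s] = _tmm_pair(X[:, s], ref, lib[s], lib[ref_idx], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizedMatrix(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=counts.columns, name="lib_size"),
    )


def log_cpm(counts: pd.DataFrame, factors: pd.Series | NormalizedMatrix,
            prior: float = 0.5) -> NormalizedMatrix:
    """log2 counts per million on TMM-effective library sizes.

    ``log2((count + prior) / (lib * factor + 2 * prior) * 1e6)``.
    """
    if isinstance(factors, NormalizedMatrix):
        norm = factors
    else:
        lib = counts.sum(axis=0).astype(float)
        norm = NormalizedMatrix(factors=factors, lib_sizes=lib)
    eff = norm.lib_sizes.to_numpy(dtype=float) * norm.factors.reindex(counts.columns).to_numpy()
    vals = np.log2((counts.to_numpy(dtype=float) + prior)
                   / (eff[None, :] + 2.0 * prior) * 1e6)
    norm.logcpm = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    norm.prior = prior
    return norm


def _parse_contrast(contrast: str) -> tuple[str, str]:
    parts = contrast.replace("_vs_", ":").split(":")
    if len(parts) != 2:
        raise ValueError(f"contrast must look like 'DES:DOM', got {contrast!r}")
    return parts[0], parts[1]


def _fit_core(Y: np.ndarray, cond_codes: np.ndarray, n_cond: int,
              idx_a: int, idx_b: int):
    """Cell-means fit: per-gene (lfc, t, p) for condition a minus b.

    ``Y`` is genes x samples; residual variance is pooled over all
    conditions, df = n_samples - n_conditions.
    """
    n_samples = Y.shape[1]
    df = n_samples - n_cond
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    group_n = np.bincount(cond_codes, minlength=n_cond).astype(float)
    ind = np.zeros((n_samples, n_cond))
    ind[np.arange(n_samples), cond_codes] = 1.0
    sums = Y @ ind
    means = sums / group_n[None, :]
    resid_ss = (Y ** 2).sum(axis=1) - (means ** 2 * group_n[None, :]).sum(axis=1)
    s2 = np.maximum(resid_ss, 0.0) / df
    lfc = means[:, idx_a] - means[:, idx_b]
    se = np.sqrt(s2 * (1.0 / group_n[idx_a] + 1.0 / group_n[idx_b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se > 0, p, 1.0)
    return lfc, t, p


def contrast_fit(logcpm: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: str) -> pd.DataFrame:
    """Per-gene log2FC, t and raw p for one condition contrast.

    A linear model with a mean per social condition is fit to every gene;
    the contrast estimate equals the difference of the two condition means
    of log-CPM and the t statistic uses the residual variance pooled across
    all conditions.
    """
    cond_a, cond_b = _parse_contrast(contrast)
    meta = metadata.set_index("sample_id").loc[logcpm.columns]
    cond_codes, cond_levels = pd.factorize(meta["condition"])
    levels = list(cond_levels)
    for c in (cond_a, cond_b):
        if c not in levels:
            raise ValueError(f"condition {c!r} absent from metadata")
        if (meta["condition"] == c).sum() < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    lfc, t, p = _fit_core(logcpm.to_numpy(dtype=float), cond_codes, len(levels),
                          levels.index(cond_a), levels.index(cond_b))
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p}, index=logcpm.index)


def permutation_null_pvalues(logcpm: pd.DataFrame, metadata: pd.DataFrame,
                             contrast: str, n_perm: int = 5000,
                             seed: int | None = None) -> np.ndarray:
    """Null p-values from label permutations, pooled across genes.

    Condition labels are shuffled across all samples within the full design
    and the same contrast model is refit; returns an ``(n_perm, n_genes)``
    array of null p-values.
    """
    cond_a, cond_b = _parse_contrast(contrast)
    meta = metadata.set_index("sample_id").loc[logcpm.columns]
    cond_codes, cond_levels = pd.factorize(meta["condition"])
    levels = list(cond_levels)
    idx_a, idx_b = levels.index(cond_a), levels.index(cond_b)
    Y = logcpm.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, Y.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(cond_codes)
        _, _, null[b] = _fit_core(Y, perm, len(levels), idx_a, idx_b)
    return null


def empirical_fdr(p_obs: np.ndarray, null_p: np.ndarray) -> np.ndarray:
    """Empirical FDR of each observed p against a pooled permutation null.

    ``eFDR(p) = [mean over permutations of #{null p <= p}] / #{obs p <= p}``,
    clipped to [0, 1] and monotonized (cumulative minimum from the largest
    observed p downward).  ``null_p`` is ``(n_perm, n_genes)`` or any array
    whose first dimension indexes permutations.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    n_perm = null_p.shape[0]
    null_sorted = np.sort(null_p.ravel())
    order = np.argsort(p_obs, kind="mergesort")
    obs_sorted = p_obs[order]
    obs_le = np.searchsorted(obs_sorted, obs_sorted, side="right")
    null_le = np.searchsorted(null_sorted, obs_sorted, side="right") / n_perm
    efdr_sorted = np.clip(null_le / obs_le, 0.0, 1.0)
    efdr_sorted = np.minimum.accumulate(efdr_sorted[::-1])[::-1]
    efdr = np.empty_like(efdr_sorted)
    efdr[order] = efdr_sorted
    return efdr


def call_degs(result: pd.DataFrame, lfc_min: float = 0.2,
              efdr_max: float = 0.05) -> dict:
    """Signed DEG calls and the |log2FC| threshold-bin inventory.

    A gene is called ``up``/``down`` when ``|log2fc| >= lfc_min`` and
    ``efdr < efdr_max``; everything else is ``none``.  The bin table counts
    calls in |log2FC| bins 0.20-0.75 (closed), 0.75-1.50 and >1.50, whose
    sum is the >=0.20 total.
    """
    lfc = result["log2fc"].to_numpy()
    efdr = result["efdr"].to_numpy()
    significant = (np.abs(lfc) >= lfc_min) & (efdr < efdr_max)
    call = np.where(significant & (lfc > 0), "up",
                    np.where(significant & (lfc < 0), "down", "none"))
    table = result.copy()
    table["call"] = call
    up = set(table.index[table["call"] == "up"])
    down = set(table.index[table["call"] == "down"])
    abs_lfc = np.abs(lfc)
    rows = {}
    rows[f">={lfc_min:.2f}"] = {
        "up": int(np.sum(significant & (lfc > 0))),
        "down": int(np.sum(significant & (lfc < 0))),
    }
    for (lo, hi), label in zip(LFC_BINS, LFC_BIN_LABELS):
        in_bin = significant & (abs_lfc >= lo if lo == LFC_BINS[0][0] else abs_lfc > lo) \
            & (abs_lfc <= hi)
        rows[label] = {
            "up": int(np.sum(in_bin & (lfc > 0))),
            "down": int(np.sum(in_bin & (lfc < 0))),
        }
    bins = pd.DataFrame(rows).T
    bins.index.name = "lfc_bin"
    return {"table": table, "up": up, "down": down, "bins": bins}


def deg_asymmetry_ratio(n_a: int, n_b: int) -> tuple[float, float]:
    """DEG-count asymmetry ratio and a two-sided exact binomial p at 0.5.

    Returns ``(ratio, p)`` where the ratio is ``n_a / n_b`` rounded to one
    decimal for reporting (infinite when ``n_b == 0``).
    """
    if n_a < 0 or n_b < 0 or (n_a == 0 and n_b == 0):
        raise ValueError("counts must be non-negative and not both zero")
    ratio = float("inf") if n_b == 0 else round(n_a / n_b, 1)
    p = float(stats.binomtest(n_a, n_a + n_b, 0.5).pvalue)
    return ratio, p


class DifferentialExpressionModel:
    """Permutation-eFDR differential expression over a count matrix.

    Parameters
    ----------
    counts : genes x samples DataFrame of raw integer counts.
    metadata : DataFrame with ``sample_id``, ``condition`` (and optionally
        ``group_id``) rows covering every count column.
    min_total : low-count filter threshold (summed count over all samples).
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame,
                 min_total: int = 10):
        self.metadata = metadata
        self.counts = filter_low_counts(counts, min_total=min_total)
        self.norm = log_cpm(self.counts, tmm_normalize(self.counts))

    @classmethod
    def from_files(cls, counts_tsv, metadata_csv, **kw) -> "DifferentialExpressionModel":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="gene_id")
        metadata = pd.read_csv(metadata_csv)
        return cls(counts, metadata, **kw)

    @property
    def logcpm(self) -> pd.DataFrame:
        return self.norm.logcpm

    def fit(self, contrast: str, n_perm: int = 5000, seed: int | None = None,
            lfc_min: float = 0.2, efdr_max: float = 0.05) -> "DGEResults":
        obs = contrast_fit(self.logcpm, self.metadata, contrast)
        null = permutation_null_pvalues(self.logcpm, self.metadata, contrast,
                                        n_perm=n_perm, seed=seed)
        obs["efdr"] = empirical_fdr(obs["p"].to_numpy(), null)
        calls = call_degs(obs, lfc_min=lfc_min, efdr_max=efdr_max)
        return DGEResults(self, contrast, calls, n_perm=n_perm, seed=seed,
                          lfc_min=lfc_min, efdr_max=efdr_max)


class DGEResults:
    """Per-gene contrast estimates, eFDR values and DEG calls."""

    def __init__(self, model, contrast, calls, n_perm, seed, lfc_min, efdr_max):
        self.model = model
        self.contrast = contrast
        self.table = calls["table"]
        self.up = calls["up"]
        self.down = calls["down"]
        self.bins = calls["bins"]
        self.n_perm = n_perm
        self.seed = seed
        self.lfc_min = lfc_min
        self.efdr_max = efdr_max

    @property
    def n_degs(self) -> int:
        return len(self.up) + len(self.down)

    def signed_gene_set(self):
        from .concordance import SignedGeneSet

        return SignedGeneSet(label=self.contrast, up=set(self.up), down=set(self.down))

    def to_frame(self) -> pd.DataFrame:
        out = self.table[["log2fc", "p", "efdr", "call"]].copy()
        out.index.name = "gene_id"
        return out

    def summary(self) -> str:
        lines = [f"Differential expression: {self.contrast}", "=" * 40]
        lines.append(f"genes tested: {len(self.table)}   "
                     f"label permutations: {self.n_perm}")
        lines.append(f"DEG thresholds: |log2FC| >= {self.lfc_min}, "
                     f"eFDR < {self.efdr_max}")
        lines.append(f"DEGs: {self.n_degs}  (up {len(self.up)}, down {len(self.down)})")
        lines.append("")
        lines.append(self.bins.to_string())
        return "\n".join(lines)
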