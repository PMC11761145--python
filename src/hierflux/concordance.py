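"""Cross-comparison gene-set statistics.

Given signed DEG sets from two (or four) condition contrasts, this module
answers three questions:

* Is the **overlap** between two DEG lists larger than chance?  The null
  draws two independent uniform subsets (of the two observed DEG counts)
  from the filtered gene universe and records their intersection size;
  the expected overlap is ``n1 * n2 / N`` (e.g. 2255 x 1357 / 15184 = 201.5).
* Is the **direction** of shared DEGs concordant?  The shared genes are
  cross-tabulated as a 2x2 up/down table and tested with the
  Yates-continuity-corrected chi-square; two phi coefficients are reported
  (``sqrt(chi2_corrected / n)`` and the classic ``(ad - bc)/sqrt(margins)``)
  because both conventions are in common use.
* Which genes transition **in all four** status-change contrasts
  (DES vs DOM, DES vs CDOM, ASC vs SUB, ASC vs CSUB) with a consistent
  sign?  Plus a binomial test of whether immediate-early genes (IEGs) skew
  toward one side of a contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignedGeneSet",
    "ConcordanceTable",
    "OverlapPermResult",
    "overlap_permutation",
    "concordance_table",
    "yates_chi_square",
    "strict_transition_genes",
    "ieg_direction_test",
]


@dataclass
class SignedGeneSet:
    """Up- and down-regulated gene sets for one comparison."""

    label: str
    up: set
    down: set

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes in both up and down sets: {sorted(overlap)[:5]}")

    @property
    def all(self) -> set:
        return self.up | self.down


@dataclass
class ConcordanceTable:
    """2x2 direction cross-tabulation of shared DEGs.

    ``a`` = up in both, ``d`` = down in both, ``b``/``c`` = discordant.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class OverlapPermResult:
    observed: int
    n_perm: int
    null_mean: float
    null_sd: float
    null_max: int
    expected: float  # analytic n1*n2/N
    p: float


def overlap_permutation(n1: int, n2: int, N: int, observed: int,
                        n_perm: int = 10000,
                        seed: int | None = None) -> OverlapPermResult:
    """Permutation test for the overlap of two DEG lists.

    Each replicate draws two *independent* uniform subsets without
    replacement of sizes ``n1`` and ``n2`` from ``{1..N}`` and records their
    intersection size; ``p = (1 + #{overlap >= observed}) / (n_perm + 1)``
    (upper tail).  The analytic expectation ``n1*n2/N`` is reported
    alongside as a cross-check.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("subset sizes must lie in [0, N]")
    if not (0 <= observed <= min(n1, n2)):
        raise ValueError("observed overlap must lie in [0, min(n1, n2)]")
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_perm, dtype=int)
    mask = np.zeros(N, dtype=bool)
    for b in range(n_perm):
        a_idx = rng.permutation(N)[:n1]
        b_idx = rng.permutation(N)[:n2]
        mask[a_idx] = True
        sizes[b] = int(mask[b_idx].sum())
        mask[a_idx] = False
    p = (1 + int(np.sum(sizes >= observed))) / (n_perm + 1)
    return OverlapPermResult(
        observed=int(observed), n_perm=int(n_perm),
        null_mean=float(sizes.mean()), null_sd=float(sizes.std(ddof=1)),
        null_max=int(sizes.max()), expected=n1 * n2 / N, p=float(p),
    )


def concordance_table(set_a: SignedGeneSet, set_b: SignedGeneSet):
    """Cross-tabulate shared DEG directions between two comparisons.

    Returns ``(table, shared)`` where ``shared`` maps each cell to its gene
    list (keys ``both_up``, ``both_down``, ``a_up_b_down``, ``a_down_b_up``).
    """
    shared = {
        "both_up": sorted(set_a.up & set_b.up),
        "a_up_b_down": sorted(set_a.up & set_b.down),
        "a_down_b_up": sorted(set_a.down & set_b.up),
        "both_down": sorted(set_a.down & set_b.down),
    }
    table = ConcordanceTable(
        a=len(shared["both_up"]), b=len(shared["a_up_b_down"]),
        c=len(shared["a_down_b_up"]), d=len(shared["both_down"]),
    )
    return table, shared


def yates_chi_square(table: ConcordanceTable) -> tuple[float, float, float, float]:
    """Continuity-corrected chi-square and phi coefficients of a 2x2 table.

    Returns ``(chi2, p, phi_corrected, phi_uncorrected)`` with
    ``chi2 = sum (|O - E| - 0.5)^2 / E`` over the four cells (expected
    values from the margins), ``p`` from the 1-df chi-square distribution,
    ``phi_corrected = sqrt(chi2 / n)`` and
    ``phi_uncorrected = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))``.
    """
    O = table.as_array()
    n = O.sum()
    if n < 1:
        raise ValueError("chi-square undefined for an empty table")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    E = np.outer(row, col) / n
    chi2 = float(np.sum(np.maximum(np.abs(O - E) - 0.5, 0.0) ** 2 / E))
    p = float(stats.chi2.sf(chi2, df=1))
    phi_corr = float(np.sqrt(chi2 / n))
    a, b, c, d = table.a, table.b, table.c, table.d
    phi_uncorr = float((a * d - b * c) / np.sqrt(row.prod() * col.prod()))
    return chi2, p, phi_corr, phi_uncorr


def strict_transition_genes(sets) -> dict:
    """Genes significant with consistent sign in all four transition contrasts.

    ``sets`` is an iterable of four :class:`SignedGeneSet` (typically
    DES:DOM, DES:CDOM, ASC:SUB, ASC:CSUB); the result is order-independent.
    Returns ``{"up": ..., "down": ..., "discordant": ...}`` where
    ``discordant`` genes are significant in all four with mixed signs.
    """
    sets = list(sets)
    if not sets:
        return {"up": set(), "down": set(), "discordant": set()}
    up = set.intersection(*(s.up for s in sets))
    down = set.intersection(*(s.down for s in sets))
    in_all = set.intersection(*(s.all for s in sets))
    return {"up": up, "down": down, "discordant": in_all - up - down}


def ieg_direction_test(result, ieg_genes) -> dict:
    """Do immediate-early genes skew toward one side of a contrast?

    ``result`` is a :class:`~hierflux.dge.DGEResults` (or any object with
    ``up``/``down`` gene sets and a ``table`` indexed by gene id);
    ``ieg_genes`` is the curated IEG list.  With ``k1`` IEGs called up and
    ``k2`` called down, the test is a two-sided exact binomial of ``k1``
    successes in ``k1 + k2`` trials at p0 = 0.5; proportions are reported
    against the IEG universe present in the filtered data.
    """
    universe = set(ieg_genes) & set(result.table.index)
    if not universe:
        raise ValueError("no IEGs present in the filtered gene universe")
    k1 = len(universe & set(result.up))
    k2 = len(universe & set(result.down))
    if k1 + k2 == 0:
        raise ValueError("no IEG is differentially expressed; test undefined")
    p = float(stats.binomtest(k1, k1 + k2, 0.5).pvalue)
    return {
        "n_ieg_universe": len(universe),
        "k_up": k1,
        "k_down": k2,
        "prop_up": k1 / len(universe),
        "prop_down": k2 / len(universe),
        "p": p,
    }
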