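"""Dominance-hierarchy statistics from agonistic interaction streams.

A social group's agonistic history is summarised as a *sociomatrix* ``W``
with ``W[i, j]`` the number of contests individual ``i`` won against ``j``.
From it this module computes:

* **David's Scores** (DS) — a cardinal dominance rating per individual.
  Each dyad's raw win proportion ``P_ij = s_ij / n_ij`` is shrunk toward
  chance by the dyad's sample size, ``D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1)``,
  and DS sums direct and opponent-weighted wins minus losses:
  ``DS_i = w_i + w2_i - l_i - l2_i`` with ``w_i = sum_j D_ij``,
  ``w2_i = sum_j D_ij * w_j``, ``l_i = sum_j D_ji``,
  ``l2_i = sum_j D_ji * l_j``.  The scores always sum to zero.
* **Directional consistency** (DC) — the excess of interactions flowing in
  each dyad's majority direction, ``sum(H - L) / sum(H + L)`` over contested
  dyads; 1 means perfectly one-directional aggression.
* A **randomization test** for DC that flips the direction of every single
  interaction independently with probability 1/2 (the exchangeable null for
  a group with no rank structure).
* Ordinal **ranks** from DS, rank-**emergence trajectories** (cumulative DS
  after each successive contest), and day-2 **stability binomial tests**.

The statsmodels-style entry point is :class:`HierarchyModel`; the free
functions underneath are the computational surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WinLossMatrix",
    "DominanceResult",
    "build_sociomatrix",
    "davids_score",
    "directional_consistency",
    "dc_randomization_test",
    "rank_from_ds",
    "emergence_trajectory",
    "stability_binomial",
    "HierarchyModel",
    "HierarchyResults",
]

EVENT_COLUMNS = ["timestamp", "group_id", "winner_id", "loser_id", "behavior"]


@dataclass
class WinLossMatrix:
    """Square dyadic win-count matrix with individual identifiers.

    ``W[i, j]`` counts wins of ``ids[i]`` over ``ids[j]``.  The diagonal is
    zero and entries are non-negative integers.
    """

    ids: list
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError(f"matrix shape {self.W.shape} does not match {n} ids")
        if np.any(self.W < 0):
            raise ValueError("win counts must be non-negative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal (self-interactions) must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.ids, columns=self.ids)


@dataclass
class DominanceResult:
    """David's Scores and the quantities they are built from.

    Attributes
    ----------
    ds : pd.Series
        David's Score per individual (sums to zero).
    P : ndarray
        Dyadic win proportions; 0 where a dyad is uncontested.
    D : ndarray
        Chance-corrected dyadic indices; ``D + D.T == 1`` on contested dyads.
    w, w2, l, l2 : pd.Series
        The four DS summands.
    ranks : pd.Series or None
        Ordinal ranks 1..N (1 = highest DS), filled by :func:`rank_from_ds`.
    dc, dc_p : float or None
        Directional consistency and its randomization p-value, when computed.
    """

    ids: list
    ds: pd.Series
    P: np.ndarray
    D: np.ndarray
    w: pd.Series
    w2: pd.Series
    l: pd.Series
    l2: pd.Series
    matrix: WinLossMatrix
    ranks: pd.Series | None = None
    dc: float | None = None
    dc_p: float | None = None


def build_sociomatrix(events: pd.DataFrame, ids=None) -> WinLossMatrix:
    """Tally a win/loss sociomatrix from an agonistic event table.

    Parameters
    ----------
    events : DataFrame with ``winner_id`` and ``loser_id`` columns.
    ids : optional explicit ordering of individuals.  When omitted, the
        sorted union of winners and losers is used.
    """
    winners = events["winner_id"].to_numpy()
    losers = events["loser_id"].to_numpy()
    if np.any(winners == losers):
        raise ValueError("self-interaction: winner equals loser in some event")
    if ids is None:
        ids = sorted(set(winners) | set(losers))
    ids = list(ids)
    index = {a: k for k, a in enumerate(ids)}
    unknown = (set(winners) | set(losers)) - set(ids)
    if unknown:
        raise ValueError(f"events mention ids not in the id list: {sorted(unknown)}")
    W = np.zeros((len(ids), len(ids)), dtype=int)
    for w_, l_ in zip(winners, losers):
        W[index[w_], index[l_]] += 1
    return WinLossMatrix(ids=ids, W=W)


def davids_score(M: WinLossMatrix) -> DominanceResult:
    """Compute David's Scores with the chance-corrected dyadic index.

    Uncontested dyads contribute zero to every summand.  An all-zero matrix
    yields all-zero scores with a warning.
    """
    W = M.W.astype(float)
    if M.n < 2:
        raise ValueError("need at least two individuals")
    n_dyad = W + W.T
    contested = n_dyad > 0
    if not contested.any():
        warnings.warn("sociomatrix has no contests; David's Scores are all zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(contested, W / np.where(contested, n_dyad, 1.0), 0.0)
    D = np.where(contested, P - (P - 0.5) / (n_dyad + 1.0), 0.0)
    w = D.sum(axis=1)
    w2 = D @ w
    l = D.sum(axis=0)
    l2 = D.T @ l
    ds = w + w2 - l - l2
    as_series = lambda v: pd.Series(v, index=M.ids)
    return DominanceResult(
        ids=M.ids,
        ds=as_series(ds),
        P=P,
        D=D,
        w=as_series(w),
        w2=as_series(w2),
        l=as_series(l),
        l2=as_series(l2),
        matrix=M,
    )


def _dyad_counts(M: WinLossMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (wins_ij, totals) for contested dyads."""
    iu, ju = np.triu_indices(M.n, k=1)
    wins = M.W[iu, ju]
    totals = wins + M.W[ju, iu]
    keep = totals > 0
    return wins[keep].astype(int), totals[keep].astype(int)


def directional_consistency(M: WinLossMatrix) -> float:
    """DC = sum(H - L) / sum(H + L) over contested dyads (H >= L counts)."""
    wins, totals = _dyad_counts(M)
    if totals.size == 0:
        raise ValueError("directional consistency undefined: no contested dyads")
    hl_diff = np.abs(2 * wins - totals)  # H - L
    return float(hl_diff.sum() / totals.sum())


def dc_randomization_test(
    M: WinLossMatrix, n_perm: int = 10000, seed: int | None = None
) -> float:
    """Randomization p-value for directional consistency.

    Each permutation re-assigns the direction of every individual interaction
    independently with probability 0.5 within its dyad (so dyad totals are
    preserved) and recomputes DC.  The add-one estimator
    ``p = (1 + #{DC_perm >= DC_obs}) / (n_perm + 1)`` avoids p = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    wins, totals = _dyad_counts(M)
    if totals.size == 0:
        raise ValueError("directional consistency undefined: no contested dyads")
    dc_obs = np.abs(2 * wins - totals).sum() / totals.sum()
    rng = np.random.default_rng(seed)
    perm_wins = rng.binomial(totals, 0.5, size=(n_perm, totals.size))
    dc_perm = np.abs(2 * perm_wins - totals).sum(axis=1) / totals.sum()
    exceed = int(np.sum(dc_perm >= dc_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def rank_from_ds(result: DominanceResult) -> pd.Series:
    """Ordinal ranks from David's Scores (1 = highest).

    Ties are broken by total wins (more wins ranks higher), then by
    lexicographic individual id, so the ordering is deterministic.
    """
    total_wins = result.matrix.W.sum(axis=1)
    order = sorted(
        range(len(result.ids)),
        key=lambda k: (-result.ds.iloc[k], -total_wins[k], str(result.ids[k])),
    )
    ranks = pd.Series(0, index=result.ds.index, dtype=int)
    for r, k in enumerate(order, start=1):
        ranks.iloc[k] = r
    result.ranks = ranks
    return ranks


def emergence_trajectory(events: pd.DataFrame, ids=None) -> pd.DataFrame:
    """Cumulative David's Scores after each successive contest.

    Row ``k`` (1-based contest index) holds the DS of the sociomatrix built
    from the first ``k`` events.  Events must be time-ordered; non-monotone
    timestamps raise unless a plain contest index is supplied instead.
    """
    ts = events["timestamp"].to_numpy()
    if len(ts) > 1:
        try:
            monotone = bool(np.all(pd.Series(ts).diff().dropna() >= pd.Timedelta(0)))
        except TypeError:
            monotone = bool(np.all(np.diff(np.asarray(ts, dtype=float)) >= 0))
        if not monotone:
            raise ValueError("events are not time-ordered; sort or supply contest indices")
    if ids is None:
        ids = sorted(set(events["winner_id"]) | set(events["loser_id"]))
    ids = list(ids)
    index = {a: k for k, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)), dtype=int)
    rows = []
    for _, ev in events.iterrows():
        W[index[ev["winner_id"]], index[ev["loser_id"]]] += 1
        rows.append(davids_score(WinLossMatrix(ids=ids, W=W.copy())).ds.to_numpy())
    out = pd.DataFrame(rows, columns=ids)
    out.index = pd.RangeIndex(1, len(rows) + 1, name="contest")
    return out


def stability_binomial(
    day2_events: pd.DataFrame, day1_ranks: pd.Series
) -> pd.DataFrame:
    """Per-rank binomial tests of day-2 hierarchy stability.

    For each day-1 rank ``r``, count the animals of that rank that lost more
    fights than they won against lower-ranked animals on day 2 (``k`` of
    ``n``); the one-sided p-value is the lower binomial tail at p0 = 0.5.
    A small ``p`` means upsets are rarer than coin-flipping would give.
    """
    animals = set(day2_events["winner_id"]) | set(day2_events["loser_id"])
    missing = animals - set(day1_ranks.index)
    if missing:
        raise ValueError(f"day-1 ranks missing for: {sorted(missing)}")
    rows = []
    max_rank = int(day1_ranks.max())
    for r in range(1, max_rank):  # the lowest rank has no lower-ranked opponents
        members = day1_ranks.index[day1_ranks == r]
        k = 0
        for a in members:
            won = lost = 0
            for _, ev in day2_events.iterrows():
                w_, l_ = ev["winner_id"], ev["loser_id"]
                if w_ == a and day1_ranks[l_] > r:
                    won += 1
                elif l_ == a and day1_ranks[w_] > r:
                    lost += 1
            if lost > won:
                k += 1
        n = len(members)
        p = float(stats.binom.cdf(k, n, 0.5)) if n else float("nan")
        rows.append({"rank": r, "k_upsets": k, "n_animals": n, "p": p})
    return pd.DataFrame(rows)


class HierarchyModel:
    """Dominance-hierarchy model for a single social group.

    Parameters
    ----------
    events : DataFrame of agonistic interactions (``winner_id``/``loser_id``
        columns; one group), or ``None`` when ``matrix`` is given directly.
    ids : optional explicit individual ordering.
    matrix : optional pre-built :class:`WinLossMatrix`.
    """

    def __init__(self, events: pd.DataFrame | None = None, ids=None,
                 matrix: WinLossMatrix | None = None):
        if (events is None) == (matrix is None):
            raise ValueError("supply exactly one of events or matrix")
        self.events = events
        self.matrix = matrix if matrix is not None else build_sociomatrix(events, ids)

    def fit(self, n_perm: int = 10000, seed: int | None = None) -> "HierarchyResults":
        res = davids_score(self.matrix)
        rank_from_ds(res)
        try:
            res.dc = directional_consistency(self.matrix)
            res.dc_p = dc_randomization_test(self.matrix, n_perm=n_perm, seed=seed)
        except ValueError:
            res.dc = res.dc_p = None
        return HierarchyResults(self, res, n_perm=n_perm, seed=seed)

    @classmethod
    def from_csv(cls, path, group_id=None) -> "HierarchyModel":
        events = pd.read_csv(path)
        if group_id is not None:
            events = events[events["group_id"] == group_id]
        return cls(events=events)


class HierarchyResults:
    """Fitted hierarchy statistics: DS, ranks, DC and its p-value."""

    def __init__(self, model: HierarchyModel, result: DominanceResult,
                 n_perm: int, seed):
        self.model = model
        self._result = result
        self.n_perm = n_perm
        self.seed = seed

    @property
    def ds(self) -> pd.Series:
        return self._result.ds

    @property
    def ranks(self) -> pd.Series:
        return self._result.ranks

    @property
    def dc(self):
        return self._result.dc

    @property
    def dc_p(self):
        return self._result.dc_p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual": self._result.ds.index,
            "ds": self._result.ds.to_numpy(),
            "rank": self._result.ranks.to_numpy(),
            "dc": self._result.dc,
            "dc_p": self._result.dc_p,
        })

    def emergence(self) -> pd.DataFrame:
        if self.model.events is None:
            raise ValueError("emergence trajectory requires the raw event stream")
        return emergence_trajectory(self.model.events, ids=self._result.ids)

    def plot_emergence(self, ax=None):
        """Line plot of cumulative DS per individual across contests."""
        import matplotlib.pyplot as plt

        traj = self.emergence()
        if ax is None:
            _, ax = plt.subplots()
        for col in traj.columns:
            ax.plot(traj.index, traj[col], label=str(col))
        ax.set_xlabel("contest")
        ax.set_ylabel("David's Score")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        lines = ["Dominance hierarchy summary", "=" * 30]
        dc = "n/a" if self.dc is None else f"{self.dc:.3f}"
        dcp = "n/a" if self.dc_p is None else f"{self.dc_p:.4g}"
        lines.append(f"individuals: {len(self.ds)}   contests: {int(self.model.matrix.W.sum())}")
        lines.append(f"directional consistency: {dc}  (randomization p = {dcp}, "
                     f"{self.n_perm} permutations)")
        lines.append("")
        lines.append(f"{'individual':<14}{'rank':>6}{'DS':>10}")
        for ind in self.ranks.sort_values().index:
            lines.append(f"{str(ind):<14}{self.ranks[ind]:>6}{self.ds[ind]:>10.3f}")
        return "\n".join(lines)


def fit_groups(events: pd.DataFrame, n_perm: int = 10000,
               seed: int | None = None) -> pd.DataFrame:
    """Fit a :class:`HierarchyModel` per ``group_id``; tidy results table."""
    frames = []
    ss = np.random.SeedSequence(seed)
    groups = sorted(events["group_id"].unique())
    for gid, child in zip(groups, ss.spawn(len(groups))):
        sub = events[events["group_id"] == gid]
        res = HierarchyModel(events=sub).fit(
            n_perm=n_perm, seed=int(child.generate_state(1)[0] % (2**31)))
        frame = res.to_frame()
        frame.insert(0, "group_id", gid)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
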