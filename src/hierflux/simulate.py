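"""Synthetic agonistic event streams and RNA-seq count matrices with ground truth.

Every downstream stage of the package is testable against data whose
generating process is known.  Two kinds of data are emulated:

1. **Agonistic event streams** from groups of four male mice.  Each contest
   is a pairwise dyadic interaction; the probability that the animal with
   the higher latent rank wins is a logistic function of
   ``steepness * (rank difference)``.  ``steepness = 0`` gives exchangeable
   win directions (no hierarchy); the default ``steepness = 4`` gives an
   upset probability of ~2% between adjacent ranks, which reproduces the
   near-unidirectional aggression (directional consistency ~0.98) observed
   in stable murine hierarchies.

2. **Negative-binomial count matrices** for the six social conditions
   (DOM, DES, ASC, SUB, CDOM, CSUB).  Gene-wise log2 means are shifted by
   planted log2 fold changes in designated conditions, by planted
   "transition genes" (a shared-direction shift in both DES and ASC), and
   by additive per-module Gaussian latent factors (the simplest structure a
   co-expression analysis can recover).  Library sizes vary uniformly
   within a configured range; counts are NB with variance ``m + phi*m^2``.

All randomness flows through a single explicit seed per call; identical
seed and configuration reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dominance

__all__ = [
    "HierarchySimConfig",
    "CountsSimConfig",
    "GroundTruth",
    "simulate_hierarchy_events",
    "simulate_reorganization",
    "simulate_counts",
    "DEFAULT_CONDITION_SIZES",
]

#: sample sizes of the six social conditions in the study design
DEFAULT_CONDITION_SIZES = {
    "DOM": 7, "DES": 7, "ASC": 7, "SUB": 7, "CDOM": 6, "CSUB": 6,
}


@dataclass
class HierarchySimConfig:
    """Configuration of the agonistic event-stream generator.

    Defaults are the study conditions: 65 groups of 4 animals, ~82 agonistic
    interactions per group, steepness tuned to near-unidirectional dyads.
    """

    n_groups: int = 65
    group_size: int = 4
    n_events_per_group: int = 82
    steepness: float = 4.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_events_per_group < 1:
            raise ValueError("n_groups and n_events_per_group must be positive")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.steepness < 0:
            raise ValueError("steepness must be non-negative")


@dataclass
class CountsSimConfig:
    """Configuration of the negative-binomial count generator.

    ``planted_degs`` holds ``(gene_index, comparison, log2fc)`` triples where
    a comparison such as ``"DES:DOM"`` shifts the first-named condition by
    ``log2fc`` log2 units.  ``planted_transition_genes`` holds
    ``(gene_index, sign)`` pairs shifted by ``sign * transition_lfc`` in both
    DES and ASC (so the DES:DOM and ASC:SUB contrasts agree in direction).
    ``planted_modules`` holds ``(gene_index_set, loading)`` pairs: a latent
    standard-normal factor per sample enters those genes' log2 means with the
    given loading.
    """

    n_genes: int = 15000
    condition_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_SIZES))
    baseline_mean_log: float = 5.0
    gene_sd: float = 2.0
    dispersion: float = 0.05
    library_size_range: tuple = (4_000_000, 6_000_000)
    planted_degs: list = field(default_factory=list)
    planted_transition_genes: list = field(default_factory=list)
    transition_lfc: float = 1.0
    planted_modules: list = field(default_factory=list)
    seed: int | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if not self.condition_sizes:
            raise ValueError("condition_sizes must be non-empty")
        for g, comp, lfc in self.planted_degs:
            if not np.isfinite(lfc):
                raise ValueError("planted fold changes must be finite")
            if not (0 <= g < self.n_genes):
                raise ValueError(f"planted gene index {g} out of range")
            cond = comp.split(":")[0]
            if cond not in self.condition_sizes:
                raise ValueError(f"unknown condition in comparison {comp!r}")
        for g, sign in self.planted_transition_genes:
            if sign not in (-1, 1):
                raise ValueError("transition gene sign must be +1 or -1")
            if not (0 <= g < self.n_genes):
                raise ValueError(f"planted gene index {g} out of range")


@dataclass
class GroundTruth:
    """Planted truth: latent ranks, signed DEG sets, module labels."""

    latent_ranks: dict = field(default_factory=dict)
    deg_truth: dict = field(default_factory=dict)
    module_truth: dict = field(default_factory=dict)


def simulate_hierarchy_events(config: HierarchySimConfig):
    """Generate agonistic event tables for groups with latent ranks.

    Returns ``(events, truth)``: an event DataFrame with columns
    ``timestamp, group_id, winner_id, loser_id, behavior`` (timestamp is the
    within-group contest index) and a :class:`GroundTruth` carrying the
    planted latent rank of every individual (1 = most dominant).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth = GroundTruth()
    for g in range(config.n_groups):
        gid = f"G{g + 1:03d}"
        members = [f"{gid}-M{k + 1}" for k in range(config.group_size)]
        ranks = rng.permutation(config.group_size) + 1  # latent rank per member
        for m, r in zip(members, ranks):
            truth.latent_ranks[m] = int(r)
        for t in range(config.n_events_per_group):
            i, j = rng.choice(config.group_size, size=2, replace=False)
            # probability that the higher-ranked (smaller rank number) wins
            delta = abs(int(ranks[i]) - int(ranks[j]))
            p_high = 1.0 / (1.0 + np.exp(-config.steepness * delta))
            hi, lo = (i, j) if ranks[i] < ranks[j] else (j, i)
            winner, loser = (hi, lo) if rng.random() < p_high else (lo, hi)
            rows.append({
                "timestamp": t + 1,
                "group_id": gid,
                "winner_id": members[winner],
                "loser_id": members[loser],
                "behavior": "fighting",
            })
    return pd.DataFrame(rows, columns=dominance.EVENT_COLUMNS), truth


def _prior_ranks(pre_events: pd.DataFrame) -> pd.DataFrame:
    """Per-individual (origin_group, prior_rank) from pre-reorganization events."""
    rows = []
    for gid in sorted(pre_events["group_id"].unique()):
        sub = pre_events[pre_events["group_id"] == gid]
        res = dominance.davids_score(dominance.build_sociomatrix(sub))
        ranks = dominance.rank_from_ds(res)
        for ind, r in ranks.items():
            rows.append({"individual": ind, "origin_group": gid, "prior_rank": int(r)})
    return pd.DataFrame(rows)


def simulate_reorganization(
    pre_events: pd.DataFrame,
    origin_effect: float,
    seed: int | None = None,
    n_events_per_group: int = 82,
    steepness: float = 4.0,
):
    """Reorganize animals into new groups of equal prior status.

    Origin groups are blocked into sets of four; within each block the four
    rank-``r`` animals form one new group (one animal per origin group, all
    of equal prior rank — the study's reorganization design).  The achieved
    post-rank of animal *i* orders a latent score
    ``origin_effect * u[origin_i] + eps_i`` within its new group, so
    ``origin_effect = 0`` makes post-ranks independent of origin while a
    large ``origin_effect`` forces animals from the same origin group to the
    same post-rank in every new group.

    Returns ``(post_events, table)`` where ``table`` has columns
    ``individual, origin_group, prior_rank, post_group, post_rank``.
    """
    if origin_effect < 0:
        raise ValueError("origin_effect must be non-negative")
    prior = _prior_ranks(pre_events)
    group_size = int(prior["prior_rank"].max())
    origins = sorted(prior["origin_group"].unique())
    if len(origins) < 4 or len(origins) % 4 != 0:
        raise ValueError("number of origin groups must be a positive multiple of 4")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(origins))
    blocks = [sorted(np.asarray(origins)[order[k:k + 4]]) for k in range(0, len(origins), 4)]
    u = {g: rng.normal() for g in origins}

    rows = []
    post_rank_truth = {}
    event_frames = []
    for b, block in enumerate(blocks):
        for r in range(1, group_size + 1):
            pgid = f"R{b + 1:03d}-rank{r}"
            members = prior[(prior["origin_group"].isin(block))
                            & (prior["prior_rank"] == r)]
            inds = list(members["individual"])
            scores = np.array([origin_effect * u[g] for g in members["origin_group"]])
            scores = scores + rng.normal(size=len(inds))
            post_ranks = np.empty(len(inds), dtype=int)
            post_ranks[np.argsort(-scores)] = np.arange(1, len(inds) + 1)
            for ind, og, pr in zip(inds, members["origin_group"], post_ranks):
                rows.append({
                    "individual": ind, "origin_group": og, "prior_rank": r,
                    "post_group": pgid, "post_rank": int(pr),
                })
                post_rank_truth[ind] = int(pr)
            # post-reorganization contests driven by the achieved ranks
            ev = []
            for t in range(n_events_per_group):
                i, j = rng.choice(len(inds), size=2, replace=False)
                delta = abs(post_ranks[i] - post_ranks[j])
                p_high = 1.0 / (1.0 + np.exp(-steepness * delta))
                hi, lo = (i, j) if post_ranks[i] < post_ranks[j] else (j, i)
                winner, loser = (hi, lo) if rng.random() < p_high else (lo, hi)
                ev.append({
                    "timestamp": t + 1, "group_id": pgid,
                    "winner_id": inds[winner], "loser_id": inds[loser],
                    "behavior": "fighting",
                })
            event_frames.append(pd.DataFrame(ev, columns=dominance.EVENT_COLUMNS))
    table = pd.DataFrame(rows)
    post_events = pd.concat(event_frames, ignore_index=True)
    return post_events, table


def _condition_effects(config: CountsSimConfig) -> dict:
    """Per-condition per-gene log2 shifts; raises on conflicting plants."""
    effects: dict[str, dict[int, float]] = {c: {} for c in config.condition_sizes}

    def add(cond: str, gene: int, lfc: float) -> None:
        prev = effects[cond].get(gene)
        if prev is not None and not np.isclose(prev, lfc):
            raise ValueError(
                f"conflicting planted effects for gene {gene} in condition {cond}")
        effects[cond][gene] = lfc

    for g, comp, lfc in config.planted_degs:
        add(comp.split(":")[0], int(g), float(lfc))
    for g, sign in config.planted_transition_genes:
        for cond in ("DES", "ASC"):
            if cond in effects:
                add(cond, int(g), sign * config.transition_lfc)
    return effects


def simulate_counts(config: CountsSimConfig):
    """Generate a raw NB count matrix, sample metadata, and ground truth.

    Returns ``(counts, metadata, truth)``: ``counts`` is a genes x samples
    DataFrame of raw integer counts with index ``gene_id``; ``metadata`` has
    ``sample_id, condition, group_id`` (group ids pair the conditions that
    shared a cage in the study design: DES with DOM, ASC with SUB, CDOM with
    CSUB); ``truth.deg_truth`` maps each comparison to its signed planted
    gene sets and ``truth.module_truth`` maps gene ids to module labels.
    """
    config.validate()
    effects = _condition_effects(config)
    rng = np.random.default_rng(config.seed)

    genes = [f"gene{g + 1:05d}" for g in range(config.n_genes)]
    conditions = []
    sample_ids = []
    for cond, n in config.condition_sizes.items():
        for k in range(n):
            sample_ids.append(f"{cond}_{k + 1}")
            conditions.append(cond)
    n_samples = len(sample_ids)

    # cage pairing: DES/DOM, ASC/SUB, CDOM/CSUB animals shared groups
    pair_of = {"DES": "DOM", "ASC": "SUB", "CDOM": "CSUB"}
    group_ids = [""] * n_samples
    counters: dict[str, int] = {}
    for s, cond in enumerate(conditions):
        base = next((f"{a}{b}" for a, b in pair_of.items() if cond in (a, b)), cond)
        k = counters.get((base, cond), 0)
        counters[(base, cond)] = k + 1
        group_ids[s] = f"grp-{base}-{k + 1}"
    metadata = pd.DataFrame({
        "sample_id": sample_ids, "condition": conditions, "group_id": group_ids,
    })

    base_log2 = rng.normal(config.baseline_mean_log, config.gene_sd, size=config.n_genes)
    log2_mu = np.tile(base_log2[:, None], (1, n_samples))
    for s, cond in enumerate(conditions):
        for g, lfc in effects[cond].items():
            log2_mu[g, s] += lfc
    truth = GroundTruth()
    for g, comp, lfc in config.planted_degs:
        truth.deg_truth.setdefault(comp, {})[genes[int(g)]] = float(lfc)
    for g, sign in config.planted_transition_genes:
        for comp in ("DES:DOM", "ASC:SUB"):
            truth.deg_truth.setdefault(comp, {})[genes[int(g)]] = (
                sign * config.transition_lfc)

    for m, (gene_set, loading) in enumerate(config.planted_modules, start=1):
        factor = rng.normal(size=n_samples)
        idx = sorted(int(g) for g in gene_set)
        log2_mu[idx, :] += loading * factor[None, :]
        for g in idx:
            truth.module_truth[genes[g]] = f"module{m}"

    lo, hi = config.library_size_range
    lib_sizes = rng.integers(int(lo), int(hi) + 1, size=n_samples)
    mu = np.exp2(log2_mu)
    prop = mu / mu.sum(axis=0, keepdims=True)
    mean = prop * lib_sizes[None, :]
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=sample_ids)
    return counts_df, metadata, truth
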