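"""Lag-1 dynamic Bayesian networks over the six sites of one location.

For each (location, taxonomic family) the six per-site abundance series
(family-aggregated, log2-transformed with a pseudo-count) are discretised
into five equal-width bins and a lag-1 network is learned: an edge
parent → child means the parent site's state at time t is informative about
the child site's state at t+1, interpreted as a microbial dispersal route.

Structure search is multi-restart greedy hill climbing over single-edge
additions and deletions, scored with the BDeu (Dirichlet-multinomial
marginal likelihood) metric at equivalent sample size 1; BIC is available
as an alternative. Because every edge spans one time step, no acyclicity
constraint is needed. Transitions spanning a slot with a missing sample are
dropped from scoring rather than imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import lgamma, log
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import (
    AbundanceTable,
    SampleMetadata,
    SITES,
    SITE_CLASS,
    SITE_CLASSES,
    ValidationError,
    aggregate_to_family,
    N_TIMEPOINTS,
)

logger = logging.getLogger(__name__)

N_BINS = 5
MAX_PARENTS = 5


class FamilyAbsent(Exception):
    """Signal that a family has no abundance anywhere at a location."""


@dataclass
class FamilySeriesSet:
    """Per-site log2 family-abundance series on the 20-slot grid."""

    location: int
    family: str
    series: dict[str, np.ndarray]
    observed: dict[str, np.ndarray]

    def transition_mask(self) -> np.ndarray:
        """Transitions (t, t+1) with every site observed at both endpoints."""
        obs = np.all([self.observed[s] for s in SITES], axis=0)
        return obs[:-1] & obs[1:]


@dataclass
class DBNModel:
    location: int
    family: str
    nodes: tuple[str, ...]
    edges: list[tuple[str, str]]
    score: float
    score_metric: str = "bdeu"

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def default_epsilon(table: AbundanceTable) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    vals = table.data.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValidationError("table has no nonzero abundances")
    return float(nonzero.min() / 2.0)


def build_family_series(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    location: int,
    family: str,
    epsilon: float | None = None,
) -> FamilySeriesSet:
    """Family abundance per site per slot, log2(abundance + epsilon).

    Missing slots are linearly interpolated (in log2 space) so every value
    is finite, and flagged in ``observed`` so transitions across them can be
    excluded downstream.
    """
    if epsilon is None:
        epsilon = default_epsilon(table)
    fam_table = aggregate_to_family(table)
    fam_lineage = next(
        (t.lineage for t in fam_table.taxa if t.family == family), None
    )
    if fam_lineage is None:
        raise FamilyAbsent(f"family {family!r} not in table")
    series: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    any_present = False
    for site in SITES:
        slots = np.full(N_TIMEPOINTS, np.nan)
        for m in metadata:
            if m.location == location and m.site == site:
                slots[m.timepoint] = fam_table.data.at[m.sample_id, fam_lineage]
        obs = ~np.isnan(slots)
        if not obs.any():
            raise ValidationError(
                f"no samples at site={site} location={location}"
            )
        if np.nansum(slots) > 0:
            any_present = True
        logged = np.log2(slots + epsilon)
        if (~obs).any():
            idx = np.arange(N_TIMEPOINTS)
            logged[~obs] = np.interp(idx[~obs], idx[obs], logged[obs])
            logger.info(
                "interpolated %d missing slot(s) for %s at location %d, site %s",
                int((~obs).sum()), family, location, site,
            )
        series[site] = logged
        observed[site] = obs
    if not any_present:
        raise FamilyAbsent(f"family {family!r} absent at all sites of location {location}")
    return FamilySeriesSet(location=location, family=family, series=series, observed=observed)


def discretize_i5(values: Sequence[float], n_bins: int = N_BINS) -> np.ndarray:
    """Equal-width interval discretisation into ``n_bins`` bins over
    [min, max]; the maximum maps to the top bin. A constant series maps to
    the middle bin (logged)."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.info("constant series: all values assigned to middle bin")
        return np.full(len(x), n_bins // 2, dtype=int)
    bins = np.floor(n_bins * (x - lo) / (hi - lo)).astype(int)
    return np.clip(bins, 0, n_bins - 1)


# --------------------------------------------------------------------------
# scoring

def _encode_parent_configs(parent_states: np.ndarray, r: int) -> np.ndarray:
    """Mixed-radix encoding of parent state combinations (columns = parents)."""
    if parent_states.shape[1] == 0:
        return np.zeros(parent_states.shape[0], dtype=int)
    code = np.zeros(parent_states.shape[0], dtype=int)
    for j in range(parent_states.shape[1]):
        code = code * r + parent_states[:, j]
    return code


def _bdeu_family_score(
    child_next: np.ndarray, parent_now: np.ndarray, r: int = N_BINS, ess: float = 1.0
) -> float:
    """BDeu log marginal likelihood of one child given its parents."""
    n_parents = parent_now.shape[1]
    q = r**n_parents
    a_ij = ess / q
    a_ijk = ess / (q * r)
    codes = _encode_parent_configs(parent_now, r)
    score = 0.0
    for c in np.unique(codes):
        sel = child_next[codes == c]
        n_ij = len(sel)
        score += lgamma(a_ij) - lgamma(a_ij + n_ij)
        counts = np.bincount(sel, minlength=r)
        for n_ijk in counts[counts > 0]:
            score += lgamma(a_ijk + n_ijk) - lgamma(a_ijk)
    return score


def _bic_family_score(
    child_next: np.ndarray, parent_now: np.ndarray, r: int = N_BINS, ess: float = 1.0
) -> float:
    """BIC: maximised multinomial log-likelihood minus complexity penalty."""
    n = len(child_next)
    codes = _encode_parent_configs(parent_now, r)
    ll = 0.0
    n_configs_seen = 0
    for c in np.unique(codes):
        sel = child_next[codes == c]
        n_ij = len(sel)
        counts = np.bincount(sel, minlength=r)
        n_configs_seen += 1
        for n_ijk in counts[counts > 0]:
            ll += n_ijk * log(n_ijk / n_ij)
    q = r ** parent_now.shape[1]
    penalty = 0.5 * log(n) * q * (r - 1)
    return ll - penalty


_FAMILY_SCORERS = {"bdeu": _bdeu_family_score, "bic": _bic_family_score}


def score_network(
    edges: Iterable[tuple[str, str]],
    states: dict[str, np.ndarray],
    transition_mask: np.ndarray | None = None,
    metric: str = "bdeu",
    max_parents: int = MAX_PARENTS,
) -> float:
    """Decomposable network score: sum over children of the family score of
    child(t+1) given its parents' states at t, over usable transitions."""
    nodes = list(states)
    if not nodes:
        raise ValidationError("empty data")
    n_slots = len(next(iter(states.values())))
    if transition_mask is None:
        transition_mask = np.ones(n_slots - 1, dtype=bool)
    parents: dict[str, list[str]] = {n: [] for n in nodes}
    for p, c in edges:
        parents[c].append(p)
    for c, ps in parents.items():
        if len(ps) > max_parents:
            raise ValidationError(f"child {c} has {len(ps)} parents (max {max_parents})")
    scorer = _FAMILY_SCORERS[metric]
    t_idx = np.flatnonzero(transition_mask)
    total = 0.0
    for child in nodes:
        child_next = states[child][t_idx + 1]
        parent_now = np.column_stack(
            [states[p][t_idx] for p in sorted(parents[child])]
        ) if parents[child] else np.empty((len(t_idx), 0), dtype=int)
        total += scorer(child_next, parent_now)
    return total


# --------------------------------------------------------------------------
# structure search

def greedy_search(
    data: FamilySeriesSet,
    max_parents: int = MAX_PARENTS,
    n_restarts: int = 5,
    seed: int = 0,
    metric: str = "bdeu",
    allow_self_loops: bool = True,
    min_transitions: int = 8,
) -> DBNModel:
    """Multi-restart greedy hill climbing over lag-1 edges.

    Each restart starts from the empty network and repeatedly applies the
    first score-improving single-edge addition or deletion in a shuffled
    move order until no move improves. The best-scoring network over all
    restarts is returned; the search is deterministic given the seed (the
    best *score* is deterministic even where edge sets tie).
    """
    states = {s: discretize_i5(data.series[s]) for s in SITES}
    mask = data.transition_mask()
    if mask.sum() < min_transitions:
        warnings.warn(
            f"only {int(mask.sum())} usable transitions (< {min_transitions}); "
            "returning empty network"
        )
        return DBNModel(
            location=data.location, family=data.family, nodes=SITES,
            edges=[], score=score_network([], states, mask, metric=metric),
            score_metric=metric,
        )
    t_idx = np.flatnonzero(mask)
    now = {s: states[s][t_idx] for s in SITES}
    nxt = {s: states[s][t_idx + 1] for s in SITES}
    scorer = _FAMILY_SCORERS[metric]
    cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family_score(child: str, parents: frozenset[str]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in cache:
            pm = (
                np.column_stack([now[p] for p in sorted(parents)])
                if parents else np.empty((len(t_idx), 0), dtype=int)
            )
            cache[key] = scorer(nxt[child], pm)
        return cache[key]

    all_edges = [
        (p, c) for p in SITES for c in SITES if allow_self_loops or p != c
    ]
    rng = np.random.default_rng(seed)
    best_edges: list[tuple[str, str]] = []
    best_score = sum(family_score(c, frozenset()) for c in SITES)

    for _ in range(max(1, n_restarts)):
        parents: dict[str, frozenset[str]] = {c: frozenset() for c in SITES}
        child_scores = {c: family_score(c, frozenset()) for c in SITES}
        improved = True
        while improved:
            improved = False
            order = rng.permutation(len(all_edges))
            for k in order:
                p, c = all_edges[k]
                if p in parents[c]:
                    new_parents = parents[c] - {p}
                else:
                    if len(parents[c]) >= max_parents:
                        continue
                    new_parents = parents[c] | {p}
                new_score = family_score(c, new_parents)
                if new_score > child_scores[c]:
                    parents[c] = new_parents
                    child_scores[c] = new_score
                    improved = True
        total = sum(child_scores.values())
        if total > best_score:
            best_score = total
            best_edges = sorted(
                (p, c) for c, ps in parents.items() for p in ps
            )
    return DBNModel(
        location=data.location,
        family=data.family,
        nodes=SITES,
        edges=best_edges,
        score=float(best_score),
        score_metric=metric,
    )


def learn_all(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    metric: str = "bdeu",
    max_parents: int = MAX_PARENTS,
    n_restarts: int = 5,
    seed: int = 0,
    epsilon: float | None = None,
    families: Iterable[str] | None = None,
) -> list[DBNModel]:
    """One DBN per (location, family) with the family present there."""
    if epsilon is None:
        epsilon = default_epsilon(table)
    fam_table = aggregate_to_family(table)
    all_families = sorted({t.family for t in fam_table.taxa})
    if families is not None:
        wanted = set(families)
        all_families = [f for f in all_families if f in wanted]
    locations = sorted({m.location for m in metadata})
    models = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(locations) * len(all_families))
    i = 0
    for loc in locations:
        for fam in all_families:
            sub_seed = int(child_seeds[i] % (2**31 - 1))
            i += 1
            try:
                fss = build_family_series(table, metadata, loc, fam, epsilon=epsilon)
            except FamilyAbsent:
                continue
            models.append(
                greedy_search(
                    fss, max_parents=max_parents, n_restarts=n_restarts,
                    seed=sub_seed, metric=metric,
                )
            )
    return models


# --------------------------------------------------------------------------
# edge summaries

@dataclass
class EdgeSummary:
    class_pair_counts: pd.DataFrame       # parent_class x child_class counts
    node_counts: pd.DataFrame             # per (model, site): parent/child edge counts
    most_common_edge_type: tuple[str, str] | None
    kruskal_parent: tuple[float, float] | None
    kruskal_child: tuple[float, float] | None
    n_models: int
    n_models_with_edges: int
    total_edges: int


def summarize_edges(models: Sequence[DBNModel]) -> EdgeSummary:
    """Edge counts by site-class pair, per-node parent/child counts, and
    Kruskal-Wallis tests for class differences in parent and child roles."""
    if not models:
        raise ValidationError("no models")
    pair_counts = pd.DataFrame(
        0, index=list(SITE_CLASSES), columns=list(SITE_CLASSES)
    )
    node_rows = []
    total_edges = 0
    for mi, model in enumerate(models):
        parent_count = {s: 0 for s in SITES}
        child_count = {s: 0 for s in SITES}
        for p, c in model.edges:
            pair_counts.loc[SITE_CLASS[p], SITE_CLASS[c]] += 1
            parent_count[p] += 1
            child_count[c] += 1
            total_edges += 1
        for s in SITES:
            node_rows.append(
                {
                    "model": mi, "location": model.location, "family": model.family,
                    "site": s, "site_class": SITE_CLASS[s],
                    "n_parent_edges": parent_count[s],
                    "n_child_edges": child_count[s],
                }
            )
    node_counts = pd.DataFrame(node_rows)
    if total_edges > 0:
        flat = pair_counts.stack()
        pc, cc = flat.idxmax()
        most_common = (str(pc), str(cc))
    else:
        most_common = None

    def kw(column: str):
        groups = [
            node_counts.loc[node_counts["site_class"] == cls, column].to_numpy()
            for cls in SITE_CLASSES
        ]
        if any(len(g) == 0 for g in groups):
            return None
        flat_vals = np.concatenate(groups)
        if np.all(flat_vals == flat_vals[0]):
            return None
        h, p = stats.kruskal(*groups)
        return (float(h), float(p))

    return EdgeSummary(
        class_pair_counts=pair_counts,
        node_counts=node_counts,
        most_common_edge_type=most_common,
        kruskal_parent=kw("n_parent_edges"),
        kruskal_child=kw("n_child_edges"),
        n_models=len(models),
        n_models_with_edges=sum(1 for m in models if m.n_edges > 0),
        total_edges=total_edges,
    )
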