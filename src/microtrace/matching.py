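"""Distance-based microbiota matching and community-level comparisons.

A surface sample (the *query*) is matched against a *reference pool*: the
set of all skin samples from every person at one time point. For each
person the mean distance between the query and that person's skin samples
is computed; the person with the smallest mean distance is the predicted
match, and the match is correct when that person lives at the query's
location. Every (query, pool) combination is attempted, so accuracy can be
resolved by *sampling delay* — the signed 12-hour-step offset between query
and reference collection.

Distances follow the vegdist dialects: Bray-Curtis, and Canberra averaged
over the non-double-zero coordinates (1/NZ scaling).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import (
    AbundanceTable,
    SampleMetadata,
    SITE_CLASS,
    ValidationError,
    aggregate_to_family,
    metadata_by_id,
    period_of_timepoint,
)

logger = logging.getLogger(__name__)

HOURS_PER_TIMEPOINT = 12.0


# --------------------------------------------------------------------------
# distance kernels

def canberra_distance(x, y, scaled: bool = True) -> float:
    """Canberra distance, vegdist dialect.

    d = (1/NZ) * sum_{i: x_i+y_i>0} |x_i - y_i| / (x_i + y_i), NZ the count
    of non-double-zero coordinates. ``scaled=False`` gives the unscaled
    textbook sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors of unequal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundances")
    s = x + y
    nz = s > 0
    n_nz = int(nz.sum())
    if n_nz == 0:
        raise ValidationError("no shared support: both vectors all-zero")
    total = float(np.sum(np.abs(x[nz] - y[nz]) / s[nz]))
    return total / n_nz if scaled else total


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors of unequal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundances")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValidationError("both vectors all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


METRICS = {"canberra": canberra_distance, "bray_curtis": bray_curtis}


def _distance_matrix(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distances between rows of A and rows of B (vectorised)."""
    if metric == "bray_curtis":
        num = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)
        den = (A[:, None, :] + B[None, :, :]).sum(axis=2)
        return num / den
    if metric == "canberra":
        S = A[:, None, :] + B[None, :, :]
        D = np.abs(A[:, None, :] - B[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(S > 0, D / np.where(S > 0, S, 1.0), 0.0)
        nz = (S > 0).sum(axis=2)
        return terms.sum(axis=2) / nz
    raise ValidationError(f"unknown metric {metric!r}")


def pairwise_distances(table: AbundanceTable, metric: str = "bray_curtis") -> pd.DataFrame:
    """Square symmetric distance matrix over the table's samples."""
    X = table.data.to_numpy(dtype=float)
    D = _distance_matrix(X, X, metric)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=table.samples, columns=table.samples)


# --------------------------------------------------------------------------
# reference pools and matching

@dataclass
class ReferencePool:
    """All skin samples from every person at one time point."""

    timepoint: int
    members: dict[int, list[str]]  # person -> skin sample ids


@dataclass
class MatchResult:
    query_sample: str
    query_site: str
    query_location: int
    query_timepoint: int
    reference_timepoint: int
    delay_hours: float
    metric: str
    predicted_person: int
    correct: bool


def build_reference_pools(
    table: AbundanceTable, metadata: Sequence[SampleMetadata]
) -> list[ReferencePool]:
    """One pool per time point with at least one skin sample per person;
    time points failing that are excluded (and logged)."""
    persons = sorted({m.location for m in metadata})
    skin = [m for m in metadata if m.site_class == "skin"]
    if not skin:
        raise ValidationError("no skin samples in metadata")
    pools = []
    for t in sorted({m.timepoint for m in skin}):
        members: dict[int, list[str]] = {p: [] for p in persons}
        for m in skin:
            if m.timepoint == t:
                members[m.location].append(m.sample_id)
        if all(members[p] for p in persons):
            pools.append(ReferencePool(timepoint=t, members=members))
        else:
            lacking = [p for p in persons if not members[p]]
            logger.info("timepoint %d excluded: no skin sample for person(s) %s", t, lacking)
    if not pools:
        raise ValidationError("no eligible timepoint for reference pools")
    return pools


def match_query(
    query: str,
    table: AbundanceTable,
    pool: ReferencePool,
    metadata: Sequence[SampleMetadata] | Mapping[str, SampleMetadata],
    metric: str = "canberra",
    method: str = "person_mean",
) -> MatchResult:
    """Match one query sample against one reference pool.

    ``method='person_mean'`` (default) predicts the person with the smallest
    mean distance over their skin samples; ``'nearest'`` predicts the person
    owning the single nearest reference sample. Ties break to the lowest
    person id, with a warning logged.
    """
    meta = metadata if isinstance(metadata, Mapping) else metadata_by_id(metadata)
    qm = meta[query]
    qv = table.values_for(query)
    dist_fn = METRICS[metric]
    scores: dict[int, float] = {}
    for person, sample_ids in pool.members.items():
        d = [dist_fn(qv, table.values_for(s)) for s in sample_ids]
        scores[person] = float(np.mean(d)) if method == "person_mean" else float(np.min(d))
    best = min(scores.values())
    winners = sorted(p for p, v in scores.items() if v == best)
    if len(winners) > 1:
        logger.warning(
            "tie between persons %s for query %s; picking lowest id", winners, query
        )
    predicted = winners[0]
    return MatchResult(
        query_sample=query,
        query_site=qm.site,
        query_location=qm.location,
        query_timepoint=qm.timepoint,
        reference_timepoint=pool.timepoint,
        delay_hours=HOURS_PER_TIMEPOINT * (qm.timepoint - pool.timepoint),
        metric=metric,
        predicted_person=predicted,
        correct=predicted == qm.location,
    )


def evaluate_matching(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    metric: str = "canberra",
    query_sites: Iterable[str] | None = None,
    method: str = "person_mean",
) -> tuple[pd.DataFrame, list[MatchResult]]:
    """Attempt every (query sample, reference pool) combination.

    Returns the accuracy curve — rows of (query_site, delay_hours,
    n_attempts, n_correct, accuracy_percent) — and the per-attempt results.
    Delay is 12 h x (query timepoint - reference timepoint); negative means
    the query preceded the references.
    """
    if query_sites is None:
        query_sites = [s for s, c in SITE_CLASS.items() if c != "skin"]
    query_sites = set(query_sites)
    pools = build_reference_pools(table, metadata)
    meta = metadata_by_id(metadata)
    queries = [m for m in metadata if m.site in query_sites]
    if not queries:
        raise ValidationError(f"no query samples at sites {sorted(query_sites)}")

    # vectorised distances query x skin sample
    skin_ids = sorted({s for p in pools for ids in p.members.values() for s in ids})
    skin_index = {s: i for i, s in enumerate(skin_ids)}
    Q = table.data.loc[[m.sample_id for m in queries]].to_numpy(dtype=float)
    S = table.data.loc[skin_ids].to_numpy(dtype=float)
    D = _distance_matrix(Q, S, metric)

    results: list[MatchResult] = []
    for qi, qm in enumerate(queries):
        for pool in pools:
            scores: dict[int, float] = {}
            for person, ids in pool.members.items():
                d = D[qi, [skin_index[s] for s in ids]]
                scores[person] = float(d.mean()) if method == "person_mean" else float(d.min())
            best = min(scores.values())
            winners = sorted(p for p, v in scores.items() if v == best)
            if len(winners) > 1:
                logger.warning(
                    "tie between persons %s for query %s at reference t=%d",
                    winners, qm.sample_id, pool.timepoint,
                )
            predicted = winners[0]
            results.append(
                MatchResult(
                    query_sample=qm.sample_id,
                    query_site=qm.site,
                    query_location=qm.location,
                    query_timepoint=qm.timepoint,
                    reference_timepoint=pool.timepoint,
                    delay_hours=HOURS_PER_TIMEPOINT * (qm.timepoint - pool.timepoint),
                    metric=metric,
                    predicted_person=predicted,
                    correct=predicted == qm.location,
                )
            )
    curve = accuracy_curve(results)
    return curve, results


def accuracy_curve(results: Sequence[MatchResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "query_site": [r.query_site for r in results],
            "delay_hours": [r.delay_hours for r in results],
            "correct": [r.correct for r in results],
        }
    )
    curve = (
        df.groupby(["query_site", "delay_hours"])
        .agg(n_attempts=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    curve["accuracy_percent"] = 100.0 * curve["n_correct"] / curve["n_attempts"]
    return curve


def overall_accuracy(results: Sequence[MatchResult], site_class: str | None = None) -> float:
    """Percent correct over all attempts, optionally for one query site class."""
    sel = [
        r for r in results
        if site_class is None or SITE_CLASS[r.query_site] == site_class
    ]
    if not sel:
        raise ValidationError("no matching attempts selected")
    return 100.0 * sum(r.correct for r in sel) / len(sel)


# --------------------------------------------------------------------------
# delay and time-of-day statistics

@dataclass
class SpearmanResult:
    rho: float
    p: float
    valid: bool


def spearman_delay_accuracy(curve: pd.DataFrame, site: str) -> SpearmanResult:
    """Spearman correlation of matching accuracy against absolute delay.

    Attempts at +d and -d hours are pooled per absolute delay. Constant
    accuracy yields an undefined rho, flagged via ``valid=False``.
    """
    sub = curve[curve["query_site"] == site].copy()
    if sub.empty:
        raise ValidationError(f"no curve rows for site {site!r}")
    sub["abs_delay"] = sub["delay_hours"].abs()
    pooled = (
        sub.groupby("abs_delay")
        .agg(n_attempts=("n_attempts", "sum"), n_correct=("n_correct", "sum"))
        .reset_index()
    )
    if len(pooled) < 3:
        raise ValidationError("fewer than 3 distinct absolute delays")
    acc = 100.0 * pooled["n_correct"] / pooled["n_attempts"]
    if acc.nunique() == 1:
        return SpearmanResult(rho=float("nan"), p=float("nan"), valid=False)
    rho, p = stats.spearmanr(pooled["abs_delay"], acc)
    return SpearmanResult(rho=float(rho), p=float(p), valid=True)


def compare_accuracy_chisq(
    results_a: Sequence[MatchResult] | Sequence[bool],
    results_b: Sequence[MatchResult] | Sequence[bool],
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 correct/incorrect x group table.

    Continuity correction is off by default. Identical outcome sets give
    chi2 = 0, p = 1.
    """
    def outcomes(rs):
        return [r.correct if isinstance(r, MatchResult) else bool(r) for r in rs]

    a, b = outcomes(results_a), outcomes(results_b)
    if not a or not b:
        raise ValidationError("empty result list")
    tab = np.array(
        [[sum(a), len(a) - sum(a)], [sum(b), len(b) - sum(b)]], dtype=float
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p)


def time_of_day_accuracy(
    results: Sequence[MatchResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy stratified by (query period) x (reference period) per site
    class, with chi-squared AM-vs-PM comparisons for queries and references.

    Empty strata are reported with NaN accuracy. Returns (strata frame,
    tests frame).
    """
    if not results:
        raise ValidationError("no results")
    df = pd.DataFrame(
        {
            "site_class": [SITE_CLASS[r.query_site] for r in results],
            "query_period": [period_of_timepoint(r.query_timepoint) for r in results],
            "reference_period": [
                period_of_timepoint(r.reference_timepoint) for r in results
            ],
            "correct": [r.correct for r in results],
        }
    )
    strata_rows = []
    for cls in sorted(df["site_class"].unique()):
        for qp in ("AM", "PM"):
            for rp in ("AM", "PM"):
                sel = df[
                    (df["site_class"] == cls)
                    & (df["query_period"] == qp)
                    & (df["reference_period"] == rp)
                ]
                strata_rows.append(
                    {
                        "site_class": cls,
                        "query_period": qp,
                        "reference_period": rp,
                        "n_attempts": len(sel),
                        "n_correct": int(sel["correct"].sum()),
                        "accuracy_percent": (
                            100.0 * sel["correct"].mean() if len(sel) else np.nan
                        ),
                    }
                )
    strata = pd.DataFrame(strata_rows)

    test_rows = []
    for cls in sorted(df["site_class"].unique()):
        sub = df[df["site_class"] == cls]
        for axis in ("query_period", "reference_period"):
            am = sub.loc[sub[axis] == "AM", "correct"].tolist()
            pm = sub.loc[sub[axis] == "PM", "correct"].tolist()
            if am and pm:
                if 0 < (sum(am) + sum(pm)) < (len(am) + len(pm)):
                    chi2, p = compare_accuracy_chisq(am, pm)
                else:
                    # no outcome variation at all: the groups are
                    # indistinguishable, the chi-squared limit is 0
                    chi2, p = 0.0, 1.0
            else:
                chi2, p = np.nan, np.nan
            test_rows.append(
                {
                    "site_class": cls,
                    "comparison": axis,
                    "accuracy_am": 100.0 * np.mean(am) if am else np.nan,
                    "accuracy_pm": 100.0 * np.mean(pm) if pm else np.nan,
                    "chi2": chi2,
                    "p": p,
                }
            )
    return strata, pd.DataFrame(test_rows)


# --------------------------------------------------------------------------
# community-level tests

def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances (Anderson's sums-of-squares form)."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):  # perfect separation: F = inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    table_or_distances: AbundanceTable | pd.DataFrame | np.ndarray,
    grouping: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    metric: str = "bray_curtis",
) -> tuple[float, float]:
    """One-factor PERMANOVA on a distance matrix (computed from the table's
    Bray-Curtis distances when an AbundanceTable is given).

    p uses the +1 convention: (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValidationError("n_permutations must be >= 99")
    if isinstance(table_or_distances, AbundanceTable):
        D = pairwise_distances(table_or_distances, metric=metric).to_numpy()
    elif isinstance(table_or_distances, pd.DataFrame):
        D = table_or_distances.to_numpy(dtype=float)
    else:
        D = np.asarray(table_or_distances, dtype=float)
    labels = np.asarray(list(grouping))
    if len(labels) != D.shape[0]:
        raise ValidationError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    d2 = D**2
    f_obs = _permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return float(f_obs), float(p)


def indicator_source_profile(
    table: AbundanceTable, indicator_map: Mapping[str, str]
) -> pd.DataFrame:
    """Sum abundance per source category using a family → source map.

    Families not in the map contribute to ``unassigned``. Returns one row
    per sample with per-source sums and the top source.
    """
    if not indicator_map:
        raise ValidationError("empty indicator map")
    fam_table = aggregate_to_family(table)
    sources = sorted(set(indicator_map.values()))
    fam_of = {t.lineage: t.family for t in fam_table.taxa}
    out = pd.DataFrame(0.0, index=fam_table.samples, columns=sources + ["unassigned"])
    for lineage in fam_table.lineages:
        src = indicator_map.get(fam_of[lineage], "unassigned")
        out[src] += fam_table.data[lineage]
    out["top_source"] = out[sources + ["unassigned"]].idxmax(axis=1)
    return out.rename_axis("sample_id").reset_index()


def same_vs_different_location_test(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    surface_site: str,
) -> dict:
    """Are surface communities more similar (Bray-Curtis) to skin from the
    same location than to skin from other locations? Two-sided Mann-Whitney
    over all skin-surface pairs."""
    surface = [m for m in metadata if m.site == surface_site]
    skin = [m for m in metadata if m.site_class == "skin"]
    if not surface or not skin:
        raise ValidationError("need at least one surface and one skin sample")
    Sf = table.data.loc[[m.sample_id for m in surface]].to_numpy(dtype=float)
    Sk = table.data.loc[[m.sample_id for m in skin]].to_numpy(dtype=float)
    D = _distance_matrix(Sf, Sk, "bray_curtis")
    same, diff = [], []
    for i, ms in enumerate(surface):
        for j, mk in enumerate(skin):
            (same if ms.location == mk.location else diff).append(D[i, j])
    if not same or not diff:
        raise ValidationError("one of the pair groups is empty")
    u, p = stats.mannwhitneyu(same, diff, alternative="two-sided")
    return {
        "U": float(u),
        "p": float(p),
        "median_same_location": float(np.median(same)),
        "median_different_location": float(np.median(diff)),
        "n_same": len(same),
        "n_different": len(diff),
    }
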