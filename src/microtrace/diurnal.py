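"""Detection of diurnally varying species by seasonal decomposition.

Each abundance time series (one species at one site and location, 20 slots
= 10 days x AM/PM) is decomposed additively into trend, seasonal and random
components using the classical moving-average recipe, with a seasonal
period of 2 slots (one diurnal cycle). The strength of the seasonal
component is

    F_S = max(0, 1 - Var(R_t) / Var(S_t + R_t))

with sample variances (n-1 denominator) over the slots where the trend is
defined. Significance is assessed by permuting the abundances: p is the
proportion of permuted series whose F_S strictly exceeds the observed one.

The module also hosts the robustness re-analyses: removal of
negative-control species, single-species removal to probe compositional
(closure) artefacts, the paired signed-rank alternative test, and the
diurnal-vs-non-diurnal abundance comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import (
    AbundanceTable,
    SampleMetadata,
    SITE_CLASS,
    SITES,
    ValidationError,
    N_TIMEPOINTS,
    period_of_timepoint,
)

logger = logging.getLogger(__name__)

PRESENCE_MIN_TIMEPOINTS = 4


class SpeciesExcluded(Exception):
    """Signal that a species fails the presence filter (< 4 nonzero slots)."""


@dataclass
class AbundanceSeries:
    """A 20-slot-aligned abundance series for one (species, site, location).

    ``values`` is the trimmed, interpolated series; ``offset`` is the grid
    slot of its first element; ``periods`` holds the AM/PM label per element;
    ``imputed`` flags elements filled by seasonal-aware interpolation.
    """

    values: np.ndarray
    offset: int = 0
    species: str | None = None
    site: str | None = None
    location: int | None = None
    imputed: np.ndarray | None = None

    @property
    def periods(self) -> np.ndarray:
        return np.array(
            [period_of_timepoint(self.offset + i) for i in range(len(self.values))]
        )


@dataclass
class DecompositionResult:
    """Additive components plus (optionally filled) summary statistics."""

    seasonal: np.ndarray
    trend: np.ndarray
    random: np.ndarray
    period: int = 2
    fs: float | None = None
    p_perm: float | None = None
    peak_period: str | None = None
    am_pm_abundance_diff: float | None = None


# --------------------------------------------------------------------------
# series preparation

def seasonal_interpolate(values: np.ndarray, period: int = 2) -> np.ndarray:
    """Fill internal NaNs: deseasonalize by per-position means, linearly
    interpolate the residuals, re-add the position means.

    On a noiseless seasonal series the imputation is exact.
    """
    x = np.asarray(values, dtype=float).copy()
    n = len(x)
    pos = np.arange(n) % period
    means = np.full(period, np.nan)
    for p in range(period):
        obs = x[(pos == p) & ~np.isnan(x)]
        if obs.size:
            means[p] = obs.mean()
    if np.isnan(means).any():
        # a whole period position unobserved: fall back to the overall mean
        means[np.isnan(means)] = np.nanmean(x)
    resid = x - means[pos]
    idx = np.arange(n)
    obs_mask = ~np.isnan(resid)
    resid[~obs_mask] = np.interp(idx[~obs_mask], idx[obs_mask], resid[obs_mask])
    return resid + means[pos]


def prepare_series(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    species: str,
    site: str,
    location: int,
) -> AbundanceSeries:
    """Assemble the 20-slot series; trim end gaps; interpolate internal gaps.

    Raises :class:`SpeciesExcluded` if the species is present (abundance > 0)
    at fewer than 4 time points, mirroring the presence filter.
    """
    slots = np.full(N_TIMEPOINTS, np.nan)
    for m in metadata:
        if m.site == site and m.location == location:
            slots[m.timepoint] = table.data.at[m.sample_id, species]
    observed = ~np.isnan(slots)
    if not observed.any():
        raise ValidationError(
            f"no samples for site={site} location={location}"
        )
    n_present = int(np.sum(slots[observed] > 0))
    if n_present < PRESENCE_MIN_TIMEPOINTS:
        raise SpeciesExcluded(
            f"{species} present at {n_present} < {PRESENCE_MIN_TIMEPOINTS} time points"
        )
    first, last = np.flatnonzero(observed)[[0, -1]]
    window = slots[first : last + 1]
    imputed = np.isnan(window)
    if imputed.any():
        window = seasonal_interpolate(window, period=2)
    return AbundanceSeries(
        values=window,
        offset=int(first),
        species=species,
        site=site,
        location=location,
        imputed=imputed,
    )


# --------------------------------------------------------------------------
# decomposition

def _moving_average_trend(x: np.ndarray, period: int) -> np.ndarray:
    if period % 2 == 0:
        w = np.concatenate(([0.5], np.ones(period - 1), [0.5])) / period
    else:
        w = np.ones(period) / period
    half = len(w) // 2
    trend = np.full(len(x), np.nan)
    valid = np.convolve(x, w[::-1], mode="valid")
    trend[half : half + len(valid)] = valid
    return trend


def decompose(series: AbundanceSeries | np.ndarray, period: int = 2) -> DecompositionResult:
    """Classical additive decomposition by moving averages.

    For period 2 the trend is the centered 3-term average with weights
    (0.25, 0.5, 0.25); the seasonal figure is the per-position mean of the
    detrended series, centered to sum to zero and tiled; the random
    component is the remainder. The trend (hence the remainder) is
    undefined at the series ends.
    """
    x = series.values if isinstance(series, AbundanceSeries) else np.asarray(series, float)
    if len(x) < 2 * period:
        raise ValidationError(f"series of length {len(x)} too short for period {period}")
    trend = _moving_average_trend(x, period)
    detrended = x - trend
    pos = np.arange(len(x)) % period
    figure = np.empty(period)
    for p in range(period):
        vals = detrended[(pos == p) & ~np.isnan(detrended)]
        figure[p] = vals.mean()
    figure -= figure.mean()
    seasonal = figure[pos]
    random = x - trend - seasonal
    return DecompositionResult(seasonal=seasonal, trend=trend, random=random, period=period)


def seasonality_strength(decomp: DecompositionResult) -> float:
    """F_S = max(0, 1 - Var(R)/Var(S+R)) over slots with all components defined."""
    mask = ~np.isnan(decomp.random)
    if mask.sum() < 2:
        raise ValidationError("fewer than 2 slots with defined components")
    r = decomp.random[mask]
    sr = decomp.seasonal[mask] + r
    var_sr = np.var(sr, ddof=1)
    if var_sr == 0:
        return 0.0
    return float(max(0.0, 1.0 - np.var(r, ddof=1) / var_sr))


def _fs_rows(X: np.ndarray) -> np.ndarray:
    """Vectorised F_S for many period-2 series (rows of X, length >= 4)."""
    n = X.shape[1]
    trend = 0.25 * X[:, :-2] + 0.5 * X[:, 1:-1] + 0.25 * X[:, 2:]
    # detrended on interior slots 1..n-2; position parity relative to slot index
    interior = np.arange(1, n - 1)
    D = X[:, 1:-1] - trend
    fig = np.empty((X.shape[0], 2))
    for p in (0, 1):
        cols = interior % 2 == p
        fig[:, p] = D[:, cols].mean(axis=1)
    fig -= fig.mean(axis=1, keepdims=True)
    S = fig[:, interior % 2]
    R = D - S
    SR = S + R  # equals D
    var_r = np.var(R, axis=1, ddof=1)
    var_sr = np.var(SR, axis=1, ddof=1)
    fs = np.zeros(X.shape[0])
    ok = var_sr > 0
    fs[ok] = np.maximum(0.0, 1.0 - var_r[ok] / var_sr[ok])
    return fs


def permutation_test(
    series: AbundanceSeries | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    return_fs: bool = False,
):
    """Permutation p-value for F_S.

    The (interpolated) values are permuted uniformly over slots; each
    permuted series is decomposed and its F_S computed; p is the proportion
    of permutations with F_S strictly greater than the observed F_S (no +1
    correction, matching the plain proportion definition).
    """
    if n_permutations < 99:
        raise ValidationError("n_permutations must be >= 99")
    x = series.values if isinstance(series, AbundanceSeries) else np.asarray(series, float)
    fs_obs = _fs_rows(x[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    fs_perm = _fs_rows(perms)
    p = float(np.sum(fs_perm > fs_obs) / n_permutations)
    if return_fs:
        return p, fs_obs
    return p


# --------------------------------------------------------------------------
# catalog construction

def _series_summary(series: AbundanceSeries) -> tuple[str, float]:
    periods = series.periods
    am = series.values[periods == "AM"]
    pm = series.values[periods == "PM"]
    mean_am = am.mean() if am.size else np.nan
    mean_pm = pm.mean() if pm.size else np.nan
    peak = "AM" if mean_am >= mean_pm else "PM"
    return peak, float(abs(mean_am - mean_pm))


def detect_diurnal(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    species: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Run the F_S permutation test for every (species, site, location).

    Returns the full catalog — one row per combination passing the presence
    filter — with columns species, site, location, site_class, fs, p,
    peak_period, am_pm_diff, significant. Restrict to a species subset via
    ``species``.
    """
    lineages = list(species) if species is not None else table.lineages
    rng = np.random.default_rng(seed)
    combos = sorted({(m.site, m.location) for m in metadata})
    rows = []
    for site, loc in combos:
        for sp in lineages:
            try:
                ser = prepare_series(table, metadata, sp, site, loc)
            except SpeciesExcluded:
                continue
            if len(ser.values) < 4:
                continue
            sub_seed = int(rng.integers(0, 2**31 - 1))
            p, fs = permutation_test(
                ser, n_permutations=n_permutations, seed=sub_seed, return_fs=True
            )
            peak, diff = _series_summary(ser)
            rows.append(
                {
                    "species": sp,
                    "site": site,
                    "location": loc,
                    "site_class": SITE_CLASS[site],
                    "fs": fs,
                    "p": p,
                    "peak_period": peak,
                    "am_pm_diff": diff,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "site", "location", "site_class",
            "fs", "p", "peak_period", "am_pm_diff", "significant",
        ],
    )


def site_class_summary(catalog: pd.DataFrame) -> pd.DataFrame:
    """Per site class: proportion significant, mean F_S and mean AM/PM
    abundance difference among significant combinations."""
    rows = []
    for cls, grp in catalog.groupby("site_class"):
        sig = grp[grp["significant"]]
        rows.append(
            {
                "site_class": cls,
                "n_combinations": len(grp),
                "n_significant": len(sig),
                "proportion_significant": len(sig) / len(grp) if len(grp) else np.nan,
                "mean_fs_significant": sig["fs"].mean() if len(sig) else np.nan,
                "mean_am_pm_diff_significant": sig["am_pm_diff"].mean() if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# alternative paired test

def mann_whitney_alternative(series: AbundanceSeries) -> float:
    """Paired AM-vs-PM test: Wilcoxon signed-rank on per-day (AM, PM) pairs,
    two-sided, exact null distribution for n <= 25 pairs.

    Degenerate input (all AM == PM) returns p = 1 with a warning.
    """
    periods = series.periods
    days = (series.offset + np.arange(len(series.values))) // 2
    pairs = {}
    for d, per, v in zip(days, periods, series.values):
        pairs.setdefault(d, {})[per] = v
    am, pm = [], []
    for d in sorted(pairs):
        if "AM" in pairs[d] and "PM" in pairs[d]:
            am.append(pairs[d]["AM"])
            pm.append(pairs[d]["PM"])
    if len(am) < 4:
        raise ValidationError(f"only {len(am)} complete AM/PM day pairs (need >= 4)")
    diffs = np.asarray(am) - np.asarray(pm)
    if np.all(diffs == 0):
        warnings.warn("all AM/PM differences zero; degenerate paired test, p = 1")
        return 1.0
    method = "exact" if len(diffs) <= 25 else "auto"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(res.pvalue)


# --------------------------------------------------------------------------
# robustness re-analyses

def control_species_reanalysis(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    control_species: Iterable[str],
    baseline_catalog: pd.DataFrame | None = None,
    **detect_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Remove negative-control species, renormalize, re-run detection.

    Returns the new catalog plus a delta report: how many initially
    significant combinations were removed with the control species, lost
    significance after renormalization, or remained significant.
    """
    control = set(control_species)
    if baseline_catalog is None:
        baseline_catalog = detect_diurnal(table, metadata, **detect_kwargs)
    if not control:
        return baseline_catalog.copy(), {
            "n_removed": 0, "n_lost_significance": 0, "n_retained": 0,
        }
    reduced = table.drop_taxa(control)
    kept_meta = [m for m in metadata if m.sample_id in set(reduced.samples)]
    new_catalog = detect_diurnal(reduced, kept_meta, **detect_kwargs)
    base_sig = baseline_catalog[baseline_catalog["significant"]]
    removed = base_sig[base_sig["species"].isin(control)]
    survivors = base_sig[~base_sig["species"].isin(control)]
    new_sig_keys = set(
        map(tuple, new_catalog.loc[new_catalog["significant"],
                                   ["species", "site", "location"]].to_numpy())
    )
    retained = survivors[
        [tuple(r) in new_sig_keys
         for r in survivors[["species", "site", "location"]].to_numpy()]
    ]
    report = {
        "n_removed": int(len(removed)),
        "n_lost_significance": int(len(survivors) - len(retained)),
        "n_retained": int(len(retained)),
    }
    return new_catalog, report


def compositional_reanalysis(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    site: str,
    location: int,
    species_to_remove: str,
    baseline_catalog: pd.DataFrame | None = None,
    **detect_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe a closure artefact: drop one species at one (site, location),
    renormalize those samples, and re-run detection for the rest there.

    Returns (catalog restricted to the site/location after removal, delta
    frame listing species whose significance changed).
    """
    local = [m for m in metadata if m.site == site and m.location == location]
    if not local:
        raise ValidationError(f"no samples at site={site} location={location}")
    local_ids = [m.sample_id for m in local]
    if species_to_remove not in table.data.columns or not (
        table.data.loc[local_ids, species_to_remove] > 0
    ).any():
        raise ValidationError(
            f"{species_to_remove} absent at site={site} location={location}"
        )
    sub = table.subset_samples(local_ids).drop_taxa([species_to_remove])
    kept_meta = [m for m in local if m.sample_id in set(sub.samples)]
    if baseline_catalog is None:
        base_local = detect_diurnal(
            table.subset_samples(local_ids), local, **detect_kwargs
        )
    else:
        base_local = baseline_catalog[
            (baseline_catalog["site"] == site)
            & (baseline_catalog["location"] == location)
        ]
    new_catalog = detect_diurnal(sub, kept_meta, **detect_kwargs)
    merged = base_local[base_local["species"] != species_to_remove][
        ["species", "significant"]
    ].merge(
        new_catalog[["species", "significant"]],
        on="species", how="outer", suffixes=("_before", "_after"),
    )
    merged = merged.fillna({"significant_before": False, "significant_after": False})
    delta = merged[merged["significant_before"] != merged["significant_after"]]
    return new_catalog, delta.reset_index(drop=True)


def diurnal_vs_nondiurnal_abundance(
    catalog: pd.DataFrame,
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
) -> dict:
    """Compare abundance of diurnal vs non-diurnal combinations.

    For each catalog row, the mean relative abundance of the species at its
    (site, location) is computed excluding samples where it is absent; a
    two-sided Mann-Whitney compares significant vs non-significant rows, and
    Spearman's rho relates abundance to F_S among the significant rows.
    """
    if catalog.empty:
        raise ValidationError("empty catalog")
    by_coord: dict[tuple[str, int], list[str]] = {}
    for m in metadata:
        by_coord.setdefault((m.site, m.location), []).append(m.sample_id)
    mean_abund = []
    for r in catalog.itertuples():
        ids = by_coord.get((r.site, r.location), [])
        vals = table.data.loc[ids, r.species].to_numpy()
        vals = vals[vals > 0]
        mean_abund.append(vals.mean() if vals.size else np.nan)
    cat = catalog.assign(mean_abundance=mean_abund).dropna(subset=["mean_abundance"])
    diurnal = cat.loc[cat["significant"], "mean_abundance"]
    nondiurnal = cat.loc[~cat["significant"], "mean_abundance"]
    if diurnal.empty or nondiurnal.empty:
        raise ValidationError("one of the groups (diurnal / non-diurnal) is empty")
    u, p = stats.mannwhitneyu(diurnal, nondiurnal, alternative="two-sided")
    sig = cat[cat["significant"]]
    if len(sig) >= 3 and sig["fs"].nunique() > 1:
        rho, rho_p = stats.spearmanr(sig["mean_abundance"], sig["fs"])
    else:
        rho, rho_p = np.nan, np.nan
    return {
        "U": float(u),
        "p": float(p),
        "mean_abundance_diurnal": float(diurnal.mean()),
        "mean_abundance_nondiurnal": float(nondiurnal.mean()),
        "spearman_rho_abundance_fs": float(rho) if rho == rho else np.nan,
        "spearman_p": float(rho_p) if rho_p == rho_p else np.nan,
    }
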