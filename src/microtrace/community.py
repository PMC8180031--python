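"""Data model and I/O for relative-abundance tables on the study grid.

The sampling design is 4 residential locations, each with six sites (two
palms, two household surfaces, two public handrails near the residence),
swabbed every morning and evening for 10 days: a grid of 20 time slots per
(location, site). Sequencing failures leave holes in the grid; a missing
sample is represented by the *absence* of a metadata row, never by a
zero-filled column.

Abundances are MetaPhlAn-style relative abundances in percent (rows sum to
100), with taxa identified by their full lineage string
``k__...|p__...|f__...|s__...``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six sampled sites, in canonical order.
SITES: tuple[str, ...] = (
    "left_palm",
    "right_palm",
    "bed_headboard",
    "door_knob",
    "public_handrail",
    "subway_handrail",
)

#: Fixed site → site-class mapping: palms are skin, headboard/door knob are
#: household surfaces, handrails are public surfaces.
SITE_CLASS: dict[str, str] = {
    "left_palm": "skin",
    "right_palm": "skin",
    "bed_headboard": "household",
    "door_knob": "household",
    "public_handrail": "public",
    "subway_handrail": "public",
}

SITE_CLASSES: tuple[str, ...] = ("skin", "household", "public")

PERIODS: tuple[str, str] = ("AM", "PM")

N_TIMEPOINTS = 20  # 10 days x {AM, PM}

ROW_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when input data violate the study-grid contract."""


def timepoint_of(day: int, period: str) -> int:
    """Map (day 1-10, AM/PM) onto the 0-19 slot index."""
    return 2 * (day - 1) + (0 if period == "AM" else 1)


def period_of_timepoint(timepoint: int) -> str:
    return "AM" if timepoint % 2 == 0 else "PM"


def day_of_timepoint(timepoint: int) -> int:
    return timepoint // 2 + 1


@dataclass(frozen=True)
class SampleMetadata:
    """Coordinates of one sample on the spatiotemporal grid.

    For skin samples person identity equals ``location``: each residence is
    occupied by a single person.
    """

    sample_id: str
    location: int
    site: str
    day: int
    period: str

    def __post_init__(self) -> None:
        if self.site not in SITE_CLASS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown site label {self.site!r}; "
                f"expected one of {sorted(SITE_CLASS)}"
            )
        if not 1 <= int(self.day) <= 10:
            raise ValidationError(
                f"sample {self.sample_id!r}: day {self.day} outside 1-10"
            )
        if self.period not in PERIODS:
            raise ValidationError(
                f"sample {self.sample_id!r}: period {self.period!r} not AM/PM"
            )
        if int(self.location) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: location must be a positive integer"
            )

    @property
    def site_class(self) -> str:
        return SITE_CLASS[self.site]

    @property
    def timepoint(self) -> int:
        return timepoint_of(self.day, self.period)

    @property
    def person(self) -> int | None:
        """Person identity; defined only for skin samples."""
        return self.location if self.site_class == "skin" else None


@dataclass(frozen=True)
class Taxon:
    """A taxon identified by its lineage; ``rank`` is species or family."""

    lineage: str
    name: str
    family: str
    phylum: str
    rank: str

    @classmethod
    def from_lineage(cls, lineage: str) -> "Taxon":
        parts = dict(
            p.split("__", 1) for p in lineage.split("|") if "__" in p
        )
        if "s" in parts:
            rank = "species"
            name = parts["s"]
        elif "f" in parts:
            rank = "family"
            name = parts["f"]
        else:
            raise ValidationError(
                f"lineage {lineage!r} has neither species (s__) nor family (f__) level"
            )
        family = parts.get("f", "")
        phylum = parts.get("p", "")
        if rank == "species" and (not family or not phylum):
            raise ValidationError(
                f"species lineage {lineage!r} lacks family or phylum annotation"
            )
        return cls(lineage=lineage, name=name, family=family, phylum=phylum, rank=rank)


class AbundanceTable:
    """Samples x taxa relative abundances (percent), taxa as lineage strings.

    Backed by a pandas DataFrame with sample ids as the index and full
    lineage strings as columns. Rows are renormalized to sum to 100 on
    construction.
    """

    def __init__(self, data: pd.DataFrame, normalize: bool = True):
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxa: {dupes}")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("abundance table contains NaN values")
        if (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundance in samples {bad}")
        row_sums = values.sum(axis=1)
        if (row_sums <= 0).any():
            bad = data.index[row_sums <= 0].tolist()
            raise ValidationError(f"samples with zero total abundance: {bad}")
        if normalize:
            values = values * (100.0 / row_sums[:, None])
        self.data = pd.DataFrame(values, index=data.index, columns=data.columns)
        self.taxa: list[Taxon] = [Taxon.from_lineage(c) for c in data.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def lineages(self) -> list[str]:
        return list(self.data.columns)

    @property
    def rank(self) -> str:
        ranks = {t.rank for t in self.taxa}
        return ranks.pop() if len(ranks) == 1 else "mixed"

    def values_for(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], normalize=False)

    def drop_taxa(self, lineages: Iterable[str]) -> "AbundanceTable":
        """Remove taxa and renormalize remaining rows to 100.

        Samples emptied by the removal are dropped with a warning.
        """
        drop = [l for l in lineages if l in self.data.columns]
        kept = self.data.drop(columns=drop)
        sums = kept.sum(axis=1)
        empty = sums[sums <= 0].index.tolist()
        if empty:
            warnings.warn(
                f"removal of {len(drop)} taxa emptied samples {empty}; dropping them",
                stacklevel=2,
            )
            kept = kept.drop(index=empty)
        return AbundanceTable(kept, normalize=True)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AbundanceTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"AbundanceTable({len(self.samples)} samples x {len(self.taxa)} taxa)"


def aggregate_to_family(table: AbundanceTable) -> AbundanceTable:
    """Sum species abundances within each taxonomic family.

    A family-rank table is returned unchanged. Per-sample totals are
    preserved exactly (grouped summation).
    """
    if table.rank == "family":
        return table
    missing = [t.lineage for t in table.taxa if not t.family]
    if missing:
        raise ValidationError(f"species without family annotation: {missing}")
    fam_lineage = {}
    for t in table.taxa:
        kingdom = t.lineage.split("|", 1)[0]
        fam_lineage[t.lineage] = f"{kingdom}|p__{t.phylum}|f__{t.family}"
    grouped = table.data.T.groupby(
        [fam_lineage[l] for l in table.lineages]
    ).sum().T
    return AbundanceTable(grouped, normalize=False)


def read_abundance_table(
    path: str | Path, metadata_path: str | Path
) -> tuple[AbundanceTable, list[SampleMetadata]]:
    """Read a taxa-rows x sample-columns abundance TSV plus metadata TSV.

    The abundance file's first column holds lineage strings; the metadata
    file has one row per sample with columns sample_id, location, site, day,
    period. Rows are renormalized to 100; every sample column must appear in
    exactly one metadata row.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    table = AbundanceTable(raw.T, normalize=True)

    meta_df = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "location", "site", "day", "period"}
    if not required.issubset(meta_df.columns):
        raise ValidationError(
            f"metadata missing columns {sorted(required - set(meta_df.columns))}"
        )
    if meta_df["sample_id"].duplicated().any():
        dupes = meta_df.loc[meta_df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"samples with multiple metadata rows: {dupes}")
    metadata = [
        SampleMetadata(
            sample_id=str(r.sample_id),
            location=int(r.location),
            site=str(r.site),
            day=int(r.day),
            period=str(r.period),
        )
        for r in meta_df.itertuples()
    ]
    known = {m.sample_id for m in metadata}
    orphans = [s for s in table.samples if s not in known]
    if orphans:
        raise ValidationError(f"samples in abundance table but not metadata: {orphans}")
    metadata = [m for m in metadata if m.sample_id in set(table.samples)]
    return table, metadata


def write_abundance_table(
    table: AbundanceTable, metadata: Sequence[SampleMetadata],
    path: str | Path, metadata_path: str | Path,
) -> None:
    """Write the taxa-rows abundance TSV and the metadata TSV."""
    table.data.T.rename_axis("lineage").to_csv(path, sep="\t")
    rows = [
        {
            "sample_id": m.sample_id,
            "location": m.location,
            "site": m.site,
            "day": m.day,
            "period": m.period,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def write_results_table(records, path: str | Path) -> None:
    """Write any tabular result (DataFrame, or list of dataclasses/dicts) as TSV."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("writing empty results table to %s (header only)", path)
    df.to_csv(path, sep="\t", index=False)


def metadata_by_id(metadata: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {m.sample_id: m for m in metadata}


def samples_matching(
    metadata: Sequence[SampleMetadata],
    *,
    location: int | None = None,
    site: str | None = None,
    site_class: str | None = None,
    timepoint: int | None = None,
    period: str | None = None,
) -> list[SampleMetadata]:
    """Filter metadata rows by grid coordinates."""
    out = []
    for m in metadata:
        if location is not None and m.location != location:
            continue
        if site is not None and m.site != site:
            continue
        if site_class is not None and m.site_class != site_class:
            continue
        if timepoint is not None and m.timepoint != timepoint:
            continue
        if period is not None and m.period != period:
            continue
        out.append(m)
    return out
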