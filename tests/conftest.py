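import numpy as np
import pandas as pd
import pytest

from microtrace.community import AbundanceTable, SampleMetadata
from microtrace.synthetic import SyntheticConfig, generate


def make_table(values: dict[str, list[float]], lineages: list[str]) -> AbundanceTable:
    """Build an AbundanceTable from sample -> abundance-row mapping."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=lineages)
    return AbundanceTable(df, normalize=True)


LINEAGES_3 = [
    "k__Bacteria|p__P1|f__F1|s__S1",
    "k__Bacteria|p__P1|f__F1|s__S2",
    "k__Bacteria|p__P2|f__F2|s__S3",
]


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study grid (2 locations, 40 species)."""
    cfg = SyntheticConfig(
        n_locations=2, n_species=40, n_signature_per_location=4,
        n_diurnal_per_site=3, missing_prob=0.0, seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default-condition dataset (4 locations, 150 species)."""
    return generate(SyntheticConfig(seed=1))


def grid_metadata(n_locations=1, sites=("left_palm",), timepoints=range(20)):
    """Complete metadata grid for hand-built tables."""
    meta = []
    for loc in range(1, n_locations + 1):
        for site in sites:
            for t in timepoints:
                day, period = t // 2 + 1, ("AM" if t % 2 == 0 else "PM")
                meta.append(
                    SampleMetadata(
                        sample_id=f"L{loc}_{site}_T{t:02d}",
                        location=loc, site=site, day=day, period=period,
                    )
                )
    return meta
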