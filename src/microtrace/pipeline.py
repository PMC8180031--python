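"""End-to-end orchestration: simulate → match → diurnal → dbn.

A single :class:`PipelineConfig` (constructible from a YAML file or from
defaults) drives every stage; all outputs are TSV plus one JSON manifest
recording the configuration hash, the seeds used and the content hash of
every written file, so a second run with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .community import (
    AbundanceTable,
    SampleMetadata,
    ValidationError,
    read_abundance_table,
    write_abundance_table,
    write_results_table,
)
from .synthetic import SyntheticConfig, generate
from .matching import (
    evaluate_matching,
    overall_accuracy,
    time_of_day_accuracy,
    permanova,
)
from .diurnal import detect_diurnal, site_class_summary
from .dbn import learn_all, summarize_edges
from .community import SITE_CLASS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic generation is the default input."""

    abundance_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    seed: int = 0
    metric: str = "canberra"
    alpha: float = 0.05
    n_permutations: int = 999
    permanova_permutations: int = 999
    dbn_restarts: int = 5
    dbn_metric: str = "bdeu"
    out_dir: str = "microtrace_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if (self.abundance_path is None) != (self.metadata_path is None):
            raise ValidationError(
                "abundance_path and metadata_path must be given together"
            )
        for p in (self.abundance_path, self.metadata_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if self.n_permutations < 99 or self.permanova_permutations < 99:
            raise ValidationError("permutation counts must be >= 99")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, write per-stage TSVs and a run manifest.

    Returns the manifest dict. Any stage failure is re-raised with the
    stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }

    stage = "input"
    try:
        if config.abundance_path is not None:
            table, metadata = read_abundance_table(
                config.abundance_path, config.metadata_path
            )
            truth = None
        else:
            syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
            table, metadata, truth = generate(syn)
            write_abundance_table(
                table, metadata, out / "abundance.tsv", out / "metadata.tsv"
            )
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(
                    {
                        "signature_species": {
                            str(k): sorted(v) for k, v in truth.signature_species.items()
                        },
                        "diurnal_species": {
                            f"{site}|{loc}": pairs
                            for (site, loc), pairs in truth.diurnal_species.items()
                        },
                        "dispersal_edges": truth.dispersal_edges,
                    },
                    fh, indent=2, sort_keys=True,
                )
        manifest["stages"]["input"] = {
            "n_samples": len(table.samples), "n_taxa": len(table.taxa),
        }

        stage = "matching"
        curve, results = evaluate_matching(table, metadata, metric=config.metric)
        write_results_table(results, out / "match_results.tsv")
        write_results_table(curve, out / "accuracy_curve.tsv")
        strata, tod_tests = time_of_day_accuracy(results)
        write_results_table(strata, out / "time_of_day_accuracy.tsv")
        write_results_table(tod_tests, out / "time_of_day_tests.tsv")
        f_obs, p_amppm = permanova(
            table,
            [m.period for m in metadata],
            n_permutations=config.permanova_permutations,
            seed=config.seed,
        )
        manifest["stages"]["matching"] = {
            "metric": config.metric,
            "accuracy_household_percent": overall_accuracy(results, "household"),
            "accuracy_public_percent": overall_accuracy(results, "public"),
            "permanova_pseudo_f_am_pm": f_obs,
            "permanova_p_am_pm": p_amppm,
        }

        stage = "diurnal"
        catalog = detect_diurnal(
            table, metadata,
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        write_results_table(catalog, out / "diurnal_catalog.tsv")
        summary = site_class_summary(catalog)
        write_results_table(summary, out / "diurnal_summary.tsv")
        manifest["stages"]["diurnal"] = {
            "n_combinations": int(len(catalog)),
            "n_significant": int(catalog["significant"].sum()),
        }

        stage = "dbn"
        models = learn_all(
            table, metadata,
            metric=config.dbn_metric,
            n_restarts=config.dbn_restarts,
            seed=config.seed,
        )
        model_rows = pd.DataFrame(
            [
                {
                    "location": m.location, "family": m.family,
                    "n_edges": m.n_edges, "score": m.score,
                    "edges": ";".join(f"{p}->{c}" for p, c in m.edges),
                }
                for m in models
            ]
        )
        write_results_table(model_rows, out / "dbn_models.tsv")
        summary_e = summarize_edges(models)
        write_results_table(
            summary_e.class_pair_counts.rename_axis("parent_class").reset_index(),
            out / "dbn_edge_summary.tsv",
        )
        manifest["stages"]["dbn"] = {
            "n_models": summary_e.n_models,
            "fraction_with_edges": (
                summary_e.n_models_with_edges / summary_e.n_models
            ),
            "total_edges": summary_e.total_edges,
            "most_common_edge_type": summary_e.most_common_edge_type,
        }
    except ValidationError:
        raise
    except Exception as exc:  # attach stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name == "manifest.json":
            continue
        manifest["files"][f.name] = _sha256(f)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
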