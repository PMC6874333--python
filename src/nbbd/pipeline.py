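"""End-to-end pipeline: data -> phenotype networks -> node scores -> selected
features -> trained/evaluated classifier, with every artifact written to disk
and a manifest sufficient to replay the run.

Outputs are deterministic given the config (fixed seeds, no timestamps), so
two runs from one config file produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import evaluate, train_rf
from .networks import build_mb, build_proxi, build_rmt, build_sparcc, write_edge_list
from .ntps import PROPERTIES, ntps_score, ntps_score_table
from .otu import (OTUTable, nested_subsets, read_otu_table, split_by_phenotype,
                  write_metadata, write_otu_table)
from .resilience import MEASURES, optimize_all
from .selection import hybrid_score, rffi, select_top_k
from .simulate import GeneratorParams, make_benchmark

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

NETWORK_BUILDERS = {
    "proxi": build_proxi,
    "sparcc": build_sparcc,
    "mb": build_mb,
    "rmt": build_rmt,
}


@dataclass
class RunConfig:
    """Settings for one pipeline run; round-trips losslessly through YAML."""

    out_dir: str = "nbbd_run"
    # data: either paths to a table+metadata, or synthetic generator settings
    table_path: str | None = None
    metadata_path: str | None = None
    label_column: str = "label"
    simulate: dict = field(default_factory=dict)  # GeneratorParams overrides
    # analysis
    network_method: str = "proxi"
    network_params: dict = field(default_factory=dict)
    scoring: str = "ntps"           # "ntps", "cass" or "hybrid"
    property_name: str = "btw"      # for ntps / hybrid
    measure: str = "vat"            # for cass
    k: int = 10
    n_per_group_fs: int | None = None  # feature-selection subset size
    n_trees: int = 500
    seed: int = 7

    def validate(self) -> None:
        if self.network_method not in NETWORK_BUILDERS:
            raise ValueError(f"unknown network method: {self.network_method!r}")
        if self.scoring not in ("ntps", "cass", "hybrid"):
            raise ValueError(f"unknown scoring: {self.scoring!r}")
        if self.scoring in ("ntps", "hybrid") and self.property_name not in PROPERTIES:
            raise ValueError(f"unknown property: {self.property_name!r}")
        if self.scoring == "cass" and self.measure not in MEASURES:
            raise ValueError(f"unknown measure: {self.measure!r}")
        if self.table_path is not None and not Path(self.table_path).exists():
            raise FileNotFoundError(self.table_path)
        if self.metadata_path is not None and not Path(self.metadata_path).exists():
            raise FileNotFoundError(self.metadata_path)
        if self.table_path is not None and self.metadata_path is None:
            raise ValueError("a table_path requires a metadata_path with labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_table(config: RunConfig) -> OTUTable:
    if config.table_path is not None:
        return read_otu_table(config.table_path, metadata=config.metadata_path,
                              label_column=config.label_column)
    params = GeneratorParams(seed=config.seed, **config.simulate)
    return make_benchmark(params).table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status_path = out / "status.json"
    from . import __version__ as version
    manifest: dict = {"nbbd_version": version,
                      "config": dataclasses.asdict(config)}
    try:
        table = _load_table(config)
        write_otu_table(table, out / "table.tsv")
        write_metadata(table, out / "metadata.tsv")

        # feature-selection subset (FSDS): optionally a nested class-balanced
        # draw; feature ranking happens on it, training on the full table.
        if config.n_per_group_fs is not None:
            fsds = nested_subsets(table, [config.n_per_group_fs],
                                  seed=config.seed)[0]
        else:
            fsds = table
        group_a, group_b = split_by_phenotype(fsds)
        builder = NETWORK_BUILDERS[config.network_method]
        g_a = builder(group_a, **config.network_params)
        g_b = builder(group_b, **config.network_params)
        labels = sorted(table.labels.unique())
        write_edge_list(g_a, out / f"network_{labels[0]}.tsv")
        write_edge_list(g_b, out / f"network_{labels[1]}.tsv")
        manifest["networks"] = {labels[0]: g_a.number_of_edges(),
                                labels[1]: g_b.number_of_edges()}

        if config.scoring == "cass":
            results_a = optimize_all(g_a)
            results_b = optimize_all(g_b)
            shared = sorted(results_a[config.measure].attack_set
                            & results_b[config.measure].attack_set)
            attack = {
                labels[0]: {m: sorted(r.attack_set) for m, r in results_a.items()},
                labels[1]: {m: sorted(r.attack_set) for m, r in results_b.items()},
            }
            (out / "attack_sets.json").write_text(
                json.dumps(attack, indent=2, sort_keys=True) + "\n")
            features = shared
            scores = {t: 1.0 for t in shared}
            _write_scores(out / "scores.tsv", scores, config.scoring)
        else:
            scores = ntps_score(g_a, g_b, config.property_name)
            ntps_score_table(g_a, g_b, config.property_name).to_csv(
                out / "scores.tsv", sep="\t", float_format="%.10g")
            if config.scoring == "hybrid":
                forest_scores = rffi(fsds, n_trees=config.n_trees,
                                     seed=config.seed)
                scores = hybrid_score(forest_scores, scores)
            features = select_top_k(scores, min(config.k, len(scores)),
                                    method=config.scoring).ranked_taxa

        (out / "selected_features.txt").write_text(
            "\n".join(features) + ("\n" if features else ""))
        manifest["n_selected"] = len(features)

        if features:
            model = train_rf(table, features, n_trees=config.n_trees,
                             seed=config.seed)
            report = evaluate(model, table)  # resubstitution report
            manifest["resubstitution"] = report.as_dict()
            with open(out / "report.tsv", "w") as fh:
                d = report.as_dict()
                keys = ["n_features", "acc", "sn", "sp", "mcc", "auc"]
                fh.write("\t".join(keys) + "\n")
                fh.write("\t".join(_fmt(d[k]) for k in keys) + "\n")
        else:
            manifest["resubstitution"] = None
            (out / "report.tsv").write_text("status\nno_features\n")

        manifest["status"] = "ok"
        status_path.write_text(json.dumps({"status": "ok"}) + "\n")
    except Exception as exc:
        status_path.write_text(
            json.dumps({"status": "error", "error": str(exc)}) + "\n")
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_scores(path: Path, scores: dict[str, float], method: str) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tmethod\tscore\n")
        for t in sorted(scores):
            fh.write(f"{t}\t{method}\t{scores[t]:.10g}\n")
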