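"""End-to-end pipeline: cohort -> covariance networks -> null-normalized
metrics -> group statistics, with every intermediate written to disk.

All randomness is driven by explicit seeds in the config; a rerun with an
identical config is bit-identical. Every output table carries provenance
headers (config hash, seed, stage) and the run writes a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graphmetrics import normalized_metrics
from .groupstats import (demographics_tests, network_metric_anova,
                         regional_ancova, regional_correspondence)
from .io import (read_morphometry_tables, read_subjects_table, write_covariance_matrix,
                 write_long_table, write_subjects_table, write_table)
from .netbuild import DensityGrid, build_covariance_network, min_connected_density
from .synthetic import CELLS, Cohort, CohortConfig, generate_cohort

log = logging.getLogger("morphnet")


def _cell_key(group: str, field: str) -> str:
    return f"{group}_{field}"


@dataclass
class PipelineConfig:
    """Everything a run needs; serializes losslessly to YAML/JSON."""

    cohort: CohortConfig | None = dc_field(default_factory=CohortConfig)
    input_long_table: str | None = None     # alternative to the synthetic cohort
    input_subjects_table: str | None = None
    grid: DensityGrid = dc_field(default_factory=DensityGrid)
    n_null: int = 100
    n_restarts: int = 20
    ranking: str = "signed"
    q_level: float = 0.05
    alpha: float = 0.05
    correspondence_pooling: str = "region_by_subject"
    seed: int = 0
    output_dir: str = "morphnet_run"

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_long_table is None:
            raise ValueError("config needs either a synthetic cohort or an input table")
        if self.ranking not in ("signed", "absolute"):
            raise ValueError("ranking must be 'signed' or 'absolute'")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            c = d["cohort"]
            n = self.cohort.n_subjects_per_cell
            if not isinstance(n, int):
                c["n_subjects_per_cell"] = {_cell_key(g, f): int(v)
                                            for (g, f), v in n.items()}
            c["region_labels"] = list(self.cohort.region_labels)
            for key in ("ct_baseline", "gwc_baseline"):
                if isinstance(c[key], np.ndarray):
                    c[key] = c[key].tolist()
            c["within_module_corr"] = dict(c["within_module_corr"])
            c["between_module_corr"] = dict(c["between_module_corr"])
            c["age_range"] = list(c["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            c = dict(d["cohort"])
            n = c.get("n_subjects_per_cell")
            if isinstance(n, dict):
                c["n_subjects_per_cell"] = {tuple(k.split("_")): int(v)
                                            for k, v in n.items()}
            if c.get("region_labels") is not None:
                c["region_labels"] = tuple(c["region_labels"])
            if c.get("age_range") is not None:
                c["age_range"] = tuple(c["age_range"])
            for key in ("ct_baseline", "gwc_baseline"):
                if isinstance(c.get(key), list):
                    c[key] = np.asarray(c[key], dtype=float)
            d["cohort"] = CohortConfig(**c)
        if isinstance(d.get("grid"), dict):
            d["grid"] = DensityGrid(**d["grid"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(config: PipelineConfig):
    if config.input_long_table is not None:
        tables = read_morphometry_tables(config.input_long_table, dialect="long_tsv")
        table_map = {(t.measure, t.group, t.field): t for t in tables}
        subjects = (read_subjects_table(config.input_subjects_table)
                    if config.input_subjects_table else None)
        return table_map, subjects, None
    cohort = generate_cohort(config.cohort)
    return dict(cohort.tables), cohort.subjects, cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``output_dir``.

    Returns a dict of artifact paths plus the in-memory results. Fails at
    the network stage, with the suggested minimum printed, if the grid
    starts below the minimum fully-connected density of any cell.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.seed,
            "morphnet_version": __version__}
    artifacts: dict = {"output_dir": str(out)}

    # stage 1: cohort ------------------------------------------------------
    table_map, subjects, cohort = _load_tables(config)
    measures = sorted({m for (m, _, _) in table_map})
    cells = sorted({(g, f) for (_, g, f) in table_map})
    if cohort is not None:
        long = cohort.to_long()
        artifacts["morphometry_long"] = str(write_long_table(
            long, out / "tables" / "morphometry_long.tsv", {**prov, "stage": "simulate"}))
    if subjects is not None:
        artifacts["subjects"] = str(write_subjects_table(
            subjects, out / "tables" / "subjects.tsv", {**prov, "stage": "simulate"}))
    log.info("stage simulate/load done (%.1fs): %d tables", time.time() - t0,
             len(table_map))

    # stage 2: covariance networks ----------------------------------------
    networks = {}
    for (measure, group, field), table in sorted(table_map.items()):
        net = build_covariance_network(table)
        d_min = min_connected_density(net, grid_resolution=config.grid.step,
                                      ranking=config.ranking)
        if d_min > config.grid.min_density + 1e-12:
            raise ValueError(
                f"network stage failed for ({measure}, {group}, {field}): grid "
                f"minimum {config.grid.min_density} leaves the graph disconnected; "
                f"minimum fully-connected density is {d_min}")
        networks[(measure, group, field)] = net
        artifacts[f"cov_{measure}_{_cell_key(group, field)}"] = str(
            write_covariance_matrix(
                net, out / "networks" / f"cov_{measure}_{_cell_key(group, field)}.tsv",
                {**prov, "stage": "network", "measure": measure,
                 "cell": _cell_key(group, field)}))
    log.info("stage network done (%.1fs): %d networks", time.time() - t0, len(networks))

    # stage 3: null-normalized metrics ------------------------------------
    metric_frames = []
    for idx, ((measure, group, field), net) in enumerate(sorted(networks.items())):
        net_seed = int(np.random.SeedSequence([config.seed, idx]).generate_state(1)[0]
                       % (2 ** 31))
        rec = normalized_metrics(net, grid=config.grid, n_null=config.n_null,
                                 seed=net_seed, n_restarts=config.n_restarts,
                                 ranking=config.ranking)
        rec.insert(0, "measure", measure)
        rec.insert(1, "group", group)
        rec.insert(2, "field", field)
        rec.insert(3, "cell", _cell_key(group, field))
        metric_frames.append(rec)
    metrics = pd.concat(metric_frames, ignore_index=True)
    artifacts["metrics"] = str(write_table(
        metrics, out / "metrics" / "metrics.tsv", {**prov, "stage": "metrics"}))
    log.info("stage metrics done (%.1fs)", time.time() - t0)

    # stage 4: statistics --------------------------------------------------
    stats_results: dict = {}
    anova = network_metric_anova(metrics, q_level=config.q_level, alpha=config.alpha)
    stats_results["network_anova"] = anova
    flat = anova.copy()
    flat["posthoc"] = flat["posthoc"].map(
        lambda ph: "; ".join(f"{a}-{b}: d={d['difference']:+.4g} p={d['p_adj']:.3g}"
                             f"{'*' if d['significant'] else ''}"
                             for (a, b), d in ((p["pair"], p) for p in ph)))
    artifacts["network_anova"] = str(write_table(
        flat, out / "stats" / "network_anova.tsv", {**prov, "stage": "stats"}))

    if subjects is not None:
        for measure in measures:
            tables = [table_map[(measure, g, f)] for (g, f) in cells]
            anc = regional_ancova(tables, subjects, q_level=config.q_level,
                                  alpha=config.alpha)
            stats_results[f"ancova_{measure}"] = anc
            flat = anc.drop(columns="posthoc")
            artifacts[f"ancova_{measure}"] = str(write_table(
                flat, out / "stats" / f"regional_ancova_{measure}.tsv",
                {**prov, "stage": "stats"}))
        demo = demographics_tests(subjects)
        stats_results["demographics"] = demo
        artifacts["demographics"] = str(write_table(
            demo.drop(columns="expected"), out / "stats" / "demographics.tsv",
            {**prov, "stage": "stats"}))

    corr_rows = []
    for measure in measures:
        for group in sorted({g for (g, _) in cells}):
            pair = [(m, g, f) for (m, g, f) in table_map if m == measure and g == group]
            if len(pair) == 2:
                (m, g, f1), (_, _, f2) = sorted(pair, key=lambda k: k[2])
                try:
                    res = regional_correspondence(
                        table_map[(m, g, f1)], table_map[(m, g, f2)],
                        pooling=config.correspondence_pooling)
                except ValueError:
                    log.warning(
                        "correspondence: %s/%s subject sets differ across fields; "
                        "falling back to region_means pooling", measure, group)
                    res = regional_correspondence(
                        table_map[(m, g, f1)], table_map[(m, g, f2)],
                        pooling="region_means")
                corr_rows.append({"measure": measure, "group": group,
                                  "pooling": config.correspondence_pooling,
                                  "r": res.r, "p": res.p, "n_points": res.n_points,
                                  "slope": res.slope, "intercept": res.intercept})
    if corr_rows:
        corr = pd.DataFrame(corr_rows)
        stats_results["correspondence"] = corr
        artifacts["correspondence"] = str(write_table(
            corr, out / "stats" / "correspondence.tsv", {**prov, "stage": "stats"}))
    log.info("stage stats done (%.1fs)", time.time() - t0)

    # manifest + report ----------------------------------------------------
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "seed": config.seed, "morphnet_version": __version__,
                "artifacts": {k: v for k, v in artifacts.items() if k != "results"},
                "runtime_s": round(time.time() - t0, 2)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = str(out / "manifest.json")

    lines = [f"morphnet run {config.config_hash()} (seed {config.seed})", ""]
    for _, row in anova.iterrows():
        lines.append(f"{row['measure'] or ''} {row['metric']}: "
                     f"F({row['df1']},{row['df2']}) = {row['F']:.2f}, "
                     f"p = {row['p']:.3g}, q = {row['q']:.3g}"
                     f"{' *' if row['reject'] else ''}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    artifacts["report"] = str(out / "report.txt")
    artifacts["results"] = {"metrics": metrics, **stats_results}
    return artifacts
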