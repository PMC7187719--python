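"""Tabular input/output: long/wide morphometry tables, FreeSurfer-style
stats tables, covariance matrices and metrics tables (all TSV)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import desikan_killiany_labels, normalize_region_label
from .morphometry import RegionalMorphometryTable
from .netbuild import CovarianceNetwork

log = logging.getLogger("morphnet")

LONG_COLUMNS = ["subject_id", "group", "field", "measure", "region", "value"]

DIALECTS = ("long_tsv", "wide_tsv", "freesurfer_stats")

_FS_SUFFIXES = {"_thickness": "CT", "_pctmean": "GWc", "_gwc": "GWc"}


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_long_table(long: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Write a long-format morphometry table (columns subject_id, group,
    field, measure, region, value) as TSV with ``#`` provenance headers."""
    path = Path(path)
    missing = [c for c in LONG_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"long table missing columns {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        long[LONG_COLUMNS].to_csv(fh, sep="\t", index=False)
    return path


def write_subjects_table(subjects: pd.DataFrame, path,
                         provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        subjects.to_csv(fh, sep="\t", index=False)
    return path


def read_subjects_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _tables_from_long(long: pd.DataFrame, valid_regions) -> list[RegionalMorphometryTable]:
    missing = [c for c in LONG_COLUMNS if c not in long.columns]
    if missing:
        raise ValueError(f"long table missing required columns {missing}")
    long = long.copy()
    long["region"] = long["region"].map(normalize_region_label)
    unknown = sorted(set(long["region"]) - set(valid_regions)) if valid_regions else []
    if unknown:
        log.warning("unrecognized region labels (kept as-is): %s", unknown)
    tables = []
    for (measure, group, field), block in long.groupby(
            ["measure", "group", "field"], sort=True):
        dup = block.duplicated(["subject_id", "region"])
        if dup.any():
            pairs = block.loc[dup, ["subject_id", "region"]].values.tolist()
            raise ValueError(f"duplicate (subject, region) entries: {pairs[:5]}")
        wide = block.pivot(index="subject_id", columns="region", values="value")
        if wide.isna().any().any():
            holes = [(s, r) for s, r in zip(*np.where(wide.isna().to_numpy()))]
            named = [(wide.index[s], wide.columns[r]) for s, r in holes[:5]]
            raise ValueError(f"incomplete table: missing (subject, region) pairs {named}")
        wide.columns.name = None
        if valid_regions and set(wide.columns) <= set(valid_regions):
            wide = wide[[r for r in valid_regions if r in wide.columns]]
        tables.append(RegionalMorphometryTable(
            values=wide, measure=measure, group=group, field=field))
    return tables


def read_morphometry_tables(
    path,
    dialect: str = "long_tsv",
    measure: str | None = None,
    group: str | None = None,
    field: str | None = None,
    region_labels: list[str] | None = None,
) -> list[RegionalMorphometryTable]:
    """Read regional morphometry tables from TSV.

    Dialects: ``long_tsv`` (subject_id/group/field/measure/region/value,
    may hold several cells), ``wide_tsv`` (subject_id + one column per
    region; measure/group/field given as arguments) and
    ``freesurfer_stats`` (aparc-style per-region summary table whose
    column names carry a measure suffix such as ``lh_bankssts_thickness``).
    Region names are normalized onto the bundled 68-label list;
    unrecognized labels are reported (and, for freesurfer_stats, the
    non-regional bookkeeping columns are dropped).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    valid = region_labels if region_labels is not None else desikan_killiany_labels()

    if dialect == "long_tsv":
        return _tables_from_long(pd.read_csv(path, sep="\t", comment="#"), valid)

    raw = pd.read_csv(path, sep="\t", comment="#")
    id_col = raw.columns[0]
    if dialect == "wide_tsv":
        if measure is None:
            raise ValueError("wide_tsv needs an explicit measure")
        wide = raw.set_index(id_col)
        wide.index.name = "subject_id"
        wide.columns = [normalize_region_label(c) for c in wide.columns]
        unknown = sorted(set(wide.columns) - set(valid))
        if unknown:
            log.warning("unrecognized region labels (kept as-is): %s", unknown)
        return [RegionalMorphometryTable(values=wide, measure=measure,
                                         group=group, field=field)]

    # freesurfer_stats: strip measure suffixes, drop non-atlas columns
    wide = raw.set_index(id_col)
    wide.index.name = "subject_id"
    keep, dropped = {}, []
    inferred = None
    for col in wide.columns:
        name = normalize_region_label(col)
        for suffix, meas in _FS_SUFFIXES.items():
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                inferred = inferred or meas
                break
        if name in valid:
            keep[col] = name
        else:
            dropped.append(col)
    if dropped:
        log.warning("dropping non-regional columns: %s", dropped)
    if not keep:
        raise ValueError("no atlas region columns recognized")
    wide = wide[list(keep)].rename(columns=keep)
    measure = measure or inferred
    if measure is None:
        raise ValueError("could not infer the measure; pass measure= explicitly")
    return [RegionalMorphometryTable(values=wide, measure=measure,
                                     group=group, field=field)]


def read_morphometry_table(path, dialect: str = "long_tsv", **kwargs
                           ) -> RegionalMorphometryTable:
    """Read a single-cell morphometry table (errors if the file holds several)."""
    tables = read_morphometry_tables(path, dialect=dialect, **kwargs)
    if len(tables) != 1:
        cells = [(t.measure, t.group, t.field) for t in tables]
        raise ValueError(f"expected a single table, file holds {cells}")
    return tables[0]


def write_covariance_matrix(net: CovarianceNetwork, path,
                            provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(net.matrix, index=net.region_labels,
                         columns=net.region_labels)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, sep="\t", index_label="region")
    return path


def read_covariance_matrix(path, **net_kwargs) -> CovarianceNetwork:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CovarianceNetwork(matrix=frame.to_numpy(dtype=float),
                             region_labels=list(frame.columns), **net_kwargs)


def write_graph_edgelist(g, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = g.graph.get("region_labels")
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("source\ttarget\n")
        for i, j in sorted(g.edges()):
            if labels:
                fh.write(f"{labels[i]}\t{labels[j]}\n")
            else:
                fh.write(f"{i}\t{j}\n")
    return path


def write_graph_matrix(g, path, provenance: dict | None = None) -> Path:
    """Write a binary graph as a square 0/1 adjacency matrix (TSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = g.number_of_nodes()
    labels = g.graph.get("region_labels") or list(range(n))
    adj = np.zeros((n, n), dtype=int)
    for i, j in g.edges():
        adj[i, j] = adj[j, i] = 1
    frame = pd.DataFrame(adj, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, sep="\t", index_label="region")
    return path


def write_table(frame: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Generic TSV writer with provenance headers (metrics, stats tables)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        frame.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_volume(path) -> np.ndarray:
    """Load a 3-D volume (NIfTI via nibabel, or .npy) as a float array."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(float)
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
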