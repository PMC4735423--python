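"""Plain-text readers and writers for every pipeline artefact.

All formats are tab-separated or JSON so outputs diff cleanly under
version control.  Floats are serialised with ``%.12g``, which round-trips
to 12 significant digits — enough for byte-identical re-runs under a
fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .metrics import TopologyProfile
from .networks import (
    ROIFeatureTable,
    SubjectConnectivityMatrix,
    ThresholdedGraph,
)

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _split_checked(lines: list, path, expected: int | None = None) -> list:
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if expected is None:
            expected = len(parts)
        if len(parts) != expected:
            raise ParseError(
                f"{path}: line {lineno} has {len(parts)} fields, expected {expected}"
            )
        rows.append((lineno, parts))
    return rows


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: not a number: {token!r}") from None
    if np.isnan(v):
        raise ParseError(f"{path}: line {lineno}: NaN value")
    return v


# -- feature tables ---------------------------------------------------------


def write_feature_table(table: ROIFeatureTable, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("subject\tgroup\t" + "\t".join(table.region_names) + "\n")
        for sid, grp, row in zip(table.subject_ids, table.group_labels, table.values):
            fh.write(f"{sid}\t{grp}\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_feature_table(path, feature: str = "feature") -> ROIFeatureTable:
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    if not lines:
        raise ParseError(f"{path}: empty file")
    rows = _split_checked(lines, path)
    header = rows[0][1]
    if header[:2] != ["subject", "group"]:
        raise ParseError(f"{path}: line 1: header must start 'subject<TAB>group'")
    region_names = header[2:]
    sids, grps, vals = [], [], []
    for lineno, parts in rows[1:]:
        sids.append(parts[0])
        grps.append(parts[1])
        vals.append([_parse_float(t, path, lineno) for t in parts[2:]])
    return ROIFeatureTable(
        subject_ids=sids,
        group_labels=grps,
        region_names=region_names,
        values=np.array(vals, dtype=float),
        feature=feature,
    )


# -- connectivity matrices --------------------------------------------------


def write_matrix(matrix: SubjectConnectivityMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("region\t" + "\t".join(matrix.region_names) + "\n")
        for name, row in zip(matrix.region_names, matrix.counts):
            fh.write(name + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_matrix(
    path, normalized: bool = False, symmetric: bool = False, subject_id: str = ""
) -> SubjectConnectivityMatrix:
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    if not lines:
        raise ParseError(f"{path}: empty file")
    rows = _split_checked(lines, path)
    region_names = rows[0][1][1:]
    n = len(region_names)
    if len(rows) - 1 != n:
        raise ParseError(
            f"{path}: {len(rows) - 1} data rows for {n} regions in header"
        )
    counts = np.empty((n, n))
    for r, (lineno, parts) in enumerate(rows[1:]):
        if parts[0] != region_names[r]:
            raise ParseError(
                f"{path}: line {lineno}: row label {parts[0]!r} does not match "
                f"header region {region_names[r]!r}"
            )
        counts[r] = [_parse_float(t, path, lineno) for t in parts[1:]]
    return SubjectConnectivityMatrix(
        region_names=region_names,
        counts=counts,
        normalized=normalized,
        symmetric=symmetric,
        subject_id=subject_id or path.stem,
    )


# -- thresholded graphs -----------------------------------------------------


def write_edge_list(graph: ThresholdedGraph, path) -> None:
    """Edge list with a structured header recording the densities."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# target_density\t{_fmt(graph.target_density)}\n")
        fh.write(f"# achieved_density\t{_fmt(graph.achieved_density)}\n")
        fh.write(f"# n_nodes\t{graph.n_nodes}\n")
        iu, ju = np.nonzero(np.triu(graph.adjacency, k=1))
        for i, j in zip(iu, ju):
            fh.write(f"{graph.region_names[i]}\t{graph.region_names[j]}\n")


def read_edge_list(path, region_names: list) -> ThresholdedGraph:
    path = Path(path)
    target = None
    index = {name: k for k, name in enumerate(region_names)}
    n = len(region_names)
    adjacency = np.zeros((n, n), dtype=np.int8)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "target_density":
                target = float(parts[1])
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        try:
            i, j = index[parts[0]], index[parts[1]]
        except KeyError as e:
            raise ParseError(f"{path}: line {lineno}: unknown region {e}") from None
        adjacency[i, j] = adjacency[j, i] = 1
    if target is None:
        raise ParseError(f"{path}: missing '# target_density' header")
    return ThresholdedGraph(
        region_names=list(region_names), adjacency=adjacency, target_density=target
    )


# -- topology profiles ------------------------------------------------------


def write_profiles(profiles: list, path) -> None:
    """Long-format TSV: entity, metric, density, value."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("entity\tmetric\tdensity\tvalue\n")
        for p in profiles:
            for name in sorted(p.metrics):
                for d, v in zip(p.densities, p.metrics[name]):
                    fh.write(f"{p.entity_id}\t{name}\t{_fmt(d)}\t{_fmt(v)}\n")


def read_profiles(path) -> list:
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    rows = _split_checked(lines, path, expected=4)
    if not rows or rows[0][1] != ["entity", "metric", "density", "value"]:
        raise ParseError(f"{path}: line 1: bad profile header")
    data: dict = {}
    for lineno, (ent, met, d, v) in ((ln, p) for ln, p in rows[1:]):
        data.setdefault(ent, {}).setdefault(met, []).append(
            (_parse_float(d, path, lineno), _parse_float(v, path, lineno))
        )
    profiles = []
    for ent, metrics in data.items():
        densities = None
        series = {}
        for met, pairs in metrics.items():
            ds = np.array([d for d, _ in pairs])
            if densities is None:
                densities = ds
            elif not np.allclose(ds, densities):
                raise ParseError(f"{path}: entity {ent!r} has inconsistent densities")
            series[met] = np.array([v for _, v in pairs])
        profiles.append(
            TopologyProfile(entity_id=ent, densities=densities, metrics=series)
        )
    return profiles


# -- structured text (truth, config, reports, manifest) ---------------------


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
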