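"""Readers and writers for the plain-text interchange formats.

Time courses: TSV, first column the variable id, header row the (floating
point, strictly increasing) time stamps; one file per condition.
Topology: SIF-style TSV, one ``parent<TAB>child`` edge per line; ``#``
comments and blank lines allowed.

Floats are serialized with 12 significant digits so reader(writer(x))
round-trips byte-stably for canonically formatted files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .timecourse import SuperPathwayTopology, TimeCourseSet

__all__ = [
    "read_timecourse", "write_timecourse",
    "read_topology", "write_topology",
    "write_json",
]

_FMT = "%.12g"


def read_timecourse(path, condition_label: str | None = None) -> TimeCourseSet:
    """Parse a time-course TSV into a TimeCourseSet."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:
        raise ParseError(f"cannot read TSV: {exc}", path=path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise ParseError(f"duplicate variable id(s): {', '.join(map(str, dup))}",
                         path=path)
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"non-numeric time stamp in header: {exc}",
                         path=path, line=1)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise ParseError(
            f"time stamps not strictly increasing at column "
            f"'{df.columns[bad[0] + 1]}'", path=path, line=1)
    values = np.empty(df.shape, dtype=float)
    for i, (vid, row) in enumerate(df.iterrows()):
        converted = pd.to_numeric(row, errors="coerce")
        if converted.isna().any():
            col = row.index[converted.isna().argmax()]
            raise ParseError(
                f"non-numeric value for variable '{vid}' at time '{col}'",
                path=path, line=i + 2)
        values[i] = converted.to_numpy()
    return TimeCourseSet(condition_label or path.stem, times, values,
                         [str(v) for v in df.index])


def write_timecourse(tc: TimeCourseSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("variable\t" + "\t".join(_FMT % t for t in tc.times) + "\n")
        for vid in tc.variable_ids:
            row = tc.series(vid)
            fh.write(vid + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def read_topology(path) -> SuperPathwayTopology:
    """Parse a SIF-style parent<TAB>child edge list."""
    path = Path(path)
    edges = []
    nodes = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 1:  # isolated node declaration
                nodes.add(parts[0])
                continue
            if len(parts) != 2:
                raise ParseError(
                    f"expected 'parent<TAB>child', got {len(parts)} fields",
                    path=path, line=lineno)
            edges.append((parts[0], parts[1]))
            nodes.update(parts)
    if not edges and not nodes:
        warnings.warn(f"empty topology file: {path}", stacklevel=2)
        return SuperPathwayTopology([])
    uniq = sorted(set(edges))
    if len(uniq) < len(edges):
        warnings.warn(f"{len(edges) - len(uniq)} duplicate edge(s) removed",
                      stacklevel=2)
    return SuperPathwayTopology(sorted(nodes), uniq)


def write_topology(topology: SuperPathwayTopology, path) -> None:
    with open(path, "w") as fh:
        for parent, child in sorted(topology.edges):
            fh.write(f"{parent}\t{child}\n")
        # isolated nodes round-trip as single-field lines
        isolated = set(topology.nodes) - {n for e in topology.edges for n in e}
        for n in sorted(isolated):
            fh.write(f"{n}\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
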