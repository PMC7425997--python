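"""Read connectome edge lists, apply the connection filters, build records.

Input contract (plain CSV, UTF-8, header required):

* edges:    ``pre_id,post_id,synapse_count`` — one row per (pre, post)
  observation; duplicate pairs are summed.
* metadata: ``neuron_id,cell_type,side,claw_count`` — ``side`` in
  {left, right, unknown}; ``claw_count`` may be empty.

Filtering follows the analysis conventions for mushroom-body wiring
diagrams: connections with fewer than ``min_synapses`` synapses are
discarded (single-synapse contacts are unreliable in EM reconstructions;
``min_synapses=1`` restores them as a robustness variant), and connections
to/from configured partner classes (e.g. the APL interneuron, dopaminergic
and octopaminergic modulatory neurons) are excluded.  A neuron's degree
``K`` is its number of retained distinct partners in the chosen direction
and ``Sbar`` the summed synapse count over those retained connections —
i.e. ``Sbar`` counts post-filter synapses only, preserving
``Sbar >= min_synapses * K``.  Neurons with no retained partner are
omitted: the degree models are zero-truncated because such neurons are
unobservable in these data.  Left/right homologues are kept as separate
records.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .evidence import NeuronRecord

__all__ = [
    "read_edges",
    "read_metadata",
    "build_records",
    "group_records",
]

EDGE_COLUMNS = ("pre_id", "post_id", "synapse_count")
METADATA_COLUMNS = ("neuron_id", "cell_type", "side", "claw_count")
_SIDES = {"left", "right", "unknown"}


def read_edges(path) -> pd.DataFrame:
    """Parse and aggregate an edge-list CSV.

    Duplicate ``(pre_id, post_id)`` rows are summed.  Raises ``ValueError``
    naming the offending row for missing columns or non-positive counts.
    """
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge file {path} lacks required column(s): {missing}")
    counts = pd.to_numeric(df["synapse_count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 1) | (counts != counts.round())]
    if len(bad):
        raise ValueError(
            f"edge file {path}: synapse_count must be a positive integer "
            f"(first bad row: {int(bad[0]) + 2} counting the header)")
    df["synapse_count"] = counts.astype(int)
    agg = (df.groupby(["pre_id", "post_id"], as_index=False, sort=True)["synapse_count"]
           .sum())
    return agg


def read_metadata(path) -> pd.DataFrame:
    """Parse a neuron-metadata CSV, indexed by ``neuron_id``."""
    df = pd.read_csv(path, dtype={"neuron_id": str, "cell_type": str, "side": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks required column(s): {missing}")
    if df["neuron_id"].duplicated().any():
        dup = df["neuron_id"][df["neuron_id"].duplicated()].iloc[0]
        raise ValueError(f"metadata file {path}: duplicate neuron_id {dup!r}")
    bad_side = set(df["side"].fillna("unknown")) - _SIDES
    if bad_side:
        raise ValueError(f"metadata file {path}: unknown side value(s) {sorted(bad_side)}")
    df["side"] = df["side"].fillna("unknown")
    df["claw_count"] = pd.to_numeric(df["claw_count"], errors="coerce").astype("Int64")
    return df.set_index("neuron_id", drop=False)


def build_records(
    edges: pd.DataFrame,
    metadata: pd.DataFrame,
    direction: str = "out",
    min_synapses: int = 2,
    excluded_types: Iterable[str] = (),
) -> list[NeuronRecord]:
    """Filter connections and reduce to per-neuron (K, Sbar) records.

    ``direction='out'``: K counts a neuron's retained postsynaptic partners;
    ``'in'`` is symmetric.  Excluded cell types are removed as *partners*
    (the focal neuron keeps its record as long as any partner survives).
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    excluded = set(excluded_types)

    ids = set(metadata.index)
    endpoints = set(edges["pre_id"]) | set(edges["post_id"])
    unknown = sorted(endpoints - ids)
    if unknown:
        raise ValueError(f"edge endpoints missing from metadata: {unknown[:10]}"
                         + (" ..." if len(unknown) > 10 else ""))

    focal_col, partner_col = ("pre_id", "post_id") if direction == "out" else ("post_id", "pre_id")
    kept = edges[edges["synapse_count"] >= min_synapses]
    types = metadata["cell_type"]
    if excluded:
        partner_type = kept[partner_col].map(types)
        focal_type = kept[focal_col].map(types)
        kept = kept[~partner_type.isin(excluded) & ~focal_type.isin(excluded)]

    grouped = kept.groupby(focal_col)["synapse_count"].agg(["count", "sum"])
    records = [
        NeuronRecord(neuron_id=str(nid), cell_type=str(types[nid]),
                     degree=int(row["count"]), total_synapses=int(row["sum"]))
        for nid, row in grouped.iterrows()
    ]
    records.sort(key=lambda r: r.neuron_id)
    return records


GroupSpec = Mapping[str, "set[str] | Callable[[pd.Series], bool]"]


def group_records(
    records: Sequence[NeuronRecord],
    metadata: pd.DataFrame | None = None,
    grouping: GroupSpec | None = None,
) -> dict[str, list[NeuronRecord]]:
    """Partition records by cell type, or by an explicit grouping scheme.

    ``grouping`` maps a group label to either a set of cell-type labels
    (composite groups like ``{"single-claw", "multi-claw"}`` are allowed) or
    a predicate over the neuron's metadata row (e.g. ``claw_count >= 3``);
    predicates require ``metadata``.  With ``grouping=None`` each base cell
    type becomes its own group.  Empty groups are returned empty, but a
    label naming a cell type absent from the data is an error.
    """
    if grouping is None:
        out: dict[str, list[NeuronRecord]] = {}
        for r in records:
            out.setdefault(r.cell_type, []).append(r)
        return out

    known_types = {r.cell_type for r in records}
    if metadata is not None:
        known_types |= set(metadata["cell_type"])
    out = {}
    for label, spec in grouping.items():
        if callable(spec):
            if metadata is None:
                raise ValueError(f"group {label!r} uses a predicate but no metadata given")
            out[label] = [r for r in records
                          if r.neuron_id in metadata.index and spec(metadata.loc[r.neuron_id])]
        else:
            unknown = set(spec) - known_types
            if unknown:
                raise ValueError(f"group {label!r} names unknown cell type(s) {sorted(unknown)}")
            out[label] = [r for r in records if r.cell_type in spec]
    return out
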