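"""Synthetic per-neuron datasets with the statistical structure the fits assume.

Each neuron gets a total synapse count ``Sbar`` from a configurable law and
a degree ``K`` drawn from a chosen degree family conditioned on ``Sbar`` (or
on ``(N, q)`` for the binomial null, which ignores ``Sbar``).  The default
preset is larva-like: 110 neurons and a discretized lognormal ``Sbar`` with
log-mean 4.5 and log-sd 0.5 (median ~90 synapses), emulating the observed
heterogeneity of Kenyon-cell synapse counts without claiming to reproduce
any particular reconstruction.

Randomness contract: one master seed; each neuron consumes an independent
substream spawned deterministically from it, so draws do not depend on
iteration order.

``generate_edge_list`` additionally materializes each record as an edge list
(synapses distributed over ``K`` distinct partners, each connection getting
at least ``min_synapses``) plus a metadata table, written in the same CSV
dialect that :mod:`flexdegree.connectome_io` reads — a round-trip fixture
for the whole ingestion pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .degree_models import DegreeModel, Family, sample_degree
from .evidence import NeuronRecord

__all__ = [
    "SbarLaw",
    "SyntheticConfig",
    "larva_like_config",
    "generate_records",
    "generate_edge_list",
]


@dataclass(frozen=True)
class SbarLaw:
    """Law for per-neuron total synapse counts, discretized to integers >= 1.

    kinds: ``lognormal(log_mean, log_sd)``, ``empirical(values)``,
    ``constant(value)``.
    """

    kind: Literal["lognormal", "empirical", "constant"] = "lognormal"
    log_mean: float = 4.5
    log_sd: float = 0.5
    values: tuple[int, ...] = ()
    value: int = 0

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "lognormal":
            s = int(round(math.exp(rng.normal(self.log_mean, self.log_sd))))
        elif self.kind == "empirical":
            if not self.values:
                raise ValueError("empirical law needs values")
            s = int(rng.choice(np.asarray(self.values)))
        elif self.kind == "constant":
            s = int(self.value)
        else:
            raise ValueError(f"unknown sbar law {self.kind!r}")
        if s < 1:
            raise ValueError(f"sbar law produced {s} < 1")
        return s


@dataclass(frozen=True)
class SyntheticConfig:
    family: Family = Family.FIXED_AREA
    alpha: float | None = 0.25
    N: int | None = None
    q: float | None = None
    n_neurons: int = 110
    sbar_law: SbarLaw = field(default_factory=SbarLaw)
    scaling_exponent: float = 0.0
    seed: int = 0
    cell_type_label: str = "synthetic"
    min_synapses: int = 2
    infeasible_policy: Literal["resample", "error"] = "resample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")

    def model(self) -> DegreeModel:
        if self.family is Family.BINOMIAL:
            return DegreeModel(self.family, N=self.N, q=self.q)
        return DegreeModel(self.family, alpha=self.alpha)


def larva_like_config(**overrides) -> SyntheticConfig:
    """The default study-condition preset (see module docstring)."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _draw_neuron(config: SyntheticConfig, model: DegreeModel,
                 rng: np.random.Generator, index: int) -> NeuronRecord:
    max_tries = 1000
    for _ in range(max_tries):
        sbar = config.sbar_law.draw(rng)
        if model.family is Family.BINOMIAL:
            K = sample_degree(model, None, rng)
        else:
            K = sample_degree(model, float(sbar), rng)
        if model.family is Family.BINOMIAL or sbar >= K * config.min_synapses:
            return NeuronRecord(f"n{index:05d}", config.cell_type_label,
                                degree=K, total_synapses=max(sbar, K))
        if config.infeasible_policy == "error":
            raise ValueError(
                f"neuron {index}: Sbar={sbar} cannot host K={K} connections "
                f"of >= {config.min_synapses} synapses")
    raise RuntimeError(f"neuron {index}: no feasible (K, Sbar) in {max_tries} tries")


def generate_records(config: SyntheticConfig) -> list[NeuronRecord]:
    """Draw ``n_neurons`` records, reproducibly from ``config.seed``."""
    model = config.model()
    rngs = _substreams(config.seed, max(config.n_neurons, 1))
    return [_draw_neuron(config, model, rngs[i], i) for i in range(config.n_neurons)]


def generate_edge_list(
    config: SyntheticConfig,
    partner_pool_size: int,
    n_decoy_partners: int = 0,
    decoy_type: str = "excluded-decoy",
) -> tuple[pd.DataFrame, pd.DataFrame, list[NeuronRecord]]:
    """Materialize records as (edges, metadata) tables plus the records.

    Focal neurons project onto a shared pool of ``partner_pool_size``
    postsynaptic partners: each record's ``Sbar`` synapses are spread over
    ``K`` distinct partners with every connection receiving at least
    ``min_synapses`` (the remainder multinomially).  Optional decoy edges
    onto ``n_decoy_partners`` partners of an excludable cell type exercise
    the type filter without perturbing the recoverable (K, Sbar).
    Reading the tables back through :func:`connectome_io.build_records`
    (direction='out', same ``min_synapses``, decoy type excluded) recovers
    the generated records exactly.
    """
    records = generate_records(config)
    max_K = max((r.degree for r in records), default=0)
    if partner_pool_size < max_K:
        raise ValueError(
            f"partner_pool_size={partner_pool_size} < max sampled degree {max_K}")

    rngs = _substreams(config.seed ^ 0x5EED, max(len(records), 1))
    pool = [f"p{j:05d}" for j in range(partner_pool_size)]
    decoys = [f"d{j:05d}" for j in range(n_decoy_partners)]
    rows: list[tuple[str, str, int]] = []
    for i, rec in enumerate(records):
        rng = rngs[i]
        partners = rng.choice(partner_pool_size, size=rec.degree, replace=False)
        extra = rec.total_synapses - rec.degree * config.min_synapses
        if extra < 0:
            raise ValueError("record infeasible for the configured min_synapses")
        alloc = rng.multinomial(extra, np.full(rec.degree, 1.0 / rec.degree))
        for j, a in zip(partners, alloc):
            rows.append((rec.neuron_id, pool[j], config.min_synapses + int(a)))
        for d in decoys:
            rows.append((rec.neuron_id, d, 1 + int(rng.integers(0, 5))))
    edges = pd.DataFrame(rows, columns=["pre_id", "post_id", "synapse_count"])

    meta_rows = ([(r.neuron_id, r.cell_type, "unknown", pd.NA) for r in records]
                 + [(p, "partner", "unknown", pd.NA) for p in pool]
                 + [(d, decoy_type, "unknown", pd.NA) for d in decoys])
    metadata = pd.DataFrame(meta_rows,
                            columns=["neuron_id", "cell_type", "side", "claw_count"])
    metadata["claw_count"] = metadata["claw_count"].astype("Int64")
    metadata = metadata.set_index("neuron_id", drop=False)
    return edges, metadata, records
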