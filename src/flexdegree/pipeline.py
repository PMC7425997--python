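"""End-to-end comparison pipeline: fits, evidences, log odds, marginals.

For each group of neurons (cell type × direction) the pipeline fits every
degree family, computes Laplace evidences under one or both priors, and
tabulates all pairwise log odds with the conservative interval convention
(the fixed-weight family's evidence is an interval, so its odds are reported
as lower/upper bounds).  Raw log odds are reported with no multiplicity
correction, matching how such comparisons are normally read.  Reports are
deterministic functions of (inputs, config): serializing the same analysis
twice yields identical bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint_geometry import Norm
from .degree_models import DegreeModel, Family, marginal_pmf
from .evidence import (EvidenceResult, FitResult, ModelComparison, NeuronRecord,
                       fit_alpha_bounded, fit_alpha_fixed, fit_q_binomial,
                       log_evidence_flat, log_evidence_jeffreys, log_odds,
                       records_to_arrays)

__all__ = [
    "PipelineConfig",
    "GroupResult",
    "ComparisonReport",
    "pearson_r",
    "compare_group",
    "run_comparison",
]


@dataclass(frozen=True)
class PipelineConfig:
    direction: str = "out"
    min_synapses: int = 2
    excluded_types: tuple[str, ...] = ()
    binomial_N: int | None = None          # None -> infer from the partner pool
    priors: tuple[str, ...] = ("flat",)
    include_manhattan: bool = False        # 1-norm fixed model is a variant analysis
    marginal_k_max: int | None = None
    seed: int = 0


def pearson_r(records: Sequence[NeuronRecord]) -> float:
    """Sample Pearson correlation between Sbar and K; NaN if undefined."""
    if len(records) < 2:
        return math.nan
    K, S = records_to_arrays(records)
    if np.ptp(K) == 0 or np.ptp(S) == 0:
        return math.nan
    K = K - K.mean()
    S = S - S.mean()
    return float(np.dot(S, K) / math.sqrt(np.dot(S, S) * np.dot(K, K)))


def _infer_binomial_N(records: Sequence[NeuronRecord],
                      metadata: pd.DataFrame | None,
                      excluded_types: Sequence[str]) -> int:
    """Potential-partner count for the binomial null.

    With metadata: the number of non-excluded neurons in the dataset (every
    traced neuron is a potential partner).  Without metadata no anatomical
    census is available and twice the largest observed degree is used as a
    documented fallback.
    """
    if metadata is not None:
        eligible = metadata[~metadata["cell_type"].isin(set(excluded_types))]
        return int(len(eligible))
    return 2 * max(r.degree for r in records)


def _evidence(fit: FitResult, records: Sequence[NeuronRecord], prior: str) -> EvidenceResult | None:
    try:
        if prior == "flat":
            return log_evidence_flat(fit, records)
        return log_evidence_jeffreys(fit, records)
    except ValueError:
        return None  # e.g. Jeffreys at a degenerate boundary fit


@dataclass
class GroupResult:
    label: str
    n_records: int
    pearson: float
    fits: dict[str, FitResult]
    evidences: dict[str, dict[str, EvidenceResult]]     # prior -> family -> result
    odds: dict[str, dict[str, ModelComparison]]         # prior -> "a_vs_b" -> result
    marginals: dict[str, np.ndarray]
    marginal_support: np.ndarray
    degenerate: bool = False


def compare_group(records: Sequence[NeuronRecord], *, N: int,
                  priors: Sequence[str] = ("flat",),
                  include_manhattan: bool = False,
                  marginal_k_max: int | None = None,
                  with_marginals: bool = True,
                  label: str = "all") -> GroupResult:
    """Fit all families on one group and assemble every pairwise comparison."""
    K, S = records_to_arrays(records)
    fits: dict[str, FitResult] = {
        Family.BOUNDED_VOLUME.value: fit_alpha_bounded(records),
        Family.FIXED_AREA.value: fit_alpha_fixed(records, Norm.EUCLIDEAN),
        Family.BINOMIAL.value: fit_q_binomial(records, N),
    }
    if include_manhattan:
        fits[Family.FIXED_AREA_1NORM.value] = fit_alpha_fixed(records, Norm.MANHATTAN)
    degenerate = any(f.degenerate for f in fits.values())

    evidences: dict[str, dict[str, EvidenceResult]] = {}
    odds: dict[str, dict[str, ModelComparison]] = {}
    for prior in priors:
        ev = {fam: _evidence(fit, records, prior) for fam, fit in fits.items()}
        evidences[prior] = {fam: e for fam, e in ev.items() if e is not None}
        pairs = {}
        fams = list(evidences[prior])
        for i, fa in enumerate(fams):
            for fb in fams[i + 1:]:
                pairs[f"{fa}_vs_{fb}"] = log_odds(evidences[prior][fa], evidences[prior][fb])
        odds[prior] = pairs

    sbar_list = S.tolist()
    k_max = marginal_k_max or int(max(2 * S.max(), K.max() + 10))
    marginals: dict[str, np.ndarray] = {}
    support = np.arange(1, k_max + 1)
    for fam, fit in fits.items():
        if fit.degenerate or not with_marginals:
            continue
        if fam == Family.BINOMIAL.value:
            model = DegreeModel(Family.BINOMIAL, N=fit.N, q=fit.point_estimate)
        else:
            model = DegreeModel(Family(fam), alpha=fit.point_estimate)
        pmf = marginal_pmf(model, sbar_list, K_max=None if fam == Family.BINOMIAL.value else k_max)
        probs = np.zeros(k_max)
        m = min(k_max, len(pmf.probs))
        probs[:m] = pmf.probs[:m]
        marginals[fam] = probs / probs.sum()

    return GroupResult(label=label, n_records=len(records), pearson=pearson_r(records),
                       fits=fits, evidences=evidences, odds=odds,
                       marginals=marginals, marginal_support=support,
                       degenerate=degenerate)


@dataclass
class ComparisonReport:
    config: dict
    groups: dict[str, GroupResult]

    def to_dict(self) -> dict:
        def enc_ev(e: EvidenceResult) -> dict:
            v = e.log_evidence
            return {"family": e.family.value, "prior": e.prior,
                    "log_evidence": list(v) if isinstance(v, tuple) else v,
                    "n": e.n_records}

        def enc_fit(f: FitResult) -> dict:
            d = {"family": f.family.value, "point_estimate": f.point_estimate,
                 "sigma2": None if (f.sigma2 != f.sigma2) else f.sigma2,
                 "max_loglik": f.max_loglik, "degenerate": f.degenerate,
                 "n": f.n_records}
            if f.sigma2_lower is not None:
                d["sigma2_lower"] = f.sigma2_lower
                d["sigma2_upper"] = (None if not math.isfinite(f.sigma2_upper)
                                     else f.sigma2_upper)
            if f.bracket is not None:
                d["bracket"] = list(f.bracket)
            if f.N is not None:
                d["N"] = f.N
            return d

        out = {"config": self.config, "groups": {}}
        for label, g in self.groups.items():
            out["groups"][label] = {
                "n_records": g.n_records,
                "pearson_r": None if g.pearson != g.pearson else g.pearson,
                "degenerate": g.degenerate,
                "fits": {fam: enc_fit(f) for fam, f in g.fits.items()},
                "evidence": {prior: {fam: enc_ev(e) for fam, e in evs.items()}
                             for prior, evs in g.evidences.items()},
                "log_odds": {prior: {pair: (list(c.log_odds) if isinstance(c.log_odds, tuple)
                                            else c.log_odds)
                                     for pair, c in pairs.items()}
                             for prior, pairs in g.odds.items()},
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for label, g in self.groups.items():
            row: dict = {"group": label, "n": g.n_records, "pearson_r": g.pearson}
            for fam, f in g.fits.items():
                row[f"{fam}.estimate"] = f.point_estimate
            for prior, pairs in g.odds.items():
                for pair, c in pairs.items():
                    if isinstance(c.log_odds, tuple):
                        row[f"L[{prior}].{pair}.lower"] = c.log_odds[0]
                        row[f"L[{prior}].{pair}.upper"] = c.log_odds[1]
                    else:
                        row[f"L[{prior}].{pair}"] = c.log_odds
            rows.append(row)
        return pd.DataFrame(rows)

    def marginal_table(self) -> pd.DataFrame:
        frames = []
        for label, g in self.groups.items():
            df = pd.DataFrame({"group": label, "K": g.marginal_support})
            for fam, probs in g.marginals.items():
                df[fam] = probs
            frames.append(df)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.summary_table().to_csv(out / "report.tsv", sep="\t", index=False)
        self.marginal_table().to_csv(out / "marginals.tsv", sep="\t", index=False)


def run_comparison(
    grouped_records: Mapping[str, Sequence[NeuronRecord]],
    config: PipelineConfig = PipelineConfig(),
    metadata: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Run the full model comparison on pre-grouped records.

    ``config.binomial_N`` overrides the potential-partner count; otherwise
    it is inferred per :func:`_infer_binomial_N`.
    """
    groups: dict[str, GroupResult] = {}
    for label, records in grouped_records.items():
        if len(records) == 0:
            continue
        N = config.binomial_N or _infer_binomial_N(records, metadata, config.excluded_types)
        N = max(N, max(r.degree for r in records))
        groups[label] = compare_group(
            records, N=N, priors=config.priors,
            include_manhattan=config.include_manhattan,
            marginal_k_max=config.marginal_k_max, label=label)
    cfg = asdict(config)
    cfg["excluded_types"] = list(cfg["excluded_types"])
    cfg["priors"] = list(cfg["priors"])
    return ComparisonReport(config=cfg, groups=groups)
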