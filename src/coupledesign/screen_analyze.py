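"""Strategy filtering and phenotype analytics.

Filtering applies three criteria in order and reports the first failure:

1. the mutant is feasible under the environmental conditions;
2. its maximum growth reaches at least 1% of the wild-type maximum;
3. the FVA minimum of the product flux at 90% of the mutant's maximum
   growth is non-zero (growth coupling).

Analytics cover production robustness, BPCY, carbon yield, pathway
distributions and knockout frequencies, all computed on pFBA phenotypes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coupledesign._lp import TOL_ACT
from coupledesign.model_core import (
    Environment,
    MetabolicModel,
    apply_knockouts,
    require_objective,
    set_environment,
)
from coupledesign.phenotype_sim import (
    EPSILON,
    FluxDistribution,
    classify_coupling,
    fba,
    flux_extremum,
    pfba,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterCriteria:
    """Thresholds and context of the three-stage strategy filter."""

    product_id: str
    env: Environment | None = None
    min_growth_fraction_of_wt: float = 0.01
    coupling_growth_fraction: float = 0.90
    eps: float = EPSILON

    def __post_init__(self) -> None:
        for frac in (self.min_growth_fraction_of_wt, self.coupling_growth_fraction):
            if not 0.0 < frac <= 1.0:
                raise ValueError("filter fractions must lie in (0, 1]")


@dataclass
class PhenotypeReport:
    """Per-strategy metrics computed from pFBA/FVA phenotypes."""

    strategy: frozenset[str]
    max_growth: float
    biomass_flux: float
    substrate_flux: float
    product_flux: float
    robustness_low: float
    robustness_high: float
    bpcy_value: float | None
    carbon_yield_value: float | None
    coupling: str
    pathway_distribution: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "strategy": ";".join(sorted(self.strategy)),
            "size": len(self.strategy),
            "max_growth": self.max_growth,
            "biomass_flux": self.biomass_flux,
            "substrate_flux": self.substrate_flux,
            "product_flux": self.product_flux,
            "robustness_1pct": self.robustness_low,
            "robustness_90pct": self.robustness_high,
            "bpcy": self.bpcy_value,
            "carbon_yield": self.carbon_yield_value,
            "coupling": self.coupling,
        }


@dataclass
class PathwayMatrix:
    """Binary pathway-by-reaction membership matrix."""

    p: np.ndarray
    pathways: list[str]
    reactions: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p)
        keep = self.p.sum(axis=1) > 0
        if not keep.all():
            dropped = [self.pathways[i] for i in np.flatnonzero(~keep)]
            logger.warning("dropping empty pathway rows: %s", ", ".join(dropped))
            self.p = self.p[keep]
            self.pathways = [p for p, k in zip(self.pathways, keep) if k]

    @classmethod
    def from_tsv(cls, path: str, model: MetabolicModel) -> "PathwayMatrix":
        """Read a two-column (reaction_id, pathway_name) membership table."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        pathways = sorted(df["pathway_name"].unique())
        p = np.zeros((len(pathways), model.n_reactions), dtype=int)
        pw_index = {p_: i for i, p_ in enumerate(pathways)}
        for _, row in df.iterrows():
            rid = row["reaction_id"]
            if rid in model.reaction_ids:
                p[pw_index[row["pathway_name"]], model.index(rid)] = 1
        return cls(p=p, pathways=pathways, reactions=list(model.reaction_ids), source=path)


def _normalize(strategy) -> frozenset[str]:
    if hasattr(strategy, "reactions"):
        return frozenset(strategy.reactions)
    if hasattr(strategy, "knockouts"):
        return frozenset(strategy.knockouts)
    return frozenset(strategy)


def _mutant(model: MetabolicModel, strategy, env: Environment | None) -> MetabolicModel:
    mut = apply_knockouts(model, strategy)
    return set_environment(mut, env) if env is not None else mut


def filter_strategies(
    model: MetabolicModel,
    strategies,
    criteria: FilterCriteria,
) -> tuple[list[frozenset[str]], list[tuple[frozenset[str], str]]]:
    """Apply the three-criteria filter; rejections carry the first failed criterion."""
    biomass_id = require_objective(model)
    wt = _mutant(model, (), criteria.env)
    wt_growth = fba(wt, biomass_id)
    if not wt_growth.optimal:
        raise RuntimeError("wild-type is infeasible under the given environment")
    wt_max = wt_growth.objective_value
    kept: list[frozenset[str]] = []
    rejected: list[tuple[frozenset[str], str]] = []
    for raw in strategies:
        strategy = _normalize(raw)
        mut = _mutant(model, strategy, criteria.env)
        growth = fba(mut, biomass_id)
        if not growth.optimal:
            rejected.append((strategy, "environment"))
            continue
        mu = growth.objective_value
        if mu < criteria.min_growth_fraction_of_wt * wt_max:
            rejected.append((strategy, "growth"))
            continue
        min_p = flux_extremum(
            mut, criteria.product_id, "min",
            extra_lb={biomass_id: criteria.coupling_growth_fraction * mu},
        )
        if min_p is None or min_p <= TOL_ACT:
            rejected.append((strategy, "coupling"))
            continue
        kept.append(strategy)
    return kept, rejected


def production_robustness(
    model: MetabolicModel,
    strategy,
    x: float,
    product_id: str,
    env: Environment | None = None,
) -> float:
    """Minimum feasible product flux with growth held at ``x`` of the mutant maximum."""
    biomass_id = require_objective(model)
    mut = _mutant(model, strategy, env)
    growth = fba(mut, biomass_id)
    if not growth.optimal:
        raise RuntimeError("mutant infeasible; robustness undefined")
    value = flux_extremum(
        mut, product_id, "min", extra_lb={biomass_id: x * growth.objective_value}
    )
    if value is None:
        raise RuntimeError("robustness subproblem infeasible")
    return value


def bpcy(v_biomass: float, v_product: float, v_substrate: float) -> float:
    """Biomass-product coupled yield: growth times production over uptake."""
    if v_substrate <= 0:
        raise ValueError("BPCY undefined for non-positive substrate uptake")
    return v_biomass * v_product / v_substrate


def carbon_yield(
    v_product: float, v_substrate: float, c_product: int, c_substrate: int
) -> float:
    """Product/substrate carbon yield (carbon atoms out per carbon atom in)."""
    if c_product <= 0 or c_substrate <= 0:
        raise ValueError("carbon counts must be positive")
    if v_substrate <= 0:
        raise ValueError("carbon yield undefined for non-positive uptake")
    return (v_product * c_product) / (v_substrate * c_substrate)


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a chemical formula string."""
    m = re.search(r"C(\d*)(?![a-z])", formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def pathway_distribution(
    v: FluxDistribution | dict[str, float],
    pm: PathwayMatrix,
    tol: float = TOL_ACT,
) -> np.ndarray:
    """Fraction of each pathway's reactions carrying non-zero flux.

    Entry ``j`` is ``sum_i p_ji * |sgn(v_i)| / sum_i p_ji`` with the sign
    function evaluated at tolerance ``tol``.
    """
    fluxes = v.fluxes if isinstance(v, FluxDistribution) else v
    active = np.array(
        [1.0 if abs(fluxes.get(r, 0.0)) > tol else 0.0 for r in pm.reactions]
    )
    return (pm.p @ active) / pm.p.sum(axis=1)


def pathway_delta(
    strategy_fluxes: list[FluxDistribution | dict],
    wild_type_flux: FluxDistribution | dict,
    pm: PathwayMatrix,
) -> np.ndarray:
    """Mean pathway distribution of a strategy set minus the wild-type's."""
    if not strategy_fluxes:
        raise ValueError("need at least one strategy flux distribution")
    P = np.vstack([pathway_distribution(v, pm) for v in strategy_fluxes])
    return P.mean(axis=0) - pathway_distribution(wild_type_flux, pm)


def knockout_frequency(strategies, max_combo_size: int = 2) -> pd.DataFrame:
    """Relative frequency of single knockouts and knockout combinations."""
    from itertools import combinations

    sets = [_normalize(s) for s in strategies]
    if not sets:
        return pd.DataFrame(columns=["combination", "size", "frequency"])
    counts: dict[tuple[str, ...], int] = {}
    for s in sets:
        for size in range(1, max_combo_size + 1):
            for combo in combinations(sorted(s), size):
                counts[combo] = counts.get(combo, 0) + 1
    rows = [
        {"combination": ";".join(combo), "size": len(combo), "frequency": c / len(sets)}
        for combo, c in counts.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["frequency", "size", "combination"], ascending=[False, True, True]
    ).reset_index(drop=True)


def build_report(
    model: MetabolicModel,
    strategies,
    criteria: FilterCriteria,
    pathway_matrix: PathwayMatrix | None = None,
    substrate_id: str | None = None,
    carbon_counts: dict[str, int] | None = None,
) -> tuple[list[PhenotypeReport], dict]:
    """Per-strategy phenotype reports plus a set-level summary (mean/min/max)."""
    biomass_id = require_objective(model)
    reports: list[PhenotypeReport] = []
    for raw in strategies:
        strategy = _normalize(raw)
        mut = _mutant(model, strategy, criteria.env)
        growth = fba(mut, biomass_id)
        if not growth.optimal:
            logger.warning("skipping infeasible strategy %s", sorted(strategy))
            continue
        dist = pfba(mut, biomass_id)
        v_b = dist[biomass_id]
        v_p = dist[criteria.product_id]
        v_s = abs(dist[substrate_id]) if substrate_id else float("nan")
        rob_lo = production_robustness(model, strategy, criteria.min_growth_fraction_of_wt,
                                       criteria.product_id, criteria.env)
        rob_hi = production_robustness(model, strategy, criteria.coupling_growth_fraction,
                                       criteria.product_id, criteria.env)
        bp = bpcy(v_b, v_p, v_s) if substrate_id and v_s > 0 else None
        cy = None
        if carbon_counts and substrate_id and v_s > 0:
            cp = carbon_counts.get(criteria.product_id, 0)
            cs = carbon_counts.get(substrate_id, 0)
            if cp > 0 and cs > 0:
                cy = carbon_yield(v_p, v_s, cp, cs)
        coupling = classify_coupling(model, strategy, criteria.product_id,
                                     env=criteria.env)
        pd_vec = pathway_distribution(dist, pathway_matrix) if pathway_matrix else None
        reports.append(
            PhenotypeReport(
                strategy=strategy,
                max_growth=growth.objective_value,
                biomass_flux=v_b,
                substrate_flux=v_s,
                product_flux=v_p,
                robustness_low=rob_lo,
                robustness_high=rob_hi,
                bpcy_value=bp,
                carbon_yield_value=cy,
                coupling=coupling.kind,
                pathway_distribution=pd_vec,
            )
        )
    if not reports:
        logger.warning("empty strategy set: nothing to report")
        return [], {}
    summary: dict[str, dict[str, float]] = {}
    metrics = {
        "max_growth": [r.max_growth for r in reports],
        "robustness_1pct": [r.robustness_low for r in reports],
        "robustness_90pct": [r.robustness_high for r in reports],
        "bpcy": [r.bpcy_value for r in reports if r.bpcy_value is not None],
        "carbon_yield": [r.carbon_yield_value for r in reports
                         if r.carbon_yield_value is not None],
        "size": [float(len(r.strategy)) for r in reports],
    }
    for name, values in metrics.items():
        if values:
            summary[name] = {
                "mean": float(np.mean(values)),
                "min": float(np.min(values)),
                "max": float(np.max(values)),
            }
    return reports, summary


def write_reports_tsv(reports: list[PhenotypeReport], path: str) -> None:
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summary: dict, path: str) -> None:
    rows = [
        {"metric": metric, **stats}
        for metric, stats in summary.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
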