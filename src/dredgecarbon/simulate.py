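"""Seeded Monte Carlo propagation of %TOC and mass uncertainty.

The carbon-disturbance model is a single product,

    kg of sediment disturbed x (%TOC / 100) = kg of organic carbon disturbed,

but the %TOC of the sediment actually removed by a given works is unknown, and
for some historical records the sediment mass itself is unknown.  Each
simulation run therefore redraws a %TOC value per event from the empirical
pool matching that event's context (coastal pool for port dredging; the
sand/coarse/mixed pool, or the combined pool, for aggregates) and, for events
lacking any quantity, redraws the mass from the fitted log10-normal model.
Accumulated run totals give the mean, standard deviation and empirical
percentile bounds per (industry, scope, year).

Seeding: one master seed spawns an independent, stable substream per scope
group (keyed by industry/country/site/year), so a country simulated alone
reproduces exactly its share of a joint shelf run, and per-run totals sum
exactly across countries and ports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imputation import Log10MassModel
from .records import HarmonisedEvent, Industry, SedimentType
from .toc import EmpiricalTocDistribution

__all__ = [
    "MT_KG", "SimulationConfig", "CarbonEstimate", "carbon_mass",
    "run_simulation", "aggregate_country_to_shelf", "aggregate_ports_to_nation",
    "convergence_study", "sensitivity_sediment_proportions",
    "estimates_to_dataframe",
]

#: One megaton in kilograms.
MT_KG = 1e9


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings.

    ``draw_scope`` controls whether each event gets its own %TOC draw per run
    (``per_record``, default — narrower bands) or one draw is shared by a
    scope-year's total mass (``per_year_total`` — wider bands).
    ``fix_imputed_masses`` freezes one imputed mass per record across runs
    instead of redrawing each run (default redraws).
    """

    n_runs: int = 10000
    seed: int = 0
    p_low: float = 5.0
    p_high: float = 95.0
    draw_scope: str = "per_record"  # per_record | per_year_total
    fix_imputed_masses: bool = False

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.p_low < self.p_high < 100.0:
            raise ValueError("need 0 < p_low < p_high < 100")
        if self.draw_scope not in ("per_record", "per_year_total"):
            raise ValueError(f"unknown draw_scope {self.draw_scope!r}")


@dataclass(frozen=True)
class CarbonEstimate:
    """Monte Carlo summary for one (industry, scope, year/period).

    All masses in kg of organic carbon; ``year_end > year`` marks a period
    estimate (historical multi-year works), for which the per-year mean is
    ``mean_kgc / n_years``.  ``run_totals`` is retained so estimates can be
    summed run-by-run into shelf or national estimates.
    """

    industry: Industry
    scope_type: str  # country | port | nation | shelf
    scope_id: str
    country: str
    year: int
    year_end: int
    mean_kgc: float
    sd_kgc: float
    p_low_kgc: float
    p_high_kgc: float
    n_runs: int
    run_totals: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year + 1

    @property
    def mean_mt(self) -> float:
        return self.mean_kgc / MT_KG


def carbon_mass(mass_kg: float, toc_pct) -> float:
    """Organic carbon (kg) in ``mass_kg`` of sediment at ``toc_pct`` %TOC."""
    if mass_kg < 0:
        raise ValueError("mass must be non-negative")
    toc = np.asarray(toc_pct, dtype=float)
    if np.any(toc < 0) or np.any(toc > 100):
        raise ValueError("toc_pct outside [0, 100]")
    out = mass_kg * toc / 100.0
    return float(out) if np.isscalar(toc_pct) else out


def _scope_rng(seed: int, key: tuple) -> np.random.Generator:
    """Stable, key-derived substream of the master seed."""
    tag = "\x1f".join(str(k) for k in key).encode()
    h = int.from_bytes(hashlib.blake2b(tag, digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


def resolve_distribution(
    event: HarmonisedEvent,
    dists: dict[str, EmpiricalTocDistribution],
) -> EmpiricalTocDistribution:
    """Map an event to its %TOC pool.

    Port dredging draws from the coastal pool; aggregate extraction from the
    pool of its sediment type, falling back to the combined pool when the
    type is unknown.
    """
    if event.industry is Industry.PORT_DREDGING:
        label = "coastal"
    elif event.sediment_type is SedimentType.UNKNOWN:
        label = "combined"
    else:
        label = event.sediment_type.value
    if label not in dists:
        raise ValueError(f"event {event.record_id!r}: no %TOC distribution {label!r}")
    return dists[label]


def _summarise(
    run_totals: np.ndarray,
    industry: Industry,
    scope_type: str,
    scope_id: str,
    country: str,
    year: int,
    year_end: int,
    config: SimulationConfig,
    keep_runs: bool = True,
) -> CarbonEstimate:
    n = run_totals.size
    return CarbonEstimate(
        industry=industry,
        scope_type=scope_type,
        scope_id=scope_id,
        country=country,
        year=year,
        year_end=year_end,
        mean_kgc=float(run_totals.mean()),
        sd_kgc=float(run_totals.std(ddof=1)) if n > 1 else 0.0,
        p_low_kgc=float(np.percentile(run_totals, config.p_low)),
        p_high_kgc=float(np.percentile(run_totals, config.p_high)),
        n_runs=n,
        run_totals=run_totals if keep_runs else None,
    )


def run_simulation(
    events: Sequence[HarmonisedEvent],
    dists: dict[str, EmpiricalTocDistribution],
    mass_model: Log10MassModel | None = None,
    config: SimulationConfig = SimulationConfig(),
) -> list[CarbonEstimate]:
    """Monte Carlo carbon-disturbance estimates per (industry, scope, year).

    Events are grouped by industry, country, site and year (period events by
    their full span); site-tagged events produce port-level estimates, all
    others country-level ones.  Events flagged ``needs_imputation`` require
    ``mass_model``; their mass is redrawn every run (or frozen once when
    ``config.fix_imputed_masses``).  Identical seed and config give
    bit-identical run totals.
    """
    groups: dict[tuple, list[HarmonisedEvent]] = {}
    for ev in events:
        if ev.needs_imputation and mass_model is None:
            raise ValueError(f"event {ev.record_id!r} needs imputation but no mass model given")
        resolve_distribution(ev, dists)  # fail early, naming the record
        key = (ev.industry.value, ev.country, ev.site, ev.year, ev.year_end)
        groups.setdefault(key, []).append(ev)

    estimates: list[CarbonEstimate] = []
    for key in sorted(groups):
        industry_val, country, site, year, year_end = key
        evs = sorted(groups[key], key=lambda e: e.record_id)
        rng = _scope_rng(config.seed, key)
        totals = np.zeros(config.n_runs)
        if config.draw_scope == "per_record":
            for ev in evs:
                mass = _event_masses(ev, mass_model, rng, config)
                toc = rng.choice(resolve_distribution(ev, dists).values, size=config.n_runs)
                totals += mass * toc / 100.0
        else:  # per_year_total: one %TOC draw shared by the group total
            mass_total = np.zeros(config.n_runs)
            for ev in evs:
                mass_total = mass_total + _event_masses(ev, mass_model, rng, config)
            toc = rng.choice(resolve_distribution(evs[0], dists).values, size=config.n_runs)
            totals = mass_total * toc / 100.0
        estimates.append(
            _summarise(
                totals,
                Industry(industry_val),
                "port" if site else "country",
                site or country,
                country,
                year,
                year_end,
                config,
            )
        )
    return estimates


def _event_masses(
    ev: HarmonisedEvent,
    mass_model: Log10MassModel | None,
    rng: np.random.Generator,
    config: SimulationConfig,
):
    if not ev.needs_imputation:
        return ev.mass_kg
    from .imputation import sample_imputed_mass

    if config.fix_imputed_masses:
        return float(sample_imputed_mass(mass_model, rng, 1)[0])
    return sample_imputed_mass(mass_model, rng, config.n_runs)


def _sum_runs(
    members: Sequence[CarbonEstimate],
    industry: Industry,
    scope_type: str,
    scope_id: str,
    country: str,
    year: int,
    year_end: int,
    config: SimulationConfig,
) -> CarbonEstimate:
    n_runs = {e.n_runs for e in members}
    if len(n_runs) != 1:
        raise ValueError(f"mismatched n_runs across estimates: {sorted(n_runs)}")
    if any(e.run_totals is None for e in members):
        raise ValueError("aggregation needs retained run_totals")
    summed = np.sum([e.run_totals for e in members], axis=0)
    return _summarise(summed, industry, scope_type, scope_id, country, year, year_end, config)


def aggregate_country_to_shelf(
    estimates: Sequence[CarbonEstimate],
    config: SimulationConfig = SimulationConfig(),
) -> list[CarbonEstimate]:
    """Sum aligned country run totals into shelf-wide estimates per year.

    Run totals are summed run-by-run, so shelf mean = sum of country means
    exactly and the shelf percentile band reflects the joint distribution.
    """
    groups: dict[tuple, list[CarbonEstimate]] = {}
    for est in estimates:
        if est.scope_type != "country":
            continue
        groups.setdefault((est.industry.value, est.year, est.year_end), []).append(est)
    return [
        _sum_runs(
            members, Industry(ind), "shelf", "shelf", "", year, year_end, config,
        )
        for (ind, year, year_end), members in sorted(groups.items())
    ]


def aggregate_ports_to_nation(
    estimates: Sequence[CarbonEstimate],
    config: SimulationConfig = SimulationConfig(),
) -> list[CarbonEstimate]:
    """Sum aligned port-level run totals into national estimates.

    Used for historical records that exist only as port-level works: carbon
    is estimated per port first, then summed run-by-run to the nation, and
    the percentile band is taken on the summed vector.
    """
    groups: dict[tuple, list[CarbonEstimate]] = {}
    for est in estimates:
        if est.scope_type != "port":
            continue
        groups.setdefault((est.industry.value, est.country, est.year, est.year_end), []).append(est)
    return [
        _sum_runs(members, Industry(ind), "nation", cty, cty, year, year_end, config)
        for (ind, cty, year, year_end), members in sorted(groups.items())
    ]


def convergence_study(
    events: Sequence[HarmonisedEvent],
    dists: dict[str, EmpiricalTocDistribution],
    mass_model: Log10MassModel | None = None,
    run_grid: Sequence[int] = (100, 500, 1000, 5000, 10000),
    n_iterations: int = 10,
    seed: int = 0,
    stabilisation_tol: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat independently-seeded simulations over a grid of run counts.

    For each run count the simulation is repeated ``n_iterations`` times with
    independent seeds and the grand-total mean recorded; the inter-iteration
    spread shows how many runs the output needs to stabilise.  Returns
    (per-iteration table, summary table); the summary flags run counts whose
    relative inter-iteration SD falls below ``stabilisation_tol``.
    """
    if list(run_grid) != sorted(run_grid):
        raise ValueError("run_grid must be ascending")
    rows = []
    master = np.random.SeedSequence(seed)
    iter_seeds = master.generate_state(len(run_grid) * n_iterations) % (2**31)
    k = 0
    for n_runs in run_grid:
        for it in range(n_iterations):
            cfg = SimulationConfig(n_runs=int(n_runs), seed=int(iter_seeds[k]))
            k += 1
            ests = run_simulation(events, dists, mass_model, cfg)
            rows.append(
                {"runs": int(n_runs), "iteration": it, "mean_kgc": sum(e.mean_kgc for e in ests)}
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("runs")["mean_kgc"]
        .agg(mean="mean", inter_iteration_sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = summary["inter_iteration_sd"] / summary["mean"].abs()
    summary["stabilised"] = (rel.fillna(0.0) < stabilisation_tol)
    return table, summary


def sensitivity_sediment_proportions(
    total_mass_kg: float,
    dists: dict[str, EmpiricalTocDistribution],
    proportion_grid: Sequence[tuple[float, float, float]],
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Vary the assumed (sand, coarse, mixed) split of an untyped mass.

    Each grid point divides ``total_mass_kg`` among the three substrate
    classes, draws %TOC per fraction from the matching pool in every run, and
    summarises the resulting carbon estimate.  Quantifies how sensitive an
    untyped-record estimate is to the assumed sediment composition.
    """
    classes = ("sand", "coarse", "mixed")
    rows = []
    for i, props in enumerate(proportion_grid):
        props = tuple(float(p) for p in props)
        if any(p < 0 for p in props):
            raise ValueError("proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(props)}")
        rng = _scope_rng(config.seed, ("sensitivity", i) + props)
        totals = np.zeros(config.n_runs)
        for cls, p in zip(classes, props):
            if p == 0.0:
                continue
            toc = rng.choice(dists[cls].values, size=config.n_runs)
            totals += total_mass_kg * p * toc / 100.0
        rows.append(
            {
                "p_sand": props[0], "p_coarse": props[1], "p_mixed": props[2],
                "mean_kgc": float(totals.mean()),
                "sd_kgc": float(totals.std(ddof=1)) if config.n_runs > 1 else 0.0,
                "p_low_kgc": float(np.percentile(totals, config.p_low)),
                "p_high_kgc": float(np.percentile(totals, config.p_high)),
                "n_runs": config.n_runs,
            }
        )
    return pd.DataFrame(rows)


def estimates_to_dataframe(estimates: Iterable[CarbonEstimate], seed: int | None = None) -> pd.DataFrame:
    """Flatten estimates to the results table (user-facing units: Mt).

    Percentiles are linearly interpolated order statistics; values are
    reported in megatons (1 Mt = 1e9 kg).
    """
    rows = []
    for e in estimates:
        rows.append(
            {
                "industry": e.industry.value,
                "scope_type": e.scope_type,
                "scope_id": e.scope_id,
                "country": e.country,
                "year": e.year,
                "year_end": e.year_end,
                "mean_Mt": e.mean_kgc / MT_KG,
                "sd_Mt": e.sd_kgc / MT_KG,
                "p5_Mt": e.p_low_kgc / MT_KG,
                "p95_Mt": e.p_high_kgc / MT_KG,
                "n_runs": e.n_runs,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
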