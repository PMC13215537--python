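"""Multi-year summaries and run manifests.

Headline numbers of the form "X ± Y Mt organic carbon per year over
1995-2021" are the arithmetic mean and SD of the *annual mean* estimates
within the range (default), or alternatively the mean of annual means with a
pooled run-level SD; both are computed and labelled because the two spreads
answer different questions (between-year variability vs simulation
uncertainty).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from .simulate import CarbonEstimate, MT_KG

__all__ = ["summarise_multi_year", "RunManifest"]


def summarise_multi_year(
    estimates: Sequence[CarbonEstimate],
    year_range: tuple[int, int] | None = None,
    method: str = "across_years",
) -> dict:
    """Mean ± SD of annual mean carbon disturbance over a year range (Mt).

    ``across_years`` (default): SD is the n-1 SD of the per-year mean
    estimates — spread between years.  ``pooled_runs``: SD is the SD of the
    per-run multi-year annual averages — pure simulation uncertainty.
    Period estimates enter through their per-year annualised mean.
    """
    if year_range is not None:
        lo, hi = year_range
        estimates = [e for e in estimates if e.year >= lo and e.year_end <= hi]
    if not estimates:
        raise ValueError("no estimates in the requested year range")
    by_year: dict[int, float] = {}
    runs_by_year: dict[int, np.ndarray] = {}
    for e in estimates:
        annual = e.mean_kgc / e.n_years
        for yr in range(e.year, e.year_end + 1):
            by_year[yr] = by_year.get(yr, 0.0) + annual
            if e.run_totals is not None:
                prev = runs_by_year.get(yr)
                cur = e.run_totals / e.n_years
                runs_by_year[yr] = cur if prev is None else prev + cur
    annual_means = np.array([by_year[y] for y in sorted(by_year)])
    mean_mt = float(annual_means.mean()) / MT_KG
    if method == "across_years":
        sd = float(annual_means.std(ddof=1)) / MT_KG if annual_means.size > 1 else 0.0
    elif method == "pooled_runs":
        if not runs_by_year:
            raise ValueError("pooled_runs needs retained run_totals")
        stacked = np.mean([runs_by_year[y] for y in sorted(runs_by_year)], axis=0)
        sd = float(stacked.std(ddof=1)) / MT_KG
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "mean_mt_per_yr": mean_mt,
        "sd_mt_per_yr": sd,
        "n_years": int(annual_means.size),
        "years": (int(min(by_year)), int(max(by_year))),
        "method": method,
    }


@dataclass(frozen=True)
class RunManifest:
    """Provenance stamp tying result files to config, inputs and seed."""

    config_hash: str
    input_digests: dict
    seed: int
    package_version: str
    created_utc: str

    @classmethod
    def create(cls, config_obj, input_paths: Sequence[str], seed: int) -> "RunManifest":
        from . import __version__

        cfg_repr = json.dumps(getattr(config_obj, "__dict__", str(config_obj)), sort_keys=True, default=str)
        digests = {}
        for p in input_paths:
            h = hashlib.sha256()
            with open(p, "rb") as fh:
                h.update(fh.read())
            digests[str(p)] = h.hexdigest()
        return cls(
            config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
            input_digests=digests,
            seed=seed,
            package_version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
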