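"""Missing-mass imputation for extraction records.

Two-stage strategy mirroring how 19th-century port records degrade: records
listing only the monetary cost of dredging works are converted to mass through
an average cost-per-kg rate calibrated on the few ports that reported both
cost and quantity; records listing neither quantity nor cost are imputed
stochastically inside the Monte Carlo from a normal distribution fitted to
the log10 of all masses that could be estimated (reported + cost-derived),
back-transformed to kg at draw time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "CostRateModel", "Log10MassModel",
    "fit_cost_rate", "estimate_mass_from_cost",
    "fit_log10_mass_model", "sample_imputed_mass",
]


@dataclass(frozen=True)
class CostRateModel:
    """Average cost per kg of sediment removed (currency units per kg)."""

    rate_per_kg: float
    n_pairs: int
    pair_ids: tuple = ()
    method: str = "mean_of_ratios"

    def __post_init__(self) -> None:
        if self.rate_per_kg <= 0:
            raise ValueError("rate_per_kg must be positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class Log10MassModel:
    """Normal model on log10(mass in kg) for stochastic mass imputation.

    ``shapiro_w``/``shapiro_p`` describe the normality of the calibration
    sample on the log10 scale; they are reported, not used as a gate.
    A degenerate fit (``sigma == 0``) is flagged and refuses to impute.
    """

    mu: float
    sigma: float
    n: int
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    calibration_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0 or self.n < 3

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Log10MassModel":
        d = dict(d)
        d["calibration_ids"] = tuple(d.get("calibration_ids", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Log10MassModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_cost_rate(
    pairs: Sequence[tuple[float, float]],
    pair_ids: Sequence[str] = (),
    method: str = "mean_of_ratios",
) -> CostRateModel:
    """Calibrate the average cost per kg from (cost, mass_kg) pairs.

    ``mean_of_ratios`` (default) averages the per-port cost/mass ratios;
    ``pooled`` divides total cost by total mass.  The two differ when works
    vary in scale; both are exposed so the choice can be reported.
    """
    if len(pairs) == 0:
        raise ValueError("no calibration pairs")
    costs = np.asarray([c for c, _ in pairs], dtype=float)
    masses = np.asarray([m for _, m in pairs], dtype=float)
    if np.any(masses <= 0) or np.any(costs <= 0):
        raise ValueError("costs and masses must be strictly positive")
    if method == "mean_of_ratios":
        rate = float(np.mean(costs / masses))
    elif method == "pooled":
        rate = float(costs.sum() / masses.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return CostRateModel(rate_per_kg=rate, n_pairs=len(pairs), pair_ids=tuple(pair_ids), method=method)


def estimate_mass_from_cost(cost: float, model: CostRateModel) -> float:
    """Mass in kg implied by a monetary cost under the calibrated rate."""
    if cost < 0:
        raise ValueError("cost must be non-negative")
    return cost / model.rate_per_kg


def fit_log10_mass_model(
    masses_kg: Sequence[float],
    calibration_ids: Sequence[str] = (),
) -> Log10MassModel:
    """Fit a normal on log10(kg): mean, sample SD (n-1), Shapiro-Wilk.

    Requires at least 3 strictly positive masses.  With a constant sample the
    Shapiro-Wilk statistic is undefined; the model is returned with sigma = 0
    and flagged degenerate instead.
    """
    masses = np.asarray(masses_kg, dtype=float)
    if masses.size < 3:
        raise ValueError("insufficient data: need at least 3 masses")
    if np.any(masses <= 0):
        raise ValueError("all masses must be strictly positive")
    logs = np.log10(masses)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0.0:
        w = p = None
    else:
        w, p = stats.shapiro(logs)
        w, p = float(w), float(p)
    return Log10MassModel(
        mu=mu, sigma=sigma, n=int(masses.size),
        shapiro_w=w, shapiro_p=p, calibration_ids=tuple(calibration_ids),
    )


def sample_imputed_mass(
    model: Log10MassModel,
    rng: np.random.Generator,
    n_draws: int,
) -> np.ndarray:
    """Draw masses as 10**N(mu, sigma); strictly positive by construction."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if model.n < 3:
        raise ValueError("model fitted on fewer than 3 masses; imputation disabled")
    x = rng.normal(model.mu, model.sigma, size=n_draws)
    return np.power(10.0, x)
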