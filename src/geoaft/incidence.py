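"""Age-adjusted incidence rates with gamma-method confidence intervals.

Direct standardization: with age-band weights :math:`w_a` (a standard
population restricted to the bands supplied — here typically ages 40+ — and
renormalized to sum to one), event counts :math:`y_a` and person-years
:math:`n_a`, the rate is :math:`R = \\mathrm{scale} \\sum_a w_a y_a / n_a`.

The confidence interval is the Fay–Feuer gamma interval, the standard
registry construction: with :math:`V = \\sum_a w_a^2 y_a / n_a^2` and
:math:`w^* = \\max_a w_a / n_a`,

* lower: :math:`\\mathrm{Gamma}(R^2/V,\\; V/R)` quantile at :math:`\\alpha/2`
  (0 when R = 0);
* upper: :math:`\\mathrm{Gamma}((R+w^*)^2/(V+w^{*2}),\\;
  (V+w^{*2})/(R+w^*))` quantile at :math:`1-\\alpha/2`.

In the single-stratum, unit-weight limit this reduces to the exact Poisson
gamma interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardPopulation", "age_adjusted_rate", "gamma_ci", "rate_report"]


@dataclass
class StandardPopulation:
    """Age-band weights: non-overlapping closed integer bands [start, end]."""

    band_start: np.ndarray
    band_end: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.band_start = np.asarray(self.band_start, dtype=int)
        self.band_end = np.asarray(self.band_end, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        order = np.argsort(self.band_start)
        self.band_start = self.band_start[order]
        self.band_end = self.band_end[order]
        self.weight = self.weight[order]
        if (self.weight < 0).any():
            raise ValueError("weights must be nonnegative")
        if (self.band_end < self.band_start).any():
            raise ValueError("band_end must be >= band_start")
        if (self.band_start[1:] <= self.band_end[:-1]).any():
            raise ValueError("bands must be non-overlapping")

    @classmethod
    def us_2000(cls) -> "StandardPopulation":
        """The 2000 U.S. standard million by 5-year band (85+ open-ended)."""
        path = importlib.resources.files("geoaft.data") / "std_pop_2000_us.csv"
        df = pd.read_csv(path, comment="#")
        return cls(df["band_start"], df["band_end"], df["weight"])

    def restrict(self, age_floor: int = 40) -> "StandardPopulation":
        """Keep bands fully at or above the floor; renormalize to sum 1.

        Bands straddling the floor are dropped, not prorated.
        """
        keep = self.band_start >= age_floor
        w = self.weight[keep]
        if w.sum() <= 0:
            raise ValueError("no weight remains above the age floor")
        return StandardPopulation(self.band_start[keep], self.band_end[keep], w / w.sum())

    def normalized(self) -> "StandardPopulation":
        return StandardPopulation(self.band_start, self.band_end,
                                  self.weight / self.weight.sum())


def _check(strata: pd.DataFrame, std: StandardPopulation):
    need = {"band_start", "events", "person_years"}
    if not need <= set(strata.columns):
        raise ValueError(f"strata table needs columns {sorted(need)}")
    s = strata.sort_values("band_start")
    if not np.array_equal(s["band_start"].to_numpy(), std.band_start):
        raise ValueError("strata bands do not match the standard population")
    y = s["events"].to_numpy(dtype=float)
    n = s["person_years"].to_numpy(dtype=float)
    if (n <= 0).any():
        raise ValueError("person_years must be positive in every band")
    if (y < 0).any():
        raise ValueError("event counts must be nonnegative")
    w = std.weight / std.weight.sum()
    return y, n, w


def age_adjusted_rate(
    strata: pd.DataFrame, std: StandardPopulation, scale: float = 1e5
) -> float:
    """Directly standardized rate, by default per 100,000 person-years."""
    y, n, w = _check(strata, std)
    return float(scale * np.sum(w * y / n))


def gamma_ci(
    strata: pd.DataFrame,
    std: StandardPopulation,
    alpha: float = 0.05,
    scale: float = 1e5,
) -> tuple[float, float]:
    """Fay–Feuer gamma confidence interval for the standardized rate."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y, n, w = _check(strata, std)
    rate = float(np.sum(w * y / n))
    var = float(np.sum(w**2 * y / n**2))
    wmax = float(np.max(w / n))
    lower = 0.0
    if rate > 0:
        lower = stats.gamma.ppf(alpha / 2, rate**2 / var, scale=var / rate)
    upper = stats.gamma.ppf(
        1 - alpha / 2,
        (rate + wmax) ** 2 / (var + wmax**2),
        scale=(var + wmax**2) / (rate + wmax),
    )
    return float(scale * lower), float(scale * upper)


def rate_report(
    cases: pd.DataFrame,
    person_years: pd.DataFrame,
    std: StandardPopulation | None = None,
    group: str | None = None,
    age_floor: int = 40,
    scale: float = 1e5,
) -> pd.DataFrame:
    """Stratify case counts into the standard's age bands and report
    rate + gamma CI, overall or per level of ``group``.

    ``person_years`` needs columns band_start / person_years (optionally per
    group level in a ``group`` column matching ``cases``).
    """
    std = (std or StandardPopulation.us_2000()).restrict(age_floor)

    def one(sub: pd.DataFrame, py: pd.DataFrame) -> dict:
        edges = np.append(std.band_start, std.band_end[-1] + 1)
        counts = np.histogram(sub["age_at_dx"].to_numpy(), bins=edges)[0]
        strata = pd.DataFrame({
            "band_start": std.band_start,
            "events": counts,
            "person_years": py.set_index("band_start")
            .loc[std.band_start, "person_years"].to_numpy(),
        })
        r = age_adjusted_rate(strata, std, scale)
        lo, hi = gamma_ci(strata, std, scale=scale)
        return {"rate": r, "lower": lo, "upper": hi, "n_events": int(counts.sum())}

    if group is None:
        return pd.DataFrame([{"group": "all", **one(cases, person_years)}])
    rows = []
    for g, sub in cases.groupby(group, observed=True):
        py = person_years
        if group in person_years.columns:
            py = person_years[person_years[group] == g]
        rows.append({"group": g, **one(sub, py)})
    return pd.DataFrame(rows)
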