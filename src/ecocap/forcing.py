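"""Climate forcing series: daily climatologies, delta bias correction, looping.

A :class:`ForcingSeries` is one climatological year of daily temperature
(365 values, no leap days) plus per-group productivity scalars, looped
to force the simulator without interannual variability. Projection
output from a biased climate model is reconciled with a hindcast via the
standard delta method before being collapsed to a climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ForcingDataError

__all__ = [
    "DAYS_PER_YEAR",
    "ForcingSeries",
    "delta_correct",
    "build_daily_climatology",
    "loop_forcing",
    "warm_regime",
]

DAYS_PER_YEAR = 365


@dataclass
class ForcingSeries:
    """One climatological year of forcing defining a climate regime.

    ``daily_T``: 365 daily temperatures (deg C). ``productivity_scalars``
    maps group id -> fraction in (0, 1] applied to that pool's logistic
    growth (default 1.0 for unnamed groups). ``label`` names the regime.
    """

    daily_T: np.ndarray
    productivity_scalars: dict = field(default_factory=dict)
    label: str = "unnamed"

    def __post_init__(self):
        self.daily_T = np.asarray(self.daily_T, dtype=float)
        if self.daily_T.shape != (DAYS_PER_YEAR,):
            raise ForcingDataError(
                f"forcing {self.label!r}: daily_T must have exactly "
                f"{DAYS_PER_YEAR} values (got {self.daily_T.shape})"
            )
        if not np.all(np.isfinite(self.daily_T)):
            raise ForcingDataError(f"forcing {self.label!r}: non-finite temperature")
        for gid, s in self.productivity_scalars.items():
            if not (0.0 < s <= 1.0):
                raise ForcingDataError(
                    f"forcing {self.label!r}: productivity scalar for {gid!r} "
                    f"must lie in (0, 1]"
                )

    def scalar_for(self, group_id: str) -> float:
        return float(self.productivity_scalars.get(group_id, 1.0))

    def step_means(self, steps_per_year: int) -> np.ndarray:
        """Mean temperature over each of ``steps_per_year`` equal slices of the year."""
        chunks = np.array_split(self.daily_T, steps_per_year)
        return np.array([c.mean() for c in chunks])

    @property
    def annual_mean(self) -> float:
        return float(self.daily_T.mean())


def delta_correct(proj_value, hindcast_mean, historical_mean):
    """Delta-method bias correction: x' = x_hind_mean + (x_proj - x_hist_mean).

    The projected value's anomaly relative to the free-running
    historical model mean is added to the reanalysis-driven hindcast
    mean, removing the climate model's mean bias. Exact arithmetic,
    applied elementwise over daily series.
    """
    proj = np.asarray(proj_value, dtype=float)
    for name, v in (("proj_value", proj),
                    ("hindcast_mean", np.asarray(hindcast_mean, dtype=float)),
                    ("historical_mean", np.asarray(historical_mean, dtype=float))):
        if not np.all(np.isfinite(v)):
            raise ForcingDataError(f"delta_correct: non-finite {name}")
    out = hindcast_mean + (proj - historical_mean)
    return float(out) if np.ndim(out) == 0 else out


def build_daily_climatology(multi_year_daily) -> np.ndarray:
    """Collapse years x 365 daily values to a single 365-day climatology.

    Element d is the mean across years of day-d values. Input may be a
    2-D array or a flat series whose length is a multiple of 365 (leap
    days removed by the caller).
    """
    arr = np.asarray(multi_year_daily, dtype=float)
    if arr.ndim == 1:
        if arr.size % DAYS_PER_YEAR != 0:
            raise ForcingDataError(
                f"daily series length {arr.size} is not a multiple of {DAYS_PER_YEAR}"
            )
        arr = arr.reshape(-1, DAYS_PER_YEAR)
    if arr.ndim != 2 or arr.shape[1] != DAYS_PER_YEAR or arr.shape[0] < 1:
        raise ForcingDataError(
            f"expected (n_years, {DAYS_PER_YEAR}) daily values, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ForcingDataError("non-finite value in daily series")
    return arr.mean(axis=0)


def loop_forcing(climatology, n_years: int) -> np.ndarray:
    """Tile one climatological year into ``n_years`` of daily values.

    The result has zero interannual variance of any same-day-of-year
    statistic by construction.
    """
    if n_years < 1:
        raise ForcingDataError("loop_forcing requires n_years >= 1")
    clim = np.asarray(climatology, dtype=float)
    if clim.shape != (DAYS_PER_YEAR,):
        raise ForcingDataError(
            f"climatology must have {DAYS_PER_YEAR} values, got {clim.shape}"
        )
    return np.tile(clim, n_years)


def warm_regime(base: ForcingSeries, corrected_climatology,
                plankton_ids, known_ids=None, label: str = "projected"
                ) -> ForcingSeries:
    """Build the warm-scenario regime from a corrected climatology.

    Carries the delta-corrected daily temperatures and halves the
    productivity of the named plankton groups (scalar 0.5), leaving all
    other groups at 1.0. ``known_ids``, when given, is used to reject
    unknown plankton ids.
    """
    plankton_ids = list(plankton_ids)
    if known_ids is not None:
        unknown = [g for g in plankton_ids if g not in set(known_ids)]
        if unknown:
            raise ConfigurationError(f"warm_regime: unknown group ids {unknown}")
    scalars = {gid: 0.5 for gid in plankton_ids}
    return replace(base, daily_T=np.asarray(corrected_climatology, dtype=float),
                   productivity_scalars=scalars, label=label)
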