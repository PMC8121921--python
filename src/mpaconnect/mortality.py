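"""Thermal-tolerance fate rules and per-site fate accounting.

Eggs and larvae die immediately and permanently when the water temperature
they sample leaves the lethal window: below ``t_min`` → hypothermia, above
``t_max`` → hyperthermia, with survival inclusive of both bounds.  The
non-acclimated window is 24–30 °C; transgenerational acclimation is
modelled as raising only the upper bound by +3 °C (24–33 °C).  Leaving the
model domain is a separate, exclusive fate (advected out) that takes
precedence over a simultaneous lethal temperature, since temperature is
undefined outside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
import scipy.stats

from .errors import IntegrityError, ValidationError

__all__ = [
    "Fate",
    "ToleranceWindow",
    "classify_temperature",
    "tally_fates",
    "compare_scenarios",
    "ACCLIMATION_OFFSET",
]

#: acclimation raises only the upper lethal bound, by this much (°C)
ACCLIMATION_OFFSET = 3.0


class Fate(IntEnum):
    ALIVE = 0
    DEAD_HYPOTHERMIA = 1
    DEAD_HYPERTHERMIA = 2
    ADVECTED_OUT = 3

    @property
    def label(self) -> str:
        return self.name.lower()


FATE_COLUMNS = ("alive", "dead_hypothermia", "dead_hyperthermia", "advected_out")


@dataclass(frozen=True)
class ToleranceWindow:
    """Lethal temperature window [t_min, t_max] °C, survival inclusive."""

    t_min: float = 24.0
    t_max: float = 30.0
    label: str = "non_acclimated"

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValidationError("t_min must be strictly below t_max")

    @classmethod
    def non_acclimated(cls) -> "ToleranceWindow":
        """Present-day thermal tolerance: 24–30 °C."""
        return cls(24.0, 30.0, "non_acclimated")

    @classmethod
    def acclimated(cls) -> "ToleranceWindow":
        """Acclimated tolerance: upper bound raised +3 °C → 24–33 °C."""
        return cls(24.0, 30.0 + ACCLIMATION_OFFSET, "acclimated")

    @classmethod
    def named(cls, label: str) -> "ToleranceWindow":
        try:
            return {"non_acclimated": cls.non_acclimated, "acclimated": cls.acclimated}[label]()
        except KeyError:
            raise ValidationError(f"unknown tolerance window {label!r}") from None


def classify_temperature(temperature, window: ToleranceWindow) -> np.ndarray:
    """Vectorized fate of a sampled temperature under a tolerance window.

    Returns Fate codes: ALIVE inside [t_min, t_max] (bounds inclusive),
    DEAD_HYPOTHERMIA below, DEAD_HYPERTHERMIA above.
    """
    t = np.asarray(temperature, dtype=float)
    out = np.full(t.shape, Fate.ALIVE, dtype=np.int8)
    out[t < window.t_min] = Fate.DEAD_HYPOTHERMIA
    out[t > window.t_max] = Fate.DEAD_HYPERTHERMIA
    return out if out.shape else out[()]


def tally_fates(trajectories, registry) -> pd.DataFrame:
    """Count end-of-run fates per source site.

    Returns a DataFrame indexed by site id with columns ``released``,
    ``alive``, ``dead_hypothermia``, ``dead_hyperthermia``, ``advected_out``
    and ``total_mortality_pct`` = 100·(released − alive)/released.  The
    counts are exhaustive and exclusive; conservation is asserted exactly.
    """
    sources = np.asarray(trajectories.source)
    fates = np.asarray(trajectories.fate)
    known = set(registry.ids)
    unknown = set(np.unique(sources)) - known
    if unknown:
        raise IntegrityError(f"particles with unknown source site(s): {sorted(unknown)}")

    rows = {}
    for sid in registry.ids:
        sel = sources == sid
        released = int(sel.sum())
        counts = {
            col: int(np.sum(fates[sel] == code))
            for col, code in zip(FATE_COLUMNS, Fate)
        }
        if released != sum(counts.values()):
            raise IntegrityError(f"fate conservation violated at site {sid}")
        mortality = 100.0 * (released - counts["alive"]) / released if released else np.nan
        rows[sid] = {"released": released, **counts, "total_mortality_pct": mortality}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site"
    return df


def combine_tallies(tallies: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool several fate tallies (e.g. release events) into one."""
    if not tallies:
        raise ValidationError("no tallies to combine")
    count_cols = ["released", *FATE_COLUMNS]
    total = sum(t[count_cols] for t in tallies)
    total["total_mortality_pct"] = np.where(
        total["released"] > 0,
        100.0 * (total["released"] - total["alive"]) / total["released"],
        np.nan,
    )
    return total


def compare_scenarios(*groups, labels=None):
    """Kruskal–Wallis H test across ≥2 groups of mortality percentages.

    Replicates are per-year-per-season total mortality values.  Uses
    tie-corrected ranks.  When every observation is identical across all
    groups the statistic is degenerate and (H, p) = (0, 1) is returned.
    Returns (H, p).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    for a in arrays:
        if a.size < 1:
            raise ValidationError("each group needs at least one replicate")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = scipy.stats.kruskal(*arrays)
    return float(stat), float(p)
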