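"""Field estimators of temporal migration and mortality from tagged rosettes.

A cohort of vegetative rosettes tagged in one summer is revisited the next:
each tagged plant is dead, still vegetative, or has become reproductive.
Plants that stayed vegetative delayed flowering by a year — they are the
temporal migrants moving genes between the odd-year and even-year demes.

    mortality          = 100 * dead / resampled
    temporal migration = 100 * vegetative / (vegetative + reproductive)

The migration denominator is the survivors: the rate is the share of
surviving rosettes that postponed reproduction. A packaged fixture CSV ships
the reference transition counts for four wild wallflower (Erysimum
mediohispanicum) sites over the 2010-11 and 2011-12 transitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TransitionRecord",
    "temporal_migration_rate",
    "mortality_rate",
    "load_transition_table",
    "rate_table",
    "transition_summary",
]


@dataclass(frozen=True)
class TransitionRecord:
    """Fates of one site's tagged rosettes over one year-to-year transition."""

    transition: str
    site: str
    resampled: int
    dead: int | None
    vegetative: int | None
    reproductive: int | None

    @property
    def complete(self) -> bool:
        return None not in (self.dead, self.vegetative, self.reproductive)

    def validate(self) -> None:
        counts = [self.resampled, self.dead, self.vegetative, self.reproductive]
        if any(c is not None and c < 0 for c in counts):
            raise ValueError(f"{self.site} {self.transition}: negative count")
        if self.complete and self.resampled != (
            self.dead + self.vegetative + self.reproductive
        ):
            raise ValueError(
                f"{self.site} {self.transition}: resampled "
                f"({self.resampled}) != dead + vegetative + reproductive"
            )


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (display convention)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def temporal_migration_rate(vegetative: int, reproductive: int) -> float:
    """Percent of surviving rosettes that stayed vegetative (delayed
    flowering): 100 * vegetative / (vegetative + reproductive)."""
    if vegetative < 0 or reproductive < 0:
        raise ValueError("counts must be non-negative")
    survivors = vegetative + reproductive
    if survivors == 0:
        return np.nan  # no survivors: rate undefined
    return 100.0 * vegetative / survivors


def mortality_rate(dead: int, resampled: int) -> float:
    """Percent of re-sampled tagged rosettes found dead."""
    if dead < 0 or resampled < 0:
        raise ValueError("counts must be non-negative")
    if resampled == 0:
        return np.nan
    return 100.0 * dead / resampled


def load_transition_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a transition-count CSV (columns: transition, site, resampled,
    dead, vegetative, reproductive). With no path, the packaged reference
    fixture is used. The accounting identity
    resampled = dead + vegetative + reproductive is enforced for complete
    rows; incomplete rows (blank cells) are kept but flagged."""
    if path is None:
        ref = resources.files("temporal_demes").joinpath("data/table1_transitions.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"transition", "site", "resampled", "dead", "vegetative", "reproductive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for _, row in df.iterrows():
        rec = TransitionRecord(
            transition=str(row["transition"]),
            site=str(row["site"]),
            resampled=int(row["resampled"]),
            dead=None if pd.isna(row["dead"]) else int(row["dead"]),
            vegetative=None if pd.isna(row["vegetative"]) else int(row["vegetative"]),
            reproductive=None
            if pd.isna(row["reproductive"])
            else int(row["reproductive"]),
        )
        rec.validate()
    return df


def rate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-record mortality and temporal-migration percentages (2-decimal
    display rounding); incomplete records yield NaN rates."""
    out = df.copy()
    mort, migr = [], []
    for _, row in df.iterrows():
        if pd.isna(row["dead"]):
            mort.append(np.nan)
        else:
            mort.append(mortality_rate(int(row["dead"]), int(row["resampled"])))
        if pd.isna(row["vegetative"]) or pd.isna(row["reproductive"]):
            migr.append(np.nan)
        else:
            migr.append(
                temporal_migration_rate(
                    int(row["vegetative"]), int(row["reproductive"])
                )
            )
    out["mortality_pct"] = [round2(m) if np.isfinite(m) else np.nan for m in mort]
    out["migration_pct"] = [round2(m) if np.isfinite(m) else np.nan for m in migr]
    return out


def transition_summary(df: pd.DataFrame, transition: str) -> pd.DataFrame:
    """Unweighted mean and sample SD (n-1) across sites of each rate within
    one transition; sites with undefined rates are excluded. Rates enter at
    full precision; only the returned values are display quantities."""
    sub = df[df["transition"] == transition]
    if sub.empty:
        raise ValueError(f"no records for transition {transition!r}")
    rows = []
    for stat, fn, cols in (
        ("mortality", mortality_rate, ("dead", "resampled")),
        ("migration", temporal_migration_rate, ("vegetative", "reproductive")),
    ):
        vals = []
        for _, row in sub.iterrows():
            if any(pd.isna(row[c]) for c in cols):
                continue
            v = fn(int(row[cols[0]]), int(row[cols[1]]))
            if np.isfinite(v):
                vals.append(v)
        if not vals:
            raise ValueError(f"no valid {stat} rates in {transition!r}")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append(
            {
                "transition": transition,
                "statistic": stat,
                "n_sites": len(vals),
                "mean": mean,
                "sd": sd,
            }
        )
    return pd.DataFrame(rows)
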