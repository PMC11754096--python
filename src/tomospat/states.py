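"""Duty-cycle state accounting.

Converts per-class particle counts (open chaperonin with 0/1/2 bound
prefoldin, closed chaperonin) into state-distribution percentages and
side-by-side condition comparisons. Percentages for the prefoldin classes
are expressed over *all* particles (open + closed), which is how the
in-cell tallies are conventionally quoted (e.g. 875 single-PFD particles of
7,407 total ~ 12%).

Module-level constants carry the published in-cell tallies from cryo-ET of
human cells under normal growth ("untreated") and translation inhibition
with homoharringtonine ("treated"); they serve as reference inputs for the
accounting functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "StateCounts",
    "StateDistribution",
    "state_distribution",
    "compare_distributions",
    "duty_cycle_table",
    "UNTREATED_COUNTS",
    "TREATED_COUNTS",
]

OPEN_STATES = ("open_noPFD", "open_1PFD", "open_2PFD")
CYCLE_ORDER = ("open_noPFD", "open_1PFD", "open_2PFD", "closed")


@dataclass(frozen=True)
class StateCounts:
    """Per-class particle tallies for one dataset."""

    label: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if int(v) != v or v < 0:
                raise ValueError(f"count for {k!r} must be a non-negative integer, got {v}")
        object.__setattr__(self, "counts", {k: int(v) for k, v in self.counts.items()})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_particles(cls, ps, label: str = "custom") -> "StateCounts":
        """Tally the state labels of a ParticleSet."""
        return cls(label, ps.state_counts())


#: In-cell tallies: 3,353 open (2,395 / 875 / 83 with 0/1/2 PFD) + 4,054 closed.
UNTREATED_COUNTS = StateCounts(
    "untreated",
    {"open_noPFD": 2395, "open_1PFD": 875, "open_2PFD": 83, "closed": 4054},
)
#: Translation-inhibited tallies: 3,785 open (2,334 / 1,287 / 164) + 3,418 closed.
TREATED_COUNTS = StateCounts(
    "treated",
    {"open_noPFD": 2334, "open_1PFD": 1287, "open_2PFD": 164, "closed": 3418},
)


@dataclass
class StateDistribution:
    """Counts and percentages per state, with open/closed aggregate split."""

    label: str
    table: pd.DataFrame  # state, count, percent
    total: int

    def percent(self, state: str) -> float:
        sel = self.table.loc[self.table["state"] == state, "percent"]
        if sel.empty:
            raise KeyError(f"unknown state {state!r}")
        return float(sel.iloc[0])

    @property
    def open_percent(self) -> float:
        present = [s for s in OPEN_STATES if s in set(self.table["state"])]
        return float(sum(self.percent(s) for s in present))

    @property
    def closed_percent(self) -> float:
        return self.percent("closed") if "closed" in set(self.table["state"]) else 0.0

    def summary(self) -> str:
        out = self.table.copy()
        out["percent"] = out["percent"].map(lambda p: f"{p:.1f}")
        return "\n".join(
            [
                f"State distribution ({self.label}, n={self.total})",
                out.to_string(index=False),
                f"  open total   : {self.open_percent:.1f}%",
                f"  closed total : {self.closed_percent:.1f}%",
            ]
        )


def state_distribution(sc: StateCounts) -> StateDistribution:
    """Percent of all particles in each state (percent = 100 * count / total)."""
    if sc.total <= 0:
        raise ValueError("total count must be positive")
    states = list(sc.counts)
    counts = np.array([sc.counts[s] for s in states], dtype=float)
    table = pd.DataFrame(
        {"state": states, "count": counts.astype(int), "percent": 100.0 * counts / sc.total}
    )
    return StateDistribution(sc.label, table, sc.total)


def compare_distributions(a: StateDistribution, b: StateDistribution) -> pd.DataFrame:
    """Per-state percentage-point deltas with pooled two-proportion z-tests.

    No multiplicity correction is applied; the z and p columns are per-state
    marginal tests.
    """
    if set(a.table["state"]) != set(b.table["state"]):
        raise ValueError("state vocabularies differ between the two distributions")
    rows = []
    for state in a.table["state"]:
        ca = int(a.table.loc[a.table["state"] == state, "count"].iloc[0])
        cb = int(b.table.loc[b.table["state"] == state, "count"].iloc[0])
        pa, pb = ca / a.total, cb / b.total
        pool = (ca + cb) / (a.total + b.total)
        se = np.sqrt(pool * (1 - pool) * (1 / a.total + 1 / b.total))
        z = (pb - pa) / se if se > 0 else 0.0
        rows.append(
            {
                "state": state,
                f"percent_{a.label}": 100 * pa,
                f"percent_{b.label}": 100 * pb,
                "delta_pp": 100 * (pb - pa),
                "z": z,
                "p_value": 2 * norm.sf(abs(z)),
            }
        )
    return pd.DataFrame(rows)


def duty_cycle_table(untreated: StateCounts, treated: StateCounts) -> pd.DataFrame:
    """Side-by-side cycle-step percentages for the two conditions.

    One row per cycle step (open without PFD, open + 1 PFD, open + 2 PFD,
    closed); zero-count classes are retained as 0.0% rows.
    """
    da, db = state_distribution(untreated), state_distribution(treated)
    states = [s for s in CYCLE_ORDER if s in untreated.counts or s in treated.counts]
    extra = [s for s in untreated.counts if s not in states]
    rows = []
    for s in states + extra:
        rows.append(
            {
                "cycle_step": s,
                f"count_{untreated.label}": untreated.counts.get(s, 0),
                f"percent_{untreated.label}": da.percent(s) if s in set(da.table["state"]) else 0.0,
                f"count_{treated.label}": treated.counts.get(s, 0),
                f"percent_{treated.label}": db.percent(s) if s in set(db.table["state"]) else 0.0,
            }
        )
    return pd.DataFrame(rows)
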