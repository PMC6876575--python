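"""Severing statistics and the two-color reannealing ratio.

Two complementary quantifications of filament severing:

* the global, cumulative number of severing events per µm of filament,
  f(t) = sum_{u<=t} N_sev(u) / sum_i l_i(u), where the denominator uses
  filament lengths *at the event's frame* (filaments keep shrinking while
  the assay runs);
* the per-cofilin-domain Kaplan-Meier survival of "has not yet severed",
  where domains lost to severing by another domain, to merging, or to the
  end of observation are right-censored.

Reannealing of severed filaments is scored as the fraction of two-colored
filaments among all analyzed filaments, with an exact (Clopper-Pearson)
binomial 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

DOMAIN_OUTCOMES = ("severed", "lost-other-domain", "merged", "censored")


@dataclass
class SeveringRecord:
    """Severing event log and per-frame filament length table.

    ``events``: columns time_s, filament_id, position_um.
    ``lengths``: columns time_s, filament_id, length_um (covering every frame
    at which events may occur).
    """

    events: pd.DataFrame
    lengths: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.lengths) and (self.lengths["length_um"] < 0).any():
            raise ValueError("filament lengths must be >= 0")


@dataclass
class DomainHistory:
    """Lifetime of one cofilin domain, timed from its nucleation frame."""

    domain_id: int
    duration_s: float
    outcome: str

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.outcome not in DOMAIN_OUTCOMES:
            raise ValueError(f"outcome must be one of {DOMAIN_OUTCOMES}")


@dataclass
class ReannealingCount:
    """Two-color filament count with exact binomial 95% CI."""

    n_two_color: int
    n_total: int
    ratio: float
    ci_low: float
    ci_high: float


def cumulative_severing_per_micron(record: SeveringRecord) -> pd.DataFrame:
    """Evaluate the cumulative severing statistic f(t) exactly.

    For every frame time u with events, the increment is N_sev(u) divided by
    the total filament length present at u; f is the running sum, carried
    forward over event-free frames.  Returns a stepwise series with columns
    time_s, n_events, total_length_um, f_per_um.
    """
    lengths = record.lengths
    totals = lengths.groupby("time_s")["length_um"].sum().sort_index()
    counts = (
        record.events.groupby("time_s").size()
        if len(record.events)
        else pd.Series(dtype=int)
    )
    out_rows = []
    f = 0.0
    for t, total in totals.items():
        n = int(counts.get(t, 0))
        if n > 0:
            if total <= 0:
                raise ValueError(f"severing events at t={t} but zero total length")
            f += n / total
        out_rows.append((t, n, total, f))
    missing = set(counts.index) - set(totals.index)
    if missing:
        raise ValueError(f"no length data for event frames {sorted(missing)}")
    return pd.DataFrame(
        out_rows, columns=["time_s", "n_events", "total_length_um", "f_per_um"]
    )


def km_domain_survival(
    histories: Iterable[DomainHistory], ci: bool = False
) -> pd.DataFrame:
    """Kaplan-Meier survival of the fraction of domains not yet severed.

    ``severed`` is the event; every other outcome (lost to another domain's
    severing, merged, censored at the end of observation) is right-censoring.
    Returns a step function with columns time_s, survival (and Greenwood
    95% bounds when ``ci``).
    """
    from lifelines import KaplanMeierFitter

    hist = list(histories)
    if not hist:
        raise ValueError("need at least one domain history")
    durations = np.array([h.duration_s for h in hist])
    observed = np.array([h.outcome == "severed" for h in hist])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    out = pd.DataFrame(
        {"time_s": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )
    if ci:
        ci_df = kmf.confidence_interval_survival_function_
        out["ci_low"] = ci_df.iloc[:, 0].to_numpy()
        out["ci_high"] = ci_df.iloc[:, 1].to_numpy()
    return out


def reannealing_ratio(n_two_color: int, n_total: int) -> ReannealingCount:
    """Two-color fraction with an exact Clopper-Pearson 95% CI."""
    if not (0 <= n_two_color <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_two_color <= n_total with n_total > 0")
    from statsmodels.stats.proportion import proportion_confint

    low, high = proportion_confint(n_two_color, n_total, alpha=0.05, method="beta")
    return ReannealingCount(
        n_two_color=n_two_color,
        n_total=n_total,
        ratio=n_two_color / n_total,
        ci_low=float(low),
        ci_high=float(high),
    )
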