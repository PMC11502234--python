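"""Prepulse-inhibition (%PPI) and startle-sensitization metrics.

A session is a table of startle trials: the maximal voltage deflection per
trial, labeled by trial type. Baseline startle is the mean amplitude over
"startle alone" trials; prepulse trial types are summarized relative to it.

%PPI is reported as the percent reduction of the startle response,
``100 * (1 - mean_prepulse / baseline)``, floored at 0% — so a trial type
whose response exceeds baseline reports 0% PPI and instead counts as
sensitized. The raw response ratio (``100 * mean/baseline``) is kept as a
diagnostic column; note that a pure ratio cannot go negative, which is why
the inhibition form is the one the 0% cap applies to.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["StartleSession", "percent_ppi", "sensitization_trials"]

BASELINE_TYPE = "startle_alone"


@dataclass(frozen=True)
class StartleSession:
    """Trial table with columns ``trial_type`` and ``amplitude`` (a.u. >= 0)."""

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"trial_type", "amplitude"} - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if (self.trials["amplitude"] < 0).any():
            raise ValueError("amplitudes must be nonnegative")

    @property
    def baseline(self) -> float:
        alone = self.trials.loc[self.trials["trial_type"] == BASELINE_TYPE, "amplitude"]
        if alone.empty:
            raise ValueError(f"no {BASELINE_TYPE!r} trials; baseline undefined")
        return float(alone.mean())

    def prepulse_types(self) -> list[str]:
        types = [t for t in self.trials["trial_type"].unique() if t != BASELINE_TYPE]
        return types


def percent_ppi(session: StartleSession) -> pd.DataFrame:
    """Percent prepulse inhibition per trial type.

    Returns a frame indexed by trial type with columns ``ppi_pct``
    (inhibition, floored at 0), ``startle_ratio_pct`` (diagnostic: response
    as percent of baseline), ``mean_amplitude`` and ``baseline``.
    """
    baseline = session.baseline
    if baseline <= 0:
        raise ValueError("baseline startle must be positive")
    types = session.prepulse_types()
    if not types:
        raise ValueError("session has no prepulse trials")
    rows = {}
    for t in types:
        mean_amp = float(
            session.trials.loc[session.trials["trial_type"] == t, "amplitude"].mean()
        )
        ratio = mean_amp / baseline
        rows[t] = {
            "ppi_pct": max(0.0, 100.0 * (1.0 - ratio)),
            "startle_ratio_pct": 100.0 * ratio,
            "mean_amplitude": mean_amp,
            "baseline": baseline,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def sensitization_trials(session: StartleSession) -> tuple[pd.Series, int]:
    """Baseline-normalized startle per trial type and the sensitized count.

    The normalized value is the trial-type mean as a percentage of baseline
    startle; a type is sensitized when it exceeds 100% (response beyond
    baseline instead of inhibition).
    """
    table = percent_ppi(session)
    normalized = table["startle_ratio_pct"]
    return normalized, int((normalized > 100.0).sum())
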