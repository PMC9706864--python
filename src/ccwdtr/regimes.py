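"""Threshold-based dynamic regimes for dialysis initiation.

A regime is a 4-tuple of thresholds: a pH cutoff and a potassium cutoff for
oliguric patients, and a separate pair for non-oliguric patients.  At every
daily decision point a regime prescribes initiation iff the stage-2
creatinine criterion has been met and, within the trailing 24 h, at least
one of the following occurred: pH fell strictly below the applicable pH
cutoff, potassium reached the applicable potassium cutoff, or the stage-3
oliguria criterion (urine output < 0.3 ml/kg/h sustained for 24 h) was met.
The oliguria branch is shared by all regimes.

Which threshold pair applies is selected by whether the stage-2 oliguria
criterion has (ever) been met by the decision day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: default threshold grids
PH_GRID = (7.0, 7.1, 7.2)
K_GRID = (6.0, 6.5, 7.0)


@dataclass(frozen=True)
class Regime:
    """One dynamic treatment regime.

    Attributes
    ----------
    index:
        1-based position in the canonical grid enumeration.
    x_ph_olig, x_ph_nonolig:
        pH thresholds (initiate when pH < threshold) for oliguric and
        non-oliguric patients respectively.
    x_k_olig, x_k_nonolig:
        potassium thresholds in mEq/l (initiate when K >= threshold).
    """

    index: int
    x_ph_olig: float
    x_ph_nonolig: float
    x_k_olig: float
    x_k_nonolig: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_ph_olig, self.x_ph_nonolig, self.x_k_olig, self.x_k_nonolig)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Regime {self.index}: pH<{self.x_ph_olig}/{self.x_ph_nonolig} "
            f"K>={self.x_k_olig}/{self.x_k_nonolig} (olig/non-olig)"
        )


@dataclass
class DecisionState:
    """Patient state at one daily decision point (pre-initiation).

    Lab extrema are taken over the trailing 24-h window; on a daily grid
    this is the day's recorded value.
    """

    day: int
    creatinine_criterion_met: bool
    oliguric_stage2_met: bool
    min_ph_last_24h: float
    max_k_last_24h: float
    oliguric_stage3_last_24h: bool
    rrt_active: bool = False


def enumerate_regimes(
    ph_grid: Sequence[float] = PH_GRID, k_grid: Sequence[float] = K_GRID
) -> list[Regime]:
    """Enumerate the full regime grid in canonical order.

    The index advances with the oliguric potassium threshold fastest, then
    the non-oliguric potassium threshold, then the oliguric pH threshold,
    then the non-oliguric pH threshold.  For the default 3x3x3x3 grid this
    yields 81 regimes with regime 1 = (7.0, 7.0, 6.0, 6.0) and
    regime 81 = (7.2, 7.2, 7.0, 7.0).
    """
    regimes = []
    idx = 1
    for ph_no in ph_grid:
        for ph_o in ph_grid:
            for k_no in k_grid:
                for k_o in k_grid:
                    regimes.append(
                        Regime(
                            index=idx,
                            x_ph_olig=ph_o,
                            x_ph_nonolig=ph_no,
                            x_k_olig=k_o,
                            x_k_nonolig=k_no,
                        )
                    )
                    idx += 1
    return regimes


def regime_by_index(index: int) -> Regime:
    """Look up a regime of the default grid by its 1-based index."""
    regimes = enumerate_regimes()
    if not 1 <= index <= len(regimes):
        raise ValueError(f"regime index out of range: {index}")
    return regimes[index - 1]


def regime_table(regimes: Iterable[Regime] | None = None) -> pd.DataFrame:
    """Regime grid as a table (one row per regime)."""
    if regimes is None:
        regimes = enumerate_regimes()
    return pd.DataFrame(
        [
            {
                "regime_index": r.index,
                "x_ph_olig": r.x_ph_olig,
                "x_ph_nonolig": r.x_ph_nonolig,
                "x_k_olig": r.x_k_olig,
                "x_k_nonolig": r.x_k_nonolig,
            }
            for r in regimes
        ]
    )


def prescribes_initiation(regime: Regime, state: DecisionState) -> bool:
    """Whether `regime` prescribes starting dialysis in `state`.

    Raises
    ------
    ValueError
        if the trailing-window lab values are missing (NaN); such a
        decision point is non-evaluable.
    """
    if state.rrt_active:
        raise ValueError("decision undefined once dialysis is active")
    if np.isnan(state.min_ph_last_24h) or np.isnan(state.max_k_last_24h):
        raise ValueError(f"missing lab window at day {state.day}")
    if not state.creatinine_criterion_met:
        return False
    if state.oliguric_stage2_met:
        x_ph, x_k = regime.x_ph_olig, regime.x_k_olig
    else:
        x_ph, x_k = regime.x_ph_nonolig, regime.x_k_nonolig
    return (
        state.min_ph_last_24h < x_ph
        or state.max_k_last_24h >= x_k
        or state.oliguric_stage3_last_24h
    )


def prescription_matrix(
    regime: Regime,
    creat_criterion_met: np.ndarray,
    oliguric_stage2_met: np.ndarray,
    min_ph: np.ndarray,
    max_k: np.ndarray,
    oliguric_stage3: np.ndarray,
) -> np.ndarray:
    """Vectorised `prescribes_initiation` over arrays of decision states.

    All inputs are broadcastable arrays (typically patients x days).
    Returns a boolean array of the same shape.  NaN labs yield False
    (callers mask non-evaluable cells separately).
    """
    x_ph = np.where(oliguric_stage2_met, regime.x_ph_olig, regime.x_ph_nonolig)
    x_k = np.where(oliguric_stage2_met, regime.x_k_olig, regime.x_k_nonolig)
    with np.errstate(invalid="ignore"):
        trigger = (min_ph < x_ph) | (max_k >= x_k) | oliguric_stage3
    return np.asarray(creat_criterion_met & trigger, dtype=bool)
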