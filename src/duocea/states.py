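"""Health states and DSI strata of the transition model."""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class HealthState(IntEnum):
    """Annual-cycle health states.

    The treated-large event slot (``LARGE_TREATED_VH``) is the single
    post-treatment bleeding substate: "re-bleeding" in standard-of-care
    naming, "post-treatment VH" in intervention naming.
    """

    NO_VARICES = 0
    SMALL_VARICES_NO_VH = 1
    SMALL_VARICES_VH = 2
    LARGE_UNTREATED_NO_VH = 3
    LARGE_UNTREATED_VH = 4
    LARGE_TREATED_STABLE = 5
    LARGE_TREATED_VH = 6
    DC_FIRST_YEAR = 7
    DC_SUBSEQUENT = 8
    DEAD_LIVER = 9
    DEAD_PROCEDURE = 10
    DEAD_OTHER = 11


N_STATES = len(HealthState)

#: alive states, in index order
ALIVE = np.arange(HealthState.NO_VARICES, HealthState.DEAD_LIVER)
#: alive states under varices surveillance (everything except DC)
SURVEILLANCE = np.arange(HealthState.NO_VARICES, HealthState.DC_FIRST_YEAR)
DEAD = np.arange(HealthState.DEAD_LIVER, N_STATES)


class Stratum(IntEnum):
    """DSI stratum relative to the 18.3 cutoff."""

    ABOVE = 0  # DSI > 18.3 (poor function, higher risk)
    BELOW = 1  # DSI <= 18.3 (stable function, lower risk)


N_STRATA = len(Stratum)
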