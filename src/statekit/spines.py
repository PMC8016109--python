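"""Dendritic-spine bookkeeping on longitudinal presence tables.

turnover_t = (gained_t + lost_t) / present_t between consecutive imaging
sessions; survival fraction = percentage of first-session spines still
present at each later session (a lost spine never rejoins the survivor
set); density = present spines per micrometer of dendrite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import PresenceTable


def turnover_metrics(pt: PresenceTable, denominator: str = "present_t"
                     ) -> pd.DataFrame:
    """Per-session turnover ratio with gained and lost fractions.

    For each session t >= 1 (0-based): gained = rows absent at t-1 and
    present at t; lost = present at t-1 and absent at t; the turnover
    denominator is the count present at t (``denominator='present_t'``,
    default) or the mean of the counts at t-1 and t
    (``denominator='mean'``). A zero denominator gives NaN.
    """
    P = pt.presence
    rows = []
    for t in range(1, pt.n_sessions):
        gained = int((~P[:, t - 1] & P[:, t]).sum())
        lost = int((P[:, t - 1] & ~P[:, t]).sum())
        present_t = int(P[:, t].sum())
        if denominator == "present_t":
            denom = present_t
        elif denominator == "mean":
            denom = 0.5 * (present_t + int(P[:, t - 1].sum()))
        else:
            raise ValueError("denominator must be 'present_t' or 'mean'")
        rows.append({
            "session": t,
            "gained": gained,
            "lost": lost,
            "present": present_t,
            "turnover": (gained + lost) / denom if denom > 0 else np.nan,
            "gained_frac": gained / present_t if present_t > 0 else np.nan,
            "lost_frac": lost / present_t if present_t > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def survival_fraction(pt: PresenceTable) -> np.ndarray:
    """Percentage of first-session spines still present at each session.

    Once a spine is absent at any session it leaves the survivor set for
    good, even if the same row is marked present later (a reappearing
    protrusion is a new spine under the upstream identity convention), so
    the fraction is non-increasing by construction.
    """
    P = pt.presence
    initial = P[:, 0]
    n0 = int(initial.sum())
    if n0 == 0:
        raise ValueError("no spines present at the first session")
    alive = initial.copy()
    out = np.empty(pt.n_sessions)
    for t in range(pt.n_sessions):
        alive = alive & P[:, t]
        out[t] = 100.0 * alive.sum() / n0
    return out


def density(pt: PresenceTable) -> np.ndarray:
    """Present spines per micrometer of dendrite at each session."""
    return pt.presence.sum(axis=0) / pt.dendrite_length
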