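"""Maximally selected log-rank cut-point search.

Dichotomising a continuous prognostic feature at the threshold that maximises
the two-group log-rank statistic is the core operation of cut-point software
such as X-tile. The scan below evaluates every observed feature value as a
candidate threshold (group = value > threshold), subject to a minimum group
fraction on each side, and returns the smallest threshold achieving the
maximal statistic. No multiplicity correction is applied inside the search,
which makes the selected p-value optimistic; downstream use should rely on
held-out data.
"""

from __future__ import annotations

import warnings

import numpy as np


class CutpointError(ValueError):
    """No admissible threshold exists for the requested group-size floor."""


def logrank_statistic(time, event, group) -> float:
    """Two-group log-rank chi-square statistic (1 df, ties by the standard
    hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    # counts at risk just before each unique time
    n_at_risk = n - start
    g_cum = np.concatenate(([0], np.cumsum(g)))
    n1_at_risk = int(g.sum()) - g_cum[start]
    d = np.add.reduceat(e.astype(int), start)
    d1 = np.add.reduceat((e & g).astype(int), start)
    has_event = d > 0
    nj = n_at_risk[has_event].astype(float)
    n1j = n1_at_risk[has_event].astype(float)
    dj = d[has_event].astype(float)
    d1j = d1[has_event].astype(float)
    if len(dj) == 0:
        return 0.0
    observed = d1j.sum()
    expected = (dj * n1j / nj).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1.0)
    var = np.nansum(np.where(nj > 1, var_terms, 0.0))
    if var <= 0:
        return 0.0
    return float((observed - expected) ** 2 / var)


def find_cutoff(values, time, event, min_fraction: float = 0.1) -> float:
    """Threshold on *values* maximising the two-group log-rank statistic.

    Candidates are the observed values; the high group is ``value >
    threshold``; both groups must hold at least ``min_fraction`` of the
    patients. Deterministic: on ties the smallest threshold wins.

    Raises :class:`CutpointError` when no threshold satisfies the floor
    (e.g. a constant feature).
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if np.isnan(values).any():
        raise ValueError("values contain NaN; impute before cut-point search")
    n = len(values)
    if n < 30:
        warnings.warn("cut-point search on fewer than 30 patients is unstable")
    if int(event.sum()) < 10:
        warnings.warn("cut-point search with fewer than 10 events is unstable")
    min_count = int(np.ceil(min_fraction * n))
    candidates = np.unique(values)
    best_stat = -1.0
    best_cut = None
    for c in candidates:
        high = values > c
        n_high = int(high.sum())
        if n_high < min_count or n - n_high < min_count:
            continue
        stat = logrank_statistic(time, event, high)
        if stat > best_stat + 1e-12:
            best_stat = stat
            best_cut = float(c)
    if best_cut is None:
        raise CutpointError(
            f"no threshold leaves at least {min_count} patients on each side"
        )
    return best_cut
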