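"""Replica-exchange ladder construction and exchange/mixing diagnostics.

The temperature ladder is geometric: T_i = T_min * (T_max/T_min)^(i/(N-1))
for i = 0..N-1, so the ratio of successive rungs is constant and both
endpoints are hit exactly.  Diagnostics operate purely on exchange logs; no
simulation energetics are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MembindError
from .io import ExchangeLog


@dataclass(frozen=True)
class LadderSpec:
    T_min: float
    T_max: float
    N_rep: int
    temperatures: tuple[float, ...]

    @property
    def common_ratio(self) -> float:
        if self.N_rep < 2:
            return 1.0
        return self.temperatures[1] / self.temperatures[0]


def make_ladder(T_min: float, T_max: float, N_rep: int) -> LadderSpec:
    """Geometric temperature ladder with exact endpoints.

    ``N_rep == 1`` is allowed only in the degenerate case T_min == T_max.
    """
    if T_min <= 0 or T_max < T_min:
        raise MembindError("require 0 < T_min <= T_max")
    if N_rep < 1:
        raise MembindError("N_rep must be >= 1")
    if N_rep == 1:
        if T_min != T_max:
            raise MembindError(
                "a single replica requires T_min == T_max"
            )
        return LadderSpec(T_min, T_max, 1, (float(T_min),))
    i = np.arange(N_rep)
    temps = T_min * np.exp(i * np.log(T_max / T_min) / (N_rep - 1))
    temps[0] = T_min
    temps[-1] = T_max
    return LadderSpec(T_min, T_max, N_rep, tuple(float(t) for t in temps))


@dataclass
class ExchangeDiagnostics:
    """Per-pair acceptance plus ladder-mixing statistics."""

    pair_attempted: dict[tuple[int, int], int]
    pair_accepted: dict[tuple[int, int], int]
    pair_rates: dict[tuple[int, int], float]  # NaN when never attempted
    mean_rate_pairs: float
    mean_rate_replicas: float
    visited_rungs: list[set[int]] | None = None
    all_rungs_visited: list[bool] | None = None
    round_trips: list[int] | None = None
    frozen_replicas: list[int] | None = None


def exchange_rates(log: ExchangeLog) -> ExchangeDiagnostics:
    """Per-adjacent-pair acceptance rates and their means.

    ``mean_rate_pairs`` averages over the N-1 pairs; ``mean_rate_replicas``
    averages per-replica rates (attempts involving each replica rung), the
    other reading of an 'average over replicas'.  Pairs with no attempts
    get a NaN rate and are excluded from the means.
    """
    pairs = [(i, i + 1) for i in range(log.n_replicas - 1)]
    attempted = {p: 0 for p in pairs}
    accepted = {p: 0 for p in pairs}
    for _, pair, acc in log.attempts:
        attempted[pair] += 1
        if acc:
            accepted[pair] += 1
    rates = {
        p: (accepted[p] / attempted[p]) if attempted[p] else float("nan")
        for p in pairs
    }
    valid = [r for r in rates.values() if not np.isnan(r)]
    mean_pairs = float(np.mean(valid)) if valid else float("nan")

    rep_att = np.zeros(log.n_replicas)
    rep_acc = np.zeros(log.n_replicas)
    for (i, j), n in attempted.items():
        rep_att[i] += n
        rep_att[j] += n
        rep_acc[i] += accepted[(i, j)]
        rep_acc[j] += accepted[(i, j)]
    with np.errstate(invalid="ignore"):
        rep_rates = np.where(rep_att > 0, rep_acc / np.maximum(rep_att, 1), np.nan)
    mean_reps = (
        float(np.nanmean(rep_rates)) if np.any(rep_att > 0) else float("nan")
    )
    return ExchangeDiagnostics(
        pair_attempted=attempted,
        pair_accepted=accepted,
        pair_rates=rates,
        mean_rate_pairs=mean_pairs,
        mean_rate_replicas=mean_reps,
    )


def mixing_diagnostics(log: ExchangeLog) -> ExchangeDiagnostics:
    """Rung visitation and bottom-to-top-and-back round trips per replica.

    A replica that fails to visit every rung is flagged as frozen/poorly
    mixed.
    """
    diag = exchange_rates(log)
    series = log.replica_temperature_series
    if series is None:
        raise MembindError("exchange log lacks a replayed temperature series")
    n_rep = log.n_replicas
    top = n_rep - 1
    visited = []
    all_visited = []
    round_trips = []
    frozen = []
    for r in range(n_rep):
        s = series[r]
        vis = set(int(x) for x in np.unique(s))
        visited.append(vis)
        complete = len(vis) == n_rep
        all_visited.append(complete)
        # round trip state machine: 0 -> top -> 0 counts one trip
        trips = 0
        stage = None  # None until first touch of rung 0
        for x in s:
            if x == 0:
                if stage == "up":
                    trips += 1
                stage = "bottom"
            elif x == top and stage in ("bottom", "up"):
                stage = "up"
        round_trips.append(trips)
        if not complete:
            frozen.append(r)
    diag.visited_rungs = visited
    diag.all_rungs_visited = all_visited
    diag.round_trips = round_trips
    diag.frozen_replicas = frozen
    return diag
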