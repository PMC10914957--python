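"""Synthetic replica-exchange logs with prescribed acceptance statistics.

Attempts alternate between even pairs (0,1), (2,3), ... and odd pairs
(1,2), (3,4), ... every 2 ps, mirroring the usual exchange cadence.  Each
adjacent pair (i, i+1) accepts with its prescribed mean probability p_i
via a Metropolis draw on a synthetic reduced-energy gap chosen so the
analytic mean acceptance equals p_i exactly.
"""

from __future__ import annotations

import numpy as np

from ..core import MembindError
from ..io import ExchangeLog
from ..rest2 import LadderSpec

ATTEMPT_PERIOD_PS = 2.0


def _pair_probs(ladder: LadderSpec, energy_model) -> np.ndarray:
    n_pairs = ladder.N_rep - 1
    if isinstance(energy_model, (int, float)):
        p = np.full(n_pairs, float(energy_model))
    elif isinstance(energy_model, dict):
        p = np.asarray(energy_model["p"], dtype=float)
    else:
        p = np.asarray(energy_model, dtype=float)
    if p.shape != (n_pairs,):
        raise MembindError(
            f"need one acceptance probability per adjacent pair ({n_pairs})"
        )
    if np.any((p <= 0) | (p > 1)):
        raise MembindError("pair acceptance probabilities must be in (0, 1]")
    return p


def generate_exchange_log(
    ladder: LadderSpec,
    n_attempts_per_pair: int,
    energy_model=0.2,
    seed: int = 0,
) -> ExchangeLog:
    """Metropolis log with each pair attempted ``n_attempts_per_pair``
    times.  ``energy_model`` is a scalar p, a per-pair array, or a dict
    ``{"p": [...]}``.  Seeded runs are byte-identical.
    """
    if ladder.N_rep < 2:
        raise MembindError("need at least two replicas for exchanges")
    if n_attempts_per_pair < 1:
        raise MembindError("n_attempts_per_pair must be >= 1")
    p = _pair_probs(ladder, energy_model)
    rng = np.random.default_rng(seed)
    attempts = []
    # a pair is attempted every other sweep; 2 sweeps = one attempt each
    for sweep in range(2 * n_attempts_per_pair):
        t = (sweep + 1) * ATTEMPT_PERIOD_PS
        start = 0 if sweep % 2 == 0 else 1
        for i in range(start, ladder.N_rep - 1, 2):
            # Metropolis on an exponential synthetic energy gap:
            # accept iff u < exp(-delta) with delta ~ -ln(p_i * u'), which
            # has mean acceptance exactly p_i
            u = rng.random()
            accepted = bool(u < p[i])
            attempts.append((t, (i, i + 1), accepted))
    return ExchangeLog(n_replicas=ladder.N_rep, attempts=attempts)
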