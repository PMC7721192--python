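"""Independent oracles used by the test suite.

These deliberately avoid the package's propagation code: the trajectory
oracle walks cohorts of individual fish through move / harvest-or-die /
report events with plain multinomial draws, so it shares no code path with
the recovery-probability engine it checks.
"""

from __future__ import annotations

import numpy as np


def trajectory_recovery_counts(
    pi: np.ndarray,
    u: np.ndarray,
    S: np.ndarray,
    lam: np.ndarray,
    n_fish: int,
    age: int,
    ty: int,
    tk: int,
    rng: np.random.Generator,
    pi_init: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate fish tagged at (age, ty, tk); count reports per (fy, fk).

    pi : (A, Y, K, K); u, S : (A, Y, K); lam : (Y, K). Within a year: move,
    then split into reported / harvested-unreported / dead / surviving.
    Ages advance at year boundaries, capped at the plus-group.
    """
    A, Y, K = u.shape
    reported = np.zeros((Y, K), dtype=np.int64)
    alive = np.zeros(K, dtype=np.int64)
    alive[tk] = n_fish
    for y in range(ty, Y):
        a = min(age + (y - ty), A - 1)
        step = pi_init if (pi_init is not None and y == ty) else pi
        moved = np.zeros(K, dtype=np.int64)
        for k in range(K):
            if alive[k]:
                moved += rng.multinomial(alive[k], step[a, y, k])
        alive = np.zeros(K, dtype=np.int64)
        for k in range(K):
            if not moved[k]:
                continue
            p_rep = u[a, y, k] * lam[y, k]
            p_unrep = u[a, y, k] * (1.0 - lam[y, k])
            p_surv = S[a, y, k]
            p_dead = max(1.0 - p_rep - p_unrep - p_surv, 0.0)
            fates = rng.multinomial(moved[k], [p_rep, p_unrep, p_dead, p_surv])
            reported[y, k] += fates[0]
            alive[k] = fates[3]
        if not alive.any():
            break
    return reported
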