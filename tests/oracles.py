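"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations

import numpy as np


def brute_force_concordance(lp, time, event, alpha: float = 1.0):
    """O(n^2) pair enumeration of the (weighted) concordance index.

    A pair is relevant iff the member with the strictly shorter time has an
    event; concordance credit 1 / 0.5 / 0 by the linear-predictor ordering;
    case-control pairs (the longer-lived member is not a case) weighted
    1/alpha.  Returns (estimate, counts) with counts ordered
    (c1, d1, u1, c0, d0, u0).
    """
    n = len(lp)
    counts = dict(c1=0, d1=0, u1=0, c0=0, d0=0, u0=0)
    num = 0.0
    den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j] or event[i] != 1:
                continue
            cls = "1" if event[j] == 1 else "0"
            w = 1.0 if cls == "1" else 1.0 / alpha
            if lp[i] > lp[j]:
                counts["c" + cls] += 1
                num += w
            elif lp[i] < lp[j]:
                counts["d" + cls] += 1
            else:
                counts["u" + cls] += 1
                num += 0.5 * w
            den += w
    est = num / den
    return est, tuple(counts[k] for k in ("c1", "d1", "u1", "c0", "d0", "u0"))


def nelson_aalen(time, event):
    """Breslow/Nelson-Aalen cumulative hazard at each distinct event time."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    times = np.unique(t[e == 1])
    ch = []
    total = 0.0
    for tk in times:
        d = np.sum((t == tk) & (e == 1))
        at_risk = np.sum(t >= tk)
        total += d / at_risk
        ch.append(total)
    return times, np.array(ch)
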