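"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def c_index_oracle(scores, times, events):
    """Exhaustive ordered-pair enumeration of Harrell's C."""
    conc = ties = n = 0
    m = len(scores)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            n += 1
            if scores[i] > scores[j]:
                conc += 1
            elif scores[i] == scores[j]:
                ties += 1
    return (conc + 0.5 * ties) / n, n


def two_group_logrank_oracle(t1, e1, t2, e2):
    """Hand observed/expected log-rank chi-square for two groups."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(times[events == 1]):
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
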