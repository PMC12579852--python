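"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized implementations: plain
Python loops and textbook formulas only, so that agreement is meaningful.
"""

from itertools import accumulate

import numpy as np


def brute_force_sequence_metrics(breaths):
    """Recompute every sequence metric from a list of (start, end) pairs."""
    starts = [s for s, _ in breaths]
    ends = [e for _, e in breaths]
    inh = [(e - s) / 2.0 for s, e in breaths]
    n = len(breaths)
    out = {
        "breath_count": n,
        "sequence_duration_s": starts[-1] - starts[0],
        "total_inhalation_s": sum(inh),
        "initial_inhalation_s": inh[0],
        "mean_ibi_s": None,
        "accumulation_rate": None,
        "terminal_inhalation_s": None,
    }
    if n >= 2:
        gaps = [starts[k + 1] - ends[k] for k in range(n - 1)]
        out["mean_ibi_s"] = sum(gaps) / len(gaps)
        xs = [s - starts[0] for s in starts]
        ys = list(accumulate(inh))
        xbar = sum(xs) / n
        ybar = sum(ys) / n
        sxx = sum((x - xbar) ** 2 for x in xs)
        sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
        out["accumulation_rate"] = sxy / sxx
        out["terminal_inhalation_s"] = inh[-1]
    return out


def random_breath_sequence(rng, max_breaths=6):
    """One random, well-ordered sequence of (start, end) breath intervals."""
    n = int(rng.integers(1, max_breaths + 1))
    t = float(rng.uniform(0, 1000))
    breaths = []
    for _ in range(n):
        dur = float(rng.uniform(0.5, 5.0))
        breaths.append((t, t + dur))
        t += dur + float(rng.uniform(1.0, 40.0))
    return breaths


def zero_truncated_poisson_mean(lam):
    return lam / (1.0 - np.exp(-lam))
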