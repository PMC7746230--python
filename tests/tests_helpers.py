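"""Helpers shared by test modules (kept out of conftest fixtures)."""
import numpy as np

from afmbone import Condition, PullMetrics, summarize_condition


def condition_summary(substrate, solution, mean, ph=7.4, n=10, sd=0.1):
    cond = Condition(substrate, solution, ph)
    vals = mean + sd * np.linspace(-1, 1, n)
    metrics = [PullMetrics(1e-9, 5e-7, float(v), condition=cond.key)
               for v in vals]
    return summarize_condition(metrics, cond)
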