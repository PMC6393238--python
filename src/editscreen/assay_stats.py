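"""Supporting statistics for perturbation experiments on the reporter.

Knockdown and interferon-induction experiments are summarised as a fold
change of the treated group's mean Nluc/FFL ratio over the control mean,
with a two-sided two-sample Student's t-test (equal variances by default;
Welch available). Significance stars follow the common figure-legend
convention: ** for p < 0.01, *** for p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupComparison:
    treated: tuple[float, ...]
    control: tuple[float, ...]
    fold: float
    p_value: float | None
    n_treated: int
    n_control: int

    @property
    def stars(self) -> str:
        if self.p_value is None:
            return "n/a"
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        return "NS"


def fold_change(
    treated: Sequence[float],
    control: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Mean fold change treated/control with a two-sided t-test.

    Both groups must be non-empty with positive means (these are ratio
    measurements). With fewer than two values in either group the fold is
    still reported but no p-value is attached. The statistic is scale
    invariant: rescaling both groups by a common factor changes neither
    fold nor p.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (t.mean() > 0 and c.mean() > 0):
        raise ValueError("group means must be positive for a fold change")
    fold = float(t.mean() / c.mean())
    p: float | None = None
    if t.size >= 2 and c.size >= 2:
        p = float(stats.ttest_ind(t, c, equal_var=equal_var).pvalue)
    return GroupComparison(tuple(t), tuple(c), fold, p, int(t.size), int(c.size))
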