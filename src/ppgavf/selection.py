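"""Statistical feature selection: before-vs-after dialysis t-tests.

A candidate pulse feature (rising or falling slope) is kept for classification
when its per-patient values differ significantly between the pre- and
post-dialysis recordings.  Two test variants are provided:

``paired``
    Student's paired t on the per-patient differences d_i = after_i - before_i,
    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.  This is the default: it is the
    variant that matches the published decisions for this kind of
    before/after design (the same subjects are measured twice).
``welch``
    The unpaired unequal-variance statistic
    t = (xbar1 - xbar2) / sqrt(S1^2/n1 + S2^2/n2) with Welch–Satterthwaite
    degrees of freedom.

Both report two-sided p-values from the Student-t distribution, and a feature
is selected when p < alpha (strict inequality), alpha = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    feature_name: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float
    variant: str

    @property
    def rejected(self) -> bool:
        """True when the no-difference hypothesis is rejected (p < alpha)."""
        return self.p_value < self.alpha

    @property
    def decision(self) -> str:
        return "rejected" if self.rejected else "not_rejected"

    def to_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "variant": self.variant,
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "alpha": self.alpha,
            "decision": self.decision,
        }


def t_test(
    before: Sequence[float],
    after: Sequence[float],
    variant: str = "paired",
    alpha: float = DEFAULT_ALPHA,
    feature_name: str = "",
) -> TTestResult:
    """Two-sided before/after t-test on per-patient feature values."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    if variant == "paired":
        if before.size != after.size:
            raise ValueError(
                f"paired test needs equal sample sizes, got {before.size} and {after.size}"
            )
        n = before.size
        if n < 2:
            raise ValueError("paired test needs at least 2 pairs")
        diff = after - before
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("t statistic undefined: differences have zero variance")
        t_stat = diff.mean() / (sd / np.sqrt(n))
        df = float(n - 1)
    elif variant == "welch":
        n1, n2 = before.size, after.size
        if n1 < 2 or n2 < 2:
            raise ValueError("welch test needs at least 2 values per group")
        v1 = before.var(ddof=1)
        v2 = after.var(ddof=1)
        denom_sq = v1 / n1 + v2 / n2
        if denom_sq == 0:
            raise ValueError("t statistic undefined: both groups have zero variance")
        t_stat = (before.mean() - after.mean()) / np.sqrt(denom_sq)
        df = denom_sq**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValueError(f"variant must be 'paired' or 'welch', got {variant!r}")

    p_value = 2.0 * stats.t.sf(abs(t_stat), df)
    return TTestResult(
        feature_name=feature_name,
        t_statistic=float(t_stat),
        degrees_of_freedom=float(df),
        p_value=float(p_value),
        alpha=alpha,
        variant=variant,
    )


def select_features(
    results: Mapping[str, TTestResult], alpha: float | None = None
) -> list[str]:
    """Names of the features whose tests reject the no-difference hypothesis.

    Selection uses strict inequality p < alpha; a p-value exactly at alpha is
    not selected.  An empty ``results`` mapping is rejected — callers that
    want a fall-back when nothing is significant handle it themselves (the
    pipeline warns and keeps all candidate features in that case).
    """
    if not results:
        raise ValueError("no t-test results supplied")
    selected = []
    for name, result in results.items():
        a = alpha if alpha is not None else result.alpha
        if result.p_value < a:
            selected.append(name)
    return selected
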