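"""Confusion-matrix metrics with Clopper-Pearson exact binomial intervals.

Used to benchmark predicted prophage classes against experimentally
established induction modes (mitomycin-C induction assays, EMSA binding
data).  The exact interval is the right choice at the small n typical of
wet-lab truth sets: at k = n successes its lower bound has the closed form
(alpha/2)^(1/n), e.g. 24/24 at 95% gives 0.858.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import beta

SUP_POLICIES = ("count_as_wrong", "exclude")


@dataclass(frozen=True)
class ValidationResult:
    n: int
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    level: float = 0.95


def exact_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval for a binomial proportion."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def confusion_metrics(
    truth: Sequence[str],
    predicted: Sequence[str],
    positive_label: str = "SdP",
    level: float = 0.95,
    sup_policy: str = "count_as_wrong",
) -> ValidationResult:
    """Sensitivity, specificity, accuracy and an exact accuracy CI.

    ``truth`` holds binary labels ({SdP, SiP}); ``predicted`` may also contain
    SuP, handled per ``sup_policy``: counted as wrong against either truth
    (default) or excluded from the tally.
    """
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    if sup_policy not in SUP_POLICIES:
        raise ValueError(f"sup_policy must be one of {SUP_POLICIES}")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if p == "SuP":
            if sup_policy == "exclude":
                continue
            # an uncertain call is wrong against either truth label
            if t == positive_label:
                fn += 1
            else:
                fp += 1
            continue
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    n = tp + tn + fp + fn
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    accuracy = (tp + tn) / n if n else float("nan")
    ci = exact_binomial_ci(tp + tn, n, level) if n else (float("nan"), float("nan"))
    return ValidationResult(
        n=n, tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sensitivity, specificity=specificity, accuracy=accuracy,
        accuracy_ci=ci, level=level,
    )
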