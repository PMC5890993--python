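"""Evaluation against ground truth.

Sensitivity is TP / (TP + FN) over the expected variants; specificity is
TN / (TN + FP) over the full space of variant tests the panel supports
(base pairs x 4), with the false-positive rate also expressed per 10,000
variant tests, the natural currency when panels differ in size. AF
windows restrict which variants count: the window applies to the
EXPECTED allele frequency of truth variants (sensitivity is quoted for a
spike range) and to the OBSERVED allele frequency of false-positive
calls (specificity is quoted "calling down to" an AF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matrix import VariantKey


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    variant_tests: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fp_rate(self) -> float:
        return 1.0 - self.specificity

    @property
    def fp_per_10k(self) -> float:
        return self.fp_rate * 10_000.0

    def summary(self) -> str:
        return (
            f"TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn} "
            f"(of {self.variant_tests} variant tests)\n"
            f"sensitivity = {self.sensitivity:.4%}\n"
            f"specificity = {self.specificity:.4%}\n"
            f"false positives per 10k variant tests = {self.fp_per_10k:.4g}\n"
        )


def evaluate(
    calls: Iterable[tuple[VariantKey, float]],
    truth: Iterable[tuple[VariantKey, float]],
    variant_tests: int,
    af_window: Sequence[float] | None = None,
) -> EvalResult:
    """Confusion-matrix evaluation by exact VariantKey matching.

    ``calls`` pairs each called key with its observed mean AF; ``truth``
    pairs each expected key with its expected AF. A call matching a
    truth variant outside the AF window is neither TP nor FP (it is a
    real variant, just not one the window asks about).
    """
    truth_af = dict(truth)
    call_af = dict(calls)
    if variant_tests < len(truth_af):
        raise ValueError(
            f"variant_tests = {variant_tests} below the {len(truth_af)} truth variants"
        )
    lo, hi = (af_window if af_window is not None else (0.0, 1.0))
    truth_in = {k for k, af in truth_af.items() if lo <= af <= hi}
    tp = sum(1 for k in truth_in if k in call_af)
    fn = len(truth_in) - tp
    fp = sum(
        1
        for k, af in call_af.items()
        if k not in truth_af and lo <= af <= hi
    )
    tn = variant_tests - len(truth_in) - fp
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn, variant_tests=variant_tests)


def fp_rate_floor(n_tests: int) -> float:
    """Smallest demonstrable nonzero FP rate, as a percentage.

    A study that tests only n candidate sites can never demonstrate a
    false-positive rate below 1/n; quoting this floor makes specificity
    claims from small pre-selected test sets comparable with panel-wide
    ones.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 100.0 / n_tests
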