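"""Concordance statistics for paired reference/test labels.

Seven measures are computed from a 2x2 table: percent agreement, AUCR,
sensitivity, specificity, NPV, PPV, and Cohen's kappa.  For a single
dichotomous test the empirical ROC has one operating point, so AUCR is the
trapezoidal area (sensitivity + specificity) / 2, i.e. balanced accuracy.

Confidence intervals use the percentile bootstrap: participants are
resampled with replacement (paired labels travel together), the measure is
recomputed per replicate, and the CI is the empirical (alpha/2,
1 - alpha/2) quantile pair over the defined replicates.  Replicates where a
measure is undefined (empty denominator) are dropped and counted rather
than imputed; more than 50% undefined replicates is an error.

Measures with an empty denominator return NaN (an "undefined" marker, not
zero and not an exception) so the bootstrap can handle them uniformly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort_io import RunConfig
from .surgical_typology import COMPARISONS

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "percent_agreement",
    "aucr",
    "cohens_kappa",
    "METRICS",
    "BootstrapCI",
    "bootstrap_ci",
    "Estimate",
    "AccuracyReport",
    "full_report",
    "paired_labels",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts for one reference-vs-test comparison."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(
    reference: Mapping[str, Mapping[str, bool]],
    test: Mapping[str, Mapping[str, bool]],
    key: str = "overall",
) -> ContingencyTable:
    """Cross-tabulate one comparison (``overall``/``SE``/``OE``/``DE``).

    Both label maps must cover exactly the same participant set.
    """
    if set(reference) != set(test):
        missing = sorted(set(reference) ^ set(test))
        raise ValueError(f"participant sets differ; mismatched ids: {missing}")
    tp = fp = fn = tn = 0
    for pid, ref in reference.items():
        r, t = ref[key], test[pid][key]
        if r and t:
            tp += 1
        elif r and not t:
            fn += 1
        elif t:
            fp += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def sensitivity(t: ContingencyTable) -> float:
    return _ratio(t.tp, t.tp + t.fn)


def specificity(t: ContingencyTable) -> float:
    return _ratio(t.tn, t.tn + t.fp)


def ppv(t: ContingencyTable) -> float:
    return _ratio(t.tp, t.tp + t.fp)


def npv(t: ContingencyTable) -> float:
    return _ratio(t.tn, t.tn + t.fn)


def percent_agreement(t: ContingencyTable) -> float:
    """Observed agreement as a fraction in [0, 1] (multiply by 100 for %)."""
    return _ratio(t.tp + t.tn, t.n)


def aucr(t: ContingencyTable) -> float:
    return (sensitivity(t) + specificity(t)) / 2.0


def cohens_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement, (p_o - p_e) / (1 - p_e).

    When chance agreement is exactly 1 the statistic is defined as 1 for
    perfect observed agreement and NaN otherwise.  N = 0 is an error.
    """
    n = t.n
    if n == 0:
        raise ValueError("cohens_kappa requires at least one participant")
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1.0 - p_e)


METRICS: Mapping[str, Callable[[ContingencyTable], float]] = {
    "percent_agreement": percent_agreement,
    "aucr": aucr,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "npv": npv,
    "ppv": ppv,
    "kappa": cohens_kappa,
}


class BootstrapCI(NamedTuple):
    lower: float
    upper: float
    n_undefined: int


def paired_labels(
    reference: Mapping[str, Mapping[str, bool]],
    test: Mapping[str, Mapping[str, bool]],
    key: str = "overall",
) -> list[Tuple[bool, bool]]:
    """Extract (reference, test) boolean pairs for one comparison, in a
    deterministic participant order."""
    if set(reference) != set(test):
        missing = sorted(set(reference) ^ set(test))
        raise ValueError(f"participant sets differ; mismatched ids: {missing}")
    return [
        (bool(reference[pid][key]), bool(test[pid][key]))
        for pid in sorted(reference)
    ]


def _categories(labels: Sequence[Tuple[bool, bool]]) -> np.ndarray:
    # 3 = TP, 2 = FN, 1 = FP, 0 = TN
    arr = np.asarray(labels, dtype=bool)
    return (2 * arr[:, 0] + arr[:, 1]).astype(np.int64)


def _resample_counts(
    cat: np.ndarray, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, 4) array of TN/FP/FN/TP counts over bootstrap resamples."""
    n = cat.shape[0]
    idx = rng.integers(0, n, size=(reps, n))
    resampled = cat[idx]
    counts = np.empty((reps, 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = (resampled == k).sum(axis=1)
    return counts


def _percentile_ci(
    values: np.ndarray, ci_level: float, context: str, strict: bool = True
) -> BootstrapCI:
    defined = values[~np.isnan(values)]
    n_undefined = values.size - defined.size
    if n_undefined > 0.5 * values.size:
        if strict:
            raise ValueError(
                f"{context}: metric undefined in {n_undefined}/{values.size} "
                "bootstrap replicates; a larger sample is needed"
            )
        # report assembly degrades gracefully so one degenerate cell does
        # not sink the whole table
        return BootstrapCI(math.nan, math.nan, int(n_undefined))
    alpha = (1.0 - ci_level) / 2.0
    lower, upper = np.percentile(defined, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(float(lower), float(upper), int(n_undefined))


def _bootstrap_metric_values(
    counts: np.ndarray, metric: Callable[[ContingencyTable], float]
) -> np.ndarray:
    values = np.empty(counts.shape[0])
    for i, (tn_, fp_, fn_, tp_) in enumerate(counts):
        values[i] = metric(
            ContingencyTable(tp=int(tp_), fp=int(fp_), fn=int(fn_), tn=int(tn_))
        )
    return values


def bootstrap_ci(
    labels: Sequence[Tuple[bool, bool]],
    metric: Callable[[ContingencyTable], float],
    config: RunConfig,
    rng: np.random.Generator | None = None,
) -> BootstrapCI:
    """Percentile-bootstrap CI of ``metric`` over participant resamples.

    Fully reproducible given ``config.rng_seed``; returns the CI bounds and
    the number of dropped (undefined) replicates.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("bootstrap requires at least 2 participants")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    cat = _categories(labels)
    counts = _resample_counts(cat, config.bootstrap_reps, rng)
    values = _bootstrap_metric_values(counts, metric)
    name = getattr(metric, "__name__", "metric")
    return _percentile_ci(values, config.ci_level, name)


@dataclasses.dataclass(frozen=True)
class Estimate:
    """Point estimate with percentile-bootstrap CI bounds."""

    point: float
    lower: float
    upper: float
    n_undefined: int = 0


@dataclasses.dataclass
class AccuracyReport:
    """All seven measures for the overall and subtype comparisons."""

    comparisons: dict[str, dict[str, Estimate]]
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: comparison, metric, point, lower, upper."""
        rows = []
        for comp, metrics in self.comparisons.items():
            for name, est in metrics.items():
                rows.append(
                    {
                        "comparison": comp,
                        "metric": name,
                        "point": est.point,
                        "lower": est.lower,
                        "upper": est.upper,
                        "n_undefined_replicates": est.n_undefined,
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Human-readable table, metric rows by comparison columns."""

        def cell(name: str, est: Estimate) -> str:
            if name == "percent_agreement":
                return (
                    f"{100 * est.point:.1f}%"
                    f"({100 * est.lower:.1f}%, {100 * est.upper:.1f}%)"
                )
            return f"{est.point:.2f}({est.lower:.2f}, {est.upper:.2f})"

        comps = list(self.comparisons)
        width = 26
        header = "measure".ljust(20) + "".join(c.ljust(width) for c in comps)
        lines = [header, "-" * len(header)]
        for name in METRICS:
            row = name.ljust(20)
            for comp in comps:
                row += cell(name, self.comparisons[comp][name]).ljust(width)
            lines.append(row)
        return "\n".join(lines)


def full_report(
    reference: Mapping[str, Mapping[str, bool]],
    test: Mapping[str, Mapping[str, bool]],
    config: RunConfig,
) -> AccuracyReport:
    """Compute every measure for every comparison, with bootstrap CIs.

    Subtype comparisons use all N participants: subtype-negative includes
    both controls and cases of other subtypes.  One set of resamples per
    comparison is shared across the seven measures, seeded from
    ``config.rng_seed`` and the comparison index.
    """
    comparisons: dict[str, dict[str, Estimate]] = {}
    for idx, comp in enumerate(COMPARISONS):
        labels = paired_labels(reference, test, comp)
        table = build_contingency(reference, test, comp)
        rng = np.random.default_rng([config.rng_seed, idx])
        counts = _resample_counts(
            _categories(labels), config.bootstrap_reps, rng
        )
        metrics: dict[str, Estimate] = {}
        for name, fn in METRICS.items():
            values = _bootstrap_metric_values(counts, fn)
            ci = _percentile_ci(
                values, config.ci_level, f"{comp}/{name}", strict=False
            )
            metrics[name] = Estimate(
                point=fn(table),
                lower=ci.lower,
                upper=ci.upper,
                n_undefined=ci.n_undefined,
            )
        comparisons[comp] = metrics
    return AccuracyReport(comparisons=comparisons, n=len(reference))
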