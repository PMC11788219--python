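"""Error analysis, subgroup (diversity) analysis, and pipeline orchestration.

False negatives (surgically confirmed cases with no retained administrative
code) are profiled by the categories of the codes they *do* carry in the
study window — laparoscopy/laparotomy, pain, other symptom, other.  False
positives are tallied by the administrative subtype recorded for them.
Subgroup analysis recomputes agreement, AUCR, and kappa within race and
ethnicity strata.
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import claims_processing, cohort_io, diagnostic_accuracy
from .cohort_io import (
    ClaimRecord,
    HispanicEthnicity,
    RaceGroup,
    RunConfig,
    SurgicalRecord,
)
from .diagnostic_accuracy import Estimate
from .surgical_typology import reference_labels

__all__ = [
    "DEFAULT_FN_VOCAB",
    "error_analysis_fn",
    "error_analysis_fp",
    "subgroup_report",
    "run_pipeline",
    "SmallSampleWarning",
]

# Code-prefix vocabulary for binning false-negative participants' retained
# codes; dots optional, longest semantics not needed (first matching
# category wins per code, a participant may land in several categories).
DEFAULT_FN_VOCAB: Mapping[str, Sequence[str]] = {
    "laparoscopy_laparotomy": ["54.21", "54.19", "54.11", "0DJ", "0UJ"],
    "pain": ["625.9", "789.0", "R10", "338", "625.5"],
    "other_symptom": ["626", "780", "R53", "627"],
}

SUBGROUP_METRICS = ("percent_agreement", "aucr", "kappa")


class SmallSampleWarning(UserWarning):
    """A stratum has too few participants for stable estimates."""


def _norm(code: str) -> str:
    return code.strip().upper().replace(".", "")


def error_analysis_fn(
    fn_participants: Iterable[str],
    claims: Iterable[ClaimRecord],
    vocab: Mapping[str, Sequence[str]],
) -> Counter:
    """Bin false-negative participants by the categories of their retained
    codes.

    ``claims`` must already be window-filtered.  A participant contributes
    at most once to each category; codes matching no vocabulary prefix fall
    into ``other``.  Returns an empty counter when there are no false
    negatives (or no retained codes).
    """
    fn_set = set(fn_participants)
    normalized_vocab = {
        cat: [_norm(p) for p in prefixes] for cat, prefixes in vocab.items()
    }
    per_participant: dict[str, set[str]] = {}
    for c in claims:
        if c.participant_id not in fn_set:
            continue
        code = _norm(c.code)
        matched = [
            cat
            for cat, prefixes in normalized_vocab.items()
            if any(code.startswith(p) for p in prefixes)
        ]
        cats = per_participant.setdefault(c.participant_id, set())
        cats.update(matched if matched else ["other"])
    counts: Counter = Counter()
    for cats in per_participant.values():
        counts.update(cats)
    return counts


def error_analysis_fp(
    fp_participants: Iterable[str],
    test: Mapping[str, Mapping[str, bool]],
) -> Counter:
    """Tally the administrative subtype flags among false positives.

    ``NOS`` counts participants whose retained codes carried no
    subtype-specific mapping.  Empty when there are no false positives.
    """
    counts: Counter = Counter()
    for pid in fp_participants:
        labels = test[pid]
        any_subtype = False
        for key in ("SE", "OE", "DE"):
            if labels[key]:
                counts[key] += 1
                any_subtype = True
        if labels["overall"] and not any_subtype:
            counts["NOS"] += 1
    return counts


def _stratum_estimates(
    reference: Mapping[str, Mapping[str, bool]],
    test: Mapping[str, Mapping[str, bool]],
    pids: Sequence[str],
    config: RunConfig,
    seed_index: int,
) -> dict[str, Estimate]:
    ref = {pid: reference[pid] for pid in pids}
    tst = {pid: test[pid] for pid in pids}
    labels = diagnostic_accuracy.paired_labels(ref, tst, "overall")
    table = diagnostic_accuracy.build_contingency(ref, tst, "overall")
    rng = np.random.default_rng([config.rng_seed, 1000 + seed_index])
    counts = diagnostic_accuracy._resample_counts(
        diagnostic_accuracy._categories(labels), config.bootstrap_reps, rng
    )
    out: dict[str, Estimate] = {}
    for name in SUBGROUP_METRICS:
        fn = diagnostic_accuracy.METRICS[name]
        values = diagnostic_accuracy._bootstrap_metric_values(counts, fn)
        ci = diagnostic_accuracy._percentile_ci(
            values, config.ci_level, name, strict=False
        )
        out[name] = Estimate(fn(table), ci.lower, ci.upper, ci.n_undefined)
    return out


def subgroup_report(
    reference: Mapping[str, Mapping[str, bool]],
    test: Mapping[str, Mapping[str, bool]],
    records: Iterable[SurgicalRecord],
    config: RunConfig,
) -> dict[str, dict]:
    """Overall-diagnosis accuracy within race and ethnicity strata.

    Race strata are "woc" (every race_group other than white; unknown race
    joins this stratum when ``config.include_unknown_race_in_woc``, the
    default, otherwise it is excluded) and "white".  Ethnicity strata are
    "hispanic" / "non_hispanic"; participants with missing ethnicity are
    excluded from that contrast.  Strata with fewer than 10 participants
    carry a small-sample flag and emit :class:`SmallSampleWarning`.
    """
    records = list(records)
    woc_races = {RaceGroup.WOC}
    if config.include_unknown_race_in_woc:
        woc_races.add(RaceGroup.UNKNOWN)
    strata: dict[str, list[str]] = {
        "woc": [r.participant_id for r in records if r.race_group in woc_races],
        "white": [
            r.participant_id
            for r in records
            if r.race_group is RaceGroup.WHITE
        ],
        "hispanic": [
            r.participant_id
            for r in records
            if r.hispanic is HispanicEthnicity.YES
        ],
        "non_hispanic": [
            r.participant_id
            for r in records
            if r.hispanic is HispanicEthnicity.NO
        ],
    }
    report: dict[str, dict] = {}
    for idx, (name, pids) in enumerate(strata.items()):
        small = len(pids) < 10
        if small:
            warnings.warn(
                f"stratum {name!r} has only {len(pids)} participants; "
                "estimates are unstable",
                SmallSampleWarning,
                stacklevel=2,
            )
        report[name] = {
            "n": len(pids),
            "small_sample": small,
            "metrics": _stratum_estimates(reference, test, pids, config, idx),
        }
    return report


def _subgroup_frame(subgroups: Mapping[str, dict]) -> pd.DataFrame:
    rows = []
    for stratum, entry in subgroups.items():
        for name, est in entry["metrics"].items():
            rows.append(
                {
                    "stratum": stratum,
                    "n": entry["n"],
                    "small_sample": entry["small_sample"],
                    "metric": name,
                    "point": est.point,
                    "lower": est.lower,
                    "upper": est.upper,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    surgical_csv: Union[str, Path],
    claims_csv: Union[str, Path],
    config: RunConfig,
    out_dir: Union[str, Path],
) -> dict:
    """Execute the full validation pipeline and write the report bundle.

    Stages: read tables -> surgical typology -> claims window/mapping ->
    accuracy report with bootstrap CIs -> error and subgroup analyses.
    Outputs under ``out_dir``: accuracy_table.csv, accuracy_table.txt,
    subgroup_table.csv, error_fn.csv, error_fp.csv, run_log.txt.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def staged(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    records = staged("read_surgical", lambda: cohort_io.read_surgical_table(surgical_csv))
    claims = staged("read_claims", lambda: cohort_io.read_claims_table(claims_csv))
    surgery_dates = {r.participant_id: r.surgery_date for r in records}

    reference = staged("surgical_typology", lambda: reference_labels(records))
    retained = staged(
        "window_filter",
        lambda: claims_processing.filter_claims_window(claims, surgery_dates, config),
    )
    test = staged(
        "claims_labels",
        lambda: claims_processing.test_labels(claims, surgery_dates, config),
    )
    report = staged(
        "accuracy", lambda: diagnostic_accuracy.full_report(reference, test, config)
    )

    overall = diagnostic_accuracy.build_contingency(reference, test, "overall")
    fn_ids = sorted(
        pid
        for pid in reference
        if reference[pid]["overall"] and not test[pid]["overall"]
    )
    fp_ids = sorted(
        pid
        for pid in reference
        if not reference[pid]["overall"] and test[pid]["overall"]
    )
    fn_counts = staged(
        "error_fn", lambda: error_analysis_fn(fn_ids, retained, config.fn_vocab)
    )
    fp_counts = staged("error_fp", lambda: error_analysis_fp(fp_ids, test))
    subgroups = staged(
        "subgroups", lambda: subgroup_report(reference, test, records, config)
    )

    report.to_frame().to_csv(out_dir / "accuracy_table.csv", index=False)
    (out_dir / "accuracy_table.txt").write_text(report.to_text() + "\n")
    _subgroup_frame(subgroups).to_csv(out_dir / "subgroup_table.csv", index=False)
    pd.DataFrame(
        sorted(fn_counts.items()), columns=["category", "n_participants"]
    ).to_csv(out_dir / "error_fn.csv", index=False)
    pd.DataFrame(
        sorted(fp_counts.items()), columns=["subtype", "n_participants"]
    ).to_csv(out_dir / "error_fp.csv", index=False)

    n_cases = sum(1 for r in records if r.endometriosis_confirmed)
    stage_counts = {
        "participants": len(records),
        "cases": n_cases,
        "claims_read": len(claims),
        "claims_retained": len(retained),
        "claims_removed_window": len(claims) - len(retained),
        "false_negatives": overall.fn,
        "false_positives": overall.fp,
    }
    log_lines = [
        f"surgical_csv: {surgical_csv}",
        f"claims_csv: {claims_csv}",
        f"rng_seed: {config.rng_seed}",
        f"window_days: {config.window_days}",
        f"study_period: {config.study_start} .. {config.study_end}",
        f"bootstrap_reps: {config.bootstrap_reps}",
        f"ci_level: {config.ci_level}",
    ] + [f"{k}: {v}" for k, v in stage_counts.items()]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "records": records,
        "claims": claims,
        "retained_claims": retained,
        "reference_labels": reference,
        "test_labels": test,
        "report": report,
        "overall_table": overall,
        "fn_participants": fn_ids,
        "fp_participants": fp_ids,
        "fn_counts": fn_counts,
        "fp_counts": fp_counts,
        "subgroups": subgroups,
        "stage_counts": stage_counts,
    }
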