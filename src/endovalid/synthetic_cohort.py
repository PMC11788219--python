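"""Synthetic surgical + claims cohort generator.

The real operative cohort cannot be shared, so this module fabricates a
cohort with the same statistical structure: ~42% surgically confirmed
prevalence, non-exclusive subtype labels, imperfect diagnostic coding with
configurable sensitivity/specificity, distractor (pain/procedure) codes,
and codes dated outside the post-surgery window.

Coding errors are modeled at the participant level: one latent coded /
not-coded draw, then 1-3 claim rows are emitted for coded participants.
Deep-subtype draws take precedence over the superficial flag so that every
generated lesion list classifies back to exactly the sampled subtype set
under the strict "only superficial" rule.

``late_code_rate`` adds an independent out-of-window code per participant
(it never converts a coded participant's true code), so the generating
sensitivity and specificity remain recoverable by the pipeline.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence, Tuple

import numpy as np

from .cohort_io import (
    ClaimRecord,
    ClaimSource,
    CodeSystem,
    HispanicEthnicity,
    LesionDepth,
    LesionRecord,
    LesionSite,
    RaceGroup,
    RasrmStage,
    SurgicalRecord,
)

__all__ = [
    "GeneratorSpec",
    "generate_cohort",
    "generate_fixture_small",
    "FIXTURE_EXPECTED",
]

_STUDY_START = dt.date(2007, 1, 15)
_SURGERY_LAST = dt.date(2009, 6, 30)  # leaves room for late codes in-period

_SUBTYPE_CODES: Mapping[str, Sequence[Tuple[str, CodeSystem]]] = {
    "SE": (("617.3", CodeSystem.ICD9), ("N80.3", CodeSystem.ICD10)),
    "OE": (("617.1", CodeSystem.ICD9), ("N80.1", CodeSystem.ICD10)),
    "DE": (
        ("617.4", CodeSystem.ICD9),
        ("N80.4", CodeSystem.ICD10),
        ("617.5", CodeSystem.ICD9),
        ("N80.5", CodeSystem.ICD10),
    ),
    "NOS": (
        ("617.9", CodeSystem.ICD9),
        ("N80.9", CodeSystem.ICD10),
        ("617.0", CodeSystem.ICD9),
    ),
}

# pain / procedure / other-symptom vocabulary, mirroring the code profile
# seen among false negatives
_DISTRACTORS: Sequence[Tuple[str, CodeSystem]] = (
    ("54.21", CodeSystem.ICD9),   # laparoscopy
    ("54.19", CodeSystem.ICD9),   # laparotomy
    ("625.9", CodeSystem.ICD9),   # pelvic pain
    ("789.03", CodeSystem.ICD9),  # abdominal pain
    ("R10.2", CodeSystem.ICD10),  # pelvic and perineal pain
    ("626.2", CodeSystem.ICD9),   # excessive menstruation
    ("780.79", CodeSystem.ICD9),  # malaise and fatigue
)

_SOURCES = tuple(ClaimSource)


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclasses.dataclass
class GeneratorSpec:
    """Parameters of the synthetic cohort.

    ``subtype_probs`` are the per-case draw probabilities of SE/OE/DE
    (non-exclusive; an all-false draw is resampled; the SE draw is
    overridden whenever a deep subtype is drawn, to keep the lesion list
    classifiable back to the sampled set).  ``subtype_sensitivity`` values
    are marginal targets: the probability that a case with that subtype
    gets a retained subtype-specific code, so the conditional emission
    probability given overall coding is ``value / coding_sensitivity``.
    """

    n_participants: int = 412
    prevalence: float = 0.42
    subtype_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"SE": 0.827, "OE": 0.220, "DE": 0.335}
    )
    coding_sensitivity: float = 0.88
    coding_specificity: float = 0.87
    subtype_sensitivity: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"SE": 0.86, "OE": 0.82, "DE": 0.12}
    )
    fp_subtype_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"SE": 0.50, "OE": 0.20, "DE": 0.05, "NOS": 0.25}
    )
    distractor_rate: float = 0.6
    late_code_rate: float = 0.05
    missing_lesion_info_rate: float = 10 / 173
    race_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "white": 363 / 412,
            "woc": 33 / 412,
            "unknown": 16 / 412,
        }
    )
    hispanic_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "yes": 51 / 412,
            "no": 339 / 412,
            "missing": 22 / 412,
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be a positive integer")
        _check_fraction("prevalence", self.prevalence)
        _check_fraction("coding_sensitivity", self.coding_sensitivity)
        _check_fraction("coding_specificity", self.coding_specificity)
        for name, probs in (
            ("subtype_probs", self.subtype_probs),
            ("subtype_sensitivity", self.subtype_sensitivity),
        ):
            for key in ("SE", "OE", "DE"):
                _check_fraction(f"{name}[{key}]", probs[key])
        _check_fraction("late_code_rate", self.late_code_rate)
        _check_fraction("missing_lesion_info_rate", self.missing_lesion_info_rate)
        if self.distractor_rate < 0:
            raise ValueError("distractor_rate must be non-negative")
        for name, probs in (
            ("race_probs", self.race_probs),
            ("hispanic_probs", self.hispanic_probs),
            ("fp_subtype_mix", self.fp_subtype_mix),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")

    @classmethod
    def noise_free(cls, **overrides) -> "GeneratorSpec":
        """A spec whose cohort yields a perfect accuracy report."""
        defaults = dict(
            coding_sensitivity=1.0,
            coding_specificity=1.0,
            subtype_sensitivity={"SE": 1.0, "OE": 1.0, "DE": 1.0},
            distractor_rate=0.0,
            late_code_rate=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _sample_subtypes(rng: np.random.Generator, probs: Mapping[str, float]):
    """Draw a non-empty, surgically realizable subtype set."""
    while True:
        se = rng.random() < probs["SE"]
        oe = rng.random() < probs["OE"]
        de = rng.random() < probs["DE"]
        if oe or de:
            se = False  # a deep trigger excludes "only superficial"
        if se or oe or de:
            return se, oe, de


def _lesions_for(rng: np.random.Generator, se: bool, oe: bool, de: bool):
    lesions: list[LesionRecord] = []
    if se:
        site = LesionSite.OVARY if rng.random() < 0.5 else LesionSite.PERITONEUM
        lesions.append(LesionRecord(site, LesionDepth.SUPERFICIAL))
        if rng.random() < 0.3:
            other = (
                LesionSite.PERITONEUM
                if site is LesionSite.OVARY
                else LesionSite.OVARY
            )
            lesions.append(LesionRecord(other, LesionDepth.SUPERFICIAL))
    if oe:
        lesions.append(LesionRecord(LesionSite.OVARY, LesionDepth.DEEP))
    if de:
        if rng.random() < 0.7:
            lesions.append(LesionRecord(LesionSite.PERITONEUM, LesionDepth.DEEP))
        else:
            lesions.append(
                LesionRecord(
                    LesionSite.CUL_DE_SAC,
                    LesionDepth.SUPERFICIAL,
                    cul_de_sac_obliteration=True,
                )
            )
    if (oe or de) and rng.random() < 0.4:
        # incidental superficial lesion; must not flip classification
        lesions.append(LesionRecord(LesionSite.PERITONEUM, LesionDepth.SUPERFICIAL))
    return lesions


def _choice(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(0, len(items)))]


def _weighted(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    idx = rng.choice(len(keys), p=np.array([probs[k] for k in keys]))
    return keys[int(idx)]


_STAGE_WEIGHTS = {
    RasrmStage.I: 98,
    RasrmStage.II: 26,
    RasrmStage.III: 17,
    RasrmStage.IV: 27,
}


def generate_cohort(
    spec: GeneratorSpec,
) -> Tuple[list[SurgicalRecord], list[ClaimRecord]]:
    """Generate paired surgical and claims tables.

    Deterministic given ``spec.rng_seed``.  Every case's lesion list
    classifies back to its sampled subtype set; claims follow the
    participant-level coding error model described in the module docstring.
    """
    rng = np.random.default_rng(spec.rng_seed)
    span = (_SURGERY_LAST - _STUDY_START).days
    width = len(str(spec.n_participants))
    records: list[SurgicalRecord] = []
    claims: list[ClaimRecord] = []
    stage_keys = list(_STAGE_WEIGHTS)
    stage_p = np.array(list(_STAGE_WEIGHTS.values()), dtype=float)
    stage_p /= stage_p.sum()

    for i in range(spec.n_participants):
        pid = f"P{i + 1:0{width}d}"
        surgery = _STUDY_START + dt.timedelta(days=int(rng.integers(0, span + 1)))
        race = RaceGroup(_weighted(rng, spec.race_probs))
        hispanic = HispanicEthnicity(_weighted(rng, spec.hispanic_probs))
        is_case = rng.random() < spec.prevalence

        if is_case:
            se, oe, de = _sample_subtypes(rng, spec.subtype_probs)
            missing_info = rng.random() < spec.missing_lesion_info_rate
            if missing_info:
                se, oe, de = True, False, False
                lesions: list[LesionRecord] = []
            else:
                lesions = _lesions_for(rng, se, oe, de)
            stage = stage_keys[int(rng.choice(len(stage_keys), p=stage_p))]
            records.append(
                SurgicalRecord(
                    participant_id=pid,
                    surgery_date=surgery,
                    endometriosis_confirmed=True,
                    lesions=lesions,
                    rasrm_stage=stage,
                    lesion_info_available=not missing_info,
                    race_group=race,
                    hispanic=hispanic,
                )
            )
        else:
            se = oe = de = False
            records.append(
                SurgicalRecord(
                    participant_id=pid,
                    surgery_date=surgery,
                    endometriosis_confirmed=False,
                    lesions=[],
                    rasrm_stage=RasrmStage.NONE,
                    lesion_info_available=True,
                    race_group=race,
                    hispanic=hispanic,
                )
            )

        def emit(code: str, system: CodeSystem, date: dt.date) -> None:
            claims.append(
                ClaimRecord(
                    participant_id=pid,
                    code_system=system,
                    code=code,
                    service_date=date,
                    source=_choice(rng, _SOURCES),
                )
            )

        def in_window_date() -> dt.date:
            return surgery + dt.timedelta(days=int(rng.integers(0, 31)))

        emitted: list[Tuple[str, CodeSystem, dt.date]] = []
        if is_case:
            coded = rng.random() < spec.coding_sensitivity
            if coded:
                for flag, key in ((se, "SE"), (oe, "OE"), (de, "DE")):
                    if not flag:
                        continue
                    conditional = min(
                        1.0,
                        spec.subtype_sensitivity[key]
                        / max(spec.coding_sensitivity, 1e-12),
                    )
                    if rng.random() < conditional:
                        code, system = _choice(rng, _SUBTYPE_CODES[key])
                        emitted.append((code, system, in_window_date()))
                if not emitted:
                    code, system = _choice(rng, _SUBTYPE_CODES["NOS"])
                    emitted.append((code, system, in_window_date()))
        else:
            if rng.random() < 1.0 - spec.coding_specificity:
                key = _weighted(rng, spec.fp_subtype_mix)
                code, system = _choice(rng, _SUBTYPE_CODES[key])
                emitted.append((code, system, in_window_date()))

        if emitted and rng.random() < 0.3:
            emitted.append(_choice(rng, emitted))  # duplicate claim row
        for code, system, date in emitted:
            emit(code, system, date)

        if rng.random() < spec.late_code_rate:
            code, system = _choice(rng, _SUBTYPE_CODES["NOS"])
            late = surgery + dt.timedelta(days=int(rng.integers(31, 121)))
            emit(code, system, late)

        for _ in range(int(rng.poisson(spec.distractor_rate))):
            code, system = _choice(rng, _DISTRACTORS)
            offset = int(rng.integers(-10, 31))
            emit(code, system, surgery + dt.timedelta(days=offset))

    return records, claims


# ---------------------------------------------------------------------------
# Hand-written 10-participant fixture
#
# Exercises every branch: SE-only, OE-only, DE via cul-de-sac obliteration,
# OE+DE, missing-lesion-info -> SE, a control with a false-positive code, a
# case whose only endometriosis code is out-of-window (p07, the single
# participant made test-negative purely by the window rule), and a control
# with distractor codes only.  The expected tables below were enumerated by
# hand and are shipped beside the fixture as its ground truth.

FIXTURE_EXPECTED = {
    "reference_labels": {
        "p01": {"overall": True, "SE": True, "OE": False, "DE": False},
        "p02": {"overall": True, "SE": False, "OE": True, "DE": False},
        "p03": {"overall": True, "SE": False, "OE": False, "DE": True},
        "p04": {"overall": True, "SE": False, "OE": True, "DE": True},
        "p05": {"overall": True, "SE": True, "OE": False, "DE": False},
        "p06": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p07": {"overall": True, "SE": True, "OE": False, "DE": False},
        "p08": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p09": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p10": {"overall": True, "SE": True, "OE": False, "DE": False},
    },
    "test_labels": {
        "p01": {"overall": True, "SE": True, "OE": False, "DE": False},
        "p02": {"overall": True, "SE": False, "OE": True, "DE": False},
        "p03": {"overall": True, "SE": False, "OE": False, "DE": True},
        "p04": {"overall": True, "SE": False, "OE": True, "DE": True},
        "p05": {"overall": True, "SE": False, "OE": False, "DE": False},
        "p06": {"overall": True, "SE": True, "OE": False, "DE": False},
        "p07": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p08": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p09": {"overall": False, "SE": False, "OE": False, "DE": False},
        "p10": {"overall": False, "SE": False, "OE": False, "DE": False},
    },
    # (tp, fp, fn, tn), hand-tallied from the label maps above
    "tables": {
        "overall": (5, 1, 2, 2),
        "SE": (1, 1, 3, 5),
        "OE": (2, 0, 0, 8),
        "DE": (2, 0, 0, 8),
    },
    "fn_participants": ["p07", "p10"],
    "fp_participants": ["p06"],
    "fn_code_categories": {"pain": 1, "laparoscopy_laparotomy": 1},
    "fp_subtypes": {"SE": 1},
    "window_removed_claims": 1,
}


def generate_fixture_small() -> Tuple[list[SurgicalRecord], list[ClaimRecord]]:
    """The deterministic 10-participant hand fixture (see FIXTURE_EXPECTED)."""
    d = dt.date

    def surg(pid, date, confirmed, lesions, stage, info, race, hisp):
        return SurgicalRecord(
            participant_id=pid,
            surgery_date=date,
            endometriosis_confirmed=confirmed,
            lesions=lesions,
            rasrm_stage=stage,
            lesion_info_available=info,
            race_group=race,
            hispanic=hisp,
        )

    W, C, U = RaceGroup.WHITE, RaceGroup.WOC, RaceGroup.UNKNOWN
    Y, N, M = HispanicEthnicity.YES, HispanicEthnicity.NO, HispanicEthnicity.MISSING
    sup, deep = LesionDepth.SUPERFICIAL, LesionDepth.DEEP
    ov, per, cds = LesionSite.OVARY, LesionSite.PERITONEUM, LesionSite.CUL_DE_SAC

    records = [
        surg("p01", d(2008, 3, 10), True, [LesionRecord(ov, sup)],
             RasrmStage.I, True, W, N),
        surg("p02", d(2008, 4, 1), True, [LesionRecord(ov, deep)],
             RasrmStage.III, True, W, N),
        surg("p03", d(2008, 5, 5), True,
             [LesionRecord(cds, sup, cul_de_sac_obliteration=True)],
             RasrmStage.IV, True, C, N),
        surg("p04", d(2008, 6, 1), True,
             [LesionRecord(ov, deep), LesionRecord(per, deep)],
             RasrmStage.IV, True, W, Y),
        surg("p05", d(2008, 2, 15), True, [], RasrmStage.II, False, W, N),
        surg("p06", d(2008, 7, 7), False, [], RasrmStage.NONE, True, W, Y),
        surg("p07", d(2008, 8, 1), True, [LesionRecord(per, sup)],
             RasrmStage.I, True, W, N),
        surg("p08", d(2008, 9, 10), False, [], RasrmStage.NONE, True, W, N),
        surg("p09", d(2008, 10, 1), False, [], RasrmStage.NONE, True, U, M),
        surg("p10", d(2008, 11, 11), True,
             [LesionRecord(ov, sup), LesionRecord(per, sup)],
             RasrmStage.I, True, C, Y),
    ]

    I9, I10 = CodeSystem.ICD9, CodeSystem.ICD10
    amb, inp, ehr = ClaimSource.AMBULATORY, ClaimSource.INPATIENT, ClaimSource.EHR
    claims = [
        ClaimRecord("p01", I9, "617.3", d(2008, 3, 15), amb),
        ClaimRecord("p02", I10, "N80.1", d(2008, 4, 20), ehr),
        ClaimRecord("p03", I10, "N80.4", d(2008, 5, 5), inp),
        ClaimRecord("p04", I9, "617.1", d(2008, 6, 2), amb),
        ClaimRecord("p04", I9, "617.4", d(2008, 6, 2), amb),
        ClaimRecord("p05", I9, "617.9", d(2008, 2, 20), ehr),
        ClaimRecord("p06", I9, "617.3", d(2008, 7, 10), amb),
        # p07: endometriosis code at surgery + 45 days -> removed by window
        ClaimRecord("p07", I10, "N80.9", d(2008, 9, 15), ehr),
        ClaimRecord("p07", I9, "625.9", d(2008, 8, 5), amb),
        ClaimRecord("p08", I9, "54.21", d(2008, 9, 12), inp),
        ClaimRecord("p10", I9, "54.21", d(2008, 11, 12), inp),
    ]
    return records, claims
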