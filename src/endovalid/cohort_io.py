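"""Domain types and I/O for the validation cohort.

Two tabular inputs drive the analysis: a surgical reference table (one row
per participant, carrying the operative findings from the standardized
surgical form) and an administrative claims table (one row per coded
diagnosis).  Both are plain CSV with ISO-8601 dates.  A flat YAML file
configures the run (temporal window, bootstrap settings, code map).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "CohortIOError",
    "RasrmStage",
    "RaceGroup",
    "HispanicEthnicity",
    "CodeSystem",
    "ClaimSource",
    "LesionSite",
    "LesionDepth",
    "LesionRecord",
    "SurgicalRecord",
    "ClaimRecord",
    "RunConfig",
    "read_surgical_table",
    "write_surgical_table",
    "read_claims_table",
    "write_claims_table",
    "load_config",
    "SURGICAL_COLUMNS",
    "CLAIMS_COLUMNS",
]


class CohortIOError(ValueError):
    """Malformed input table, record, or configuration."""


class RasrmStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    NONE = "none"


class RaceGroup(str, enum.Enum):
    WHITE = "white"
    WOC = "woc"
    UNKNOWN = "unknown"


class HispanicEthnicity(str, enum.Enum):
    YES = "yes"
    NO = "no"
    MISSING = "missing"


class CodeSystem(str, enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class ClaimSource(str, enum.Enum):
    INPATIENT = "inpatient"
    AMBULATORY = "ambulatory"
    EHR = "ehr"


class LesionSite(str, enum.Enum):
    OVARY = "ovary"
    PERITONEUM = "peritoneum"
    CUL_DE_SAC = "cul_de_sac"


class LesionDepth(str, enum.Enum):
    SUPERFICIAL = "superficial"
    DEEP = "deep"


@dataclasses.dataclass(frozen=True)
class LesionRecord:
    """One lesion noted on the operative form.

    ``depth_class = deep`` corresponds to >5 mm invasion for peritoneal
    lesions.  ``cul_de_sac_obliteration`` is only meaningful for
    cul-de-sac sites.
    """

    site: LesionSite
    depth_class: LesionDepth
    cul_de_sac_obliteration: bool = False


@dataclasses.dataclass
class SurgicalRecord:
    """One participant's reference-method (surgical) data."""

    participant_id: str
    surgery_date: dt.date
    endometriosis_confirmed: bool
    lesions: list[LesionRecord]
    rasrm_stage: RasrmStage
    lesion_info_available: bool
    race_group: RaceGroup
    hispanic: HispanicEthnicity

    def __post_init__(self) -> None:
        if not self.endometriosis_confirmed:
            if self.lesions:
                raise CohortIOError(
                    f"participant {self.participant_id!r}: lesions listed "
                    "for an unconfirmed participant"
                )
            if self.rasrm_stage is not RasrmStage.NONE:
                raise CohortIOError(
                    f"participant {self.participant_id!r}: stage "
                    f"{self.rasrm_stage.value} on an unconfirmed participant"
                )
        if not self.lesion_info_available and self.lesions:
            raise CohortIOError(
                f"participant {self.participant_id!r}: lesions listed but "
                "lesion_info_available is false"
            )


@dataclasses.dataclass(frozen=True)
class ClaimRecord:
    """One coded administrative diagnosis."""

    participant_id: str
    code_system: CodeSystem
    code: str
    service_date: dt.date
    source: ClaimSource

    def __post_init__(self) -> None:
        if not self.code:
            raise CohortIOError(
                f"participant {self.participant_id!r}: empty diagnosis code"
            )


def _default_code_map():
    # local import: claims_processing depends on this module
    from .claims_processing import DEFAULT_CODE_MAP

    return dict(DEFAULT_CODE_MAP)


def _default_fn_vocab():
    from .analysis_reports import DEFAULT_FN_VOCAB

    return {k: list(v) for k, v in DEFAULT_FN_VOCAB.items()}


@dataclasses.dataclass
class RunConfig:
    """Run-level parameters for the validation pipeline.

    ``window_days`` is the number of days after surgery beyond which claims
    are discarded ("more than one month after" rule, 1 month = 30 days,
    boundary inclusive).  ``code_map`` maps diagnosis-code prefixes to
    subtype sets; see :mod:`endovalid.claims_processing` for the default.
    """

    window_days: int = 30
    study_start: dt.date = dt.date(2007, 1, 1)
    study_end: dt.date = dt.date(2009, 12, 31)
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    rng_seed: int = 0
    code_map: Optional[Mapping[str, object]] = None
    include_unknown_race_in_woc: bool = True
    fn_vocab: Optional[Mapping[str, Sequence[str]]] = None

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise CohortIOError("window_days must be a positive integer")
        if self.bootstrap_reps <= 0:
            raise CohortIOError("bootstrap_reps must be a positive integer")
        if not (0.0 < self.ci_level < 1.0):
            raise CohortIOError(
                f"ci_level must be strictly between 0 and 1, got {self.ci_level}"
            )
        if self.study_start >= self.study_end:
            raise CohortIOError("study_start must precede study_end")
        if self.code_map is None:
            self.code_map = _default_code_map()
        if self.fn_vocab is None:
            self.fn_vocab = _default_fn_vocab()


# ---------------------------------------------------------------------------
# CSV schemas

SURGICAL_COLUMNS = [
    "participant_id",
    "surgery_date",
    "endometriosis_confirmed",
    "rasrm_stage",
    "lesions",
    "culdesac_obliteration",
    "lesion_info_available",
    "race_group",
    "hispanic",
]

CLAIMS_COLUMNS = [
    "participant_id",
    "code_system",
    "code",
    "service_date",
    "source",
]

_BOOL = {"true": True, "false": False}


def _parse_bool(text: str, where: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise CohortIOError(f"{where}: expected true/false, got {text!r}") from None


def _parse_date(text: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise CohortIOError(f"{where}: malformed ISO date {text!r}") from None


def _parse_enum(cls, text: str, where: str):
    try:
        return cls(text.strip())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise CohortIOError(
            f"{where}: unknown value {text!r} (allowed: {allowed})"
        ) from None


def _parse_lesions(text: str, obliteration: bool, where: str) -> list[LesionRecord]:
    text = text.strip()
    if not text:
        return []
    lesions = []
    for token in text.split("|"):
        parts = token.strip().split(":")
        if len(parts) != 2:
            raise CohortIOError(
                f"{where}: malformed lesion token {token!r} "
                "(expected site:depth)"
            )
        site = _parse_enum(LesionSite, parts[0], where)
        depth = _parse_enum(LesionDepth, parts[1], where)
        lesions.append(
            LesionRecord(
                site=site,
                depth_class=depth,
                cul_de_sac_obliteration=(
                    obliteration and site is LesionSite.CUL_DE_SAC
                ),
            )
        )
    if obliteration and not any(
        l.site is LesionSite.CUL_DE_SAC for l in lesions
    ):
        raise CohortIOError(
            f"{where}: culdesac_obliteration is true but no cul_de_sac "
            "lesion is listed"
        )
    return lesions


def _check_header(fieldnames, expected, path) -> None:
    if fieldnames is None or list(fieldnames) != expected:
        raise CohortIOError(
            f"{path}: expected header {','.join(expected)}, "
            f"got {','.join(fieldnames or [])}"
        )


def read_surgical_table(path: Union[str, Path]) -> list[SurgicalRecord]:
    """Read the surgical reference table.

    One record per participant; a duplicate ``participant_id`` is a hard
    error.  Any malformed field raises :class:`CohortIOError` naming the
    offending row (1-based, counting the header as row 1).
    """
    path = Path(path)
    records: list[SurgicalRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SURGICAL_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            where = f"{path.name} row {i}"
            pid = row["participant_id"].strip()
            if not pid:
                raise CohortIOError(f"{where}: empty participant_id")
            if pid in seen:
                raise CohortIOError(
                    f"{where}: duplicate participant_id {pid!r}"
                )
            seen.add(pid)
            obliteration = _parse_bool(
                row["culdesac_obliteration"], where
            )
            try:
                record = SurgicalRecord(
                    participant_id=pid,
                    surgery_date=_parse_date(row["surgery_date"], where),
                    endometriosis_confirmed=_parse_bool(
                        row["endometriosis_confirmed"], where
                    ),
                    lesions=_parse_lesions(row["lesions"], obliteration, where),
                    rasrm_stage=_parse_enum(
                        RasrmStage, row["rasrm_stage"], where
                    ),
                    lesion_info_available=_parse_bool(
                        row["lesion_info_available"], where
                    ),
                    race_group=_parse_enum(RaceGroup, row["race_group"], where),
                    hispanic=_parse_enum(
                        HispanicEthnicity, row["hispanic"], where
                    ),
                )
            except CohortIOError as exc:
                if where in str(exc):
                    raise
                raise CohortIOError(f"{where}: {exc}") from None
            records.append(record)
    return records


def write_surgical_table(
    records: Iterable[SurgicalRecord], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SURGICAL_COLUMNS)
        for r in records:
            lesions = "|".join(
                f"{l.site.value}:{l.depth_class.value}" for l in r.lesions
            )
            obliteration = any(l.cul_de_sac_obliteration for l in r.lesions)
            writer.writerow(
                [
                    r.participant_id,
                    r.surgery_date.isoformat(),
                    str(r.endometriosis_confirmed).lower(),
                    r.rasrm_stage.value,
                    lesions,
                    str(obliteration).lower(),
                    str(r.lesion_info_available).lower(),
                    r.race_group.value,
                    r.hispanic.value,
                ]
            )


def read_claims_table(path: Union[str, Path]) -> list[ClaimRecord]:
    """Read the administrative claims table.

    All rows are retained in order; no filtering happens at read time
    (window and cohort-membership rules are applied downstream).
    """
    path = Path(path)
    claims: list[ClaimRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, CLAIMS_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            where = f"{path.name} row {i}"
            pid = row["participant_id"].strip()
            if not pid:
                raise CohortIOError(f"{where}: empty participant_id")
            code = row["code"].strip()
            if not code:
                raise CohortIOError(f"{where}: empty diagnosis code")
            claims.append(
                ClaimRecord(
                    participant_id=pid,
                    code_system=_parse_enum(
                        CodeSystem, row["code_system"], where
                    ),
                    code=code,
                    service_date=_parse_date(row["service_date"], where),
                    source=_parse_enum(ClaimSource, row["source"], where),
                )
            )
    return claims


def write_claims_table(
    claims: Iterable[ClaimRecord], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CLAIMS_COLUMNS)
        for c in claims:
            writer.writerow(
                [
                    c.participant_id,
                    c.code_system.value,
                    c.code,
                    c.service_date.isoformat(),
                    c.source.value,
                ]
            )


# ---------------------------------------------------------------------------
# Run configuration

_CONFIG_KEYS = {
    "window_days",
    "study_start",
    "study_end",
    "bootstrap_reps",
    "ci_level",
    "rng_seed",
    "code_map",
    "include_unknown_race_in_woc",
    "fn_vocab",
}


def _coerce_date(value, key: str) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, str):
        return _parse_date(value, f"config key {key!r}")
    raise CohortIOError(f"config key {key!r}: expected an ISO date, got {value!r}")


def _parse_code_map(raw) -> dict:
    from .surgical_typology import SubtypeSet

    if not isinstance(raw, Mapping):
        raise CohortIOError("config key 'code_map': expected a mapping")
    code_map = {}
    valid = {"SE", "OE", "DE"}
    for prefix, entry in raw.items():
        prefix = str(prefix)
        if isinstance(entry, str):
            names = [entry]
        elif isinstance(entry, Sequence):
            names = [str(x) for x in entry]
        else:
            raise CohortIOError(
                f"config code_map entry {prefix!r}: expected a subtype name "
                f"or list of names, got {entry!r}"
            )
        names = [n.upper() for n in names]
        if names == ["NOS"]:
            code_map[prefix] = SubtypeSet(nos_only=True)
            continue
        bad = sorted(set(names) - valid)
        if bad:
            raise CohortIOError(
                f"config code_map entry {prefix!r}: unknown subtype(s) {bad}"
            )
        code_map[prefix] = SubtypeSet(
            has_se="SE" in names, has_oe="OE" in names, has_de="DE" in names
        )
    return code_map


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML file.

    All keys are optional; unspecified fields take the documented defaults.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, Mapping):
        raise CohortIOError(f"{path}: config must be a key/value mapping")
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        raise CohortIOError(f"{path}: unknown config key(s) {unknown}")
    kwargs: dict = dict(data)
    for key in ("study_start", "study_end"):
        if key in kwargs:
            kwargs[key] = _coerce_date(kwargs[key], key)
    if "code_map" in kwargs:
        kwargs["code_map"] = _parse_code_map(kwargs["code_map"])
    if "fn_vocab" in kwargs:
        vocab = kwargs["fn_vocab"]
        if not isinstance(vocab, Mapping) or not all(
            isinstance(v, Sequence) and not isinstance(v, str)
            for v in vocab.values()
        ):
            raise CohortIOError(
                f"{path}: fn_vocab must map category -> list of code prefixes"
            )
        kwargs["fn_vocab"] = {k: [str(x) for x in v] for k, v in vocab.items()}
    return RunConfig(**kwargs)
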