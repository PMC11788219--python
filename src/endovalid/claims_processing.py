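"""Test-method labels from ICD-coded administrative claims.

Endometriosis is identified by the 617.x (ICD-9) / N80.x (ICD-10) code
families.  A configurable prefix map assigns subtype-informative codes to
SE/OE/DE; codes in the family without a subtype-specific entry count toward
the overall diagnosis only (NOS).  Claims dated more than ``window_days``
days after the participant's surgery, or outside the study period, are
discarded before labels are derived.

The default map is reconstructed from the anatomic sites in the ICD code
titles and is fully overridable via the run configuration:

* SE  <- 617.3 / N80.3   (pelvic peritoneum)
* OE  <- 617.1 / N80.1   (ovary)
* DE  <- 617.4, 617.5 / N80.4, N80.5  (rectovaginal septum & vagina,
  intestine)
* all other 617.x / N80.x -> NOS (overall only)

Codes are compared case-insensitively with the dot optional, so "N801" and
"n80.1" both match "N80.1".
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping, Sequence, Union

from .cohort_io import ClaimRecord, CodeSystem, RunConfig
from .surgical_typology import SubtypeSet

__all__ = [
    "DEFAULT_CODE_MAP",
    "is_endometriosis_code",
    "map_code_to_subtype",
    "filter_claims_window",
    "test_labels",
]

DEFAULT_CODE_MAP: Mapping[str, SubtypeSet] = {
    "617.3": SubtypeSet(has_se=True),
    "N80.3": SubtypeSet(has_se=True),
    "617.1": SubtypeSet(has_oe=True),
    "N80.1": SubtypeSet(has_oe=True),
    "617.4": SubtypeSet(has_de=True),
    "617.5": SubtypeSet(has_de=True),
    "N80.4": SubtypeSet(has_de=True),
    "N80.5": SubtypeSet(has_de=True),
}

_ROOTS = {CodeSystem.ICD9: "617", CodeSystem.ICD10: "N80"}


def _normalize(code: str) -> str:
    return code.strip().upper().replace(".", "")


def is_endometriosis_code(code: str, system: Union[CodeSystem, str]) -> bool:
    """True iff the code belongs to the endometriosis family of its system
    (root 617 for ICD-9, N80 for ICD-10); bare roots also match."""
    system = CodeSystem(system)
    return _normalize(code).startswith(_ROOTS[system])


def map_code_to_subtype(
    code: str, code_map: Mapping[str, SubtypeSet]
) -> SubtypeSet:
    """Map an endometriosis code to its subtype set by longest-prefix match.

    Codes with no subtype-specific entry return ``nos_only``.  Calling this
    on a code outside both endometriosis families is an error.
    """
    normalized = _normalize(code)
    if not (normalized.startswith("617") or normalized.startswith("N80")):
        raise ValueError(f"{code!r} is not an endometriosis code")
    best: SubtypeSet | None = None
    best_len = -1
    for prefix, subtypes in code_map.items():
        p = _normalize(prefix)
        if normalized.startswith(p) and len(p) > best_len:
            best, best_len = subtypes, len(p)
    return best if best is not None else SubtypeSet(nos_only=True)


def filter_claims_window(
    claims: Iterable[ClaimRecord],
    surgery_dates: Mapping[str, dt.date],
    config: RunConfig,
) -> list[ClaimRecord]:
    """Keep claims inside the study period and at most ``window_days`` days
    after the participant's surgery (boundary inclusive).

    Claims before surgery but inside the study period are retained.  A claim
    for a participant without a surgery date is a hard error listing the
    offending ids.  Idempotent; output preserves input order.
    """
    claims = list(claims)
    unknown = sorted(
        {c.participant_id for c in claims if c.participant_id not in surgery_dates}
    )
    if unknown:
        raise ValueError(
            f"claims reference participants absent from the surgical table: "
            f"{unknown}"
        )
    window = dt.timedelta(days=config.window_days)
    kept = []
    for c in claims:
        cutoff = min(config.study_end, surgery_dates[c.participant_id] + window)
        if config.study_start <= c.service_date <= cutoff:
            kept.append(c)
    return kept


def test_labels(
    claims: Iterable[ClaimRecord],
    surgery_dates: Mapping[str, dt.date],
    config: RunConfig,
) -> dict[str, Mapping[str, bool]]:
    """Per-participant administrative labels for all four comparisons.

    Window filtering is applied internally, so raw claims may be passed.
    ``overall`` is true when any retained endometriosis-family code exists;
    a subtype flag is true when any retained code maps to that subtype.
    Participants with no (retained) claims get all-false labels.  Invariant
    to claim row order and duplication.
    """
    retained = filter_claims_window(claims, surgery_dates, config)
    sets: dict[str, SubtypeSet] = {pid: SubtypeSet() for pid in surgery_dates}
    overall: dict[str, bool] = {pid: False for pid in surgery_dates}
    for c in retained:
        if is_endometriosis_code(c.code, c.code_system):
            overall[c.participant_id] = True
            sets[c.participant_id] = sets[c.participant_id].union(
                map_code_to_subtype(c.code, config.code_map)
            )
    return {
        pid: {
            "overall": overall[pid],
            "SE": sets[pid].has_se,
            "OE": sets[pid].has_oe,
            "DE": sets[pid].has_de,
        }
        for pid in surgery_dates
    }
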