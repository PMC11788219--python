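"""Reference-method subtype classification from operative lesion records.

A surgically confirmed case is assigned a non-exclusive set of subtypes:

* SE (superficial): only superficial lesions on the ovary or peritoneum.
* OE (ovarian endometrioma): any deep lesion in the ovary.
* DE (deep infiltrating): any deep peritoneal/cul-de-sac lesion, or
  obliteration of the posterior cul-de-sac.

"Only superficial" is read strictly: a case with both superficial lesions
and a deep trigger is OE/DE, not SE.  Cases lacking lesion detail are
assumed SE.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from .cohort_io import LesionDepth, LesionSite, SurgicalRecord

__all__ = ["SubtypeSet", "classify_surgical_subtypes", "reference_labels"]

COMPARISONS = ("overall", "SE", "OE", "DE")


@dataclasses.dataclass(frozen=True)
class SubtypeSet:
    """Non-exclusive subtype flags.

    ``nos_only`` marks an administrative-side diagnosis whose code carries
    no subtype information; it is always false on the reference side.
    """

    has_se: bool = False
    has_oe: bool = False
    has_de: bool = False
    nos_only: bool = False

    @property
    def is_empty(self) -> bool:
        return not (self.has_se or self.has_oe or self.has_de or self.nos_only)

    def union(self, other: "SubtypeSet") -> "SubtypeSet":
        return SubtypeSet(
            has_se=self.has_se or other.has_se,
            has_oe=self.has_oe or other.has_oe,
            has_de=self.has_de or other.has_de,
            nos_only=self.nos_only or other.nos_only,
        )


def classify_surgical_subtypes(record: SurgicalRecord) -> SubtypeSet:
    """Classify one confirmed case into its surgical subtype set.

    Raises ``ValueError`` when called on a participant without surgically
    confirmed disease.  Cases without lesion information are assumed SE.
    """
    if not record.endometriosis_confirmed:
        raise ValueError(
            f"participant {record.participant_id!r} is not a confirmed case"
        )
    if not record.lesion_info_available or not record.lesions:
        return SubtypeSet(has_se=True)

    has_oe = any(
        l.site is LesionSite.OVARY and l.depth_class is LesionDepth.DEEP
        for l in record.lesions
    )
    has_de = any(
        (
            l.site in (LesionSite.PERITONEUM, LesionSite.CUL_DE_SAC)
            and l.depth_class is LesionDepth.DEEP
        )
        or l.cul_de_sac_obliteration
        for l in record.lesions
    )
    # strict reading: SE only when no deep trigger exists at all
    has_se = not (has_oe or has_de)
    return SubtypeSet(has_se=has_se, has_oe=has_oe, has_de=has_de)


def reference_labels(
    records: Iterable[SurgicalRecord],
) -> dict[str, Mapping[str, bool]]:
    """Per-participant reference labels for all four comparisons.

    ``overall`` is the surgical confirmation flag; subtype flags come from
    :func:`classify_surgical_subtypes` for cases and are all false for
    non-cases.
    """
    labels: dict[str, Mapping[str, bool]] = {}
    for r in records:
        if r.participant_id in labels:
            raise ValueError(f"duplicate participant_id {r.participant_id!r}")
        if r.endometriosis_confirmed:
            s = classify_surgical_subtypes(r)
            labels[r.participant_id] = {
                "overall": True,
                "SE": s.has_se,
                "OE": s.has_oe,
                "DE": s.has_de,
            }
        else:
            labels[r.participant_id] = {
                "overall": False,
                "SE": False,
                "OE": False,
                "DE": False,
            }
    return labels
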