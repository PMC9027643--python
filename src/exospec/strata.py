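"""Biopsy-outcome strata for the prostate-cancer risk cohort.

Every patient carries one :class:`GleasonStratum`, the ordered biopsy
outcome from which all binary endpoints (any cancer, Gleason >= 3+4,
Gleason >= 4+3) and the continuous training outcome derive.  The two
no-cancer subgroups are kept distinct: men with no evidence of cancer
(age-normal PSA, normal DRE, never biopsied) and men with a raised PSA
whose biopsy was negative.
"""

from __future__ import annotations

import enum


class GleasonStratum(enum.Enum):
    """Ordered biopsy-outcome category.

    Ordinality (for ordinal regression and planted effect gradients) is
    NEC = NEG_BIOPSY < GS3_3 < GS3_4 < GS4_3 < GS4PLUS; the two no-cancer
    subtypes share rank 0.
    """

    NEC = "NEC"
    NEG_BIOPSY = "NEG_BIOPSY"
    GS3_3 = "GS3_3"
    GS3_4 = "GS3_4"
    GS4_3 = "GS4_3"
    GS4PLUS = "GS4PLUS"

    @property
    def any_cancer(self) -> bool:
        return self not in (GleasonStratum.NEC, GleasonStratum.NEG_BIOPSY)

    @property
    def ge_3_4(self) -> bool:
        """Clinically significant disease: Gleason score >= 3+4."""
        return self in (GleasonStratum.GS3_4, GleasonStratum.GS4_3, GleasonStratum.GS4PLUS)

    @property
    def ge_4_3(self) -> bool:
        """High-grade disease: dominant Gleason pattern 4 or worse."""
        return self in (GleasonStratum.GS4_3, GleasonStratum.GS4PLUS)

    @property
    def ordinal(self) -> int:
        """Rank on the merged ordinal scale NC < 3+3 < 3+4 < 4+3 < >=4+4."""
        return _ORDINAL[self]


_ORDINAL = {
    GleasonStratum.NEC: 0,
    GleasonStratum.NEG_BIOPSY: 0,
    GleasonStratum.GS3_3: 1,
    GleasonStratum.GS3_4: 2,
    GleasonStratum.GS4_3: 3,
    GleasonStratum.GS4PLUS: 4,
}

#: canonical display order, used by tables and group-size maps
STRATUM_ORDER = (
    GleasonStratum.NEC,
    GleasonStratum.NEG_BIOPSY,
    GleasonStratum.GS3_3,
    GleasonStratum.GS3_4,
    GleasonStratum.GS4_3,
    GleasonStratum.GS4PLUS,
)


def parse_stratum(token: str) -> GleasonStratum:
    try:
        return GleasonStratum(token)
    except ValueError as exc:
        raise ValueError(f"unknown Gleason stratum token {token!r}") from exc
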