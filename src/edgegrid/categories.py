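"""IUCN Red List threat categories and the severity lattice used throughout.

Categories form a total order on severity for CR > EN > VU > NT > LC; DD
(Data Deficient) sits outside the order and is never compared by severity.
The GE weight (LC=0, NT=1, VU=2, EN=3, CR=4) encodes a doubling of
extinction risk per category step and feeds the EDGE score.
"""

from __future__ import annotations

import enum


class ThreatCategory(str, enum.Enum):
    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    DD = "DD"

    @property
    def severity_rank(self) -> int:
        """CR=5 .. LC=1; DD=0 (outside the severity order)."""
        return _SEVERITY[self]

    @property
    def ge_weight(self) -> int:
        """Threat weight for the EDGE score (LC=0 .. CR=4); DD has none."""
        if self is ThreatCategory.DD:
            raise ValueError("DD has no GE weight")
        return _SEVERITY[self] - 1

    @property
    def is_threatened(self) -> bool:
        return self in (ThreatCategory.CR, ThreatCategory.EN, ThreatCategory.VU)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SEVERITY = {
    ThreatCategory.CR: 5,
    ThreatCategory.EN: 4,
    ThreatCategory.VU: 3,
    ThreatCategory.NT: 2,
    ThreatCategory.LC: 1,
    ThreatCategory.DD: 0,
}

#: Assessable (non-DD) categories, most to least severe.
ASSESSABLE = (
    ThreatCategory.CR,
    ThreatCategory.EN,
    ThreatCategory.VU,
    ThreatCategory.NT,
    ThreatCategory.LC,
)


def max_severity(a: ThreatCategory, b: ThreatCategory) -> ThreatCategory:
    """Join on the severity lattice; DD acts as the identity element.

    Combining a category with DD yields the other category; DD with DD is DD.
    This implements the rule that a taxon is CR overall if it is CR under at
    least one criterion.
    """
    if a is ThreatCategory.DD:
        return b
    if b is ThreatCategory.DD:
        return a
    return a if a.severity_rank >= b.severity_rank else b
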