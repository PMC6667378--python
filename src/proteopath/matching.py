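"""Proteoform comparison semantics.

Eight matching stringencies decide whether a query proteoform
corresponds to a reference proteoform.  All of them first require an
identical accession and isoform; they differ in how the two PTM
multisets are compared:

* ``STRICT`` — same number of PTMs and a one-to-one assignment between
  the multisets with exact site equality (no margin; unknown sites match
  only unknown sites).
* ``SUPERSET`` — every reference PTM matches some input PTM.
* ``SUBSET`` — every input PTM matches some reference PTM.
* ``ONE`` — at least one input PTM matches a reference PTM.
* ``*_NO_TYPES`` — as above, ignoring modification types.
* ``ACCESSION`` — accession + isoform identity only.

Two known sites match when their absolute distance is at most the
user-provided margin (in residues).  An unknown input site matches any
reference site ("input is less specific"), and a known input site
matches an unknown reference site ("input is more specific").  The
reserved input type ``00000`` matches any reference type.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .proteoforms import Proteoform, Ptm, WILDCARD_TYPE, format_proteoform


class MatchingType(str, Enum):
    """The eight proteoform matching stringencies."""

    STRICT = "strict"
    SUPERSET = "superset"
    SUPERSET_NO_TYPES = "superset_no_types"
    SUBSET = "subset"
    SUBSET_NO_TYPES = "subset_no_types"
    ONE = "one"
    ONE_NO_TYPES = "one_no_types"
    ACCESSION = "accession"

    @property
    def uses_types(self) -> bool:
        return self in (
            MatchingType.STRICT,
            MatchingType.SUPERSET,
            MatchingType.SUBSET,
            MatchingType.ONE,
        )


@dataclass(frozen=True)
class MatchingConfig:
    """Matching stringency plus the site margin (in amino acids).

    The margin is ignored for ``STRICT`` (exact sites only) and for
    ``ACCESSION`` (PTMs are not compared at all).
    """

    matching_type: MatchingType = MatchingType.SUBSET
    margin: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "matching_type", MatchingType(self.matching_type)
        )
        if not isinstance(self.margin, int) or isinstance(self.margin, bool) \
                or self.margin < 0:
            raise ValueError(f"margin must be a non-negative integer, got {self.margin!r}")


@dataclass(frozen=True)
class MatchResult:
    """One (input proteoform, matched reference) pair."""

    input_proteoform: Proteoform
    matched_reference: Proteoform
    matching_type: MatchingType
    margin: int


def match_coordinate(
    input_site: int | None, ref_site: int | None, margin: int
) -> bool:
    """Compare an input and a reference modification coordinate.

    Total on raw integers: a zero or negative input coordinate is never
    a match.  ``None`` denotes an unknown site; the reference-side legacy
    sentinel ``-1`` is treated as unknown.
    """
    if input_site is None:
        return True  # input is less specific
    if not isinstance(input_site, int) or isinstance(input_site, bool) \
            or input_site < 1:
        return False  # zero/negative input coordinates are invalid
    if ref_site is None or ref_site == -1:
        return True  # input is more specific
    if not isinstance(ref_site, int) or isinstance(ref_site, bool) or ref_site < 1:
        return False
    return abs(input_site - ref_site) <= margin


def match_ptm(
    input_ptm: Ptm, ref_ptm: Ptm, margin: int, use_types: bool = True
) -> bool:
    """Compare two PTMs under the given margin.

    When ``use_types`` is true, type identifiers must be identical unless
    the input type is the ``00000`` wildcard.
    """
    if not match_coordinate(input_ptm.site, ref_ptm.site, margin):
        return False
    if use_types:
        return (
            input_ptm.type_id == ref_ptm.type_id
            or input_ptm.type_id == WILDCARD_TYPE
        )
    return True


def _strict_ptm_match(input_ptm: Ptm, ref_ptm: Ptm) -> bool:
    # exact-site semantics: both the same positive integer or both unknown
    if input_ptm.site != ref_ptm.site:
        return False
    return (
        input_ptm.type_id == ref_ptm.type_id
        or input_ptm.type_id == WILDCARD_TYPE
    )


def _has_perfect_matching(
    inputs: Sequence[Ptm], refs: Sequence[Ptm]
) -> bool:
    """Kuhn's augmenting-path algorithm for a one-to-one PTM assignment."""
    if len(inputs) != len(refs):
        return False
    adj = [
        [j for j, r in enumerate(refs) if _strict_ptm_match(i, r)]
        for i in inputs
    ]
    match_of_ref: list[int | None] = [None] * len(refs)

    def try_assign(i: int, seen: list[bool]) -> bool:
        for j in adj[i]:
            if not seen[j]:
                seen[j] = True
                if match_of_ref[j] is None or try_assign(match_of_ref[j], seen):
                    match_of_ref[j] = i
                    return True
        return False

    for i in range(len(inputs)):
        if not try_assign(i, [False] * len(refs)):
            return False
    return True


def match_proteoform(
    input_p: Proteoform, ref_p: Proteoform, config: MatchingConfig
) -> bool:
    """Decide whether an input proteoform matches a reference proteoform."""
    if input_p.accession != ref_p.accession or input_p.isoform != ref_p.isoform:
        return False
    mt = config.matching_type
    if mt is MatchingType.ACCESSION:
        return True
    if mt is MatchingType.STRICT:
        return _has_perfect_matching(input_p.ptms, ref_p.ptms)

    use_types = mt.uses_types
    margin = config.margin
    inp, ref = input_p.ptms, ref_p.ptms
    if mt in (MatchingType.SUBSET, MatchingType.SUBSET_NO_TYPES):
        return all(
            any(match_ptm(i, r, margin, use_types) for r in ref) for i in inp
        )
    if mt in (MatchingType.SUPERSET, MatchingType.SUPERSET_NO_TYPES):
        return all(
            any(match_ptm(i, r, margin, use_types) for i in inp) for r in ref
        )
    # ONE / ONE_NO_TYPES: false on empty input PTM sets
    return any(
        match_ptm(i, r, margin, use_types) for i in inp for r in ref
    )


def match_against_kb(
    inputs: Iterable[Proteoform],
    kb_proteoforms: Iterable[Proteoform],
    config: MatchingConfig,
) -> list[MatchResult]:
    """Match every input proteoform against a reference collection.

    Returns one :class:`MatchResult` per matching (input, reference)
    pair, in input order then canonical reference serialization order.
    """
    refs = sorted(set(kb_proteoforms), key=format_proteoform)
    by_accession: dict[tuple[str, int | None], list[Proteoform]] = {}
    for r in refs:
        by_accession.setdefault((r.accession, r.isoform), []).append(r)

    results: list[MatchResult] = []
    for p in inputs:
        for r in by_accession.get((p.accession, p.isoform), ()):
            if match_proteoform(p, r, config):
                results.append(
                    MatchResult(p, r, config.matching_type, config.margin)
                )
    return results
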