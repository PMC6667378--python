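"""Proteoform data model and its text notation.

A proteoform is one specific form of a protein product: a UniProt
accession, an optional isoform number, and a multiset of
post-translational modifications (PTMs).  Each PTM pairs a 5-digit
PSI-MOD ontology identifier (e.g. ``00046`` = O-phospho-L-serine) with a
1-based residue coordinate on the UniProt sequence; the coordinate may
be unknown.

The text notation is::

    ACCESSION[-ISOFORM];TYPE:SITE,TYPE:SITE,...

for example ``P01308;00087:53,00798:31,00798:43``.  The ``MOD:`` prefix
before a type identifier is accepted and stripped.  An unknown site is
written ``?`` (``null`` and an empty site are accepted on input).  The
reserved type ``00000`` is a wildcard that matches any modification type
when used on the query side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .exceptions import (
    InputValidationError,
    InvalidCoordinateError,
    InvalidPtmTypeError,
    ProteoformParseError,
)

#: Reserved PTM type identifier matching any modification type on the
#: query side.
WILDCARD_TYPE = "00000"

#: Marker for a modification whose sequence coordinate is not known.
#: (``None`` is used as the in-memory representation.)
UNKNOWN_SITE = None

#: PSI-MOD identifiers for phosphorylated serine, threonine and tyrosine.
PHOSPHO_TYPE_BY_RESIDUE = {"S": "00046", "T": "00047", "Y": "00048"}

_TYPE_RE = re.compile(r"[0-9]{5}")


def _validate_site(site: object) -> int | None:
    if site is None:
        return None
    if isinstance(site, bool) or not isinstance(site, int):
        raise InvalidCoordinateError(
            f"modification site must be a positive integer or unknown, got {site!r}"
        )
    if site < 1:
        raise InvalidCoordinateError(
            f"modification site must be >= 1, got {site}"
        )
    return site


@dataclass(frozen=True)
class Ptm:
    """A post-translational modification: PSI-MOD type at a residue site.

    ``site`` is a 1-based coordinate on the UniProt sequence, or ``None``
    (:data:`UNKNOWN_SITE`) when the position is not known.
    """

    type_id: str
    site: int | None = UNKNOWN_SITE

    def __post_init__(self) -> None:
        if not isinstance(self.type_id, str) or not _TYPE_RE.fullmatch(self.type_id):
            raise InvalidPtmTypeError(
                f"PTM type must be 5 decimal digits, got {self.type_id!r}"
            )
        _validate_site(self.site)

    @property
    def sort_key(self) -> tuple[str, int, int]:
        """Canonical ordering: by type, then site, unknown sites last."""
        return (self.type_id, self.site is None, self.site or 0)

    def __str__(self) -> str:
        site = "?" if self.site is None else str(self.site)
        return f"{self.type_id}:{site}"


@dataclass(frozen=True)
class Proteoform:
    """A protein accession with optional isoform and a PTM multiset.

    PTMs are stored in canonical order, so two proteoforms differing only
    in the order of their PTMs compare (and hash) equal.  Duplicate
    (type, site) pairs are preserved: the PTM collection is a multiset.
    """

    accession: str
    isoform: int | None = None
    ptms: tuple[Ptm, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.accession:
            raise ProteoformParseError("accession must be non-empty")
        if self.isoform is not None and (
            isinstance(self.isoform, bool)
            or not isinstance(self.isoform, int)
            or self.isoform < 1
        ):
            raise ProteoformParseError(
                f"isoform must be a positive integer, got {self.isoform!r}"
            )
        object.__setattr__(
            self, "ptms", tuple(sorted(self.ptms, key=lambda m: m.sort_key))
        )

    @property
    def is_canonical(self) -> bool:
        """True for the unmodified canonical gene product."""
        return self.isoform is None and not self.ptms

    def __str__(self) -> str:
        return format_proteoform(self)


@dataclass(frozen=True)
class PhosphoSite:
    """A phosphorylated residue: accession, residue letter (S/T/Y), site."""

    accession: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_TYPE_BY_RESIDUE:
            raise InputValidationError(
                f"phosphosite residue must be one of S, T, Y, got {self.residue!r}"
            )
        if isinstance(self.position, bool) or not isinstance(self.position, int) \
                or self.position < 1:
            raise InvalidCoordinateError(
                f"phosphosite position must be >= 1, got {self.position!r}"
            )


def _parse_ptm_token(
    token: str, *, negative_sentinel_as_unknown: bool = False
) -> Ptm:
    if ":" not in token:
        raise ProteoformParseError(
            f"malformed PTM token {token!r}: missing ':' separator"
        )
    parts = token.split(":")
    if parts and parts[0].strip().upper() == "MOD":
        parts = parts[1:]
    if len(parts) != 2:
        raise ProteoformParseError(
            f"malformed PTM token {token!r}: expected TYPE:SITE"
        )
    type_str = parts[0].strip()
    site_str = parts[1].strip()
    if not _TYPE_RE.fullmatch(type_str):
        raise InvalidPtmTypeError(
            f"PTM type in token {token!r} must be 5 decimal digits"
        )
    site: int | None
    if site_str == "?" or site_str.lower() == "null" or site_str == "":
        site = UNKNOWN_SITE
    elif negative_sentinel_as_unknown and site_str == "-1":
        site = UNKNOWN_SITE
    else:
        try:
            site = int(site_str)
        except ValueError:
            raise InvalidCoordinateError(
                f"site {site_str!r} in token {token!r} is not an integer"
            ) from None
        if site < 1:
            raise InvalidCoordinateError(
                f"site {site} in token {token!r} is not a valid 1-based coordinate"
            )
    return Ptm(type_str, site)


def parse_proteoform(
    text: str, *, negative_sentinel_as_unknown: bool = False
) -> Proteoform:
    """Parse a proteoform notation string.

    The first ``;`` separates the accession (with optional ``-<n>``
    isoform suffix) from the PTM list; PTM tokens may be separated by
    either ``,`` or ``;``.  Set ``negative_sentinel_as_unknown`` to
    accept the legacy reference-side site sentinel ``-1`` as an unknown
    site (used when loading knowledge-base files).

    Raises :class:`ProteoformParseError` (or a subclass) on malformed
    input.
    """
    text = text.strip()
    if not text:
        raise ProteoformParseError("empty proteoform string")
    head, sep, tail = text.partition(";")
    head = head.strip()
    if not head:
        raise ProteoformParseError(f"missing accession in {text!r}")

    accession = head
    isoform: int | None = None
    # a trailing "-<digits>" suffix denotes the isoform number
    m = re.fullmatch(r"(.+)-([0-9]+)", head)
    if m:
        accession = m.group(1)
        isoform = int(m.group(2))
        if isoform < 1:
            raise ProteoformParseError(
                f"isoform suffix in {head!r} must be a positive integer"
            )

    ptms: list[Ptm] = []
    if sep and tail.strip():
        for token in re.split(r"[,;]", tail):
            token = token.strip()
            if not token:
                continue
            ptms.append(
                _parse_ptm_token(
                    token,
                    negative_sentinel_as_unknown=negative_sentinel_as_unknown,
                )
            )
    return Proteoform(accession, isoform, tuple(ptms))


def format_proteoform(p: Proteoform) -> str:
    """Serialize a proteoform to its canonical notation string.

    PTMs are emitted sorted by (type, site) with unknown sites last and
    written as ``?``; :func:`parse_proteoform` inverts this exactly.
    """
    acc = p.accession if p.isoform is None else f"{p.accession}-{p.isoform}"
    return f"{acc};" + ",".join(str(m) for m in p.ptms)


def phosphosite_to_proteoform(s: PhosphoSite) -> Proteoform:
    """Build the single-PTM proteoform representing a phosphosite.

    The PSI-MOD type is 00046, 00047 or 00048 for phosphorylated serine,
    threonine or tyrosine, respectively.
    """
    return Proteoform(
        s.accession,
        None,
        (Ptm(PHOSPHO_TYPE_BY_RESIDUE[s.residue], s.position),),
    )


def read_proteoform_list(path) -> list[Proteoform]:
    """Read a proteoform list file: one notation string per line.

    Blank lines and ``#`` comment lines are ignored.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(parse_proteoform(line))
    return out
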