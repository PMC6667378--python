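"""Reading and resolving the supported input types.

Six kinds of entity list are supported, one entity per line: gene names,
genetic variants (rsID or ``chr:pos``), protein accessions, peptide
sequences, modified peptides (``SEQUENCE;type:pos,...`` with
peptide-relative 1-based PTM positions), and proteoforms in the standard
notation.  Each list is modeled as a set of proteins or proteoforms:
protein-level inputs yield proteoforms with empty PTM sets, while
modified peptides and proteoforms carry their PTM annotation through to
the matching step.

Resolution never invents accessions: a token that cannot be mapped
through the knowledge base's identifier maps or sequences is recorded as
unresolved.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import InputValidationError, ProteoformParseError
from .kb import KnowledgeBase
from .proteoforms import Proteoform, Ptm, parse_proteoform

INPUT_KINDS = (
    "gene",
    "variant",
    "protein",
    "peptide",
    "modified_peptide",
    "proteoform",
)

#: Input kinds that resolve to unmodified proteins (matched by accession).
PROTEIN_LEVEL_KINDS = ("gene", "variant", "protein", "peptide")

_PEPTIDE_RE = re.compile(r"[A-Za-z]+")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with PTMs at peptide-relative 1-based positions."""

    sequence: str
    ptms: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or not _PEPTIDE_RE.fullmatch(self.sequence):
            raise InputValidationError(
                f"peptide sequence must be alphabetic, got {self.sequence!r}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        for type_id, pos in self.ptms:
            if not 1 <= pos <= len(self.sequence):
                raise InputValidationError(
                    f"PTM position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )
            Ptm(type_id, pos)  # validates the type identifier

    @classmethod
    def parse(cls, token: str) -> "ModifiedPeptide":
        """Parse a ``SEQUENCE;type:pos,type:pos`` token."""
        seq, _, tail = token.partition(";")
        ptms = []
        for part in tail.split(","):
            part = part.strip()
            if not part:
                continue
            ptm = _parse_peptide_ptm(part)
            ptms.append(ptm)
        return cls(seq.strip(), tuple(ptms))


def _parse_peptide_ptm(token: str) -> tuple[str, int]:
    parts = token.split(":")
    if parts and parts[0].strip().upper() == "MOD":
        parts = parts[1:]
    if len(parts) != 2:
        raise InputValidationError(
            f"malformed peptide PTM token {token!r}: expected TYPE:POS"
        )
    try:
        pos = int(parts[1].strip())
    except ValueError:
        raise InputValidationError(
            f"peptide PTM position {parts[1]!r} is not an integer"
        ) from None
    return parts[0].strip(), pos


@dataclass(frozen=True)
class InputEntities:
    """Resolved input: (source token, proteoform) pairs plus leftovers.

    One token may fan out to several proteoforms (a variant hitting two
    proteins, a peptide found in two sequences), and several tokens may
    resolve to the same proteoform; ``pairs`` keeps the full association
    while :attr:`entities` is the duplicate-free proteoform collection.
    """

    kind: str
    raw_count: int
    pairs: tuple[tuple[str, Proteoform], ...]
    unresolved: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in INPUT_KINDS:
            raise InputValidationError(
                f"input kind must be one of {INPUT_KINDS}, got {self.kind!r}"
            )

    @property
    def entities(self) -> tuple[Proteoform, ...]:
        """Distinct resolved proteoforms, in first-seen order."""
        seen: dict[Proteoform, None] = {}
        for _, p in self.pairs:
            seen.setdefault(p)
        return tuple(seen)


def read_input(path: str | Path, kind: str | None = None) -> list[str]:
    """Read raw input tokens: one per line, blank and ``#`` lines skipped."""
    tokens = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.append(line)
    if not tokens:
        warnings.warn(f"input file {path} contains no entities", stacklevel=2)
    return tokens


def _dedup_pairs(
    pairs: Iterable[tuple[str, Proteoform]]
) -> tuple[tuple[str, Proteoform], ...]:
    seen: dict[tuple[str, Proteoform], None] = {}
    for pair in pairs:
        seen.setdefault(pair)
    return tuple(seen)


def _dedup_tokens(tokens: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for t in tokens:
        seen.setdefault(t)
    return tuple(seen)


def map_genes(gene_names: Sequence[str], kb: KnowledgeBase) -> InputEntities:
    """Resolve gene names through the gene↔accession map (exact match)."""
    pairs, unresolved = [], []
    for name in gene_names:
        accs = kb.gene_map.get(name)
        if not accs:
            unresolved.append(name)
            continue
        for acc in accs:
            pairs.append((name, Proteoform(acc)))
    return InputEntities(
        "gene", len(gene_names), _dedup_pairs(pairs), _dedup_tokens(unresolved)
    )


def map_variants(variants: Sequence[str], kb: KnowledgeBase) -> InputEntities:
    """Resolve rsID / ``chr:pos`` variant identifiers through the variant map.

    Ambiguous variants fan out to every associated accession.
    """
    if kb.variant_map is None:
        raise InputValidationError(
            "knowledge base has no variant map (variants.tsv)"
        )
    pairs, unresolved = [], []
    for vid in variants:
        accs = kb.variant_map.get(vid)
        if not accs:
            unresolved.append(vid)
            continue
        for acc in accs:
            pairs.append((vid, Proteoform(acc)))
    return InputEntities(
        "variant", len(variants), _dedup_pairs(pairs), _dedup_tokens(unresolved)
    )


def map_proteins(accessions: Sequence[str], kb: KnowledgeBase) -> InputEntities:
    """Resolve protein accessions (with optional ``-<n>`` isoform suffix)."""
    pairs, unresolved = [], []
    for token in accessions:
        try:
            p = parse_proteoform(token if ";" in token else token + ";")
        except ProteoformParseError:
            unresolved.append(token)
            continue
        p = Proteoform(p.accession, p.isoform)  # drop any stray PTMs
        if p.accession not in kb.accessions:
            unresolved.append(token)
            continue
        pairs.append((token, p))
    return InputEntities(
        "protein", len(accessions), _dedup_pairs(pairs), _dedup_tokens(unresolved)
    )


def map_peptides(peptides: Sequence[str], kb: KnowledgeBase) -> InputEntities:
    """Map peptides to every protein whose sequence contains them exactly."""
    if kb.sequences is None:
        raise InputValidationError(
            "knowledge base has no protein sequences (sequences.fasta)"
        )
    pairs, unresolved = [], []
    for pep in peptides:
        query = pep.strip().upper()
        hits = [
            acc for acc in sorted(kb.sequences) if query in kb.sequences[acc]
        ]
        if not hits:
            unresolved.append(pep)
            continue
        for acc in hits:
            pairs.append((pep, Proteoform(acc)))
    return InputEntities(
        "peptide", len(peptides), _dedup_pairs(pairs), _dedup_tokens(unresolved)
    )


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based start offsets of needle."""
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def map_modified_peptides(
    peptides: Sequence[ModifiedPeptide | str], kb: KnowledgeBase
) -> InputEntities:
    """Build candidate proteoforms from modified peptides.

    For each occurrence of a peptide at 1-based start ``s`` in a protein
    sequence, a peptide-relative PTM position ``q`` becomes protein site
    ``s + q - 1``.  Every occurrence yields one candidate proteoform; the
    matching step decides which candidates correspond to reference
    proteoforms.
    """
    if kb.sequences is None:
        raise InputValidationError(
            "knowledge base has no protein sequences (sequences.fasta)"
        )
    pairs, unresolved = [], []
    for item in peptides:
        pep = ModifiedPeptide.parse(item) if isinstance(item, str) else item
        token = item if isinstance(item, str) else (
            pep.sequence + ";" + ",".join(f"{t}:{q}" for t, q in pep.ptms)
        )
        found = False
        for acc in sorted(kb.sequences):
            for start0 in _occurrences(kb.sequences[acc], pep.sequence):
                ptms = tuple(
                    Ptm(type_id, start0 + pos) for type_id, pos in pep.ptms
                )
                pairs.append((token, Proteoform(acc, None, ptms)))
                found = True
        if not found:
            unresolved.append(token)
    return InputEntities(
        "modified_peptide",
        len(peptides),
        _dedup_pairs(pairs),
        _dedup_tokens(unresolved),
    )


def map_proteoforms(tokens: Sequence[str], kb: KnowledgeBase) -> InputEntities:
    """Parse proteoform notation tokens; accessions must exist in the KB."""
    pairs, unresolved = [], []
    for token in tokens:
        p = parse_proteoform(token)
        if p.accession not in kb.accessions:
            unresolved.append(token)
            continue
        pairs.append((token, p))
    return InputEntities(
        "proteoform", len(tokens), _dedup_pairs(pairs), _dedup_tokens(unresolved)
    )


def resolve(tokens: Sequence[str], kind: str, kb: KnowledgeBase) -> InputEntities:
    """Dispatch raw tokens to the mapper for the given input kind."""
    if kind == "gene":
        return map_genes(tokens, kb)
    if kind == "variant":
        return map_variants(tokens, kb)
    if kind == "protein":
        return map_proteins(tokens, kb)
    if kind == "peptide":
        return map_peptides(tokens, kb)
    if kind == "modified_peptide":
        return map_modified_peptides(tokens, kb)
    if kind == "proteoform":
        return map_proteoforms(tokens, kb)
    raise InputValidationError(f"unknown input kind {kind!r}")
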