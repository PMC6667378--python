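"""Pathway knowledge-base model, flat-file IO, and synthetic generator.

The knowledge base mirrors the structure of curated pathway databases
such as Reactome: hierarchical pathways contain biochemical reactions
whose participants are proteoforms acting in one of four roles (input,
output, catalyst, regulator), individually or as part of a complex or
set.  Identifier maps attach gene names, genetic variants and protein
sequences to the reference proteoforms.

On disk a knowledge base is a directory of five UTF-8, headered,
tab-separated files — ``proteoforms.tsv``, ``genes.tsv``,
``reactions.tsv``, ``pathways.tsv``, ``pathway_reactions.tsv`` — plus an
optional ``variants.tsv`` and ``sequences.fasta``.

The module also implements the robustness experiment used to
characterize the matching stringencies: reference proteoforms are
perturbed (first PTM type replaced by the ``00000`` wildcard, sites
shifted by +5 residues) and matched back against the database, reporting
how often each stringency recovers the original annotation versus other
same-accession proteoforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    ConfigurationError,
    IntegrityError,
    InputValidationError,
    ProteoformParseError,
)
from .matching import MatchingConfig, MatchingType, match_proteoform
from .proteoforms import (
    Proteoform,
    Ptm,
    WILDCARD_TYPE,
    format_proteoform,
    parse_proteoform,
)

ROLES = ("input", "output", "catalyst", "regulator")

REQUIRED_FILES = (
    "proteoforms.tsv",
    "genes.tsv",
    "reactions.tsv",
    "pathways.tsv",
    "pathway_reactions.tsv",
)

#: PSI-MOD types used by the synthetic generator: phospho-S/T/Y plus a
#: few other common modifications (acetylation, glycosylation, methylation,
#: ubiquitination, palmitoylation).
SYNTHETIC_PTM_TYPES = (
    "00046",
    "00047",
    "00048",
    "00064",
    "00087",
    "00134",
    "00798",
    "01148",
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _validate_context(context: str) -> None:
    if context == "individual":
        return
    kind, _, ident = context.partition(":")
    if kind in ("complex", "set") and ident:
        return
    raise InputValidationError(
        f"participant context must be 'individual', 'complex:<id>' or "
        f"'set:<id>', got {context!r}"
    )


@dataclass(frozen=True)
class Participant:
    """A proteoform taking part in a reaction with a role and context."""

    proteoform: Proteoform
    role: str
    context: str = "individual"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputValidationError(
                f"role must be one of {ROLES}, got {self.role!r}"
            )
        _validate_context(self.context)

    @property
    def sort_key(self) -> tuple[str, str, str]:
        return (format_proteoform(self.proteoform), self.role, self.context)


@dataclass(frozen=True)
class Reaction:
    """A biochemical reaction with at least one participant.

    Participants are stored in canonical order, so reactions compare
    equal independently of the order their participants were listed in.
    """

    reaction_id: str
    name: str
    participants: tuple[Participant, ...]

    def __post_init__(self) -> None:
        if not self.participants:
            raise InputValidationError(
                f"reaction {self.reaction_id!r} has no participants"
            )
        object.__setattr__(
            self,
            "participants",
            tuple(sorted(self.participants, key=lambda p: p.sort_key)),
        )


@dataclass(frozen=True)
class Pathway:
    """A pathway: optional parent pathway and a list of member reactions."""

    pathway_id: str
    name: str
    parent_id: str | None = None
    reaction_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reaction_ids", tuple(sorted(set(self.reaction_ids)))
        )


@dataclass(frozen=True)
class AlterationRecord:
    """An original reference proteoform and its perturbed counterpart."""

    original: Proteoform
    altered: Proteoform


@dataclass
class KnowledgeBase:
    """Pathways ⊃ reactions ⊃ participants, plus identifier maps."""

    proteoforms: tuple[Proteoform, ...]
    reactions: dict[str, Reaction]
    pathways: dict[str, Pathway]
    gene_map: dict[str, tuple[str, ...]]
    variant_map: dict[str, tuple[str, ...]] | None = None
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.proteoforms = tuple(
            sorted(set(self.proteoforms), key=format_proteoform)
        )
        self.validate()

    # -- integrity ---------------------------------------------------

    def validate(self) -> None:
        """Check cross-reference closure; raise :class:`IntegrityError`."""
        known = set(self.proteoforms)
        for rid, reaction in self.reactions.items():
            if rid != reaction.reaction_id:
                raise IntegrityError(
                    f"reaction keyed {rid!r} carries id {reaction.reaction_id!r}"
                )
            for part in reaction.participants:
                if part.proteoform not in known:
                    raise IntegrityError(
                        f"reaction {rid!r} references unlisted proteoform "
                        f"{format_proteoform(part.proteoform)!r}"
                    )
        for pid, pathway in self.pathways.items():
            if pid != pathway.pathway_id:
                raise IntegrityError(
                    f"pathway keyed {pid!r} carries id {pathway.pathway_id!r}"
                )
            if pathway.parent_id is not None and pathway.parent_id not in self.pathways:
                raise IntegrityError(
                    f"pathway {pid!r} references unknown parent "
                    f"{pathway.parent_id!r}"
                )
            for rid in pathway.reaction_ids:
                if rid not in self.reactions:
                    raise IntegrityError(
                        f"pathway {pid!r} references unknown reaction {rid!r}"
                    )
        # parent links must be acyclic
        for pid in self.pathways:
            seen = {pid}
            cur = self.pathways[pid].parent_id
            while cur is not None:
                if cur in seen:
                    raise IntegrityError(
                        f"pathway parent links form a cycle at {cur!r}"
                    )
                seen.add(cur)
                cur = self.pathways[cur].parent_id

    # -- derived indexes ---------------------------------------------

    @cached_property
    def accessions(self) -> frozenset[str]:
        """All protein accessions known to the KB."""
        accs = {p.accession for p in self.proteoforms}
        for mapped in self.gene_map.values():
            accs.update(mapped)
        return frozenset(accs)

    @cached_property
    def accession_to_genes(self) -> dict[str, tuple[str, ...]]:
        rev: dict[str, list[str]] = {}
        for gene in sorted(self.gene_map):
            for acc in self.gene_map[gene]:
                rev.setdefault(acc, []).append(gene)
        return {acc: tuple(sorted(genes)) for acc, genes in rev.items()}

    @cached_property
    def participants_by_proteoform(
        self,
    ) -> dict[Proteoform, tuple[tuple[str, Participant], ...]]:
        """Map each proteoform to its (reaction_id, participant) occurrences."""
        idx: dict[Proteoform, list[tuple[str, Participant]]] = {}
        for rid in sorted(self.reactions):
            for part in self.reactions[rid].participants:
                idx.setdefault(part.proteoform, []).append((rid, part))
        return {p: tuple(v) for p, v in idx.items()}

    @cached_property
    def pathways_of_reaction(self) -> dict[str, tuple[str, ...]]:
        idx: dict[str, list[str]] = {}
        for pid in sorted(self.pathways):
            for rid in self.pathways[pid].reaction_ids:
                idx.setdefault(rid, []).append(pid)
        return {rid: tuple(v) for rid, v in idx.items()}

    @cached_property
    def children_of_pathway(self) -> dict[str, tuple[str, ...]]:
        idx: dict[str, list[str]] = {}
        for pid in sorted(self.pathways):
            parent = self.pathways[pid].parent_id
            if parent is not None:
                idx.setdefault(parent, []).append(pid)
        return {pid: tuple(v) for pid, v in idx.items()}

    def ancestors(self, pathway_id: str) -> list[str]:
        """Parent chain of a pathway, nearest first (excludes itself)."""
        out = []
        cur = self.pathways[pathway_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.pathways[cur].parent_id
        return out

    def top_level(self, pathway_id: str) -> str:
        """The top-level ancestor of a pathway (itself if it is a root)."""
        chain = self.ancestors(pathway_id)
        return chain[-1] if chain else pathway_id

    def reaction_closure(self, pathway_id: str) -> tuple[str, ...]:
        """Reactions of a pathway and of all its descendant pathways."""
        rids: set[str] = set()
        stack = [pathway_id]
        while stack:
            pid = stack.pop()
            rids.update(self.pathways[pid].reaction_ids)
            stack.extend(self.children_of_pathway.get(pid, ()))
        return tuple(sorted(rids))

    def pathway_participants(self, pathway_id: str) -> frozenset[Proteoform]:
        """Distinct participant proteoforms in a pathway's reaction closure."""
        out: set[Proteoform] = set()
        for rid in self.reaction_closure(pathway_id):
            out.update(p.proteoform for p in self.reactions[rid].participants)
        return frozenset(out)


# ---------------------------------------------------------------------------
# flat-file reader / writer
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing required columns {missing}"
        )
    return df


def _parse_cell(path: Path, row: int, text: str) -> Proteoform:
    try:
        return parse_proteoform(text, negative_sentinel_as_unknown=True)
    except ProteoformParseError as exc:
        raise ProteoformParseError(f"{path.name}, line {row + 2}: {exc}") from exc


def load_kb(directory: str | Path) -> KnowledgeBase:
    """Load a knowledge base from its directory of flat files.

    Raises :class:`ConfigurationError` when a required file is missing,
    :class:`IntegrityError` on dangling references, and propagates
    :class:`ProteoformParseError` (annotated with file and line) on
    malformed proteoform cells.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigurationError(f"knowledge base directory not found: {directory}")
    for name in REQUIRED_FILES:
        if not (directory / name).is_file():
            raise ConfigurationError(
                f"knowledge base is missing required file {name!r} in {directory}"
            )

    pf_path = directory / "proteoforms.tsv"
    pf_df = _read_tsv(pf_path, ["proteoform"])
    proteoforms = tuple(
        _parse_cell(pf_path, i, cell)
        for i, cell in enumerate(pf_df["proteoform"])
    )

    genes_df = _read_tsv(directory / "genes.tsv", ["gene_name", "accession"])
    gene_map: dict[str, list[str]] = {}
    for _, row in genes_df.iterrows():
        gene_map.setdefault(row["gene_name"], []).append(row["accession"])
    gene_map_t = {g: tuple(sorted(set(a))) for g, a in gene_map.items()}

    rx_path = directory / "reactions.tsv"
    rx_df = _read_tsv(
        rx_path, ["reaction_id", "reaction_name", "proteoform", "role", "context"]
    )
    rx_parts: dict[str, list[Participant]] = {}
    rx_names: dict[str, str] = {}
    for i, row in rx_df.iterrows():
        rid = row["reaction_id"]
        rx_names[rid] = row["reaction_name"]
        rx_parts.setdefault(rid, []).append(
            Participant(
                _parse_cell(rx_path, i, row["proteoform"]),
                row["role"],
                row["context"],
            )
        )
    reactions = {
        rid: Reaction(rid, rx_names[rid], tuple(parts))
        for rid, parts in rx_parts.items()
    }

    pw_df = _read_tsv(
        directory / "pathways.tsv", ["pathway_id", "pathway_name", "parent_id"]
    )
    pr_df = _read_tsv(
        directory / "pathway_reactions.tsv", ["pathway_id", "reaction_id"]
    )
    pw_reactions: dict[str, list[str]] = {}
    for _, row in pr_df.iterrows():
        if row["pathway_id"] not in set(pw_df["pathway_id"]):
            raise IntegrityError(
                f"pathway_reactions.tsv references unknown pathway "
                f"{row['pathway_id']!r}"
            )
        pw_reactions.setdefault(row["pathway_id"], []).append(row["reaction_id"])
    pathways = {}
    for _, row in pw_df.iterrows():
        pid = row["pathway_id"]
        parent = row["parent_id"] if row["parent_id"] not in ("-", "") else None
        pathways[pid] = Pathway(
            pid,
            row["pathway_name"],
            parent,
            tuple(pw_reactions.get(pid, ())),
        )

    variant_map = None
    var_path = directory / "variants.tsv"
    if var_path.is_file():
        var_df = _read_tsv(var_path, ["variant_id", "accession"])
        vmap: dict[str, list[str]] = {}
        for _, row in var_df.iterrows():
            vmap.setdefault(row["variant_id"], []).append(row["accession"])
        variant_map = {v: tuple(sorted(set(a))) for v, a in vmap.items()}

    sequences = None
    fasta_path = directory / "sequences.fasta"
    if fasta_path.is_file():
        sequences = {
            record.id: str(record.seq)
            for record in SeqIO.parse(str(fasta_path), "fasta")
        }

    return KnowledgeBase(
        proteoforms=proteoforms,
        reactions=reactions,
        pathways=pathways,
        gene_map=gene_map_t,
        variant_map=variant_map,
        sequences=sequences,
    )


def save_kb(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write a knowledge base to a directory with deterministic row order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {"proteoform": [format_proteoform(p) for p in kb.proteoforms]}
    ).to_csv(directory / "proteoforms.tsv", sep="\t", index=False)

    gene_rows = sorted(
        (gene, acc) for gene, accs in kb.gene_map.items() for acc in accs
    )
    pd.DataFrame(gene_rows, columns=["gene_name", "accession"]).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )

    rx_rows = []
    for rid in sorted(kb.reactions):
        reaction = kb.reactions[rid]
        for part in reaction.participants:
            rx_rows.append(
                (
                    rid,
                    reaction.name,
                    format_proteoform(part.proteoform),
                    part.role,
                    part.context,
                )
            )
    pd.DataFrame(
        rx_rows,
        columns=["reaction_id", "reaction_name", "proteoform", "role", "context"],
    ).to_csv(directory / "reactions.tsv", sep="\t", index=False)

    pw_rows = [
        (pid, kb.pathways[pid].name, kb.pathways[pid].parent_id or "-")
        for pid in sorted(kb.pathways)
    ]
    pd.DataFrame(
        pw_rows, columns=["pathway_id", "pathway_name", "parent_id"]
    ).to_csv(directory / "pathways.tsv", sep="\t", index=False)

    pr_rows = sorted(
        (pid, rid)
        for pid in kb.pathways
        for rid in kb.pathways[pid].reaction_ids
    )
    pd.DataFrame(pr_rows, columns=["pathway_id", "reaction_id"]).to_csv(
        directory / "pathway_reactions.tsv", sep="\t", index=False
    )

    if kb.variant_map is not None:
        var_rows = sorted(
            (vid, acc)
            for vid, accs in kb.variant_map.items()
            for acc in accs
        )
        pd.DataFrame(var_rows, columns=["variant_id", "accession"]).to_csv(
            directory / "variants.tsv", sep="\t", index=False
        )

    if kb.sequences is not None:
        records = [
            SeqRecord(Seq(seq), id=acc, description="")
            for acc, seq in sorted(kb.sequences.items())
        ]
        SeqIO.write(records, str(directory / "sequences.fasta"), "fasta")


# ---------------------------------------------------------------------------
# synthetic knowledge-base generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticKBConfig:
    """Counts and proportions controlling the synthetic generator.

    ``ptm_fraction`` is the probability that a protein carries PTM-annotated
    proteoforms; each such protein receives 2–3 modified forms (drawn from
    ``modified_forms_range``) in addition to its unmodified canonical form,
    so that proteins with multiple modified proteoforms — the population
    probed by the sensitivity experiment — are abundant.  Modification
    sites are drawn so that a +5 shift never exceeds the synthetic
    sequence length.
    """

    n_proteins: int = 200
    isoform_fraction: float = 0.1
    ptm_fraction: float = 0.5
    max_ptms_per_proteoform: int = 3
    modified_forms_range: tuple[int, int] = (2, 3)
    n_reactions: int = 300
    participants_per_reaction_range: tuple[int, int] = (2, 6)
    n_pathways: int = 40
    hierarchy_depth: int = 3
    sequence_length_range: tuple[int, int] = (120, 360)
    n_variants: int = 100

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_reactions", "n_pathways",
                     "hierarchy_depth", "max_ptms_per_proteoform"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("isoform_fraction", "ptm_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        lo, hi = self.participants_per_reaction_range
        if lo < 2 or hi < lo:
            raise ConfigurationError(
                "participants_per_reaction_range must be (lo, hi) with 2 <= lo <= hi"
            )
        lo, hi = self.sequence_length_range
        if lo < 30 or hi < lo:
            raise ConfigurationError(
                "sequence_length_range must be (lo, hi) with 30 <= lo <= hi"
            )


def generate_synthetic_kb(
    config: SyntheticKBConfig = SyntheticKBConfig(), seed: int = 0
) -> KnowledgeBase:
    """Generate a reproducible synthetic knowledge base.

    The output emulates a curated pathway database: hierarchical pathways
    containing reactions whose participants are proteoforms with roles
    and complex/set context, a configurable fraction of PTM-annotated
    proteins, gene and variant identifier maps, and protein sequences.
    Identical ``(config, seed)`` pairs yield byte-identical files after
    :func:`save_kb`.
    """
    rng = random.Random(seed)

    accessions = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    sequences: dict[str, str] = {}
    gene_map: dict[str, tuple[str, ...]] = {}
    proteoforms: list[Proteoform] = []

    for i, acc in enumerate(accessions, start=1):
        length = rng.randint(*config.sequence_length_range)
        sequences[acc] = "".join(rng.choices(_AMINO_ACIDS, k=length))
        gene_map[f"GENE{i:05d}"] = (acc,)

        proteoforms.append(Proteoform(acc))
        if rng.random() < config.ptm_fraction:
            n_forms = rng.randint(*config.modified_forms_range)
            seen = {Proteoform(acc)}
            for _ in range(n_forms):
                n_ptms = rng.randint(1, config.max_ptms_per_proteoform)
                # cap sites so a +5 shift stays a valid coordinate
                sites = rng.sample(range(1, length - 9), n_ptms)
                ptms = tuple(
                    Ptm(rng.choice(SYNTHETIC_PTM_TYPES), site)
                    for site in sites
                )
                isoform = (
                    rng.randint(2, 3)
                    if rng.random() < config.isoform_fraction
                    else None
                )
                form = Proteoform(acc, isoform, ptms)
                if form not in seen:
                    seen.add(form)
                    proteoforms.append(form)

    lo, hi = config.participants_per_reaction_range
    if hi > len(proteoforms):
        raise ConfigurationError(
            f"participants_per_reaction_range max {hi} exceeds the "
            f"{len(proteoforms)} generated proteoforms"
        )

    reactions: dict[str, Reaction] = {}
    covered: set[Proteoform] = set()
    participant_lists: dict[str, list[Participant]] = {}
    for j in range(1, config.n_reactions + 1):
        rid = f"R{j:05d}"
        members = rng.sample(proteoforms, rng.randint(lo, hi))
        parts = []
        for p in members:
            u = rng.random()
            if u < 0.70:
                context = "individual"
            elif u < 0.85:
                context = f"complex:C{j:05d}"
            else:
                context = f"set:S{j:05d}"
            parts.append(Participant(p, rng.choice(ROLES), context))
            covered.add(p)
        participant_lists[rid] = parts

    # ensure every proteoform participates in at least one reaction
    rids = sorted(participant_lists)
    for p in proteoforms:
        if p not in covered:
            rid = rng.choice(rids)
            participant_lists[rid].append(
                Participant(p, rng.choice(ROLES), "individual")
            )
            covered.add(p)
    for rid, parts in participant_lists.items():
        reactions[rid] = Reaction(rid, f"Reaction {int(rid[1:])}", tuple(parts))

    # pathway hierarchy: roots first, then children attached to any
    # pathway whose depth leaves room below hierarchy_depth
    n_roots = max(1, config.n_pathways // 4)
    pathway_ids = [f"PW{m:04d}" for m in range(1, config.n_pathways + 1)]
    depth_of: dict[str, int] = {}
    parent_of: dict[str, str | None] = {}
    for m, pid in enumerate(pathway_ids):
        if m < n_roots:
            parent_of[pid] = None
            depth_of[pid] = 1
        else:
            candidates = [
                q for q in pathway_ids[:m] if depth_of[q] < config.hierarchy_depth
            ]
            parent = rng.choice(candidates) if candidates else None
            parent_of[pid] = parent
            depth_of[pid] = depth_of[parent] + 1 if parent else 1

    pw_reactions: dict[str, list[str]] = {pid: [] for pid in pathway_ids}
    for rid in rids:
        for pid in rng.sample(pathway_ids, rng.randint(1, 2)):
            pw_reactions[pid].append(rid)
    pathways = {
        pid: Pathway(pid, f"Pathway {int(pid[2:])}", parent_of[pid],
                     tuple(pw_reactions[pid]))
        for pid in pathway_ids
    }

    variant_map: dict[str, tuple[str, ...]] = {}
    for v in range(1, config.n_variants + 1):
        if v % 2 == 0:
            vid = f"rs{100000 + v}"
        else:
            vid = f"{rng.randint(1, 22)}:{rng.randint(1_000, 9_999_999)}"
        accs = {rng.choice(accessions)}
        if rng.random() < 0.10:  # occasional fan-out to a second protein
            accs.add(rng.choice(accessions))
        variant_map[vid] = tuple(sorted(accs))

    return KnowledgeBase(
        proteoforms=tuple(proteoforms),
        reactions=reactions,
        pathways=pathways,
        gene_map=gene_map,
        variant_map=variant_map,
        sequences=sequences,
    )


# ---------------------------------------------------------------------------
# alteration / sensitivity experiment
# ---------------------------------------------------------------------------


def alter_proteoform(p: Proteoform) -> AlterationRecord:
    """Perturb a modified proteoform to emulate mismatching annotation.

    The first PTM (in canonical serialization order) has its type
    replaced by the ``00000`` wildcard and its site increased by 5
    residues; if a second PTM exists, its site is increased by 5 as well.
    Remaining PTMs are unchanged.  Unknown sites stay unknown.
    """
    if not p.ptms:
        raise InputValidationError(
            "cannot alter a proteoform with no PTMs"
        )
    ptms = list(p.ptms)
    first = ptms[0]
    ptms[0] = Ptm(
        WILDCARD_TYPE, None if first.site is None else first.site + 5
    )
    if len(ptms) >= 2:
        second = ptms[1]
        ptms[1] = Ptm(
            second.type_id, None if second.site is None else second.site + 5
        )
    return AlterationRecord(p, Proteoform(p.accession, p.isoform, tuple(ptms)))


def eligible_proteoforms(kb: KnowledgeBase) -> list[Proteoform]:
    """Modified proteoforms of proteins with multiple modified proteoforms.

    These are the candidates for the sensitivity experiment: only
    proteins carrying at least two PTM-annotated proteoforms are kept,
    and all of their PTM-annotated proteoforms are returned.
    """
    by_accession: dict[str, list[Proteoform]] = {}
    for p in kb.proteoforms:
        if p.ptms:
            by_accession.setdefault(p.accession, []).append(p)
    pool = []
    for acc in sorted(by_accession):
        if len(by_accession[acc]) >= 2:
            pool.extend(by_accession[acc])
    return pool


def sensitivity_experiment(
    kb: KnowledgeBase,
    n_samples: int = 10,
    sample_size: int = 300,
    configs: Sequence[MatchingConfig] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Alter sampled reference proteoforms and match them back to the KB.

    Draws ``n_samples`` samples of ``sample_size`` eligible proteoforms
    without replacement, perturbs each with :func:`alter_proteoform`, and
    for every matching configuration reports, per sample, the percentage
    of altered proteoforms that match their own original (*Original*) and
    the percentage that match any other same-accession reference
    proteoform (*Others*).

    Returns a tidy DataFrame with columns ``matching_type``, ``margin``,
    ``sample``, ``original_pct``, ``others_pct``.
    """
    if configs is None:
        configs = [MatchingConfig(mt, 5) for mt in MatchingType]
    pool = eligible_proteoforms(kb)
    if len(pool) < sample_size:
        raise ConfigurationError(
            f"knowledge base has only {len(pool)} eligible proteoforms; "
            f"{sample_size} required per sample"
        )

    same_accession: dict[str, list[Proteoform]] = {}
    for p in kb.proteoforms:
        same_accession.setdefault(p.accession, []).append(p)

    rng = random.Random(seed)
    rows = []
    for s in range(1, n_samples + 1):
        sample = rng.sample(pool, sample_size)
        records = [alter_proteoform(p) for p in sample]
        for cfg in configs:
            n_original = 0
            n_others = 0
            for rec in records:
                if match_proteoform(rec.altered, rec.original, cfg):
                    n_original += 1
                others = (
                    q
                    for q in same_accession[rec.original.accession]
                    if q != rec.original
                )
                if any(match_proteoform(rec.altered, q, cfg) for q in others):
                    n_others += 1
            rows.append(
                {
                    "matching_type": cfg.matching_type.value,
                    "margin": cfg.margin,
                    "sample": s,
                    "original_pct": 100.0 * n_original / sample_size,
                    "others_pct": 100.0 * n_others / sample_size,
                }
            )
    return pd.DataFrame(rows)
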