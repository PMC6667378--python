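"""Pathway search and binomial overrepresentation analysis.

The search maps every resolved input entity to the reactions in which a
matched reference proteoform participates, and lists each containing
pathway together with all of its ancestors up to the top level.

The overrepresentation analysis models the matching of each input entity
to a pathway as a Bernoulli trial: with ``n`` distinct input entities,
a pathway holding ``entities_total`` of the ``database_total`` entities
in the database has per-trial success probability
``p = entities_total / database_total``, and the p-value of observing
``k`` matched entities is the binomial right tail Pr(X >= k).  Raw
p-values are adjusted with the Benjamini–Hochberg procedure.  At protein
granularity entities are accessions; at proteoform granularity they are
full proteoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .inputs import InputEntities, PROTEIN_LEVEL_KINDS
from .kb import KnowledgeBase
from .matching import MatchingConfig, MatchingType, match_against_kb
from .proteoforms import Proteoform, format_proteoform

GRANULARITIES = ("protein", "proteoform")


@dataclass(frozen=True)
class SearchRow:
    """One (input, matched reference, reaction, pathway) association."""

    input_token: str
    entity: Proteoform
    matched: Proteoform
    reaction_id: str
    reaction_name: str
    pathway_id: str
    pathway_name: str
    top_pathway_id: str
    top_pathway_name: str
    role: str
    context: str


@dataclass(frozen=True)
class Universe:
    """The entity universe for the Bernoulli model at a granularity."""

    granularity: str
    database_total: int

    def __post_init__(self) -> None:
        if self.granularity not in GRANULARITIES:
            raise ValueError(
                f"granularity must be one of {GRANULARITIES}, "
                f"got {self.granularity!r}"
            )
        if self.database_total < 1:
            raise ValueError("database_total must be >= 1")


@dataclass(frozen=True)
class PathwayStatistics:
    """Per-pathway overrepresentation statistics."""

    pathway_id: str
    pathway_name: str
    entities_found: int
    entities_total: int
    p: float
    n: int
    p_value: float
    fdr: float


def make_universe(kb: KnowledgeBase, granularity: str) -> Universe:
    """Count the distinct KB entities at the requested granularity."""
    if granularity == "protein":
        total = len({p.accession for p in kb.proteoforms})
    else:
        total = len(set(kb.proteoforms))
    return Universe(granularity, total)


def _entity_identity(p: Proteoform, granularity: str):
    return p.accession if granularity == "protein" else p


def search(
    entities: InputEntities, kb: KnowledgeBase, config: MatchingConfig
) -> list[SearchRow]:
    """List all reactions and pathways linked to the resolved input.

    Protein-level input kinds (genes, variants, proteins, peptides) are
    matched by accession regardless of the configured stringency;
    proteoform-level kinds use ``config``.  Pathway rows include every
    ancestor pathway up to the top level.
    """
    if entities.kind in PROTEIN_LEVEL_KINDS:
        config = MatchingConfig(MatchingType.ACCESSION, 0)

    rows: list[SearchRow] = []
    seen: set[tuple] = set()
    for token, entity in entities.pairs:
        for result in match_against_kb([entity], kb.proteoforms, config):
            ref = result.matched_reference
            for rid, part in kb.participants_by_proteoform.get(ref, ()):
                reaction = kb.reactions[rid]
                pathway_ids: set[str] = set()
                for pid in kb.pathways_of_reaction.get(rid, ()):
                    pathway_ids.add(pid)
                    pathway_ids.update(kb.ancestors(pid))
                for pid in sorted(pathway_ids):
                    top = kb.top_level(pid)
                    row = SearchRow(
                        input_token=token,
                        entity=entity,
                        matched=ref,
                        reaction_id=rid,
                        reaction_name=reaction.name,
                        pathway_id=pid,
                        pathway_name=kb.pathways[pid].name,
                        top_pathway_id=top,
                        top_pathway_name=kb.pathways[top].name,
                        role=part.role,
                        context=part.context,
                    )
                    key = (
                        token, entity, ref, rid, pid, part.role, part.context
                    )
                    if key not in seen:
                        seen.add(key)
                        rows.append(row)
    return rows


def binomial_right_tail(k: int, n: int, p: float) -> float:
    """Pr(X >= k) for X ~ Binomial(n, p), via the survival function.

    Evaluated as ``sf(k - 1)`` so the right tail is computed stably
    rather than by naive subtraction from 1.
    """
    if not isinstance(k, (int, np.integer)) or not isinstance(n, (int, np.integer)):
        raise ValueError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in the input order."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0.0) | (arr > 1.0)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def analyse(
    rows: Sequence[SearchRow],
    entities: InputEntities,
    kb: KnowledgeBase,
    universe: Universe,
    n_mode: str = "mapped",
) -> list[PathwayStatistics]:
    """Overrepresentation statistics for every pathway with >= 1 match.

    ``n`` counts distinct resolved input entities at the universe's
    granularity; with the default ``n_mode="mapped"`` only entities that
    matched the knowledge base are counted, with ``n_mode="resolved"``
    all resolved entities are.  ``entities_found`` (k) counts distinct
    input entities per pathway; ``entities_total`` counts the distinct
    participants in the pathway's reaction closure (own reactions plus
    all descendant pathways').
    """
    if n_mode not in ("mapped", "resolved"):
        raise ValueError(f"n_mode must be 'mapped' or 'resolved', got {n_mode!r}")
    g = universe.granularity

    if n_mode == "mapped":
        n = len({_entity_identity(r.entity, g) for r in rows})
    else:
        n = len({_entity_identity(p, g) for p in entities.entities})
    if n == 0:
        return []

    found: dict[str, set] = {}
    for r in rows:
        found.setdefault(r.pathway_id, set()).add(_entity_identity(r.entity, g))

    stats = []
    pvals = []
    for pid in sorted(found):
        k = len(found[pid])
        participants = kb.pathway_participants(pid)
        total = len({_entity_identity(p, g) for p in participants})
        p = total / universe.database_total
        pval = binomial_right_tail(k, n, p)
        stats.append((pid, k, total, p, pval))
        pvals.append(pval)

    fdrs = bh_adjust(pvals)
    return [
        PathwayStatistics(
            pathway_id=pid,
            pathway_name=kb.pathways[pid].name,
            entities_found=k,
            entities_total=total,
            p=p,
            n=n,
            p_value=pval,
            fdr=float(fdr),
        )
        for (pid, k, total, p, pval), fdr in zip(stats, fdrs)
    ]


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

SEARCH_COLUMNS = (
    "input",
    "entity",
    "matched",
    "reaction_id",
    "reaction_name",
    "pathway_id",
    "pathway_name",
    "top_pathway_id",
    "top_pathway_name",
    "role",
    "context",
)

ANALYSIS_COLUMNS = (
    "pathway_id",
    "pathway_name",
    "entities_found",
    "entities_total",
    "p",
    "n",
    "p_value",
    "fdr",
)


def search_to_frame(rows: Sequence[SearchRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.input_token,
                format_proteoform(r.entity),
                format_proteoform(r.matched),
                r.reaction_id,
                r.reaction_name,
                r.pathway_id,
                r.pathway_name,
                r.top_pathway_id,
                r.top_pathway_name,
                r.role,
                r.context,
            )
            for r in rows
        ],
        columns=list(SEARCH_COLUMNS),
    )


def analysis_to_frame(stats: Sequence[PathwayStatistics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.pathway_id,
                s.pathway_name,
                s.entities_found,
                s.entities_total,
                s.p,
                s.n,
                s.p_value,
                s.fdr,
            )
            for s in stats
        ],
        columns=list(ANALYSIS_COLUMNS),
    )


def write_search_tsv(rows: Sequence[SearchRow], path: str | Path) -> None:
    search_to_frame(rows).to_csv(path, sep="\t", index=False)


def write_analysis_tsv(
    stats: Sequence[PathwayStatistics], path: str | Path
) -> None:
    # probabilities serialized with 6 significant digits
    analysis_to_frame(stats).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
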