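# Methods

## Proteoform model and notation

A proteoform is `(accession, isoform, PTM multiset)`. The isoform is an
optional positive integer (`accession-3` style suffix); absence means
the canonical isoform, and isoform numbers are compared literally — a
canonical query never matches an isoform-annotated reference. Each PTM
is a 5-digit PSI-MOD type identifier plus a 1-based residue coordinate
on the UniProt sequence, or an unknown-site marker. PTMs form a
*multiset*: duplicate (type, site) pairs are preserved, since reference
annotations may list one modification per subunit occurrence. In memory
the PTM collection is kept in canonical order (type, then site, unknown
last), making equality and hashing order-insensitive.

The parser accepts both `,` and `;` as separators between PTM tokens
(the accession terminator is always the first `;`), the optional `MOD:`
prefix, and `?`/`null`/empty as unknown-site spellings; the serializer
always emits `,`-separated tokens with unknown sites as `?`, so
`parse ∘ format` is the identity and `format ∘ parse` is idempotent.
Zero, negative, and fractional coordinates are rejected at construction.
When loading knowledge-base files (only there), the legacy reference
sentinel `-1` is normalized to the unknown site.

## Coordinate and PTM comparison

Two known sites agree when |input − reference| ≤ margin; the margin is
an inclusive non-negative integer number of residues (default 0, i.e.
exact). An unknown input site matches any reference site (the input is
less specific), a known input site matches an unknown reference site
(the input is more specific), and invalid raw input coordinates (≤ 0)
never match. With types enabled, identifiers must be identical unless
the input carries the `00000` wildcard; the wildcard is honored on the
query side only — a reference annotated `00000` is a literal type. Typed
matching therefore implies untyped matching, which gives the containment
lattice the tests verify (`strict ⇒ subset ∧ superset`,
`subset ⇒ one` for non-empty inputs, typed ⇒ untyped, everything ⇒
`accession`).

`strict` uses exact-site semantics (no margin; unknown matches only
unknown) and requires a one-to-one assignment between the two equal-size
PTM multisets. The assignment is found with Kuhn's augmenting-path
bipartite matching rather than a greedy pairing: with wildcard inputs
such as {`00000@5`, `00046@5`} against {`00046@5`, `00047@5`} a bijection
exists only if the wildcard takes `00047`, which greedy pairing in
canonical order misses. The quantified types (`subset`, `superset`,
`one`) need no injectivity and are evaluated as their literal
quantifiers. Quantifications over empty domains are vacuously true
(an unmodified query subset-matches every same-accession reference);
`one` is false on an empty input PTM set.

## Knowledge-base model and flat files

Pathways form a forest via `parent_id` links (checked acyclic);
pathways list member reactions; reactions hold ≥ 1 participant, each a
proteoform with a role from {input, output, catalyst, regulator} and a
context of `individual`, `complex:<id>` or `set:<id>`. Contexts are
annotation only — they do not change edge construction. Loading
validates full cross-reference closure (participants against the
proteoform list, reactions and parents against their tables) and
reports dangling identifiers. Saving orders every table
deterministically, so save/load round-trips are identities and
generation is byte-reproducible.

## Synthetic generator

The generator emulates the structure of a curated pathway database at
desk scale. Defaults: 200 proteins with sequences of 120–360 residues;
half the proteins (`ptm_fraction = 0.5`) carry 2–3 modified proteoforms
of 1–3 PTMs each in addition to their unmodified canonical form, with
types drawn from a catalogue of common modifications (phospho-S/T/Y,
acetylation, glycosylation, methylation, ubiquitination, palmitoylation)
and 10% of modified forms on a non-canonical isoform; 300 reactions with
2–6 participants (roles uniform; 70% individual / 15% complex / 15% set
context); 40 pathways in a hierarchy of depth ≤ 3 with roughly a quarter
as roots, each reaction attached to 1–2 pathways; 100 variants
(alternating rsID and `chr:pos` spellings, 10% mapping to two proteins).
Proteins left out of the random draw are appended to a random reaction so
every proteoform participates somewhere. Modification sites are capped
at sequence length − 10 so a +5 perturbation (below) always remains a
valid coordinate. All draws come from one seeded `random.Random`;
identical (config, seed) pairs produce byte-identical files.

What the generator does **not** emulate: realistic sequence composition
or homology (peptides are matched by exact substring, so shared
subsequences between real paralogues are absent), realistic PTM
co-occurrence patterns, pathway size distributions, or the heavy-tailed
participation of real hub proteins. Passing tests on synthetic data
therefore demonstrate the correctness of the matching, counting and
network semantics — not biological performance on any particular
curated database release.

## Sensitivity experiment

Eligible candidates are the PTM-carrying proteoforms of proteins with at
least two PTM-carrying proteoforms. Sampled candidates are perturbed:
the first PTM (canonical order) has its type replaced by the `00000`
wildcard and its site shifted +5; a second PTM, when present, is also
shifted +5 (the same offset, chosen for symmetry); further PTMs are
unchanged; unknown sites stay unknown. Each altered proteoform is
matched back against the whole reference set per stringency, reporting
the share recovering its own original (*Original*) and the share hitting
any other same-accession reference (*Others*), per sample. Defaults
follow the experiment's design: 10 samples of 300, margin 5, sampling
without replacement from a seeded RNG. Because the wildcard also
satisfies typed matching on the query side, every non-strict stringency
recovers the original at margin 5 (the +5 shift is exactly at the
inclusive margin); `strict` recovers none (sites moved, no margin) —
the stringency ordering of Original shares is therefore ≥, not strictly
decreasing.

## Input mapping

Gene names resolve through the gene↔accession table (case-sensitive
exact match); variants through the variant table (rsID or 1-based
`chr:pos` keys, fan-out preserved); peptides by exact substring search
over the FASTA sequences (no I/L equivalence, no missed-cleavage
expansion — every containing protein is returned); modified peptides map
each occurrence at 1-based start *s* so a peptide-relative PTM position
*q* becomes protein site *s + q − 1*, one candidate proteoform per
occurrence, with matching deciding which candidates are real. Unmapped
tokens are recorded as unresolved, never invented. Protein-level inputs
yield proteoforms with empty PTM sets and are searched by accession
regardless of the configured stringency.

## Search and overrepresentation analysis

Search rows enumerate (input token, entity, matched reference, reaction,
pathway, role, context), with each pathway's ancestors listed up to the
top level. The ORA universe is the distinct accessions (protein
granularity) or distinct proteoforms (proteoform granularity) of the
reference set; proteoform granularity is used when the input kind can
carry PTMs (proteoforms, modified peptides), protein granularity
otherwise. Per pathway, `entities_total` counts distinct participants
over the pathway's *reaction closure* (its own reactions plus all
descendant pathways'), so that matches inherited by ancestors can never
exceed the pathway's entity count. `n` defaults to the distinct input
entities with at least one match in the database ("mapped"); counting
all resolved entities instead is exposed as `n_mode="resolved"` because
the alternative reading is also defensible — the mapped convention keeps
p-values well defined when inputs contain unmappable tokens. The right
tail Pr(X ≥ k) is evaluated through the binomial survival function
(`sf(k − 1)`), not naive `1 − cdf`, so deep tails do not cancel to 0;
BH adjustment uses the standard step-up procedure over the emitted
p-value vector. Pathways with no matched entity are not emitted, and
top-level pathways are not excluded.

## Networks

Per reaction, every unordered pair of distinct projected identities
yields one edge record; identities equal after projection (e.g. two
proteoforms of one accession at protein granularity) produce no
self-edge. The on-disk edge list is therefore a multigraph keyed by
reaction, preserving per-reaction role/context annotation, while degree
and subnetwork membership collapse multiplicity to distinct neighbours —
one convention serving both the annotated edge output and degree
summaries. At gene granularity an accession maps to its
(alphabetically first) gene name; accessions with no gene mapping keep
their accession with a warning. A node is *canonical* when it
represents at least one unmodified canonical proteoform and *specific*
otherwise. Roles never filter edges: co-participation alone connects,
and complex/set membership is annotation, not an edge source.

## Numerical and design choices

* Margins are inclusive (|Δ| ≤ margin) and margin 0 is legal; `strict`
  and `accession` ignore the margin entirely.
* Probabilities are written with 6 significant digits; all TSV outputs
  are sorted deterministically, making whole CLI runs byte-reproducible.
* Problem sizes in the test suite and the acceptance script (KBs of
  40–200 proteins, 1,200 oracle pairs, 3 × 100 sensitivity samples) are
  chosen so every property is exercised across seeds while the whole
  suite completes in seconds.
* Exit codes: 0 success, 2 configuration error, 3 data-integrity error;
  logs go to stderr, data only to files.

## Known limitations

* No sequence-level validation that a modified residue matches the PTM
  type (e.g. `00046` on a non-serine is accepted).
* Cross-isoform matching is not supported by design; proteoforms of
  different isoforms never match, even under `accession`.
* Peptide mapping is exact-substring only; real search engines tolerate
  ambiguity this package does not model.
* The ORA inherits the usual independence assumptions of the Bernoulli
  model; overlapping pathways are tested marginally.
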