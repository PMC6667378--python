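# proteopath

Proteoform-aware mapping of multi-omics data onto pathway knowledge bases.

## The problem

Pathway analysis usually reduces both the input data and the pathway
annotation to gene- or protein-centric lists, discarding isoform and
post-translational modification (PTM) state.  Yet many biochemical
reactions only occur when the participating proteins are in a specific
posttranslational state — a kinase phosphorylated at one site and the
same kinase unmodified are different actors.  `proteopath` keeps that
distinction: it models **proteoforms** (a protein accession, an optional
isoform number, and a multiset of PSI-MOD-typed modifications at 1-based
sequence coordinates), matches them against a pathway knowledge base
under an explicit, tunable stringency, and builds interaction networks
in which different forms of one protein are different nodes.

It is aimed at proteomics and systems-biology analysts who have lists of
genes, variants, proteins, peptides (possibly modified), phosphosites or
proteoforms and want to know which reactions and pathways those entities
can participate in — at the granularity their data actually supports.

## The method

**Proteoform notation.** `ACCESSION[-ISOFORM];TYPE:SITE,TYPE:SITE,...`,
e.g. `P01308;00087:53,00798:31,00798:43`. Types are 5-digit PSI-MOD
identifiers (`MOD:` prefix optional); `?` marks an unknown site; `00000`
is a query-side wildcard matching any modification type.

**Matching stringencies.** A match always requires identical accession
and isoform. Two known sites agree when |input − reference| ≤ *margin*
(a user-set residue tolerance); an unknown site on either side agrees
with anything. Given PTM multisets *I* (input) and *R* (reference):

| Stringency | Rule |
|---|---|
| `strict`   | \|I\| = \|R\| and a one-to-one assignment with exact sites (no margin) |
| `superset` | every PTM of *R* matches some PTM of *I* |
| `subset`   | every PTM of *I* matches some PTM of *R* |
| `one`      | at least one PTM of *I* matches a PTM of *R* |
| `*_no_types` | as above, ignoring modification types |
| `accession`  | accession + isoform identity only |

**Overrepresentation analysis.** Matching an entity to a pathway is a
Bernoulli trial with success probability *p* = (entities in the pathway)
/ (entities in the database). For *n* distinct input entities of which
*k* fall in the pathway, the p-value is the binomial right tail
Pr(X ≥ k) = 1 − F(k − 1; n, p), adjusted across pathways with
Benjamini–Hochberg.

**Networks.** Two entities are connected when they co-participate in a
reaction; node identity is the gene name, protein accession, or full
proteoform depending on the chosen granularity. Edges carry the
reaction, each endpoint's role (input/output/catalyst/regulator) and
complex/set context. Given an input list, *internal* edges connect two
input nodes and *external* edges connect an input node to the rest.

## Worked example

Knowledge bases are directories of five TSV files (plus optional
variant map and FASTA); a synthetic but structurally realistic one can
be generated:

```bash
proteopath generate-kb -o kb --seed 11 --n-proteins 60 --n-reactions 70 --n-pathways 10
# generated KB: proteoforms=123 reactions=70 pathways=10 genes=60 variants=100
```

Query three proteoforms (the second has its phosphosite displaced by two
residues from the annotation) with subset matching and a 5-residue
margin:

```bash
cat > input.txt <<EOF
P00001;00046:167,00048:203
P00001;00046:222
P00003;
EOF
proteopath match-proteoforms input.txt --kb kb -o out \
    --matching subset --margin 5 --graph proteoform
# [proteoform] raw=3 resolved=3 unresolved=0 matched_references=3 search_rows=25 pathways=9
# [proteoform] proteoform network: nodes=123 edges=494 internal=1 external=20
```

`out/search.tsv` lists every (entity, matched reference, reaction,
pathway) association, including ancestor pathways. The displaced
phosphosite still finds its reference because 222 is within 5 residues
of the annotated site 224:

```text
input             entity            matched                     reaction_id  reaction_name  pathway_id
P00001;00046:222  P00001;00046:222  P00001;00046:224,00087:156  R00006       Reaction 6     PW0001
```

`out/analysis.tsv` holds the overrepresentation statistics; with n = 3
input proteoforms, Pathway 1 contains all three of its k = 3 matched
entities but also 118 of the 123 database proteoforms (p = 0.959), so it
is not enriched:

```text
pathway_id  pathway_name  entities_found  entities_total  p        n  p_value   fdr
PW0001      Pathway 1     3               118             0.95935  3  0.882939  0.935787
PW0002      Pathway 2     2               62              0.504065 3  0.506097  0.81487
```

`out/proteoform_network_{nodes,edges}.tsv` hold the full co-participation
network and `out/proteoform_{internal,external}_edges.tsv` the
subnetworks around the input. The other input kinds work the same way
(`match-genes`, `match-variants`, `match-proteins`, `match-peptides`,
`match-modified-peptides`), and `proteopath sensitivity` runs the
annotation-robustness experiment (perturb reference proteoforms, match
them back, report recovery per stringency).

All of the above is also available as a library:

```python
from proteopath import (parse_proteoform, MatchingConfig, MatchingType,
                        load_kb, search, analyse, make_universe)
```

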