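"""Independent reference implementations used only to check the package.

These evaluate the definitions literally — explicit quantifiers, full
permutation search for one-to-one assignments, exact rational arithmetic
for the binomial tail, and the textbook Benjamini–Hochberg procedure —
without sharing code with the implementation under test.
"""

from fractions import Fraction
from itertools import permutations
from math import comb
import random

from proteopath import MatchingType, Proteoform, Ptm


# -- proteoform matching ----------------------------------------------------

def _sites_match(a, b, margin):
    if a is None:
        return True
    if not isinstance(a, int) or a < 1:
        return False
    if b is None or b == -1:
        return True
    if not isinstance(b, int) or b < 1:
        return False
    return abs(a - b) <= margin


def _ptm_match(a: Ptm, b: Ptm, margin, use_types):
    if not _sites_match(a.site, b.site, margin):
        return False
    if use_types and a.type_id != b.type_id and a.type_id != "00000":
        return False
    return True


def _strict_ptm(a: Ptm, b: Ptm):
    return a.site == b.site and (a.type_id == b.type_id or a.type_id == "00000")


def oracle_match(inp: Proteoform, ref: Proteoform, mt: MatchingType,
                 margin: int) -> bool:
    """Literal quantifier evaluation of the eight matching stringencies."""
    if inp.accession != ref.accession or inp.isoform != ref.isoform:
        return False
    if mt is MatchingType.ACCESSION:
        return True
    if mt is MatchingType.STRICT:
        if len(inp.ptms) != len(ref.ptms):
            return False
        return any(
            all(_strict_ptm(i, r) for i, r in zip(inp.ptms, perm))
            for perm in permutations(ref.ptms)
        )
    use_types = mt in (MatchingType.SUPERSET, MatchingType.SUBSET,
                       MatchingType.ONE)
    if mt in (MatchingType.SUBSET, MatchingType.SUBSET_NO_TYPES):
        return all(any(_ptm_match(i, r, margin, use_types) for r in ref.ptms)
                   for i in inp.ptms)
    if mt in (MatchingType.SUPERSET, MatchingType.SUPERSET_NO_TYPES):
        return all(any(_ptm_match(i, r, margin, use_types) for i in inp.ptms)
                   for r in ref.ptms)
    return any(_ptm_match(i, r, margin, use_types)
               for i in inp.ptms for r in ref.ptms)


def random_proteoform_pairs(n_pairs, seed, *, allow_wildcard=True,
                            allow_unknown=False, max_ptms=4):
    """Seeded random (input, reference) proteoform pairs sharing accession
    space, for exercising all eight stringencies."""
    rng = random.Random(seed)
    accessions = ["A00001", "A00002", "A00003"]
    types = ["00046", "00047", "00048", "00087"]
    pairs = []
    for _ in range(n_pairs):
        acc = rng.choice(accessions)
        iso_in = rng.choice([None, None, None, 2])
        iso_ref = iso_in if rng.random() < 0.8 else rng.choice([None, 2])

        def ptms(is_input):
            out = []
            for _ in range(rng.randint(0, max_ptms)):
                t = rng.choice(types)
                if is_input and allow_wildcard and rng.random() < 0.15:
                    t = "00000"
                site = None if (allow_unknown and rng.random() < 0.1) \
                    else rng.randint(1, 30)
                out.append(Ptm(t, site))
            return tuple(out)

        pairs.append((
            Proteoform(acc, iso_in, ptms(True)),
            Proteoform(rng.choice([acc, acc, acc, "A00009"]), iso_ref,
                       ptms(False)),
            rng.choice([0, 1, 5]),
        ))
    return pairs


# -- overrepresentation analysis --------------------------------------------

def exact_binomial_tail(k: int, n: int, p: float) -> float:
    """Pr(X >= k) by exact rational summation of the binomial pmf."""
    pf = Fraction(p)  # the exact binary value of the float argument
    total = sum(
        comb(n, i) * pf**i * (1 - pf) ** (n - i) for i in range(k, n + 1)
    )
    return float(total)


def exact_binomial_tail_grid(n: int, p: float) -> list:
    """Pr(X >= k) for every k in 0..n, by exact pmf suffix sums."""
    pf = Fraction(p)
    pmf = [comb(n, i) * pf**i * (1 - pf) ** (n - i) for i in range(n + 1)]
    tails = [Fraction(0)] * (n + 1)
    acc = Fraction(0)
    for k in range(n, -1, -1):
        acc += pmf[k]
        tails[k] = acc
    return [float(t) for t in tails]


def textbook_bh(pvals):
    """Benjamini–Hochberg as printed in textbooks: sort, scale by m/rank,
    enforce monotonicity from the largest rank down, cap at 1, restore order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
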