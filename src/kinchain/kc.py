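"""Kinship-chain (KC) nomenclature.

A kinship chain encodes the sex-labeled path that connects two individuals
through their mutual relatives as a compact string.  Single persons are
written ``M`` or ``F``; ``→`` points from parent to child (``M→F`` is a
father and his daughter); ``←FM→`` is a full-sibling junction through a
couple (``M←FM→F`` are brother and sister); and unrelated pairs are the
arrow-free strings ``MM``, ``FM`` and ``FF``.

Because a chain can be read from either end, every chain has two spellings.
The canonical spelling is the lexicographically smaller of the two under an
ordering in which ``→`` sorts before ``←``; :func:`parse_kc` always returns
the canonical object.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

RIGHT = "→"  # →  parent on the left
LEFT = "←"   # ←  parent on the right
COUPLE = "FM"

#: relationship class -> degree of relatedness (0 = unrelated)
DEGREE_OF_CLASS = {
    "PO": 1, "FS": 1,
    "GP": 2, "HS": 2, "AV": 2,
    "GGP": 3, "1C": 3, "HAV": 3, "GAV": 3,
    "UN": 0,
}

#: degree -> autosomal kinship coefficient
_KINSHIP_BY_DEGREE = {1: 0.25, 2: 0.125, 3: 0.0625, 0: 0.0}

# arrow sorting rank used by canonicalization (→ before ←)
_ARROW_RANK = {RIGHT: "\x00", LEFT: "\x01"}


class KCParseError(ValueError):
    """Raised for malformed or unsupported kinship-chain strings."""


@dataclass(frozen=True)
class KinshipChain:
    """A canonical kinship chain.

    ``tokens`` alternate person tokens (``M``/``F``/``FM``) and arrow tokens;
    an unrelated chain is two person tokens with no arrow.  Instances are
    always stored in canonical orientation, so ``==`` compares chains as
    relationships, not spellings.
    """

    tokens: tuple[str, ...]
    relationship_class: str

    def __str__(self) -> str:
        return "".join(self.tokens)

    @property
    def degree(self) -> int:
        return DEGREE_OF_CLASS[self.relationship_class]

    @property
    def persons(self) -> tuple[str, ...]:
        """Person tokens along the path (couples appear as one ``FM`` token)."""
        return tuple(t for t in self.tokens if t not in (RIGHT, LEFT))

    @property
    def junctions(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if t in (RIGHT, LEFT))

    @property
    def endpoint_sexes(self) -> tuple[str, str]:
        p = self.persons
        return p[0], p[-1]


@dataclass(frozen=True)
class LineageProfile:
    """Obligate lineage-sharing properties of a kinship chain.

    ``same_paternal_lineage`` — the two endpoints are both male and connected
    purely through father→son transmissions, so they carry the same Y
    haplotype (up to mutation).  ``same_maternal_lineage`` — the endpoints
    trace to a common matriline, so they carry the same mtDNA haplotype.
    ``x_ibd_guaranteed`` — at every X locus the pair shares at least one
    allele identical by descent no matter how the intervening meioses fall.
    """

    same_paternal_lineage: bool
    same_maternal_lineage: bool
    x_ibd_guaranteed: bool
    endpoint_sexes: tuple[str, str]
    kinship_coefficient_autosomal: float


# ---------------------------------------------------------------------------
# parsing

def _tokenize(text: str) -> list[tuple[str, int]]:
    """Split into (token, char-position) runs of letters / single arrows."""
    text = text.replace("->", RIGHT).replace("<-", LEFT)
    if not text:
        raise KCParseError("empty chain")
    runs: list[tuple[str, int]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c in (RIGHT, LEFT):
            if runs and runs[-1][0] in (RIGHT, LEFT):
                raise KCParseError(f"two adjacent arrows at position {i}")
            if not runs:
                raise KCParseError("chain starts with an arrow at position 0")
            runs.append((c, i))
            i += 1
        elif c in "MF":
            start = i
            while i < len(text) and text[i] in "MF":
                i += 1
            runs.append((text[start:i], start))
        else:
            raise KCParseError(f"unexpected character {c!r} at position {i}")
    return runs


def _validate_tokens(runs: list[tuple[str, int]]) -> tuple[str, ...]:
    if runs[-1][0] in (RIGHT, LEFT):
        raise KCParseError(
            f"chain ends with an arrow at position {runs[-1][1]}")
    tokens = [t for t, _ in runs]
    if len(runs) == 1:
        # arrow-free: an unrelated pair of two sexes
        letters, pos = runs[0]
        if len(letters) != 2:
            raise KCParseError(
                f"arrow-free chain must be two sex letters, got {letters!r} "
                f"at position {pos}")
        return tuple(letters)
    for idx, (tok, pos) in enumerate(runs):
        if tok in (RIGHT, LEFT):
            continue
        if tok in ("M", "F"):
            continue
        if tok == COUPLE:
            ok = (0 < idx < len(runs) - 1
                  and runs[idx - 1][0] == LEFT and runs[idx + 1][0] == RIGHT)
            if not ok:
                raise KCParseError(
                    f"couple token FM at position {pos} must be flanked as "
                    f"←FM→")
            continue
        raise KCParseError(
            f"invalid person token {tok!r} at position {pos} "
            f"(expected M, F or ←FM→)")
    if sum(1 for t in tokens if t == COUPLE) > 1:
        raise KCParseError("more than one couple junction is not supported")
    return tuple(tokens)


def _reverse_tokens(tokens: Sequence[str]) -> tuple[str, ...]:
    flip = {RIGHT: LEFT, LEFT: RIGHT}
    return tuple(flip.get(t, t) for t in reversed(tokens))


def _sort_key(tokens: Sequence[str]) -> tuple[str, ...]:
    return tuple(_ARROW_RANK.get(t, t) for t in tokens)


def _canonical_tokens(tokens: tuple[str, ...]) -> tuple[str, ...]:
    if len(tokens) == 2 and all(t in "MF" for t in tokens):
        return tuple(sorted(tokens))  # unrelated pair: unordered sexes
    rev = _reverse_tokens(tokens)
    return min(tokens, rev, key=_sort_key)


def _classify(tokens: tuple[str, ...]) -> str:
    persons = tuple(t for t in tokens if t not in (RIGHT, LEFT))
    if len(tokens) == 2:
        return "UN"
    for cand in (tokens, _reverse_tokens(tokens)):
        arrows = tuple(t for t in cand if t in (RIGHT, LEFT))
        pers = tuple(t for t in cand if t not in (RIGHT, LEFT))
        couple_at = pers.index(COUPLE) if COUPLE in pers else None
        if arrows == (RIGHT,) and couple_at is None:
            return "PO"
        if arrows == (LEFT, RIGHT):
            return "FS" if couple_at == 1 else "HS"
        if arrows == (RIGHT, RIGHT) and couple_at is None:
            return "GP"
        if arrows == (LEFT, RIGHT, RIGHT):
            if couple_at == 1:
                return "AV"
            if couple_at is None:
                return "HAV"
        if arrows == (RIGHT, RIGHT, RIGHT) and couple_at is None:
            return "GGP"
        if arrows == (LEFT, LEFT, RIGHT, RIGHT) and couple_at == 2:
            return "1C"
        if arrows == (LEFT, RIGHT, RIGHT, RIGHT) and couple_at == 1:
            return "GAV"
    raise KCParseError(
        f"chain {''.join(tokens)!r} is not one of the supported pairwise "
        f"relationship shapes (degrees 1–3 or unrelated)")


def parse_kc(text: str) -> KinshipChain:
    """Parse a KC string into its canonical :class:`KinshipChain`.

    ASCII arrows ``->``/``<-`` are accepted on input.  The two spellings of
    the same chain (a chain and its reversal) parse to equal objects.
    """
    runs = _tokenize(text)
    tokens = _validate_tokens(runs)
    cls = _classify(tokens)
    return KinshipChain(_canonical_tokens(tokens), cls)


def canonical_form(kc: KinshipChain | str) -> str:
    """Canonical string of a chain: the lexicographically smaller of the two
    spellings, with ``→`` ordered before ``←``."""
    if isinstance(kc, str):
        kc = parse_kc(kc)
    return str(kc)


def serialize(kc: KinshipChain) -> str:
    return str(kc)


# ---------------------------------------------------------------------------
# enumeration

# path templates: persons are slots (None = free sex, "FM" = couple),
# interleaved with arrows
_TEMPLATES: dict[str, tuple] = {
    "PO": (None, RIGHT, None),
    "FS": (None, LEFT, COUPLE, RIGHT, None),
    "GP": (None, RIGHT, None, RIGHT, None),
    "HS": (None, LEFT, None, RIGHT, None),
    "AV": (None, LEFT, COUPLE, RIGHT, None, RIGHT, None),
    "GGP": (None, RIGHT, None, RIGHT, None, RIGHT, None),
    "1C": (None, LEFT, None, LEFT, COUPLE, RIGHT, None, RIGHT, None),
    "HAV": (None, LEFT, None, RIGHT, None, RIGHT, None),
    "GAV": (None, LEFT, COUPLE, RIGHT, None, RIGHT, None, RIGHT, None),
    "UN": (None, None),
}


def enumerate_kcs(classes: Iterable[str] | None = None) -> list[str]:
    """Enumerate all canonical KC strings for the given relationship classes.

    With the full class set this yields 7 first-degree, 22 second-degree,
    58 third-degree and 3 unrelated chains — 90 in total.
    """
    if classes is None:
        classes = DEGREE_OF_CLASS.keys()
    classes = list(classes)
    for c in classes:
        if c not in _TEMPLATES:
            raise ValueError(f"unknown relationship class {c!r}")
    out: set[str] = set()
    for c in classes:
        template = _TEMPLATES[c]
        free = [i for i, slot in enumerate(template) if slot is None]
        for sexes in itertools.product("MF", repeat=len(free)):
            tokens = list(template)
            for i, s in zip(free, sexes):
                tokens[i] = s
            out.add(str(parse_kc("".join(tokens))))
    return sorted(out)


def kcs_by_degree(degree: int) -> list[str]:
    """All canonical KCs of one degree of relatedness (0 = unrelated)."""
    classes = [c for c, d in DEGREE_OF_CLASS.items() if d == degree]
    if not classes:
        raise ValueError(f"no relationship classes of degree {degree}")
    return enumerate_kcs(classes)


# ---------------------------------------------------------------------------
# pedigree expansion and lineage properties

@dataclass
class PathPedigree:
    """The minimal pedigree realizing a chain.

    ``sex``: per-person sex; ``father``/``mother``: parent ids where the
    parent lies on the path (missing parents are unrelated founders).
    ``endpoints``: ids of the two compared individuals.
    """

    sex: dict[int, str]
    father: dict[int, int]
    mother: dict[int, int]
    endpoints: tuple[int, int]

    def topological_order(self) -> list[int]:
        order: list[int] = []
        placed: set[int] = set()
        pending = set(self.sex)
        while pending:
            ready = [p for p in pending
                     if (p not in self.father or self.father[p] in placed)
                     and (p not in self.mother or self.mother[p] in placed)]
            if not ready:
                raise ValueError("cycle in path pedigree")
            for p in sorted(ready):
                order.append(p)
                placed.add(p)
                pending.discard(p)
        return order


def path_pedigree(kc: KinshipChain) -> PathPedigree:
    """Expand a chain into explicit persons with parent links.

    Couple tokens expand into two persons (the F and the M of the couple).
    """
    sex: dict[int, str] = {}
    father: dict[int, int] = {}
    mother: dict[int, int] = {}
    # node id for each path position; couples map to a (female, male) pair
    nodes: list[tuple[int, ...]] = []
    nid = 0
    for tok in kc.persons:
        if tok == COUPLE:
            sex[nid], sex[nid + 1] = "F", "M"
            nodes.append((nid, nid + 1))
            nid += 2
        else:
            sex[nid] = tok
            nodes.append((nid,))
            nid += 1

    def link(parents: tuple[int, ...], child_group: tuple[int, ...]) -> None:
        (child,) = child_group
        for p in parents:
            if sex[p] == "M":
                father[child] = p
            else:
                mother[child] = p

    arrows = kc.junctions
    persons = kc.persons
    for i, arrow in enumerate(arrows):
        ln, rn = nodes[i], nodes[i + 1]
        if persons[i] == COUPLE and arrow == RIGHT:
            link(ln, rn)
        elif persons[i + 1] == COUPLE and arrow == LEFT:
            link(rn, ln)
        elif arrow == RIGHT:
            link(ln, rn)
        else:
            link(rn, ln)

    endpoints = (nodes[0][0], nodes[-1][-1])
    if kc.relationship_class == "UN":
        father.clear()
        mother.clear()
    return PathPedigree(sex, father, mother, endpoints)


def _lineage_closure(ped: PathPedigree, start: int, parent: dict[int, int]
                     ) -> set[int]:
    out = {start}
    cur = start
    while cur in parent:
        cur = parent[cur]
        out.add(cur)
    return out


def _x_ibd_guaranteed(ped: PathPedigree) -> bool:
    """Exhaustive per-locus gene-drop on X: does the endpoint pair share at
    least one allele identical by descent under every possible sequence of
    maternal-meiosis choices?  Missing parents contribute unique founder
    alleles."""
    order = ped.topological_order()
    # persons whose mother is on the path: one binary choice each
    choosers = [p for p in order if p in ped.mother]
    fresh = itertools.count()

    for choices in itertools.product((0, 1), repeat=len(choosers)):
        pick = dict(zip(choosers, choices))
        alleles: dict[int, tuple[int, ...]] = {}
        for p in order:
            mat = (alleles[ped.mother[p]][pick[p]] if p in ped.mother
                   else next(fresh))
            if ped.sex[p] == "M":
                alleles[p] = (mat,)
            else:
                if p in ped.father:
                    pat = alleles[ped.father[p]][0]  # male X passes intact
                else:
                    pat = next(fresh)
                alleles[p] = (mat, pat)
        a, b = ped.endpoints
        if not set(alleles[a]) & set(alleles[b]):
            return False
    return True


def chain_properties(kc: KinshipChain | str) -> LineageProfile:
    """Derive the obligate lineage-sharing profile of a chain by symbolic
    gene-dropping through its minimal pedigree."""
    if isinstance(kc, str):
        kc = parse_kc(kc)
    ped = path_pedigree(kc)
    a, b = ped.endpoints
    if kc.relationship_class == "UN":
        return LineageProfile(False, False, False, kc.endpoint_sexes, 0.0)
    paternal = (ped.sex[a] == "M" and ped.sex[b] == "M"
                and bool(_lineage_closure(ped, a, ped.father)
                         & _lineage_closure(ped, b, ped.father)))
    maternal = bool(_lineage_closure(ped, a, ped.mother)
                    & _lineage_closure(ped, b, ped.mother))
    return LineageProfile(
        same_paternal_lineage=paternal,
        same_maternal_lineage=maternal,
        x_ibd_guaranteed=_x_ibd_guaranteed(ped),
        endpoint_sexes=kc.endpoint_sexes,
        kinship_coefficient_autosomal=_KINSHIP_BY_DEGREE[kc.degree],
    )


def sex_matched_unrelated(kc: KinshipChain | str) -> str:
    """The unrelated KC with the same endpoint sexes ("MM", "FM" or "FF")."""
    if isinstance(kc, str):
        kc = parse_kc(kc)
    return "".join(sorted(kc.endpoint_sexes))
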