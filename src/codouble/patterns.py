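"""Binary site patterns and their minimal-substitution classification.

Every gap-free, strictly biallelic alignment column is coded as a
six-bit binary pattern in the fixed role order (bx, by, hx, hy, mx,
my), with the outgroup (platypus) variant mapped to 0 and the
alternative variant to 1.  Columns with one variant (monomorphic) or
three or more variants (likely hypermutable) are rejected.

Each of the 64 possible patterns is then classified by parsimony on
the preradiation gametolog tree

    (out, (bx, (hx, mx) sx) xstem, (by, (hy, my) sy) ystem)

i.e. the topology in which the X gametologs of all three species form
one clade and the Y gametologs another, because X-Y differentiation
predates the species radiation.  A substitution on any of the ten
ingroup branches flips the states of the leaves below it; a
substitution on the branch to the outgroup merely exchanges 0s and 1s,
so a pattern and its bitwise complement are treated equivalently.

The categories relevant to the gene-conversion test are the six
*within-lineage* double patterns (explainable by X+Y substitutions in
one lineage — or by a single substitution plus a gene conversion
within that lineage) and the twelve *among-lineage* double patterns
(X and Y substitutions in different lineages, which conversion cannot
mimic because those chromosomes never co-occurred in one organism).
Substitutions on the bovine terminal branch and on the X (resp. Y)
stem uniting human and mouse are pooled into the lumped classes
``bsx``/``bsy``: with only one Laurasiatheria representative the two
placements produce complementary patterns and cannot be told apart.
Double patterns that cross the lumped classes (e.g. bovine-X with
stem-Y) fall outside the 18-pattern scheme and are classified
``complex``, as is anything needing three or more substitutions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import INGROUP_ROLES, SiteColumn

__all__ = [
    "BinarySitePattern",
    "PatternClass",
    "PatternCounts",
    "SiteRejection",
    "polarize",
    "classify_pattern",
    "tabulate",
    "count_patterns_from_states",
    "WITHIN_PATTERNS",
    "AMONG_PATTERNS",
    "TABLE_PATTERNS",
]

# --------------------------------------------------------------------------
# Tree structure: leaves flipped by a substitution on each ingroup branch.
# --------------------------------------------------------------------------

BRANCH_LEAVES: dict[str, frozenset[str]] = {
    "bx": frozenset({"bx"}),
    "by": frozenset({"by"}),
    "hx": frozenset({"hx"}),
    "hy": frozenset({"hy"}),
    "mx": frozenset({"mx"}),
    "my": frozenset({"my"}),
    "sx": frozenset({"hx", "mx"}),
    "sy": frozenset({"hy", "my"}),
    "xstem": frozenset({"bx", "hx", "mx"}),
    "ystem": frozenset({"by", "hy", "my"}),
}

_BIT = {role: 1 << (5 - i) for i, role in enumerate(INGROUP_ROLES)}
_BRANCH_MASK = {
    b: sum(_BIT[leaf] for leaf in leaves) for b, leaves in BRANCH_LEAVES.items()
}
_ALL_ONES = 0b111111

#: bsx/bsy lumping: bovine terminal and Euarchontoglires stem pooled.
LUMP = {"bx": "bsx", "sx": "bsx", "by": "bsy", "sy": "bsy"}

# Same-lineage X+Y branch pairs -> the within-lineage double classes.
_WITHIN_BRANCH_PAIRS: dict[frozenset[str], frozenset[str]] = {
    frozenset({"bx", "by"}): frozenset({"bsx", "bsy"}),
    frozenset({"sx", "sy"}): frozenset({"bsx", "bsy"}),
    frozenset({"hx", "hy"}): frozenset({"hx", "hy"}),
    frozenset({"mx", "my"}): frozenset({"mx", "my"}),
}

# Cross-lineage terminal X+Y pairs -> the among-lineage double classes.
_AMONG_BRANCH_PAIRS: dict[frozenset[str], frozenset[str]] = {
    frozenset({"bx", "hy"}): frozenset({"bsx", "hy"}),
    frozenset({"by", "hx"}): frozenset({"bsy", "hx"}),
    frozenset({"bx", "my"}): frozenset({"bsx", "my"}),
    frozenset({"by", "mx"}): frozenset({"bsy", "mx"}),
    frozenset({"hx", "my"}): frozenset({"hx", "my"}),
    frozenset({"hy", "mx"}): frozenset({"hy", "mx"}),
}


def _minimal_subsets() -> dict[int, tuple[int, list[frozenset[str]]]]:
    """For every 6-bit target, all minimal branch subsets producing it.

    A subset of ingroup branches produces the pattern equal to the XOR
    of its leaf masks (each substitution flips the leaves below it).
    """
    branches = sorted(_BRANCH_MASK)
    best: dict[int, tuple[int, list[frozenset[str]]]] = {}
    for r in range(len(branches) + 1):
        for combo in itertools.combinations(branches, r):
            target = 0
            for b in combo:
                target ^= _BRANCH_MASK[b]
            if target in best:
                if best[target][0] == r:
                    best[target][1].append(frozenset(combo))
                continue
            best[target] = (r, [frozenset(combo)])
    return best


_MIN_SUBSETS = _minimal_subsets()


@dataclass(frozen=True)
class PatternClass:
    """Parsimony category of a six-bit pattern on the preradiation tree.

    ``branches`` holds the branch labels of the minimal explanation
    (lumped to ``bsx``/``bsy`` for the double categories, matching the
    published 18-pattern scheme); ``min_substitutions`` counts the
    substitutions of that explanation, not charging the outgroup-branch
    flip used when the complement orientation is the cheaper one.
    """

    category: str  # monomorphic | root_single | single | within_double | among_double | complex
    branches: frozenset[str]
    min_substitutions: int

    @property
    def is_double(self) -> bool:
        return self.category in ("within_double", "among_double")


def _bits_to_int(bits: Sequence[int]) -> int:
    if len(bits) != 6 or any(b not in (0, 1) for b in bits):
        raise ValueError(f"need 6 binary digits, got {bits!r}")
    value = 0
    for b in bits:
        value = (value << 1) | b
    return value


def _classify_int(value: int) -> PatternClass:
    if value == 0:
        return PatternClass("monomorphic", frozenset(), 0)
    if value == _ALL_ONES:
        return PatternClass("root_single", frozenset({"root"}), 1)
    k1, subs1 = _MIN_SUBSETS[value]
    k2, subs2 = _MIN_SUBSETS[value ^ _ALL_ONES]
    # The cheaper orientation wins; on ties keep the polarized one.
    k, subsets = (k1, subs1) if k1 <= k2 else (k2, subs2)
    if k == 1:
        (branch,) = next(iter(subsets))
        return PatternClass("single", frozenset({branch}), 1)
    if k == 2:
        pairs = {s for s in subsets}
        within = {_WITHIN_BRANCH_PAIRS[p] for p in pairs if p in _WITHIN_BRANCH_PAIRS}
        among = {_AMONG_BRANCH_PAIRS[p] for p in pairs if p in _AMONG_BRANCH_PAIRS}
        unmatched = [
            p for p in pairs if p not in _WITHIN_BRANCH_PAIRS and p not in _AMONG_BRANCH_PAIRS
        ]
        if within and not among and not unmatched and len(within) == 1:
            return PatternClass("within_double", next(iter(within)), 2)
        if among and not within and not unmatched and len(among) == 1:
            return PatternClass("among_double", next(iter(among)), 2)
        return PatternClass("complex", frozenset(), 2)
    return PatternClass("complex", frozenset(), k)


#: Full classification of all 64 patterns, keyed by pattern integer.
CLASSIFICATION: dict[int, PatternClass] = {v: _classify_int(v) for v in range(64)}


def pattern_string(value: int) -> str:
    """Render a pattern integer as a six-digit bit string, e.g. '001100'."""
    return format(value, "06b")


def pattern_int(bits: str | Sequence[int]) -> int:
    """Parse a pattern given as digits string or 6-tuple into an int."""
    if isinstance(bits, str):
        cleaned = bits.replace(" ", "")
        return _bits_to_int([int(c) for c in cleaned])
    return _bits_to_int(list(bits))


def classify_pattern(bits: str | Sequence[int]) -> PatternClass:
    """Classify a six-bit pattern (tuple or string, spaces allowed)."""
    return CLASSIFICATION[pattern_int(bits)]


#: The 6 within-lineage patterns, in the published row order.
WITHIN_PATTERNS: tuple[str, ...] = (
    "000011", "001100", "110000", "001111", "110011", "111100",
)

#: The 12 among-lineage patterns, in the published row order.
AMONG_PATTERNS: tuple[str, ...] = (
    "100100", "011000",
    "010010", "100001",
    "001001", "000110",
    "111001", "110110",
    "101101", "011110",
    "100111", "011011",
)

#: All 18 double patterns of the classification scheme.
TABLE_PATTERNS: tuple[str, ...] = WITHIN_PATTERNS + AMONG_PATTERNS

_WITHIN_INTS = frozenset(pattern_int(p) for p in WITHIN_PATTERNS)
_AMONG_INTS = frozenset(pattern_int(p) for p in AMONG_PATTERNS)


@dataclass(frozen=True)
class BinarySitePattern:
    """A polarized biallelic site: six bits plus the two variants.

    ``variant0`` is the outgroup (ancestral) nucleotide, ``variant1``
    the derived alternative; ``site_index`` is the 0-based alignment
    column the pattern came from.
    """

    bits: tuple[int, int, int, int, int, int]
    site_index: int
    variant0: str
    variant1: str

    def __post_init__(self) -> None:
        if len(self.bits) != 6 or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be six 0/1 digits, got {self.bits!r}")
        if self.variant0 == self.variant1:
            raise ValueError("variant0 and variant1 must differ")
        for v in (self.variant0, self.variant1):
            if v not in "ACGT":
                raise ValueError(f"invalid nucleotide {v!r}")

    @property
    def value(self) -> int:
        return _bits_to_int(self.bits)

    @property
    def pattern_class(self) -> PatternClass:
        return CLASSIFICATION[self.value]


@dataclass(frozen=True)
class SiteRejection:
    """A gap-free column excluded from pattern coding.

    ``reason`` is ``monomorphic`` (one variant) or ``multiallelic``
    (three or more variants; such sites are likely hypermutable).
    """

    site_index: int
    reason: str


def polarize(column: SiteColumn) -> BinarySitePattern | SiteRejection:
    """Code a gap-free column as a polarized binary pattern.

    Requires exactly two distinct nucleotides among the seven roles;
    the outgroup state maps to 0.  Raises if the column still carries
    a gap or 'N' (callers must filter with
    :func:`codouble.alignment.gapless_columns` first).
    """
    states = [column.states[r] for r in INGROUP_ROLES]
    out_state = column.states["out"]
    for s in states + [out_state]:
        if s not in "ACGT":
            raise ValueError(
                f"column {column.index} contains unresolved state {s!r}; "
                "polarize requires gap-free, fully resolved columns"
            )
    variants = sorted(set(states) | {out_state})
    if len(variants) == 1:
        return SiteRejection(column.index, "monomorphic")
    if len(variants) > 2:
        return SiteRejection(column.index, "multiallelic")
    variant1 = next(v for v in variants if v != out_state)
    bits = tuple(0 if s == out_state else 1 for s in states)
    return BinarySitePattern(
        bits=bits, site_index=column.index, variant0=out_state, variant1=variant1
    )


@dataclass
class PatternCounts:
    """Per-gene tallies of classified site patterns.

    ``per_pattern`` keeps both orientations of the 18 double patterns
    separately (the published tables list them that way); ``pooled``
    merges each pattern with its complement.  ``singles`` tallies
    single-substitution patterns by branch (including ``root``,
    ``xstem`` and ``ystem``); ``other`` counts complex/unclassified
    biallelic patterns.
    """

    gene_name: str
    per_pattern: dict[str, int]
    singles: dict[str, int]
    other: int
    n_gapless_sites: int

    @property
    def within_total(self) -> int:
        return sum(self.per_pattern[p] for p in WITHIN_PATTERNS)

    @property
    def among_total(self) -> int:
        return sum(self.per_pattern[p] for p in AMONG_PATTERNS)

    @property
    def pooled(self) -> dict[frozenset[str], int]:
        """Counts with complement orientations merged (9 canonical pairs)."""
        out: dict[frozenset[str], int] = {}
        for p in TABLE_PATTERNS:
            comp = pattern_string(pattern_int(p) ^ _ALL_ONES)
            key = frozenset({p, comp})
            out[key] = out.get(key, 0) + self.per_pattern[p]
        return out

    @property
    def n_classified(self) -> int:
        return self.within_total + self.among_total + sum(self.singles.values()) + self.other

    def to_dict(self) -> dict:
        return {
            "gene_name": self.gene_name,
            "per_pattern": dict(self.per_pattern),
            "singles": dict(self.singles),
            "other": self.other,
            "n_gapless_sites": self.n_gapless_sites,
            "within_total": self.within_total,
            "among_total": self.among_total,
        }

    @classmethod
    def from_pattern_table(
        cls, gene_name: str, counts: Mapping[str, int], n_gapless_sites: int = 0
    ) -> "PatternCounts":
        """Build counts from a published per-pattern count table.

        ``counts`` maps six-digit pattern strings (spaces allowed) to
        non-negative counts; each pattern is run through the
        classifier, so the within/among totals are derived, never
        copied.
        """
        per_pattern = {p: 0 for p in TABLE_PATTERNS}
        singles: dict[str, int] = {}
        other = 0
        for raw, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for pattern {raw!r}")
            value = pattern_int(raw)
            cls_ = CLASSIFICATION[value]
            key = pattern_string(value)
            if cls_.is_double and key in per_pattern:
                per_pattern[key] += n
            elif cls_.category in ("single", "root_single"):
                (branch,) = cls_.branches
                singles[branch] = singles.get(branch, 0) + n
            elif cls_.category == "monomorphic":
                continue
            else:
                other += n
        return cls(
            gene_name=gene_name,
            per_pattern=per_pattern,
            singles=singles,
            other=other,
            n_gapless_sites=n_gapless_sites,
        )


def tabulate(
    patterns: Iterable[BinarySitePattern],
    gene_name: str = "",
    n_gapless_sites: int = 0,
) -> PatternCounts:
    """Tally classified patterns from one gene into :class:`PatternCounts`."""
    per_pattern = {p: 0 for p in TABLE_PATTERNS}
    singles: dict[str, int] = {}
    other = 0
    for pat in patterns:
        cls_ = pat.pattern_class
        if cls_.is_double:
            per_pattern[pattern_string(pat.value)] += 1
        elif cls_.category in ("single", "root_single"):
            (branch,) = cls_.branches
            singles[branch] = singles.get(branch, 0) + 1
        elif cls_.category == "monomorphic":
            continue
        else:
            other += 1
    return PatternCounts(
        gene_name=gene_name,
        per_pattern=per_pattern,
        singles=singles,
        other=other,
        n_gapless_sites=n_gapless_sites,
    )


# --------------------------------------------------------------------------
# Vectorized path for simulation studies.
# --------------------------------------------------------------------------

_CATEGORY_CODE = {
    "monomorphic": 0,
    "root_single": 1,
    "single": 2,
    "within_double": 3,
    "among_double": 4,
    "complex": 5,
}
_CODE_OF_PATTERN = np.array(
    [_CATEGORY_CODE[CLASSIFICATION[v].category] for v in range(64)], dtype=np.int8
)
_SINGLE_BRANCH_OF_PATTERN = {
    v: next(iter(CLASSIFICATION[v].branches))
    for v in range(64)
    if CLASSIFICATION[v].category in ("single", "root_single")
}
_POW2 = np.array([32, 16, 8, 4, 2, 1], dtype=np.int64)


def count_patterns_from_states(
    states: np.ndarray, gene_name: str = ""
) -> PatternCounts:
    """Tabulate patterns directly from a (7, n_sites) integer state array.

    Row order is (bx, by, hx, hy, mx, my, out) with nucleotides coded
    0-3; no gaps are allowed (the simulator never produces them).
    Numerically identical to running :func:`polarize` +
    :func:`tabulate` column by column, but vectorized for the
    operating-characteristics simulations.
    """
    states = np.asarray(states)
    if states.shape[0] != 7:
        raise ValueError("states must have 7 rows (bx,by,hx,hy,mx,my,out)")
    n = states.shape[1]
    present = np.stack([(states == v).any(axis=0) for v in range(4)])
    n_variants = present.sum(axis=0)
    biallelic = n_variants == 2
    bits = states[:6, biallelic] != states[6, biallelic]
    values = (_POW2[:, None] * bits).sum(axis=0)
    counts64 = np.bincount(values, minlength=64)
    per_pattern = {p: int(counts64[pattern_int(p)]) for p in TABLE_PATTERNS}
    singles: dict[str, int] = {}
    for v, branch in _SINGLE_BRANCH_OF_PATTERN.items():
        if counts64[v]:
            singles[branch] = singles.get(branch, 0) + int(counts64[v])
    other = int(counts64[_CODE_OF_PATTERN[np.arange(64)] == 5].sum())
    return PatternCounts(
        gene_name=gene_name,
        per_pattern=per_pattern,
        singles=singles,
        other=other,
        n_gapless_sites=n,
    )


def write_pattern_report(counts: PatternCounts, path) -> None:
    """Write the per-pattern TSV report (stable published row order)."""
    with open(path, "w") as fh:
        fh.write("gene\tpattern\tclass\tbranches\tcount\n")
        for p in TABLE_PATTERNS:
            cls_ = CLASSIFICATION[pattern_int(p)]
            branches = "+".join(sorted(cls_.branches))
            fh.write(
                f"{counts.gene_name}\t{p}\t{cls_.category}\t{branches}\t"
                f"{counts.per_pattern[p]}\n"
            )
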