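"""Transition/transversion and synonymous/nonsynonymous breakdowns.

Functional constraint could distort the within:among comparison if it
acted differently on the two pattern classes.  Two homogeneity checks
guard against that: sites are split into transitions vs transversions,
and codons into synonymous vs nonsynonymous variant pairs, each
cross-tabulated against the within/among lineage class and tested
with a chi-square whose p-value is obtained from margin-fixed
simulated tables (the small expected cells rule out the asymptotic
reference distribution).

For the codon analysis the outgroup is excluded: requiring exactly two
codon variants across all seven sequences would leave too few codons,
so variants are counted across the six ingroup gametologs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .alignment import INGROUP_ROLES, RoleAlignment

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_tstv(variant0: str, variant1: str) -> str:
    """'transition' for purine-purine / pyrimidine-pyrimidine pairs."""
    pair = {variant0, variant1}
    if len(pair) != 2:
        raise ValueError("variants must be two distinct nucleotides")
    if not pair <= frozenset("ACGT"):
        raise ValueError(f"invalid nucleotides {pair}")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def classify_codon_pair(codon0: str, codon1: str) -> str:
    """'synonymous' iff both codons encode the same amino acid.

    Pairs involving a stop codon are flagged nonsynonymous with a
    warning (a stop is not an amino acid, so 'same residue' cannot
    hold in a meaningful way).
    """
    for c in (codon0, codon1):
        if len(c) != 3 or set(c) - set("ACGT"):
            raise ValueError(f"invalid codon {c!r}")
    if codon0 == codon1:
        raise ValueError("codons must differ")
    aa0 = str(Seq(codon0).translate())
    aa1 = str(Seq(codon1).translate())
    if "*" in (aa0, aa1):
        logger.warning("stop codon in pair (%s, %s); counted nonsynonymous", codon0, codon1)
        return "nonsynonymous"
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


@dataclass
class ContingencyTable2x2:
    """2x2 table of lineage class (rows) by substitution type (columns)."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("within", "among")
    col_labels: tuple[str, str] = ("transition", "transversion")
    p_sim: float | None = None
    n_sim: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for row in self.cells for c in row):
            raise ValueError("cell counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=float)

    @property
    def chi2_stat(self) -> float:
        t = self.array
        n = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (t - expected) ** 2 / expected
        return float(np.nansum(contrib))

    def to_dict(self) -> dict:
        return {
            "cells": [list(r) for r in self.cells],
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "p_sim": self.p_sim,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def tstv_contingency(
    site_classes: Mapping[int, str], site_variants: Mapping[int, tuple[str, str]]
) -> ContingencyTable2x2:
    """Cross-tabulate within/among sites by transition/transversion.

    ``site_classes`` maps alignment column -> 'within' | 'among';
    ``site_variants`` maps the same columns to (variant0, variant1).
    """
    cells = {( r, c): 0 for r in ("within", "among") for c in ("transition", "transversion")}
    for idx, lineage in site_classes.items():
        if lineage not in ("within", "among"):
            raise ValueError(f"bad lineage class {lineage!r}")
        kind = classify_tstv(*site_variants[idx])
        cells[(lineage, kind)] += 1
    return ContingencyTable2x2(
        cells=(
            (cells[("within", "transition")], cells[("within", "transversion")]),
            (cells[("among", "transition")], cells[("among", "transversion")]),
        )
    )


def _ingroup_gapless_indices(aln: RoleAlignment) -> list[int]:
    seqs = [aln.sequences[r] for r in INGROUP_ROLES]
    return [
        i
        for i in range(aln.length)
        if all(s[i] in "ACGT" for s in seqs)
    ]


def codon_contingency(
    aln: RoleAlignment, site_classes: Mapping[int, str]
) -> ContingencyTable2x2:
    """Cross-tabulate qualifying codons by lineage class and syn/nonsyn.

    Codon windows are consecutive triples of ingroup gap-free columns,
    starting at ``aln.cds_frame_offset`` within that column list;
    codons overlapping an excluded column are thereby dropped.  A codon
    qualifies if the six ingroup sequences show exactly two distinct
    codon variants.  Its lineage class comes from the classified sites
    it contains (``site_classes``: alignment column -> 'within' |
    'among'); a codon containing sites of both classes is counted once
    per class, with a warning.
    """
    idx = _ingroup_gapless_indices(aln)
    offset = aln.cds_frame_offset
    cells = {(r, c): 0 for r in ("within", "among") for c in ("synonymous", "nonsynonymous")}
    usable = idx[offset:]
    if len(usable) < 3:
        raise ValueError("frame cannot be established: fewer than 3 usable columns")
    for k in range(0, len(usable) - 2, 3):
        cols = usable[k : k + 3]
        codons = {
            "".join(aln.sequences[r][c] for c in cols) for r in INGROUP_ROLES
        }
        if len(codons) != 2:
            continue
        classes = {site_classes[c] for c in cols if c in site_classes}
        if not classes:
            continue
        if len(classes) > 1:
            logger.warning(
                "codon at columns %s contains both within- and among-lineage "
                "sites; counted once per class",
                cols,
            )
        kind = classify_codon_pair(*sorted(codons))
        for lineage in classes:
            cells[(lineage, kind)] += 1
    return ContingencyTable2x2(
        cells=(
            (cells[("within", "synonymous")], cells[("within", "nonsynonymous")]),
            (cells[("among", "synonymous")], cells[("among", "nonsynonymous")]),
        ),
        col_labels=("synonymous", "nonsynonymous"),
    )


def chisq_simulated(
    table: ContingencyTable2x2,
    n_sim: int = 10**5,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo chi-square p-value with fixed margins.

    Tables are drawn from the multiple hypergeometric distribution
    with the observed row and column margins; the p-value is the
    add-one-corrected proportion of draws whose chi-square statistic
    is at least the observed one.  A zero row or column margin leaves
    nothing to test: p = 1 with a warning.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    t = table.array
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        logger.warning("zero margin; simulated chi-square p set to 1")
        return 1.0
    observed = table.chi2_stat
    a = rng.hypergeometric(int(rows[0]), int(rows[1]), int(cols[0]), size=n_sim)
    sim = np.stack(
        [a, rows[0] - a, cols[0] - a, rows[1] - cols[0] + a], axis=1
    ).astype(float)
    expected = np.array(
        [
            rows[0] * cols[0],
            rows[0] * cols[1],
            rows[1] * cols[0],
            rows[1] * cols[1],
        ]
    ) / n
    stats_sim = ((sim - expected) ** 2 / expected).sum(axis=1)
    hits = int((stats_sim >= observed - 1e-12).sum())
    return (1 + hits) / (n_sim + 1)


def write_table_tsv(table: ContingencyTable2x2, path, gene_name: str = "") -> None:
    """Write the 2x2 table (plus simulated p if present) as TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tclass\t%s\t%s\n" % table.col_labels)
        for label, row in zip(table.row_labels, table.cells):
            fh.write(f"{gene_name}\t{label}\t{row[0]}\t{row[1]}\n")
        if table.p_sim is not None:
            fh.write(f"# simulated p = {table.p_sim} (n_sim = {table.n_sim})\n")
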