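"""Role-keyed gametolog alignments and gap-free column extraction.

The co-double test operates on a seven-sequence alignment of coding
sequences: the X and Y gametologs of cattle (``bx``, ``by``), human
(``hx``, ``hy``) and mouse (``mx``, ``my``), plus an outgroup (``out``,
platypus) used to polarize ancestral vs. derived states.  Because
record headers from public databases are heterogeneous, the mapping
from FASTA record IDs to roles is an explicit two-column TSV input
rather than something parsed out of headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed role order; the first six are the ingroup gametologs in the
#: order used by the binary site-pattern coding, the last the outgroup.
ROLES: tuple[str, ...] = ("bx", "by", "hx", "hy", "mx", "my", "out")

#: Ingroup roles only (outgroup excluded), in pattern-bit order.
INGROUP_ROLES: tuple[str, ...] = ROLES[:6]

_ALPHABET = frozenset("ACGTN-")
_UNRESOLVED = frozenset("N-")


class AlignmentError(ValueError):
    """Raised when an alignment or role map violates a precondition."""


@dataclass(frozen=True)
class RoleAlignment:
    """A validated seven-role nucleotide alignment.

    Parameters
    ----------
    sequences
        Mapping from each role in :data:`ROLES` to an aligned,
        upper-case nucleotide string over ``{A, C, G, T, N, -}``.
    gene_name
        Free-text label used in reports.
    cds_frame_offset
        Column offset (0, 1 or 2) of the first complete codon,
        counted in ingroup gap-free columns; used by the codon-level
        synonymous/nonsynonymous analysis.
    """

    sequences: Mapping[str, str]
    gene_name: str = ""
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.sequences]
        if missing:
            raise AlignmentError(f"role {missing[0]} unassigned")
        extra = [r for r in self.sequences if r not in ROLES]
        if extra:
            raise AlignmentError(f"unknown role(s): {sorted(extra)}")
        lengths = {r: len(s) for r, s in self.sequences.items()}
        if len(set(lengths.values())) != 1:
            a, b = sorted(set(lengths.values()))[:2]
            raise AlignmentError(
                f"sequences have unequal lengths (e.g. {a} vs {b}): {lengths}"
            )
        if next(iter(lengths.values())) < 1:
            raise AlignmentError("alignment length must be >= 1")
        for role, seq in self.sequences.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlignmentError(
                    f"role {role} contains invalid characters {sorted(bad)}"
                )
        if self.cds_frame_offset not in (0, 1, 2):
            raise AlignmentError("cds_frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences["out"])

    def column(self, index: int) -> "SiteColumn":
        """Return the :class:`SiteColumn` at a 0-based alignment index."""
        if not 0 <= index < self.length:
            raise IndexError(index)
        return SiteColumn(
            index=index, states={r: self.sequences[r][index] for r in ROLES}
        )


@dataclass(frozen=True)
class SiteColumn:
    """One alignment column: a 0-based index and one state per role."""

    index: int
    states: Mapping[str, str]


def read_rolemap(path: str | Path) -> dict[str, str]:
    """Read a record-ID → role TSV (header ``record_id<TAB>role``)."""
    mapping: dict[str, str] = {}
    seen_roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(
                    f"{path}:{lineno + 1}: expected two tab-separated columns"
                )
            rec_id, role = parts[0].strip(), parts[1].strip().lower()
            if lineno == 0 and (rec_id, role) == ("record_id", "role"):
                continue
            if role not in ROLES:
                raise AlignmentError(f"{path}:{lineno + 1}: unknown role {role!r}")
            if role in seen_roles:
                raise AlignmentError(
                    f"duplicate role assignment: {role} given to both "
                    f"{seen_roles[role]!r} and {rec_id!r}"
                )
            seen_roles[role] = rec_id
            mapping[rec_id] = role
    missing = [r for r in ROLES if r not in seen_roles]
    if missing:
        raise AlignmentError(f"role {missing[0]} unassigned")
    return mapping


def read_alignment(
    fasta_path: str | Path,
    rolemap_path: str | Path,
    gene_name: str | None = None,
    cds_frame_offset: int = 0,
) -> RoleAlignment:
    """Read an aligned FASTA plus role map into a :class:`RoleAlignment`.

    Records present in the FASTA but absent from the role map are
    ignored with a logged warning.  Lowercase nucleotides are
    normalized to uppercase.
    """
    rolemap = read_rolemap(rolemap_path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        role = rolemap.get(record.id)
        if role is None:
            logger.warning("record %r not in role map; ignored", record.id)
            continue
        sequences[role] = str(record.seq).upper()
    missing = [r for r in ROLES if r not in sequences]
    if missing:
        raise AlignmentError(
            f"role {missing[0]} unassigned: record "
            f"{[k for k, v in rolemap.items() if v == missing[0]][0]!r} "
            f"not found in {fasta_path}"
        )
    return RoleAlignment(
        sequences=sequences,
        gene_name=gene_name if gene_name is not None else Path(fasta_path).stem,
        cds_frame_offset=cds_frame_offset,
    )


def write_alignment(
    aln: RoleAlignment, fasta_path: str | Path, rolemap_path: str | Path | None = None
) -> None:
    """Write the alignment back to FASTA (record IDs = role names).

    Mostly a debugging aid; with ``rolemap_path`` also writes the
    matching identity role map so the output round-trips through
    :func:`read_alignment`.
    """
    records = [
        SeqRecord(Seq(aln.sequences[r]), id=r, description="") for r in ROLES
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if rolemap_path is not None:
        with open(rolemap_path, "w") as fh:
            fh.write("record_id\trole\n")
            for r in ROLES:
                fh.write(f"{r}\t{r}\n")


def gapless_columns(aln: RoleAlignment) -> list[SiteColumn]:
    """Columns where none of the seven roles carries ``-`` or ``N``.

    'N' is treated like a gap: ambiguity codes cannot be polarized, so
    only fully resolved columns enter the analysis.  Original 0-based
    alignment indices are preserved in the returned columns.
    """
    out: list[SiteColumn] = []
    seqs = [aln.sequences[r] for r in ROLES]
    for i in range(aln.length):
        states = [s[i] for s in seqs]
        if any(c in _UNRESOLVED for c in states):
            continue
        out.append(SiteColumn(index=i, states=dict(zip(ROLES, states))))
    return out
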