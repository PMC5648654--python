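"""Shared fixtures: tiny alignments built programmatically."""

from __future__ import annotations

import pytest

from codouble.alignment import ROLES, RoleAlignment


def make_alignment(columns: list[dict[str, str]], gene_name: str = "toy", **kw) -> RoleAlignment:
    """Build a RoleAlignment from a list of per-column role->state dicts."""
    sequences = {r: "".join(col[r] for col in columns) for r in ROLES}
    return RoleAlignment(sequences=sequences, gene_name=gene_name, **kw)


def uniform_column(state: str = "A") -> dict[str, str]:
    return {r: state for r in ROLES}


def column_from_bits(bits: str, variant0: str = "A", variant1: str = "G") -> dict[str, str]:
    """Column whose ingroup states follow a six-bit pattern, outgroup = variant0."""
    cleaned = bits.replace(" ", "")
    col = {"out": variant0}
    for role, b in zip(ROLES[:6], cleaned):
        col[role] = variant1 if b == "1" else variant0
    return col


@pytest.fixture
def write_alignment_files(tmp_path):
    """Write a RoleAlignment to FASTA + role map files; returns the paths."""

    def _write(aln: RoleAlignment, ids: dict[str, str] | None = None):
        ids = ids or {r: r for r in ROLES}
        fasta = tmp_path / "aln.fasta"
        rolemap = tmp_path / "roles.tsv"
        with open(fasta, "w") as fh:
            for r in ROLES:
                fh.write(f">{ids[r]}\n{aln.sequences[r]}\n")
        with open(rolemap, "w") as fh:
            fh.write("record_id\trole\n")
            for r in ROLES:
                fh.write(f"{ids[r]}\t{r}\n")
        return fasta, rolemap

    return _write
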