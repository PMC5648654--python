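"""Preradiation-topology prerequisite checks.

The co-double test is only valid when X-Y differentiation predates
the species radiation, i.e. the gene tree groups {bx, hx, mx} apart
from {by, hy, my}.  Two independent indicators are combined: a
neighbor-joining tree built from simple pairwise distances must show
the X clade, and stem-branch single-substitution site patterns
(10 10 10-type) must outnumber the species-synapomorphy patterns
(11 00 00-type) that a postradiation topology would produce as
singles.  Branch lengths and bootstrap support are deliberately out
of scope: the prerequisite is about topology only, so plain
p-distances (or their Jukes-Cantor transform) stand in for more
elaborate distance models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .alignment import ROLES, RoleAlignment, gapless_columns
from .patterns import PatternCounts

X_CLADE = frozenset({"bx", "hx", "mx"})
Y_SIDE = frozenset({"by", "hy", "my", "out"})


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between the seven roles."""

    labels: tuple[str, ...]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class TopologyVerdict:
    """Outcome of the preradiation prerequisite check."""

    preradiation_support: int
    postradiation_support: int
    nj_preradiative: bool
    verdict: str  # preradiation | postradiation | ambiguous

    def to_dict(self) -> dict:
        return {
            "preradiation_support": self.preradiation_support,
            "postradiation_support": self.postradiation_support,
            "nj_preradiative": self.nj_preradiative,
            "verdict": self.verdict,
        }


def distance_matrix(aln: RoleAlignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise p-distance (or JC69 transform) over gap-free columns."""
    if model not in ("p_distance", "jc69"):
        raise ValueError("model must be 'p_distance' or 'jc69'")
    cols = gapless_columns(aln)
    if not cols:
        raise ValueError("no gap-free columns")
    n = len(cols)
    states = {r: np.array([c.states[r] for c in cols]) for r in ROLES}
    k = len(ROLES)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = float((states[ROLES[i]] != states[ROLES[j]]).mean())
            if model == "jc69":
                if p >= 0.75:
                    raise ValueError(
                        f"jc69 undefined for pair ({ROLES[i]}, {ROLES[j]}): p = {p:.3f} >= 0.75"
                    )
                p = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=ROLES, d=d, model=model)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou-Nei agglomeration) as Newick text."""
    if len(dm.labels) < 4:
        raise ValueError("neighbor joining needs at least 4 taxa")
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    tree = nj(_SkbioDM(dm.d, ids=list(dm.labels)))
    return str(tree).strip()


def _splits(newick: str) -> set[frozenset[str]]:
    tree = TreeNode.read([newick])
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        names = frozenset(t.name for t in node.tips())
        out.add(names)
        out.add(all_tips - names)
    return out


def has_x_clade(newick: str) -> bool:
    """True if the (unrooted) tree contains the {bx, hx, mx} split."""
    return X_CLADE in _splits(newick)


def preradiation_check(counts: PatternCounts, tree_newick: str) -> TopologyVerdict:
    """Combine NJ topology and site-pattern support into a verdict.

    ``preradiation`` requires the NJ tree to show the X clade *and*
    more stem-branch single patterns than species-synapomorphy
    patterns; if the two indicators disagree the verdict is
    ``ambiguous``, and ``postradiation`` needs both to point the other
    way.  With no variable-site signal at all the verdict is
    ``ambiguous``.
    """
    pre = counts.singles.get("xstem", 0) + counts.singles.get("ystem", 0)
    # Under a postradiation (species-first) topology the within-double
    # patterns would be single species synapomorphies.
    post = counts.within_total
    nj_ok = has_x_clade(tree_newick)
    if pre == 0 and post == 0:
        verdict = "ambiguous"
    elif nj_ok and pre > post:
        verdict = "preradiation"
    elif not nj_ok and pre <= post:
        verdict = "postradiation"
    else:
        verdict = "ambiguous"
    return TopologyVerdict(
        preradiation_support=pre,
        postradiation_support=post,
        nj_preradiative=nj_ok,
        verdict=verdict,
    )
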