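"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's XOR-mask shortcut: substitutions
are simulated as explicit state propagation from the root of the
preradiation tree, enumerating every subset of the eleven branches
(ten ingroup branches plus the branch to the outgroup).
"""

from __future__ import annotations

import itertools

# (child, parent, branch_label); root node is "R"
TREE_EDGES = [
    ("out", "R", "root"),
    ("XR", "R", "xstem"),
    ("YR", "R", "ystem"),
    ("bx", "XR", "bx"),
    ("XS", "XR", "sx"),
    ("hx", "XS", "hx"),
    ("mx", "XS", "mx"),
    ("by", "YR", "by"),
    ("YS", "YR", "sy"),
    ("hy", "YS", "hy"),
    ("my", "YS", "my"),
]
BRANCHES = [e[2] for e in TREE_EDGES]
LEAF_ORDER = ("bx", "by", "hx", "hy", "mx", "my")


def propagate(substituted: set[str]) -> tuple[int, ...]:
    """Polarized leaf pattern after substitutions on the given branches.

    Binary states flip on every substituted branch; the observed
    pattern is each ingroup leaf XOR the outgroup leaf (polarization
    maps the outgroup variant to 0).
    """
    state = {"R": 0}
    for child, parent, branch in TREE_EDGES:
        state[child] = state[parent] ^ (1 if branch in substituted else 0)
    return tuple(state[leaf] ^ state["out"] for leaf in LEAF_ORDER)


def exhaustive_min_substitutions() -> dict[tuple[int, ...], int]:
    """Minimum ingroup substitutions per pattern over all 2^11 subsets.

    The outgroup-branch substitution is not charged: it only exchanges
    0s and 1s, and inverse patterns are treated equivalently.
    """
    best: dict[tuple[int, ...], int] = {}
    for r in range(len(BRANCHES) + 1):
        for combo in itertools.combinations(BRANCHES, r):
            cost = len([b for b in combo if b != "root"])
            pattern = propagate(set(combo))
            if pattern not in best or cost < best[pattern]:
                best[pattern] = cost
    return best
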