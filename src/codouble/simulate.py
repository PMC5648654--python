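"""Synthetic gametolog alignments on the preradiation tree.

Each site evolves independently: a root state is drawn from the base
frequencies and propagated down the preradiation topology

    root -> outgroup
    root -> X stem -> (bx, sx -> (hx, mx))
    root -> Y stem -> (by, sy -> (hy, my))

with a per-branch Bernoulli substitution probability; a substitution
jumps to one of the other three nucleotides uniformly.  After the
terminal branches, each lineage (bovine, human, mouse) independently
experiences gene conversion with its per-site probability: the
acceptor gametolog's state is overwritten by the donor's, in a fixed
or random direction.  Conversion is applied as a whole-site (tract
length 1) event by default; a geometric tract-length option exists to
build clustered counter-example fixtures for the autocorrelation
check.

The default branch probabilities encode the study conditions the test
is aimed at: Y branches longer than X (higher Y mutation rate), mouse
branches longest (short rodent generation time), a short internal
branch between the Laurasiatheria split and the primate/rodent split
(~8 vs ~76 million years), and substantial gametolog stems whose
length reflects a variable time of X-Y differentiation before the
radiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import ROLES, RoleAlignment
from .conversion import exact_tail_p
from .patterns import PatternCounts, count_patterns_from_states

BRANCHES: tuple[str, ...] = (
    "out", "xstem", "ystem", "bx", "by", "sx", "sy", "hx", "hy", "mx", "my",
)
LINEAGES: tuple[str, ...] = ("bovine", "human", "mouse")
_LINEAGE_ROLES = {"bovine": ("bx", "by"), "human": ("hx", "hy"), "mouse": ("mx", "my")}
_ROLE_INDEX = {r: i for i, r in enumerate(ROLES)}

#: Default per-site substitution probabilities (see module docstring).
DEFAULT_BRANCH_PROBS: dict[str, float] = {
    "out": 0.15,
    "xstem": 0.05,
    "ystem": 0.075,
    "bx": 0.02,
    "by": 0.03,
    "sx": 0.002,
    "sy": 0.003,
    "hx": 0.02,
    "hy": 0.03,
    "mx": 0.026,
    "my": 0.039,
}

DEFAULT_BASE_FREQS = (0.25, 0.25, 0.25, 0.25)

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic alignment generator."""

    n_sites: int = 5000
    branch_sub_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_PROBS)
    )
    conv_prob: Mapping[str, float] = field(
        default_factory=lambda: {lin: 0.0 for lin in LINEAGES}
    )
    conv_direction: Mapping[str, str] = field(
        default_factory=lambda: {lin: "random" for lin in LINEAGES}
    )
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    seed: int = 0
    tract_mean: float = 1.0
    gene_name: str = "sim"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for b in BRANCHES:
            p = self.branch_sub_prob.get(b)
            if p is None:
                raise ValueError(f"missing substitution probability for branch {b}")
            if not 0 <= p <= 1:
                raise ValueError(f"branch {b}: probability {p} outside [0, 1]")
        for lin in LINEAGES:
            c = self.conv_prob.get(lin)
            if c is None:
                raise ValueError(f"missing conversion probability for lineage {lin}")
            if not 0 <= c <= 1:
                raise ValueError(f"lineage {lin}: probability {c} outside [0, 1]")
            if self.conv_direction.get(lin) not in ("x_to_y", "y_to_x", "random"):
                raise ValueError(f"lineage {lin}: bad conversion direction")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.tract_mean < 1.0:
            raise ValueError("tract_mean must be >= 1")


def _evolve(parent: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """One branch: Bernoulli substitution to a uniform other nucleotide."""
    child = parent.copy()
    hit = rng.random(parent.size) < prob
    n_hit = int(hit.sum())
    if n_hit:
        # add 1..3 mod 4: uniform over the three other nucleotides
        child[hit] = (parent[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return child


def _apply_conversion(
    x: np.ndarray,
    y: np.ndarray,
    prob: float,
    direction: str,
    tract_mean: float,
    rng: np.random.Generator,
) -> None:
    """Overwrite acceptor states with donor states, in place."""
    n = x.size
    if prob <= 0:
        return
    if tract_mean == 1.0:
        converted = np.flatnonzero(rng.random(n) < prob)
        lengths = np.ones(converted.size, dtype=int)
    else:
        # start-event rate scaled so the marginal per-site conversion
        # probability stays ~prob for geometric tracts of mean tract_mean
        starts = np.flatnonzero(rng.random(n) < prob / tract_mean)
        lengths = rng.geometric(1.0 / tract_mean, size=starts.size)
        converted = starts
    for start, length in zip(converted, lengths):
        stop = min(n, start + int(length))
        if direction == "random":
            d = "x_to_y" if rng.random() < 0.5 else "y_to_x"
        else:
            d = direction
        if d == "x_to_y":
            y[start:stop] = x[start:stop]
        else:
            x[start:stop] = y[start:stop]


def simulate_states(
    params: SimParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate one alignment as a (7, n_sites) array of 0-3 states.

    Row order matches :data:`codouble.alignment.ROLES`.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params.branch_sub_prob
    n = params.n_sites
    root = rng.choice(4, size=n, p=np.asarray(params.base_freqs))
    out = _evolve(root, p["out"], rng)
    xr = _evolve(root, p["xstem"], rng)
    yr = _evolve(root, p["ystem"], rng)
    bx = _evolve(xr, p["bx"], rng)
    xs = _evolve(xr, p["sx"], rng)
    hx = _evolve(xs, p["hx"], rng)
    mx = _evolve(xs, p["mx"], rng)
    by = _evolve(yr, p["by"], rng)
    ys = _evolve(yr, p["sy"], rng)
    hy = _evolve(ys, p["hy"], rng)
    my = _evolve(ys, p["my"], rng)
    pairs = {"bovine": (bx, by), "human": (hx, hy), "mouse": (mx, my)}
    for lin in LINEAGES:
        _apply_conversion(
            pairs[lin][0],
            pairs[lin][1],
            params.conv_prob[lin],
            params.conv_direction[lin],
            params.tract_mean,
            rng,
        )
    states = np.stack([bx, by, hx, hy, mx, my, out])
    return states.astype(np.int8)


def simulate_alignment(
    params: SimParams, rng: np.random.Generator | None = None
) -> RoleAlignment:
    """Simulate a :class:`RoleAlignment` (deterministic given the seed)."""
    states = simulate_states(params, rng=rng)
    sequences = {
        role: "".join(_NUCS[states[_ROLE_INDEX[role]]]) for role in ROLES
    }
    return RoleAlignment(sequences=sequences, gene_name=params.gene_name)


def simulate_counts(
    params: SimParams, rng: np.random.Generator | None = None
) -> PatternCounts:
    """Simulate and tabulate in one step (vectorized fast path)."""
    states = simulate_states(params, rng=rng)
    return count_patterns_from_states(states, gene_name=params.gene_name)


def operating_characteristics(
    params_grid: Sequence[SimParams],
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the co-double test over a parameter grid.

    For each grid point, ``n_reps`` alignments are simulated, the
    exact one-sided test is run on the tabulated within/among counts,
    and the fraction of replicates with p <= alpha is reported, along
    with the mean within fraction.  Replicates with no double pattern
    at all are counted as non-rejections.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, params in enumerate(params_grid):
        rng = np.random.default_rng(ss.spawn(1)[0])
        rejections = 0
        within_fracs = []
        for _ in range(n_reps):
            counts = simulate_counts(params, rng=rng)
            w, a = counts.within_total, counts.among_total
            if w + a == 0:
                continue
            within_fracs.append(w / (w + a))
            if exact_tail_p(w, a) <= alpha:
                rejections += 1
        rows.append(
            {
                "point": i,
                "conv_prob_mean": float(np.mean([params.conv_prob[l] for l in LINEAGES])),
                "n_sites": params.n_sites,
                "n_reps": n_reps,
                "rejection_rate": rejections / n_reps,
                "mean_within_frac": float(np.mean(within_fracs)) if within_fracs else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def with_conversion(params: SimParams, prob: float, direction: str = "random") -> SimParams:
    """Copy of ``params`` with the same conversion setting in all lineages."""
    return replace(
        params,
        conv_prob={lin: prob for lin in LINEAGES},
        conv_direction={lin: direction for lin in LINEAGES},
    )
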