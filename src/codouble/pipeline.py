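"""End-to-end per-gene pipeline and machine-readable report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np

from . import alignment as aln_io
from . import autocorr, codon, conversion, patterns, topology

logger = logging.getLogger(__name__)


class TopologyNotPreradiative(RuntimeError):
    """Raised when the topology prerequisite fails and --force is off."""


def _version() -> str:
    try:
        return _pkg_version("codouble")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class GeneReport:
    """Aggregated per-gene results (JSON-serializable)."""

    gene: str
    n_gapless_sites: int
    pattern_counts: patterns.PatternCounts
    topology: topology.TopologyVerdict
    test: conversion.ConversionTestResult | None
    tstv: codon.ContingencyTable2x2
    syn_nonsyn: codon.ContingencyTable2x2 | None
    qq: autocorr.QQData | None
    newick: str
    seed: int
    version: str

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_gapless_sites": self.n_gapless_sites,
            "pattern_counts": self.pattern_counts.to_dict(),
            "topology": self.topology.to_dict(),
            "test": self.test.to_dict() if self.test else None,
            "tstv": self.tstv.to_dict(),
            "syn_nonsyn": self.syn_nonsyn.to_dict() if self.syn_nonsyn else None,
            "qq": self.qq.to_dict() if self.qq else None,
            "newick": self.newick,
            "seed": self.seed,
            "version": self.version,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def read_report(path) -> dict:
    """Read a report written by :meth:`GeneReport.to_json`."""
    with open(path) as fh:
        return json.load(fh)


def run_pipeline(
    fasta_path,
    rolemap_path,
    gene_name: str | None = None,
    cds_frame_offset: int = 0,
    n_draws: int = conversion.DEFAULT_N_DRAWS,
    seed: int = conversion.DEFAULT_SEED,
    force: bool = False,
    qq_target: str = "000011",
    qq_pool_complement: bool = True,
    run_codon_analysis: bool = True,
) -> GeneReport:
    """Run the full per-gene analysis.

    Steps: gap-free filtering, polarization, pattern classification and
    tabulation, topology prerequisite check, the co-double test,
    transition/transversion and synonymous/nonsynonymous tables, and
    the geometric Q-Q of the target pattern's spacing.  When the
    topology verdict is not ``preradiation`` the conversion p-value is
    withheld (the test's null hinges on the preradiation tree) unless
    ``force`` is set.

    Stochastic stages draw their seeds from one master ``seed`` via a
    spawned seed sequence, in a fixed order.
    """
    aln = aln_io.read_alignment(
        fasta_path, rolemap_path, gene_name=gene_name, cds_frame_offset=cds_frame_offset
    )
    gene = aln.gene_name
    cols = aln_io.gapless_columns(aln)
    polarized = [patterns.polarize(c) for c in cols]
    pats = [p for p in polarized if isinstance(p, patterns.BinarySitePattern)]
    counts = patterns.tabulate(pats, gene_name=gene, n_gapless_sites=len(cols))

    dm = topology.distance_matrix(aln, model="p_distance")
    newick = topology.neighbor_joining(dm)
    verdict = topology.preradiation_check(counts, newick)

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2)

    test = None
    if counts.within_total + counts.among_total >= 1:
        if verdict.verdict == "preradiation" or force:
            test = conversion.codouble_test(
                counts.within_total,
                counts.among_total,
                n_draws=n_draws,
                seed=seed,
                rng=np.random.default_rng(child[0]),
            )
        else:
            raise TopologyNotPreradiative(
                f"{gene}: topology not preradiative (verdict: {verdict.verdict}); "
                "use force=True to test anyway"
            )

    site_classes: dict[int, str] = {}
    site_variants: dict[int, tuple[str, str]] = {}
    for p in pats:
        cls_ = p.pattern_class
        if cls_.category == "within_double":
            site_classes[p.site_index] = "within"
        elif cls_.category == "among_double":
            site_classes[p.site_index] = "among"
        else:
            continue
        site_variants[p.site_index] = (p.variant0, p.variant1)

    tstv = codon.tstv_contingency(site_classes, site_variants)
    tstv.p_sim = codon.chisq_simulated(
        tstv, rng=np.random.default_rng(child[1])
    )
    tstv.n_sim = 10**5
    tstv.seed = seed

    syn_nonsyn = None
    if run_codon_analysis:
        syn_nonsyn = codon.codon_contingency(aln, site_classes)

    qq = None
    ranks = autocorr.target_site_ranks(
        pats, target=qq_target, pool_complement=qq_pool_complement
    )
    dists = autocorr.pattern_distances(ranks)
    if len(dists) >= 2:
        qq = autocorr.geometric_qq(dists)
    else:
        logger.warning("%s: too few %s occurrences for a Q-Q", gene, qq_target)

    return GeneReport(
        gene=gene,
        n_gapless_sites=len(cols),
        pattern_counts=counts,
        topology=verdict,
        test=test,
        tstv=tstv,
        syn_nonsyn=syn_nonsyn,
        qq=qq,
        newick=newick,
        seed=seed,
        version=_version(),
    )
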