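"""Base-call association matrices between ordered pairs of het sites.

The association matrix for an ordered site pair (upstream, downstream) is the
4x4 table of co-occurrence counts of base calls across linked fragments, in
the fixed base order A, C, G, T. The full 4x4 table is kept even though only
a 2x2 block is expected for a biallelic pair: the off-allele cells are what
the error decomposition measures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .readers import BASES, BASE_INDEX, HetSite, LinkedFragment

log = logging.getLogger("matephase")


class UsageError(Exception):
    """API misuse (bad site ordering, disconnected chain, ...)."""


@dataclass
class AssociationMatrix:
    """4x4 co-occurrence counts between an ordered pair of het sites.

    ``counts[i, j]`` is the number of fragments calling base ``BASES[i]`` at
    the upstream site and ``BASES[j]`` at the downstream site.
    """

    upstream: HetSite
    downstream: HetSite
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))
    #: sites skipped over when this matrix bridges a low-coverage junction
    bridged_over: tuple[HetSite, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise UsageError("association matrix counts must be 4x4")
        if (self.counts < 0).any():
            raise UsageError("association matrix counts must be non-negative")
        if self.upstream.pos >= self.downstream.pos:
            raise UsageError("upstream site must precede downstream site")

    @property
    def total(self) -> int:
        """Number of fragments observing both sites."""
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    def row(self, base: str) -> np.ndarray:
        """Downstream base-call counts for fragments carrying ``base`` upstream."""
        return self.counts[BASE_INDEX[base]]

    def cell(self, up_base: str, down_base: str) -> int:
        return int(self.counts[BASE_INDEX[up_base], BASE_INDEX[down_base]])

    @property
    def span(self) -> int:
        return self.downstream.pos - self.upstream.pos


def build_association_matrix(fragments: Iterable[LinkedFragment],
                             upstream: HetSite,
                             downstream: HetSite) -> AssociationMatrix:
    """Tally co-observed base calls between two het sites over fragments.

    Fragments missing an observation at either site contribute nothing.
    """
    if upstream.pos == downstream.pos:
        raise UsageError("cannot associate a site with itself")
    if upstream.pos > downstream.pos:
        raise UsageError("sites must be given in genomic order")
    counts = np.zeros((4, 4), dtype=np.int64)
    p1, p2 = upstream.pos, downstream.pos
    for frag in fragments:
        b1 = frag.observations.get(p1)
        if b1 is None:
            continue
        b2 = frag.observations.get(p2)
        if b2 is None:
            continue
        counts[BASE_INDEX[b1], BASE_INDEX[b2]] += 1
    return AssociationMatrix(upstream, downstream, counts)


def all_pairs_matrices(fragments: Sequence[LinkedFragment],
                       sites: Sequence[HetSite]) -> list[AssociationMatrix]:
    """One matrix per ordered site pair (i < j); empty matrices are retained."""
    if len(sites) < 2:
        raise UsageError("need at least two sites for pairwise association")
    ordered = sorted(sites, key=lambda s: s.pos)
    out = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            out.append(build_association_matrix(fragments, ordered[i], ordered[j]))
    return out


@dataclass
class ChainPlan:
    """Adjacent-pair matrices forming a phasing chain, plus gaps.

    ``matrices`` link consecutive anchor sites (each matrix's upstream site is
    the previous one's downstream site, within a segment). ``skipped`` holds
    sites bridged over because their adjacent junction fell below ``min_total``
    (to be phased later from their nearest anchored neighbor). ``breaks`` holds
    upstream sites of junctions where no bridge restored coverage: the chain
    restarts after each with a fresh phase set.
    """

    matrices: list[AssociationMatrix]
    skipped: list[HetSite]
    breaks: list[HetSite]

    @property
    def anchor_sites(self) -> list[HetSite]:
        sites: list[HetSite] = []
        for m in self.matrices:
            if not sites or sites[-1].pos != m.upstream.pos:
                sites.append(m.upstream)
            sites.append(m.downstream)
        return sites


def adjacent_pairs_matrices(fragments: Sequence[LinkedFragment],
                            sites: Sequence[HetSite],
                            min_total: int = 20) -> ChainPlan:
    """Build the chain A_1 = (h_0, h_1), A_2 = (h_1, h_2), ...

    If an adjacent pair's total falls below ``min_total``, the junction is
    bridged by skipping ahead to the next site whose matrix restores
    ``total >= min_total``; skipped sites are reported for neighbor-based
    phasing. If no bridge exists, a chain break is declared at that junction.
    """
    if len(sites) < 2:
        raise UsageError("need at least two sites to chain")
    ordered = sorted(sites, key=lambda s: s.pos)
    matrices: list[AssociationMatrix] = []
    skipped: list[HetSite] = []
    breaks: list[HetSite] = []

    i = 0
    while i < len(ordered) - 1:
        found = None
        for j in range(i + 1, len(ordered)):
            m = build_association_matrix(fragments, ordered[i], ordered[j])
            if m.total >= min_total:
                found = (j, m)
                break
        if found is None:
            breaks.append(ordered[i])
            log.warning("chain break after %s: no downstream pair reaches %d linked fragments",
                        ordered[i], min_total)
            i += 1
            continue
        j, m = found
        if j > i + 1:
            bridged = tuple(ordered[i + 1:j])
            m.bridged_over = bridged
            skipped.extend(bridged)
            log.info("bridging %d low-coverage site(s) between %s and %s",
                     len(bridged), ordered[i], ordered[j])
        matrices.append(m)
        i = j
    return ChainPlan(matrices, skipped, breaks)


def write_matrices_tsv(matrices: Sequence[AssociationMatrix], out_path: str) -> None:
    """Per-matrix TSV report: site pair, the 16 counts, total."""
    cols = [f"n_{a}{b}" for a in BASES for b in BASES]
    with open(out_path, "w") as fh:
        fh.write("up_pos\tup_label\tdown_pos\tdown_label\t" + "\t".join(cols) + "\ttotal\n")
        for m in matrices:
            cells = "\t".join(str(int(c)) for c in m.counts.ravel())
            fh.write(f"{m.upstream.pos}\t{m.upstream.label}\t{m.downstream.pos}\t"
                     f"{m.downstream.label}\t{cells}\t{m.total}\n")
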