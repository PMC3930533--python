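"""Diagnostics around the phasing statistics: linked coverage vs distance,
CI width vs coverage, and decomposition of linkage errors into recombinant
(chimeric) versus other (random) error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import UsageError
from .phasing import bootstrap_row
from .readers import HetSite, LinkedFragment

log = logging.getLogger("matephase")

ReadIntervals = tuple[tuple[int, int], tuple[int, int]]


@dataclass
class LinkedCoverageProfile:
    """Mean number of fragments linking x and x+delta, per delta."""

    deltas: np.ndarray
    mean_linked_coverage: np.ndarray
    region: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta": self.deltas,
                             "mean_linked_coverage": self.mean_linked_coverage})

    def write_tsv(self, out_path: str) -> None:
        df = self.to_frame()
        df["mean_linked_coverage"] = df["mean_linked_coverage"].map("{:.6g}".format)
        df.to_csv(out_path, sep="\t", index=False)


def linked_coverage_profile(read_intervals: Sequence[ReadIntervals],
                            region: tuple[int, int],
                            delta_min: int = 101,
                            delta_max: int = 3000) -> LinkedCoverageProfile:
    """Average linked coverage as a function of inter-position distance.

    For each delta, averages over positions x in ``region`` (1-based,
    inclusive) the number of fragments with one read covering x and a read
    covering x + delta. A single read covering both positions counts too
    (possible only for delta < read length).
    """
    if delta_min > delta_max:
        raise UsageError("delta_min must not exceed delta_max")
    lo, hi = region
    if lo > hi:
        raise UsageError("bad region bounds")
    deltas = np.arange(delta_min, delta_max + 1)
    n_pos = hi - lo + 1

    # Merge each fragment's (possibly overlapping) read spans into <= 2
    # disjoint intervals. The linked count for one fragment at distance d is
    # |U ∩ (U - d) ∩ [lo, hi]| where U is that disjoint union; the pieces
    # U_i ∩ (U_j - d) are pairwise disjoint, so their lengths just add.
    n = len(read_intervals)
    iv = np.zeros((n, 2, 2), dtype=np.int64)  # (frag, interval, lo/hi)
    for f, (r1, r2) in enumerate(read_intervals):
        (a1, a2), (b1, b2) = sorted((tuple(r1), tuple(r2)))
        if b1 <= a2 + 1:  # overlapping or adjacent reads: one interval
            iv[f, 0] = (a1, max(a2, b2))
            iv[f, 1] = (1, 0)  # empty sentinel
        else:
            iv[f, 0] = (a1, a2)
            iv[f, 1] = (b1, b2)

    counts = np.zeros(len(deltas), dtype=np.int64)
    for di, d in enumerate(deltas):
        total = 0
        for i in range(2):
            for j in range(2):
                x1 = np.maximum(np.maximum(iv[:, i, 0], iv[:, j, 0] - d), lo)
                x2 = np.minimum(np.minimum(iv[:, i, 1], iv[:, j, 1] - d), hi)
                total += int(np.maximum(x2 - x1 + 1, 0).sum())
        counts[di] = total
    return LinkedCoverageProfile(deltas, counts / n_pos, region)


def ci_width_vs_coverage(row_probs: Sequence[float] | np.ndarray,
                         coverage_grid: Sequence[int],
                         error_mass: float = 0.01,
                         n_iter: int = 1000,
                         replicates: int = 100,
                         seed: int | None = 0) -> pd.DataFrame:
    """Mean bootstrap CI width as a function of row coverage N.

    Per coverage N and replicate: draw multinomial(N, row_probs) counts, run
    the row bootstrap, and average the CI width over all four bases; the
    returned width is the further average over replicates.
    """
    p = np.asarray(row_probs, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise UsageError("row_probs must be 4 non-negative values summing to 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for N, child in zip(coverage_grid, ss.spawn(len(coverage_grid))):
        if N < 1:
            raise UsageError("coverage grid must be positive")
        rng = np.random.default_rng(child)
        widths = np.empty(replicates)
        for r in range(replicates):
            counts = rng.multinomial(N, p)
            res = bootstrap_row(counts, error_mass, n_iter, rng=rng)
            widths[r] = float(np.mean(res.ci_high - res.ci_low))
        rows.append((int(N), float(widths.mean()), float(widths.std(ddof=1))))
    return pd.DataFrame(rows, columns=["coverage", "mean_ci_width", "sd_ci_width"])


@dataclass
class ErrorDecomposition:
    """Classification of linked observation pairs against a known phase.

    concordant: both bases from one haplotype; recombinant: each base a valid
    allele but from different haplotypes (chimera signature); other: any base
    that is not a valid allele of its site.
    """

    per_pair: pd.DataFrame
    total: int
    concordant: int
    recombinant: int
    other: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {"concordant": 0.0, "recombinant": 0.0, "other": 0.0}
        return {"concordant": self.concordant / self.total,
                "recombinant": self.recombinant / self.total,
                "other": self.other / self.total}

    def write_tsv(self, out_path: str) -> None:
        df = self.per_pair.copy()
        pooled = pd.DataFrame([{
            "pos1": 0, "pos2": 0, "total": self.total,
            "concordant": self.concordant, "recombinant": self.recombinant,
            "other": self.other,
            **{f"frac_{k}": v for k, v in self.fractions.items()},
        }])
        pd.concat([df, pooled], ignore_index=True).to_csv(
            out_path, sep="\t", index=False, float_format="%.6g")


def decompose_errors(fragments: Sequence[LinkedFragment],
                     sites: Sequence[HetSite],
                     known_phase: Mapping[int, tuple[str, str]]) -> ErrorDecomposition:
    """Classify every linked observation pair given the known phase.

    ``known_phase`` maps position -> (hap1 base, hap2 base); every site must
    be phased. Fractions are symmetric under swapping the haplotype labels.
    """
    ordered = sorted(sites, key=lambda s: s.pos)
    for s in ordered:
        if s.pos not in known_phase:
            raise UsageError(f"known_phase missing site {s}")
        b1, b2 = known_phase[s.pos]
        if {b1, b2} != set(s.alleles):
            raise UsageError(f"known_phase at {s.pos} is not a het assignment")

    pair_counts: dict[tuple[int, int], np.ndarray] = {
        (a.pos, b.pos): np.zeros(3, dtype=np.int64)
        for a, b in combinations(ordered, 2)}
    hap1 = {p: known_phase[p][0] for p in known_phase}
    hap2 = {p: known_phase[p][1] for p in known_phase}
    alleles = {s.pos: set(s.alleles) for s in ordered}

    for frag in fragments:
        pos_seen = sorted(p for p in frag.observations if p in alleles)
        for p, q in combinations(pos_seen, 2):
            bp, bq = frag.observations[p], frag.observations[q]
            if bp not in alleles[p] or bq not in alleles[q]:
                cls = 2  # other: invalid allele
            elif ((bp == hap1[p] and bq == hap1[q])
                  or (bp == hap2[p] and bq == hap2[q])):
                cls = 0  # concordant
            else:
                cls = 1  # recombinant pattern
            pair_counts[(p, q)][cls] += 1

    rows = []
    for (p, q), c in pair_counts.items():
        tot = int(c.sum())
        fr = c / tot if tot else np.zeros(3)
        rows.append((p, q, tot, int(c[0]), int(c[1]), int(c[2]),
                     float(fr[0]), float(fr[1]), float(fr[2])))
    per_pair = pd.DataFrame(rows, columns=[
        "pos1", "pos2", "total", "concordant", "recombinant", "other",
        "frac_concordant", "frac_recombinant", "frac_other"])
    return ErrorDecomposition(
        per_pair,
        int(per_pair["total"].sum()),
        int(per_pair["concordant"].sum()),
        int(per_pair["recombinant"].sum()),
        int(per_pair["other"].sum()),
    )
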