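"""Synthetic diploid amplicon and PE+MP linked-read library simulator.

Emulates the library that drives read-backed phasing: a diploid amplicon
(default 10 kb) carrying K heterozygous SNVs with a known truth phase, a
mixed fragment library of short paired-end (PE, uniform 100-600 bp) and large
mate-pair (MP, 500-5000 bp, mean 2000 bp) fragments sequenced as 101 bp reads
from both fragment ends, fragment-level recombination chimeras (template
switch to the other haplotype at a uniform internal breakpoint, default rate
7%) and random base-call error at het sites (default 2% per call).

The MP size law is a truncated log-normal: sigma is fixed by reading the
stated 500-5000 bp range as the central 95% of the untruncated law
(sigma = ln 10 / (2 * 1.96)), and mu is solved so the truncated mean equals
the configured mean. A uniform law is available for analytic tests.

All randomness derives from one seed via named sub-streams (sequence, sizes,
starts, haplotype choice, chimeras, errors), so reruns are bit-identical and
single components can be varied reproducibly.
"""
from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import optimize, stats

from .readers import BASES, BASE_INDEX, HetSite, LinkedFragment

log = logging.getLogger("matephase")

_Z95 = 1.959963984540054


class ConfigError(Exception):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    ``het_sites`` is a tuple of (pos, ref, alt); ``hap1_bases`` gives the base
    carried by haplotype 1 at each site (haplotype 2 carries the other
    allele), defining the truth phase. ``coverage`` is the mean per-base read
    depth; ``n_fragments`` overrides the depth-derived fragment count when
    set (used to hit a target *linked* coverage, see
    :func:`fragments_for_linked_coverage`).
    """

    seed: int
    region_length: int = 10000
    chrom: str = "amplicon"
    het_sites: tuple[tuple[int, str, str], ...] = ()
    hap1_bases: tuple[str, ...] = ()
    coverage: float = 1000.0
    n_fragments: int | None = None
    pe_fraction: float = 0.2
    pe_size_range: tuple[int, int] = (100, 600)
    mp_size_range: tuple[int, int] = (500, 5000)
    mp_size_mean: float = 2000.0
    mp_size_law: Literal["lognormal", "uniform"] = "lognormal"
    read_length: int = 101
    recombination_rate: float = 0.07
    random_error_rate: float = 0.02

    def __post_init__(self) -> None:
        for name, r in (("recombination_rate", self.recombination_rate),
                        ("random_error_rate", self.random_error_rate),
                        ("pe_fraction", self.pe_fraction)):
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if self.region_length < 2 * self.read_length:
            raise ConfigError("region shorter than one read pair")
        if len(self.het_sites) != len(self.hap1_bases):
            raise ConfigError("hap1_bases must match het_sites in length")
        last = 0
        for (pos, ref, alt), h1 in zip(self.het_sites, self.hap1_bases):
            if not (1 <= pos <= self.region_length):
                raise ConfigError(f"het position {pos} outside region")
            if pos <= last:
                raise ConfigError("het positions must be strictly increasing")
            last = pos
            if ref == alt or ref not in BASE_INDEX or alt not in BASE_INDEX:
                raise ConfigError(f"bad alleles at {pos}: {ref}>{alt}")
            if h1 not in (ref, alt):
                raise ConfigError(f"hap1 base at {pos} must be ref or alt")
        if self.mp_size_range[0] > self.mp_size_range[1] or self.pe_size_range[0] > self.pe_size_range[1]:
            raise ConfigError("size ranges must be (lo, hi) with lo <= hi")
        for kind in ("pe", "mp"):
            lo, hi = self.effective_size_range(kind)
            if lo > hi:
                raise ConfigError(f"{kind} size range empty after clamping to "
                                  f"read length / region length")

    @property
    def sites(self) -> list[HetSite]:
        return [HetSite(self.chrom, pos, ref, alt, label=f"site{i + 1}")
                for i, (pos, ref, alt) in enumerate(self.het_sites)]

    @property
    def truth_phase(self) -> dict[int, tuple[str, str]]:
        """Position -> (hap1 base, hap2 base)."""
        out = {}
        for (pos, ref, alt), h1 in zip(self.het_sites, self.hap1_bases):
            out[pos] = (h1, alt if h1 == ref else ref)
        return out

    def fragment_count(self) -> int:
        if self.n_fragments is not None:
            return self.n_fragments
        return int(round(self.coverage * self.region_length / (2 * self.read_length)))

    def effective_size_range(self, kind: Literal["pe", "mp"]) -> tuple[int, int]:
        # a fragment cannot be shorter than one read nor longer than the amplicon
        lo, hi = self.pe_size_range if kind == "pe" else self.mp_size_range
        return max(lo, self.read_length), min(hi, self.region_length)


def evenly_spaced_sites(region_length: int, n_sites: int, seed: int,
                        margin: int = 200) -> tuple[tuple[tuple[int, str, str], ...],
                                                    tuple[str, ...]]:
    """Deterministically positioned het sites with seeded random alleles/phase."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if n_sites == 0:
        return (), ()
    pos = np.linspace(margin, region_length - margin, n_sites).round().astype(int)
    return _random_alleles(pos, rng)


def random_sites(region_length: int, n_sites: int, seed: int,
                 margin: int = 200, min_gap: int = 20
                 ) -> tuple[tuple[tuple[int, str, str], ...], tuple[str, ...]]:
    """Uniformly placed het sites (with a minimum gap), random alleles/phase."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if n_sites == 0:
        return (), ()
    lo, hi = margin, region_length - margin
    pos: list[int] = []
    while len(pos) < n_sites:
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - p) >= min_gap for p in pos):
            pos.append(cand)
    return _random_alleles(np.sort(np.array(pos)), rng)


def _random_alleles(positions: np.ndarray, rng: np.random.Generator
                    ) -> tuple[tuple[tuple[int, str, str], ...], tuple[str, ...]]:
    sites = []
    hap1 = []
    for p in positions:
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append((int(p), BASES[ref], BASES[alt]))
        hap1.append(BASES[ref] if rng.random() < 0.5 else BASES[alt])
    return tuple(sites), tuple(hap1)


# ---------------------------------------------------------------------------
# MP fragment-size law

@functools.lru_cache(maxsize=64)
def mp_lognormal_params(lo: int, hi: int, mean: float) -> tuple[float, float]:
    """(mu, sigma) of the truncated log-normal MP size law.

    sigma reads [lo, hi] as the central 95% of the untruncated law; mu is
    solved so the mean truncated to [lo, hi] equals ``mean``.
    """
    sigma = math.log(hi / lo) / (2 * _Z95)

    def trunc_mean(mu: float) -> float:
        a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        m = math.exp(mu + sigma**2 / 2)
        frac = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
        return m * frac / z

    mu = optimize.brentq(lambda m: trunc_mean(m) - mean,
                         math.log(lo), math.log(hi), xtol=1e-10)
    return mu, sigma


def _sample_mp_sizes(config: SimulationConfig, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.effective_size_range("mp")
    if config.mp_size_law == "uniform":
        return rng.integers(lo, hi + 1, size=n)
    mu, sigma = mp_lognormal_params(*config.mp_size_range, config.mp_size_mean)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    f_lo, f_hi = dist.cdf(lo), dist.cdf(hi)
    u = rng.random(n)
    sizes = dist.ppf(f_lo + u * (f_hi - f_lo))
    return np.clip(np.round(sizes).astype(np.int64), lo, hi)


def size_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discretized fragment-size law of the PE+MP mixture: (sizes, weights)."""
    pe_lo, pe_hi = config.effective_size_range("pe")
    mp_lo, mp_hi = config.effective_size_range("mp")
    smin, smax = min(pe_lo, mp_lo), max(pe_hi, mp_hi)
    sizes = np.arange(smin, smax + 1)
    w = np.zeros_like(sizes, dtype=float)
    pe_mask = (sizes >= pe_lo) & (sizes <= pe_hi)
    w[pe_mask] += config.pe_fraction / pe_mask.sum()
    if config.mp_size_law == "uniform":
        mp_mask = (sizes >= mp_lo) & (sizes <= mp_hi)
        w[mp_mask] += (1 - config.pe_fraction) / mp_mask.sum()
    else:
        mu, sigma = mp_lognormal_params(*config.mp_size_range, config.mp_size_mean)
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        edges = np.arange(mp_lo - 0.5, mp_hi + 1.5)
        pm = np.diff(dist.cdf(edges))
        pm /= pm.sum()
        mp_mask = (sizes >= mp_lo) & (sizes <= mp_hi)
        w[mp_mask] += (1 - config.pe_fraction) * pm
    return sizes, w


def expected_linked_fraction(config: SimulationConfig, p1: int, p2: int) -> float:
    """P(a random fragment's reads cover both ``p1`` and ``p2``).

    Integrates over the fragment-size law the fraction of uniform start
    positions for which each site lands in one of the two read windows.
    """
    if p1 > p2:
        p1, p2 = p2, p1
    rl, L = config.read_length, config.region_length
    sizes, w = size_pmf(config)
    total = 0.0
    for S, ws in zip(sizes, w):
        if ws == 0.0 or S > L:
            continue
        n_starts = L - S + 1
        # start positions s for which site p is covered by read1 or read2
        def cov(p: int) -> list[tuple[int, int]]:
            return [(p - rl + 1, p), (p - S + 1, p - S + rl)]
        good = _intersect_unions(cov(p1), cov(p2), 1, L - S + 1)
        if good:
            total += ws * good / n_starts
    return total


def _intersect_unions(a: list[tuple[int, int]], b: list[tuple[int, int]],
                      lo: int, hi: int) -> int:
    """Integer measure of (U a) ∩ (U b) ∩ [lo, hi] for short interval lists."""
    pieces: list[tuple[int, int]] = []
    for a1, a2 in a:
        for b1, b2 in b:
            x1, x2 = max(a1, b1, lo), min(a2, b2, hi)
            if x1 <= x2:
                pieces.append((x1, x2))
    if not pieces:
        return 0
    pieces.sort()
    count = 0
    cur1, cur2 = pieces[0]
    for x1, x2 in pieces[1:]:
        if x1 > cur2 + 1:
            count += cur2 - cur1 + 1
            cur1, cur2 = x1, x2
        else:
            cur2 = max(cur2, x2)
    count += cur2 - cur1 + 1
    return count


def fragments_for_linked_coverage(config: SimulationConfig, p1: int, p2: int,
                                  target: float) -> int:
    """Fragment count giving expected linked coverage ``target`` at (p1, p2)."""
    frac = expected_linked_fraction(config, p1, p2)
    if frac <= 0:
        raise ConfigError(f"no fragment size can link {p1} and {p2}")
    return int(math.ceil(target / frac))


# ---------------------------------------------------------------------------
# Reference and fragments

@dataclass
class DiploidReference:
    """Two haplotype sequences over a common random background."""

    config: SimulationConfig
    reference: str   # background with REF alleles at het sites
    hap1: str
    hap2: str


def make_diploid_reference(config: SimulationConfig) -> DiploidReference:
    """Random background sequence; haplotypes differ exactly at the het sites."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    codes = rng.integers(0, 4, size=config.region_length, dtype=np.int8)
    ref = codes.copy()
    h1 = codes.copy()
    h2 = codes.copy()
    for (pos, r, a), (b1, b2) in zip(config.het_sites, config.truth_phase.values()):
        ref[pos - 1] = BASE_INDEX[r]
        h1[pos - 1] = BASE_INDEX[b1]
        h2[pos - 1] = BASE_INDEX[b2]
    lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    decode = lambda arr: lut[arr].tobytes().decode()
    return DiploidReference(config, decode(ref), decode(h1), decode(h2))


@dataclass
class FragmentSet:
    """Vectorized record of all simulated fragments plus their truth."""

    config: SimulationConfig
    start: np.ndarray        # 1-based fragment start
    size: np.ndarray
    is_pe: np.ndarray
    hap: np.ndarray          # source haplotype at the fragment start (0/1)
    is_chimera: np.ndarray
    breakpoint: np.ndarray   # first position on the switched haplotype; -1 if none
    obs: np.ndarray          # (n, K) int8 emitted base codes at sites; -1 = not covered
    error: np.ndarray        # (n, K) bool: emitted base differs from source base

    @property
    def n(self) -> int:
        return len(self.start)

    @property
    def site_positions(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.config.het_sites])

    def fragment_ids(self) -> list[str]:
        return [f"frag{i:08d}" for i in range(self.n)]

    def covered_mask(self) -> np.ndarray:
        return self.obs >= 0

    def linked_mask(self, p1: int, p2: int) -> np.ndarray:
        """Fragments observing both sites."""
        pos = list(self.site_positions)
        i, j = pos.index(p1), pos.index(p2)
        return (self.obs[:, i] >= 0) & (self.obs[:, j] >= 0)

    def chimera_spanning_mask(self, p1: int, p2: int) -> np.ndarray:
        """Linked fragments whose chimeric breakpoint falls between the sites."""
        if p1 > p2:
            p1, p2 = p2, p1
        return (self.linked_mask(p1, p2) & self.is_chimera
                & (self.breakpoint > p1) & (self.breakpoint <= p2))

    def to_linked_fragments(self, min_observations: int = 1) -> list[LinkedFragment]:
        """Materialize per-fragment observation maps (the extractor's output)."""
        pos = self.site_positions
        covered = self.obs >= 0
        keep = np.flatnonzero(covered.sum(axis=1) >= min_observations)
        out = []
        for i in keep:
            obs = {int(pos[k]): BASES[self.obs[i, k]]
                   for k in np.flatnonzero(covered[i])}
            out.append(LinkedFragment(f"frag{i:08d}", obs))
        return out

    def read_intervals(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """1-based inclusive aligned spans of (read1, read2) per fragment."""
        rl = self.config.read_length
        end = self.start + self.size - 1
        return [((int(s), int(s + rl - 1)), (int(e - rl + 1), int(e)))
                for s, e in zip(self.start, end)]

    def truth_table(self) -> pd.DataFrame:
        """Long-format truth: one row per fragment-site observation."""
        pos = self.site_positions
        ids = self.fragment_ids()
        rows = []
        covered = self.obs >= 0
        for i in range(self.n):
            for k in np.flatnonzero(covered[i]):
                rows.append((ids[i], int(self.hap[i]) + 1, bool(self.is_chimera[i]),
                             int(self.breakpoint[i]), int(pos[k]),
                             BASES[self.obs[i, k]], bool(self.error[i, k])))
        return pd.DataFrame(rows, columns=["fragment_id", "haplotype", "chimera",
                                           "breakpoint", "pos", "emitted_base",
                                           "error"])


def simulate_fragments(config: SimulationConfig) -> FragmentSet:
    """Draw the fragment library and the per-fragment het-site base calls."""
    n = config.fragment_count()
    L, rl = config.region_length, config.read_length
    streams = [np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(k,)))
               for k in range(1, 7)]
    rng_type, rng_size, rng_start, rng_hap, rng_chim, rng_err = streams

    is_pe = rng_type.random(n) < config.pe_fraction
    sizes = np.empty(n, dtype=np.int64)
    pe_lo, pe_hi = config.effective_size_range("pe")
    sizes[is_pe] = rng_size.integers(pe_lo, pe_hi + 1, size=int(is_pe.sum()))
    sizes[~is_pe] = _sample_mp_sizes(config, int((~is_pe).sum()), rng_size)

    starts = 1 + (rng_start.random(n) * (L - sizes + 1)).astype(np.int64)
    hap = rng_hap.integers(0, 2, size=n, dtype=np.int8)
    is_chim = rng_chim.random(n) < config.recombination_rate
    offset = np.where(sizes > 1,
                      1 + (rng_chim.random(n) * (sizes - 1)).astype(np.int64), 1)
    bkpt = np.where(is_chim, starts + offset, -1)

    K = len(config.het_sites)
    obs = np.full((n, K), -1, dtype=np.int8)
    err = np.zeros((n, K), dtype=bool)
    if K:
        ends = starts + sizes - 1
        site_pos = np.array([p for p, _, _ in config.het_sites])
        h1 = np.array([BASE_INDEX[b] for b in config.hap1_bases], dtype=np.int8)
        truth = config.truth_phase
        h2 = np.array([BASE_INDEX[truth[p][1]] for p, _, _ in config.het_sites],
                      dtype=np.int8)
        for k, p in enumerate(site_pos):
            covered = (((starts <= p) & (p <= starts + rl - 1))
                       | ((ends - rl + 1 <= p) & (p <= ends)))
            idx = np.flatnonzero(covered)
            if idx.size == 0:
                continue
            src = hap[idx].copy()
            flip = is_chim[idx] & (bkpt[idx] <= p) & (bkpt[idx] > 0)
            src[flip] = 1 - src[flip]
            base = np.where(src == 0, h1[k], h2[k]).astype(np.int8)
            e = rng_err.random(idx.size) < config.random_error_rate
            if e.any():
                shift = rng_err.integers(1, 4, size=int(e.sum()))
                base[e] = (base[e] + shift) % 4
            obs[idx, k] = base
            err[idx, k] = e
    fs = FragmentSet(config, starts, sizes, is_pe, hap, is_chim, bkpt, obs, err)
    if K >= 2:
        pos = fs.site_positions
        worst = min(int(fs.linked_mask(int(pos[i]), int(pos[i + 1])).sum())
                    for i in range(K - 1))
        if worst == 0:
            log.warning("an adjacent het pair has zero linked fragments "
                        "(coverage too low or sites too far apart)")
    return fs


# ---------------------------------------------------------------------------
# Writers

def write_fasta(ref: DiploidReference, out_path: str) -> None:
    with open(out_path, "w") as fh:
        fh.write(f">{ref.config.chrom}\n")
        seq = ref.reference
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")


def write_sam(fragments: FragmentSet, ref: DiploidReference, out_path: str) -> None:
    """Emit the library as coordinate-sorted SAM (101M reads from both ends)."""
    cfg = fragments.config
    rl = cfg.read_length
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": cfg.region_length}],
        "PG": [{"ID": "matephase-simulate", "PN": "matephase"}],
    })
    haps = [np.frombuffer(ref.hap1.encode(), dtype=np.uint8),
            np.frombuffer(ref.hap2.encode(), dtype=np.uint8)]
    site_pos = fragments.site_positions
    qual = pysam.qualitystring_to_array("F" * rl)

    records: list[tuple[int, int, pysam.AlignedSegment]] = []
    ids = fragments.fragment_ids()
    for i in range(fragments.n):
        s = int(fragments.start[i])
        size = int(fragments.size[i])
        h = int(fragments.hap[i])
        if fragments.is_chimera[i]:
            b = int(fragments.breakpoint[i])
            seq = np.concatenate([haps[h][s - 1:b - 1], haps[1 - h][b - 1:s + size - 1]])
        else:
            seq = haps[h][s - 1:s + size - 1].copy()
        for k in np.flatnonzero(fragments.obs[i] >= 0):
            seq[int(site_pos[k]) - s] = ord(BASES[fragments.obs[i, k]])
        r1 = seq[:rl].tobytes().decode()
        r2 = seq[size - rl:].tobytes().decode()
        pos1, pos2 = s, s + size - rl
        for mate, (pos, other, sq, flag) in enumerate((
                (pos1, pos2, r1, 0x1 | 0x2 | 0x20 | 0x40),
                (pos2, pos1, r2, 0x1 | 0x2 | 0x10 | 0x80))):
            a = pysam.AlignedSegment(header)
            a.query_name = ids[i]
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.next_reference_id = 0
            a.next_reference_start = other - 1
            a.template_length = size if mate == 0 else -size
            a.query_sequence = sq
            a.query_qualities = qual
            records.append((pos, mate, a))
    records.sort(key=lambda t: (t[0], t[1]))
    with pysam.AlignmentFile(str(out_path), "wh", header=header) as out:
        for _, _, a in records:
            out.write(a)


def write_truth_vcf(config: SimulationConfig, out_path: str,
                    sample_name: str = "SIM") -> None:
    """Het-site VCF (unphased 0/1 genotypes) consumed by the phasing pipeline."""
    header = pysam.VariantHeader()
    header.add_meta("source", value="matephase-simulate")
    header.contigs.add(config.chrom, length=config.region_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_name)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for i, (pos, ref, alt) in enumerate(config.het_sites):
            rec = out.new_record(contig=config.chrom, start=pos - 1,
                                 alleles=(ref, alt), id=f"site{i + 1}")
            rec.samples[sample_name]["GT"] = (0, 1)
            rec.samples[sample_name].phased = False
            out.write(rec)


def write_truth_phase_tsv(config: SimulationConfig, out_path: str) -> None:
    with open(out_path, "w") as fh:
        fh.write("pos\tref\talt\thap1\thap2\n")
        for (pos, ref, alt), (b1, b2) in zip(config.het_sites,
                                             config.truth_phase.values()):
            fh.write(f"{pos}\t{ref}\t{alt}\t{b1}\t{b2}\n")


def read_truth_phase_tsv(path: str) -> dict[int, tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return {int(r.pos): (str(r.hap1), str(r.hap2)) for r in df.itertuples()}


def write_truth_fragments_tsv(fragments: FragmentSet, out_path: str) -> None:
    fragments.truth_table().to_csv(out_path, sep="\t", index=False)
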