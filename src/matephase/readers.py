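"""Input/output for read-backed phasing.

Reads biallelic heterozygous SNVs from VCF, extracts per-fragment base-call
observations at those sites from aligned paired reads (SAM/BAM), and writes
phased VCF (GT + PS) and TSV reports.

Coordinates are 1-based inclusive everywhere user-facing (VCF convention);
pysam's 0-based internals never leak out of this module.
"""
from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

log = logging.getLogger("matephase")

#: Fixed base order used for all 4x4 association matrices.
BASES: tuple[str, str, str, str] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}


class InputError(Exception):
    """Unreadable or malformed input (bad VCF/SAM, missing region)."""


class ConsistencyError(Exception):
    """Internal contradiction, e.g. a site phased to a non-allele base."""


@dataclass(frozen=True)
class HetSite:
    """One biallelic heterozygous SNV position.

    Parameters
    ----------
    chrom : contig name.
    pos : 1-based genomic coordinate.
    ref : reference base, one of A/C/G/T.
    alt : alternate base, one of A/C/G/T, distinct from ``ref``.
    label : free-text display name, e.g. ``"c.60G>A"``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for b in (self.ref, self.alt):
            if b not in BASE_INDEX:
                raise ValueError(f"base must be one of {BASES}, got {b!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt base must differ (biallelic SNV)")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref, self.alt)

    def other_allele(self, base: str) -> str:
        """The allele opposite to ``base`` (which must be ref or alt)."""
        if base == self.ref:
            return self.alt
        if base == self.alt:
            return self.ref
        raise ConsistencyError(f"{base!r} is not an allele of {self}")

    def __str__(self) -> str:  # pragma: no cover - display helper
        name = self.label or f"{self.chrom}:{self.pos}"
        return f"{name}[{self.ref}>{self.alt}]"


@dataclass
class LinkedFragment:
    """Base-call observations of one sequenced fragment at het sites.

    ``observations`` maps 1-based site position to a single base call; a
    fragment whose two reads disagreed at a site carries no call there.
    """

    fragment_id: str
    observations: dict[int, str]

    def base_at(self, pos: int) -> str | None:
        return self.observations.get(pos)

    def covers(self, *positions: int) -> bool:
        return all(p in self.observations for p in positions)


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive)."""
    m = _REGION_RE.match(region)
    if not m:
        raise InputError(f"cannot parse region {region!r}")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    if start is None:
        return chrom, None, None
    lo, hi = int(start), int(end)
    if lo < 1 or hi < lo:
        raise InputError(f"bad region bounds in {region!r}")
    return chrom, lo, hi


def _is_het(gt: tuple | None) -> bool:
    if gt is None:
        return False
    alleles = [a for a in gt if a is not None]
    return sorted(set(alleles)) == [0, 1]


def read_het_sites(vcf_path: str, region: str | None = None,
                   sample: str | None = None) -> list[HetSite]:
    """Read heterozygous biallelic SNVs from a VCF.

    Multi-allelic records, indels/MNVs and non-heterozygous genotypes are
    skipped (with a logged tally). Returns sites sorted by position.
    An empty list is a valid result (nothing to phase), not an error.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {vcf_path}: {exc}") from exc

    chrom = lo = hi = None
    if region is not None:
        chrom, lo, hi = parse_region(region)

    samples = list(vf.header.samples)
    if not samples:
        raise InputError(f"VCF {vcf_path} has no sample column; genotypes required")
    sample = sample or samples[0]
    if sample not in samples:
        raise InputError(f"sample {sample!r} not in VCF {vcf_path}")

    sites: list[HetSite] = []
    skipped = {"multiallelic": 0, "not_snv": 0, "not_het": 0, "off_region": 0}
    for rec in vf:
        if chrom is not None and rec.chrom != chrom:
            skipped["off_region"] += 1
            continue
        if lo is not None and not (lo <= rec.pos <= hi):
            skipped["off_region"] += 1
            continue
        alts = rec.alts or ()
        if len(alts) != 1:
            skipped["multiallelic"] += 1
            continue
        ref, alt = rec.ref.upper(), alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASE_INDEX or alt not in BASE_INDEX:
            skipped["not_snv"] += 1
            continue
        if not _is_het(rec.samples[sample].get("GT")):
            skipped["not_het"] += 1
            continue
        label = rec.id or ""
        sites.append(HetSite(rec.chrom, rec.pos, ref, alt, label))
    vf.close()

    sites.sort(key=lambda s: s.pos)
    dropped = {k: v for k, v in skipped.items() if v}
    if dropped:
        log.info("read_het_sites: kept %d sites, skipped %s", len(sites), dropped)
    if not sites:
        log.warning("read_het_sites: no heterozygous SNVs found")
    return sites


def extract_linked_fragments(alignment_path: str, sites: Sequence[HetSite],
                             min_base_quality: int = 20,
                             min_mapping_quality: int = 20) -> list[LinkedFragment]:
    """Collect per-fragment base calls at het sites from aligned paired reads.

    A fragment is identified by read name (QNAME); both mates contribute.
    Secondary, supplementary and duplicate-flagged alignments are ignored.
    If both reads of a pair cover the same site and agree, one call is
    recorded; if they disagree, that site's call is dropped for the fragment.
    Only calls in A/C/G/T passing the quality floors are kept; fragments with
    zero observations are omitted.
    """
    if not sites:
        raise InputError("extract_linked_fragments requires a non-empty site list")
    chrom = sites[0].chrom
    site_pos = {s.pos for s in sites}
    lo, hi = min(site_pos), max(site_pos)

    try:
        af = pysam.AlignmentFile(str(alignment_path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read alignments {alignment_path}: {exc}") from exc

    # qname -> pos -> set of agreeing/conflicting bases seen
    calls: dict[str, dict[int, set[str]]] = defaultdict(dict)
    n_unmapped_mates = 0
    with af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.reference_name != chrom:
                continue
            if (read.mapping_quality or 0) < min_mapping_quality:
                continue
            if read.is_paired and read.mate_is_unmapped:
                n_unmapped_mates += 1
            # cheap reject: read interval cannot touch any site
            if read.reference_end is None or read.reference_end < lo or read.reference_start + 1 > hi:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                if pos1 not in site_pos:
                    continue
                base = seq[qpos].upper()
                if base not in BASE_INDEX:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                calls[read.query_name].setdefault(pos1, set()).add(base)

    if n_unmapped_mates:
        log.info("extract_linked_fragments: %d reads had unmapped mates", n_unmapped_mates)

    fragments: list[LinkedFragment] = []
    n_discordant = 0
    for qname, per_pos in calls.items():
        obs: dict[int, str] = {}
        for pos, bases in per_pos.items():
            if len(bases) == 1:
                obs[pos] = next(iter(bases))
            else:
                n_discordant += 1  # intra-fragment disagreement: drop the call
        if obs:
            fragments.append(LinkedFragment(qname, obs))
    if n_discordant:
        log.info("extract_linked_fragments: dropped %d discordant site calls", n_discordant)
    log.info("extract_linked_fragments: %d fragments with >=1 observation", len(fragments))
    return fragments


@dataclass(frozen=True)
class PhasedCall:
    """Phased genotype of one site: haplotype-1 base, haplotype-2 base, phase set."""

    hap1: str
    hap2: str
    phase_set: int


def write_phased_vcf(sites: Sequence[HetSite],
                     assignments: Mapping[int, PhasedCall],
                     out_path: str,
                     sample_name: str = "SAMPLE",
                     contig_length: int | None = None) -> None:
    """Write a phased VCF with GT and PS FORMAT fields.

    Sites present in ``assignments`` are written phased (``0|1`` / ``1|0``)
    with PS equal to the first position of their phase-set segment; the
    remaining sites are written unphased (``0/1``).
    """
    if not sites:
        raise InputError("write_phased_vcf requires at least one site")
    chrom = sites[0].chrom
    header = pysam.VariantHeader()
    header.add_meta("source", value="matephase")
    length = contig_length or max(s.pos for s in sites) + 1000
    header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.add_sample(sample_name)

    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: s.pos):
            rec = out.new_record(contig=chrom, start=site.pos - 1,
                                 alleles=(site.ref, site.alt), id=site.label or None)
            call = assignments.get(site.pos)
            fmt = rec.samples[sample_name]
            if call is None:
                fmt["GT"] = (0, 1)
                fmt.phased = False
            else:
                idx = {}
                for hap, base in (("hap1", call.hap1), ("hap2", call.hap2)):
                    if base == site.ref:
                        idx[hap] = 0
                    elif base == site.alt:
                        idx[hap] = 1
                    else:
                        raise ConsistencyError(
                            f"site {site} phased to non-allele base {base!r}")
                if idx["hap1"] == idx["hap2"]:
                    raise ConsistencyError(f"site {site} phased homozygous")
                fmt["GT"] = (idx["hap1"], idx["hap2"])
                fmt.phased = True
                fmt["PS"] = call.phase_set
            out.write(rec)


def write_fragment_tsv(fragments: Iterable[LinkedFragment], out_path: str) -> None:
    """Debug dump of per-fragment observations: fragment_id, pos, base."""
    with open(out_path, "w") as fh:
        fh.write("fragment_id\tpos\tbase\n")
        for frag in fragments:
            for pos in sorted(frag.observations):
                fh.write(f"{frag.fragment_id}\t{pos}\t{frag.observations[pos]}\n")
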