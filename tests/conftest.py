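"""Shared fixtures: tiny hand-written VCF/SAM files and reusable simulations.

All fixtures are generated programmatically at test time; nothing is stored.
"""
from __future__ import annotations

import textwrap

import numpy as np
import pytest

import matephase as mp


@pytest.fixture
def toy_vcf(tmp_path):
    """Five records: three het SNVs, one indel, one hom-ref SNV."""
    text = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=10000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
        chr1\t100\tc.60G>A\tG\tA\t.\tPASS\t.\tGT\t0/1
        chr1\t800\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1
        chr1\t2100\tIVS2-13A>G\tA\tG\t.\tPASS\t.\tGT\t1|0
        chr1\t3000\t.\tC\tT\t.\tPASS\t.\tGT\t0/0
        chr1\t5000\t.\tT\tC\t.\tPASS\t.\tGT\t0/1
        """)
    path = tmp_path / "sites.vcf"
    path.write_text(text)
    return str(path)


def make_sam(path, reads, chrom="chr1", length=10000):
    """Write a minimal SAM; ``reads`` are (qname, flag, pos, seq, qual_char)."""
    lines = [f"@HD\tVN:1.6\tSO:coordinate",
             f"@SQ\tSN:{chrom}\tLN:{length}"]
    for qname, flag, pos, seq, qc in sorted(reads, key=lambda r: r[2]):
        cigar = f"{len(seq)}M"
        lines.append(f"{qname}\t{flag}\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0"
                     f"\t{seq}\t{qc * len(seq)}")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def sam_factory(tmp_path):
    def factory(reads, name="reads.sam", **kw):
        return make_sam(tmp_path / name, reads, **kw)
    return factory


def pair_config(seed=101, delta=2000, region=2500, linked=500,
                recomb=0.07, error=0.02, hap1=("G", "A")):
    """Two het sites ``delta`` apart, library sized for the target linked
    coverage. ``hap1=("G", "A")`` is cis truth; ``("G", "G")`` is trans."""
    p1 = (region - delta) // 2
    p2 = p1 + delta
    sites = ((p1, "G", "A"), (p2, "A", "G"))
    base = mp.SimulationConfig(seed=seed, region_length=region, het_sites=sites,
                               hap1_bases=hap1, recombination_rate=recomb,
                               random_error_rate=error)
    n = mp.fragments_for_linked_coverage(base, p1, p2, linked)
    return mp.SimulationConfig(seed=seed, region_length=region, het_sites=sites,
                               hap1_bases=hap1, recombination_rate=recomb,
                               random_error_rate=error, n_fragments=n)


@pytest.fixture(scope="session")
def clean_pair():
    """Error-free two-site library plus its fragments (session-cached)."""
    cfg = pair_config(seed=301, linked=300, recomb=0.0, error=0.0)
    fs = mp.simulate_fragments(cfg)
    return cfg, fs


@pytest.fixture(scope="session")
def noisy_pair():
    """Two-site library at the default chimera/error rates (session-cached)."""
    cfg = pair_config(seed=302, linked=400)
    fs = mp.simulate_fragments(cfg)
    return cfg, fs


def chain_config(seed=207, n_sites=12, region=10000, linked=1000):
    """Evenly spaced het sites with a library hitting the target linked
    coverage at the least-covered adjacent pair."""
    sites, hap1 = mp.evenly_spaced_sites(region, n_sites, seed=seed)
    base = mp.SimulationConfig(seed=seed, region_length=region,
                               het_sites=sites, hap1_bases=hap1)
    frac = min(mp.expected_linked_fraction(base, sites[i][0], sites[i + 1][0])
               for i in range(n_sites - 1))
    n = int(np.ceil(linked / frac))
    return mp.SimulationConfig(seed=seed, region_length=region, het_sites=sites,
                               hap1_bases=hap1, n_fragments=n)


@pytest.fixture(scope="session")
def chained_region():
    """12-site 10 kb library with its linked fragments (session-cached)."""
    cfg = chain_config()
    fs = mp.simulate_fragments(cfg)
    frags = fs.to_linked_fragments(min_observations=2)
    return cfg, fs, frags
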