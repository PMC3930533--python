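"""Statistical core: row-wise multinomial bootstrap, cis/trans calls, and
Markov-chain haplotype extension with cumulative confidence.

Model
-----
For one upstream allele (a row of an association matrix), the observed
downstream base-call counts ``c`` (row total ``n``) are converted to adjusted
probabilities

    p_b = (1 - eps) * c_b / n + eps / 4

where ``eps`` (default 0.01) is an injected uniform error mass modelling
random sequencing error. ``n_iter`` multinomial resamples of size ``n`` are
drawn from ``p``; per-base confidence intervals are the 1st and 99th
nearest-rank percentiles of the resampled proportions (reported as "99% CI",
the literal percentile rule; see docs/methods.md for the nominal-coverage
caveat).

Chaining follows a Markov model: at each step the row of the previously
selected base is bootstrapped, the highest-probability downstream base is
selected, and a cumulative probability (running product of step
probabilities) and cumulative CI (percentiles of the per-iteration product of
bootstrap draws, iterations paired by index across independently resampled
matrices) relate each site back to the chain start. A step is confident while
its cumulative CI lower bound stays above the CI upper bound of every
rejected base at that step.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .association import AssociationMatrix, ChainPlan, UsageError
from .readers import BASES, BASE_INDEX, HetSite, LinkedFragment, PhasedCall

log = logging.getLogger("matephase")

DEFAULT_ERROR_MASS = 0.01
DEFAULT_N_ITER = 1000
CI_LOW_PCT = 0.01
CI_HIGH_PCT = 0.99

StartRule = Literal["ref", "alt", "lexicographic"]


class ZeroCoverageError(Exception):
    """A required matrix row has zero linked observations."""


def nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest of ``sorted_values``."""
    n = len(sorted_values)
    k = max(int(math.ceil(q * n)), 1)
    return float(sorted_values[k - 1])


@dataclass
class RowBootstrapResult:
    """Bootstrap of one association-matrix row (one upstream base)."""

    upstream_base: str
    probs: np.ndarray          # adjusted probabilities, one per downstream base
    ci_low: np.ndarray         # 1st nearest-rank percentile per base
    ci_high: np.ndarray        # 99th nearest-rank percentile per base
    n_row: int
    n_iter: int
    error_mass: float
    draws: np.ndarray = field(repr=False)  # (n_iter, 4) resampled proportions

    def selected(self) -> tuple[str, bool]:
        """Argmax downstream base and whether the argmax was tied.

        Ties break to the lowest base in the fixed order A < C < G < T.
        """
        idx = int(np.argmax(self.probs))
        tie = bool(np.sum(self.probs == self.probs[idx]) > 1)
        return BASES[idx], tie

    def rejected_ci_high(self, selected_base: str) -> float:
        """Largest CI upper bound among the non-selected bases."""
        sel = BASE_INDEX[selected_base]
        return float(max(self.ci_high[b] for b in range(4) if b != sel))


def bootstrap_row(row_counts: Sequence[int] | np.ndarray,
                  error_mass: float = DEFAULT_ERROR_MASS,
                  n_iter: int = DEFAULT_N_ITER,
                  rng: np.random.Generator | None = None,
                  seed: int | None = None,
                  upstream_base: str = "") -> RowBootstrapResult:
    """Multinomial bootstrap of one matrix row with injected error mass.

    Raises
    ------
    ZeroCoverageError
        If the row total is zero (the caller must treat this as a chain
        break, not as an interval).
    """
    counts = np.asarray(row_counts, dtype=np.int64)
    if counts.shape != (4,):
        raise UsageError("row_counts must have length 4")
    if not (0.0 <= error_mass < 1.0):
        raise UsageError("error_mass must be in [0, 1)")
    if n_iter < 1:
        raise UsageError("n_iter must be positive")
    n = int(counts.sum())
    if n == 0:
        raise ZeroCoverageError("zero linked observations in row")
    if rng is None:
        rng = np.random.default_rng(seed)

    probs = (1.0 - error_mass) * counts / n + error_mass / 4.0
    draws = rng.multinomial(n, probs, size=n_iter) / n
    draws_sorted = np.sort(draws, axis=0)
    k_low = max(int(math.ceil(CI_LOW_PCT * n_iter)), 1) - 1
    k_high = max(int(math.ceil(CI_HIGH_PCT * n_iter)), 1) - 1
    return RowBootstrapResult(
        upstream_base=upstream_base,
        probs=probs,
        ci_low=draws_sorted[k_low].copy(),
        ci_high=draws_sorted[k_high].copy(),
        n_row=n,
        n_iter=n_iter,
        error_mass=error_mass,
        draws=draws,
    )


PhaseCall = Literal["cis", "trans", "ambiguous"]


@dataclass
class PairPhase:
    """Result of phasing a single pair of het sites."""

    matrix: AssociationMatrix
    ref_row: RowBootstrapResult      # row of the upstream REF allele
    alt_row: RowBootstrapResult      # row of the upstream ALT allele
    ref_selected: str
    alt_selected: str
    call: PhaseCall
    confident: bool                  # both rows pass the CI-separation test

    @property
    def step_probabilities(self) -> tuple[float, float]:
        return (float(self.ref_row.probs[BASE_INDEX[self.ref_selected]]),
                float(self.alt_row.probs[BASE_INDEX[self.alt_selected]]))


def _row_confident(row: RowBootstrapResult, selected: str) -> bool:
    sel = BASE_INDEX[selected]
    return float(row.ci_low[sel]) > row.rejected_ci_high(selected)


def phase_pair(matrix: AssociationMatrix,
               error_mass: float = DEFAULT_ERROR_MASS,
               n_iter: int = DEFAULT_N_ITER,
               seed: int | None = 0) -> PairPhase:
    """Call the cis/trans configuration of one site pair.

    Both upstream allele rows are bootstrapped independently. The call is
    ``cis`` if ref selects ref and alt selects alt downstream, ``trans`` if
    ref selects alt and alt selects ref, and ``ambiguous`` if the two rows
    select the same base, a selection ties, a selected base is not a
    downstream allele, or any selected base's CI lower bound fails to exceed
    every rejected base's CI upper bound in its row.
    """
    up, down = matrix.upstream, matrix.downstream
    ss = np.random.SeedSequence(seed)
    rng_ref, rng_alt = (np.random.default_rng(c) for c in ss.spawn(2))
    try:
        ref_row = bootstrap_row(matrix.row(up.ref), error_mass, n_iter,
                                rng=rng_ref, upstream_base=up.ref)
        alt_row = bootstrap_row(matrix.row(up.alt), error_mass, n_iter,
                                rng=rng_alt, upstream_base=up.alt)
    except ZeroCoverageError as exc:
        raise ZeroCoverageError(
            f"pair {up} / {down} unphaseable: {exc}") from exc

    ref_sel, ref_tie = ref_row.selected()
    alt_sel, alt_tie = alt_row.selected()
    confident = (not ref_tie and not alt_tie
                 and _row_confident(ref_row, ref_sel)
                 and _row_confident(alt_row, alt_sel))

    call: PhaseCall = "ambiguous"
    if ref_sel != alt_sel and confident:
        if ref_sel == down.ref and alt_sel == down.alt:
            call = "cis"
        elif ref_sel == down.alt and alt_sel == down.ref:
            call = "trans"
        else:
            log.warning("pair %s/%s selected non-allele bases (%s, %s)",
                        up, down, ref_sel, alt_sel)
    return PairPhase(matrix, ref_row, alt_row, ref_sel, alt_sel, call, confident)


Verdict = Literal["confident", "ambiguous"]


@dataclass
class PhaseStep:
    """One chaining step: chosen upstream base -> selected downstream base."""

    matrix: AssociationMatrix
    upstream_base: str
    selected_base: str
    row: RowBootstrapResult
    step_probability: float
    tie: bool
    cumulative_prob: float
    cumulative_ci_low: float
    cumulative_ci_high: float
    verdict: Verdict
    after_ambiguity: bool
    phase_set: int          # position of the first site in this phase segment
    break_before: bool      # a zero-coverage break immediately precedes this step

    @property
    def site(self) -> HetSite:
        return self.matrix.downstream


@dataclass
class HaplotypeChain:
    """Ordered phased calls for one allele along a chain of matrices."""

    start_site: HetSite
    start_base: str
    steps: list[PhaseStep]

    def calls(self) -> dict[int, str]:
        """Position -> phased base, including the chain start site."""
        out = {self.start_site.pos: self.start_base}
        for st in self.steps:
            out[st.site.pos] = st.selected_base
        return out

    def phase_sets(self) -> dict[int, int]:
        """Position -> phase-set id (segment start position)."""
        out = {self.start_site.pos: self.start_site.pos}
        for st in self.steps:
            out[st.site.pos] = st.phase_set
        return out

    @property
    def cumulative_prob(self) -> np.ndarray:
        return np.array([st.cumulative_prob for st in self.steps])

    @property
    def verdicts(self) -> list[Verdict]:
        return [st.verdict for st in self.steps]

    @property
    def all_confident(self) -> bool:
        return all(v == "confident" for v in self.verdicts)


def cumulative_ci(step_draws: Sequence[np.ndarray]) -> list[tuple[float, float]]:
    """Cumulative bootstrap CI per step from per-step selected-base draws.

    Iteration ``b`` of the cumulative distribution at step ``k`` is the
    product of draw ``b`` from every step ``j <= k`` (iterations paired by
    index; each step's draws were resampled independently). Returns the
    1st/99th nearest-rank percentiles at each step.
    """
    if not step_draws:
        return []
    n_iter = len(step_draws[0])
    if any(len(d) != n_iter for d in step_draws):
        raise UsageError("all steps must share n_iter")
    out = []
    running = np.ones(n_iter)
    for d in step_draws:
        running = running * np.asarray(d)
        s = np.sort(running)
        out.append((nearest_rank(s, CI_LOW_PCT), nearest_rank(s, CI_HIGH_PCT)))
    return out


def _start_base(site: HetSite, rule: StartRule, allele: int) -> str:
    """Starting base at a (re)start site for chain ``allele`` in {1, 2}."""
    if rule == "ref":
        first = site.ref
    elif rule == "alt":
        first = site.alt
    elif rule == "lexicographic":
        first = min(site.ref, site.alt)
    else:
        raise UsageError(f"unknown start_base_rule {rule!r}")
    return first if allele == 1 else site.other_allele(first)


def _build_chain(matrices: Sequence[AssociationMatrix], allele: int,
                 start_rule: StartRule, error_mass: float, n_iter: int,
                 seed_seq: np.random.SeedSequence) -> HaplotypeChain:
    start_site = matrices[0].upstream
    current = _start_base(start_site, start_rule, allele)
    chain = HaplotypeChain(start_site, current, [])

    seg_start = start_site.pos
    cum_prob = 1.0
    cum_draws = np.ones(n_iter)
    ambiguous_seen = False
    children = seed_seq.spawn(len(matrices))

    for k, m in enumerate(matrices):
        rng = np.random.default_rng(children[k])
        break_before = False
        try:
            row = bootstrap_row(m.row(current), error_mass, n_iter,
                                rng=rng, upstream_base=current)
        except ZeroCoverageError:
            # restart with a fresh phase set at the downstream site
            log.warning("zero-coverage row at %s (base %s): chain break, "
                        "restarting at %s", m.upstream, current, m.downstream)
            current = _start_base(m.downstream, start_rule, allele)
            seg_start = m.downstream.pos
            cum_prob = 1.0
            cum_draws = np.ones(n_iter)
            ambiguous_seen = False
            chain.steps.append(PhaseStep(
                matrix=m, upstream_base="", selected_base=current, row=None,  # type: ignore[arg-type]
                step_probability=float("nan"), tie=False,
                cumulative_prob=1.0, cumulative_ci_low=float("nan"),
                cumulative_ci_high=float("nan"), verdict="ambiguous",
                after_ambiguity=False, phase_set=seg_start, break_before=True))
            continue

        selected, tie = row.selected()
        sel_idx = BASE_INDEX[selected]
        step_p = float(row.probs[sel_idx])
        cum_prob *= step_p
        cum_draws = cum_draws * row.draws[:, sel_idx]
        s = np.sort(cum_draws)
        lo, hi = nearest_rank(s, CI_LOW_PCT), nearest_rank(s, CI_HIGH_PCT)

        verdict: Verdict = "confident"
        if tie or lo <= row.rejected_ci_high(selected):
            verdict = "ambiguous"
        chain.steps.append(PhaseStep(
            matrix=m, upstream_base=current, selected_base=selected, row=row,
            step_probability=step_p, tie=tie, cumulative_prob=cum_prob,
            cumulative_ci_low=lo, cumulative_ci_high=hi, verdict=verdict,
            after_ambiguity=ambiguous_seen, phase_set=seg_start,
            break_before=break_before))
        if verdict == "ambiguous":
            ambiguous_seen = True
        current = selected
    return chain


def chain_phase(matrices: Sequence[AssociationMatrix],
                start_base_rule: StartRule = "ref",
                error_mass: float = DEFAULT_ERROR_MASS,
                n_iter: int = DEFAULT_N_ITER,
                seed: int | None = 0) -> tuple[HaplotypeChain, HaplotypeChain]:
    """Phase both alleles along a connected chain of association matrices.

    The allele-1 chain starts from the base chosen by ``start_base_rule`` at
    h_0; the allele-2 chain starts from the alternate base. A zero-coverage
    row mid-chain records a break and restarts with a fresh phase set at the
    next site. The two chains use independent bootstrap streams derived from
    ``seed``.
    """
    if not matrices:
        raise UsageError("chain_phase requires at least one matrix")
    for a, b in zip(matrices, matrices[1:]):
        if a.downstream.pos != b.upstream.pos:
            raise UsageError(
                f"matrices not connected: {a.downstream} -> {b.upstream}")
    ss = np.random.SeedSequence(seed)
    ss1, ss2 = ss.spawn(2)
    chain1 = _build_chain(matrices, 1, start_base_rule, error_mass, n_iter, ss1)
    chain2 = _build_chain(matrices, 2, start_base_rule, error_mass, n_iter, ss2)
    return chain1, chain2


def confidence_verdict(chain: HaplotypeChain) -> list[Verdict]:
    """Recompute per-step verdicts from the stored bootstrap CIs.

    Step k is confident iff its cumulative CI lower bound exceeds the CI
    upper bound of every rejected base at that step. Steps after the first
    ambiguity remain flagged via ``after_ambiguity``.
    """
    out: list[Verdict] = []
    for st in chain.steps:
        if st.row is None or st.tie:
            out.append("ambiguous")
            continue
        rejected = st.row.rejected_ci_high(st.selected_base)
        out.append("confident" if st.cumulative_ci_low > rejected else "ambiguous")
    return out


def chains_complementary(chain1: HaplotypeChain, chain2: HaplotypeChain) -> bool:
    """Opposite-allele cross-check: the two chains must disagree everywhere."""
    c1, c2 = chain1.calls(), chain2.calls()
    return all(c1[p] != c2.get(p) for p in c1 if p in c2)


@dataclass
class PhasingResult:
    """Everything produced by one end-to-end phasing run."""

    sites: list[HetSite]
    plan: ChainPlan
    chain1: HaplotypeChain
    chain2: HaplotypeChain
    complementary: bool
    assignments: dict[int, PhasedCall]      # confidently phased sites only
    side_notes: dict[int, str]              # pos -> note for non-chain sites

    @property
    def n_phased(self) -> int:
        return len(self.assignments)


def _segment_assignments(chain1: HaplotypeChain, chain2: HaplotypeChain
                         ) -> dict[int, PhasedCall]:
    """Phased-VCF assignments from the two chains.

    Phase sets split at ambiguous or broken junctions; a site is assigned only
    when both chains call it with complementary bases and its segment keeps at
    least two members (phasing needs >= 2 sites).
    """
    calls1, calls2 = chain1.calls(), chain2.calls()
    # walk chain1's steps, segmenting at ambiguous/broken junctions
    segments: list[list[int]] = [[chain1.start_site.pos]]
    for st in chain1.steps:
        if st.break_before or st.verdict == "ambiguous":
            segments.append([st.site.pos])
        else:
            segments[-1].append(st.site.pos)
    out: dict[int, PhasedCall] = {}
    for seg in segments:
        members = [p for p in seg if p in calls2 and calls1[p] != calls2[p]]
        if len(members) < 2:
            continue
        ps = members[0]
        for p in members:
            out[p] = PhasedCall(calls1[p], calls2[p], ps)
    return out


def _phase_skipped_site(fragments: Sequence[LinkedFragment], site: HetSite,
                        anchors: Sequence[HetSite], calls1: Mapping[int, str],
                        calls2: Mapping[int, str], assignments: dict[int, PhasedCall],
                        min_total: int, error_mass: float, n_iter: int,
                        rng_seq: np.random.SeedSequence) -> str:
    """Phase a bridged-over site from its nearest anchored neighbor."""
    from .association import build_association_matrix

    for anchor in sorted(anchors, key=lambda a: abs(a.pos - site.pos)):
        if anchor.pos not in assignments:
            continue
        up, down = (anchor, site) if anchor.pos < site.pos else (site, anchor)
        m = build_association_matrix(fragments, up, down)
        if m.total < min_total:
            continue
        bases = {}
        ok = True
        for allele, calls in ((1, calls1), (2, calls2)):
            anchor_base = calls[anchor.pos]
            rng = np.random.default_rng(rng_seq.spawn(1)[0])
            try:
                if anchor is up:
                    row = bootstrap_row(m.row(anchor_base), error_mass, n_iter, rng=rng)
                    sel, tie = row.selected()
                else:  # phase upstream site from the downstream anchor: use the column
                    col = m.counts[:, BASE_INDEX[anchor_base]]
                    row = bootstrap_row(col, error_mass, n_iter, rng=rng)
                    sel, tie = row.selected()
            except ZeroCoverageError:
                ok = False
                break
            if tie or not _row_confident(row, sel) or sel not in site.alleles:
                ok = False
                break
            bases[allele] = sel
        if ok and bases[1] != bases[2]:
            assignments[site.pos] = PhasedCall(
                bases[1], bases[2], assignments[anchor.pos].phase_set)
            return f"phased from neighbor {anchor.pos}"
    return "unphaseable (low linked coverage)"


def phase_region(fragments: Sequence[LinkedFragment], sites: Sequence[HetSite],
                 *, min_total: int = 20,
                 start_base_rule: StartRule = "ref",
                 error_mass: float = DEFAULT_ERROR_MASS,
                 n_iter: int = DEFAULT_N_ITER,
                 seed: int | None = 0) -> PhasingResult:
    """End-to-end phasing: adjacent matrices -> two chains -> assignments.

    Composes :func:`adjacent_pairs_matrices`, :func:`chain_phase`, the
    opposite-allele cross-check, neighbor phasing of bridged sites, and the
    phase-set segmentation consumed by the VCF writer.
    """
    from .association import adjacent_pairs_matrices

    ordered = sorted(sites, key=lambda s: s.pos)
    if len(ordered) < 2:
        raise UsageError("phasing needs at least two het sites")
    plan = adjacent_pairs_matrices(fragments, ordered, min_total=min_total)
    if not plan.matrices:
        raise ZeroCoverageError("no site pair has enough linked coverage to phase")

    # chain_phase consumes spawn keys (0,) and (1,) of this seed; take (2,)
    # for the side-phasing stream so no generator is reused
    ss = np.random.SeedSequence(seed)
    ss_side = ss.spawn(3)[2]
    chain1, chain2 = chain_phase(plan.matrices, start_base_rule, error_mass,
                                 n_iter, seed=seed)
    complementary = chains_complementary(chain1, chain2)
    if not complementary:
        log.warning("opposite-allele cross-check FAILED: chains are not complementary")

    assignments = _segment_assignments(chain1, chain2) if complementary else {}
    side_notes: dict[int, str] = {}
    calls1, calls2 = chain1.calls(), chain2.calls()
    anchors = plan.anchor_sites
    for skipped in plan.skipped:
        side_notes[skipped.pos] = _phase_skipped_site(
            fragments, skipped, anchors, calls1, calls2, assignments,
            min_total, error_mass, n_iter, ss_side)
    return PhasingResult(ordered, plan, chain1, chain2, complementary,
                         assignments, side_notes)


def write_chain_tsv(chain1: HaplotypeChain, chain2: HaplotypeChain,
                    out_path: str) -> None:
    """Chain report: one row per (allele, step), floats at 6 significant digits."""
    def fmt(x: float) -> str:
        return "nan" if math.isnan(x) else f"{x:.6g}"

    with open(out_path, "w") as fh:
        fh.write("allele\tup_pos\tdown_pos\tup_base\tselected_base\t"
                 "step_prob\tstep_ci_low\tstep_ci_high\t"
                 "cum_prob\tcum_ci_low\tcum_ci_high\tverdict\tphase_set\n")
        for allele, chain in ((1, chain1), (2, chain2)):
            for st in chain.steps:
                if st.row is None:
                    step_lo = step_hi = float("nan")
                    step_p = float("nan")
                else:
                    sel = BASE_INDEX[st.selected_base]
                    step_lo = float(st.row.ci_low[sel])
                    step_hi = float(st.row.ci_high[sel])
                    step_p = st.step_probability
                verdict = st.verdict
                if st.break_before:
                    verdict = "break"
                elif st.after_ambiguity:
                    verdict = f"{st.verdict}(after-ambiguity)"
                fh.write(f"{allele}\t{st.matrix.upstream.pos}\t{st.site.pos}\t"
                         f"{st.upstream_base}\t{st.selected_base}\t"
                         f"{fmt(step_p)}\t{fmt(step_lo)}\t{fmt(step_hi)}\t"
                         f"{fmt(st.cumulative_prob)}\t{fmt(st.cumulative_ci_low)}\t"
                         f"{fmt(st.cumulative_ci_high)}\t{verdict}\t{st.phase_set}\n")
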