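"""In-silico PCR, SOE fusion, integration, and pop-out recombination.

The verification chain proves each design end-to-end at the string level:
PCR1 and PCR2 are simulated from the primer sequences alone (a primer
primes wherever its 3'-terminal 12 nt match a template exactly), the two
products are fused through their shared overlap, the cassette is integrated
into the locus by double crossover, and every direct-repeat pop-out is
enumerated.  A design is *seamless* iff some pop-out outcome is
byte-identical to upstream + downstream of the original record.

The 12 nt annealing anchor is deliberately stricter than the design-side
8-mer rejection rule (a site the designer would reject may still not prime
here) and far looser than full-length identity, so chimeric tails do not
block priming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .constraints import DesignConstraints, DEFAULT_CONSTRAINTS
from .errors import SimulationError
from .seqio import LocusRecord, MarkerTemplate, reverse_complement


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted PCR product."""

    sequence: str
    template_id: str
    fwd_position: int  # plus-strand start of the forward anchor match
    rev_position: int  # plus-strand start of the reverse anchor match
    size: int

    def __post_init__(self):
        assert self.size == len(self.sequence)


def _anchor_sites(primer: str, template: str, anchor: int):
    """(plus_sites, minus_sites) where the primer's 3'-terminal anchor matches.

    A plus site at p means the anchor occupies template[p:p+anchor] and
    extension runs rightward; a minus site at p means the reverse complement
    of the anchor occupies template[p:p+anchor] and extension runs leftward,
    the primer's 3' terminus facing position p.
    """
    a = primer[-anchor:]
    a_rc = reverse_complement(a)
    plus, minus = [], []
    for motif, out in ((a, plus), (a_rc, minus)):
        start = template.find(motif)
        while start != -1:
            out.append(start)
            start = template.find(motif, start + 1)
    return plus, minus


def simulate_pcr(templates: Mapping[str, str], fwd: str, rev: str,
                 anchor: int = 12,
                 max_product: int = 10000) -> list[AmpliconPrediction]:
    """Enumerate products of a primer pair over all templates.

    Every convergent (plus-site, minus-site) pairing of either primer within
    ``max_product`` yields a product; the product is the template span with
    the full primers (chimeric tails included) substituted at the ends.
    An empty list is a legitimate result.
    """
    if min(len(fwd), len(rev)) < anchor:
        raise ValueError(f"primers must be >= anchor ({anchor} nt)")
    products = []
    for template_id in sorted(templates):
        template = templates[template_id]
        sites = {"fwd": _anchor_sites(fwd, template, anchor),
                 "rev": _anchor_sites(rev, template, anchor)}
        primer_of = {"fwd": fwd, "rev": rev}
        for left_name in ("fwd", "rev"):
            for right_name in ("fwd", "rev"):
                left_primer = primer_of[left_name]
                right_primer = primer_of[right_name]
                for lp in sites[left_name][0]:
                    for rp in sites[right_name][1]:
                        interior_start = lp + anchor
                        if rp < interior_start:
                            continue
                        seq = (left_primer + template[interior_start:rp]
                               + reverse_complement(right_primer))
                        if len(seq) > max_product:
                            continue
                        products.append(AmpliconPrediction(
                            sequence=seq, template_id=template_id,
                            fwd_position=lp, rev_position=rp,
                            size=len(seq)))
    products.sort(key=lambda p: (p.template_id, p.fwd_position,
                                 p.rev_position, p.sequence))
    return products


@dataclass(frozen=True)
class SoeResult:
    fused: bool
    sequence: str = ""
    overlap_len: int = 0
    detail: str = ""


def simulate_soe(prod_a: str, prod_b: str, outer_f: str, outer_r: str,
                 min_overlap: int = 20, anchor: int = 12,
                 max_product: int = 10000) -> SoeResult:
    """Fuse two amplicons through a shared terminal overlap, then amplify.

    Fusion succeeds iff the 3' end of ``prod_a`` equals the 5' end of
    ``prod_b`` over at least ``min_overlap`` nt (the longest such overlap
    is used); the outer primers must then prime the ends of the fusion.
    A failed fusion is a result, not an exception — SOE reactions do fail.
    """
    best = 0
    for n in range(min(len(prod_a), len(prod_b)), min_overlap - 1, -1):
        if prod_a[-n:] == prod_b[:n]:
            best = n
            break
    if not best:
        return SoeResult(False, detail=f"no exact overlap >= {min_overlap}")
    fused = prod_a + prod_b[best:]
    amplified = simulate_pcr({"fusion": fused}, outer_f, outer_r,
                             anchor=anchor, max_product=max_product)
    full = [p for p in amplified if p.sequence == fused]
    if not full:
        return SoeResult(False, overlap_len=best,
                         detail="outer primers do not span the fusion")
    return SoeResult(True, sequence=fused, overlap_len=best)


def simulate_integration(locus: LocusRecord, cassette: str,
                         min_arm: int = 40) -> str:
    """Double-crossover replacement of the target by the cassette.

    Both cassette ends must carry at least ``min_arm`` of exact homology to
    the locus record; the recombinant is locus-prefix + cassette +
    locus-suffix with the longest-extension match chosen on each side
    (leftmost on ties for the left arm, rightmost for the right).
    """
    record = locus.record
    if len(cassette) < 2 * min_arm:
        raise SimulationError("integration",
                              f"cassette shorter than two {min_arm} nt arms")

    def arm_matches(seed: str, extend_right: bool):
        out = []
        pos = record.find(seed)
        while pos != -1:
            length = min_arm
            if extend_right:
                while (length < len(cassette)
                       and pos + length < len(record)
                       and cassette[length] == record[pos + length]):
                    length += 1
                out.append((pos, length))
            else:
                coff = len(cassette) - min_arm
                rstart = pos
                while (length < len(cassette) and rstart - 1 >= 0
                       and cassette[coff - 1] == record[rstart - 1]):
                    length += 1
                    coff -= 1
                    rstart -= 1
                out.append((rstart, length))
            pos = record.find(seed, pos + 1)
        return out

    left = arm_matches(cassette[:min_arm], extend_right=True)
    right = arm_matches(cassette[-min_arm:], extend_right=False)
    if not left:
        raise SimulationError("integration", "left arm has no homology")
    if not right:
        raise SimulationError("integration", "right arm has no homology")
    left_pos, _ = max(left, key=lambda x: (x[1], -x[0]))
    right_start, right_len = max(right, key=lambda x: (x[1], x[0]))
    right_end = right_start + right_len
    if right_end <= left_pos:
        raise SimulationError("integration", "arms map in the wrong order")
    return record[:left_pos] + cassette + record[right_end:]


@dataclass(frozen=True)
class ExcisionOutcome:
    """One pop-out recombination outcome between a pair of direct repeats."""

    locus: str
    repeat_positions: tuple[int, int]
    repeat_length: int
    seamless: bool


def _maximal_repeat_pairs(seq: str, min_repeat: int):
    """All maximal exact direct-repeat pairs of length >= min_repeat.

    Seeded by an index of min_repeat-mers, each occurrence pair is extended
    maximally left and right, then deduplicated.
    """
    index: dict[str, list[int]] = {}
    k = min_repeat
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    pairs = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                left = 0
                while (i - left - 1 >= 0
                       and seq[i - left - 1] == seq[j - left - 1]):
                    left += 1
                right = 0
                while (j + k + right < len(seq)
                       and seq[i + k + right] == seq[j + k + right]):
                    right += 1
                pairs.add((i - left, j - left, k + left + right))
    return sorted(pairs)


def simulate_popout(transformed: str, min_repeat: int = 20,
                    expected: str | None = None) -> list[ExcisionOutcome]:
    """Enumerate every direct-repeat recombination outcome.

    Recombination between direct repeats at (i, j) of length L loops out
    the intervening DNA and one repeat copy: the outcome keeps
    ``transformed[:i] + transformed[j:]``.  ``expected`` (the seamless
    upstream+downstream sequence) flags the scar-free outcome if supplied.
    """
    outcomes = []
    for i, j, length in _maximal_repeat_pairs(transformed, min_repeat):
        locus = transformed[:i] + transformed[j:]
        outcomes.append(ExcisionOutcome(
            locus=locus, repeat_positions=(i, j), repeat_length=length,
            seamless=(expected is not None and locus == expected)))
    return outcomes


@dataclass
class VerificationReport:
    locus_id: str
    seamless: bool
    stage_failed: str = ""
    detail: str = ""
    pcr1_size: int = 0
    pcr2_size: int = 0
    pcr3_size: int = 0
    diff: dict = field(default_factory=dict)


def locus_diff(expected: str, observed: str) -> dict:
    """Summary of how an outcome differs from the seamless locus."""
    if expected == observed:
        return {}
    lcp = 0
    while (lcp < min(len(expected), len(observed))
           and expected[lcp] == observed[lcp]):
        lcp += 1
    lcs = 0
    while (lcs < min(len(expected), len(observed)) - lcp
           and expected[-1 - lcs] == observed[-1 - lcs]):
        lcs += 1
    return {
        "expected_len": len(expected),
        "observed_len": len(observed),
        "missing_nt": len(expected) - len(observed),
        "first_divergence": lcp,
        "matching_suffix": lcs,
    }


def verify_seamless(locus: LocusRecord, primers, marker: MarkerTemplate,
                    constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
                    ) -> VerificationReport:
    """Run the full chain PCR1 -> PCR2 -> SOE -> integrate -> pop-out.

    ``primers`` needs attributes ``p1, p2, p3, p4`` (a PrimerSet or any
    equivalent).  The design is verified from the primer sequences alone.
    """
    expected = locus.upstream + locus.downstream
    report = VerificationReport(locus_id=locus.locus_id, seamless=False)
    anchor = constraints.sim_anchor

    def fail(stage, detail):
        report.stage_failed, report.detail = stage, detail
        return report

    pcr1 = simulate_pcr({locus.locus_id: locus.record}, primers.p1,
                        primers.p2, anchor, constraints.max_product)
    if len(pcr1) != 1:
        return fail("pcr1", f"{len(pcr1)} products (expected 1)")
    report.pcr1_size = pcr1[0].size

    pcr2 = simulate_pcr({marker.marker_name: marker.plasmid}, primers.p3,
                        primers.p4, anchor, constraints.max_product)
    if len(pcr2) != 1:
        return fail("pcr2", f"{len(pcr2)} products (expected 1)")
    report.pcr2_size = pcr2[0].size

    soe = simulate_soe(pcr1[0].sequence, pcr2[0].sequence,
                       primers.p1, primers.p4,
                       min_overlap=constraints.soe_min_overlap,
                       anchor=anchor, max_product=constraints.max_product)
    if not soe.fused:
        return fail("soe", soe.detail)
    report.pcr3_size = len(soe.sequence)

    try:
        transformed = simulate_integration(
            locus, soe.sequence, min_arm=constraints.integration_min_arm)
    except SimulationError as exc:
        return fail(exc.stage, exc.detail)

    outcomes = simulate_popout(transformed,
                               min_repeat=constraints.popout_min_repeat,
                               expected=expected)
    if not outcomes:
        return fail("popout", "no direct-repeat pair found")
    seamless = [o for o in outcomes if o.seamless]
    if seamless:
        report.seamless = True
        return report
    closest = min(outcomes,
                  key=lambda o: abs(len(o.locus) - len(expected)))
    report.diff = locus_diff(expected, closest.locus)
    return fail("popout", "no seamless outcome")
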