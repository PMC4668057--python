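"""The cassette-design algorithm: four interdependent primers per deletion.

A deletion cassette is built from three PCRs.  PCR1 amplifies a 500-1000 bp
window of upstream flank ending exactly at the ORF start (primers p1/p2).
PCR2 amplifies the selectable marker from its plasmid with two chimeric
primers: p3 = [reverse complement of p2's 5' end][40 nt repeat R copied
from immediately downstream of the ORF][17-20 nt marker anchor], and
p4 = [reverse complement of the ORF's final 44 nt][reverse complement of
the marker amplicon's last 18 nt].  PCR3 (SOEing) fuses the two products
through the shared overlap into the cassette

    [upstream window][R][marker][ORF 3'-end homology]

which integrates by double crossover, placing the marker between two direct
copies of R (one in the cassette, one native in the downstream flank);
counter-selection then pops the marker out through the repeats, leaving
exactly upstream + downstream — no scar, nothing extra deleted.

Candidate enumeration order is deterministic: p2 by (rules pass,
|GC - 0.4|, length), p1 by (|GC(p1) - GC(p2)|, longer amplicon first,
leftmost).  For fixed inputs and constraints, design output is
byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

from . import errors as E
from .constraints import DesignConstraints
from .errors import DesignError
from .quality import dimer_check, gc_rules_check, hairpin_check, pair_match
from .seqio import LocusRecord, MarkerTemplate, gc_fraction, reverse_complement
from .specificity import IntendedSite, specificity_filter

# pipeline depth of each failure code, for "deepest reason" reporting
_STAGE_DEPTH = {
    E.FLANK_TOO_SHORT: 0, E.ORF_TOO_SHORT: 0, E.NONSTANDARD_BASE: 0,
    E.NO_P2_CANDIDATE: 1,
    E.NO_MARKER_PAIR: 2, E.P3_TOO_LONG: 3, E.GC_3PRIME: 3,
    E.GC_OVERALL: 3, E.HOMOPOLYMER_3PRIME: 3,
    E.NO_P1_MATCH: 4, E.MISPRIME: 4,
    E.DIMER: 5, E.HAIRPIN: 5,
}


@dataclass(frozen=True)
class PrimerCandidate:
    """A candidate PCR1 primer with record coordinates.

    ``start`` is the 0-based record position of the candidate's 5'-most
    template base (for reverse candidates, of the 3' terminus).
    """

    seq: str
    start: int
    strand: str  # '+' forward, '-' reverse


@dataclass(frozen=True)
class PrimerSet:
    """The four design primers plus confirmation primers for one locus."""

    locus_id: str
    p1: str  # PCR1_F
    p2: str  # PCR1_R
    p3: str  # PCR2_F, chimeric: overlap + R + marker5
    p4: str  # PCR2_R, chimeric: rc(right homology) + rc(marker 3' end)
    p3_segments: tuple[str, str, str]      # (overlap, R, marker5)
    p4_segments: tuple[str, str]           # (right_homology_rc, marker3_rc)
    marker_pair_id: int
    marker_name: str
    p1_start: int  # record coordinate of the PCR1 amplicon start
    cps_a: str = ""
    cps_d: str = ""
    rin_cass: str = ""
    fin_cass: str = ""


@dataclass(frozen=True)
class DesignFailure:
    locus_id: str
    reason_code: str
    detail: str = ""


# --- segment extraction ---------------------------------------------------

def _require_clean(seq: str, what: str) -> None:
    if "N" in seq:
        raise DesignError(E.NONSTANDARD_BASE, f"N inside {what}")


def extract_R(locus: LocusRecord, constraints: DesignConstraints) -> str:
    """The repeat R: the first r_len nt of the downstream flank, sense strand."""
    if len(locus.downstream) < constraints.r_len:
        raise DesignError(
            E.FLANK_TOO_SHORT,
            f"downstream {len(locus.downstream)} nt < r_len {constraints.r_len}")
    r = locus.downstream[:constraints.r_len]
    _require_clean(r, "repeat R")
    return r


def extract_right_homology(locus: LocusRecord,
                           constraints: DesignConstraints) -> str:
    """The ORF's final right_homology_len nt (includes the stop codon)."""
    n = constraints.right_homology_len
    if len(locus.orf) < n:
        raise DesignError(
            E.ORF_TOO_SHORT, f"orf {len(locus.orf)} nt < right_homology {n}")
    rh = locus.orf[-n:]
    _require_clean(rh, "right homology")
    return rh


# --- PCR1 candidates ------------------------------------------------------

def _search_space(locus: LocusRecord, marker: MarkerTemplate | None):
    space = {locus.locus_id: locus.record}
    if marker is not None:
        space[marker.marker_name] = marker.plasmid
    return space


def candidate_p2(locus: LocusRecord, constraints: DesignConstraints,
                 marker: MarkerTemplate | None = None,
                 ) -> list[PrimerCandidate]:
    """Reverse-strand PCR1 candidates abutting the ORF start.

    The amplicon must end at the last upstream base (nothing of the ORF is
    amplified), so every candidate's 5' end maps there and only its length
    varies.  An empty list is legal and yields NO_P2_CANDIDATE upstream.
    """
    flank = locus.flank_len
    space = _search_space(locus, marker)
    candidates = []
    for length in range(constraints.p2_len_min, constraints.p2_len_max + 1):
        if length > flank:
            break
        site = locus.upstream[flank - length:]
        if "N" in site:
            continue
        seq = reverse_complement(site)
        if not gc_rules_check(seq, constraints).passed:
            continue
        if hairpin_check(seq, constraints):
            continue
        if dimer_check(seq, seq, constraints).flagged:
            continue
        intended = IntendedSite(locus.locus_id, flank - length, "-")
        if not specificity_filter(seq, space, constraints, intended).passed:
            continue
        candidates.append(PrimerCandidate(seq, flank - length, "-"))
    candidates.sort(key=lambda c: (abs(gc_fraction(c.seq) - 0.40),
                                   len(c.seq)))
    return candidates


def _iter_p1_windows(locus: LocusRecord, p2: PrimerCandidate,
                     constraints: DesignConstraints):
    """(start, length) windows ordered by the p1 tie-break, computed cheaply.

    GC per window comes from a prefix-sum so that tens of thousands of
    windows can be ranked before any expensive rule runs.
    """
    upstream = locus.upstream
    flank = locus.flank_len
    prefix = [0] * (flank + 1)
    for i, base in enumerate(upstream):
        prefix[i + 1] = prefix[i] + (base in "GC")
    gc_p2 = gc_fraction(p2.seq)
    lo = max(0, flank - constraints.amplicon_max)
    hi = flank - constraints.amplicon_min
    windows = []
    for start in range(lo, hi + 1):
        amplicon_len = flank - start
        for length in range(constraints.p1_len_min,
                            constraints.p1_len_max + 1):
            if start + length > flank:
                break
            gc = (prefix[start + length] - prefix[start]) / length
            windows.append((abs(gc - gc_p2), -amplicon_len, start, length))
    windows.sort()
    for _, _, start, length in windows:
        yield start, length


def iter_candidate_p1(locus: LocusRecord, p2: PrimerCandidate,
                      constraints: DesignConstraints,
                      marker: MarkerTemplate | None = None,
                      ) -> Iterator[PrimerCandidate]:
    """Lazily yield forward PCR1 candidates compatible with a fixed p2.

    The amplicon [p1 start, ORF start) must span amplicon_min..amplicon_max;
    each candidate passes composition, hairpin, self-dimer and specificity
    rules, pair-matches p2, and is dimer-compatible with p2.
    """
    space = _search_space(locus, marker)
    for start, length in _iter_p1_windows(locus, p2, constraints):
        seq = locus.upstream[start:start + length]
        if "N" in seq:
            continue
        if not gc_rules_check(seq, constraints).passed:
            continue
        if not pair_match(seq, p2.seq, constraints.pair_mode, constraints):
            continue
        if hairpin_check(seq, constraints):
            continue
        if dimer_check(seq, seq, constraints).flagged:
            continue
        if dimer_check(seq, p2.seq, constraints).flagged:
            continue
        intended = IntendedSite(locus.locus_id,
                                start + length - constraints.mispriming_k, "+")
        if not specificity_filter(seq, space, constraints, intended).passed:
            continue
        yield PrimerCandidate(seq, start, "+")


def candidate_p1(locus: LocusRecord, p2: PrimerCandidate,
                 constraints: DesignConstraints,
                 marker: MarkerTemplate | None = None,
                 limit: int = 25) -> list[PrimerCandidate]:
    """First ``limit`` passing forward candidates, in tie-break order."""
    return list(itertools.islice(
        iter_candidate_p1(locus, p2, constraints, marker), limit))


# --- marker amplicon and chimeric primers ---------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def choose_marker_amplicon(marker: MarkerTemplate,
                           constraints: DesignConstraints,
                           skip: frozenset[int] = frozenset(),
                           ) -> tuple[int, str]:
    """First configured anchor pair whose amplicon avoids forbidden intervals.

    ``skip`` lets the orchestrator fall through to later pairs when a
    chimeric primer built on an earlier one fails its rules.
    """
    for idx, (start, end) in enumerate(marker.anchor_pairs):
        if idx in skip:
            continue
        if any(_overlaps((start, end), iv)
               for iv in marker.forbidden_intervals):
            continue
        amplicon = marker.plasmid[start:end]
        if "N" in amplicon:
            continue
        return idx, amplicon
    raise DesignError(
        E.NO_MARKER_PAIR,
        "no anchor pair avoids the forbidden intervals"
        + (f" (skipped {sorted(skip)})" if skip else ""))


@dataclass(frozen=True)
class ChimericPrimer:
    seq: str
    segments: tuple[str, ...]


def _check_three_prime(seq: str, constraints: DesignConstraints,
                       what: str) -> None:
    tail = seq[-8:]
    if tail.count("G") + tail.count("C") < constraints.gc_last8_min:
        raise DesignError(E.GC_3PRIME, f"{what}: <{constraints.gc_last8_min} "
                          "G/C in last 8")
    k = constraints.mispriming_k
    if len(set(seq[-k:])) == 1:
        raise DesignError(E.HOMOPOLYMER_3PRIME,
                          f"{what}: homopolymeric 3' anchor")


def assemble_p3(p2: PrimerCandidate | str, r_seq: str, marker_amplicon: str,
                constraints: DesignConstraints) -> ChimericPrimer:
    """Build the chimeric PCR2 forward primer: overlap + R + marker anchor.

    The overlap is the reverse complement of p2's 5' end, nominally
    overlap_len nt; if its GC content is below gc_min it is extended toward
    overlap_max (a GC-poor SOE junction fuses badly).  The marker anchor is
    swept from marker5_max down to marker5_min, taking the longest that
    keeps the primer within p3_max_len and passes the overall-GC and
    3'-end composition rules (GC-poor primers amplify weakly or not at
    all, chimeric or not).
    """
    p2_seq = p2.seq if isinstance(p2, PrimerCandidate) else p2
    olen = min(constraints.overlap_len, len(p2_seq))
    max_olen = min(constraints.overlap_max, len(p2_seq))
    while (gc_fraction(p2_seq[:olen]) < constraints.gc_min
           and olen < max_olen):
        olen += 1
    overlap = reverse_complement(p2_seq[:olen])
    last_error: DesignError | None = None
    for m in range(constraints.marker5_max, constraints.marker5_min - 1, -1):
        if m > len(marker_amplicon):
            continue
        if olen + len(r_seq) + m > constraints.p3_max_len:
            last_error = last_error or DesignError(
                E.P3_TOO_LONG,
                f"{olen}+{len(r_seq)}+{m} > {constraints.p3_max_len}")
            continue
        marker5 = marker_amplicon[:m]
        seq = overlap + r_seq + marker5
        if "N" in seq:
            last_error = DesignError(E.NONSTANDARD_BASE, "N in PCR2_F")
            continue
        if gc_fraction(seq) < constraints.gc_min:
            last_error = DesignError(
                E.GC_OVERALL, f"PCR2_F overall GC {gc_fraction(seq):.2f}")
            continue
        try:
            _check_three_prime(seq, constraints, "PCR2_F")
        except DesignError as exc:
            last_error = exc
            continue
        return ChimericPrimer(seq, (overlap, r_seq, marker5))
    raise last_error or DesignError(E.P3_TOO_LONG, "no marker anchor fits")


def assemble_p4(locus: LocusRecord, marker_amplicon: str,
                constraints: DesignConstraints) -> ChimericPrimer:
    """Build the chimeric PCR2 reverse primer.

    p4 = rc(ORF's final right_homology_len nt) + rc(marker amplicon's final
    marker3_len nt); its first three bases are therefore the reverse
    complement of the ORF's stop codon.
    """
    rh = extract_right_homology(locus, constraints)
    rh_rc = reverse_complement(rh)
    marker3_rc = reverse_complement(marker_amplicon[-constraints.marker3_len:])
    seq = rh_rc + marker3_rc
    if "N" in seq:
        raise DesignError(E.NONSTANDARD_BASE, "N in PCR2_R")
    if len(seq) > constraints.p3_max_len:
        raise DesignError(E.P3_TOO_LONG, f"PCR2_R {len(seq)} nt")
    if gc_fraction(seq) < constraints.gc_min:
        raise DesignError(E.GC_OVERALL,
                          f"PCR2_R overall GC {gc_fraction(seq):.2f}")
    _check_three_prime(seq, constraints, "PCR2_R")
    return ChimericPrimer(seq, (rh_rc, marker3_rc))


# --- confirmation primers -------------------------------------------------

@dataclass(frozen=True)
class ConfirmationPrimers:
    cps_a: str
    cps_a_start: int
    cps_d: str
    cps_d_site_start: int  # plus-strand start of the annealing site
    rin_cass: str
    fin_cass: str


def design_confirmation(locus: LocusRecord, marker: MarkerTemplate,
                        constraints: DesignConstraints,
                        p1_start: int) -> ConfirmationPrimers:
    """Colony-PCR primers outside the cassette footprint.

    CPS_A: forward, in the upstream flank, ending 150-300 bp 5' of the
    PCR1 start so its product with the marker-internal RinCass exists only
    after integration.  CPS_D: reverse, in the downstream flank, 150-300 bp
    3' of the repeat R.  RinCass/FinCass are taken from the marker config.
    """
    up = locus.upstream

    def pick(region: str, offset_base: int, reverse: bool) -> tuple[str, int]:
        for off in range(constraints.conf_offset_min,
                         constraints.conf_offset_max + 1):
            for length in range(constraints.conf_len_min,
                                constraints.conf_len_max + 1):
                if reverse:
                    start = offset_base + off
                    end = start + length
                    if end > len(region):
                        continue
                    site = region[start:end]
                    seq = reverse_complement(site)
                else:
                    end = offset_base - off
                    start = end - length
                    if start < 0:
                        continue
                    site = region[start:end]
                    seq = site
                if "N" in site:
                    continue
                if not gc_rules_check(seq, constraints).passed:
                    continue
                if hairpin_check(seq, constraints):
                    continue
                return seq, start
        raise DesignError(
            E.FLANK_TOO_SHORT,
            "no room for a confirmation primer outside the cassette")

    cps_a, a_start = pick(up, p1_start, reverse=False)
    cps_d, d_start = pick(locus.downstream, constraints.r_len, reverse=True)
    return ConfirmationPrimers(cps_a, a_start, cps_d, d_start,
                               marker.rin_cass, marker.fin_cass)


# --- orchestration --------------------------------------------------------

@dataclass
class _Deepest:
    code: str = E.NO_P2_CANDIDATE
    detail: str = "no PCR1 reverse candidate passed the rules"
    depth: int = -1

    def update(self, code: str, detail: str) -> None:
        depth = _STAGE_DEPTH.get(code, 0)
        if depth > self.depth:
            self.code, self.detail, self.depth = code, detail, depth


def design_target(locus: LocusRecord, marker: MarkerTemplate,
                  constraints: DesignConstraints,
                  with_confirmation: bool = True,
                  p1_limit: int = 10,
                  ) -> PrimerSet | DesignFailure:
    """Run the full per-locus design and return a PrimerSet or a failure.

    Stages: enumerate p2 candidates; per p2, pick a marker amplicon and
    assemble the chimeric p3/p4 (retrying later anchor pairs on rule
    failures); then search p1 candidates and apply the cross-pair dimer
    checks (PCR2 pair p3/p4, SOE outer pair p1/p4) and the 3'-specificity
    of p3/p4 against locus + plasmid.  The first fully passing combination
    wins; otherwise the deepest reason reached is reported.  Deterministic
    for fixed inputs.
    """
    deepest = _Deepest()
    try:
        r_seq = extract_R(locus, constraints)
        extract_right_homology(locus, constraints)
    except DesignError as exc:
        return DesignFailure(locus.locus_id, exc.code, exc.detail)

    space = _search_space(locus, marker)
    p2s = candidate_p2(locus, constraints, marker)
    if not p2s:
        return DesignFailure(locus.locus_id, deepest.code, deepest.detail)

    for p2 in p2s:
        # choose an anchor pair for which both chimeric primers pass
        skip: set[int] = set()
        chosen = None
        while chosen is None:
            try:
                pair_id, amplicon = choose_marker_amplicon(
                    marker, constraints, frozenset(skip))
            except DesignError as exc:
                deepest.update(exc.code, exc.detail)
                break
            try:
                p3 = assemble_p3(p2, r_seq, amplicon, constraints)
                p4 = assemble_p4(locus, amplicon, constraints)
                start, end = marker.anchor_pairs[pair_id]
                m = len(p3.segments[2])
                k = constraints.mispriming_k
                for primer, intended in (
                    (p3.seq, IntendedSite(marker.marker_name,
                                          start + m - k, "+")),
                    (p4.seq, IntendedSite(marker.marker_name,
                                          end - constraints.marker3_len, "-")),
                ):
                    result = specificity_filter(primer, space, constraints,
                                                intended)
                    if not result.passed:
                        raise DesignError(result.reason,
                                          "chimeric primer 3' end")
                if dimer_check(p3.seq, p4.seq, constraints).flagged:
                    raise DesignError(E.DIMER, "PCR2 pair p3/p4")
                chosen = (pair_id, amplicon, p3, p4)
            except DesignError as exc:
                deepest.update(exc.code, exc.detail)
                skip.add(pair_id)
        if chosen is None:
            continue
        pair_id, amplicon, p3, p4 = chosen

        found_p1 = False
        for p1 in itertools.islice(
                iter_candidate_p1(locus, p2, constraints, marker), p1_limit):
            found_p1 = True
            if dimer_check(p1.seq, p4.seq, constraints).flagged:
                deepest.update(E.DIMER, "SOE outer pair p1/p4")
                continue
            cps = None
            if with_confirmation:
                try:
                    cps = design_confirmation(locus, marker, constraints,
                                              p1.start)
                except DesignError:
                    cps = None  # design still valid; CPS columns left empty
            return PrimerSet(
                locus_id=locus.locus_id,
                p1=p1.seq, p2=p2.seq, p3=p3.seq, p4=p4.seq,
                p3_segments=p3.segments, p4_segments=p4.segments,
                marker_pair_id=pair_id, marker_name=marker.marker_name,
                p1_start=p1.start,
                cps_a=cps.cps_a if cps else "",
                cps_d=cps.cps_d if cps else "",
                rin_cass=marker.rin_cass, fin_cass=marker.fin_cass,
            )
        if not found_p1:
            deepest.update(E.NO_P1_MATCH,
                           "no forward candidate paired with this p2")
    if deepest.depth < 0:
        deepest.update(E.NO_P1_MATCH, "no passing combination")
    return DesignFailure(locus.locus_id, deepest.code, deepest.detail)


def shifted_repeat_variant(primer_set: PrimerSet, locus: LocusRecord,
                           shift: int = 20) -> PrimerSet:
    """Control design with R copied ``shift`` bp further downstream.

    This reproduces the older imprecise cassette geometry: the repeat no
    longer abuts the ORF, so pop-out additionally deletes the ``shift`` bp
    of intergenic DNA between the ORF and the repeat.  Used to demonstrate
    that the seamlessness check actually detects the loss.
    """
    overlap, r_seq, marker5 = primer_set.p3_segments
    shifted_r = locus.downstream[shift:shift + len(r_seq)]
    if len(shifted_r) < len(r_seq):
        raise DesignError(E.FLANK_TOO_SHORT, "downstream too short to shift R")
    return PrimerSet(
        locus_id=primer_set.locus_id,
        p1=primer_set.p1, p2=primer_set.p2,
        p3=overlap + shifted_r + marker5, p4=primer_set.p4,
        p3_segments=(overlap, shifted_r, marker5),
        p4_segments=primer_set.p4_segments,
        marker_pair_id=primer_set.marker_pair_id,
        marker_name=primer_set.marker_name,
        p1_start=primer_set.p1_start,
        cps_a=primer_set.cps_a, cps_d=primer_set.cps_d,
        rin_cass=primer_set.rin_cass, fin_cass=primer_set.fin_cass,
    )


# --- cassette plan --------------------------------------------------------

NG_PER_PMOL_PER_BP = 0.66  # ~660 g/mol per bp of dsDNA
NOMINAL_YIELD_PMOL_PER_50UL = 3.0  # a crude Taq reaction; ~50 ng/ul at 1.25 kb


def product_mass_ng(length_bp: int) -> float:
    """Expected mass of one 50 ul reaction's product at nominal yield."""
    return round(NOMINAL_YIELD_PMOL_PER_50UL * NG_PER_PMOL_PER_BP * length_bp, 1)


@dataclass(frozen=True)
class CassettePlan:
    """Predicted products and post-transformation sequences for one design."""

    locus_id: str
    pcr1_product: str
    pcr2_product: str
    pcr3_product: str
    overlap_len: int
    pcr1_size: int = 0
    pcr2_size: int = 0
    pcr3_size: int = 0
    pcr1_mass_ng: float = 0.0
    pcr2_mass_ng: float = 0.0
    pcr3_mass_ng: float = 0.0
    post_integration: str = ""
    post_popout: str = ""


def plan_cassette(primer_set: PrimerSet, locus: LocusRecord,
                  marker: MarkerTemplate) -> CassettePlan:
    """Predicted PCR products and locus sequences, by direct construction.

    (The in-silico PCR simulator re-derives these independently from the
    primer sequences alone; this plan is the design-side expectation.)
    """
    overlap, r_seq, _ = primer_set.p3_segments
    rh_rc, _ = primer_set.p4_segments
    rh = reverse_complement(rh_rc)
    amplicon = marker.amplicon(primer_set.marker_pair_id)
    pcr1 = locus.upstream[primer_set.p1_start:]
    pcr2 = overlap + r_seq + amplicon + rh
    pcr3 = pcr1 + pcr2[len(overlap):]
    post_integration = (locus.upstream + r_seq + amplicon + rh
                        + locus.downstream)
    return CassettePlan(
        locus_id=primer_set.locus_id,
        pcr1_product=pcr1, pcr2_product=pcr2, pcr3_product=pcr3,
        overlap_len=len(overlap),
        pcr1_size=len(pcr1), pcr2_size=len(pcr2), pcr3_size=len(pcr3),
        pcr1_mass_ng=product_mass_ng(len(pcr1)),
        pcr2_mass_ng=product_mass_ng(len(pcr2)),
        pcr3_mass_ng=product_mass_ng(len(pcr3)),
        post_integration=post_integration,
        post_popout=locus.upstream + locus.downstream,
    )
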