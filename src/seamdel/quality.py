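"""Per-primer and per-pair quality rules.

The dimer model is deliberately rule-based rather than thermodynamic: long
chimeric primers (up to 100-mers) defeat nearest-neighbour duplex models,
so a primer pair is scored by weighted Watson-Crick complementarity of one
primer's 3'-terminal window against every ungapped register of the other
(A:T = 2, G:C = 4), and separately by the longest contiguous complementary
run anywhere in the duplex — the "caterpillar hump" geometry in which the
interior of two long primers zips up even though their ends are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constraints import DesignConstraints
from .errors import ConfigError, GC_OVERALL, GC_3PRIME, DIMER, HAIRPIN
from .seqio import gc_fraction, melting_temp, reverse_complement

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
# classic 2-4 rule: two H-bonds for A:T, (weighting) four for G:C
_PAIR_WEIGHT = {("A", "T"): 2, ("T", "A"): 2, ("G", "C"): 4, ("C", "G"): 4}


def _is_pair(x: str, y: str) -> bool:
    return _COMPLEMENT.get(x) == y


@dataclass(frozen=True)
class DimerReport:
    """Result of a self- or pair-dimer check between two primers."""

    score: int
    partner_offset: int
    hump_length: int
    flagged: bool


@dataclass
class QualityReport:
    """Composition and structure report for a single primer."""

    gc_overall: float
    gc_last8_count: int
    has_gc_clamp: bool
    tm: float | None
    self_dimer_score: int = 0
    hairpin_flag: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def three_prime_affinity(a: str, b: str, window: int = 8) -> int:
    """Max weighted complementarity of ``a``'s 3'-terminal window against ``b``.

    ``a``'s last ``window`` bases (read 5'->3') are slid across every
    ungapped antiparallel register of ``b``; at each register the weights of
    Watson-Crick-paired positions are summed (A:T=2, G:C=4) and the maximum
    over registers is returned.  Only ``a``'s 3' end is windowed — scoring
    a-against-b is therefore not symmetric with b-against-a.
    """
    if window > len(a):
        raise ValueError(f"window {window} exceeds primer length {len(a)}")
    a3 = a[-window:]
    b_rev = b[::-1]  # antiparallel geometry: a 5'->3' faces b 3'->5'
    nb = len(b_rev)
    best = 0
    for shift in range(1 - window, nb):
        total = 0
        for i in range(window):
            j = shift + i
            if 0 <= j < nb and _is_pair(a3[i], b_rev[j]):
                total += _PAIR_WEIGHT[(a3[i], b_rev[j])]
        if total > best:
            best = total
    return best


def _best_register(a: str, b: str, window: int) -> int:
    a3 = a[-window:]
    b_rev = b[::-1]
    nb = len(b_rev)
    best, best_shift = -1, 0
    for shift in range(1 - window, nb):
        total = sum(
            _PAIR_WEIGHT[(a3[i], b_rev[shift + i])]
            for i in range(window)
            if 0 <= shift + i < nb and _is_pair(a3[i], b_rev[shift + i]))
        if total > best:
            best, best_shift = total, shift
    return best_shift


def longest_complementary_run(a: str, b: str) -> int:
    """Longest contiguous Watson-Crick run over all ungapped registers of a vs b."""
    b_rev = b[::-1]
    na, nb = len(a), len(b_rev)
    best = 0
    for shift in range(1 - na, nb):
        run = 0
        for i in range(na):
            j = shift + i
            if 0 <= j < nb and _is_pair(a[i], b_rev[j]):
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


def dimer_check(a: str, b: str,
                constraints: DesignConstraints) -> DimerReport:
    """Pair-dimer report; self-dimer is ``dimer_check(p, p, constraints)``."""
    w = constraints.dimer_window
    score = max(three_prime_affinity(a, b, w), three_prime_affinity(b, a, w))
    hump = longest_complementary_run(a, b)
    flagged = (score >= constraints.dimer_score_max
               or hump >= constraints.hump_run_max)
    return DimerReport(
        score=score,
        partner_offset=_best_register(a, b, w),
        hump_length=hump,
        flagged=flagged,
    )


def hairpin_check(p: str, constraints: DesignConstraints) -> bool:
    """True iff ``p`` can fold into a stem-loop.

    A hairpin is an inverted repeat: stem of at least ``hairpin_stem_min``
    whose two halves are separated by a loop of ``hairpin_loop_min`` to
    ``hairpin_loop_max`` unpaired bases.  Existence of any stem >= min is
    equivalent to existence of a stem of exactly min length, so only that
    is scanned.
    """
    m = constraints.hairpin_stem_min
    n = len(p)
    for i in range(n - 2 * m - constraints.hairpin_loop_min + 1):
        stem_rc = reverse_complement(p[i:i + m])
        for loop in range(constraints.hairpin_loop_min,
                          constraints.hairpin_loop_max + 1):
            j = i + m + loop
            if j + m > n:
                break
            if p[j:j + m] == stem_rc:
                return True
    return False


def gc_last8_count(p: str) -> int:
    tail = p[-8:]
    return tail.count("G") + tail.count("C")


def gc_rules_check(p: str, constraints: DesignConstraints) -> QualityReport:
    """Composition rules: overall GC >= gc_min, >=gc_last8_min G/C in the last 8.

    A G/C 3'-terminal base (GC clamp) is recorded as a preference, not a
    failure — clamp-free primers demonstrably still amplify.
    """
    gc = gc_fraction(p)
    last8 = gc_last8_count(p)
    reasons = []
    if gc < constraints.gc_min:
        reasons.append(GC_OVERALL)
    if last8 < constraints.gc_last8_min:
        reasons.append(GC_3PRIME)
    return QualityReport(
        gc_overall=gc,
        gc_last8_count=last8,
        has_gc_clamp=p[-1] in "GC",
        tm=melting_temp(p) if len(p) >= 14 else None,
        reasons=reasons,
    )


def primer_quality(p: str, constraints: DesignConstraints) -> QualityReport:
    """Full single-primer report: composition + hairpin + self-dimer."""
    report = gc_rules_check(p, constraints)
    self_dimer = dimer_check(p, p, constraints)
    report.self_dimer_score = self_dimer.score
    if self_dimer.flagged:
        report.reasons.append(DIMER)
    if hairpin_check(p, constraints):
        report.hairpin_flag = True
        report.reasons.append(HAIRPIN)
    return report


def pair_match(p: str, q: str, mode: str,
               constraints: DesignConstraints) -> bool:
    """Annealing compatibility of a primer pair.

    ``tm`` mode compares estimated melting temperatures; ``length_gc`` mode
    (the long-primer-friendly alternative) requires similar lengths and
    similar GC percentages.
    """
    if mode == "tm":
        return abs(melting_temp(p) - melting_temp(q)) <= constraints.tm_tol
    if mode == "length_gc":
        return (abs(len(p) - len(q)) <= constraints.len_tol
                and abs(100 * gc_fraction(p) - 100 * gc_fraction(q))
                <= constraints.gc_tol_points)
    raise ConfigError(f"unknown pair mode: {mode!r}")
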