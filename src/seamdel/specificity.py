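"""Exact 3'-anchored mis-priming search.

Polymerase extension starts at a primer's 3' terminus, so a secondary site
whose sequence exactly matches the primer's 3'-terminal k-mer can prime
even when full-length similarity is too weak for BLAST/FASTA to report —
the failure mode this exact search replaces those tools for.  Every exact
occurrence of the 3'-terminal k-mer on either strand of the search space is
a hit; the designed annealing site is marked ``intended`` and any other hit
fails the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from .constraints import DesignConstraints
from .errors import HOMOPOLYMER_3PRIME, MISPRIME
from .seqio import reverse_complement

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


@dataclass(frozen=True)
class SpecificityHit:
    """One exact 3'-anchored priming site.

    ``position`` is the 0-based start of the matched k-mer on the template's
    plus strand (for minus-strand hits, the start of the reverse-complement
    occurrence; the primer's 3' terminus sits at ``position``).
    ``matched_len`` is the k-mer match extended maximally toward the
    primer's 5' end.
    """

    template_id: str
    position: int
    strand: str  # '+' or '-'
    matched_len: int
    intended: bool = False


class IntendedSite(NamedTuple):
    template_id: str
    position: int
    strand: str


def _find_all(template: str, motif: str) -> Iterable[int]:
    start = template.find(motif)
    while start != -1:
        yield start
        start = template.find(motif, start + 1)


def anchored_match_scan(primer: str, templates: Mapping[str, str],
                        k: int = 8,
                        intended: IntendedSite | None = None,
                        ) -> list[SpecificityHit]:
    """All exact occurrences of the primer's 3'-terminal k-mer, both strands.

    Each hit's match is extended maximally 5'-ward along the primer to give
    ``matched_len``.  Results are in deterministic (template, strand,
    position) order.
    """
    if len(primer) < k:
        raise ValueError(f"primer shorter than anchor k={k}")
    kmer = primer[-k:]
    kmer_rc = reverse_complement(kmer)
    hits: list[SpecificityHit] = []
    for template_id in sorted(templates):
        template = templates[template_id]
        # plus strand: template[pos:pos+k] == primer[-k:];
        # extend while earlier primer bases keep matching leftward.
        for pos in _find_all(template, kmer):
            length = k
            while (length < len(primer) and pos - (length - k) - 1 >= 0
                   and primer[-(length + 1)]
                   == template[pos - (length - k) - 1]):
                length += 1
            hits.append(SpecificityHit(
                template_id, pos, "+", length,
                intended == IntendedSite(template_id, pos, "+")))
        # minus strand: template[pos:pos+k] == revcomp(primer[-k:]);
        # the primer's 3' terminus faces template position pos and its 5'
        # extension runs rightward on the plus strand.
        for pos in _find_all(template, kmer_rc):
            length = k
            while (length < len(primer) and pos + length < len(template)
                   and _COMPLEMENT[primer[-(length + 1)]]
                   == template[pos + length]):
                length += 1
            hits.append(SpecificityHit(
                template_id, pos, "-", length,
                intended == IntendedSite(template_id, pos, "-")))
    hits.sort(key=lambda h: (h.template_id, h.strand, h.position))
    return hits


def homopolymer_anchor(primer: str, constraints: DesignConstraints) -> bool:
    """True iff the primer's 3'-terminal k-mer sits inside a homopolymeric run.

    A 3' anchor drawn from a run of one base of length >=
    ``homopolymer_min`` cannot uniquely anchor anywhere (prominent in
    homopolymer-rich genomes, and harmless to enforce everywhere), so such
    candidates are disqualified outright.
    """
    k = constraints.mispriming_k
    tail = primer[-k:]
    if len(set(tail)) != 1:
        return False
    base = tail[0]
    run = k
    i = len(primer) - k - 1
    while i >= 0 and primer[i] == base:
        run += 1
        i -= 1
    return run >= constraints.homopolymer_min


class SpecificityResult(NamedTuple):
    passed: bool
    reason: str | None  # MISPRIME, HOMOPOLYMER_3PRIME, or None
    hits: list[SpecificityHit]


def specificity_filter(primer: str, search_space: Mapping[str, str],
                       constraints: DesignConstraints,
                       intended: IntendedSite | None = None,
                       ) -> SpecificityResult:
    """Reject a candidate with any non-intended exact 3'-anchored site.

    The search space defaults (at call sites) to the local area: the target
    locus record plus the marker plasmid.  A homopolymeric 3' anchor is
    rejected regardless of hit count.
    """
    if homopolymer_anchor(primer, constraints):
        return SpecificityResult(False, HOMOPOLYMER_3PRIME, [])
    hits = anchored_match_scan(primer, search_space,
                               k=constraints.mispriming_k,
                               intended=intended)
    off_target = [h for h in hits if not h.intended]
    if off_target:
        return SpecificityResult(False, MISPRIME, hits)
    return SpecificityResult(True, None, hits)
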