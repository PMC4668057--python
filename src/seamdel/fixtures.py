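"""Deterministic synthetic loci and marker plasmids, plus packaged worked examples.

Everything the pipeline needs can be generated here with no downloads.  The
pseudo-random generator is an explicit 64-bit linear congruential generator
(Knuth's MMIX constants) rather than a library RNG: its algorithm is part
of this package's reproducibility contract, so fixture sequences are
bit-identical across platforms and library versions for a given seed.

Synthetic loci emulate flanked-ORF records: i.i.d. bases at a requested GC
fraction, the ORF framed ATG...stop.  They deliberately do not mimic real
genome features beyond GC and optional implanted homopolymers/decoys —
no codon bias, repeats families, or chromatin context.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass

from .errors import ConfigError
from .seqio import LocusRecord, MarkerTemplate, STOP_CODONS, reverse_complement

GENERATOR_VERSION = "lcg64-mmix-v1"

_LCG_A = 6364136223846793005
_LCG_C = 1442695040888963407
_LCG_M = 1 << 64


class Lcg:
    """64-bit LCG (MMIX constants); top 32 bits are the output word."""

    def __init__(self, seed: int):
        self.state = (seed ^ 0x9E3779B97F4A7C15) % _LCG_M
        self._step()
        self._step()

    def _step(self) -> int:
        self.state = (_LCG_A * self.state + _LCG_C) % _LCG_M
        return self.state >> 32

    def random(self) -> float:
        return self._step() / 4294967296.0

    def randint(self, lo: int, hi: int) -> int:
        """Uniform integer in [lo, hi]."""
        return lo + self._step() % (hi - lo + 1)

    def choice(self, items):
        return items[self._step() % len(items)]

    def base(self, gc: float) -> str:
        """One base: G/C with probability gc (split evenly), else A/T."""
        if self.random() < gc:
            return "G" if self.random() < 0.5 else "C"
        return "A" if self.random() < 0.5 else "T"

    def seq(self, length: int, gc: float) -> str:
        return "".join(self.base(gc) for _ in range(length))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic locus; equal specs give identical records."""

    seed: int
    flank_len: int = 1000
    orf_len: int = 900
    gc: float = 0.40
    locus_id: str = ""
    # (record_position, octamer) overwrites for mis-priming scenarios
    decoys: tuple[tuple[int, str], ...] = ()
    # (record_position, base, run_length) overwrites
    homopolymers: tuple[tuple[int, str, int], ...] = ()

    def resolved_id(self) -> str:
        return self.locus_id or f"SYN{self.seed:06d}"


@dataclass(frozen=True)
class MarkerSpec:
    """Recipe for a synthetic marker plasmid."""

    seed: int
    plasmid_len: int = 4000
    amplicon_len: int = 1140
    gc: float = 0.45
    anchor_pair_count: int = 4
    marker_name: str = ""

    def resolved_name(self) -> str:
        return self.marker_name or f"pSYN{self.seed:04d}"


_BOUNDARY_GUARD = 8  # nt either side of each ORF boundary kept insert-free


def generate_locus(spec: FixtureSpec) -> LocusRecord:
    """Pseudorandom locus: flank + (ATG ... stop) ORF + flank at requested GC."""
    if spec.orf_len < 50:
        raise ConfigError(f"orf_len {spec.orf_len} too short to frame and "
                          "carry a right-homology segment")
    if not 0.0 < spec.gc < 1.0:
        raise ConfigError("gc must be strictly between 0 and 1")
    rng = Lcg(spec.seed)
    upstream = rng.seq(spec.flank_len, spec.gc)
    interior = rng.seq(spec.orf_len - 6, spec.gc)
    stop = rng.choice(STOP_CODONS)
    orf = "ATG" + interior + stop
    downstream = rng.seq(spec.flank_len, spec.gc)
    locus = LocusRecord(spec.resolved_id(), upstream, orf, downstream)
    for pos, base, run in spec.homopolymers:
        locus = _overwrite(locus, pos, base * run)
    for pos, octamer in spec.decoys:
        locus = implant_decoy(locus, octamer, pos)
    return locus


def _overwrite(locus: LocusRecord, pos: int, insert: str) -> LocusRecord:
    record = locus.record
    if not (0 <= pos and pos + len(insert) <= len(record)):
        raise ConfigError(f"overwrite at {pos} falls outside the record")
    new = record[:pos] + insert + record[pos + len(insert):]
    f, o = locus.flank_len, locus.orf_len
    return LocusRecord(locus.locus_id, new[:f], new[f:f + o], new[f + o:])


def implant_decoy(locus: LocusRecord, octamer: str, where: int) -> LocusRecord:
    """Overwrite the record with a mis-priming decoy octamer at ``where``.

    Placements that touch the ORF boundary guard regions are refused: they
    would silently change the repeat/homology segments the design copies.
    """
    for boundary in (locus.orf_start, locus.orf_end):
        if (where < boundary + _BOUNDARY_GUARD
                and where + len(octamer) > boundary - _BOUNDARY_GUARD):
            raise ConfigError(
                f"decoy at {where} overlaps the ORF boundary guard "
                f"around {boundary}")
    return _overwrite(locus, where, octamer)


def _unique_octamer(plasmid: str, octamer: str) -> bool:
    rc = reverse_complement(octamer)
    n = plasmid.count(octamer) + plasmid.count(rc)
    if octamer == rc:
        n //= 2
    return n == 1


def _viable_positions(plasmid: str, edge: int, count: int,
                      forward: bool, stagger: int = 24,
                      search: int = 40) -> list[int]:
    """Anchor coordinates near an amplicon edge that a curator would accept.

    For a forward anchor at start ``s`` the design anneals its chimeric
    primer over ``plasmid[s : s+20]`` and extends from an octamer ending
    at s+20; for a reverse anchor ending at ``e`` the primer's octamer is
    the reverse complement of ``plasmid[e-18 : e-10]``.  A position is
    viable when that octamer is unique in the plasmid (both strands) and
    carries >= 2 G/C.  Candidates are staggered so the chosen anchors have
    distinct 3' octamers.
    """
    out: list[int] = []
    cursor = edge
    scanned = 0
    while len(out) < count and scanned <= search * count:
        if forward:
            octamer = plasmid[cursor + 12:cursor + 20]
        else:
            octamer = reverse_complement(plasmid[cursor - 18:cursor - 10])
        if (octamer.count("G") + octamer.count("C") >= 2
                and _unique_octamer(plasmid, octamer)):
            out.append(cursor)
            cursor += stagger if forward else -stagger
        else:
            cursor += 1 if forward else -1
        scanned += 1
    if len(out) < count:
        raise ConfigError("could not curate enough viable anchor positions")
    return out


def generate_marker(spec: MarkerSpec) -> MarkerTemplate:
    """Circular pseudorandom plasmid with a marker amplicon region.

    Layout: a marker region of ``amplicon_len`` (default 1140 bp, so a
    designed PCR2 product lands near 1.25 kb), four staggered anchor pairs
    inside it, and two 34 bp palindromic forbidden intervals immediately
    flanking it (recombinase-site stand-ins that no amplicon may include).
    Universal marker-internal confirmation primers are drawn from the
    amplicon interior.
    """
    if spec.anchor_pair_count < 1:
        raise ConfigError("anchor_pair_count must be >= 1")
    rng = Lcg(spec.seed)
    amp_start = 1200
    amp_end = amp_start + spec.amplicon_len
    if amp_end + 200 > spec.plasmid_len:
        raise ConfigError("plasmid too short for the amplicon layout")
    plasmid = list(rng.seq(spec.plasmid_len, spec.gc))

    def palindrome(length: int) -> str:
        half = rng.seq(length // 2, 0.5)
        return half + reverse_complement(half)

    lox_left = (amp_start - 50, amp_start - 16)
    lox_right = (amp_end + 16, amp_end + 50)
    plasmid[lox_left[0]:lox_left[1]] = palindrome(34)
    plasmid[lox_right[0]:lox_right[1]] = palindrome(34)
    seq = "".join(plasmid)

    # Real marker configs are curated: each anchor pair was chosen so its
    # chimeric 3' anchors actually work.  Emulate that curation: accept
    # only anchor positions whose 3'-terminal octamer is unique on both
    # plasmid strands and GC-adequate, staggered so pairs differ.
    pairs = tuple(zip(
        _viable_positions(seq, amp_start, spec.anchor_pair_count,
                          forward=True),
        _viable_positions(seq, amp_end, spec.anchor_pair_count,
                          forward=False)))
    name = spec.resolved_name()
    rin_site = amp_start + 300
    fin_site = amp_end - 322
    return MarkerTemplate(
        marker_name=name,
        plasmid=seq,
        anchor_pairs=pairs,
        forbidden_intervals=(lox_left, lox_right),
        circular=True,
        rin_cass=reverse_complement(seq[rin_site:rin_site + 22]),
        fin_cass=seq[fin_site:fin_site + 22],
    )


def batch_locus_specs(n: int, base_seed: int = 1,
                      flank_len: int = 1000) -> list[FixtureSpec]:
    """Specs for a design batch: seeds base_seed..base_seed+n-1.

    Each locus draws its own ORF length (300-1500 nt, codon-granular) and
    GC fraction (0.35-0.45) from its seed, emulating the spread of real
    flanked-ORF collections.
    """
    specs = []
    for seed in range(base_seed, base_seed + n):
        rng = Lcg(seed * 2654435761 % (1 << 31))
        orf_len = 300 + 3 * rng.randint(0, 400)
        gc = 0.35 + 0.10 * rng.random()
        specs.append(FixtureSpec(seed=seed, flank_len=flank_len,
                                 orf_len=orf_len, gc=round(gc, 4)))
    return specs


# --- packaged worked examples ----------------------------------------------

WORKED_EXAMPLE_ORFS = ("YAL023C", "YBR052C", "YDL174C", "YIR013C")
PRIMER_ROLES = ("PCR1_F", "PCR1_R", "PCR2_F", "PCR2_R")


@dataclass(frozen=True)
class WorkedExampleFixture:
    """The four published worked-example primer sets.

    ``primers[orf][role]`` is the printed sequence; ``segments[(orf, role)]``
    splits chimeric primers into their annotated parts (overlap/R/marker for
    PCR2_F, target/marker for PCR2_R).  ``cross_row_quirk`` records the two
    ORFs whose printed PCR1 rows reverse-complement-match the *other* row's
    PCR2_F overlap; structural cross-row tests should use the other two.
    """

    primers: dict
    segments: dict
    cross_row_quirk: tuple[str, str] = ("YAL023C", "YBR052C")


def worked_example_fixture() -> WorkedExampleFixture:
    """Load the packaged worked-example primer table."""
    primers: dict[str, dict[str, str]] = {orf: {} for orf in WORKED_EXAMPLE_ORFS}
    segments: dict[tuple[str, str], tuple[str, ...]] = {}
    path = importlib.resources.files("seamdel.data") / "worked_example_primers.csv"
    with path.open() as handle:
        for row in csv.DictReader(handle):
            orf, role, seq = row["orf"], row["role"], row["sequence"]
            primers[orf][role] = seq
            if row["segments"]:
                lengths = [int(x) for x in row["segments"].split(":")]
                parts, at = [], 0
                for ln in lengths:
                    parts.append(seq[at:at + ln])
                    at += ln
                if at != len(seq):
                    raise ConfigError(
                        f"segment lengths for {orf} {role} do not tile "
                        f"the sequence ({at} != {len(seq)})")
                segments[(orf, role)] = tuple(parts)
    return WorkedExampleFixture(primers=primers, segments=segments)


def longest_common_suffix(seqs) -> str:
    """Longest string that is a suffix of every input."""
    seqs = list(seqs)
    if not seqs:
        return ""
    n = min(len(s) for s in seqs)
    out = 0
    for i in range(1, n + 1):
        ch = seqs[0][-i]
        if all(s[-i] == ch for s in seqs):
            out = i
        else:
            break
    return seqs[0][len(seqs[0]) - out:] if out else ""


def rc_prefix_overlap(chimeric: str, partner: str) -> int:
    """Length of the longest prefix of ``chimeric`` whose reverse complement
    is a prefix of ``partner`` (how a SOE overlap is recovered from printed
    primers)."""
    best = 0
    for n in range(1, min(len(chimeric), len(partner)) + 1):
        if reverse_complement(chimeric[:n]) == partner[:n]:
            best = n
    return best
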