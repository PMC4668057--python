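"""Nucleotide sequence primitives, locus/marker parsing, and primer-library I/O.

Sequences are plain uppercase ``str`` over {A,C,G,T}. ``N`` is tolerated at
parse time (real flank files contain them) but any candidate primer or
homology segment touching an N is rejected downstream with the
``NONSTANDARD_BASE`` reason code.

Coordinates are 0-based, half-open, relative to each locus record, which is
stored in the deleted element's sense orientation: the ORF occupies
``[flank_len, flank_len + orf_len)``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

from .errors import (
    NONSTANDARD_BASE,
    FLANK_TOO_SHORT,
    AlphabetError,
    DegenerateBaseError,
    FormatError,
)

STRICT_ALPHABET = frozenset("ACGT")
PARSE_ALPHABET = frozenset("ACGTN")
STOP_CODONS = ("TAA", "TAG", "TGA")


def normalize_seq(text: str, allow_n: bool = False) -> str:
    """Uppercase, strip whitespace, and validate a raw sequence string.

    With ``allow_n=False`` (the design-input context) an ``N`` raises
    :class:`DegenerateBaseError`; any other non-ACGTN character always
    raises :class:`AlphabetError`.
    """
    if not text or not text.strip():
        raise AlphabetError("empty sequence")
    seq = "".join(text.split()).upper()
    bad = set(seq) - PARSE_ALPHABET
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} in sequence")
    if not allow_n and "N" in seq:
        raise DegenerateBaseError(
            f"{NONSTANDARD_BASE}: N not allowed in design input")
    return seq


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement (delegates to Biopython)."""
    return str(_bio_revcomp(s))


def gc_fraction(s: str) -> float:
    """(#G + #C) / length, in [0, 1]."""
    if not s:
        raise ValueError("gc_fraction of empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def melting_temp(s: str) -> float:
    """Length/GC melting-temperature estimate for long oligos (>=14 nt).

    Tm = 81.5 + 0.41 * GC% - 675 / N.  Nearest-neighbour models are tuned
    for short oligos and extrapolate poorly to the 30-100-mers used here;
    this classic salt-free estimate is monotone in GC at fixed length,
    which is all pairing decisions need.
    """
    n = len(s)
    if n < 14:
        raise ValueError(f"melting_temp requires >=14 nt, got {n}")
    return 81.5 + 0.41 * (100.0 * gc_fraction(s)) - 675.0 / n


@dataclass(frozen=True)
class LocusRecord:
    """A deletion target: upstream flank + ORF (element to excise) + downstream flank.

    Stored in the element's sense orientation; minus-strand genes must be
    reverse-complemented upstream of this tool (flanked-ORF exports already
    do this).
    """

    locus_id: str
    upstream: str
    orf: str
    downstream: str

    @property
    def flank_len(self) -> int:
        return len(self.upstream)

    @property
    def orf_len(self) -> int:
        return len(self.orf)

    @property
    def record(self) -> str:
        """The full record: upstream + orf + downstream."""
        return self.upstream + self.orf + self.downstream

    @property
    def orf_start(self) -> int:
        return len(self.upstream)

    @property
    def orf_end(self) -> int:
        return len(self.upstream) + len(self.orf)


@dataclass(frozen=True)
class MarkerTemplate:
    """Marker plasmid plus the configuration that constrains marker amplicons.

    ``anchor_pairs`` are (forward_anchor_start, reverse_anchor_end) 0-based
    half-open plasmid intervals defining the candidate marker amplicons;
    ``forbidden_intervals`` are regions (e.g. palindromic loxP sites) that
    no amplicon may touch.  ``rin_cass``/``fin_cass`` are the universal
    marker-internal colony-PCR primers.
    """

    marker_name: str
    plasmid: str
    anchor_pairs: tuple[tuple[int, int], ...]
    forbidden_intervals: tuple[tuple[int, int], ...] = ()
    circular: bool = True
    rin_cass: str = ""
    fin_cass: str = ""

    def __post_init__(self):
        if not self.anchor_pairs:
            raise ValueError("anchor_pairs must be non-empty")
        for start, end in self.anchor_pairs:
            if not (0 <= start < end <= len(self.plasmid)):
                raise ValueError(f"anchor pair ({start},{end}) out of range")

    def amplicon(self, pair_index: int) -> str:
        start, end = self.anchor_pairs[pair_index]
        return self.plasmid[start:end]


class ParseFailure(NamedTuple):
    locus_id: str
    reason_code: str
    detail: str


class ParseResult(NamedTuple):
    records: list[LocusRecord]
    failures: list[ParseFailure]


def parse_flanked_orf_fasta(source, flank_len: int) -> ParseResult:
    """Split flanked-ORF FASTA records into (upstream, orf, downstream).

    Each record is assumed to be ``flank_len`` nt of upstream sequence, the
    element itself, then ``flank_len`` nt of downstream sequence.  Records
    too short to contain both flanks are recorded as ``FLANK_TOO_SHORT``
    failures and parsing continues.  The locus id is the first header token.
    """
    records: list[LocusRecord] = []
    failures: list[ParseFailure] = []
    for rec in SeqIO.parse(source, "fasta"):
        locus_id = rec.id
        try:
            seq = normalize_seq(str(rec.seq), allow_n=True)
        except AlphabetError as exc:
            failures.append(ParseFailure(locus_id, NONSTANDARD_BASE, str(exc)))
            continue
        if len(seq) <= 2 * flank_len:
            failures.append(ParseFailure(
                locus_id, FLANK_TOO_SHORT,
                f"record {len(seq)} nt cannot hold two {flank_len} nt flanks"))
            continue
        records.append(LocusRecord(
            locus_id=locus_id,
            upstream=seq[:flank_len],
            orf=seq[flank_len:-flank_len],
            downstream=seq[-flank_len:],
        ))
    return ParseResult(records, failures)


def read_plasmid(source, fmt: str = "fasta") -> tuple[str, str]:
    """Read the first record of a FASTA/GenBank plasmid file -> (id, sequence)."""
    for rec in SeqIO.parse(source, fmt):
        return rec.id, normalize_seq(str(rec.seq), allow_n=True)
    raise FormatError("no sequence records found in plasmid file")


# --- primer library CSV ---------------------------------------------------

LIBRARY_COLUMNS = [
    "locus_id", "PCR1_F", "PCR1_R", "PCR2_F", "PCR2_R",
    "CPS_A", "CPS_D", "RinCass", "FinCass",
    "PCR1_size_bp", "PCR2_size_bp", "PCR3_size_bp",
    "PCR3_mass_ng_per_50ul", "status", "failure_reason",
]

STATUS_DESIGNED = "designed"
STATUS_FAILED = "failed"


@dataclass
class PrimerLibraryRow:
    """One locus row of the primer-library CSV (empty strings where absent)."""

    locus_id: str
    PCR1_F: str = ""
    PCR1_R: str = ""
    PCR2_F: str = ""
    PCR2_R: str = ""
    CPS_A: str = ""
    CPS_D: str = ""
    RinCass: str = ""
    FinCass: str = ""
    PCR1_size_bp: int | None = None
    PCR2_size_bp: int | None = None
    PCR3_size_bp: int | None = None
    PCR3_mass_ng_per_50ul: float | None = None
    status: str = STATUS_FAILED
    failure_reason: str = ""

    def __post_init__(self):
        if self.status == STATUS_DESIGNED:
            missing = [c for c in ("PCR1_F", "PCR1_R", "PCR2_F", "PCR2_R")
                       if not getattr(self, c)]
            if missing:
                raise ValueError(
                    f"designed row {self.locus_id} missing {missing}")
            for c in ("PCR1_size_bp", "PCR2_size_bp", "PCR3_size_bp"):
                v = getattr(self, c)
                if not v or v <= 0:
                    raise ValueError(
                        f"designed row {self.locus_id} has invalid {c}={v}")


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_primer_library(rows: Iterable[PrimerLibraryRow], stream: TextIO,
                         header_comments: Sequence[str] = ()) -> None:
    """Write rows as CSV; ``header_comments`` become leading ``#`` lines."""
    for line in header_comments:
        stream.write(f"# {line}\n")
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(LIBRARY_COLUMNS)
    for row in rows:
        writer.writerow([_cell(getattr(row, col)) for col in LIBRARY_COLUMNS])


def read_primer_library(stream: TextIO) -> list[PrimerLibraryRow]:
    """Read a primer-library CSV back into rows (inverse of write)."""
    lines = [ln for ln in stream if not ln.startswith("#")]
    reader = csv.reader(io.StringIO("".join(lines)))
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty primer library") from None
    if header != LIBRARY_COLUMNS:
        extra = set(header) - set(LIBRARY_COLUMNS)
        missing = set(LIBRARY_COLUMNS) - set(header)
        raise FormatError(
            f"primer library schema mismatch: unexpected={sorted(extra)} "
            f"missing={sorted(missing)}")
    int_cols = {"PCR1_size_bp", "PCR2_size_bp", "PCR3_size_bp"}
    rows = []
    for raw in reader:
        if not raw:
            continue
        kwargs = {}
        for col, cell in zip(LIBRARY_COLUMNS, raw):
            if col in int_cols:
                kwargs[col] = int(cell) if cell else None
            elif col == "PCR3_mass_ng_per_50ul":
                kwargs[col] = float(cell) if cell else None
            else:
                kwargs[col] = cell
        rows.append(PrimerLibraryRow(**kwargs))
    return rows
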