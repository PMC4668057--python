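"""Failure reason codes and exception types shared across the design pipeline.

Every way a locus can fail design is classified under exactly one reason
code, so batch runs can report a failure histogram instead of a stack trace.
"""

from __future__ import annotations

# Reason codes, ordered roughly by pipeline depth (later == further along).
NO_P2_CANDIDATE = "NO_P2_CANDIDATE"
NO_P1_MATCH = "NO_P1_MATCH"
NO_MARKER_PAIR = "NO_MARKER_PAIR"
P3_TOO_LONG = "P3_TOO_LONG"
GC_OVERALL = "GC_OVERALL"
GC_3PRIME = "GC_3PRIME"
DIMER = "DIMER"
HAIRPIN = "HAIRPIN"
MISPRIME = "MISPRIME"
HOMOPOLYMER_3PRIME = "HOMOPOLYMER_3PRIME"
ORF_TOO_SHORT = "ORF_TOO_SHORT"
FLANK_TOO_SHORT = "FLANK_TOO_SHORT"
NONSTANDARD_BASE = "NONSTANDARD_BASE"

REASON_CODES = frozenset({
    NO_P2_CANDIDATE, NO_P1_MATCH, NO_MARKER_PAIR, P3_TOO_LONG,
    GC_OVERALL, GC_3PRIME, DIMER, HAIRPIN, MISPRIME, HOMOPOLYMER_3PRIME,
    ORF_TOO_SHORT, FLANK_TOO_SHORT, NONSTANDARD_BASE,
})


class SeamdelError(Exception):
    """Base class for all package errors."""


class AlphabetError(SeamdelError):
    """Sequence contains a character outside the accepted alphabet."""


class DegenerateBaseError(SeamdelError):
    """An N (or other degenerate base) appeared in a design-input context."""

    code = NONSTANDARD_BASE


class FormatError(SeamdelError):
    """A file does not conform to the expected schema."""


class ConfigError(SeamdelError):
    """Invalid or inconsistent configuration."""


class DesignError(SeamdelError):
    """A design step failed with a classified reason code."""

    def __init__(self, code: str, detail: str = ""):
        if code not in REASON_CODES:
            raise ValueError(f"unknown reason code: {code}")
        self.code = code
        self.detail = detail
        super().__init__(f"{code}: {detail}" if detail else code)


class SimulationError(SeamdelError):
    """An in-silico verification stage failed."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        self.detail = detail
        super().__init__(f"{stage}: {detail}" if detail else stage)
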