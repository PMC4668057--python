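"""Every numeric rule of the design algorithm, with defaults, as one config object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Mapping

from .errors import ConfigError

PAIR_MODES = ("tm", "length_gc")


@dataclass(frozen=True)
class DesignConstraints:
    """All tunable rules of the cassette-design algorithm.

    Lengths are nt, GC values are fractions unless the name says points.
    Defaults follow the published deletion workflow: a 500-1000 bp upstream
    amplicon, 30-60 nt PCR1 primers, a chimeric PCR2 forward primer capped
    at 100 nt (25-40 nt SOE overlap + 40 nt repeat + 17-20 nt marker
    anchor), a 44 nt gene 3'-end homology with an 18 nt marker anchor on
    the PCR2 reverse primer, >=30% overall GC with >=2 G/C among the last
    8 bases, and an exact 8-mer 3'-anchored mis-priming search.
    """

    # PCR1 geometry
    amplicon_min: int = 500
    amplicon_max: int = 1000
    p1_len_min: int = 30
    p1_len_max: int = 60
    p2_len_min: int = 30
    p2_len_max: int = 60
    # chimeric primer geometry
    p3_max_len: int = 100
    overlap_len: int = 25
    overlap_max: int = 40
    r_len: int = 40
    marker5_min: int = 17
    marker5_max: int = 20
    marker3_len: int = 18
    right_homology_len: int = 44
    # composition rules
    gc_min: float = 0.30
    gc_last8_min: int = 2
    # pairing rules
    pair_mode: str = "length_gc"
    tm_tol: float = 3.0
    len_tol: int = 10
    gc_tol_points: float = 10.0
    # dimer / hairpin rules
    dimer_window: int = 8
    dimer_score_max: int = 24
    hump_run_max: int = 8
    hairpin_stem_min: int = 6
    hairpin_loop_min: int = 3
    hairpin_loop_max: int = 8
    # specificity rules
    mispriming_k: int = 8
    homopolymer_min: int = 8
    # in-silico verification
    sim_anchor: int = 12
    soe_min_overlap: int = 20
    integration_min_arm: int = 40
    popout_min_repeat: int = 20
    max_product: int = 10000
    # confirmation primers
    conf_len_min: int = 18
    conf_len_max: int = 25
    conf_offset_min: int = 150
    conf_offset_max: int = 300

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        c = self
        checks = [
            (0 < c.amplicon_min <= c.amplicon_max, "amplicon range empty"),
            (0 < c.p1_len_min <= c.p1_len_max, "p1 length range empty"),
            (0 < c.p2_len_min <= c.p2_len_max, "p2 length range empty"),
            (0 < c.marker5_min <= c.marker5_max, "marker5 range empty"),
            (c.overlap_len <= c.overlap_max, "overlap_len > overlap_max"),
            (c.overlap_len + c.r_len + c.marker5_min <= c.p3_max_len,
             "minimal chimeric primer already exceeds p3_max_len"),
            (0 <= c.gc_min <= 1, "gc_min outside [0,1]"),
            (0 <= c.gc_last8_min <= 8, "gc_last8_min outside [0,8]"),
            (c.pair_mode in PAIR_MODES, f"pair_mode must be one of {PAIR_MODES}"),
            (c.mispriming_k >= 1, "mispriming_k must be >=1"),
            (c.dimer_window >= 1, "dimer_window must be >=1"),
            (c.hairpin_loop_min <= c.hairpin_loop_max, "hairpin loop range empty"),
            (c.marker3_len > 0 and c.right_homology_len > 0, "p4 segments empty"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def with_overrides(self, **overrides) -> "DesignConstraints":
        return replace(self, **overrides)

    def to_mapping(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "DesignConstraints":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown constraint keys: {sorted(unknown)}")
        return cls(**dict(mapping))


DEFAULT_CONSTRAINTS = DesignConstraints()
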