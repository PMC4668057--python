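"""Design a deletion-cassette primer set for one synthetic locus.

Builds a pseudo-random flanked-ORF locus and marker plasmid, runs the
design algorithm, and prints the four interdependent primers with their
chimeric segment structure and predicted product sizes.
"""

from seamdel import (
    DEFAULT_CONSTRAINTS,
    FixtureSpec,
    MarkerSpec,
    generate_locus,
    generate_marker,
    plan_cassette,
)
from seamdel.design import design_target

locus = generate_locus(FixtureSpec(seed=2, flank_len=1000, orf_len=900,
                                   gc=0.40))
marker = generate_marker(MarkerSpec(seed=1))
primer_set = design_target(locus, marker, DEFAULT_CONSTRAINTS)

print(f"locus {locus.locus_id}: {locus.orf_len} nt ORF, "
      f"{locus.flank_len} nt flanks")
print(f"PCR1_F ({len(primer_set.p1)} nt): {primer_set.p1}")
print(f"PCR1_R ({len(primer_set.p2)} nt): {primer_set.p2}")
overlap, r, marker5 = primer_set.p3_segments
print(f"PCR2_F ({len(primer_set.p3)} nt): "
      f"[overlap {len(overlap)}][R {len(r)}][marker {len(marker5)}]")
print(f"       {primer_set.p3}")
print(f"PCR2_R ({len(primer_set.p4)} nt): "
      f"[gene-3' {len(primer_set.p4_segments[0])}]"
      f"[marker {len(primer_set.p4_segments[1])}]")
print(f"       {primer_set.p4}")
print(f"marker amplicon: anchor pair {primer_set.marker_pair_id}")

plan = plan_cassette(primer_set, locus, marker)
print(f"\npredicted sizes: PCR1 {plan.pcr1_size} bp, PCR2 {plan.pcr2_size} bp,"
      f" PCR3 {plan.pcr3_size} bp")
print(f"PCR3 = PCR1 + PCR2 - overlap ({plan.overlap_len} nt): "
      f"{plan.pcr1_size} + {plan.pcr2_size} - {plan.overlap_len} "
      f"= {plan.pcr3_size}")
# The PCR1 amplicon sits immediately upstream of the ORF; the cassette
# carries the 40 nt repeat R so the marker can later pop out scar-free.
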