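"""Inspect the packaged four-gene worked-example primer table.

The packaged table carries the 16 primers of four real deletion designs.
This script recovers the chimeric structure from the raw sequences alone:
the SOE overlap (reverse complement of the PCR1 reverse primer's 5' end),
the 40 nt repeat, the marker anchor, and the 18 nt marker homology shared
by every PCR2 reverse primer.
"""

from seamdel import worked_example_fixture
from seamdel.fixtures import longest_common_suffix, rc_prefix_overlap

t1 = worked_example_fixture()

suffix = longest_common_suffix(
    [t1.primers[orf]["PCR2_R"] for orf in sorted(t1.primers)])
print(f"shared PCR2_R 3' marker homology: {suffix} ({len(suffix)} nt)")

for orf in sorted(t1.primers):
    p3 = t1.primers[orf]["PCR2_F"]
    p2 = t1.primers[orf]["PCR1_R"]
    overlap = rc_prefix_overlap(p3, p2)
    marker_seg = len(p3) - overlap - 40
    note = " (cross-row quirk)" if orf in t1.cross_row_quirk else ""
    print(f"{orf}: PCR2_F {len(p3)} nt = "
          f"overlap {overlap} + R 40 + marker {marker_seg}{note}")
# For YAL023C/YBR052C the printed PCR1 rows pair with the *other* gene's
# chimeric overlap, so their own-row overlap recovery reads 0; the two
# clean rows decompose as 25 + 40 + 17.
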