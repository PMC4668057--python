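"""Render a per-design wet-lab protocol sheet as plain text.

The thermocycling programs, primer/template amounts and ratios are fixed
workflow facts (the outer primers 1 and 4 are used in 10-fold excess to
deplete the inner primers 2 and 3 so that crude products can be fused
without purification); only the sequences, sizes and calculated masses are
design-specific.
"""

from __future__ import annotations

from .design import CassettePlan, PrimerSet

_SHEET = """\
Seamless deletion protocol — {locus_id}
=======================================

Primers (5'-3')
  PCR1_F (primer 1, excess): {p1}
  PCR1_R (primer 2, limiting): {p2}
  PCR2_F (primer 3, limiting; chimeric overlap|R|marker): {p3}
  PCR2_R (primer 4, excess; chimeric target|marker): {p4}
  CPS_A: {cps_a}
  CPS_D: {cps_d}
  RinCass: {rin_cass}
  FinCass: {fin_cass}

Expected products
  PCR1: {pcr1_size} bp (~{pcr1_mass} ng per 50 ul)
  PCR2: {pcr2_size} bp (~{pcr2_mass} ng per 50 ul)
  PCR3 (fused cassette): {pcr3_size} bp (~{pcr3_mass} ng per 50 ul)

1. PCR1: 100 pmol PCR1_F, 10 pmol PCR1_R, 0.5 ug purified genomic DNA.
2. PCR2: 10 pmol PCR2_F, 100 pmol PCR2_R, 80 pg marker plasmid DNA.
3. Run PCR1 and PCR2 simultaneously: 94 C 20 s; touchdown 65->60 C over
   5 cycles; then 25 cycles of 94 C 20 s, 58 C 30 s, 68 C 120 s.
4. Verify PCR1/PCR2 on a 1% agarose gel against the sizes above.
5. PCR3 (SOE): 1 ul each of crude PCR1 and PCR2 product (ideally ~50 ng
   each). 10 cycles of 94 C 20 s, 52 C 30 s, 68 C 150 s; then add
   100 pmol each of PCR1_F and PCR2_R and run 20 cycles of 94 C 20 s,
   58 C 30 s, 68 C 150 s; final extension 68 C 5 min.
6. Verify PCR3 on a 1% gel; compare against the calculated mass above.
7. Transform with 0.5-5 ug of PCR3 product; select on marker dropout
   medium.
8. Verify integration by colony PCR with CPS_A x RinCass (product exists
   only on the integrated locus).
9. Counter-select on 5-FOA medium to pop the marker out through the
   repeats.
10. Confirm the seamless deletion by colony PCR with CPS_A x CPS_D and
    sequence the product: it should equal upstream + downstream exactly,
    i.e. shrink by the ORF length relative to wild type.
"""


def render_protocol(primer_set: PrimerSet, plan: CassettePlan) -> str:
    """Fill the protocol sheet for one designed locus."""
    return _SHEET.format(
        locus_id=primer_set.locus_id,
        p1=primer_set.p1, p2=primer_set.p2,
        p3=primer_set.p3, p4=primer_set.p4,
        cps_a=primer_set.cps_a or "(not designed: insufficient flank)",
        cps_d=primer_set.cps_d or "(not designed: insufficient flank)",
        rin_cass=primer_set.rin_cass or "-", fin_cass=primer_set.fin_cass or "-",
        pcr1_size=plan.pcr1_size, pcr1_mass=plan.pcr1_mass_ng,
        pcr2_size=plan.pcr2_size, pcr2_mass=plan.pcr2_mass_ng,
        pcr3_size=plan.pcr3_size, pcr3_mass=plan.pcr3_mass_ng,
    )
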