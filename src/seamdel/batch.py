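"""Batch orchestration: design many loci, build library rows, verify libraries."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Iterable, Sequence

from .constraints import DesignConstraints, DEFAULT_CONSTRAINTS
from .design import (
    DesignFailure,
    PrimerSet,
    design_target,
    plan_cassette,
    product_mass_ng,
)
from .seqio import (
    LocusRecord,
    MarkerTemplate,
    PrimerLibraryRow,
    STATUS_DESIGNED,
    STATUS_FAILED,
)
from .simulate import VerificationReport, verify_seamless


@dataclass
class BatchResult:
    rows: list[PrimerLibraryRow]
    primer_sets: dict[str, PrimerSet]
    failures: list[DesignFailure]

    @property
    def n_designed(self) -> int:
        return len(self.primer_sets)

    def failure_histogram(self) -> Counter:
        return Counter(f.reason_code for f in self.failures)

    def summary(self) -> str:
        hist = ", ".join(f"{code}={n}" for code, n
                         in sorted(self.failure_histogram().items()))
        return (f"designed {self.n_designed}/{len(self.rows)} loci"
                + (f"; failures: {hist}" if hist else ""))


def row_for_set(primer_set: PrimerSet, locus: LocusRecord,
                marker: MarkerTemplate) -> PrimerLibraryRow:
    plan = plan_cassette(primer_set, locus, marker)
    return PrimerLibraryRow(
        locus_id=primer_set.locus_id,
        PCR1_F=primer_set.p1, PCR1_R=primer_set.p2,
        PCR2_F=primer_set.p3, PCR2_R=primer_set.p4,
        CPS_A=primer_set.cps_a, CPS_D=primer_set.cps_d,
        RinCass=primer_set.rin_cass, FinCass=primer_set.fin_cass,
        PCR1_size_bp=plan.pcr1_size, PCR2_size_bp=plan.pcr2_size,
        PCR3_size_bp=plan.pcr3_size,
        PCR3_mass_ng_per_50ul=product_mass_ng(plan.pcr3_size),
        status=STATUS_DESIGNED,
    )


def design_batch(loci: Iterable[LocusRecord], marker: MarkerTemplate,
                 constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
                 ) -> BatchResult:
    """Design every locus; one library row per locus, failures classified."""
    rows: list[PrimerLibraryRow] = []
    sets: dict[str, PrimerSet] = {}
    failures: list[DesignFailure] = []
    for locus in loci:
        outcome = design_target(locus, marker, constraints)
        if isinstance(outcome, PrimerSet):
            sets[locus.locus_id] = outcome
            rows.append(row_for_set(outcome, locus, marker))
        else:
            failures.append(outcome)
            rows.append(PrimerLibraryRow(
                locus_id=locus.locus_id, status=STATUS_FAILED,
                failure_reason=outcome.reason_code))
    return BatchResult(rows=rows, primer_sets=sets, failures=failures)


def verify_library(rows: Sequence[PrimerLibraryRow],
                   loci: Iterable[LocusRecord], marker: MarkerTemplate,
                   constraints: DesignConstraints = DEFAULT_CONSTRAINTS,
                   ) -> list[VerificationReport]:
    """Verify each designed row against its locus from the sequences alone."""
    by_id = {locus.locus_id: locus for locus in loci}
    reports = []
    for row in rows:
        if row.status != STATUS_DESIGNED:
            continue
        locus = by_id.get(row.locus_id)
        if locus is None:
            reports.append(VerificationReport(
                locus_id=row.locus_id, seamless=False,
                stage_failed="input", detail="locus sequence not provided"))
            continue
        primers = SimpleNamespace(p1=row.PCR1_F, p2=row.PCR1_R,
                                  p3=row.PCR2_F, p4=row.PCR2_R)
        reports.append(verify_seamless(locus, primers, marker, constraints))
    return reports
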