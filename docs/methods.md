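# Methods

## The deletion geometry

A target is a flanked record `upstream | ORF | downstream` in the ORF's
sense orientation (minus-strand genes must be reverse-complemented before
input, as flanked-ORF genome exports already do). The deletion cassette
assembled by the three PCRs is

    [upstream window (500–1000 bp)] [R (40 nt)] [marker amplicon] [ORF 3′ end (44 nt)]

where `R` is copied from the first 40 nt of the downstream flank. After
double-crossover integration the locus reads
`upstream ⊕ R ⊕ marker ⊕ ORF-3′ ⊕ downstream`; because the downstream
flank itself begins with `R`, the marker now sits between two direct
copies of `R`. Counter-selection favours recombination between the copies,
which excises `marker ⊕ ORF-3′ ⊕ R` and leaves exactly
`upstream ⊕ downstream`. Placing the right homology arm at the extreme 3′
end of the ORF (stop codon included) is what makes the excision seamless:
the older geometry, with the repeat taken from deeper in the intergenic
region, deletes that intergenic segment too. The package ships this
imprecise geometry as an explicit control (`shifted_repeat_variant`) and
the verifier shows it losing exactly the shifted distance.

The repeat may legitimately overlap the neighbouring gene's sequence —
nothing of it is ever lost, so compact genomes are safe.

## Why the primers are interdependent

Primer 2's 3′ end is pinned to the base before the ORF start, so the
design degrees of freedom are: primer 2's length, primer 1's position and
length, the marker anchor pair, and the marker-anchor length inside
primer 3. The search is ordered and deterministic:

1. **p2 candidates** (length 30–60 nt) pass composition, hairpin,
   self-dimer, and specificity screens; ranked by |GC − 0.40| then length.
2. Per p2: a **marker anchor pair** is taken in configured order, skipping
   any whose amplicon touches a forbidden interval (palindromic
   recombinase sites must never enter the cassette), and the chimeric
   **p3/p4** are assembled and screened; rule failures fall through to the
   next pair.
3. **p1 candidates** are ranked by |GC(p1) − GC(p2)|, then longer
   amplicons first, then leftmost. Thousands of windows are ranked
   cheaply by prefix-sum GC before any expensive screen runs; screens are
   applied lazily in rank order.
4. Cross-checks: pair-dimer for {p1,p2}, {p3,p4}, and the SOE outer pair
   {p1,p4}; 3′-specificity of p3/p4 against locus + plasmid. The first
   fully passing combination is returned; otherwise the deepest reason
   reached becomes the locus's single failure code.

Identical inputs and constraints always yield byte-identical output.

## Rule engines

**Dimers.** Long chimeric primers (to 100 nt) rule out nearest-neighbour
thermodynamics, so two rule-based signals are used. (1) 3′-window
affinity: the last 8 bases of one primer are slid over every ungapped
antiparallel register of the other; Watson–Crick pairs score A:T = 2,
G:C = 4; the maximum over registers and over both orientations is the
score, flagged at ≥ 24 (an all-G/C 6-pair 3′ clamp). Only 3′ ends prime
extension, which is why the window sits there. (2) Caterpillar humps: the
longest contiguous complementary run anywhere in the full ungapped duplex,
flagged at ≥ 8 — two long primers can zip up in their interiors while
both ends stay free, a geometry the 3′ window alone misses. The weights
and thresholds are package defaults, configurable per run.

**Hairpins.** A candidate is rejected if it contains an inverted repeat
with stem ≥ 6 bp and loop 3–8 nt. A stem threshold of 4 is sometimes
quoted as standard practice, but as a *hard* exact-match filter it flags
~40% of random 30–60-mers (an expected ~1.3 stem-4 placements per
60-mer), which desk measurement showed leaves a third of loci with zero
usable reverse primers; stems that short are also irrelevant at a 58 °C
annealing temperature. Six is the default; the threshold is configurable
and the detector itself is threshold-agnostic.

**Composition.** Overall G+C ≥ 30% and ≥ 2 G/C among the last 8 bases,
applied to PCR1 primers *and* to the assembled chimerics — primers below
30% G+C amplify weakly or not at all, chimeric or not. A 3′-terminal G/C
(GC clamp) is recorded as a preference, never a rejection: clamp-free
primers demonstrably still amplify.

**Mis-priming.** Exact search, not alignment: every occurrence of the
primer's 3′-terminal 8-mer on either strand of the local search space
(the locus record plus the marker plasmid) is a priming site; any
non-intended site rejects the candidate. Eight exact 3′ bases can prime
even when full-length identity is far below alignment reporting
thresholds, which is precisely the observed failure mode of
similarity-search prefiltering. A 3′ anchor drawn from a homopolymeric
run of ≥ 8 nt is rejected outright (`HOMOPOLYMER_3PRIME`): such an
anchor cannot be unique against any homopolymer-rich template, and the
rule is harmless where runs are rare. Whole-genome scanning is a
straightforward extension (the scan takes any template mapping) but the
default space is local, keeping per-locus cost milliseconds.

**Tm.** `Tm = 81.5 + 0.41·GC% − 675/N`, the classic salt-free long-oligo
estimate, valid for N ≥ 14; nearest-neighbour models extrapolate poorly
to this length regime. Pairing can use Tm (±3 °C) or, by default, similar
length (±10 nt) and G+C (±10 points).

## In-silico verification

The verifier re-derives everything from the primer strings alone — it
shares no state with the designer. A primer primes wherever its
3′-terminal 12 nt match a template exactly; 12 is deliberately stricter
than the 8-mer design-side *rejection* rule (a site the designer tolerates
may still not prime) and far looser than full-length identity (chimeric
tails must not block priming). Products substitute the full primer,
tails included, at each end. SOE fusion requires an exact terminal overlap
≥ 20 nt plus outer primers that span the fusion. Integration requires
≥ 40 nt of exact homology at both cassette ends and applies the
longest-extension match on each side. Pop-out enumerates *every* maximal
direct-repeat pair ≥ 20 nt (k-mer index, maximal extension, dedup) and
recombines each; the design passes iff some outcome equals
`upstream ⊕ downstream` exactly. Crossovers at different positions within
the same repeat give identical recombinants, so enumerating maximal pairs
is exhaustive — the test suite proves this against position-by-position
brute force. Mismatched (homeologous) recombination is not modelled.

Plasmids are treated as linear strings for scanning; the synthetic
generator keeps the marker region away from the origin, and a user
supplying a real plasmid should rotate it likewise.

## Parameters

| key | default | meaning |
| --- | --- | --- |
| amplicon_min/max | 500 / 1000 bp | PCR1 window, abutting the ORF start |
| p1_len, p2_len | 30–60 nt | PCR1 primer lengths (long, for hot annealing) |
| overlap_len / overlap_max | 25 / 40 nt | SOE overlap; extended toward 40 when its G+C < gc_min |
| r_len | 40 nt | repeat copied from downstream flank |
| marker5_min/max | 17–20 nt | marker anchor in PCR2_F (longest fitting under the cap) |
| marker3_len | 18 nt | marker anchor in PCR2_R |
| right_homology_len | 44 nt | ORF 3′-end homology in PCR2_R |
| p3_max_len | 100 nt | chimeric-primer cap (synthesis cost/quality) |
| gc_min, gc_last8_min | 0.30, 2 | composition rules |
| dimer_score_max, hump_run_max | 24, 8 | dimer flags |
| hairpin_stem_min, loop | 6, 3–8 | hairpin flag |
| mispriming_k, homopolymer_min | 8, 8 | specificity rules |
| sim_anchor, soe_min_overlap, integration_min_arm, popout_min_repeat | 12, 20, 40, 20 | verifier |

The worked-example table shows 25 nt overlaps; production practice favours
extending toward 40 nt where the junction is GC-poor, and both are
supported (`overlap_len`/`overlap_max`). Only the p3-side 5′ extension is
implemented; extending p2 instead would change the PCR1 product and is
not needed for the cap arithmetic (40 + 40 + 20 = 100 exactly).

## Synthetic data

Loci and marker plasmids are generated by an explicit 64-bit LCG (MMIX
multiplier; the algorithm is part of the package contract, frozen by
test, so fixtures are bit-identical across platforms and library
versions). Loci are i.i.d. bases at a requested G+C with the ORF framed
`ATG … stop`; the default batch draws ORF lengths of 300–1500 nt and G+C
of 0.35–0.45 per locus. Decoy octamers and homopolymer runs can be
implanted at stated positions to reconstruct mis-priming scenarios. The
synthetic marker carries a ~1.14 kb amplicon region (so PCR2 lands near
1.25 kb), four *curated* anchor pairs — staggered positions whose
3′-terminal octamers are unique in the plasmid and G/C-adequate, as a
real marker configuration would be hand-curated — and two palindromic
forbidden intervals flanking the amplicon.

What the generator does **not** emulate: codon usage, repeat families,
segmental duplication, base-composition autocorrelation, or any real
intergenic structure. Passing tests therefore demonstrate the algorithm's
internal correctness (segment algebra, rule enforcement, seamlessness)
and its behaviour on composition-realistic sequence — not off-target
rates on a real genome, where paralogy makes mis-priming far more common
than the i.i.d. model predicts.

Under defaults, 80–90% of random loci design successfully; the remainder
fail honestly, dominated by loci whose fixed 60 nt pre-ORF window is too
AT-rich or structured (`NO_P2_CANDIDATE`) or whose fixed chimeric
segments form an unavoidable complementary run (`DIMER`). This is
structural, not a bug: the reverse PCR1 primer's position admits no
freedom, so some flanks simply contain no compliant primer — the same
reason real genome-scale libraries top out around 85–90% coverage.
Relaxing `gc_min` or the dimer thresholds trades coverage against primer
quality, and every output file records the constraint set used.

## Numerical and tie-break choices

- All coordinates 0-based half-open; the ORF occupies
  `[flank_len, flank_len + orf_len)`.
- Candidate ordering (above) is total and documented; ties cannot occur
  because position and length enter the key.
- `N` bases: tolerated in parsed flanks, fatal (`NONSTANDARD_BASE`) inside
  any candidate primer or copied segment.
- Mass estimates use 660 g·mol⁻¹·bp⁻¹ dsDNA at a nominal crude-reaction
  yield of 3 pmol per 50 µl, i.e. `ng = 1.98 × bp` — this makes 1 µl of a
  1.25 kb product ≈ 50 ng, matching the protocol's assumption; it is a
  gel-comparison aid, not a quantification.
- The p1 search evaluates candidates lazily in rank order with a bounded
  number of accepted candidates per p2 (default 10 tried against the
  outer-pair dimer check) to keep worst-case loci fast.

## Known limitations

- No thermodynamic (ΔG) duplex or hairpin model; the rules are
  deliberately simple, fast, and configurable.
- No multi-marker scheduling for sequential deletions, and no two-gene
  marker cassettes.
- The verifier models recombination between exact repeats only.
- Confirmation primers (CPS_A/CPS_D) need flank sequence 150–300 bp
  outside the cassette footprint; with 1 kb flanks and a full-length
  1 kb PCR1 window there is no such room, and the design is returned
  with the confirmation fields empty rather than failed.
- Genome-scale coverage numbers depend on the genome build and the real
  marker anchor configuration; this package reports per-batch coverage
  for whatever inputs it is given rather than claiming fixed totals.
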