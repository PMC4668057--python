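# seamdel — seamless, scar-free deletion-cassette primer design

Deleting many genomic elements from one genome requires recycling the
selectable marker, and most recycling schemes either leave scar sequences
behind (a source of genome instability) or remove untargeted intergenic
DNA along with the gene. `seamdel` designs the primers for a deletion
method that is precise, scar-free, and automation-friendly: three
interdependent PCRs build a cassette that replaces the target ORF with a
counter-selectable marker flanked by a native direct repeat, and
recombination between the repeats later pops the marker out, leaving the
locus byte-identical to `upstream + downstream` — the ORF gone, nothing
else touched.

It is written for yeast/bacterial genome engineers building knockout
primer libraries (one locus or thousands), and for anyone who wants a
transparent, rule-based, fully configurable alternative to black-box
primer pipelines.

## The design problem

For a target ORF stored as a flanked record `upstream | ORF | downstream`,
four primers are chosen together:

- **PCR1** (primers 1, 2) amplifies a 500–1000 bp window of upstream flank
  whose 3′ edge abuts the ORF start. Primer 2's location is therefore
  fixed; only its length (30–60 nt) can vary. Primer 1 slides and must
  pair with primer 2 (similar length and G+C, or similar Tm).
- **PCR2** (primers 3, 4) amplifies the marker from its plasmid with two
  chimeric primers:
  - `p3 = revcomp(p2[:overlap]) ⊕ R ⊕ marker5′` where `R` is the first
    40 nt of downstream flank and `marker5′` is a 17–20 nt marker anchor;
    total length capped at 100 nt (no HPLC purification needed).
  - `p4 = revcomp(ORF[-44:]) ⊕ revcomp(marker3′)` with an 18 nt marker
    anchor; its first three bases are the reverse complement of the stop
    codon.
- **PCR3** (SOEing) fuses the crude PCR1/PCR2 products through the shared
  overlap: `len(PCR3) = len(PCR1) + len(PCR2) − overlap`.

Every candidate passes rule-based screens: overall G+C ≥ 30%, ≥ 2 G/C
among the last 8 bases, hairpin and self/pair-dimer checks scored by
weighted 3′-end complementarity (A:T = 2, G:C = 4) plus a
"caterpillar-hump" longest-complementary-run test, and an **exact
3′-anchored mis-priming search**: any second exact occurrence of a
primer's 3′-terminal 8-mer in the locus or plasmid rejects the candidate —
a failure mode full-length similarity searches demonstrably miss.

An in-silico verifier then replays the whole experiment (PCR1, PCR2, SOE
fusion, double-crossover integration, enumeration of every direct-repeat
pop-out) and asserts the seamless outcome exists.

## Worked example

```
$ python examples/design_single_locus.py
locus SYN000002: 900 nt ORF, 1000 nt flanks
PCR1_F (33 nt): TACACGTACACGTCCTTCTAGTGTTGACTTGCG
PCR1_R (33 nt): ACTGTCAAGAAAGTTGGAAGCAGATCTCCCGTC
PCR2_F (85 nt): [overlap 25][R 40][marker 20]
       ATCTGCTTCCAACTTTCTTGACAGTACGTTGGCAGTTTTCTGATCCGTAAAGTGCTTAAATCACGTATATGATGGTAGTCTTTTA
PCR2_R (62 nt): [gene-3' 44][marker 18]
       TCAAAATTAAATTCTGTGAGAAGGTTGTAATTCCTAAACCAATGTATCATCCCAGGTGGACA
marker amplicon: anchor pair 0

predicted sizes: PCR1 950 bp, PCR2 1248 bp, PCR3 2173 bp
PCR3 = PCR1 + PCR2 - overlap (25 nt): 950 + 1248 - 25 = 2173
```

The 85 nt chimeric forward primer decomposes into the 25 nt SOE overlap
(reverse complement of PCR1_R's 5′ end), the 40 nt repeat copied from
immediately downstream of the ORF, and a 20 nt marker anchor. PCR2 lands
near 1.25 kb and the fused cassette at ~2.2 kb — typical for a ~1 kb
upstream arm plus a ~1.1 kb marker amplicon. `examples/verify_in_silico.py`
then prints `seamless=True` for this design and shows that a control with
the repeat shifted 20 bp downstream loses exactly those 20 nt.

Other entry points:

- `examples/batch_design.py` — 50-locus synthetic library with a failure
  histogram (designed 43/50 under defaults; the rest classify as
  NO_P2_CANDIDATE / DIMER / MISPRIME, mirroring the fact that some loci
  genuinely admit no compliant primers).
- `examples/worked_example_table.py` — recovers the chimeric structure of
  the packaged four-gene worked-example primer table from raw sequence.
- CLI: `seamdel fixtures`, `seamdel design`, `seamdel verify`,
  `seamdel protocol` (see `seamdel --help`); every output file embeds the
  resolved constraint configuration for traceability.

## Layout

- `src/seamdel/seqio.py` — sequence primitives, flanked-ORF FASTA parsing,
  primer-library CSV I/O
- `src/seamdel/quality.py` — composition, hairpin, and rule-based dimer
  scoring for long primers
- `src/seamdel/specificity.py` — exact 3′-anchored mis-priming search
- `src/seamdel/design.py` — the design algorithm proper
- `src/seamdel/simulate.py` — in-silico PCR / SOE / integration / pop-out
- `src/seamdel/fixtures.py` — deterministic synthetic loci and markers;
  packaged worked examples
- `src/seamdel/batch.py`, `cli.py`, `protocol.py` — orchestration and
  presentation

See `docs/methods.md` for the model, parameter defaults, and limitations.
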