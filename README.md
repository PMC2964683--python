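# ctpp-design

Genetic-algorithm design of **confronting two-pair primer (CTPP) sets**
for enzyme-free SNP genotyping by PCR and gel electrophoresis.

## The problem

PCR-CTPP genotypes a biallelic SNP without restriction enzymes or
probes. Four primers run in one tube:

```
5' ---Pf1-->............[SNP].......................... 3'
                 <--Pr1--|                                (3' end on SNP, minor allele)
                 |--Pf2-->                                (3' end on SNP, major allele)
                         ..................<--Pr2--
```

`Pf1/Pr1` amplify a product of length `Pl1` only from the
minor-allele chromosome, `Pf2/Pr2` a product of length `Pl2` only
from the major-allele chromosome, and `Pf1/Pr2` a common outer
product whose length follows from the confronting overlap:

```
Pl3 = Pl1 + Pl2 - Rl1 - Fl2 + 1
```

Each genotype therefore shows a distinct band pattern on a gel. The
hard part is computational: the four primers must simultaneously
satisfy length balance, GC content (20–80%), a GC clamp, melting
temperatures inside 45–62 °C with pairwise gaps ≤ 1 °C, no
cross/self-dimers or hairpins, template-unique binding sites, and
three product lengths > 100 bp separated roughly as 8 : 13 : 20 so
the bands resolve cleanly.

## The method

A candidate design is a six-integer chromosome vector
`Pv = (Fl1, Pl1, Rl1, Fl2, Pl2, Rl2)` — four primer lengths
(16–28 bp) and the two short product lengths. Every constraint is a
*defect counter* (number of failed checks) and the search minimizes

```
Fitness(Pv) = 3·(Len_diff + GC_proportion + GC_clamp)
            + 10·(dimer + hairpin + specificity)
            + 50·(Tm + Tm_diff)
            + 100·Avg_Tm_diff
            + 60·PCR_len
```

with the salt-adjusted melting temperature
`Tm = 81.5 + 16.6·log10[Na+] + 0.41·GC% − 675/|P|`.
A steady-state genetic algorithm (random pair selection, six-bit
uniform crossover with feasibility repair, one-point mutation,
worst-two replacement) runs until a zero-fitness design appears or a
generation budget is exhausted. Defaults follow the classic
DeJong/Spears operating point: population 50, crossover 0.6,
mutation 0.001, 1000 generations.

## Worked example

Generate a synthetic 521 bp template carrying a C/G SNP at position
261 (with a feasible design embedded), then design primers. The flat
YAML config pins all primer lengths to 20 bp:

```bash
ctpp-design fixtures --flank 260 --plant-zero-set --seed 4 --out demo.fasta
printf 'len_min: 20\nlen_max: 20\n' > cfg.yaml
ctpp-design design --input demo.fasta --alleles C,G --config cfg.yaml \
    --pop-size 500 --generations 20000 --pm 0.25 --seed 1 --out -
```

prints

```
CTPP primer set for synthetic_seed4
template 521 bp, SNP at 261 (C/G), Na+ 0.05 M, seed 1

Primer Sequence (5'->3')                 Len    GC%      Tm   Start     End Strand
----------------------------------------------------------------------------------
Pf1    CCTTTTCAAACGACTGCTGG               20   50.0   46.65     121     140      +
Pr1    GACATTGCTAGACTCGACAC               20   50.0   46.65     261     280      -
Pf2    ATCGCTGAATCTTGTCTGCC               20   50.0   46.65     242     261      +
Pr2    CATTTGGACACCTGTTGCAC               20   50.0   46.65     482     501      -

Product sizes (bp): Pl1 (Pf1/Pr1) = 160, Pl2 (Pf2/Pr2) = 260, Pl3 (Pf1/Pr2) = 381
Tm differences (C): Pf1/Pr1 = 0.00, Pf2/Pr2 = 0.00, Pf1/Pr2 = 0.00
Fitness total: 0.0000 (optimal, 980 generations)
```

Reading the output: `Pr1` and `Pf2` both end 3' on the SNP (positions
261) carrying the allele-specific bases, so the 160 bp band is
minor-allele specific, the 260 bp band major-allele specific, and the
381 bp outer band (160 + 260 − 20 − 20 + 1) is the common control.
All four primers share one melting temperature (46.65 °C at
0.05 M Na+), every defect counter is zero, so the fitness is 0 and
the process exits with status 0 (`3` would mean best-effort). The
`batch` subcommand designs every record of a multi-FASTA and writes
per-constraint satisfaction statistics; `--trace` records the
per-generation best/mean fitness.

Library use mirrors the CLI:

```python
from ctpp_design import parse_template, run_ga, ConstraintConfig, GAConfig

t = parse_template("ACGTT...[A/C]...GGTCA", alleles=("A", "C"))
result = run_ga(t, ConstraintConfig(), GAConfig(seed=1))
print(result.best_breakdown.total, result.primer_set.products)
```

## Scope

Template-only specificity (no genome-wide search), true biallelic
SNPs only (no indels or multi-nucleotide variants), and sequence
heuristics rather than nearest-neighbor thermodynamics for the dimer
and hairpin screens. See `docs/methods.md` for the model, parameter
meanings, and known limitations.
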