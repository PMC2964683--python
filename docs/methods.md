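# Methods

## Design model

A template is a DNA string with one *defined SNP*: a single IUPAC
ambiguity character (or a dbSNP-style `[X/Y]` bracket token, which is
converted to the corresponding code at parse time). When several
ambiguity characters are present, the leftmost is the defined SNP and
the rest are treated as extra polymorphic positions. Indel and
multi-nucleotide bracket tokens are rejected: the confronting-primer
geometry assumes a single-base substitution.

A candidate design is the integer vector
`Pv = (Fl1, Pl1, Rl1, Fl2, Pl2, Rl2)`. Given the SNP position, all
four primer windows follow deterministically: the inner reverse
primer `Pr1` occupies the `Rl1` bases starting at the SNP (so its
3' terminus, after reverse complementation, is the complement of the
minor allele); the inner forward primer `Pf2` occupies the `Fl2`
bases ending at the SNP (3' terminus = major allele); `Pf1` is placed
so the `Pf1/Pr1` product has length `Pl1`; `Pr2` so the `Pf2/Pr2`
product has length `Pl2`. The outer product length is the identity
`Pl3 = Pl1 + Pl2 − Rl1 − Fl2 + 1` (the two short products share the
`Rl1 + Fl2 − 1` bases around the SNP).

Internally coordinates are 0-based half-open; everything user-facing
is 1-based inclusive. This split keeps the window arithmetic
off-by-one free while reports read conventionally.

*Hard feasibility* (enforced during search, never priced): primer
lengths within `[len_min, len_max]`, all windows inside the template,
`Pf1` strictly upstream and `Pr2` strictly downstream of the SNP, and
the extra-SNP exclusion — a primer window covering an additional
polymorphic position is rejected outright, because an uncontrolled
second variant under a primer makes its effective Tm unpredictable.
The exclusion always applies to the outer primers; for the inner
primers it is on by default and can be disabled
(`reject_extra_in_inner=False`). No minimum gap is enforced between
`Pf1` and `Pr1`'s windows; abutting is legal.

The maximal feasible short products `(δ1, δ2)` are defined
operationally: `δ1` is the largest `Pl1` whose product window still
fits the upstream template side for some admissible `Rl1` (so the
product may start at base 1), and `δ2` the downstream analogue. A
side that cannot host `product_min` bases is an infeasible template.

## Constraints and fitness

Each soft constraint returns a defect value = number of failed
checks; the weighted sum is minimized:

| term | checks | range | weight |
|---|---|---|---|
| length difference | Fl1/Rl1, Fl2/Rl2, Fl1/Rl2 gaps ≤ 3 bp | 0–3 | 3 |
| GC proportion | 20% ≤ GC ≤ 80% per primer | 0–4 | 3 |
| GC clamp | 3' base is G or C per primer | 0–4 | 3 |
| Tm range | 45 ≤ Tm ≤ 62 °C per primer | 0–4 | 50 |
| Tm difference | pairwise gaps ≤ 1 °C (3 working pairs) | 0–3 | 50 |
| average Tm gap | mean of the 3 gaps, continuous (°C) | ≥ 0 | 100 |
| dimer | 6 cross + 4 self checks clean | 0–10 | 10 |
| hairpin | per primer | 0–4 | 10 |
| specificity | any repeated binding site in template | 0–1 | 10 |
| product lengths | 3 strict >100 bp floors, 3 ratio checks, all-ratios bonus | 0–7 | 60 |

All range checks are inclusive; the product floor is strict. The GC
window is deliberately loose (20–80% rather than the usual 40–60%)
because the two inner primers are pinned to the SNP and cannot be
shifted to tune composition. The Tm terms carry the largest weights:
in a one-tube CTPP reaction all three amplicons compete, and
genotyping fails first through unbalanced annealing. The average Tm
gap enters continuously (no rounding), so a total of exactly zero
requires identical Tm values; a configurable epsilon (default 1e−9)
guards the float comparison in the termination test.

**Melting temperature.** Salt-adjusted formula
`Tm = 81.5 + 16.6·log10[Na+] + 0.41·GC% − 675/|P|`, GC% on the 0–100
scale, default `[Na+] = 0.05 M`. The default is a package choice — a
typical monovalent-cation operating point — and every report echoes
it, so printed Tm values are always interpretable. The cruder
`2·AT + 4·GC` rule is intentionally not offered. Because the formula
depends only on length and GC count, any four equal-length primers
with equal GC counts have exactly equal Tm — the property the
synthetic fixtures exploit.

**Dimer screen.** The two primers are slid across all antiparallel
ungapped offsets; a dimer is flagged when the longest run of
Watson–Crick pairs reaches `dimer_stem_min` (default 5), or
`dimer_3p_min` (default 3) when the run covers either primer's
3'-terminal base (3' duplexes prime extension and are the dangerous
case). **Hairpin screen:** flagged when a `hairpin_stem_min` (4)
window's reverse complement reappears at least `hairpin_loop_min` (3)
bases downstream within the same primer. Both are sequence
heuristics, not free-energy models; the thresholds are exposed in
config, and both screens are verified against exhaustive
duplex/stem-loop enumeration oracles in the test suite.

**Specificity** is template-only by design: each primer's binding
site (sense strand for forward primers, reverse complement for
reverse primers) must occur exactly once, with IUPAC-aware matching
so the SNP site matches under either allele. Genome-scale uniqueness
is out of scope.

**Product ratios.** The three products should separate cleanly on a
gel; targets default to 8 : 13 : 20. With unit
`u = (Pl1+Pl2+Pl3)/(r1+r2+r3)`, product *i* "corresponds" to ratio
*i* when `|Pl_i − r_i·u| ≤ tol·r_i·u`. The tolerance defaults to
0.25: band separation is a visual criterion, and a strict
proportionality test would reject visibly fine designs (including
the wet-lab-validated reference set, whose products 228/105/294 are
not close to 8 : 13 : 20 under any assignment).

## The genetic algorithm

Steady-state loop: each generation draws two distinct parents
uniformly at random, applies uniform crossover with probability
`crossover_prob` (a six-bit mask; bit = 1 exchanges that gene), then
one-point mutation with probability `mutation_prob` *per offspring*
(the chromosome has six integer genes, not bits, so a per-gene rate
would be meaningless at 0.001), and replaces the two worst members.
Ties among the worst break by stable order (later-inserted members
drop first). Initialization rejects duplicates; when random sampling
cannot fill the population, the feasible space is enumerated — so a
population sized to a tiny instance's feasible count *is* that whole
space. Termination: best fitness ≤ epsilon, or `max_generations`
iterations (one selected pair per iteration).

Repair is hard-feasibility only. After crossover, exchanged genes are
restored left-to-right until both children are feasible (restoring
everything reproduces the parents, so repair terminates). A mutation
that violates feasibility reselects its point and value, up to 100
retries, after which the parent passes through unchanged with a
logged warning. One seeded `random.Random` drives every choice;
identical seed + config + input is bitwise reproducible. Fitness
evaluations are memoized per (template, config) — the mapping is
deterministic — which makes long runs on small search spaces cheap.

Defaults (population 50, 1000 generations, crossover 0.6, mutation
0.001) follow the standard DeJong/Spears settings; a population of
1000 is the documented high-accuracy variant. Batch runs seed record
*i* with `master_seed + i`, so any single record reruns identically
outside the batch.

## Synthetic fixtures and what they show

`fixtures_oracle` generates templates as i.i.d. draws at a configured
GC fraction (default 0.4) around a single SNP with 500 bp flanks
(the standard flank retrieval length for this assay family), and can
plant: a **defect-free design** (four equal-length windows with equal
GC counts — hence identical Tm — clamped 3' ends, C/G alleles so both
allele-specific termini are clamped, products on the 8 : 13 : 20
ratios, jointly screened clean of dimers/hairpins, with the
background resampled until no binding site repeats), a **duplicated
20-mer** to trip the specificity check, and a **palindromic motif**
to trip the hairpin screen. Planted designs are constructed backwards
from the constraints and then verified with the actual fitness
function.

These backgrounds lack repeats, homopolymer structure and the
composition biases of real genomic flanks; passing tests certify the
constraint arithmetic and search machinery, not wet-lab performance
or genome-wide specificity of any particular primer set.

Problem sizes used in the test suite are chosen so every oracle is
exact: the GA-versus-exhaustive comparison runs on a 321 bp planted
instance with all primers pinned to 20-mers (6 561-vector space,
fully enumerated), with search settings suited to so small a space
(population 200, mutation 0.25, up to 4 000 generations — at the
DeJong rates mutation would essentially never fire in a run this
short); batch statistics run 288 templates with 150 bp flanks at a
reduced generation budget, since only the counting arithmetic, not
design quality, is under test; screen/oracle equivalence is full
enumeration over all sequences of length ≤ 8 (self) and all pairs of
length ≤ 4 (cross).

## Known limitations

- No nearest-neighbor thermodynamics or ΔG secondary-structure
  models; the screens are run-length heuristics with configurable
  thresholds and no single published operating point to match.
- Specificity is template-bounded; primers unique in a 1 kb flank
  may still multi-map genome-wide.
- The major/minor allele designation must be supplied by the user
  (flank exports do not carry frequencies); the alphabetical default
  logs a warning.
- Uniform random parent selection means all selection pressure comes
  from worst-two replacement; convergence on large templates at the
  default mutation rate typically yields a low-but-nonzero fitness
  (a best-effort design, exit status 3) rather than a certified
  optimum.
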