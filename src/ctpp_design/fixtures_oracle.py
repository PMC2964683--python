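"""Synthetic templates and independent brute-force oracles.

Everything here exists to make the designer testable without any
external sequence retrieval: deterministic random templates with a
defined SNP, optional *planted* features (a defect-free primer set, a
duplicated site that trips the specificity check, a hairpin-prone
palindromic motif), an exhaustive search over small chromosome
spaces, and brute-force reimplementations of the dimer and hairpin
screens that enumerate every duplex/stem-loop decomposition directly.

The synthetic backgrounds are i.i.d. base draws at a configured GC
fraction around a single biallelic SNP with 500 bp flanks by default.
They deliberately lack the repeat structure, homopolymer runs and
CpG-island composition of real genomic flanks, so passing tests
certify the algorithmic machinery, not genome-scale primer
specificity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .constraint_fitness import (
    ConstraintConfig,
    fitness,
    has_dimer,
    has_hairpin,
)
from .ga_engine import GeneBounds, enumerate_feasible, Evaluator
from .sequence_model import (
    ChromosomeVector,
    TemplateDNA,
    realize_primer_set,
    reverse_complement,
    _SET_TO_CODE,
)

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}

MAX_EXHAUSTIVE_SPACE = 2_000_000  # raw gene-box size guard


class SpaceTooLargeError(ValueError):
    """Raised when exhaustive search is asked to enumerate too much."""


# geometry of the default planted defect-free design: all primers
# 20-mers with 10 G/C bases (identical salt-adjusted Tm), products
# 160/260/381 which satisfy the 8:13:20 band-separation ratios within
# the default tolerance, all 3' ends G/C, alleles C/G so both
# allele-specific 3' termini are clamped.
PLANT_VECTOR = ChromosomeVector(20, 160, 20, 20, 260, 20)
# a smaller planted geometry (products 104/169/234, also on 8:13:20)
# for instances whose whole chromosome space is enumerable
PLANT_VECTOR_SMALL = ChromosomeVector(20, 104, 20, 20, 169, 20)


@dataclass(frozen=True)
class SyntheticTemplateSpec:
    """Recipe for a deterministic synthetic SNP-flanking template."""

    flank_length: int = 500        # bases on each side of the SNP
    gc_background: float = 0.4
    allele_major: str = "C"
    allele_minor: str = "G"
    plant_zero_set: bool = False   # embed a defect-free primer design
    plant_vector: ChromosomeVector = PLANT_VECTOR
    plant_repeat: bool = False     # duplicate a 20-mer to trip specificity
    plant_palindrome: bool = False # embed a hairpin-prone motif
    seed: int = 0


def _random_bases(rng: random.Random, n: int, gc: float) -> list:
    out = []
    for _ in range(n):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return out


def _random_with_gc_count(rng: random.Random, n: int, gc_count: int) -> str:
    """Random base string of length n with exactly gc_count G/C bases."""
    idx = list(range(n))
    rng.shuffle(idx)
    gc_pos = set(idx[:gc_count])
    return "".join(
        rng.choice("GC") if i in gc_pos else rng.choice("AT") for i in range(n)
    )


def _plant_windows(snp_index: int, v: ChromosomeVector) -> dict:
    """0-based half-open windows of the planted design."""
    s0 = snp_index
    return {
        "pf1": (s0 + v.rl1 - v.pl1, s0 + v.rl1 - v.pl1 + v.fl1),
        "pr1": (s0, s0 + v.rl1),
        "pf2": (s0 - v.fl2 + 1, s0 + 1),
        "pr2": (s0 - v.fl2 + 1 + v.pl2 - v.rl2, s0 - v.fl2 + 1 + v.pl2),
    }


def _sample_plant_bases(
    rng: random.Random, spec: SyntheticTemplateSpec, snp_index: int, cfg: ConstraintConfig
) -> dict:
    """Template bases for the planted windows, by rejection sampling.

    Windows are drawn with exact GC counts so all four primers share
    one Tm, then the realized primers are screened jointly for dimers
    and hairpins; the whole tuple is resampled until clean.
    """
    v = spec.plant_vector
    if len({v.fl1, v.rl1, v.fl2, v.rl2}) != 1:
        raise ValueError("planted designs require equal primer lengths")
    n = v.fl1
    gc = n // 2
    for _ in range(2000):
        # pf1: sense 20-mer, 3' end G/C
        pf1 = _random_with_gc_count(rng, n - 1, gc - 1) + rng.choice("GC")
        # pr1 window: SNP base + 19 downstream bases with 9 G/C
        pr1_win = spec.allele_minor + _random_with_gc_count(rng, n - 1, gc - 1)
        # pf2 window: 19 upstream bases with 9 G/C + SNP base
        pf2_win = _random_with_gc_count(rng, n - 1, gc - 1) + spec.allele_major
        # pr2 window: starts G/C (primer 3' end is its complement)
        pr2_win = rng.choice("GC") + _random_with_gc_count(rng, n - 1, gc - 1)

        primers = (pf1, reverse_complement(pr1_win), pf2_win, reverse_complement(pr2_win))
        pairs = [(i, j) for i in range(4) for j in range(i, 4)]
        if any(has_dimer(primers[i], primers[j], cfg) for i, j in pairs):
            continue
        if any(has_hairpin(p, cfg) for p in primers):
            continue
        return {"pf1": pf1, "pr1_win": pr1_win, "pf2_win": pf2_win, "pr2_win": pr2_win}
    raise RuntimeError("could not sample a clean planted primer set")


def generate_template(
    spec: SyntheticTemplateSpec, cfg: Optional[ConstraintConfig] = None
) -> tuple[TemplateDNA, dict]:
    """Deterministic synthetic template plus a manifest of planted features.

    The manifest records 1-based coordinates of every planted feature
    so tests can verify them by direct search.  With
    ``plant_zero_set`` the manifest's ``zero_vector`` evaluates to
    fitness 0 on the returned template.
    """
    cfg = cfg or ConstraintConfig()
    min_flank = cfg.product_min + cfg.len_max
    if spec.flank_length < min_flank:
        raise ValueError(
            f"flank_length {spec.flank_length} < {min_flank}; no product of "
            f">= {cfg.product_min} bp fits either side"
        )
    rng = random.Random(spec.seed)
    L = 2 * spec.flank_length + 1
    s0 = spec.flank_length
    manifest: dict = {"snp_position": s0 + 1, "length": L}

    for attempt in range(50):
        bases = _random_bases(rng, L, spec.gc_background)
        code = _SET_TO_CODE[frozenset({spec.allele_major, spec.allele_minor})]
        bases[s0] = code

        if spec.plant_zero_set:
            wins = _plant_windows(s0, spec.plant_vector)
            if min(a for a, _ in wins.values()) < 0 or max(b for _, b in wins.values()) > L:
                raise ValueError(
                    f"flank_length {spec.flank_length} too short for the planted "
                    f"design {tuple(spec.plant_vector)}"
                )
            planted = _sample_plant_bases(rng, spec, s0, cfg)
            for name, win_seq in (
                ("pf1", planted["pf1"]),
                ("pr1", planted["pr1_win"]),
                ("pf2", planted["pf2_win"]),
                ("pr2", planted["pr2_win"]),
            ):
                a, b = wins[name]
                for k, c in enumerate(win_seq):
                    if a + k == s0:
                        continue  # keep the ambiguity code at the SNP
                    bases[a + k] = c
            manifest["zero_vector"] = tuple(spec.plant_vector)
            manifest["planted_windows"] = {
                k: (a + 1, b) for k, (a, b) in wins.items()
            }

        if spec.plant_repeat:
            unit = "".join(_random_bases(rng, 20, 0.5))
            p1 = s0 - cfg.product_min - 220
            p2 = s0 + cfg.product_min + 160
            if p1 < 0 or p2 + 20 > L:
                raise ValueError("flank too short to plant a repeat")
            bases[p1:p1 + 20] = list(unit)
            bases[p2:p2 + 20] = list(unit)
            manifest["repeat_unit"] = unit
            manifest["repeat_positions"] = (p1 + 1, p2 + 1)

        if spec.plant_palindrome:
            motif = "GGGGAAAACCCC"  # 4-base stem, 4-base loop
            p = max(0, s0 - cfg.product_min - 300)
            bases[p:p + len(motif)] = list(motif)
            manifest["palindrome_position"] = p + 1
            manifest["palindrome_motif"] = motif

        t = TemplateDNA(
            sequence="".join(bases),
            snp_index=s0,
            allele_major=spec.allele_major,
            allele_minor=spec.allele_minor,
            extra_snp_indices=frozenset(),
            record_id=f"synthetic_seed{spec.seed}",
        )
        if spec.plant_zero_set:
            # background must not create repeats of the planted sites
            pv = spec.plant_vector
            s = realize_primer_set(t, pv, cfg.len_min, cfg.len_max,
                                   cfg.product_min, cfg.reject_extra_in_inner)
            bd = fitness(s, pv, t, cfg)
            if not bd.is_zero(cfg):
                continue
        return t, manifest
    raise RuntimeError("could not generate a template honouring the planted features")


# ---------------------------------------------------------------------------
# exhaustive search oracle

def exhaustive_search(
    t: TemplateDNA,
    cfg: ConstraintConfig,
    bounds: Optional[GeneBounds] = None,
    max_space: int = MAX_EXHAUSTIVE_SPACE,
) -> tuple[float, list]:
    """True minimum fitness over every feasible chromosome vector.

    Enumerates the gene box in lexicographic order and returns
    ``(min_fitness, argmins)`` with every minimizing vector.  Guarded:
    raises :class:`SpaceTooLargeError` instead of silently truncating
    when the raw box exceeds ``max_space`` vectors.
    """
    bounds = bounds or GeneBounds.from_template(t, cfg)
    box = 1
    for i in range(6):
        lo, hi = bounds.range_for(i)
        box *= max(0, hi - lo + 1)
    if box > max_space:
        raise SpaceTooLargeError(f"gene box of {box} vectors exceeds {max_space}")

    evaluate = Evaluator(t, cfg)
    best = float("inf")
    argmins: list = []
    for v in enumerate_feasible(t, cfg, bounds):
        total = evaluate(v).total
        if total < best - 1e-12:
            best, argmins = total, [v]
        elif abs(total - best) <= 1e-12:
            argmins.append(v)
    if not argmins:
        raise ValueError("no feasible vector in the given bounds")
    return best, argmins


# ---------------------------------------------------------------------------
# brute-force screen oracles (independent of constraint_fitness internals)

def dimer_bruteforce(p: str, q: str, cfg: Optional[ConstraintConfig] = None) -> bool:
    """Dimer verdict by enumerating every antiparallel ungapped duplex.

    Checks all substring pairs ``p[i:i+r]`` vs ``q[j:j+r]`` for full
    antiparallel Watson-Crick complementarity; a duplex of length
    >= ``dimer_stem_min`` (or >= ``dimer_3p_min`` covering either
    primer's 3'-terminal base) is a dimer.
    """
    cfg = cfg or ConstraintConfig()
    p, q = p.upper(), q.upper()
    np_, nq = len(p), len(q)
    for i in range(np_):
        for j in range(nq):
            rmax = min(np_ - i, nq - j)
            for r in range(1, rmax + 1):
                # antiparallel: p[i+k] pairs with q[j+r-1-k]
                if _WC.get(p[i + r - 1]) != q[j]:
                    # extending the duplex broke complementarity at the
                    # newly added pair; longer r at this (i, j) pairs
                    # different bases, so keep scanning r
                    continue
                if all(_WC.get(p[i + k]) == q[j + r - 1 - k] for k in range(r)):
                    covers_3p = (i + r - 1 == np_ - 1) or (j + r - 1 == nq - 1)
                    if r >= cfg.dimer_stem_min:
                        return True
                    if covers_3p and r >= cfg.dimer_3p_min:
                        return True
    return False


def hairpin_bruteforce(p: str, cfg: Optional[ConstraintConfig] = None) -> bool:
    """Hairpin verdict by enumerating every stem-loop decomposition."""
    cfg = cfg or ConstraintConfig()
    p = p.upper()
    n = len(p)
    smin, lmin = cfg.hairpin_stem_min, cfg.hairpin_loop_min
    for s in range(smin, n // 2 + 1):
        for i in range(n - 2 * s - lmin + 1):
            for j in range(i + s + lmin, n - s + 1):
                if all(_WC.get(p[i + k]) == p[j + s - 1 - k] for k in range(s)):
                    return True
    return False
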