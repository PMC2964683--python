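"""Primer-design constraints as defect counters and the weighted fitness.

Each constraint function returns a *defect value*: the number of its
checks that fail (0 means every check passed).  The GA minimizes the
weighted sum

``total = w_comp*(len_diff + gc_proportion + gc_clamp)
        + w_struct*(dimer + hairpin + specificity)
        + w_tm*(tm + tm_diff)
        + w_balance*avg_tm_diff
        + w_product*pcr_len``

with default weights (3, 10, 50, 100, 60) reflecting how strongly each
constraint class conditions a working CTPP reaction: the melting
temperatures of the four primers must be nearly identical for all
three amplicons to compete in one tube, so the Tm terms dominate.

Melting temperature uses the salt-adjusted (Bolton-McCarthy) formula
``Tm = 81.5 + 16.6*log10([Na+]) + 0.41*GC% - 675/len`` with GC% on the
0-100 scale; the monovalent-cation concentration defaults to 0.05 M
and is echoed in every report.

The dimer and hairpin screens are deliberately simple sequence
heuristics (no nearest-neighbor thermodynamics): a cross/self-dimer is
an antiparallel ungapped alignment with a long enough run of
Watson-Crick pairs, and a hairpin is a stem of reverse-complementary
windows separated by a minimum loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .sequence_model import (
    IUPAC_EXPANSION,
    AMBIGUITY_CODES,
    ChromosomeVector,
    CTPPPrimerSet,
    TemplateDNA,
    reverse_complement,
)

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ConstraintConfig:
    """Constraint bounds, screen thresholds and fitness weights.

    All range checks are inclusive; the product-length floor is strict
    (a product must exceed ``product_min``).
    """

    len_min: int = 16
    len_max: int = 28
    len_diff_max: int = 3          # bp, max pairwise primer-length gap
    gc_low: float = 20.0           # %, relaxed because inner primers are pinned to the SNP
    gc_high: float = 80.0
    tm_low: float = 45.0           # deg C
    tm_high: float = 62.0
    tm_diff_max: float = 1.0       # deg C, per primer pair
    product_min: int = 100         # bp, strict floor
    na_molar: float = 0.05         # mol/L monovalent cations
    ratios: tuple = (8, 13, 20)    # target Pl1:Pl2:Pl3 band-separation ratios
    ratio_tolerance: float = 0.25  # relative slack on each ratio target
    dimer_stem_min: int = 5        # complementary run flagging a dimer
    dimer_3p_min: int = 3          # shorter run suffices at a 3' terminus
    hairpin_stem_min: int = 4
    hairpin_loop_min: int = 3
    weight_composition: float = 3.0
    weight_structure: float = 10.0
    weight_tm: float = 50.0
    weight_product: float = 60.0
    weight_tm_balance: float = 100.0
    zero_epsilon: float = 1e-9     # |total| below this counts as a perfect design
    reject_extra_in_inner: bool = True

    @property
    def weights(self) -> tuple:
        return (
            self.weight_composition,
            self.weight_structure,
            self.weight_tm,
            self.weight_product,
            self.weight_tm_balance,
        )

    def with_weights(self, w: Sequence[float]) -> "ConstraintConfig":
        w1, w2, w3, w4, w5 = w
        return replace(
            self,
            weight_composition=w1,
            weight_structure=w2,
            weight_tm=w3,
            weight_product=w4,
            weight_tm_balance=w5,
        )


@dataclass(frozen=True)
class FitnessBreakdown:
    """Every defect value plus the continuous Tm-balance term and total."""

    len_diff_defect: int
    gc_proportion_defect: int
    gc_clamp_defect: int
    tm_defect: int
    tm_diff_defect: int
    avg_tm_diff: float
    dimer_defect: int
    hairpin_defect: int
    specificity_defect: int
    pcr_len_defect: int
    total: float

    def recombine(self, cfg: ConstraintConfig) -> float:
        """Weighted total recomputed from the stored components."""
        return (
            cfg.weight_composition
            * (self.len_diff_defect + self.gc_proportion_defect + self.gc_clamp_defect)
            + cfg.weight_structure
            * (self.dimer_defect + self.hairpin_defect + self.specificity_defect)
            + cfg.weight_tm * (self.tm_defect + self.tm_diff_defect)
            + cfg.weight_tm_balance * self.avg_tm_diff
            + cfg.weight_product * self.pcr_len_defect
        )

    def is_zero(self, cfg: ConstraintConfig) -> bool:
        return self.total <= cfg.zero_epsilon


# ---------------------------------------------------------------------------
# elementary quantities

def gc_percent(p: str) -> float:
    """GC content of a primer on the 0-100 scale."""
    if not p:
        raise ValueError("empty primer string")
    p = p.upper()
    return 100.0 * (p.count("G") + p.count("C")) / len(p)


def tm_bm(p: str, na_molar: float) -> float:
    """Salt-adjusted melting temperature (Bolton-McCarthy), deg C."""
    if not p:
        raise ValueError("empty primer string")
    if na_molar <= 0:
        raise ValueError("salt concentration must be positive")
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * gc_percent(p) - 675.0 / len(p)


def _tms(s: CTPPPrimerSet, cfg: ConstraintConfig) -> tuple[float, float, float, float]:
    return tuple(tm_bm(p, cfg.na_molar) for p in s.sequences)


def tm_pair_diffs(s: CTPPPrimerSet, cfg: ConstraintConfig) -> tuple[float, float, float]:
    """|Tm| gaps for the three working pairs (Pf1/Pr1, Pf2/Pr2, Pf1/Pr2)."""
    t1, t2, t3, t4 = _tms(s, cfg)
    return (abs(t1 - t2), abs(t3 - t4), abs(t1 - t4))


# ---------------------------------------------------------------------------
# per-constraint check lists (True = check satisfied); defect = #False

def len_diff_checks(v: ChromosomeVector, cfg: ConstraintConfig) -> list[bool]:
    m = cfg.len_diff_max
    return [
        abs(v.fl1 - v.rl1) <= m,
        abs(v.fl2 - v.rl2) <= m,
        abs(v.fl1 - v.rl2) <= m,
    ]


def gc_proportion_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    return [cfg.gc_low <= gc_percent(p) <= cfg.gc_high for p in s.sequences]


def gc_clamp_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    return [p[-1] in "GC" for p in s.sequences]


def tm_range_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    return [cfg.tm_low <= t <= cfg.tm_high for t in _tms(s, cfg)]


def tm_diff_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    return [d <= cfg.tm_diff_max for d in tm_pair_diffs(s, cfg)]


def avg_tm_diff(s: CTPPPrimerSet, cfg: Optional[ConstraintConfig] = None) -> float:
    """Mean absolute Tm gap over the three working pairs (deg C)."""
    cfg = cfg or ConstraintConfig()
    return sum(tm_pair_diffs(s, cfg)) / 3.0


def len_diff_defect(v: ChromosomeVector, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in len_diff_checks(v, cfg))


def gc_proportion_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in gc_proportion_checks(s, cfg))


def gc_clamp_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in gc_clamp_checks(s, cfg))


def tm_range_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in tm_range_checks(s, cfg))


def tm_diff_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in tm_diff_checks(s, cfg))


# ---------------------------------------------------------------------------
# dimer screen

def _diagonal_runs(p: str, q: str):
    """Complementary runs over all antiparallel ungapped alignments.

    ``p`` and ``q`` are both 5'->3'.  ``q`` is reversed so that at a
    given offset position ``i`` of ``p`` faces position ``i - k`` of
    reversed ``q`` (i.e. the strands are antiparallel).  Yields
    ``(run_length, touches_3prime)`` for every maximal run of
    Watson-Crick pairs, where ``touches_3prime`` is True when the run
    covers the 3'-terminal base of either primer.
    """
    qr = q[::-1]
    np_, nq = len(p), len(qr)
    for k in range(-(nq - 1), np_):
        i0, i1 = max(0, k), min(np_, nq + k)
        run = 0
        touches = False
        for i in range(i0, i1):
            if _WC.get(p[i]) == qr[i - k]:
                run += 1
                if i == np_ - 1 or i - k == 0:
                    touches = True  # p 3' end, or q 3' end (index 0 of qr)
            else:
                if run:
                    yield run, touches
                run, touches = 0, False
        if run:
            yield run, touches


def has_dimer(p: str, q: str, cfg: ConstraintConfig) -> bool:
    """Dimer screen for a primer pair (use ``q = p`` for a self-dimer).

    Flags a dimer when some antiparallel ungapped alignment contains a
    complementary run of at least ``dimer_stem_min`` bases, or at least
    ``dimer_3p_min`` bases when the run covers either 3' terminus.
    """
    for run, touches in _diagonal_runs(p.upper(), q.upper()):
        if run >= cfg.dimer_stem_min:
            return True
        if touches and run >= cfg.dimer_3p_min:
            return True
    return False


DIMER_PAIR_NAMES = (
    "Pf1/Pr1", "Pf2/Pr2", "Pf2/Pr1", "Pf1/Pr2", "Pf1/Pf2", "Pr1/Pr2",
    "Pf1 self", "Pr1 self", "Pf2 self", "Pr2 self",
)


def dimer_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    """The 10 dimer checks (6 cross pairs + 4 self pairs); True = clean."""
    f1, r1, f2, r2 = s.pf1, s.pr1, s.pf2, s.pr2
    pairs = [
        (f1, r1), (f2, r2), (f2, r1), (f1, r2), (f1, f2), (r1, r2),
        (f1, f1), (r1, r1), (f2, f2), (r2, r2),
    ]
    return [not has_dimer(p, q, cfg) for p, q in pairs]


def dimer_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in dimer_checks(s, cfg))


# ---------------------------------------------------------------------------
# hairpin screen

def has_hairpin(p: str, cfg: ConstraintConfig) -> bool:
    """Hairpin screen: a window of ``hairpin_stem_min`` bases whose
    reverse complement reappears downstream after a loop of at least
    ``hairpin_loop_min`` unpaired bases."""
    p = p.upper()
    stem, loop = cfg.hairpin_stem_min, cfg.hairpin_loop_min
    n = len(p)
    for i in range(n - 2 * stem - loop + 1):
        target = reverse_complement(p[i:i + stem])
        lo = i + stem + loop
        if p.find(target, lo) != -1:
            return True
    return False


def hairpin_checks(s: CTPPPrimerSet, cfg: ConstraintConfig) -> list[bool]:
    return [not has_hairpin(p, cfg) for p in s.sequences]


def hairpin_defect(s: CTPPPrimerSet, cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in hairpin_checks(s, cfg))


# ---------------------------------------------------------------------------
# specificity (template-only uniqueness of each binding site)

def count_site_occurrences(template: str, site: str) -> int:
    """Occurrences of a concrete site in an IUPAC template.

    A template character matches a site base when the base belongs to
    its IUPAC expansion, so the SNP position matches under either
    allele.  Overlapping occurrences count separately.
    """
    template = template.upper()
    site = site.upper()
    n, m = len(template), len(site)
    if m == 0 or m > n:
        return 0
    amb = [i for i, c in enumerate(template) if c in AMBIGUITY_CODES]
    # fast path: exact matches against a template with ambiguity
    # positions masked out, then window-check around each ambiguity
    masked = template
    for i in amb:
        masked = masked[:i] + "?" + masked[i + 1:]
    starts = set()
    pos = masked.find(site)
    while pos != -1:
        starts.add(pos)
        pos = masked.find(site, pos + 1)
    for a in amb:
        for start in range(max(0, a - m + 1), min(a, n - m) + 1):
            if start in starts:
                continue
            if all(
                site[k] in IUPAC_EXPANSION[template[start + k]]
                for k in range(m)
            ):
                starts.add(start)
    return len(starts)


def specificity_checks(s: CTPPPrimerSet, t: TemplateDNA) -> list[bool]:
    """Per-primer uniqueness of the binding site in the template.

    Forward primers are searched as-is (sense); reverse primers are
    searched as the sense sequence of their binding site (the reverse
    complement of the primer).
    """
    sites = (s.pf1, reverse_complement(s.pr1), s.pf2, reverse_complement(s.pr2))
    return [count_site_occurrences(t.sequence, site) <= 1 for site in sites]


def specificity_defect(s: CTPPPrimerSet, t: TemplateDNA) -> int:
    """1 when any primer's binding site repeats in the template, else 0."""
    return 0 if all(specificity_checks(s, t)) else 1


# ---------------------------------------------------------------------------
# product lengths

def ratio_targets(products: Sequence[int], cfg: ConstraintConfig) -> list[float]:
    """Ideal product lengths under the configured band-separation ratios."""
    unit = sum(products) / sum(cfg.ratios)
    return [r * unit for r in cfg.ratios]


def ratio_checks(products: Sequence[int], cfg: ConstraintConfig) -> list[bool]:
    targets = ratio_targets(products, cfg)
    return [
        abs(pl - tgt) <= cfg.ratio_tolerance * tgt
        for pl, tgt in zip(products, targets)
    ]


def pcr_len_checks(products: Sequence[int], cfg: ConstraintConfig) -> list[bool]:
    """The 7 product-length checks: three strict floors, three ratio
    correspondences, and the all-ratios bonus check."""
    floors = [pl > cfg.product_min for pl in products]
    ratios = ratio_checks(products, cfg)
    return floors + ratios + [all(ratios)]


def pcr_len_defect(products: Sequence[int], cfg: ConstraintConfig) -> int:
    return sum(not ok for ok in pcr_len_checks(products, cfg))


# ---------------------------------------------------------------------------
# aggregate

def fitness(
    s: CTPPPrimerSet,
    v: ChromosomeVector,
    t: TemplateDNA,
    cfg: Optional[ConstraintConfig] = None,
) -> FitnessBreakdown:
    """Evaluate every constraint and the weighted total for one design."""
    cfg = cfg or ConstraintConfig()
    bd = dict(
        len_diff_defect=len_diff_defect(v, cfg),
        gc_proportion_defect=gc_proportion_defect(s, cfg),
        gc_clamp_defect=gc_clamp_defect(s, cfg),
        tm_defect=tm_range_defect(s, cfg),
        tm_diff_defect=tm_diff_defect(s, cfg),
        avg_tm_diff=avg_tm_diff(s, cfg),
        dimer_defect=dimer_defect(s, cfg),
        hairpin_defect=hairpin_defect(s, cfg),
        specificity_defect=specificity_defect(s, t),
        pcr_len_defect=pcr_len_defect(s.products, cfg),
    )
    partial = FitnessBreakdown(total=0.0, **bd)
    return FitnessBreakdown(total=partial.recombine(cfg), **bd)
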