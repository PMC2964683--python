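"""Template parsing and primer-set geometry for CTPP design.

A template is a SNP-flanking DNA string in which the genotyped SNP is a
single IUPAC ambiguity character (dbSNP flank exports in the bracket
dialect ``...A[A/C]G...`` are also accepted).  A candidate design is a
six-integer chromosome vector ``(Fl1, Pl1, Rl1, Fl2, Pl2, Rl2)`` — the
four primer lengths and the two short product lengths — from which all
four primer windows follow, given the SNP position:

* ``Pf1`` (outer forward) lies strictly upstream of the SNP;
* ``Pr1`` (inner reverse) ends 3' on the SNP and carries the complement
  of the minor allele;
* ``Pf2`` (inner forward) ends 3' on the SNP and carries the major
  allele;
* ``Pr2`` (outer reverse) lies strictly downstream of the SNP.

``Pf1/Pr1`` amplify the short upstream product (length ``Pl1``,
minor-allele specific), ``Pf2/Pr2`` the short downstream product
(``Pl2``, major-allele specific), and ``Pf1/Pr2`` the long common
product whose length obeys the confronting-overlap identity
``Pl3 = Pl1 + Pl2 - Rl1 - Fl2 + 1``.

Internally all coordinates are 0-based half-open; everything user
facing (reports, error messages, the ``CTPPPrimerSet`` coordinate
fields) uses 1-based inclusive positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes -> set of unambiguous bases.
IUPAC_EXPANSION: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}

AMBIGUITY_CODES = frozenset(c for c, e in IUPAC_EXPANSION.items() if len(e) > 1)

# base-set -> code, for mapping bracket alleles back to one character
_SET_TO_CODE: dict[frozenset, str] = {
    frozenset(e): c for c, e in IUPAC_EXPANSION.items()
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "M": "K", "K": "M", "R": "Y", "Y": "R", "W": "W", "S": "S",
    "V": "B", "B": "V", "H": "D", "D": "H", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

_VALID_CHARS = frozenset(IUPAC_EXPANSION)

_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")


class TemplateParseError(ValueError):
    """Raised when a flank record cannot be parsed into a template."""


class InfeasibleTemplateError(ValueError):
    """Raised when a template cannot host any admissible primer set."""


class RealizationError(ValueError):
    """Raised when a chromosome vector cannot be realized on a template."""


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Ambiguity codes are complemented set-wise (``M`` <-> ``K`` etc.);
    the operation is an involution.
    """
    bad = set(s.upper()) - _VALID_CHARS
    if bad:
        raise ValueError(f"invalid nucleotide code(s): {sorted(bad)}")
    return s.upper().translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class TemplateDNA:
    """A SNP-flanking template with one defined (genotyped) SNP.

    ``snp_index`` is 0-based; the 1-based position used in all reports
    is available as :attr:`snp_position`.  ``extra_snp_indices`` holds
    the 0-based positions of every additional ambiguity character.
    """

    sequence: str
    snp_index: int
    allele_major: str
    allele_minor: str
    extra_snp_indices: frozenset = field(default_factory=frozenset)
    record_id: str = "template"

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise TemplateParseError(f"invalid nucleotide code(s): {sorted(bad)}")
        if not (0 <= self.snp_index < len(seq)):
            raise TemplateParseError("SNP index outside template")
        code = seq[self.snp_index]
        expansion = IUPAC_EXPANSION[code]
        if len(expansion) < 2:
            raise TemplateParseError(
                f"character {code!r} at position {self.snp_index + 1} "
                "is not an ambiguity code"
            )
        if self.allele_major == self.allele_minor:
            raise TemplateParseError("major and minor alleles must differ")
        for allele in (self.allele_major, self.allele_minor):
            if allele not in expansion:
                raise TemplateParseError(
                    f"allele {allele!r} not in IUPAC expansion {expansion!r} "
                    f"of code {code!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def snp_position(self) -> int:
        """1-based SNP position (reporting convention)."""
        return self.snp_index + 1

    @property
    def snp_code(self) -> str:
        return self.sequence[self.snp_index]


class ChromosomeVector(NamedTuple):
    """GA individual: four primer lengths and two short product lengths."""

    fl1: int
    pl1: int
    rl1: int
    fl2: int
    pl2: int
    rl2: int


# position -> human-readable gene name, in chromosome order
GENE_NAMES = ("Fl1", "Pl1", "Rl1", "Fl2", "Pl2", "Rl2")


@dataclass(frozen=True)
class CTPPPrimerSet:
    """Four realized primers with 1-based inclusive template coordinates.

    ``pf1``/``pf2`` equal their sense template windows; ``pr1``/``pr2``
    are reverse complements of their windows, written 5'->3' in priming
    orientation.  ``pr1``'s 3' base is the complement of the minor
    allele and ``pf2``'s 3' base is the major allele; both sit on the
    SNP position.
    """

    pf1: str
    pr1: str
    pf2: str
    pr2: str
    fs1: int
    fe1: int
    rs1: int
    re1: int
    fs2: int
    fe2: int
    rs2: int
    re2: int
    pl1: int
    pl2: int
    pl3: int

    def primers(self) -> Iterator[tuple[str, str, str, int, int]]:
        """Yield (name, sequence, strand, start, end) rows, 1-based."""
        yield ("Pf1", self.pf1, "+", self.fs1, self.fe1)
        yield ("Pr1", self.pr1, "-", self.rs1, self.re1)
        yield ("Pf2", self.pf2, "+", self.fs2, self.fe2)
        yield ("Pr2", self.pr2, "-", self.rs2, self.re2)

    @property
    def sequences(self) -> tuple[str, str, str, str]:
        return (self.pf1, self.pr1, self.pf2, self.pr2)

    @property
    def products(self) -> tuple[int, int, int]:
        return (self.pl1, self.pl2, self.pl3)


def _code_for_alleles(alleles: Sequence[str]) -> str:
    key = frozenset(a.upper() for a in alleles)
    code = _SET_TO_CODE.get(key)
    if code is None:
        raise TemplateParseError(f"no IUPAC code for allele set {sorted(key)}")
    return code


def parse_template(
    text: str,
    dialect: str = "auto",
    alleles: Optional[Sequence[str]] = None,
    record_id: str = "template",
) -> TemplateDNA:
    """Parse a flank record into a :class:`TemplateDNA`.

    Parameters
    ----------
    text:
        The raw flank sequence, either with IUPAC ambiguity characters
        (``iupac`` dialect) or with one dbSNP-style bracket token
        ``[X/Y]`` (``bracket`` dialect).  ``auto`` picks bracket when a
        ``[...]`` token is present.
    alleles:
        ``(major, minor)`` designation.  dbSNP flanks do not label
        allele frequency, so when omitted the alleles are ordered
        alphabetically and a warning is logged.
    """
    text = "".join(text.split()).upper()
    if not text:
        raise TemplateParseError("empty flank record")
    if dialect == "auto":
        dialect = "bracket" if "[" in text else "iupac"

    if dialect == "bracket":
        tokens = _BRACKET_RE.findall(text)
        if len(tokens) != 1:
            raise TemplateParseError(
                f"bracket dialect requires exactly one [X/Y] token, found {len(tokens)}"
            )
        raw = tokens[0]
        parts = raw.split("/")
        if len(parts) < 2:
            raise TemplateParseError(f"malformed bracket token [{raw}]")
        for p in parts:
            if p == "-" or len(p) != 1 or p not in "ACGT":
                # deletion/insertion and multi-nucleotide polymorphisms
                # are outside the CTPP design model
                raise TemplateParseError(
                    f"bracket allele {p!r} is not a single nucleotide "
                    "(indels and multi-nucleotide variants are unsupported)"
                )
        code = _code_for_alleles(parts)
        m = _BRACKET_RE.search(text)
        snp_index = m.start()
        sequence = text[: m.start()] + code + text[m.end():]
        default_alleles = sorted(set(parts))[:2]
    elif dialect == "iupac":
        sequence = text
        ambiguous = [i for i, c in enumerate(sequence) if c in AMBIGUITY_CODES]
        if not ambiguous:
            raise TemplateParseError("no SNP found: sequence has no ambiguity code")
        snp_index = ambiguous[0]  # leftmost ambiguity is the defined SNP
        default_alleles = sorted(IUPAC_EXPANSION[sequence[snp_index]])[:2]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad = set(sequence) - _VALID_CHARS
    if bad:
        raise TemplateParseError(f"invalid nucleotide code(s): {sorted(bad)}")

    if alleles is None:
        major, minor = default_alleles
        logger.warning(
            "%s: no major/minor allele designation given; "
            "defaulting alphabetically to major=%s minor=%s",
            record_id, major, minor,
        )
    else:
        if len(alleles) != 2:
            raise TemplateParseError("alleles must be a (major, minor) pair")
        major, minor = (a.upper() for a in alleles)

    extra = frozenset(
        i for i, c in enumerate(sequence)
        if c in AMBIGUITY_CODES and i != snp_index
    )
    return TemplateDNA(
        sequence=sequence,
        snp_index=snp_index,
        allele_major=major,
        allele_minor=minor,
        extra_snp_indices=extra,
        record_id=record_id,
    )


# ---------------------------------------------------------------------------
# window geometry (0-based half-open internally)

def _windows(t: TemplateDNA, v: ChromosomeVector):
    """0-based half-open windows (pf1, pr1, pf2, pr2) for vector v."""
    s0 = t.snp_index
    pr1 = (s0, s0 + v.rl1)
    pf2 = (s0 - v.fl2 + 1, s0 + 1)
    f1_start = s0 + v.rl1 - v.pl1
    pf1 = (f1_start, f1_start + v.fl1)
    e2 = s0 - v.fl2 + 1 + v.pl2
    pr2 = (e2 - v.rl2, e2)
    return pf1, pr1, pf2, pr2


def is_feasible(
    t: TemplateDNA,
    v: ChromosomeVector,
    len_min: int = 16,
    len_max: int = 28,
    product_min: int = 100,
    reject_extra_in_inner: bool = True,
) -> bool:
    """Hard feasibility of a chromosome vector on a template.

    Checks primer-length bounds, template fit of all four windows, the
    strict upstream/downstream placement of the outer primers, and the
    extra-SNP exclusion rule (outer primers must never cover an
    additional polymorphic position; inner primers likewise unless
    ``reject_extra_in_inner`` is off).
    """
    for l in (v.fl1, v.rl1, v.fl2, v.rl2):
        if not (len_min <= l <= len_max):
            return False
    if v.pl1 < product_min or v.pl2 < product_min:
        return False
    pf1, pr1, pf2, pr2 = _windows(t, v)
    s0, L = t.snp_index, t.length
    if pf1[0] < 0 or pr2[1] > L:
        return False
    if pr1[1] > L or pf2[0] < 0:
        return False
    if pf1[1] > s0:       # outer forward strictly upstream of the SNP
        return False
    if pr2[0] <= s0:      # outer reverse strictly downstream
        return False
    extras = t.extra_snp_indices
    if extras:
        outer = [pf1, pr2]
        inner = [pr1, pf2] if reject_extra_in_inner else []
        for (a, b) in outer + inner:
            if any(a <= e < b for e in extras):
                return False
    return True


def _resolve(seq: str, start: int, end: int, overrides: dict[int, str]) -> str:
    """Template slice with position overrides; remaining ambiguity codes
    collapse to their alphabetically first expansion."""
    out = []
    for i in range(start, end):
        c = overrides.get(i, seq[i])
        if c in AMBIGUITY_CODES:
            c = IUPAC_EXPANSION[c][0]
        out.append(c)
    return "".join(out)


def realize_primer_set(
    t: TemplateDNA,
    v: ChromosomeVector,
    len_min: int = 16,
    len_max: int = 28,
    product_min: int = 100,
    reject_extra_in_inner: bool = True,
) -> CTPPPrimerSet:
    """Realize a chromosome vector into four concrete primer sequences.

    Raises :class:`RealizationError` if the vector is infeasible on the
    template (window out of bounds, outer primer covering the SNP, or a
    primer window covering an additional polymorphic position).
    """
    if not is_feasible(t, v, len_min, len_max, product_min, reject_extra_in_inner):
        raise RealizationError(
            f"vector {tuple(v)} infeasible on template "
            f"{t.record_id!r} (length {t.length}, SNP at {t.snp_position})"
        )
    pf1w, pr1w, pf2w, pr2w = _windows(t, v)
    seq = t.sequence
    s0 = t.snp_index

    pf1 = _resolve(seq, *pf1w, {})
    pf2 = _resolve(seq, *pf2w, {s0: t.allele_major})
    pr1 = reverse_complement(_resolve(seq, *pr1w, {s0: t.allele_minor}))
    pr2 = reverse_complement(_resolve(seq, *pr2w, {}))

    pl3 = v.pl1 + v.pl2 - v.rl1 - v.fl2 + 1
    return CTPPPrimerSet(
        pf1=pf1, pr1=pr1, pf2=pf2, pr2=pr2,
        fs1=pf1w[0] + 1, fe1=pf1w[1],
        rs1=pr1w[0] + 1, re1=pr1w[1],
        fs2=pf2w[0] + 1, fe2=pf2w[1],
        rs2=pr2w[0] + 1, re2=pr2w[1],
        pl1=v.pl1, pl2=v.pl2, pl3=pl3,
    )


def feasible_bounds(
    t: TemplateDNA,
    len_max: int = 28,
    product_min: int = 100,
) -> tuple[int, int]:
    """Maximal feasible short-product lengths (delta1, delta2).

    ``delta1`` is the largest ``Pl1`` for which the upstream product
    window still fits the template for some admissible ``Rl1``
    (``Pl1`` may start at template position 1); ``delta2`` is the
    downstream analogue.  Raises :class:`InfeasibleTemplateError` when
    either side cannot host a product of at least ``product_min``.
    """
    s0, L = t.snp_index, t.length
    rl1_eff = min(len_max, L - s0)
    fl2_eff = min(len_max, s0 + 1)
    delta1 = s0 + rl1_eff          # = snp_position + rl1 - 1 in 1-based terms
    delta2 = (L - 1 - s0) + fl2_eff
    if delta1 < product_min:
        raise InfeasibleTemplateError(
            f"upstream flank too short: max product {delta1} < {product_min}"
        )
    if delta2 < product_min:
        raise InfeasibleTemplateError(
            f"downstream flank too short: max product {delta2} < {product_min}"
        )
    return delta1, delta2
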