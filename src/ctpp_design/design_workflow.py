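"""End-user surface: single-SNP design, batch design, and reports.

A :class:`DesignReport` is self-verifying: every printed number (GC%,
Tm, product lengths, the fitness total) is recomputable from the
printed primer sequences plus the echoed configuration, and reports
echo every default that matters to interpretation (salt concentration,
screen thresholds, ratio tolerance, weights, seed).

Batch statistics follow the per-set check counts of the design: four
per-primer checks (GC%, GC clamp, Tm, hairpin, specificity each have
4 checks per set), three pair checks (length difference, Tm
difference, product length), and ten dimer checks, so for *n* designed
sets the denominators are 4n, 3n and 10n.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, TextIO, Union

from Bio import SeqIO

from .constraint_fitness import (
    ConstraintConfig,
    FitnessBreakdown,
    dimer_checks,
    gc_clamp_checks,
    gc_percent,
    gc_proportion_checks,
    hairpin_checks,
    len_diff_checks,
    pcr_len_checks,
    ratio_checks,
    specificity_checks,
    tm_bm,
    tm_diff_checks,
    tm_pair_diffs,
    tm_range_checks,
)
from .ga_engine import GAConfig, GAResult, run_ga
from .sequence_model import CTPPPrimerSet, TemplateDNA, parse_template

logger = logging.getLogger(__name__)

PAIR_NAMES = ("Pf1/Pr1", "Pf2/Pr2", "Pf1/Pr2")


@dataclass(frozen=True)
class PrimerRow:
    name: str
    sequence: str
    length: int
    gc: float
    tm: float
    start: int
    end: int
    strand: str


@dataclass
class DesignReport:
    """Full record of one design run, ready for TSV or text output."""

    record_id: str
    template_length: int
    snp_position: int
    allele_major: str
    allele_minor: str
    vector: tuple
    rows: list
    products: tuple            # (Pl1, Pl2, Pl3)
    tm_diffs: tuple            # |Tm| gaps for the three working pairs
    breakdown: FitnessBreakdown
    config_echo: dict
    seed: Optional[int]
    generations_run: int
    converged: bool
    primer_set: CTPPPrimerSet = field(repr=False, default=None)


def _config_echo(cfg: ConstraintConfig, ga: GAConfig) -> dict:
    return {
        "na_molar": cfg.na_molar,
        "len_min": cfg.len_min,
        "len_max": cfg.len_max,
        "len_diff_max": cfg.len_diff_max,
        "gc_low": cfg.gc_low,
        "gc_high": cfg.gc_high,
        "tm_low": cfg.tm_low,
        "tm_high": cfg.tm_high,
        "tm_diff_max": cfg.tm_diff_max,
        "product_min": cfg.product_min,
        "ratios": ",".join(str(r) for r in cfg.ratios),
        "ratio_tolerance": cfg.ratio_tolerance,
        "dimer_stem_min": cfg.dimer_stem_min,
        "dimer_3p_min": cfg.dimer_3p_min,
        "hairpin_stem_min": cfg.hairpin_stem_min,
        "hairpin_loop_min": cfg.hairpin_loop_min,
        "weights": ",".join(str(w) for w in cfg.weights),
        "population_size": ga.population_size,
        "max_generations": ga.max_generations,
        "crossover_prob": ga.crossover_prob,
        "mutation_prob": ga.mutation_prob,
        "seed": ga.seed,
    }


def report_from_result(
    t: TemplateDNA, result: GAResult, cfg: ConstraintConfig, ga: GAConfig
) -> DesignReport:
    s = result.primer_set
    rows = [
        PrimerRow(
            name=name,
            sequence=seq,
            length=len(seq),
            gc=gc_percent(seq),
            tm=tm_bm(seq, cfg.na_molar),
            start=start,
            end=end,
            strand=strand,
        )
        for name, seq, strand, start, end in s.primers()
    ]
    return DesignReport(
        record_id=t.record_id,
        template_length=t.length,
        snp_position=t.snp_position,
        allele_major=t.allele_major,
        allele_minor=t.allele_minor,
        vector=tuple(result.best_vector),
        rows=rows,
        products=s.products,
        tm_diffs=tm_pair_diffs(s, cfg),
        breakdown=result.best_breakdown,
        config_echo=_config_echo(cfg, ga),
        seed=ga.seed,
        generations_run=result.generations_run,
        converged=result.converged,
        primer_set=s,
    )


def design_one(
    record: Union[str, TemplateDNA],
    cfg: Optional[ConstraintConfig] = None,
    ga: Optional[GAConfig] = None,
    dialect: str = "auto",
    alleles: Optional[Sequence[str]] = None,
    record_id: str = "template",
) -> DesignReport:
    """Run the full GA on one flank record and build its report."""
    cfg = cfg or ConstraintConfig()
    ga = ga or GAConfig()
    if isinstance(record, TemplateDNA):
        t = record
    else:
        t = parse_template(record, dialect=dialect, alleles=alleles, record_id=record_id)
    result = run_ga(t, cfg, ga)
    return report_from_result(t, result, cfg, ga)


# ---------------------------------------------------------------------------
# batch design and Table-1-style statistics

CONSTRAINT_COLUMNS = (
    ("length_difference", 3),
    ("gc_percent", 4),
    ("gc_clamp", 4),
    ("tm", 4),
    ("tm_difference", 3),
    ("product_length", 3),
    ("dimer", 10),
    ("hairpin", 4),
    ("specificity", 4),
)


@dataclass
class BatchStatistics:
    """Constraint-satisfaction counts over a batch of designed sets.

    ``counts[name] = (satisfied, total)`` where totals are linear in
    the number of sets *n*: 4n for per-primer checks, 3n for pair
    checks, 10n for dimer checks.
    """

    n_sets: int
    counts: dict

    @classmethod
    def empty(cls) -> "BatchStatistics":
        return cls(n_sets=0, counts={name: (0, 0) for name, _ in CONSTRAINT_COLUMNS})

    def add_design(
        self,
        t: TemplateDNA,
        s: CTPPPrimerSet,
        vector,
        cfg: ConstraintConfig,
    ) -> None:
        from .sequence_model import ChromosomeVector

        v = ChromosomeVector(*vector)
        floors = [pl > cfg.product_min for pl in s.products]
        ratios = ratio_checks(s.products, cfg)
        per_set = {
            "length_difference": len_diff_checks(v, cfg),
            "gc_percent": gc_proportion_checks(s, cfg),
            "gc_clamp": gc_clamp_checks(s, cfg),
            "tm": tm_range_checks(s, cfg),
            "tm_difference": tm_diff_checks(s, cfg),
            # a product counts as satisfied when it clears the length
            # floor and sits on its band-separation ratio
            "product_length": [f and r for f, r in zip(floors, ratios)],
            "dimer": dimer_checks(s, cfg),
            "hairpin": hairpin_checks(s, cfg),
            "specificity": specificity_checks(s, t),
        }
        self.n_sets += 1
        for name, checks in per_set.items():
            sat, tot = self.counts[name]
            self.counts[name] = (sat + sum(checks), tot + len(checks))

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("constraint\tsatisfied\ttotal\n")
        for name, _ in CONSTRAINT_COLUMNS:
            sat, tot = self.counts[name]
            out.write(f"{name}\t{sat}\t{tot}\n")
        return out.getvalue()


def iter_flank_records(path_or_handle, dialect: str = "auto"):
    """Yield ``(record_id, raw_text)`` from a FASTA or plain flank file."""
    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            text = fh.read()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        body = "".join(text.split())
        if body:
            yield "template", body


def design_batch(
    records: Iterable,
    cfg: Optional[ConstraintConfig] = None,
    ga: Optional[GAConfig] = None,
    dialect: str = "auto",
    alleles: Optional[Sequence[str]] = None,
) -> tuple[list, BatchStatistics]:
    """Independent seeded design per record plus aggregate statistics.

    ``records`` yields ``(record_id, text)`` pairs or ready
    :class:`TemplateDNA` objects.  Record *i* runs with seed
    ``master_seed + i`` so a single-record rerun with that seed
    reproduces its batch result exactly.
    """
    cfg = cfg or ConstraintConfig()
    ga = ga or GAConfig()
    master_seed = ga.seed if ga.seed is not None else 0
    reports = []
    stats = BatchStatistics.empty()
    for i, rec in enumerate(records):
        sub = replace(ga, seed=master_seed + i)
        if isinstance(rec, TemplateDNA):
            report = design_one(rec, cfg, sub)
            t = rec
        else:
            rec_id, text = rec
            t = parse_template(text, dialect=dialect, alleles=alleles, record_id=rec_id)
            report = design_one(t, cfg, sub)
        reports.append(report)
        stats.add_design(t, report.primer_set, report.vector, cfg)
    return reports, stats


# ---------------------------------------------------------------------------
# report I/O

TSV_PRIMER_COLUMNS = ("name", "sequence", "length", "gc_percent", "tm", "start", "end", "strand")


def write_report(report: DesignReport, out: Union[str, TextIO], format: str = "tsv") -> None:
    """Write a report as TSV (machine-readable) or text (table layout)."""
    if format not in ("tsv", "text"):
        raise ValueError(f"unknown report format {format!r}")
    own = isinstance(out, str)
    fh = open(out, "w") if own else out
    try:
        if format == "tsv":
            _write_tsv(report, fh)
        else:
            _write_text(report, fh)
    finally:
        if own:
            fh.close()


def _header_lines(report: DesignReport):
    yield f"record_id\t{report.record_id}"
    yield f"template_length\t{report.template_length}"
    yield f"snp_position\t{report.snp_position}"
    yield f"allele_major\t{report.allele_major}"
    yield f"allele_minor\t{report.allele_minor}"
    yield "vector\t" + ",".join(str(x) for x in report.vector)
    for key, val in report.config_echo.items():
        yield f"{key}\t{val}"
    yield f"generations_run\t{report.generations_run}"
    yield f"converged\t{report.converged}"


def _write_tsv(report: DesignReport, fh: TextIO) -> None:
    for line in _header_lines(report):
        fh.write(f"# {line}\n")
    fh.write("\t".join(TSV_PRIMER_COLUMNS) + "\n")
    for r in report.rows:
        fh.write(
            f"{r.name}\t{r.sequence}\t{r.length}\t{r.gc:.2f}\t{r.tm:.4f}"
            f"\t{r.start}\t{r.end}\t{r.strand}\n"
        )
    for name, pl in zip(("Pl1", "Pl2", "Pl3"), report.products):
        fh.write(f"# product\t{name}\t{pl}\n")
    for name, d in zip(PAIR_NAMES, report.tm_diffs):
        fh.write(f"# tm_diff\t{name}\t{d:.4f}\n")
    bd = report.breakdown
    for key in (
        "len_diff_defect", "gc_proportion_defect", "gc_clamp_defect",
        "tm_defect", "tm_diff_defect", "dimer_defect", "hairpin_defect",
        "specificity_defect", "pcr_len_defect",
    ):
        fh.write(f"# defect\t{key}\t{getattr(bd, key)}\n")
    fh.write(f"# defect\tavg_tm_diff\t{bd.avg_tm_diff:.6f}\n")
    fh.write(f"# fitness_total\t{bd.total:.6f}\n")


def _write_text(report: DesignReport, fh: TextIO) -> None:
    fh.write(f"CTPP primer set for {report.record_id}\n")
    fh.write(
        f"template {report.template_length} bp, SNP at {report.snp_position} "
        f"({report.allele_major}/{report.allele_minor}), "
        f"Na+ {report.config_echo['na_molar']} M, seed {report.seed}\n\n"
    )
    seq_col = "Sequence (5'->3')"
    header = (
        f"{'Primer':<6} {seq_col:<32} {'Len':>4} {'GC%':>6} {'Tm':>7} "
        f"{'Start':>7} {'End':>7} {'Strand':>6}"
    )
    fh.write(header + "\n")
    fh.write("-" * len(header) + "\n")
    for r in report.rows:
        fh.write(
            f"{r.name:<6} {r.sequence:<32} {r.length:>4} {r.gc:>6.1f} "
            f"{r.tm:>7.2f} {r.start:>7} {r.end:>7} {r.strand:>6}\n"
        )
    fh.write("\nProduct sizes (bp): ")
    fh.write(", ".join(
        f"{name} ({pair}) = {pl}"
        for name, pair, pl in zip(("Pl1", "Pl2", "Pl3"), PAIR_NAMES, report.products)
    ))
    fh.write("\nTm differences (C): ")
    fh.write(", ".join(f"{p} = {d:.2f}" for p, d in zip(PAIR_NAMES, report.tm_diffs)))
    fh.write(f"\nFitness total: {report.breakdown.total:.4f}")
    fh.write(f" ({'optimal' if report.converged else 'best effort'}, ")
    fh.write(f"{report.generations_run} generations)\n")


def read_report_tsv(path_or_handle) -> dict:
    """Re-parse a TSV report into header fields, primer rows and defects.

    The round trip is lossless for coordinates and sequences, so the
    returned rows can be re-verified against the template and config.
    """
    own = isinstance(path_or_handle, str)
    fh = open(path_or_handle) if own else path_or_handle
    try:
        header: dict = {}
        rows: list = []
        products: dict = {}
        tm_diffs: dict = {}
        defects: dict = {}
        total = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                parts = line[2:].split("\t")
                if parts[0] == "product":
                    products[parts[1]] = int(parts[2])
                elif parts[0] == "tm_diff":
                    tm_diffs[parts[1]] = float(parts[2])
                elif parts[0] == "defect":
                    defects[parts[1]] = float(parts[2])
                elif parts[0] == "fitness_total":
                    total = float(parts[1])
                else:
                    header[parts[0]] = parts[1] if len(parts) > 1 else ""
            elif not line.startswith("name\t"):
                vals = line.split("\t")
                rows.append(dict(zip(TSV_PRIMER_COLUMNS, vals)))
        return {
            "header": header,
            "rows": rows,
            "products": products,
            "tm_diffs": tm_diffs,
            "defects": defects,
            "fitness_total": total,
        }
    finally:
        if own:
            fh.close()


def write_trace(trace, out: Union[str, TextIO]) -> None:
    """Per-generation best/mean fitness as TSV."""
    own = isinstance(out, str)
    fh = open(out, "w") if own else out
    try:
        fh.write("generation\tbest_fitness\tmean_fitness\n")
        for gen, best, mean in trace:
            fh.write(f"{gen}\t{best:.6f}\t{mean:.6f}\n")
    finally:
        if own:
            fh.close()
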