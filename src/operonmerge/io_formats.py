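"""Readers and writers for annotations, expression tables, priors and reports.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read.  All tabular formats are plain TSV.  Lines starting with
``#`` are treated as comments in every reader so that files written with a
provenance header round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from operonmerge._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}

_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 0-based half-open coordinates on a stranded contig."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )


class GeneCatalog:
    """Ordered, stranded gene records; defines per-contig rank and adjacency.

    Rank is the 0-based position of a gene within its contig when genes are
    sorted by ascending start (overlaps are ignored; start order is the total
    order used for adjacency).
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        self._by_id: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            self._by_id[rec.gene_id] = rec
        self._contig_genes: dict[str, list[str]] = {}
        for contig in sorted({r.contig for r in self.records}):
            ordered = sorted(
                (r for r in self.records if r.contig == contig),
                key=lambda r: (r.start, r.end, r.gene_id),
            )
            self._contig_genes[contig] = [r.gene_id for r in ordered]
        self._rank: dict[str, int] = {
            gid: i
            for genes in self._contig_genes.values()
            for i, gid in enumerate(genes)
        }

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def contigs(self) -> list[str]:
        return list(self._contig_genes)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ValidationError(f"gene_id {gene_id!r} not in catalog") from None

    def rank(self, gene_id: str) -> int:
        self.gene(gene_id)
        return self._rank[gene_id]

    def genes_in_contig(self, contig: str) -> list[str]:
        return list(self._contig_genes[contig])

    def gene_at(self, contig: str, rank: int) -> str:
        return self._contig_genes[contig][rank]


@dataclass
class ExpressionMatrix:
    """Log-expression values per gene over shared timepoints (hours)."""

    timepoints_h: np.ndarray
    profiles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        if self.timepoints_h.ndim != 1:
            raise ValidationError("timepoints must be a 1-D vector")
        if len(self.timepoints_h) >= 2 and not np.all(np.diff(self.timepoints_h) > 0):
            raise ValidationError("timepoints must be strictly increasing")
        n = len(self.timepoints_h)
        for gid, vals in self.profiles.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValidationError(
                    f"profile {gid!r} has {vals.size} values, expected {n}"
                )
            self.profiles[gid] = vals

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.profiles

    def is_usable(self, gene_id: str) -> bool:
        """A profile is usable if present, finite throughout and length >= 2."""
        vals = self.profiles.get(gene_id)
        return (
            vals is not None and vals.size >= 2 and bool(np.all(np.isfinite(vals)))
        )


@dataclass(frozen=True)
class OperonPrediction:
    """An ordered run of same-strand, same-contig, consecutive-rank gene ids."""

    operon_id: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValidationError(f"prediction {self.operon_id!r} has no genes")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    def validate(self, catalog: GeneCatalog) -> None:
        recs = [catalog.gene(g) for g in self.gene_ids]
        contigs = {r.contig for r in recs}
        if len(contigs) > 1:
            raise ValidationError(
                f"prediction {self.operon_id!r} spans contigs {sorted(contigs)}"
            )
        strands = {r.strand for r in recs}
        if len(strands) > 1:
            raise ValidationError(f"prediction {self.operon_id!r} mixes strands")
        ranks = [catalog.rank(g) for g in self.gene_ids]
        if sorted(ranks) != list(range(min(ranks), min(ranks) + len(ranks))):
            raise ValidationError(
                f"prediction {self.operon_id!r} lists non-consecutive ranks {ranks}"
            )


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path, format: str | None = None) -> GeneCatalog:
    """Read a gene annotation (GFF3 or simple TSV) into a :class:`GeneCatalog`.

    ``format`` is ``"gff3"`` or ``"tsv"``; if ``None`` it is inferred from the
    file extension (.gff/.gff3 -> gff3, otherwise tsv).
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if format == "gff3":
        records = _read_gff3(path)
    elif format == "tsv":
        records = _read_annotation_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GeneCatalog(records)


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def _read_annotation_tsv(path: Path) -> list[GeneRecord]:
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty annotation")
    header = rows[0][1].split("\t")
    expected = ["gene_id", "contig", "strand", "start", "end"]
    if header != expected:
        raise FormatError(f"{path}: header {header} != {expected}")
    records = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        gid, contig, strand, start, end = fields
        if strand not in _STRANDS:
            raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            record = GeneRecord(gid, contig, strand, int(start), int(end))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(record)
    return records


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            attrs[key] = value
    return attrs


def _read_gff3(path: Path) -> list[GeneRecord]:
    by_type: dict[str, list[GeneRecord]] = {"gene": [], "CDS": []}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
        contig, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
        if ftype not in by_type:
            continue
        if strand not in _STRANDS:
            raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        attrs = _parse_gff3_attributes(attr_text)
        gid = attrs.get("ID")
        if gid is None:
            raise FormatError(f"{path}:{lineno}: feature lacks an ID attribute")
        try:
            # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
            record = GeneRecord(gid, contig, strand, int(start) - 1, int(end))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        by_type[ftype].append(record)
    records = by_type["gene"] or by_type["CDS"]
    if not records:
        raise FormatError(f"{path}: no gene or CDS features found")
    return records


def write_annotation_tsv(
    catalog: GeneCatalog, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tcontig\tstrand\tstart\tend\n")
        for rec in catalog.records:
            fh.write(f"{rec.gene_id}\t{rec.contig}\t{rec.strand}\t{rec.start}\t{rec.end}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table: first column gene id, other headers hours.

    Columns are reordered so timepoints ascend.  ``NA``/empty cells become
    NaN; any other non-numeric cell is a hard error naming gene and column.
    """
    path = Path(path)
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty expression table")
    header = rows[0][1].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expression table needs at least one timepoint")
    try:
        hours = [float(h) for h in header[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric timepoint header: {exc}") from exc
    order = np.argsort(hours, kind="stable")
    timepoints = np.asarray(hours, dtype=float)[order]
    if len(timepoints) >= 2 and not np.all(np.diff(timepoints) > 0):
        raise FormatError(f"{path}: duplicate timepoint headers {hours}")
    n_cols = len(header)
    profiles: dict[str, np.ndarray] = {}
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} columns, expected {n_cols})"
            )
        gid = fields[0]
        if gid in profiles:
            raise FormatError(f"{path}:{lineno}: duplicate gene row {gid!r}")
        values = np.empty(n_cols - 1)
        for j, cell in enumerate(fields[1:]):
            if cell.strip() in _MISSING_TOKENS:
                values[j] = np.nan
                continue
            try:
                values[j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} for gene "
                    f"{gid!r}, column {header[j + 1]!r}"
                ) from None
        profiles[gid] = values[order]
    return ExpressionMatrix(timepoints_h=timepoints, profiles=profiles)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cols = "\t".join(_format_hours(t) for t in matrix.timepoints_h)
        fh.write(f"gene_id\t{cols}\n")
        for gid, vals in matrix.profiles.items():
            cells = "\t".join("NA" if np.isnan(v) else repr(float(v)) for v in vals)
            fh.write(f"{gid}\t{cells}\n")


def _format_hours(t: float) -> str:
    return f"{t:g}"


# ---------------------------------------------------------------------------
# prior operon predictions


def _prior_id(index: int) -> str:
    return f"P{index + 1:04d}"


def read_prior_operons(
    path: str | Path, format: str, catalog: GeneCatalog
) -> list[OperonPrediction]:
    """Read prior operon predictions and validate them against the catalog.

    ``operon_list``: one operon per line, whitespace-separated gene ids.
    ``gene_pairs``: two-column adjacent-gene-pair rows, chained into maximal
    consecutive same-strand runs (union of the pair graph).
    """
    path = Path(path)
    if format == "operon_list":
        priors = _read_operon_list(path)
    elif format == "gene_pairs":
        priors = _read_gene_pairs(path, catalog)
    else:
        raise ValueError(f"unknown prior format {format!r}")
    for prior in priors:
        prior.validate(catalog)
    return priors


def _read_operon_list(path: Path) -> list[OperonPrediction]:
    priors = []
    for _lineno, line in _data_lines(path):
        gene_ids = tuple(line.split())
        priors.append(OperonPrediction(_prior_id(len(priors)), gene_ids))
    return priors


def _read_gene_pairs(path: Path, catalog: GeneCatalog) -> list[OperonPrediction]:
    adjacency: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        a, b = fields
        ra, rb = catalog.gene(a), catalog.gene(b)
        if ra.contig != rb.contig:
            raise FormatError(f"{path}:{lineno}: pair ({a}, {b}) spans contigs")
        if ra.strand != rb.strand:
            raise FormatError(f"{path}:{lineno}: pair ({a}, {b}) spans strands")
        if abs(catalog.rank(a) - catalog.rank(b)) != 1:
            raise FormatError(
                f"{path}:{lineno}: pair ({a}, {b}) is not rank-adjacent"
            )
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    # Union of rank-adjacent edges: components are maximal consecutive runs.
    seen: set[str] = set()
    runs: list[tuple[str, int, list[str]]] = []
    for gid in adjacency:
        if gid in seen:
            continue
        component = {gid}
        stack = [gid]
        while stack:
            for nxt in adjacency[stack.pop()]:
                if nxt not in component:
                    component.add(nxt)
                    stack.append(nxt)
        seen |= component
        ordered = sorted(component, key=catalog.rank)
        contig = catalog.gene(ordered[0]).contig
        runs.append((contig, catalog.rank(ordered[0]), ordered))
    runs.sort(key=lambda item: (item[0], item[1]))
    return [
        OperonPrediction(_prior_id(i), tuple(genes))
        for i, (_contig, _rank, genes) in enumerate(runs)
    ]


def write_prior_operons(
    priors: Sequence[OperonPrediction], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write priors in the operon_list dialect (ids are positional)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for prior in priors:
            fh.write("\t".join(prior.gene_ids) + "\n")


# ---------------------------------------------------------------------------
# merge report

REPORT_COLUMNS = ["score", "prior1_id", "prior1_genes", "prior2_id", "prior2_genes", "merged"]


def _format_score(score: float) -> str:
    return str(Decimal(repr(float(score))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def write_merge_report(candidates, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write scored merge candidates as a TSV, sorted by descending score.

    Scores are printed with 3 decimals (half-up).  ``merged`` is true/false.
    """
    for cand in candidates:
        if cand.score is None or cand.merged is None:
            raise ValidationError(
                f"candidate ({cand.prior1.operon_id}, {cand.prior2.operon_id}) is unscored"
            )
    ordered = sorted(candidates, key=lambda c: -c.score)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for cand in ordered:
            fh.write(
                "\t".join(
                    [
                        _format_score(cand.score),
                        cand.prior1.operon_id,
                        ",".join(cand.prior1.gene_ids),
                        cand.prior2.operon_id,
                        ",".join(cand.prior2.gene_ids),
                        "true" if cand.merged else "false",
                    ]
                )
                + "\n"
            )


def read_merge_report(path: str | Path) -> list[dict]:
    """Read a merge report back as a list of row dicts (scores as floats)."""
    path = Path(path)
    rows = list(_data_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty report")
    header = rows[0][1].split("\t")
    if header != REPORT_COLUMNS:
        raise FormatError(f"{path}: header {header} != {REPORT_COLUMNS}")
    out = []
    for lineno, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != len(REPORT_COLUMNS):
            raise FormatError(f"{path}:{lineno}: ragged report row")
        row = dict(zip(REPORT_COLUMNS, fields))
        row["score"] = float(row["score"])
        row["merged"] = row["merged"] == "true"
        out.append(row)
    return out
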