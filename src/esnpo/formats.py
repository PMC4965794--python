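"""Readers and writers for the external file formats the toolkit touches.

Every parser reports malformed rows with line numbers.  In strict mode
(the default) a malformed row aborts the read; in lenient mode it is
skipped and collected into the table's ``issues`` list, so that
``rows_in == rows_out + len(issues)`` always holds.

All genomic coordinates are normalised to 0-based half-open intervals on
read: BED is taken as-is, GFF start positions are decremented by one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "RowIssue",
    "EqtlAssociation",
    "EqtlTable",
    "GeneInterval",
    "SnpLocus",
    "SnpList",
    "read_eqtl_table",
    "read_snp_list",
    "read_gene_intervals",
    "read_snp_loci",
    "write_association_table",
    "read_association_table",
    "write_enrichment_report",
    "read_enrichment_report",
]

#: Default pattern a SNP identifier must match to count as a reference
#: SNP name (dbSNP rsID).  Positional names like ``chr1:12345`` fail it.
RSID_PATTERN = r"rs\d+"


class FormatError(ValueError):
    """A file could not be parsed under the requested contract."""


@dataclass(frozen=True)
class RowIssue:
    """One malformed input row, reported with its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


@dataclass(frozen=True)
class EqtlAssociation:
    """One SNP-gene association from an eQTL study."""

    snp_id: str
    gene: str
    fdr: float
    tissue: str


@dataclass
class EqtlTable:
    """A set of eQTL associations from one source, with parse diagnostics."""

    records: list[EqtlAssociation]
    tissue_label: str
    source_label: str = ""
    issues: list[RowIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneInterval:
    """A gene body on a chromosome, 0-based half-open."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."


@dataclass(frozen=True)
class SnpLocus:
    """A SNP position on a chromosome, 0-based."""

    snp_id: str
    chrom: str
    pos: int


@dataclass(frozen=True)
class SnpList:
    """An ordered, de-duplicated query SNP list."""

    snps: tuple[str, ...]
    n_raw: int

    @property
    def n_unique(self) -> int:
        return len(self.snps)


def read_eqtl_table(
    path: str | Path,
    column_map: Mapping[str, str],
    tissue: str,
    *,
    delimiter: str = "\t",
    strict: bool = True,
    source_label: str = "",
) -> EqtlTable:
    """Read a delimited eQTL association table.

    Parameters
    ----------
    column_map
        Maps the logical names ``snp``, ``gene``, ``fdr`` onto the actual
        header names of the file.
    strict
        If True (default), any unparseable row raises :class:`FormatError`;
        otherwise bad rows are skipped and reported in ``issues``.

    No filtering (FDR threshold, rsID pattern) is applied at read time;
    see :func:`esnpo.builder.filter_eqtl`.
    """
    for key in ("snp", "gene", "fdr"):
        if key not in column_map:
            raise FormatError(f"column_map must map logical column {key!r}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mapped column(s) {', '.join(missing)}; "
            f"found columns {', '.join(df.columns)}"
        )
    records: list[EqtlAssociation] = []
    issues: list[RowIssue] = []
    snp_c, gene_c, fdr_c = (column_map[k] for k in ("snp", "gene", "fdr"))
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        mapping = dict(zip(df.columns, row))
        snp = (mapping[snp_c] or "").strip() if isinstance(mapping[snp_c], str) else ""
        gene = (mapping[gene_c] or "").strip() if isinstance(mapping[gene_c], str) else ""
        raw_fdr = mapping[fdr_c]
        problem = None
        fdr = float("nan")
        if not snp:
            problem = "empty SNP identifier"
        elif not gene:
            problem = "empty gene symbol"
        else:
            try:
                fdr = float(raw_fdr)
            except (TypeError, ValueError):
                problem = f"unparseable FDR value {raw_fdr!r}"
            else:
                if not 0.0 <= fdr <= 1.0:
                    problem = f"FDR {fdr} outside [0, 1]"
        if problem is not None:
            if strict:
                raise FormatError(f"{path}: line {line}: {problem}")
            issues.append(RowIssue(line, problem))
            continue
        records.append(EqtlAssociation(snp, gene, fdr, tissue))
    return EqtlTable(records, tissue_label=tissue, source_label=source_label, issues=issues)


def read_snp_list(path: str | Path) -> SnpList:
    """Read a plain-text SNP list (one identifier per line).

    Blank lines and ``#`` comments are ignored; duplicates are removed
    preserving first occurrence.  Raises :class:`FormatError` if nothing
    is read.
    """
    seen: dict[str, None] = {}
    n_raw = 0
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            n_raw += 1
            seen.setdefault(token, None)
    if not seen:
        raise FormatError(f"{path}: no SNPs read")
    return SnpList(tuple(seen), n_raw=n_raw)


def _parse_gff_gene(attributes: str) -> str:
    for key in ("Name", "gene_name", "gene_id", "ID"):
        m = re.search(rf"(?:^|;)\s*{key}[=\s]\"?([^;\"]+)\"?", attributes)
        if m:
            return m.group(1).strip()
    return ""


def read_gene_intervals(
    path: str | Path,
    dialect: str,
    *,
    strict: bool = True,
) -> tuple[list[GeneInterval], list[RowIssue]]:
    """Read gene intervals from a BED or GFF file.

    BED is 0-based half-open and taken as-is; GFF is 1-based inclusive and
    converted (start − 1).  Returns the intervals plus any row issues
    (only populated in lenient mode).
    """
    if dialect not in ("bed", "gff"):
        raise FormatError(f"unknown dialect {dialect!r} (expected 'bed' or 'gff')")
    intervals: list[GeneInterval] = []
    issues: list[RowIssue] = []

    def fail(line: int, msg: str) -> None:
        if strict:
            raise FormatError(f"{path}: line {line}: {msg}")
        issues.append(RowIssue(line, msg))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED row needs >= 4 columns (chrom,start,end,name)")
                    chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF row needs 9 columns")
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                    end = int(fields[4])
                    strand = fields[6]
                    gene = _parse_gff_gene(fields[8])
                    if not gene:
                        raise ValueError("no gene name in GFF attributes")
            except ValueError as exc:
                fail(lineno, str(exc))
                continue
            if start >= end:
                fail(lineno, f"empty interval after normalisation: start={start} end={end}")
                continue
            if start < 0:
                fail(lineno, f"negative start {start}")
                continue
            intervals.append(GeneInterval(gene, chrom, start, end, strand))
    return intervals, issues


def read_snp_loci(path: str | Path, *, strict: bool = True) -> tuple[list[SnpLocus], list[RowIssue]]:
    """Read a SNP locus table (TSV with header columns snp, chrom, pos; 0-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("snp", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    loci: list[SnpLocus] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        mapping = dict(zip(df.columns, row))
        try:
            pos = int(mapping["pos"])
            if pos < 0:
                raise ValueError(f"negative position {pos}")
        except (TypeError, ValueError) as exc:
            if strict:
                raise FormatError(f"{path}: line {line}: {exc}")
            issues.append(RowIssue(line, str(exc)))
            continue
        loci.append(SnpLocus(str(mapping["snp"]), str(mapping["chrom"]), pos))
    return loci, issues


# ---------------------------------------------------------------------------
# Association tables (the serialised SNP -> GO-term map)
# ---------------------------------------------------------------------------

_ASSOC_COLUMNS = ("snp", "term", "namespace", "tissues", "genes")


def write_association_table(associations: Iterable, path: str | Path) -> None:
    """Write SNP-term associations as TSV, deterministically ordered.

    Rows are sorted by (snp, term); the mediating-gene and tissue sets are
    semicolon-joined in sorted order, so identical association sets always
    serialise byte-identically.
    """
    rows = sorted(associations, key=lambda a: (a.snp_id, a.term))
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for a in rows:
            fh.write(
                "\t".join(
                    (
                        a.snp_id,
                        a.term,
                        a.namespace,
                        ";".join(sorted(a.tissues)),
                        ";".join(sorted(a.genes)),
                    )
                )
                + "\n"
            )


def read_association_table(path: str | Path) -> list:
    """Read back a TSV association table written by :func:`write_association_table`."""
    from .builder import SnpTermAssociation  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        out.append(
            SnpTermAssociation(
                snp_id=rec["snp"],
                term=rec["term"],
                namespace=rec["namespace"],
                genes=frozenset(str(rec["genes"]).split(";")),
                tissues=frozenset(str(rec["tissues"]).split(";")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Enrichment reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = (
    "term",
    "name",
    "namespace",
    "N",
    "M",
    "n",
    "m",
    "p",
    "p_adj",
    "significant",
    "query_genes",
)


def write_enrichment_report(results: Sequence, path: str | Path) -> None:
    """Write per-term enrichment results as TSV (one row per tested term)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in results:
            c = r.counts
            fh.write(
                "\t".join(
                    (
                        r.term,
                        r.name,
                        r.namespace,
                        str(c.N),
                        str(c.M),
                        str(c.n),
                        str(c.m),
                        format(r.p, ".12g"),
                        format(r.p_adj, ".12g"),
                        "1" if r.significant else "0",
                        ";".join(sorted(r.query_genes)),
                    )
                )
                + "\n"
            )


def read_enrichment_report(path: str | Path) -> list:
    """Read back a TSV enrichment report (for the run-comparison step)."""
    from .enrichment import ContingencyCounts, EnrichmentResult

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        genes = str(rec["query_genes"])
        out.append(
            EnrichmentResult(
                term=rec["term"],
                name="" if pd.isna(rec["name"]) else str(rec["name"]),
                namespace=rec["namespace"],
                counts=ContingencyCounts(
                    int(rec["N"]), int(rec["M"]), int(rec["n"]), int(rec["m"])
                ),
                p=float(rec["p"]),
                p_adj=float(rec["p_adj"]),
                significant=rec["significant"] == "1",
                query_genes=frozenset() if genes in ("", "nan") else frozenset(genes.split(";")),
            )
        )
    return out
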