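"""Reading BLASTP tabular output and deriving alignment statistics.

A query-template pair is summarised by six statistics: log(EVal), the
identity and positive scores (percent of alignment columns), log of the
local alignment length (LAL), and the two length fractions LAL/query-length
and LAL/template-length.  Natural logarithms are used throughout, and
log(EVal) is floored at -450 when the reported expectation value is exactly
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, TextIO

__all__ = [
    "AlignmentRecord",
    "AlignmentStats",
    "BlastDialect",
    "DEFAULT_DIALECT",
    "MalformedLine",
    "ConfigurationError",
    "RecordValidationError",
    "LOG_EVAL_FLOOR",
    "parse_blast_tabular",
    "write_blast_tabular",
    "compute_stats",
    "blast_params_for_length",
]

#: log(EVal) assigned when BLAST reports an expectation value of exactly 0.
LOG_EVAL_FLOOR = -450.0

MANDATORY_COLUMNS = ("qseqid", "sseqid", "evalue", "length", "qlen", "slen",
                     "qstart", "qend", "sstart", "send", "qseq", "sseq")


class ConfigurationError(ValueError):
    """A column layout that cannot yield valid records."""


class RecordValidationError(ValueError):
    """An alignment record violating its internal consistency rules."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One BLASTP local alignment (HSP) between a query and a template chain.

    Coordinates are 1-based inclusive positions on the ungapped sequences;
    ``lal`` is the number of alignment columns, gaps included, following the
    BLAST ``length`` convention.
    """

    query_id: str
    template_id: str
    eval: float
    n_identical: int
    n_positive: int
    lal: int
    query_len: int
    template_len: int
    q_aln: str
    t_aln: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    def validate(self) -> None:
        if self.eval < 0:
            raise RecordValidationError(f"{self.query_id}/{self.template_id}: eval < 0")
        if self.lal <= 0:
            raise RecordValidationError(f"{self.query_id}/{self.template_id}: lal <= 0")
        if len(self.q_aln) != self.lal or len(self.t_aln) != self.lal:
            raise RecordValidationError(
                f"{self.query_id}/{self.template_id}: aligned string length "
                f"({len(self.q_aln)}, {len(self.t_aln)}) != lal ({self.lal})")
        if not (0 <= self.n_identical <= self.n_positive <= self.lal):
            raise RecordValidationError(
                f"{self.query_id}/{self.template_id}: need "
                f"0 <= nident ({self.n_identical}) <= positive "
                f"({self.n_positive}) <= lal ({self.lal})")
        q_res = sum(1 for c in self.q_aln if c != "-")
        if self.q_end - self.q_start + 1 != q_res:
            raise RecordValidationError(
                f"{self.query_id}/{self.template_id}: query span "
                f"{self.q_start}-{self.q_end} does not cover {q_res} residues")
        t_res = sum(1 for c in self.t_aln if c != "-")
        if abs(self.t_end - self.t_start) + 1 != t_res:
            raise RecordValidationError(
                f"{self.query_id}/{self.template_id}: template span "
                f"{self.t_start}-{self.t_end} does not cover {t_res} residues")


@dataclass(frozen=True)
class AlignmentStats:
    """The six derived statistics for one alignment.

    ``identity_score`` and ``positive_score`` are percentages on the 0-100
    scale; logs are natural.
    """

    log_eval: float
    identity_score: float
    positive_score: float
    log_lal: float
    frac_query: float
    frac_template: float


@dataclass(frozen=True)
class MalformedLine:
    lineno: int
    line: str
    reason: str


class BlastDialect:
    """Maps BLAST tabular column names to 0-based field positions.

    Counts of identical/positive columns may be given either directly
    (``nident``/``positive``) or as percentages (``pident``/``ppos``), which
    are converted back to counts by rounding ``pct * length / 100``.
    """

    def __init__(self, columns: Iterable[str]):
        self.columns = list(columns)
        self.index = {name: i for i, name in enumerate(self.columns)}
        for col in MANDATORY_COLUMNS:
            if col not in self.index:
                raise ConfigurationError(f"dialect is missing mandatory column '{col}'")
        if not ({"nident", "pident"} & set(self.index)):
            raise ConfigurationError("dialect needs an identity column: 'nident' or 'pident'")
        if not ({"positive", "ppos"} & set(self.index)):
            raise ConfigurationError("dialect needs a positives column: 'positive' or 'ppos'")

    def parse_line(self, line: str) -> AlignmentRecord:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(self.columns):
            raise RecordValidationError(
                f"expected {len(self.columns)} fields, got {len(fields)}")

        def get(name: str) -> str:
            return fields[self.index[name]]

        lal = int(get("length"))
        if "nident" in self.index:
            n_identical = int(get("nident"))
        else:
            n_identical = round(float(get("pident")) * lal / 100.0)
        if "positive" in self.index:
            n_positive = int(get("positive"))
        else:
            n_positive = round(float(get("ppos")) * lal / 100.0)
        rec = AlignmentRecord(
            query_id=get("qseqid"),
            template_id=get("sseqid"),
            eval=float(get("evalue")),
            n_identical=n_identical,
            n_positive=n_positive,
            lal=lal,
            query_len=int(get("qlen")),
            template_len=int(get("slen")),
            q_aln=get("qseq"),
            t_aln=get("sseq"),
            q_start=int(get("qstart")),
            q_end=int(get("qend")),
            t_start=int(get("sstart")),
            t_end=int(get("send")),
        )
        rec.validate()
        return rec


#: -outfmt "6 qseqid sseqid evalue length nident positive qlen slen
#:           qstart qend sstart send qseq sseq"
DEFAULT_DIALECT = BlastDialect([
    "qseqid", "sseqid", "evalue", "length", "nident", "positive",
    "qlen", "slen", "qstart", "qend", "sstart", "send", "qseq", "sseq",
])


def parse_blast_tabular(
    stream: TextIO | Iterable[str],
    dialect: BlastDialect = DEFAULT_DIALECT,
) -> tuple[list[AlignmentRecord], list[MalformedLine]]:
    """Parse NCBI BLAST tabular output into alignment records.

    Returns ``(records, malformed)``: malformed lines are collected with the
    line number and the reason they were rejected, never silently dropped.
    Comment lines (``#``) and blank lines are skipped.
    """
    records: list[AlignmentRecord] = []
    malformed: list[MalformedLine] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            records.append(dialect.parse_line(line))
        except (RecordValidationError, ValueError) as exc:
            malformed.append(MalformedLine(lineno, line.rstrip("\n"), str(exc)))
    return records, malformed


def write_blast_tabular(
    records: Iterable[AlignmentRecord],
    stream: TextIO,
    dialect: BlastDialect = DEFAULT_DIALECT,
) -> None:
    """Write records in the dialect's column order (round-trips with the parser)."""
    for rec in records:
        values = {
            "qseqid": rec.query_id, "sseqid": rec.template_id,
            "evalue": repr(rec.eval), "length": rec.lal,
            "nident": rec.n_identical, "positive": rec.n_positive,
            "pident": f"{100.0 * rec.n_identical / rec.lal:.3f}",
            "ppos": f"{100.0 * rec.n_positive / rec.lal:.3f}",
            "qlen": rec.query_len, "slen": rec.template_len,
            "qstart": rec.q_start, "qend": rec.q_end,
            "sstart": rec.t_start, "send": rec.t_end,
            "qseq": rec.q_aln, "sseq": rec.t_aln,
        }
        stream.write("\t".join(str(values[c]) for c in dialect.columns) + "\n")


def compute_stats(rec: AlignmentRecord) -> AlignmentStats:
    """Derive the six alignment statistics from one HSP.

    ``log_eval`` is ln(EVal), set to -450 when EVal == 0 so that exact hits
    remain finite and strictly better than any non-zero EVal the search
    cutoff admits.
    """
    if rec.lal == 0:
        raise RecordValidationError("cannot compute statistics for an empty alignment")
    log_eval = LOG_EVAL_FLOOR if rec.eval == 0 else math.log(rec.eval)
    return AlignmentStats(
        log_eval=log_eval,
        identity_score=100.0 * rec.n_identical / rec.lal,
        positive_score=100.0 * rec.n_positive / rec.lal,
        log_lal=math.log(rec.lal),
        frac_query=rec.lal / rec.query_len,
        frac_template=rec.lal / rec.template_len,
    )


def blast_params_for_length(query_len: int) -> tuple[str, int, int]:
    """Substitution matrix and gap costs recommended for a query length.

    Short queries need shallower matrices: PAM-30 below 35 residues, PAM-70
    for 35-49, BLOSUM-80 for 50-84 and BLOSUM-62 from 85 up.  The two
    boundary lengths shared by adjacent published rows (50 and 85) resolve
    to the later row, making the ranges disjoint.
    """
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    if query_len < 35:
        return ("PAM30", 9, 1)
    if query_len < 50:
        return ("PAM70", 10, 1)
    if query_len < 85:
        return ("BLOSUM80", 10, 1)
    return ("BLOSUM62", 10, 1)
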