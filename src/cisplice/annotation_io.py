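"""Gene models, sequence access, and the standard input/output formats.

Internal coordinates are 0-based half-open throughout; GTF input/output
converts from/to the 1-based inclusive convention at the boundary.  All
sequence-derived features downstream are computed on the sense strand
(5'->3' of the transcript), so the sequence accessor takes a strand and
reverse-complements minus-strand queries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "event_id",
    "gene_id",
    "pattern",
    "chrom",
    "start",
    "end",
    "strand",
    "direction",
    "fold_change",
    "p_value",
]
EXPRESSION_COLUMNS = ["gene_id", "log2_fc", "p_value", "baseline_expr"]

PATTERNS = ("EC", "IR", "ALE", "AFE", "ALT5SS", "ALT3SS", "MXE", "UNKNOWN")


@dataclass(frozen=True)
class TranscriptModel:
    """One exon chain.  Exons are (start, end) 0-based half-open, sorted by
    genomic start, non-overlapping."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ex = tuple(sorted(tuple(e) for e in self.exons))
        if not ex:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for s, e in ex:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon end {e} <= start {s}"
                )
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
        object.__setattr__(self, "exons", ex)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand.

    The span is the union hull of all transcript exons.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def span_start(self) -> int:
        return self.span[0]

    @property
    def span_end(self) -> int:
        return self.span[1]


@dataclass
class EventRecord:
    """One regulated splicing event.

    ``coords`` is the variable region (the cassette exon or the intron),
    0-based half-open.  ``direction`` follows the dPSI sign convention:
    'up' means increased inclusion/retention.
    """

    event_id: str
    gene_id: str
    pattern: str
    chrom: str
    start: int
    end: int
    strand: str
    direction: str
    fold_change: float
    p_value: float
    annotated: bool | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class ExpressionRecord:
    """One differential gene-expression record (baseline in log2 FPKM)."""

    gene_id: str
    log2_fc: float
    p_value: float
    baseline_expr: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_expr):
            raise ValueError(f"gene {self.gene_id}: baseline_expr not finite")


class SequenceAccessor:
    """Sense-strand sequence access over an indexed FASTA or an in-memory dict.

    get(chrom, start, end, strand) returns the uppercase 5'->3' sequence of
    the requested region; minus strand is reverse-complemented.
    """

    def __init__(self, source: str | Path | dict[str, str]):
        if isinstance(source, dict):
            self._seqs = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            self._fasta = Fasta(str(source))
            self._seqs = None

    def contig_length(self, chrom: str) -> int:
        if self._seqs is not None:
            if chrom not in self._seqs:
                raise KeyError(f"contig {chrom!r} not present in sequence source")
            return len(self._seqs[chrom])
        if chrom not in self._fasta:
            raise KeyError(f"contig {chrom!r} not present in FASTA")
        return len(self._fasta[chrom])

    def get(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if start < 0 or end > self.contig_length(chrom) or end < start:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside contig bounds"
            )
        if self._seqs is not None:
            seq = self._seqs[chrom][start:end]
        else:
            seq = str(self._fasta[chrom][start:end]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        return seq


def _models_from_db(db: gffutils.FeatureDB) -> list[GeneModel]:
    genes: list[GeneModel] = []
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        tid = exon.attributes["transcript_id"][0]
        info = by_gene.setdefault(
            gid, {"chrom": exon.seqid, "strand": exon.strand, "transcripts": {}}
        )
        # GTF 1-based inclusive -> 0-based half-open
        info["transcripts"].setdefault(tid, []).append((exon.start - 1, exon.end))
    for gid in sorted(by_gene):
        info = by_gene[gid]
        transcripts = tuple(
            TranscriptModel(tid, tuple(sorted(exons)))
            for tid, exons in sorted(info["transcripts"].items())
        )
        genes.append(GeneModel(gid, info["chrom"], info["strand"], transcripts))
    return genes


def read_annotation(
    gtf_path: str | Path, fasta_path: str | Path | None = None
) -> tuple[list[GeneModel], SequenceAccessor | None]:
    """Read an Ensembl-dialect GTF (and optionally a FASTA) into gene models.

    Returns the gene models (coordinates converted to 0-based half-open,
    sorted by gene_id) and a sense-strand sequence accessor (None when no
    FASTA is given).  Unparseable GTF lines are skipped with a counted
    warning.  A contig referenced by the GTF but absent from the FASTA, or
    an exon outside its contig bounds, is a hard error.
    """
    gtf_path = Path(gtf_path)
    raw = gtf_path.read_text().splitlines()
    kept, skipped = [], 0
    for line in raw:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or 'gene_id "' not in fields[8]:
            skipped += 1
            continue
        if fields[2] == "exon" and 'transcript_id "' not in fields[8]:
            skipped += 1
            continue
        kept.append(line)
    if skipped:
        logger.warning("skipped %d unparseable GTF line(s) in %s", skipped, gtf_path)
    db = gffutils.create_db(
        "\n".join(kept),
        dbfn=":memory:",
        from_string=True,
        force=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=False,
    )
    genes = _models_from_db(db)

    accessor = None
    if fasta_path is not None:
        accessor = SequenceAccessor(fasta_path)
        for gene in genes:
            try:
                clen = accessor.contig_length(gene.chrom)
            except KeyError as exc:
                raise ValueError(
                    f"contig {gene.chrom!r} (gene {gene.gene_id}) missing from FASTA"
                ) from exc
            if gene.span_end > clen:
                raise ValueError(
                    f"gene {gene.gene_id} exon beyond contig {gene.chrom} "
                    f"bounds ({gene.span_end} > {clen})"
                )
    return genes, accessor


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "cisplice") -> None:
    """Write gene models as Ensembl-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            gs, ge = gene.span
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for t in gene.transcripts:
                ts, te = t.span
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}\n"
                    )


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read a differential splicing-event TSV (0-based half-open coords)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df[EVENT_COLUMNS + [c for c in df.columns if c not in EVENT_COLUMNS]]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def events_from_frame(df: pd.DataFrame) -> list[EventRecord]:
    return [
        EventRecord(
            event_id=str(r.event_id),
            gene_id=str(r.gene_id),
            pattern=str(r.pattern),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            direction=str(r.direction),
            fold_change=float(r.fold_change),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


def filter_significant(
    records,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
):
    """Apply the significance filter: fold-change >= threshold AND p <= threshold.

    Both boundaries are inclusive.  Splicing events carry a positive
    fold-change on the inclusion ratio; expression records carry a signed
    log2 fold-change, for which the rule is |log2FC| >= log2(fc_threshold)
    in either direction.  Accepts a DataFrame (event or expression dialect)
    or a sequence of EventRecord/ExpressionRecord; order is preserved and
    the operation is idempotent.  Records with non-positive fold-change are
    rejected with a counted warning.
    """
    log2_thr = np.log2(fc_threshold)
    if isinstance(records, pd.DataFrame):
        df = records
        if "fold_change" in df.columns:
            bad = int((df["fold_change"] <= 0).sum())
            if bad:
                logger.warning("rejected %d record(s) with non-positive fold_change", bad)
            keep = (
                (df["fold_change"] > 0)
                & (df["fold_change"] >= fc_threshold)
                & (df["p_value"] <= p_threshold)
            )
        elif "log2_fc" in df.columns:
            keep = (df["log2_fc"].abs() >= log2_thr) & (df["p_value"] <= p_threshold)
        else:
            raise ValueError("frame has neither fold_change nor log2_fc")
        return df.loc[keep].copy()

    out = []
    bad = 0
    for rec in records:
        if isinstance(rec, ExpressionRecord):
            if abs(rec.log2_fc) >= log2_thr and rec.p_value <= p_threshold:
                out.append(rec)
        else:
            if rec.fold_change <= 0:
                bad += 1
                continue
            if rec.fold_change >= fc_threshold and rec.p_value <= p_threshold:
                out.append(rec)
    if bad:
        logger.warning("rejected %d record(s) with non-positive fold_change", bad)
    return out
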