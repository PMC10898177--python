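"""Per-event and per-gene cis-sequence features.

Splice-site strength is scored with first-order position weight matrices
(log2 odds against background base frequencies): a 9-nt donor window
(3 exonic + 6 intronic nt) and a 23-nt acceptor window (20 intronic +
3 exonic nt), trained on the constitutive junctions of the supplied
annotation.  The branchpoint is located with a shipped heptamer PWM
(branch A at position 6, 1-based) scanned over the window 18-100 nt
upstream of the intron 3' end; the polypyrimidine tract is the longest
contiguous C/T run between the branchpoint and the acceptor AG, scored
T=1.0 / C=0.5.

Missing features (e.g. branchpoint of a too-short intron) propagate as
NaN and are excluded pairwise from downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cisplice.annotation_io import (
    EventRecord,
    GeneModel,
    SequenceAccessor,
    TranscriptModel,
)
from cisplice.event_catalog import Catalog, CatalogEvent

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

BP_WINDOW_MIN = 18  # nt from branch A to intron 3' end
BP_WINDOW_MAX = 100
BP_OFFSET = 5  # 0-based index of the branch A within the heptamer
BP_WIDTH = 7
MIN_INTRON_FOR_BP = 25


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix with log2-odds scoring.

    probs: (width, 4) foreground probabilities (rows sum to 1, already
    pseudocount-smoothed); background: length-4 base frequencies.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be (width, 4) with width >= 1")
        if np.any(probs <= 0) or np.any(bg <= 0):
            raise ValueError("probabilities must be strictly positive (pseudocount > 0)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("foreground probabilities must sum to 1 per position")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg / bg.sum())

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 1.0,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        )
        return cls(probs, np.asarray(background, dtype=float), pseudocount)

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 1.0,
    ) -> "Pwm":
        seqs = list(sequences)
        if not seqs:
            raise ValueError("no training sequences")
        width = len(seqs[0])
        counts = np.zeros((width, 4))
        for s in seqs:
            if len(s) != width:
                raise ValueError("training sequences differ in length")
            for i, b in enumerate(s.upper()):
                if b in BASE_INDEX:
                    counts[i, BASE_INDEX[b]] += 1
        return cls.from_counts(counts, background, pseudocount)

    @classmethod
    def read_tsv(cls, path: str | Path, background=(0.25, 0.25, 0.25, 0.25)) -> "Pwm":
        """Read a PWM file: TSV, header A C G T, one row of foreground
        probabilities per position; '#' comment lines ignored."""
        df = pd.read_csv(path, sep="\t", comment="#")
        probs = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
        return cls(probs, np.asarray(background, dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.probs, columns=list(BASES))
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def score_site(pwm: Pwm, window: str) -> float:
    """Log2-odds score (bits) of one window; N contributes 0 at its position."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    lo = pwm.log_odds
    score = 0.0
    for i, b in enumerate(window.upper()):
        if b in BASE_INDEX:
            score += lo[i, BASE_INDEX[b]]
        elif b != "N":
            raise ValueError(f"invalid base {b!r} in window")
    return float(score)


def _score_many(pwm: Pwm, windows: np.ndarray) -> np.ndarray:
    """Score an (n, width) array of base indices (-1 for N) in one shot."""
    lo = pwm.log_odds
    padded = np.vstack([lo.T, np.zeros((1, lo.shape[0]))])  # row -1 -> zeros
    return padded[windows, np.arange(windows.shape[1])].sum(axis=1)


def shipped_branch_pwm() -> Pwm:
    with resources.as_file(
        resources.files("cisplice.data").joinpath("branchpoint_pwm.tsv")
    ) as p:
        return Pwm.read_tsv(p)


def genome_background(accessor: SequenceAccessor, genes: Sequence[GeneModel]) -> np.ndarray:
    """Genome-wide base frequencies estimated over the gene spans."""
    counts = np.zeros(4)
    for gene in genes:
        s, e = gene.span
        seq = accessor.get(gene.chrom, s, e, "+")
        for b, i in BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def donor_window(accessor, chrom, intron, strand) -> str:
    s, e = intron
    if strand == "+":
        return accessor.get(chrom, s - DONOR_EXONIC, s + DONOR_INTRONIC, "+")
    return accessor.get(chrom, e - DONOR_INTRONIC, e + DONOR_EXONIC, "-")


def acceptor_window(accessor, chrom, intron, strand) -> str:
    s, e = intron
    if strand == "+":
        return accessor.get(chrom, e - ACCEPTOR_INTRONIC, e + ACCEPTOR_EXONIC, "+")
    return accessor.get(chrom, s - ACCEPTOR_EXONIC, s + ACCEPTOR_INTRONIC, "-")


def train_pwms(
    genes: Sequence[GeneModel],
    accessor: SequenceAccessor,
    catalog: Catalog,
    min_junctions: int = 50,
    pseudocount: float = 1.0,
) -> tuple[Pwm, Pwm]:
    """Train donor and acceptor PWMs from constitutive junction sequences.

    Background is the genome-wide base frequency over gene spans.  Fewer
    than ``min_junctions`` usable constitutive introns is a hard error
    (supply a PWM file instead).
    """
    donors, acceptors = [], []
    for gene in genes:
        for intron in sorted(catalog.constitutive_introns.get(gene.gene_id, ())):
            try:
                donors.append(donor_window(accessor, gene.chrom, intron, gene.strand))
                acceptors.append(acceptor_window(accessor, gene.chrom, intron, gene.strand))
            except ValueError:
                continue  # junction too close to a contig edge
    if len(donors) < min_junctions:
        raise ValueError(
            f"only {len(donors)} constitutive junctions available "
            f"(minimum {min_junctions}); supply a PWM file instead"
        )
    bg = genome_background(accessor, genes)
    donor = Pwm.from_sequences(donors, background=bg, pseudocount=pseudocount)
    acceptor = Pwm.from_sequences(acceptors, background=bg, pseudocount=pseudocount)
    return donor, acceptor


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def find_branchpoint(
    intron_seq: str, branch_pwm: Pwm | None = None
) -> tuple[float, float]:
    """Locate the branchpoint adenosine in a sense-strand intron sequence.

    Scans the branch heptamer PWM over every position whose branch A lies
    18-100 nt upstream of the intron 3' end, and reports the maximum-scoring
    placement (ties resolved toward the 3' end).  Returns (bp_distance,
    bp_score); bp_distance = intron_length - (branch A index + 1).  Introns
    shorter than 25 nt yield (nan, nan).
    """
    if branch_pwm is None:
        branch_pwm = shipped_branch_pwm()
    L = len(intron_seq)
    if L < MIN_INTRON_FOR_BP:
        return (math.nan, math.nan)
    # candidate branch-A indices i: distance d = L - (i+1) in [18, 100],
    # heptamer spans [i-5, i+2)
    lo_i = max(BP_OFFSET, L - 1 - BP_WINDOW_MAX)
    hi_i = min(L - BP_WIDTH + BP_OFFSET, L - 1 - BP_WINDOW_MIN)
    if hi_i < lo_i:
        return (math.nan, math.nan)
    codes = encode(intron_seq)
    starts = np.arange(lo_i - BP_OFFSET, hi_i - BP_OFFSET + 1)
    windows = codes[starts[:, None] + np.arange(BP_WIDTH)[None, :]]
    scores = _score_many(branch_pwm, windows)
    best = np.flatnonzero(scores == scores.max())[-1]  # 3'-most maximum
    i = int(starts[best]) + BP_OFFSET
    return (float(L - (i + 1)), float(scores[best]))


def ppt_metrics(intron_seq: str, bp_index: int) -> tuple[int, float]:
    """Polypyrimidine tract length and score downstream of the branchpoint.

    The searched region runs from the base after the branch A up to, but
    excluding, the acceptor AG dinucleotide.  ppt_length is the longest
    contiguous C/T run; ppt_score sums T=1.0 / C=0.5 over that run (ties by
    score, then by proximity to the 3' end).  An empty run yields (0, 0.0).
    """
    region = intron_seq.upper()[bp_index + 1 : len(intron_seq) - 2]
    best = (0, 0.0)
    run_len, run_score = 0, 0.0
    for ch in region:
        if ch in "CT":
            run_len += 1
            run_score += 1.0 if ch == "T" else 0.5
        else:
            run_len, run_score = 0, 0.0
        if run_len > best[0] or (run_len == best[0] and run_score >= best[1]):
            best = (run_len, run_score)
    return best


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from both sides; all-N -> NaN."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    acgt = sum(s.count(b) for b in BASES)
    if acgt == 0:
        return math.nan
    return (s.count("G") + s.count("C")) / acgt


def at_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in BASES)
    if acgt == 0:
        return math.nan
    return (s.count("A") + s.count("T")) / acgt


def relative_position(region: tuple[int, int], gene: GeneModel) -> float:
    """Fraction of the gene span at the region midpoint, oriented 5'->3'.

    Minus-strand genes are mirrored so 0 is always the transcription start
    side of the unit.
    """
    s, e = gene.span
    mid = (region[0] + region[1]) / 2.0
    if not (s <= region[0] and region[1] <= e):
        raise ValueError("region outside gene span")
    frac = (mid - s) / (e - s)
    return frac if gene.strand == "+" else 1.0 - frac


@dataclass(frozen=True)
class GeneArchitecture:
    gene_id: str
    gene_length: int
    mean_intron_length: float
    intron_exon_ratio: float
    intronless: bool
    n_introns: int


def representative_transcript(gene: GeneModel) -> TranscriptModel:
    """The transcript with the greatest total exonic length; ties broken by
    lexicographic transcript_id."""
    return sorted(gene.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))[0]


def gene_architecture(gene: GeneModel) -> GeneArchitecture:
    """Length aggregates on the representative transcript."""
    t = representative_transcript(gene)
    introns = t.introns
    exon_len = t.exonic_length
    intron_len = sum(e - s for s, e in introns)
    n = len(introns)
    return GeneArchitecture(
        gene_id=gene.gene_id,
        gene_length=gene.span_end - gene.span_start,
        mean_intron_length=(intron_len / n) if n else 0.0,
        intron_exon_ratio=(intron_len / exon_len) if n else 0.0,
        intronless=(n == 0),
        n_introns=n,
    )


def architectures_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame([vars(gene_architecture(g)) for g in genes])


def _find_context(gene: GeneModel, region: tuple[int, int]):
    """Locate the region as an exon or intron of some transcript and return
    (kind, upstream flank, downstream flank) in transcription order.

    For an exon the flanks are the adjacent introns; for an intron the
    adjacent exons.  Transcripts with more exons are preferred so internal
    context is found when it exists.
    """
    for t in sorted(gene.transcripts, key=lambda t: (-len(t.exons), t.transcript_id)):
        exons = _order = t.exons if gene.strand == "+" else tuple(reversed(t.exons))
        introns = t.introns if gene.strand == "+" else tuple(reversed(t.introns))
        if region in exons:
            j = exons.index(region)
            up = introns[j - 1] if j > 0 else None
            down = introns[j] if j < len(introns) else None
            return "exon", up, down
        if region in introns:
            j = introns.index(region)
            return "intron", exons[j], exons[j + 1]
    return None, None, None


def event_features(
    event: EventRecord | CatalogEvent,
    gene: GeneModel,
    accessor: SequenceAccessor,
    donor_pwm: Pwm,
    acceptor_pwm: Pwm,
    branch_pwm: Pwm | None = None,
) -> dict:
    """The full cis-feature panel for one event (pure function).

    For exonic events (EC and kin) the splice-site scores are the exon's own
    acceptor (3'ss) and donor (5'ss), the branchpoint/PPT come from the
    upstream intron and the flanking context is intronic.  For intronic
    events (IR) the scores are the intron's own sites, branchpoint/PPT come
    from the intron itself and the flanking context is exonic.  Features
    without sequence context are NaN.
    """
    if branch_pwm is None:
        branch_pwm = shipped_branch_pwm()
    region = (event.start, event.end)
    chrom, strand = gene.chrom, gene.strand
    kind, up, down = _find_context(gene, region)
    nan = math.nan
    out = {
        "event_id": getattr(event, "event_id", f"{gene.gene_id}:{event.start}-{event.end}"),
        "gene_id": gene.gene_id,
        "pattern": event.pattern,
        "kind": kind or "region",
        "ss5_score": nan,
        "ss3_score": nan,
        "bp_distance": nan,
        "bp_score": nan,
        "ppt_length": nan,
        "ppt_score": nan,
        "gc_event": gc_fraction(accessor.get(chrom, event.start, event.end, strand)),
        "gc_up_flank": nan,
        "gc_down_flank": nan,
        "len_event": event.end - event.start,
        "len_up_flank": nan,
        "len_down_flank": nan,
        "rel_position": relative_position(region, gene),
    }

    def _flank_gc(flank):
        return gc_fraction(accessor.get(chrom, flank[0], flank[1], strand))

    if kind == "exon":
        bp_intron = up  # upstream intron in transcription order
        if up is not None:
            out["ss3_score"] = score_site(
                acceptor_pwm, acceptor_window(accessor, chrom, up, strand)
            )
            out["gc_up_flank"] = _flank_gc(up)
            out["len_up_flank"] = up[1] - up[0]
        if down is not None:
            out["ss5_score"] = score_site(
                donor_pwm, donor_window(accessor, chrom, down, strand)
            )
            out["gc_down_flank"] = _flank_gc(down)
            out["len_down_flank"] = down[1] - down[0]
    elif kind == "intron":
        bp_intron = region
        out["ss5_score"] = score_site(
            donor_pwm, donor_window(accessor, chrom, region, strand)
        )
        out["ss3_score"] = score_site(
            acceptor_pwm, acceptor_window(accessor, chrom, region, strand)
        )
        out["gc_up_flank"] = _flank_gc(up)
        out["gc_down_flank"] = _flank_gc(down)
        out["len_up_flank"] = up[1] - up[0]
        out["len_down_flank"] = down[1] - down[0]
    else:
        bp_intron = None

    if bp_intron is not None:
        intron_seq = accessor.get(chrom, bp_intron[0], bp_intron[1], strand)
        bp_distance, bp_score = find_branchpoint(intron_seq, branch_pwm)
        out["bp_distance"], out["bp_score"] = bp_distance, bp_score
        if not math.isnan(bp_distance):
            bp_index = len(intron_seq) - 1 - int(bp_distance)
            ppt_length, ppt_score = ppt_metrics(intron_seq, bp_index)
            out["ppt_length"], out["ppt_score"] = float(ppt_length), ppt_score
    return out


def features_frame(
    events: Sequence[EventRecord | CatalogEvent],
    genes_by_id: dict[str, GeneModel],
    accessor: SequenceAccessor,
    donor_pwm: Pwm,
    acceptor_pwm: Pwm,
    branch_pwm: Pwm | None = None,
) -> pd.DataFrame:
    """Feature matrix keyed by event_id for a collection of events."""
    if branch_pwm is None:
        branch_pwm = shipped_branch_pwm()
    rows = []
    for event in events:
        gene = genes_by_id.get(event.gene_id)
        if gene is None:
            continue
        rows.append(
            event_features(event, gene, accessor, donor_pwm, acceptor_pwm, branch_pwm)
        )
    return pd.DataFrame(rows)
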