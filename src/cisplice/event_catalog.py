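"""Derive the annotated splicing-event catalogue and classify supplied events.

Catalogue rules (deterministic, exact-coordinate identity):

* constitutive exon/intron: present (as exact coordinates) in every
  transcript of the gene;
* IR: an intron of >=1 transcript fully contained in an exon of another
  transcript of the same gene;
* ALT5SS / ALT3SS: two exons sharing exactly one boundary; which splice
  site varies is resolved relative to the strand;
* AFE / ALE: transcript-initial/terminal exons (in transcription order)
  that differ between transcripts, do not overlap their alternative
  partner, and are not internal to any transcript;
* MXE: two internal exons never co-occurring in any transcript, each
  attested in at least one transcript (conservative: without attested
  exclusivity they remain two ECs);
* EC: any remaining internal exon present in >=1 but not all transcripts.

Events supplied from a differential table are classified by exact
coordinate match against the catalogue; a region equal to a constitutive
intron is called IR but flagged unannotated (novel retention); anything
else is UNKNOWN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from cisplice.annotation_io import EventRecord, GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CatalogEvent:
    pattern: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    upstream_exon: tuple[int, int] | None = None
    downstream_exon: tuple[int, int] | None = None


@dataclass
class Catalog:
    """Annotated event catalogue plus the reference sets used as comparison
    baselines: constitutive exons/introns, reference (not-regulated)
    cassette exons and reference retained introns."""

    events: list[CatalogEvent]
    constitutive_exons: dict[str, set[tuple[int, int]]]
    constitutive_introns: dict[str, set[tuple[int, int]]]

    def events_of(self, pattern: str) -> list[CatalogEvent]:
        return [e for e in self.events if e.pattern == pattern]

    @property
    def cassette_exons(self) -> list[CatalogEvent]:
        return self.events_of("EC")

    @property
    def retained_introns(self) -> list[CatalogEvent]:
        return self.events_of("IR")

    def _index(self) -> dict[tuple[str, int, int], CatalogEvent]:
        return {(e.gene_id, e.start, e.end): e for e in self.events}


def _transcription_order(exons, strand):
    return exons if strand == "+" else tuple(reversed(exons))


def _classify_gene(gene: GeneModel) -> tuple[list[CatalogEvent], set, set]:
    """Assign every distinct exon and intron of one gene to constitutive or
    alternative-with-pattern."""
    n_tx = len(gene.transcripts)
    exon_tx: dict[tuple[int, int], list[int]] = {}
    intron_tx: dict[tuple[int, int], list[int]] = {}
    terminal: dict[tuple[int, int], dict[str, bool]] = {}
    for i, t in enumerate(gene.transcripts):
        order = _transcription_order(t.exons, gene.strand)
        for j, ex in enumerate(t.exons):
            exon_tx.setdefault(ex, []).append(i)
            flags = terminal.setdefault(ex, {"first": True, "last": True, "internal": False})
            pos = order.index(ex)
            if pos != 0:
                flags["first"] = False
            if pos != len(order) - 1:
                flags["last"] = False
            if 0 < pos < len(order) - 1:
                flags["internal"] = True
        for intr in t.introns:
            intron_tx.setdefault(intr, []).append(i)

    const_exons = {ex for ex, txs in exon_tx.items() if len(set(txs)) == n_tx}
    const_introns = {i for i, txs in intron_tx.items() if len(set(txs)) == n_tx}
    alt_exons = [ex for ex in sorted(exon_tx) if ex not in const_exons]

    events: list[CatalogEvent] = []
    assigned: set[tuple[int, int]] = set()

    def ev(pattern, start, end, up=None, down=None):
        events.append(
            CatalogEvent(pattern, gene.gene_id, gene.chrom, gene.strand, start, end, up, down)
        )

    # IR: intron of one transcript contained in an exon of another transcript
    for intr in sorted(intron_tx):
        s, e = intr
        for ex, txs in exon_tx.items():
            if ex[0] <= s and e <= ex[1] and set(txs) - set(intron_tx[intr]):
                ev("IR", s, e)
                break

    # ALT5SS / ALT3SS: exon pairs sharing exactly one boundary
    for a in alt_exons:
        for b in alt_exons:
            if b <= a or a in assigned or b in assigned:
                continue
            same_start = a[0] == b[0] and a[1] != b[1]
            same_end = a[1] == b[1] and a[0] != b[0]
            if not (same_start or same_end):
                continue
            if same_start:
                lo, hi = sorted((a[1], b[1]))
                varies_donor = gene.strand == "+"  # end boundary = donor on +
            else:
                lo, hi = sorted((a[0], b[0]))
                varies_donor = gene.strand == "-"
            ev("ALT5SS" if varies_donor else "ALT3SS", lo, hi)
            assigned.update((a, b))

    # AFE / ALE: differing non-overlapping terminal exons
    starts = {ex for ex in alt_exons if terminal[ex]["first"] and not terminal[ex]["internal"]}
    ends = {ex for ex in alt_exons if terminal[ex]["last"] and not terminal[ex]["internal"]}
    for group, kind in ((starts, "first"), (ends, "last")):
        group = sorted(g for g in group if g not in assigned)
        for a in group:
            partners = [
                b
                for b in group
                if b != a and (b[1] <= a[0] or a[1] <= b[0])  # non-overlapping
            ]
            if partners:
                # terminal status is computed in transcription order, so the
                # strand is already accounted for
                ev("AFE" if kind == "first" else "ALE", a[0], a[1])
                assigned.add(a)

    # MXE: two internal exons never co-occurring, each attested
    remaining = [ex for ex in alt_exons if ex not in assigned and terminal[ex]["internal"]]
    for a in remaining:
        for b in remaining:
            if b <= a or a in assigned or b in assigned:
                continue
            if a[1] <= b[0] or b[1] <= a[0]:
                co = set(exon_tx[a]) & set(exon_tx[b])
                if not co and exon_tx[a] and exon_tx[b]:
                    # exclusivity attested only if the union covers cases where
                    # each appears without the other and no transcript lacks both
                    # an internal slot; conservative: require every transcript to
                    # carry exactly one of the pair
                    carrying = set(exon_tx[a]) | set(exon_tx[b])
                    if len(carrying) == n_tx:
                        ev("MXE", a[0], a[1])
                        ev("MXE", b[0], b[1])
                        assigned.update((a, b))

    # EC: remaining internal alternative exons
    for ex in alt_exons:
        if ex in assigned or not terminal[ex]["internal"]:
            continue
        up = down = None
        for t in gene.transcripts:
            if ex in t.exons:
                order = _transcription_order(t.exons, gene.strand)
                j = order.index(ex)
                if 0 < j < len(order) - 1:
                    up, down = order[j - 1], order[j + 1]
                    break
        ev("EC", ex[0], ex[1], up, down)
        assigned.add(ex)

    events.sort(key=lambda e: (e.start, e.end, e.pattern))
    return events, const_exons, const_introns


def build_catalog(genes: Iterable[GeneModel]) -> Catalog:
    """Build the annotated event catalogue and reference sets for a gene set.

    Single-transcript genes contribute only constitutive exons/introns.
    Ordering is deterministic (gene_id, then coordinates).
    """
    all_events: list[CatalogEvent] = []
    const_exons: dict[str, set] = {}
    const_introns: dict[str, set] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        events, ce, ci = _classify_gene(gene)
        all_events.extend(events)
        const_exons[gene.gene_id] = ce
        const_introns[gene.gene_id] = ci
    return Catalog(all_events, const_exons, const_introns)


def classify_event(event: EventRecord, catalog: Catalog) -> EventRecord | None:
    """Resolve pattern and annotated flag for one event.

    Exact-coordinate match to a catalogued event wins; a region equal to a
    constitutive intron is novel IR (annotated=False); otherwise UNKNOWN.
    Events whose gene is absent from the annotation are excluded (None)
    with a counted warning.
    """
    if event.gene_id not in catalog.constitutive_exons:
        logger.warning("gene %s absent from annotation; event %s excluded",
                       event.gene_id, event.event_id)
        return None
    hit = catalog._index().get((event.gene_id, event.start, event.end))
    if hit is not None:
        return replace(event, pattern=hit.pattern, annotated=True)
    if (event.start, event.end) in catalog.constitutive_introns[event.gene_id]:
        return replace(event, pattern="IR", annotated=False)
    return replace(event, pattern="UNKNOWN", annotated=False)


def classify_events(events: Sequence[EventRecord], catalog: Catalog) -> list[EventRecord]:
    """Vector form of classify_event; drops events with unknown genes."""
    index = catalog._index()
    out = []
    dropped = 0
    for event in events:
        if event.gene_id not in catalog.constitutive_exons:
            dropped += 1
            continue
        hit = index.get((event.gene_id, event.start, event.end))
        if hit is not None:
            out.append(replace(event, pattern=hit.pattern, annotated=True))
        elif (event.start, event.end) in catalog.constitutive_introns[event.gene_id]:
            out.append(replace(event, pattern="IR", annotated=False))
        else:
            out.append(replace(event, pattern="UNKNOWN", annotated=False))
    if dropped:
        logger.warning("%d event(s) excluded: gene_id absent from annotation", dropped)
    return out


def pattern_shares(events: Sequence[EventRecord]) -> pd.DataFrame:
    """Per-pattern counts and fractions, with up/down splits.

    Fractions sum to 1 over patterns (UNKNOWN is its own row); within a
    pattern fraction_up + fraction_down = 1 when the count is positive.
    Empty input yields an empty table.
    """
    if not events:
        return pd.DataFrame(
            columns=["pattern", "count", "fraction", "fraction_up", "fraction_down"]
        )
    df = pd.DataFrame(
        {"pattern": [e.pattern for e in events], "direction": [e.direction for e in events]}
    )
    total = len(df)
    rows = []
    for pattern, sub in df.groupby("pattern", sort=True):
        n = len(sub)
        n_up = int((sub["direction"] == "up").sum())
        rows.append(
            {
                "pattern": pattern,
                "count": n,
                "fraction": n / total,
                "fraction_up": n_up / n,
                "fraction_down": (n - n_up) / n,
            }
        )
    return pd.DataFrame(rows)


def catalog_to_frame(catalog: Catalog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "pattern": e.pattern,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "strand": e.strand,
            }
            for e in catalog.events
        ]
    )


def write_catalog_bed(catalog: Catalog, path: str | Path) -> None:
    """Export the catalogue as BED (0-based half-open, name=pattern)."""
    with open(path, "w") as fh:
        for e in catalog.events:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.pattern}\t0\t{e.strand}\n")
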