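"""Genome-wide uORF scanning, topology classification, cleansing and dedup.

A uORF is a start codon lying entirely within the 5'UTR together with the
first downstream in-frame stop codon, required to end at or before the end of
the main CDS. Scanning considers ATG and the nine near-cognate start codons
(single-nucleotide variants of ATG) in all three reading frames.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace

import pandas as pd

from .annotation_io import STOP_CODONS, GenomeSequence, TranscriptModel, spliced_sequence

#: ATG plus the nine near-cognate start codons, in the field's customary order.
NEAR_COGNATE_STARTS: tuple[str, ...] = (
    "ATG", "TTG", "GTG", "CTG", "AAG", "AGG", "ACG", "ATA", "ATT", "ATC",
)

UPSTREAM = "upstream"
CDS_OVERLAP = "cds_overlap"
SHARED_STOP = "shared_stop_extension"


@dataclass(frozen=True)
class UorfRecord:
    """One scanned uORF, identified by its unique genomic coordinates.

    ``t_start``/``t_stop_end`` are transcript coordinates of the start codon's
    first base and the stop codon's third base. ``g_start``/``g_stop_end`` are
    the corresponding genomic positions; ``chain`` fingerprints any splice
    junctions inside the uORF span so spliced uORFs with identical endpoints
    but different intron structure stay distinct.
    """

    contig: str
    strand: str
    g_start: int
    g_stop_end: int
    chain: tuple[int, ...]
    transcript_id: str
    start_codon: str
    t_start: int
    t_stop_end: int
    topology: str
    frame: int

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.g_start, self.g_stop_end, self.chain)

    @property
    def length(self) -> int:
        """uORF length in nt, start codon through stop codon inclusive."""
        return self.t_stop_end - self.t_start + 1


def _stop_positions_by_frame(seq: str) -> list[list[int]]:
    """1-based positions of stop-codon first bases, bucketed by pos % 3."""
    frames: list[list[int]] = [[], [], []]
    for p in range(1, len(seq) - 1):
        if seq[p - 1 : p + 2] in STOP_CODONS:
            frames[p % 3].append(p)
    return frames


def _span_chain(model: TranscriptModel, t_lo: int, t_hi: int) -> tuple[int, ...]:
    """Genomic coordinates of splice junctions inside transcript span [lo, hi]."""
    junctions: list[int] = []
    offset = 0
    for s, e in model.exons[:-1]:
        offset += e - s + 1
        if t_lo <= offset < t_hi:
            junctions.append(e if model.strand == "+" else s)
    return tuple(junctions)


def scan_transcript(
    model: TranscriptModel,
    seq: str,
    start_codons: tuple[str, ...] = NEAR_COGNATE_STARTS,
) -> list[UorfRecord]:
    """Enumerate every uORF on one coding transcript.

    Every transcript position whose 3-mer is a permitted start codon lying
    entirely within the 5'UTR, and whose FIRST in-frame stop codon ends at or
    before the CDS end, yields exactly one record (reading-frame termination
    semantics: later in-frame stops are unreachable). Candidates without such
    a stop are discarded entirely. Codons containing N never match.
    """
    records: list[UorfRecord] = []
    cds_start, cds_end = model.cds_start, model.cds_end
    if model.biotype != "coding" or cds_start <= 3:
        return records
    start_set = frozenset(start_codons)
    stops = _stop_positions_by_frame(seq)
    for p in range(1, cds_start - 2):
        codon = seq[p - 1 : p + 2]
        if codon not in start_set:
            continue
        frame_bucket = stops[p % 3]
        i = bisect_left(frame_bucket, p + 3)
        if i == len(frame_bucket):
            continue
        q = frame_bucket[i]
        if q + 2 > cds_end:
            continue
        record = UorfRecord(
            contig=model.contig,
            strand=model.strand,
            g_start=model.transcript_to_genome(p)[1],
            g_stop_end=model.transcript_to_genome(q + 2)[1],
            chain=_span_chain(model, p, q + 2),
            transcript_id=model.transcript_id,
            start_codon=codon,
            t_start=p,
            t_stop_end=q + 2,
            topology="",
            frame=(p - cds_start) % 3,
        )
        records.append(replace(record, topology=classify_topology(record, model)))
    return records


def classify_topology(record: UorfRecord, model: TranscriptModel) -> str:
    """Label a uORF's relationship to the main CDS.

    upstream: stop ends before the CDS start; shared_stop_extension: in frame
    with the CDS and sharing its stop codon (an N-terminal extension);
    cds_overlap: everything else (out-of-frame stop inside the CDS).
    """
    if record.t_stop_end < model.cds_start:
        return UPSTREAM
    if record.frame == 0 and record.t_stop_end == model.cds_end:
        return SHARED_STOP
    return CDS_OVERLAP


def apply_cleansing(
    records: list[UorfRecord],
    atis_positions: set[tuple[str, int, str]] | None = None,
) -> tuple[list[UorfRecord], dict[str, int]]:
    """Remove N-terminal extensions and aTIS-coincident starts.

    Shared-stop (N-terminal extension) uORFs may retain function of the main
    gene product; starts annotated as alternative translation initiation
    sites of the CDS are likewise excluded. Returns the filtered list and
    removal counts.
    """
    atis_positions = atis_positions or set()
    kept: list[UorfRecord] = []
    counts = {"shared_stop_extension": 0, "atis": 0}
    for rec in records:
        if rec.topology == SHARED_STOP:
            counts["shared_stop_extension"] += 1
        elif (rec.contig, rec.g_start, rec.strand) in atis_positions:
            counts["atis"] += 1
        else:
            kept.append(rec)
    return kept, counts


def deduplicate(records: list[UorfRecord]) -> tuple[list[UorfRecord], int]:
    """Collapse records sharing a genomic key to one representative.

    The representative transcript is the lexicographically smallest id among
    carriers, so identical uORFs on multiple isoforms are counted once.
    Returns the unique list and the number of collapsed duplicates.
    """
    by_key: dict[tuple, UorfRecord] = {}
    for rec in records:
        cur = by_key.get(rec.key)
        if cur is None or rec.transcript_id < cur.transcript_id:
            by_key[rec.key] = rec
    unique = sorted(by_key.values(), key=lambda r: (r.contig, r.g_start, r.strand, r.key))
    return unique, len(records) - len(unique)


def scan_catalog(
    models: list[TranscriptModel],
    genome: GenomeSequence,
    start_codons: tuple[str, ...] = NEAR_COGNATE_STARTS,
    atis_positions: set[tuple[str, int, str]] | None = None,
) -> tuple[list[UorfRecord], dict]:
    """Scan all coding transcripts, cleanse, and deduplicate.

    Returns the unique catalog and a stats dict (raw/removed/duplicate
    counts and per-transcript uORF counts before dedup).
    """
    raw: list[UorfRecord] = []
    per_transcript: dict[str, int] = {}
    for model in models:
        if model.biotype != "coding":
            continue
        recs = scan_transcript(model, spliced_sequence(model, genome), start_codons)
        per_transcript[model.transcript_id] = len(recs)
        raw.extend(recs)
    cleansed, removed = apply_cleansing(raw, atis_positions)
    unique, n_dup = deduplicate(cleansed)
    stats = {
        "n_raw": len(raw),
        "removed": removed,
        "n_duplicates_collapsed": n_dup,
        "n_unique": len(unique),
        "per_transcript": per_transcript,
    }
    return unique, stats


def catalog_to_frame(records: list[UorfRecord]) -> pd.DataFrame:
    """Tabulate a uORF catalog (one row per unique uORF)."""
    return pd.DataFrame(
        {
            "contig": [r.contig for r in records],
            "strand": [r.strand for r in records],
            "g_start": [r.g_start for r in records],
            "g_stop_end": [r.g_stop_end for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "start_codon": [r.start_codon for r in records],
            "t_start": [r.t_start for r in records],
            "t_stop_end": [r.t_stop_end for r in records],
            "length": [r.length for r in records],
            "topology": [r.topology for r in records],
            "frame": [r.frame for r in records],
        }
    )


def catalog_to_bed12(records: list[UorfRecord]) -> pd.DataFrame:
    """BED12 rows for genome-browser display of a uORF catalog."""
    rows = []
    for r in records:
        lo, hi = sorted((r.g_start, r.g_stop_end))
        rows.append(
            (
                r.contig, lo - 1, hi,
                f"{r.transcript_id}:{r.t_start}", 0, r.strand,
                lo - 1, hi, "0,0,0", 1, hi - lo + 1, 0,
            )
        )
    cols = [
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts",
    ]
    return pd.DataFrame(rows, columns=cols)
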