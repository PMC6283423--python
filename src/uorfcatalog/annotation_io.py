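"""Genome, annotation and track I/O with spliced-transcript coordinate maps.

All transcript-space coordinates in this package are 1-based inclusive, in
transcript orientation (position 1 is the 5' cap-proximal base). Genomic
coordinates are 1-based inclusive as in GTF; BED-like and bedGraph inputs are
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence(dict):
    """Mapping of contig name -> uppercase nucleotide string (A/C/G/T/N)."""

    def __setitem__(self, contig: str, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"contig {contig!r}: invalid characters {sorted(bad)}")
        super().__setitem__(contig, seq)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        genome = cls()
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in genome:
                raise ValueError(f"duplicate contig {record.id!r} in {path}")
            genome[record.id] = str(record.seq)
        return genome


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with UTR/CDS structure and a genome mapping.

    ``exons`` are genomic (start, end) intervals, 1-based inclusive, ordered
    5'->3' in transcript orientation (descending genomic start on the minus
    strand). ``cds_start``/``cds_end`` are transcript coordinates and include
    the stop codon; both are 0 for non-coding (lncRNA) transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0
    cds_end: int = 0
    biotype: str = "coding"

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def utr5_length(self) -> int:
        return self.cds_start - 1 if self.cds_start else 0

    def transcript_to_genome(self, pos: int) -> tuple[str, int]:
        """Map a 1-based transcript position to (contig, genomic position)."""
        if pos < 1 or pos > self.length:
            raise ValueError(
                f"position {pos} out of range 1..{self.length} "
                f"for transcript {self.transcript_id}"
            )
        offset = pos - 1
        for s, e in self.exons:
            n = e - s + 1
            if offset < n:
                if self.strand == "+":
                    return self.contig, s + offset
                return self.contig, e - offset
            offset -= n
        raise AssertionError("unreachable")

    def genome_to_transcript(self, gpos: int) -> int | None:
        """Inverse of :meth:`transcript_to_genome`; None if not exonic."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                if self.strand == "+":
                    return offset + (gpos - s) + 1
                return offset + (e - gpos) + 1
            offset += e - s + 1
        return None


def spliced_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence in transcript orientation (5'->3')."""
    contig_seq = genome[model.contig]
    parts = []
    for s, e in model.exons:
        if s < 1 or e > len(contig_seq):
            raise ValueError(
                f"exon {s}-{e} of {model.transcript_id} exceeds contig "
                f"{model.contig} (length {len(contig_seq)})"
            )
        parts.append(contig_seq[s - 1 : e])
    if model.strand == "+":
        return "".join(parts)
    return "".join(reverse_complement(p) for p in parts)


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def drop(self, transcript_id: str, reason: str) -> None:
        self.n_dropped += 1
        self.drop_reasons.setdefault(reason, []).append(transcript_id)
        logger.warning("dropping transcript %s: %s", transcript_id, reason)


def _validate_coding(model: TranscriptModel, seq: str) -> str | None:
    """Return a drop reason for an invalid coding transcript, else None."""
    if model.cds_start < 1 or model.cds_end > model.length:
        return "CDS outside transcript"
    cds_len = model.cds_end - model.cds_start + 1
    if cds_len % 3 != 0:
        return "CDS length not divisible by 3"
    if seq[model.cds_end - 3 : model.cds_end] not in STOP_CODONS:
        return "CDS does not end with a stop codon"
    return None


def load_annotation(
    gtf_path, fasta_path, validate: bool = True
) -> tuple[list[TranscriptModel], GenomeSequence, LoadReport]:
    """Read a GTF + genome FASTA into TranscriptModels.

    Understands a minimal GTF subset: ``exon`` and ``CDS`` features with
    ``transcript_id``/``gene_id`` attributes and optional ``transcript_type``.
    The CDS interval is taken to include the stop codon; if separate
    ``stop_codon`` records are present they are merged into the CDS span.
    Coding transcripts failing structural invariants are dropped and counted,
    not fatal.
    """
    genome = GenomeSequence.from_fasta(fasta_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        info = per_tx.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "biotype": feat.attributes.get("transcript_type", ["coding"])[0],
                "exons": [],
                "cds": [],
            },
        )
        if feat.featuretype == "exon":
            info["exons"].append((feat.start, feat.end))
        else:
            info["cds"].append((feat.start, feat.end))

    report = LoadReport()
    models: list[TranscriptModel] = []
    for tid in sorted(per_tx):
        info = per_tx[tid]
        if info["contig"] not in genome:
            raise ValueError(
                f"transcript {tid} references contig {info['contig']!r} "
                "absent from the genome FASTA"
            )
        exons = sorted(info["exons"])
        if info["exons"] != exons and info["exons"] != exons[::-1]:
            logger.warning("transcript %s: unsorted exons repaired", tid)
        if info["strand"] == "-":
            exons = exons[::-1]
        biotype = info["biotype"]
        if biotype not in ("coding", "lncRNA"):
            biotype = "lncRNA" if "lnc" in biotype.lower() else "coding"
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene_id"],
            contig=info["contig"],
            strand=info["strand"],
            exons=tuple(exons),
            biotype=biotype if info["cds"] else "lncRNA",
        )
        if info["cds"]:
            gstarts = [s for s, _ in info["cds"]]
            gends = [e for _, e in info["cds"]]
            # transcript coords of the two genomic extremes; min is cds_start
            t1 = model.genome_to_transcript(min(gstarts))
            t2 = model.genome_to_transcript(max(gends))
            if t1 is None or t2 is None:
                report.drop(tid, "CDS not contained in exons")
                continue
            cds_start, cds_end = min(t1, t2), max(t1, t2)
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                contig=info["contig"],
                strand=info["strand"],
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
                biotype="coding",
            )
            if validate:
                seq = spliced_sequence(model, genome)
                reason = _validate_coding(model, seq)
                if reason is not None:
                    report.drop(tid, reason)
                    continue
        models.append(model)
        report.n_loaded += 1
    return models, genome, report


@dataclass
class TisCallSet:
    """Translation-initiation-site calls from one ribosome-profiling study.

    ``calls`` columns: contig, pos (1-based genomic position of the start
    codon's first base), strand, reads.
    """

    experiment_id: str
    calls: pd.DataFrame

    def __post_init__(self):
        required = {"contig", "pos", "strand", "reads"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"TIS table missing columns {sorted(missing)}")
        if (self.calls["reads"] < 0).any():
            raise ValueError("negative read counts in TIS table")


def read_tis_table(path, experiment_id: str | None = None) -> TisCallSet:
    """Read a BED-like TIS table: contig, 0-based start, strand, reads.

    Positions are converted to 1-based on read.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["contig", "start0", "strand", "reads"],
        dtype={"contig": str, "start0": int, "strand": str, "reads": int},
    )
    calls = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["start0"] + 1,
            "strand": df["strand"],
            "reads": df["reads"],
        }
    )
    if experiment_id is None:
        experiment_id = str(path)
    return TisCallSet(experiment_id, calls)


def read_conservation(path) -> dict[tuple[str, int], float]:
    """Read a bedGraph conservation track into {(contig, 1-based pos): value}."""
    track: dict[tuple[str, int], float] = {}
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["contig", "start0", "end", "value"],
        dtype={"contig": str, "start0": int, "end": int, "value": float},
    )
    for contig, start0, end, value in df.itertuples(index=False):
        for pos in range(start0 + 1, end + 1):
            track[(contig, pos)] = value
    return track


def read_expression(path) -> dict[str, float]:
    """Read a two-column TSV of transcript id -> expression value."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["transcript_id", "value"])
    return dict(zip(df["transcript_id"].astype(str), df["value"].astype(float)))


def read_position_list(path) -> set[tuple[str, int, str]]:
    """Read a TSV of (contig, 1-based position, strand) genomic sites.

    Used for aTIS exclusion lists and literature-positive uORF starts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    # tolerate an optional leading label column (gene name)
    if df.shape[1] == 4:
        df = df.iloc[:, 1:]
    df.columns = ["contig", "pos", "strand"]
    return {
        (str(c), int(p), str(s))
        for c, p, s in df.itertuples(index=False)
    }


def read_peptides(path) -> list[str]:
    """Read peptide sequences from FASTA (e.g. an MS-evidence peptide list)."""
    return [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]


def translate_orf(nt_seq: str) -> str:
    """Translate an ORF nucleotide sequence, dropping the trailing stop."""
    aa = str(Seq(nt_seq).translate())
    return aa[:-1] if aa.endswith("*") else aa
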