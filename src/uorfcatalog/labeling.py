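"""Partition scanned uORFs into 2-voted / 1-voted / unlabeled sets.

Ribosome-profiling TIS calls from each experiment are intersected with the
catalog (a call within +/-1 nt of a uORF start on the same strand counts as a
detection); literature-confirmed uORFs contribute one additional vote source.
Also provides lncRNA ORF translation calls and the ribosome-binding-strength
stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import TisCallSet, TranscriptModel
from .uorf_scan import NEAR_COGNATE_STARTS, UorfRecord, scan_transcript

logger = logging.getLogger(__name__)

TWO_VOTED = "two_voted"
ONE_VOTED = "one_voted"
UNLABELED = "unlabeled"

#: matching window (nt) around the start-codon first base
DEFAULT_WINDOW = 1


@dataclass
class LabeledUorf:
    record: UorfRecord
    detections: dict[str, bool]
    literature: bool

    @property
    def votes(self) -> int:
        return sum(self.detections.values()) + int(self.literature)

    @property
    def partition(self) -> str:
        v = self.votes
        if v >= 2:
            return TWO_VOTED
        if v == 1:
            return ONE_VOTED
        return UNLABELED


def _detected(record: UorfRecord, index: dict, window: int) -> bool:
    for d in range(-window, window + 1):
        if (record.contig, record.g_start + d, record.strand) in index:
            return True
    return False


def assign_votes(
    catalog: list[UorfRecord],
    tis_sets: list[TisCallSet],
    literature: set[tuple[str, int, str]] | None = None,
    window: int = DEFAULT_WINDOW,
    literature_is_two_voted: bool = False,
) -> list[LabeledUorf]:
    """Intersect the catalog with TIS call sets and literature positives.

    A uORF is detected by an experiment iff that experiment has a TIS call
    within ``window`` nt of the uORF start-codon first base on the same
    strand. The literature list counts as one vote source by default;
    ``literature_is_two_voted`` instead promotes literature uORFs straight to
    the 2-voted partition.
    """
    literature = literature or set()
    indexes = {}
    for ts in tis_sets:
        indexes[ts.experiment_id] = set(
            zip(ts.calls["contig"], ts.calls["pos"], ts.calls["strand"])
        )
    labeled = []
    any_hit = False
    for rec in catalog:
        detections = {
            eid: _detected(rec, idx, window) for eid, idx in indexes.items()
        }
        lit = (rec.contig, rec.g_start, rec.strand) in literature
        any_hit = any_hit or any(detections.values())
        lu = LabeledUorf(rec, detections, lit)
        if literature_is_two_voted and lit:
            # promote by counting literature as two vote sources
            lu = LabeledUorf(rec, dict(detections, __literature2__=True), lit)
        labeled.append(lu)
    total_calls = sum(len(ts.calls) for ts in tis_sets)
    if not any_hit and total_calls > 0 and catalog:
        logger.warning(
            "no TIS call intersects any catalog uORF (%d calls): "
            "possible assembly mismatch", total_calls
        )
    return labeled


def labels_to_frame(labeled: list[LabeledUorf]) -> pd.DataFrame:
    rows = []
    for lu in labeled:
        row = {
            "contig": lu.record.contig,
            "strand": lu.record.strand,
            "g_start": lu.record.g_start,
            "transcript_id": lu.record.transcript_id,
            "votes": lu.votes,
            "literature": lu.literature,
            "partition": lu.partition,
        }
        for eid, flag in lu.detections.items():
            if not eid.startswith("__"):
                row[f"detected:{eid}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LncOrfCall:
    transcript_id: str
    t_start: int
    start_codon: str
    t_stop_end: int
    reads_per_experiment: dict[str, int]
    translated_in: list[str]

    @property
    def votes(self) -> int:
        return len(self.translated_in)


def call_lncrna_orfs(
    models: list[TranscriptModel],
    sequences: dict[str, str],
    pileups: dict[str, dict[tuple[str, int, str], int]],
    start_codons: tuple[str, ...] = NEAR_COGNATE_STARTS,
    min_reads: int = 10,
    window: int = DEFAULT_WINDOW,
) -> list[LncOrfCall]:
    """Call translated ORFs on lncRNA transcripts from read pileups.

    ``pileups`` maps experiment id -> {(contig, genomic pos, strand): reads}.
    An ORF (permitted start codon with an in-frame stop on the transcript) is
    translated in an experiment iff reads summed within +/-``window`` nt of
    its start reach ``min_reads``; 2-voted means translated in >=2
    experiments.
    """
    calls: list[LncOrfCall] = []
    for model in models:
        if model.biotype == "coding":
            continue
        seq = sequences[model.transcript_id]
        # treat the transcript end as the ORF boundary: scan with a pseudo-CDS
        pseudo = TranscriptModel(
            transcript_id=model.transcript_id,
            gene_id=model.gene_id,
            contig=model.contig,
            strand=model.strand,
            exons=model.exons,
            cds_start=model.length + 1,
            cds_end=model.length + 3,
            biotype="coding",
        )
        for rec in scan_transcript(pseudo, seq + "TAA", start_codons):
            if rec.t_stop_end > model.length:
                continue
            reads = {}
            translated = []
            for eid, pileup in pileups.items():
                total = 0
                for d in range(-window, window + 1):
                    total += pileup.get((rec.contig, rec.g_start + d, rec.strand), 0)
                reads[eid] = total
                if total >= min_reads:
                    translated.append(eid)
            calls.append(
                LncOrfCall(
                    transcript_id=model.transcript_id,
                    t_start=rec.t_start,
                    start_codon=rec.start_codon,
                    t_stop_end=rec.t_stop_end,
                    reads_per_experiment=reads,
                    translated_in=translated,
                )
            )
    return calls


@dataclass
class BindingStrength:
    key: tuple
    reads: float
    expression: float
    strength: float
    strong: bool


def stratify_binding(
    labeled: list[LabeledUorf],
    reads_at_start: dict[tuple, float],
    expression: dict[str, float],
) -> tuple[list[BindingStrength], pd.DataFrame, int]:
    """Split positive uORFs by ribosome binding strength and report overlap.

    Binding strength = footprinting reads at the start codon normalized by
    transcript expression. Strong means strictly above the 50th percentile
    (linear-interpolation median) of strength among positives; a degenerate
    all-equal distribution therefore yields all-weak. Positives without
    (positive) expression are excluded and counted. The report gives, per
    experiment and class, the fraction of detected uORFs also positively
    identified in at least one other experiment.
    """
    positives = [lu for lu in labeled if lu.partition != UNLABELED]
    entries: list[tuple[LabeledUorf, float]] = []
    n_excluded = 0
    for lu in positives:
        expr = expression.get(lu.record.transcript_id, 0.0)
        if expr <= 0:
            n_excluded += 1
            logger.info("excluding %s: no expression", lu.record.transcript_id)
            continue
        reads = float(reads_at_start.get(lu.record.key, 0.0))
        entries.append((lu, reads / expr))
    if not entries:
        return [], pd.DataFrame(), n_excluded
    strengths = np.array([s for _, s in entries])
    cutoff = float(np.percentile(strengths, 50))
    result = [
        BindingStrength(
            key=lu.record.key,
            reads=float(reads_at_start.get(lu.record.key, 0.0)),
            expression=float(expression[lu.record.transcript_id]),
            strength=s,
            strong=s > cutoff,
        )
        for (lu, s) in entries
    ]
    strong_keys = {b.key for b in result if b.strong}
    experiment_ids = sorted(
        {e for lu in positives for e in lu.detections if not e.startswith("__")}
    )
    rows = []
    for eid in experiment_ids:
        for cls, keys in (("strong", strong_keys),
                          ("weak", {b.key for b in result} - strong_keys)):
            detected = [
                lu for lu, _ in entries
                if lu.detections.get(eid) and lu.record.key in keys
            ]
            cross = [
                lu for lu in detected
                if any(f for e2, f in lu.detections.items()
                       if e2 != eid and not e2.startswith("__"))
            ]
            frac = len(cross) / len(detected) if detected else float("nan")
            rows.append((eid, cls, len(detected), len(cross), frac))
    report = pd.DataFrame(
        rows, columns=["experiment", "class", "n_detected", "n_cross", "fraction_cross"]
    )
    return result, report, n_excluded
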