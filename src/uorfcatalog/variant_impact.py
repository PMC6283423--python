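"""uORF start-codon gain/loss from variants, and downstream impact summaries.

A loss event is an SNV inside the start codon of a predicted-positive uORF
that removes the codon from the permitted start set; a gain event is a 5'UTR
SNV that creates a new start codon (ATG/CTG by default) whose in-frame stop
lies before the CDS end — i.e. a complete new uORF — and, when a scorer is
supplied, whose uORF the classifier predicts positive. Events feed a
reference-codon x interrupting-variant density matrix, an rQTL enrichment
test, and a gain-versus-loss protein-expression contrast.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import GenomeSequence, TranscriptModel, spliced_sequence
from .uorf_scan import NEAR_COGNATE_STARTS, UorfRecord, _stop_positions_by_frame

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

GAIN = "gain"
LOSS = "loss"

#: gains are restricted to the predicted-positive workhorse codons
DEFAULT_GAIN_CODONS = ("ATG", "CTG")


@dataclass(frozen=True)
class Snv:
    contig: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    variant_id: str = "."


def read_vcf_snvs(path) -> tuple[list[Snv], int]:
    """Read SNVs from a VCF; indels are counted and returned separately.

    Indels introduce multiple competing effects (simultaneous gain and loss)
    and are excluded from the primary channel.
    """
    from cyvcf2 import VCF

    snvs: list[Snv] = []
    n_indels = 0
    for v in VCF(str(path)):
        for alt in v.ALT:
            if len(v.REF) == 1 and len(alt) == 1:
                snvs.append(Snv(v.CHROM, v.POS, v.REF.upper(), alt.upper(),
                                v.ID or "."))
            else:
                n_indels += 1
    return snvs, n_indels


@dataclass(frozen=True)
class StartCodonEvent:
    variant: Snv
    event: str  # gain | loss
    ref_codon: str
    codon_position: int  # 1/2/3 within the start codon
    alt_base: str  # transcript-strand base introduced
    result_codon: str
    uorf_key: tuple | None  # affected uORF (loss) or None
    transcript_id: str
    created: UorfRecord | None = None  # the new uORF (gain)


def _substitute(seq: str, pos0: int, base: str) -> str:
    return seq[:pos0] + base + seq[pos0 + 1 :]


def _first_inframe_stop(seq: str, p: int, cds_end: int) -> int | None:
    stops = _stop_positions_by_frame(seq)[p % 3]
    i = bisect_left(stops, p + 3)
    if i < len(stops) and stops[i] + 2 <= cds_end:
        return stops[i]
    return None


def detect_events(
    positive_uorfs: list[UorfRecord],
    models: list[TranscriptModel],
    genome: GenomeSequence,
    snvs: list[Snv],
    gain_codons: tuple[str, ...] = DEFAULT_GAIN_CODONS,
    loss_codons: tuple[str, ...] = NEAR_COGNATE_STARTS,
    positive_score_fn=None,
) -> tuple[list[StartCodonEvent], dict[str, int]]:
    """Call start-codon gain and loss events for a set of SNVs.

    ``positive_uorfs`` is the predicted-positive catalog whose starts are
    eligible for loss. ``positive_score_fn(record, alt_sequence) -> bool``,
    when given, gates gain events on a positive classifier score. Variants
    whose reference allele disagrees with the genome are skipped and counted
    (assembly check). Minus-strand codon arithmetic complements the alleles.
    """
    model_by_id = {m.transcript_id: m for m in models}
    seq_cache: dict[str, str] = {}

    def tx_seq(tid: str) -> str:
        if tid not in seq_cache:
            seq_cache[tid] = spliced_sequence(model_by_id[tid], genome)
        return seq_cache[tid]

    # genomic position -> (uORF, 1-based codon position) for positive starts
    start_index: dict[tuple[str, int, str], tuple[UorfRecord, int]] = {}
    for rec in positive_uorfs:
        model = model_by_id[rec.transcript_id]
        for i in range(3):
            contig, g = model.transcript_to_genome(rec.t_start + i)
            start_index[(contig, g, rec.strand)] = (rec, i + 1)

    # exon interval index for gain scanning
    trees: dict[str, IntervalTree] = {}
    for m in models:
        if m.biotype != "coding":
            continue
        tree = trees.setdefault(m.contig, IntervalTree())
        for s, e in m.exons:
            tree[s : e + 1] = m

    events: list[StartCodonEvent] = []
    counts = {"ref_mismatch": 0, "loss": 0, "gain": 0}
    gain_set = frozenset(gain_codons)
    loss_set = frozenset(loss_codons)
    start_set = frozenset(NEAR_COGNATE_STARTS)

    for snv in snvs:
        contig_seq = genome.get(snv.contig)
        if contig_seq is None or contig_seq[snv.pos - 1] != snv.ref:
            counts["ref_mismatch"] += 1
            logger.warning("skipping %s:%d %s>%s: reference mismatch",
                           snv.contig, snv.pos, snv.ref, snv.alt)
            continue

        # --- losses: SNV inside a predicted-positive start codon
        for strand in ("+", "-"):
            hit = start_index.get((snv.contig, snv.pos, strand))
            if hit is None:
                continue
            rec, codon_pos = hit
            model = model_by_id[rec.transcript_id]
            seq = tx_seq(rec.transcript_id)
            alt_base = snv.alt if strand == "+" else _COMPLEMENT[snv.alt]
            ref_codon = rec.start_codon
            result = _substitute(ref_codon, codon_pos - 1, alt_base)
            if ref_codon in loss_set and result not in loss_set:
                events.append(
                    StartCodonEvent(
                        variant=snv, event=LOSS, ref_codon=ref_codon,
                        codon_position=codon_pos, alt_base=alt_base,
                        result_codon=result, uorf_key=rec.key,
                        transcript_id=rec.transcript_id,
                    )
                )
                counts["loss"] += 1
            del model, seq

        # --- gains: SNV in a 5'UTR creating a new complete uORF
        tree = trees.get(snv.contig)
        if tree is None:
            continue
        for iv in tree[snv.pos]:
            model: TranscriptModel = iv.data
            t = model.genome_to_transcript(snv.pos)
            if t is None or model.cds_start == 0:
                continue
            seq = tx_seq(model.transcript_id)
            alt_base = snv.alt if model.strand == "+" else _COMPLEMENT[snv.alt]
            alt_seq = _substitute(seq, t - 1, alt_base)
            for p in range(max(1, t - 2), min(t, model.cds_start - 3) + 1):
                ref_codon = seq[p - 1 : p + 2]
                new_codon = alt_seq[p - 1 : p + 2]
                if new_codon not in gain_set or ref_codon in start_set:
                    continue
                q = _first_inframe_stop(alt_seq, p, model.cds_end)
                if q is None:
                    continue
                created = UorfRecord(
                    contig=model.contig, strand=model.strand,
                    g_start=model.transcript_to_genome(p)[1],
                    g_stop_end=model.transcript_to_genome(q + 2)[1],
                    chain=(), transcript_id=model.transcript_id,
                    start_codon=new_codon, t_start=p, t_stop_end=q + 2,
                    topology="upstream" if q + 2 < model.cds_start else "cds_overlap",
                    frame=(p - model.cds_start) % 3,
                )
                if positive_score_fn is not None and not positive_score_fn(
                    created, alt_seq
                ):
                    continue
                events.append(
                    StartCodonEvent(
                        variant=snv, event=GAIN, ref_codon=ref_codon,
                        codon_position=t - p + 1, alt_base=alt_base,
                        result_codon=new_codon, uorf_key=None,
                        transcript_id=model.transcript_id, created=created,
                    )
                )
                counts["gain"] += 1
    return events, counts


def density_matrix(
    events: list[StartCodonEvent],
    codons: tuple[str, ...] = NEAR_COGNATE_STARTS,
) -> pd.DataFrame:
    """Count events per (reference start codon) x (codon position, alt base).

    Defined over start-codon interruption (loss) events: every event's
    reference codon must be a permitted start codon. Identity cells (alt
    equal to the reference base at that position) are structurally zero; the
    grand total equals the number of events.
    """
    columns = [(pos, base) for pos in (1, 2, 3) for base in "ATGC"]
    mat = pd.DataFrame(
        0, index=list(codons),
        columns=pd.MultiIndex.from_tuples(columns, names=["position", "alt"]),
    )
    for ev in events:
        if ev.ref_codon not in mat.index:
            raise ValueError(
                f"event reference codon {ev.ref_codon} is not a start codon; "
                "the density matrix is defined over interruption events"
            )
        mat.loc[ev.ref_codon, (ev.codon_position, ev.alt_base)] += 1
    return mat


def rqtl_enrichment(
    n_hit_positive: int, n_total: int, baseline: float
) -> dict[str, float]:
    """Enrichment of rQTLs landing on positively-scored uORF starts.

    Observed fraction vs the rate expected if variants hit scored uORFs at
    random (the genome-wide positive fraction); two-sided exact binomial
    test.
    """
    if n_total <= 0:
        raise ValueError("no rQTL variants supplied")
    observed = n_hit_positive / n_total
    test = stats.binomtest(n_hit_positive, n_total, baseline, alternative="two-sided")
    return {
        "observed_fraction": observed,
        "baseline_fraction": baseline,
        "fold_enrichment": observed / baseline if baseline > 0 else float("inf"),
        "p_value": float(test.pvalue),
    }


@dataclass
class ExpressionContrast:
    mean_gain: float
    mean_loss: float
    t: float
    dof: int
    p_value: float
    n_gain_obs: int
    n_loss_obs: int


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), len(x) + len(y) - 2, float(res.pvalue)


def expression_contrast(
    observations: pd.DataFrame,
    sharing_threshold: int = 10,
) -> tuple[ExpressionContrast, ExpressionContrast | None]:
    """Gain-vs-loss protein-expression contrast at the observation level.

    ``observations`` has one row per (variant, carrier individual):
    columns event (gain|loss), carriers (individuals sharing the variant),
    expression (normalized protein level), and topology of the affected/new
    uORF. Rows from variants carried by <= ``sharing_threshold`` individuals
    are dropped. The primary contrast is a pooled-variance two-sample t of
    gain vs loss observations; the secondary contrast splits loss events by
    CDS-overlapping vs fully-upstream topology (uORF-uORF repression probe).
    """
    kept = observations[observations["carriers"] > sharing_threshold]
    gain = kept.loc[kept["event"] == GAIN, "expression"].to_numpy(float)
    loss = kept.loc[kept["event"] == LOSS, "expression"].to_numpy(float)
    for name, grp in (("gain", gain), ("loss", loss)):
        if len(grp) == 0:
            raise ValueError(f"empty {name} group after sharing filter")
    t, dof, p = _pooled_t(gain, loss)
    primary = ExpressionContrast(
        mean_gain=float(gain.mean()), mean_loss=float(loss.mean()),
        t=t, dof=dof, p_value=p, n_gain_obs=len(gain), n_loss_obs=len(loss),
    )
    secondary = None
    if "topology" in kept.columns:
        loss_rows = kept[kept["event"] == LOSS]
        over = loss_rows.loc[loss_rows["topology"] == "cds_overlap",
                             "expression"].to_numpy(float)
        upstream = loss_rows.loc[loss_rows["topology"] == "upstream",
                                 "expression"].to_numpy(float)
        if len(over) >= 2 and len(upstream) >= 2:
            t2, dof2, p2 = _pooled_t(over, upstream)
            secondary = ExpressionContrast(
                mean_gain=float(over.mean()), mean_loss=float(upstream.mean()),
                t=t2, dof=dof2, p_value=p2,
                n_gain_obs=len(over), n_loss_obs=len(upstream),
            )
    return primary, secondary
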