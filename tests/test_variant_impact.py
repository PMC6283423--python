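"""Start-codon gain/loss events, density matrices, enrichment and contrasts."""

import numpy as np
import pandas as pd
import pytest

from uorfcatalog.annotation_io import GenomeSequence, load_annotation
from uorfcatalog.synthetic_data import SimulationConfig, contrast_observations, simulate_study
from uorfcatalog.uorf_scan import scan_transcript
from uorfcatalog.variant_impact import (
    Snv,
    StartCodonEvent,
    density_matrix,
    detect_events,
    expression_contrast,
    read_vcf_snvs,
    rqtl_enrichment,
)
from conftest import make_single_exon

SEQ_ACG = "CCACGAAATAGC" + "ATGGATTAA"  # ACG uORF candidate site at UTR pos 3


def setup_plus():
    genome = GenomeSequence()
    genome["c"] = SEQ_ACG
    model = make_single_exon(SEQ_ACG, cds_start=13)
    positives = scan_transcript(model, SEQ_ACG)
    return genome, model, positives


def test_gain_acg_to_atg():
    """C>T at codon position 2 of an ACG site creates an ATG uORF."""
    genome, model, _ = setup_plus()
    snv = Snv("c", 4, "C", "T")  # genomic pos of the ACG's middle base
    events, counts = detect_events([], [model], genome, [snv])
    # the ACG was itself a valid (near-cognate) start, so no gain: ref in set
    assert counts["gain"] == 0
    # a site that is NOT currently a start: AAG is in the near-cognate set
    # too, so use a genuinely non-start reference (CCG -> CTG)
    seq = "CCCCGAAATAGC" + "ATGGATTAA"
    genome2 = GenomeSequence()
    genome2["c"] = seq
    model2 = make_single_exon(seq, cds_start=13)
    snv2 = Snv("c", 4, "C", "T")  # CCG -> CTG at UTR position 3
    events, counts = detect_events([], [model2], genome2, [snv2])
    assert counts["gain"] == 1
    ev = events[0]
    assert ev.event == "gain" and ev.result_codon == "CTG"
    assert ev.created is not None and ev.created.t_start == 3


def test_loss_membership_logic():
    """With the gain/loss subset {ATG, CTG}, ATG -> GTG destroys membership;
    with the full near-cognate set it does not (GTG is still a start)."""
    genome, model, positives = setup_plus()
    atg_like = [r for r in positives if r.start_codon == "ACG"]
    snv = Snv("c", 3, "A", "G")  # ACG -> GCG under full set: GCG not a start
    events, counts = detect_events(atg_like, [model], genome, [snv])
    assert counts["loss"] == 1 and events[0].result_codon == "GCG"
    # ATG->GTG only counts as loss under the restricted subset
    seq = "ATGAAATAGC" + "ATGGATTAA"
    g2 = GenomeSequence()
    g2["c"] = seq
    m2 = make_single_exon(seq, cds_start=11)
    recs = scan_transcript(m2, seq)
    snv2 = Snv("c", 1, "A", "G")
    _, full = detect_events(recs, [m2], g2, [snv2])
    assert full["loss"] == 0  # GTG remains a near-cognate start
    events, restricted = detect_events(
        recs, [m2], g2, [snv2], loss_codons=("ATG", "CTG")
    )
    assert restricted["loss"] == 1 and events[0].result_codon == "GTG"
    assert events[0].codon_position == 1


def test_minus_strand_alleles_complemented():
    """On a minus-strand uORF the VCF alt is complemented before codon
    substitution (hand-built reverse-complement fixture)."""
    tx = SEQ_ACG  # ACG uORF at transcript positions 3..5
    rc = tx.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    genome = GenomeSequence()
    genome["c"] = rc
    n = len(tx)
    model = make_single_exon(tx, cds_start=13, strand="-")
    recs = [r for r in scan_transcript(model, tx) if r.start_codon == "ACG"]
    assert recs and recs[0].g_start == n - 2
    # transcript A->G at the ACG's first base: genomic ref T, genomic alt C
    snv = Snv("c", n - 2, "T", "C")
    events, counts = detect_events(recs, [model], genome, [snv])
    assert counts["loss"] == 1
    assert events[0].alt_base == "G"  # transcript-strand base
    assert events[0].ref_codon == "ACG" and events[0].result_codon == "GCG"


def test_ref_mismatch_skipped():
    genome, model, positives = setup_plus()
    events, counts = detect_events(positives, [model], genome,
                                   [Snv("c", 3, "T", "G")])
    assert counts["ref_mismatch"] == 1 and not events


def test_density_matrix_properties():
    ev = StartCodonEvent(
        variant=Snv("c", 4, "C", "T"), event="loss", ref_codon="ACG",
        codon_position=2, alt_base="T", result_codon="ATG",
        uorf_key=None, transcript_id="t1",
    )
    mat = density_matrix([ev])
    assert mat.values.sum() == 1
    assert mat.loc["ACG", (2, "T")] == 1
    assert density_matrix([]).values.sum() == 0
    # identity columns are structurally zero: ref base at each position
    three = [ev] * 3
    assert density_matrix(three).values.sum() == 3
    for codon in ("ATG", "CTG"):
        m = density_matrix([])
        for pos in (1, 2, 3):
            assert m.loc[codon, (pos, codon[pos - 1])] == 0
    with pytest.raises(ValueError, match="not a start codon"):
        density_matrix(
            [StartCodonEvent(ev.variant, "gain", "CCG", 2, "T", "CTG", None, "t")]
        )


def test_event_round_trip_on_synthetic_bundle(mini_bundle):
    """Gain events re-scan to an existing uORF on the alt sequence; loss
    events re-scan to absence of the original start."""
    from uorfcatalog.annotation_io import spliced_sequence

    models, genome, _ = load_annotation(mini_bundle.gtf, mini_bundle.fasta)
    model_by_id = {m.transcript_id: m for m in models}
    truth = mini_bundle.truth.planted
    active = {(r.g_start, r.strand) for r in truth[truth.active].itertuples()}
    from uorfcatalog.uorf_scan import scan_catalog

    catalog, _ = scan_catalog(models, genome)
    pos = [r for r in catalog if (r.g_start, r.strand) in active]
    snvs, _ = read_vcf_snvs(mini_bundle.vcf)
    events, counts = detect_events(pos, models, genome, snvs)
    assert counts["gain"] > 0 and counts["loss"] > 0
    for ev in events:
        model = model_by_id[ev.transcript_id]
        seq = spliced_sequence(model, genome)
        t = model.genome_to_transcript(ev.variant.pos)
        alt = seq[: t - 1] + ev.alt_base + seq[t:]
        rescanned = scan_transcript(model, alt)
        if ev.event == "gain":
            assert any(
                r.t_start == ev.created.t_start
                and r.start_codon == ev.result_codon
                for r in rescanned
            )
        else:
            original = [r for r in scan_transcript(model, seq)
                        if r.key == ev.uorf_key]
            assert original, "loss event must reference a scanned uORF"
            assert not any(
                r.t_start == original[0].t_start
                and r.start_codon == original[0].start_codon
                for r in rescanned
            )


def test_rqtl_enrichment_hand_values():
    """21 of 44 rQTLs on positives vs a 14.9% baseline is ~48%, ~3.2-fold."""
    out = rqtl_enrichment(21, 44, 0.149)
    assert round(100 * out["observed_fraction"]) == 48
    assert out["fold_enrichment"] == pytest.approx(3.2, abs=0.05)
    assert out["p_value"] < 1e-6
    assert rqtl_enrichment(0, 10, 0.149)["fold_enrichment"] == 0
    assert rqtl_enrichment(149, 1000, 0.149)["fold_enrichment"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        rqtl_enrichment(0, 0, 0.149)


def test_enrichment_invariant_under_duplication():
    a = rqtl_enrichment(21, 44, 0.149)["fold_enrichment"]
    b = rqtl_enrichment(42, 88, 0.149)["fold_enrichment"]
    assert a == pytest.approx(b)


def obs_frame(gain, loss, carriers=20):
    rows = [{"event": "gain", "carriers": carriers, "expression": v,
             "topology": "upstream"} for v in gain]
    rows += [{"event": "loss", "carriers": carriers, "expression": v,
              "topology": "upstream"} for v in loss]
    return pd.DataFrame(rows)


def test_contrast_hand_values():
    primary, _ = expression_contrast(obs_frame([1.0, 2.0], [3.0, 4.0]))
    assert primary.t == pytest.approx(-2.828, abs=0.001)
    assert primary.dof == 2
    identical, _ = expression_contrast(obs_frame([1.0, 2.0], [1.0, 2.0]))
    assert identical.t == pytest.approx(0.0)


def test_contrast_sharing_filter_and_empty_group():
    frame = obs_frame([1.0], [2.0], carriers=5)
    with pytest.raises(ValueError, match="empty"):
        expression_contrast(frame, sharing_threshold=10)


def test_contrast_sign_recovery_over_seeds():
    """The planted +0.5/-0.5 SD gain/loss protein effect yields a positive
    gain-vs-loss t statistic in >=9 of 10 simulated studies."""
    hits = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed, n_transcripts=60, n_loss_variants=12,
                               n_gain_variants=6)
        import tempfile

        bundle = simulate_study(cfg, tempfile.mkdtemp())
        obs = contrast_observations(bundle)
        primary, _ = expression_contrast(obs, sharing_threshold=10)
        hits += primary.t > 0
    assert hits >= 9
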