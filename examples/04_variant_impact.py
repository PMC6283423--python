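"""Start-codon gain/loss events from variants and their expression impact.

Runs the variant channel on a synthetic study: detects SNVs that destroy
predicted-active uORF start codons (loss) or create new ATG/CTG uORFs
(gain), tabulates the interruption density matrix, and contrasts protein
expression between gain and loss carriers.
"""

import tempfile

from uorfcatalog.annotation_io import load_annotation
from uorfcatalog.synthetic_data import (
    SimulationConfig,
    contrast_observations,
    simulate_study,
)
from uorfcatalog.uorf_scan import scan_catalog
from uorfcatalog.variant_impact import (
    density_matrix,
    detect_events,
    expression_contrast,
    read_vcf_snvs,
    rqtl_enrichment,
)

bundle = simulate_study(SimulationConfig(seed=1, n_transcripts=100),
                        tempfile.mkdtemp())
models, genome, _ = load_annotation(bundle.gtf, bundle.fasta)
catalog, _ = scan_catalog(models, genome)
truth = bundle.truth.planted
active = {(int(r.g_start), r.strand) for r in truth[truth.active].itertuples()}
positives = [r for r in catalog if (r.g_start, r.strand) in active]

snvs, n_indels = read_vcf_snvs(bundle.vcf)
events, counts = detect_events(positives, models, genome, snvs)
print(f"SNVs: {len(snvs)} (indels deferred: {n_indels}); events: {counts}")

losses = [e for e in events if e.event == "loss"]
mat = density_matrix(losses)
print("density matrix row totals (interrupted reference codons):")
print(mat.sum(axis=1)[mat.sum(axis=1) > 0].to_string())

primary, stratified = expression_contrast(contrast_observations(bundle),
                                          sharing_threshold=10)
print(f"gain mean {primary.mean_gain:+.3f} vs loss mean {primary.mean_loss:+.3f}: "
      f"t = {primary.t:.2f}, dof = {primary.dof}, P = {primary.p_value:.2g}")
# A positive t recovers the planted direction: uORF gain raises and loss
# lowers downstream protein expression in this simulation.

print("rQTL-style enrichment for the published 21/44 vs 14.9% baseline:")
print({k: round(v, 3) for k, v in rqtl_enrichment(21, 44, 0.149).items()})
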