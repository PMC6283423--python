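"""Scan a genome-wide uORF catalog on a synthetic mini-study.

Builds a small annotated genome with planted uORFs, scans every coding
transcript's 5'UTR for ATG/near-cognate starts with an in-frame stop before
the CDS end, cleanses N-terminal extensions, and deduplicates by genomic
coordinates.
"""

import tempfile

from uorfcatalog.annotation_io import load_annotation
from uorfcatalog.synthetic_data import SimulationConfig, simulate_study
from uorfcatalog.uorf_scan import catalog_to_frame, scan_catalog

bundle = simulate_study(SimulationConfig(seed=0, n_transcripts=60),
                        tempfile.mkdtemp())
models, genome, report = load_annotation(bundle.gtf, bundle.fasta)
catalog, stats = scan_catalog(models, genome)

print(f"transcripts loaded: {report.n_loaded} (dropped {report.n_dropped})")
print(f"raw uORFs: {stats['n_raw']}  "
      f"N-terminal extensions removed: {stats['removed']['shared_stop_extension']}  "
      f"unique after dedup: {stats['n_unique']}")
frame = catalog_to_frame(catalog)
print(frame["topology"].value_counts().to_string())
print(frame["start_codon"].value_counts().head().to_string())
# Most candidates are background (inactive) uORFs from near-cognate codons;
# the planted uORFs are a small, known subset used as ground truth elsewhere.
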