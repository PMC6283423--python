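"""Self-contained synthetic uORF study generator.

Two layers share one configuration:

* :func:`simulate_catalog` draws a statistical uORF catalog (features,
  activity truth, per-experiment detections) at full study scale — by
  default 20,000 unique uORFs of which 1,000 are truly active, observed by
  three pseudo-experiments that each detect an active uORF with 40%
  sensitivity. This emulates the key structure of published ribosome
  profiling reference sets: high false-negative rates, hence low pairwise
  overlap, and attribute distributions shifted between active and inactive
  uORFs (conservation up; distance to the CDS 203 vs 318 nt; 5'UTR length
  360 vs 618 nt; fewer internal near-cognate starts).

* :func:`simulate_study` writes a complete miniature file bundle — genome
  FASTA, GTF, per-experiment TIS tables, conservation bedGraph, expression
  table, MS peptide FASTA, VCF of start-codon gain/loss SNVs, genotypes and
  protein-level tables — around planted uORFs with known activity, so every
  file-facing pipeline stage can run end to end without downloads.

The generator does not emulate read-level ribosome profiling, real codon
usage, isoform structure beyond simple two-exon splicing, or linkage between
variants; conclusions from it are about the pipeline's correctness, not
about real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import STOP_CODONS
from .uorf_scan import NEAR_COGNATE_STARTS

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    # statistical catalog scale
    n_uorfs: int = 20_000
    frac_active: float = 0.05  # 1,000 active among 20,000
    n_experiments: int = 3
    sensitivity: float = 0.40
    false_positive_rate: float = 0.001
    # attribute effect sizes for active uORFs
    conservation_shift: float = 2.0  # SD units at start/stop codons
    cds_distance_mean_active: float = 203.0
    cds_distance_mean_inactive: float = 318.0
    utr_length_mean_active: float = 360.0
    utr_length_mean_inactive: float = 618.0
    internal_starts_mean_active: float = 2.0
    internal_starts_mean_inactive: float = 3.0
    # file-bundle (mini-genome) scale
    n_transcripts: int = 200
    frac_active_planted: float = 0.30
    mean_tis_reads: float = 30.0
    # variants
    n_loss_variants: int = 40
    n_gain_variants: int = 10
    n_individuals: int = 46
    carrier_fraction: float = 0.35
    protein_effect_gain: float = 0.5
    protein_effect_loss: float = -0.5

    def __post_init__(self):
        for p in (self.frac_active, self.sensitivity, self.false_positive_rate,
                  self.frac_active_planted, self.carrier_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# statistical catalog
# ---------------------------------------------------------------------------

_START_PROBS_ACTIVE = {
    "ATG": 0.35, "CTG": 0.28, "GTG": 0.08, "TTG": 0.07, "ACG": 0.07,
    "ATC": 0.05, "ATT": 0.04, "ATA": 0.04, "AAG": 0.01, "AGG": 0.01,
}
_START_PROBS_INACTIVE = {
    "ATG": 0.067, "CTG": 0.193, "GTG": 0.085, "TTG": 0.085, "ACG": 0.085,
    "ATC": 0.085, "ATT": 0.08, "ATA": 0.08, "AAG": 0.12, "AGG": 0.12,
}


@dataclass
class CatalogSimulation:
    features: pd.DataFrame
    active: np.ndarray  # bool per uORF
    detections: pd.DataFrame  # bool per uORF x experiment
    config: SimulationConfig


def simulate_catalog(
    config: SimulationConfig | None = None, seed: int | None = None
) -> CatalogSimulation:
    """Draw a study-scale catalog of uORF attributes, truth and detections."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_uorfs
    active = np.zeros(n, bool)
    active[: int(round(n * config.frac_active))] = True
    rng.shuffle(active)

    def pick(a, b):
        return np.where(active, a, b)

    cons_start = rng.normal(pick(config.conservation_shift, 0.0), 1.0)
    cons_stop = rng.normal(pick(0.75 * config.conservation_shift, 0.0), 1.0)
    dist = 1.0 + rng.exponential(
        pick(config.cds_distance_mean_active, config.cds_distance_mean_inactive)
    )
    uorf_len = 9.0 + 3.0 * rng.poisson(10.0, n)
    extra_mean = np.maximum(
        pick(config.utr_length_mean_active, config.utr_length_mean_inactive)
        - dist - uorf_len,
        20.0,
    )
    utr_len = dist + uorf_len + rng.exponential(extra_mean)
    internal = rng.poisson(
        pick(config.internal_starts_mean_active, config.internal_starts_mean_inactive)
    ).astype(float)
    gc = rng.beta(9.0, 11.0, n)
    context = np.where(
        active, rng.choice([0, 1, 2, 3], n, p=[0.22, 0.26, 0.26, 0.26]),
        rng.choice([0, 1, 2, 3], n, p=[0.28, 0.26, 0.24, 0.22]),
    ).astype(float)
    codons = np.array(NEAR_COGNATE_STARTS)
    start_codon = np.where(
        active,
        rng.choice(codons, n, p=[_START_PROBS_ACTIVE[c] for c in codons]),
        rng.choice(codons, n, p=[_START_PROBS_INACTIVE[c] for c in codons]),
    )
    features = pd.DataFrame(
        {
            "cons_start": cons_start,
            "cons_stop": cons_stop,
            "dist_to_cds": np.round(dist),
            "utr5_length": np.round(utr_len),
            "uorf_length": uorf_len,
            "internal_starts": internal,
            "gc_content": gc,
            "start_context": context,
            "start_codon": start_codon,
        }
    )
    det = {}
    for e in range(config.n_experiments):
        p = np.where(active, config.sensitivity, config.false_positive_rate)
        det[f"exp{e + 1}"] = rng.random(n) < p
    return CatalogSimulation(features, active, pd.DataFrame(det), config)


# ---------------------------------------------------------------------------
# mini-genome file bundle
# ---------------------------------------------------------------------------

@dataclass
class PlantedUorf:
    transcript_id: str
    t_start: int
    start_codon: str
    t_stop_end: int
    g_start: int
    strand: str
    active: bool


@dataclass
class GroundTruth:
    planted: pd.DataFrame  # one row per planted uORF, incl. detection flags
    variants: pd.DataFrame  # one row per written variant with true event type
    n_active: int
    config: SimulationConfig


@dataclass
class StudyBundle:
    """Paths of the files written by :func:`simulate_study`."""

    root: Path
    fasta: Path
    gtf: Path
    tis: list[Path]
    conservation: Path
    expression: Path
    peptides: Path
    vcf: Path
    genotypes: Path
    protein: Path
    truth: GroundTruth


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def _orf_body(rng, n_codons: int) -> str:
    return "".join(rng.choice(_NON_STOP_CODONS, n_codons))


def _sanitize_utr(rng, seq: list[str], lo: int, hi: int, frame_anchor: int) -> None:
    """Remove stop codons in the given frame from seq[lo:hi] (codon starts
    congruent to frame_anchor mod 3), so a planted uORF keeps its first
    in-frame stop where planted."""
    p = lo + ((frame_anchor - lo) % 3)
    while p + 3 <= hi:
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            seq[p] = {"T": "C"}.get(seq[p], "C")
        p += 3


def _build_transcript(rng, config: SimulationConfig, active: bool):
    """Construct one transcript sequence with a planted uORF.

    Returns (sequence, utr5_len, planted start position, start codon,
    stop-end position, cds_start, cds_end).
    """
    probs = _START_PROBS_ACTIVE if active else _START_PROBS_INACTIVE
    codon = rng.choice(list(probs), p=list(probs.values()))
    n_body = 2 + rng.poisson(8)
    uorf_len = 3 * (n_body + 2)
    mean_d = (config.cds_distance_mean_active if active
              else config.cds_distance_mean_inactive)
    dist = int(1 + rng.exponential(mean_d / 4.0))  # mini-genome scale: /4
    mean_u = (config.utr_length_mean_active if active
              else config.utr_length_mean_inactive)
    extra = int(rng.exponential(max(mean_u / 4.0 - dist - uorf_len, 10.0)))
    utr_len = extra + uorf_len + dist
    p = extra + 1  # transcript position of planted start codon
    utr = list(_random_seq(rng, utr_len))
    stop = rng.choice(sorted(STOP_CODONS))
    planted = codon + _orf_body(rng, n_body) + stop
    utr[p - 1 : p - 1 + uorf_len] = list(planted)
    # keep the planted stop the FIRST in-frame stop: scrub the body frame
    _sanitize_utr(rng, utr, p - 1 + 3, p - 1 + uorf_len - 3, p - 1)
    cds_n = 40 + rng.poisson(30)
    cds = "ATG" + _orf_body(rng, cds_n) + rng.choice(sorted(STOP_CODONS))
    seq = "".join(utr) + cds
    cds_start = utr_len + 1
    return seq, utr_len, p, codon, p + uorf_len - 1, cds_start, len(seq)


def simulate_study(config: SimulationConfig | None = None, outdir=None) -> StudyBundle:
    """Write the miniature study bundle and return its paths + ground truth.

    Deterministic under ``config.seed``: the same configuration produces
    byte-identical files.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    contig = "chrS"
    genome_parts: list[str] = []
    offset = 0
    gtf_lines: list[str] = []
    planted_rows = []
    cons_rows: list[tuple[int, int, float]] = []  # (start0, end, value)
    expr_rows = []
    tx_meta = []  # (tid, strand, gstart, gend, seq, planted info)

    for i in range(config.n_transcripts):
        tid = f"TX{i:04d}"
        gene = f"G{i:04d}"
        active = bool(rng.random() < config.frac_active_planted)
        seq, utr_len, p, codon, stop_end, cds_start, cds_end = _build_transcript(
            rng, config, active
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = offset + 21  # 20 nt spacer
        gend = gstart + len(seq) - 1
        gseq = seq if strand == "+" else "".join(
            _COMPLEMENT[b] for b in reversed(seq)
        )
        genome_parts.append(_random_seq(rng, 20) + gseq)
        offset = gend

        def t2g(t: int) -> int:
            return gstart + t - 1 if strand == "+" else gend - t + 1

        attrs = (
            f'gene_id "{gene}"; transcript_id "{tid}"; transcript_type "coding";'
        )
        gtf_lines.append(
            f"{contig}\tsim\texon\t{gstart}\t{gend}\t.\t{strand}\t.\t{attrs}"
        )
        c_lo, c_hi = sorted((t2g(cds_start), t2g(cds_end)))
        gtf_lines.append(
            f"{contig}\tsim\tCDS\t{c_lo}\t{c_hi}\t.\t{strand}\t.\t{attrs}"
        )
        # conservation: background over the 5'UTR, shifted at planted codons
        for t in range(1, utr_len + 1):
            in_codon = p <= t <= p + 2 or stop_end - 2 <= t <= stop_end
            mu = config.conservation_shift if (active and in_codon) else 0.0
            g = t2g(t)
            cons_rows.append((g - 1, g, float(rng.normal(mu, 1.0))))
        expr_rows.append((tid, float(rng.lognormal(1.0, 0.5))))
        planted_rows.append(
            {
                "transcript_id": tid, "gene_id": gene, "t_start": p,
                "start_codon": codon, "t_stop_end": stop_end,
                "g_start": t2g(p), "strand": strand, "active": active,
            }
        )
        tx_meta.append((tid, strand, gstart, gend, seq, planted_rows[-1],
                        cds_start, cds_end))

    genome = "".join(genome_parts) + _random_seq(rng, 20)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for j in range(0, len(genome), 70):
            fh.write(genome[j : j + 70] + "\n")
    gtf = outdir / "annotation.gtf"
    gtf.write_text("\n".join(gtf_lines) + "\n")

    planted = pd.DataFrame(planted_rows)

    # per-experiment TIS tables (BED-like, 0-based starts)
    tis_paths = []
    for e in range(config.n_experiments):
        name = f"exp{e + 1}"
        detected = np.where(
            planted["active"],
            rng.random(len(planted)) < config.sensitivity,
            rng.random(len(planted)) < config.false_positive_rate,
        )
        planted[f"detected:{name}"] = detected
        rows = []
        for _, row in planted[detected].iterrows():
            reads = int(10 + rng.poisson(config.mean_tis_reads))
            rows.append(f"{contig}\t{row.g_start - 1}\t{row.strand}\t{reads}")
        path = outdir / f"tis_{name}.tsv"
        path.write_text("\n".join(rows) + ("\n" if rows else ""))
        tis_paths.append(path)

    cons_path = outdir / "conservation.bedgraph"
    with open(cons_path, "w") as fh:
        for s0, e, v in cons_rows:
            fh.write(f"{contig}\t{s0}\t{e}\t{v:.4f}\n")
    expr_path = outdir / "expression.tsv"
    expr_path.write_text("".join(f"{t}\t{v:.4f}\n" for t, v in expr_rows))

    # MS peptide evidence: tryptic-like fragments of some active uORF peptides
    from .annotation_io import translate_orf

    pep_lines = []
    k = 0
    for tid, strand, gstart, gend, seq, prow, cds_start, cds_end in tx_meta:
        if prow["active"] and rng.random() < 0.3:
            aa = translate_orf(seq[prow["t_start"] - 1 : prow["t_stop_end"]])
            if len(aa) >= 5:
                pep_lines.append(f">pep{k}\n{aa[1:6]}")
                k += 1
    peptides = outdir / "ms_peptides.fa"
    peptides.write_text("\n".join(pep_lines) + ("\n" if pep_lines else ""))

    # variants: losses on active planted starts, gains creating ATG/CTG
    variant_rows = []
    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={len(genome)}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    start_set = frozenset(NEAR_COGNATE_STARTS)
    active_idx = [j for j, m in enumerate(tx_meta) if m[5]["active"]]
    rng.shuffle(active_idx)
    vid = 0
    for j in active_idx[: config.n_loss_variants]:
        tid, strand, gstart, gend, seq, prow, cds_start, cds_end = tx_meta[j]
        p = prow["t_start"]
        codon = prow["start_codon"]
        found = None
        for cp in rng.permutation(3):
            for alt in "ACGT":
                if alt == codon[cp]:
                    continue
                new = codon[:cp] + alt + codon[cp + 1 :]
                if new not in start_set:
                    found = (int(cp), alt, new)
                    break
            if found:
                break
        if not found:
            continue
        cp, alt_t, new = found
        t = p + cp
        gpos = gstart + t - 1 if strand == "+" else gend - t + 1
        ref_g = genome[gpos - 1]
        alt_g = alt_t if strand == "+" else _COMPLEMENT[alt_t]
        vid += 1
        name = f"loss{vid}"
        vcf_lines.append(f"{contig}\t{gpos}\t{name}\t{ref_g}\t{alt_g}\t.\tPASS\t.")
        variant_rows.append(
            {"id": name, "event": "loss", "transcript_id": tid,
             "gene_id": prow["gene_id"], "pos": gpos,
             "topology": "upstream"}
        )

    n_gain = 0
    order = rng.permutation(len(tx_meta))
    for j in order:
        if n_gain >= config.n_gain_variants:
            break
        tid, strand, gstart, gend, seq, prow, cds_start, cds_end = tx_meta[j]
        hit = None
        for p in rng.permutation(np.arange(1, cds_start - 2)):
            p = int(p)
            ref_codon = seq[p - 1 : p + 2]
            if ref_codon in start_set:
                continue
            for target in ("ATG", "CTG"):
                diff = [i for i in range(3) if ref_codon[i] != target[i]]
                if len(diff) != 1:
                    continue
                cp = diff[0]
                alt_seq = seq[: p - 1 + cp] + target[cp] + seq[p + cp :]
                # the new uORF must terminate before the CDS end
                stops = [
                    q for q in range(p + 3, cds_end - 1, 3)
                    if alt_seq[q - 1 : q + 2] in STOP_CODONS
                ]
                if not stops or stops[0] + 2 > cds_end:
                    continue
                hit = (p, cp, ref_codon, target)
                break
            if hit:
                break
        if hit is None:
            continue
        p, cp, ref_codon, target = hit
        t = p + cp
        gpos = gstart + t - 1 if strand == "+" else gend - t + 1
        ref_g = genome[gpos - 1]
        alt_g = target[cp] if strand == "+" else _COMPLEMENT[target[cp]]
        vid += 1
        n_gain += 1
        name = f"gain{vid}"
        vcf_lines.append(f"{contig}\t{gpos}\t{name}\t{ref_g}\t{alt_g}\t.\tPASS\t.")
        variant_rows.append(
            {"id": name, "event": "gain", "transcript_id": tid,
             "gene_id": prow["gene_id"], "pos": gpos, "topology": "upstream"}
        )

    vcf = outdir / "variants.vcf"
    header, body = vcf_lines[:3], vcf_lines[3:]
    body.sort(key=lambda line: int(line.split("\t")[1]))
    vcf.write_text("\n".join(header + body) + "\n")
    variants = pd.DataFrame(variant_rows)

    # genotypes and protein expression
    individuals = [f"IND{i:02d}" for i in range(config.n_individuals)]
    geno = {}
    for row in variant_rows:
        geno[row["id"]] = (rng.random(config.n_individuals)
                           < config.carrier_fraction).astype(int)
    genotypes = pd.DataFrame(geno, index=individuals).T
    genotypes.index.name = "variant_id"
    geno_path = outdir / "genotypes.tsv"
    genotypes.to_csv(geno_path, sep="\t")

    by_gene: dict[str, list[dict]] = {}
    for row in variant_rows:
        by_gene.setdefault(row["gene_id"], []).append(row)
    prot_rows = []
    for gene in sorted(by_gene):
        for ind in individuals:
            effect = sum(
                (config.protein_effect_gain if row["event"] == "gain"
                 else config.protein_effect_loss)
                for row in by_gene[gene]
                if genotypes.loc[row["id"], ind]
            )
            prot_rows.append((gene, ind, float(rng.normal(effect, 1.0))))
    protein = pd.DataFrame(prot_rows, columns=["gene_id", "individual", "expression"])
    prot_path = outdir / "protein.tsv"
    protein.to_csv(prot_path, sep="\t", index=False)

    truth = GroundTruth(
        planted=planted, variants=variants,
        n_active=int(planted["active"].sum()), config=config,
    )
    return StudyBundle(
        root=outdir, fasta=fasta, gtf=gtf, tis=tis_paths,
        conservation=cons_path, expression=expr_path, peptides=peptides,
        vcf=vcf, genotypes=geno_path, protein=prot_path, truth=truth,
    )


def contrast_observations(bundle: StudyBundle) -> pd.DataFrame:
    """Observation-level table for the gain/loss expression contrast.

    One row per (variant, carrier individual) with the carrier's protein
    expression for the affected gene.
    """
    genotypes = pd.read_csv(bundle.genotypes, sep="\t", index_col=0)
    protein = pd.read_csv(bundle.protein, sep="\t")
    prot = protein.set_index(["gene_id", "individual"])["expression"]
    rows = []
    for _, var in bundle.truth.variants.iterrows():
        carriers = genotypes.loc[var["id"]]
        n_carriers = int(carriers.sum())
        for ind, g in carriers.items():
            if g:
                rows.append(
                    {
                        "variant_id": var["id"], "event": var["event"],
                        "carriers": n_carriers, "topology": var["topology"],
                        "expression": float(prot.loc[(var["gene_id"], ind)]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

def recovery_report(
    truth_active: np.ndarray,
    scores: np.ndarray | None = None,
    population_estimate: float | None = None,
    true_population: float | None = None,
    ks_table: pd.DataFrame | None = None,
    contrast_t: float | None = None,
) -> dict[str, float]:
    """Compare pipeline outputs against the generator's ground truth.

    Reports whichever metrics the supplied outputs permit: classifier AUC
    against true activity, relative population-estimate error, whether the
    shifted conservation and CDS-distance features rank in the KS top 5, and
    the sign of the gain/loss expression contrast.
    """
    from sklearn.metrics import roc_auc_score

    report: dict[str, float] = {}
    if scores is not None:
        report["classifier_auc_vs_truth"] = float(
            roc_auc_score(np.asarray(truth_active, bool), np.asarray(scores))
        )
    if population_estimate is not None and true_population:
        report["population_relative_error"] = float(
            abs(population_estimate - true_population) / true_population
        )
    if ks_table is not None:
        top5 = set(ks_table.head(5)["feature"])
        report["shifted_features_in_ks_top5"] = float(
            len({"cons_start", "dist_to_cds"} & top5)
        )
    if contrast_t is not None:
        report["contrast_sign_positive"] = float(contrast_t > 0)
    return report


def loo_auc(config: SimulationConfig | None = None, seed: int = 0) -> float:
    """Mean leave-one-experiment-out AUC on one simulated catalog."""
    from .classifier import loo_validate

    sim = simulate_catalog(config, seed=seed)
    report = loo_validate(sim.features, sim.detections)
    return report.mean_auc


def mean_loo_auc(
    config: SimulationConfig | None = None, n_seeds: int = 5, base_seed: int = 0
) -> float:
    """Mean held-out AUC over independent simulated studies."""
    return float(np.mean([loo_auc(config, seed=base_seed + s)
                          for s in range(n_seeds)]))
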