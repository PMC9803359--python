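"""Seed-deterministic generators for every input the pipeline consumes.

Three generators, each emitting standard text formats plus a machine-readable
truth table:

* ``simulate_sites`` — a two-class 5'SS population (AG//GU-like vs
  //GURAG-like, mixture weight 0.5 by default, 0.9 per-position consensus
  probability, GU at +1..+2 with probability 0.98), realised as a toy genome
  (FASTA) and annotation (GTF) whose annotated donors carry the drawn
  windows.
* ``simulate_psi`` — event x sample PSI matrices under a linear
  genotype + temperature + interaction model with Gaussian noise, matching a
  6-replicate, two-genotype design at 4/12/20/28 degC.
* ``simulate_bsa`` — pooled EMS variant depths for two F2 sibling pools with
  one recessive causal locus: the mutant pool is homozygous at the causal
  SNP (allele fraction 1), the aphenotypic pool segregates at 1/3, and
  linkage decays with distance at a per-Mb recombination fraction.

All randomness flows from one ``numpy`` Generator seeded by the spec's seed;
draws are consumed in a fixed documented order, so equal seeds give
byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_annotation_io import (
    FIVE_PRIME_POSITIONS,
    Genome,
    GenomeSequence,
    SpliceSiteWindow,
    TranscriptModel,
    rna_to_dna,
)
from .bsa_mapping import PoolVariant

log = logging.getLogger(__name__)

__all__ = [
    "SpliceSitePopulationSpec",
    "PsiSimSpec",
    "BsaSimSpec",
    "SitesSimulation",
    "PsiSimulation",
    "BsaSimulation",
    "simulate_sites",
    "simulate_psi",
    "simulate_bsa",
]

_RNA = "ACGU"


def _emission(consensus: dict[int, dict[str, float]]) -> dict[int, np.ndarray]:
    """Full per-position distributions; unspecified positions are uniform."""
    out = {}
    for pos in FIVE_PRIME_POSITIONS:
        spec = consensus.get(pos)
        if spec is None:
            out[pos] = np.full(4, 0.25)
            continue
        probs = np.zeros(4)
        named = sum(spec.values())
        rest = (1.0 - named) / (4 - len(spec)) if len(spec) < 4 else 0.0
        for i, b in enumerate(_RNA):
            probs[i] = spec.get(b, rest)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"emission at {pos:+d} does not sum to 1: {probs}")
        out[pos] = probs
    return out


@dataclass
class SpliceSitePopulationSpec:
    """Two-class donor population: AG//GU-like (strong exonic AG, degenerate
    intron tail) vs //GURAG-like (degenerate exon end, strong RAG tail)."""

    n_sites: int = 10_000
    aggu_weight: float = 0.5  # mixture weight of the AG//GU-like class
    consensus_p: float = 0.9
    gu_p: float = 0.98
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.aggu_weight <= 1:
            raise ValueError("mixture weight must be in [0, 1]")
        for p in (self.consensus_p, self.gu_p):
            if not 0 < p <= 1:
                raise ValueError("emission probabilities must be in (0, 1]")

    def emissions(self) -> dict[str, dict[int, np.ndarray]]:
        gu = {1: {"G": self.gu_p}, 2: {"U": self.gu_p}}
        aggu = _emission({**gu, -2: {"A": self.consensus_p}, -1: {"G": self.consensus_p}})
        gurag = _emission(
            {
                **gu,
                3: {"A": self.consensus_p / 2, "G": self.consensus_p / 2},
                4: {"A": self.consensus_p},
                5: {"G": self.consensus_p},
            }
        )
        return {"aggu": aggu, "gurag": gurag}


# Fixed building blocks of the toy genome; chosen so coordinates are easy to
# check by hand: every gene occupies the same-size block.
_EXON1_PAD = "CTCTGATTCGAAGCTAGGATCCTAGTCAATGGATCCTAGTCAATG"  # 45 nt before window
_INTRON_TAIL = "CTCCTATTAATTTCGGTTTTTGCAG"  # 25 nt, ends with a canonical 3'SS
_EXON2 = "CAGGATTTGGAGCTTCAGGAGATCATCGATGA"  # 32 nt
_SPACER = "GGCCGGCCGGCCGGCCGGCC"  # 20 nt between genes


@dataclass
class SitesSimulation:
    windows: list[SpliceSiteWindow]
    labels: list[str]
    genome: Genome
    transcripts: list[TranscriptModel]
    spec: SpliceSitePopulationSpec

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_index": range(len(self.windows)),
                "label": self.labels,
                "chrom": [w.origin[0] for w in self.windows],
                "donor_pos": [w.origin[2] for w in self.windows],
                "seq": [w.seq for w in self.windows],
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sites_genome.fa",
            "gtf": outdir / "sites_annotation.gtf",
            "truth": outdir / "sites_truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.genome:
                fh.write(f">{rec.name}\n")
                for i in range(0, len(rec.seq), 60):
                    fh.write(rec.seq[i:i + 60] + "\n")
        with open(paths["gtf"], "w") as fh:
            for tx in self.transcripts:
                for n, (s, e) in enumerate(tx.exons, start=1):
                    attrs = (
                        f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'exon_number "{n}";'
                    )
                    fh.write(
                        f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_sites(spec: SpliceSitePopulationSpec) -> SitesSimulation:
    """Draw a two-class donor population and realise it as a toy genome.

    Each site becomes a two-exon, one-intron gene on the + strand of a single
    chromosome; the drawn window's -3..-1 bases end exon 1 and its +1..+5
    bases start the intron, so extraction from the emitted FASTA+GTF
    reproduces the drawn windows exactly.
    """
    rng = np.random.default_rng(spec.seed)
    emissions = spec.emissions()
    labels = []
    seqs = []
    for _ in range(spec.n_sites):
        label = "aggu" if rng.random() < spec.aggu_weight else "gurag"
        labels.append(label)
        bases = [
            _RNA[rng.choice(4, p=emissions[label][pos])]
            for pos in FIVE_PRIME_POSITIONS
        ]
        seqs.append("".join(bases))

    chrom = "chrS"
    parts = []
    transcripts = []
    windows = []
    cursor = 0
    for i, (seq, label) in enumerate(zip(seqs, labels)):
        exonic, intronic = rna_to_dna(seq[:3]), rna_to_dna(seq[3:])
        gene_start = cursor
        exon1 = _EXON1_PAD + exonic  # 48 nt
        intron = intronic + _INTRON_TAIL  # 30 nt
        exon1_iv = (gene_start, gene_start + len(exon1))
        intron_start = exon1_iv[1]
        exon2_iv = (intron_start + len(intron), intron_start + len(intron) + len(_EXON2))
        parts.append(exon1 + intron + _EXON2 + _SPACER)
        cursor = exon2_iv[1] + len(_SPACER)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"T{i:05d}.1",
                gene_id=f"G{i:05d}",
                chrom=chrom,
                strand="+",
                exons=(exon1_iv, exon2_iv),
            )
        )
        windows.append(
            SpliceSiteWindow("five_prime", seq, origin=(chrom, "+", intron_start))
        )
    genome = Genome([GenomeSequence(chrom, "".join(parts))])
    return SitesSimulation(windows, labels, genome, transcripts, spec)


@dataclass
class PsiSimSpec:
    """Planted PSI effects: a fraction of events get a genotype delta, a
    fraction additionally an interaction profile added to the mutant per
    temperature; Gaussian noise on top, clipped to [0, 1]."""

    n_events: int = 1000
    frac_genotype: float = 0.2
    delta_psi: float = 0.2
    frac_interaction: float = 0.0
    interaction_profile: dict[int, float] = field(
        default_factory=lambda: {4: 0.0, 12: 0.0, 20: 0.0, 28: 0.15}
    )
    sigma: float = 0.05
    replicates: int = 6
    temperatures: tuple[int, ...] = (4, 12, 20, 28)
    baseline_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.frac_genotype <= 1 or not 0 <= self.frac_interaction <= 1:
            raise ValueError("effect fractions must be in [0, 1]")


@dataclass
class PsiSimulation:
    psi: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    clip_rate: float

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "psi": outdir / "psi_matrix.tsv",
            "design": outdir / "design.tsv",
            "truth": outdir / "psi_truth.tsv",
        }
        self.psi.rename_axis("event_id").to_csv(paths["psi"], sep="\t")
        self.design.rename_axis("sample_id").to_csv(paths["design"], sep="\t")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_psi(spec: PsiSimSpec) -> PsiSimulation:
    """PSI = baseline + genotype effect + interaction profile + N(0, sigma)."""
    rng = np.random.default_rng(spec.seed)
    samples = []
    for genotype in ("wt", "mutant"):
        for temp in spec.temperatures:
            for rep in range(1, spec.replicates + 1):
                samples.append((f"{genotype}_{temp}C_r{rep}", genotype, temp, rep))
    design = pd.DataFrame(
        samples, columns=["sample_id", "genotype", "temperature", "replicate"]
    ).set_index("sample_id")

    n = spec.n_events
    baseline = rng.uniform(*spec.baseline_range, size=n)
    has_geno = rng.random(n) < spec.frac_genotype
    sign = rng.choice([-1.0, 1.0], size=n)
    geno_delta = np.where(has_geno, sign * spec.delta_psi, 0.0)
    has_inter = (rng.random(n) < spec.frac_interaction) & has_geno

    is_mut = (design["genotype"] == "mutant").to_numpy()
    temps = design["temperature"].to_numpy()
    mean = baseline[:, None] + np.where(is_mut[None, :], geno_delta[:, None], 0.0)
    inter = np.array([spec.interaction_profile.get(int(t), 0.0) for t in temps])
    mean = mean + np.where(
        is_mut[None, :] & has_inter[:, None], (sign[:, None] * inter[None, :]), 0.0
    )
    noise = rng.normal(0.0, spec.sigma, size=mean.shape)
    raw = mean + noise
    clipped = np.clip(raw, 0.0, 1.0)
    clip_rate = float((raw != clipped).mean())
    if clip_rate > 0:
        log.info("clipped %.3f%% of simulated PSIs into [0, 1]", 100 * clip_rate)

    event_ids = [f"EV{i:05d}" for i in range(n)]
    psi = pd.DataFrame(clipped, index=event_ids, columns=design.index)
    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "baseline": baseline,
            "has_genotype_effect": has_geno,
            "genotype_delta": geno_delta,
            "has_interaction": has_inter,
        }
    )
    return PsiSimulation(psi, design, truth, clip_rate)


@dataclass
class BsaSimSpec:
    """Recessive-locus F2 pool simulation.

    Mutant pool: homozygous for the EMS allele at the causal locus, so the
    expected allele fraction at a marker at recombination fraction c is 1-c.
    Normal pool: 1/3 of chromosomes carry the causal allele, giving expected
    marker fraction 1/3 + c/3.  c = min(0.5, recomb_per_mb * distance_Mb).
    """

    chrom: str = "chr2"
    chrom_length: int = 20_000_000
    n_snps: int = 2000
    causal_pos: int | None = None  # drawn from the central 80% when None
    pool_size: int = 50  # individuals per pool
    mean_depth: float = 50.0
    recomb_per_mb: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.causal_pos is not None and not 0 <= self.causal_pos < self.chrom_length:
            raise ValueError("causal position outside chromosome")


@dataclass
class BsaSimulation:
    variants: list[PoolVariant]
    causal_pos: int
    spec: BsaSimSpec

    def write_vcf(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.spec.chrom},length={self.spec.chrom_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                "normal_pool\tmutant_pool\n"
            )
            for v in self.variants:
                fh.write(
                    f"{v.chrom}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD\t"
                    f"./.:{v.ref_depths[0]},{v.alt_depths[0]}\t"
                    f"./.:{v.ref_depths[1]},{v.alt_depths[1]}\n"
                )
        return path

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {"chrom": self.spec.chrom, "causal_pos": self.causal_pos}, fh, indent=2
            )
        return path


def expected_pool_fractions(distance_bp: float, recomb_per_mb: float) -> tuple[float, float]:
    """Expected (normal, mutant) pool EMS-allele fractions at a marker."""
    c = min(0.5, recomb_per_mb * distance_bp / 1e6)
    return (1.0 / 3.0 + c / 3.0, 1.0 - c)


def simulate_bsa(spec: BsaSimSpec) -> BsaSimulation:
    """Draw per-SNP pool allele counts binomially from the linkage model at
    Poisson depths; all records are EMS-consistent (G>A or C>T)."""
    rng = np.random.default_rng(spec.seed)
    if spec.causal_pos is None:
        lo, hi = int(0.1 * spec.chrom_length), int(0.9 * spec.chrom_length)
        causal = int(rng.integers(lo, hi))
    else:
        causal = spec.causal_pos
    positions = np.sort(rng.choice(spec.chrom_length, size=spec.n_snps, replace=False))
    # the causal site itself is always a marker
    positions[np.argmin(np.abs(positions - causal))] = causal
    positions = np.sort(positions)

    n_chrom = 2 * spec.pool_size
    variants = []
    for pos in positions:
        f_normal, f_mutant = expected_pool_fractions(abs(int(pos) - causal), spec.recomb_per_mb)
        ref, alt = ("G", "A") if rng.random() < 0.5 else ("C", "T")
        depths_ref, depths_alt = [], []
        for f in (f_normal, f_mutant):
            pool_alt = rng.binomial(n_chrom, f)  # alleles among pooled chromosomes
            depth = rng.poisson(spec.mean_depth)
            alt_reads = rng.binomial(depth, pool_alt / n_chrom) if depth > 0 else 0
            depths_ref.append(int(depth - alt_reads))
            depths_alt.append(int(alt_reads))
        variants.append(
            PoolVariant(
                spec.chrom, int(pos), ref, alt,
                (depths_ref[0], depths_ref[1]), (depths_alt[0], depths_alt[1]),
            )
        )
    return BsaSimulation(variants, causal, spec)
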