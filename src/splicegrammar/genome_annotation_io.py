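"""Genome FASTA and transcript-annotation I/O, intron and splice-site extraction.

Coordinates are 0-based half-open internally.  GFF3/GTF input (1-based
inclusive) is converted at the parsing boundary only.  Splice-site windows
are reported in transcription sense, in the RNA alphabet (U, not T), with
the signed position convention used throughout the package:

* 5'SS (donor):    positions -3..-1 exonic, +1..+5 intronic (no 0); 8 nt.
* 3'SS (acceptor): positions -5..-1 intronic, +1..+2 exonic; 7 nt.

The exon//intron boundary of a donor is written ``XX//YYYYY`` (e.g. the
near-constitutive ``UC//GUGAG``); the intron\\exon boundary of an acceptor
``YYYYY\\XX``.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "FIVE_PRIME_POSITIONS",
    "THREE_PRIME_POSITIONS",
    "FastaError",
    "AnnotationError",
    "WindowError",
    "ShortIntronError",
    "GenomeSequence",
    "Genome",
    "TranscriptModel",
    "Intron",
    "SpliceSiteWindow",
    "read_fasta",
    "read_annotation",
    "extract_introns",
    "extract_window",
    "extract_all_windows",
    "donor_window",
    "acceptor_window",
    "reverse_complement",
    "write_windows_tsv",
    "read_windows_tsv",
    "write_windows_bed",
]

FIVE_PRIME_POSITIONS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3, 4, 5)
THREE_PRIME_POSITIONS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_AMBIGUITY_CODES = set("RYSWKMBDHV")


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class AnnotationError(ValueError):
    """Malformed GFF3/GTF input or inconsistent transcript model."""


class WindowError(ValueError):
    """Splice-site window extends beyond the chromosome."""


class ShortIntronError(WindowError):
    """Intron too short to supply the intronic part of the window."""


def reverse_complement(seq: str) -> str:
    table = _RNA_COMPLEMENT if "U" in seq else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: identifier plus uppercase DNA over {A,C,G,T,N}+IUPAC."""

    name: str
    seq: str


class Genome:
    """Mapping of chromosome name to sequence with strand-aware slicing."""

    def __init__(self, sequences: Iterable[GenomeSequence]):
        self._seqs: dict[str, GenomeSequence] = {}
        for rec in sequences:
            if rec.name in self._seqs:
                raise FastaError(f"duplicate FASTA header: {rec.name!r}")
            self._seqs[rec.name] = rec

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self._seqs.values())

    def __len__(self) -> int:
        return len(self._seqs)

    def __getitem__(self, chrom: str) -> GenomeSequence:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom].seq)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """DNA slice of ``[start, end)``; minus strand is reverse-complemented."""
        if chrom not in self._seqs:
            raise WindowError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom].seq
        if start < 0 or end > len(seq) or start > end:
            raise WindowError(
                f"interval [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        if strand == "-":
            sub = reverse_complement(sub)
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return sub


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file; sequences uppercased, U converted to T internally."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()!r}"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    records = []
    n_ambig = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        ambig = sum(c in _AMBIGUITY_CODES for c in seq)
        if ambig:
            n_ambig += ambig
            log.warning("%s: %d ambiguity-code bases in %s retained verbatim", path, ambig, rec.id)
        records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records")
    return Genome(records)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = end


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gtf":
        return "gtf"
    if suffix in (".gff", ".gff3"):
        return "gff3"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 9:
                return "gtf" if 'transcript_id "' in fields[8] else "gff3"
    raise AnnotationError(f"{path}: no feature lines found")


def read_annotation(path: str | Path, dialect: str = "auto") -> list[TranscriptModel]:
    """Parse GFF3 or GTF into transcript models (0-based half-open exons).

    GTF exons must carry ``transcript_id`` (and ideally ``gene_id``); GFF3
    exons must carry ``Parent``, with gene identity taken from the parent
    mRNA/transcript feature when present.
    """
    import gffutils

    path = Path(path)
    if dialect not in ("gff3", "gtf", "auto"):
        raise ValueError(f"dialect must be gff3, gtf or auto, got {dialect!r}")
    if dialect == "auto":
        dialect = _detect_dialect(path)

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        if dialect == "gtf":
            tids = feat.attributes.get("transcript_id")
        else:
            tids = feat.attributes.get("Parent")
        if not tids:
            raise AnnotationError(f"exon without transcript attribution: {feat}")
        for tid in tids:
            entry = exons.setdefault(
                tid, {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "gene": None}
            )
            if entry["chrom"] != feat.seqid:
                raise AnnotationError(f"{tid}: exons on multiple chromosomes")
            if entry["strand"] != feat.strand:
                raise AnnotationError(f"{tid}: mixed-strand transcript: {feat}")
            entry["exons"].append((feat.start - 1, feat.end))
            if dialect == "gtf":
                gids = feat.attributes.get("gene_id")
                if gids:
                    entry["gene"] = gids[0]

    if dialect == "gff3":
        for tid, entry in exons.items():
            try:
                parent = db[tid]
                gids = parent.attributes.get("Parent") or parent.attributes.get("gene_id")
                entry["gene"] = gids[0] if gids else tid
            except gffutils.FeatureNotFoundError:
                entry["gene"] = tid

    models = []
    for tid, entry in exons.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene"] or tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=tuple(entry["exons"]),
            )
        )
    models.sort(key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id))
    return models


@dataclass(frozen=True)
class Intron:
    """One intron; donor/acceptor coordinates are strand-correct.

    ``donor_pos`` is the genomic coordinate of intron base +1 (first intronic
    base in transcription sense); ``acceptor_pos`` that of intron base -1.
    """

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start < 4:
            raise AnnotationError(
                f"intron [{self.start},{self.end}) shorter than 4 nt (no room for GU..AG)"
            )

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor_pos(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def __len__(self) -> int:
        return self.end - self.start


def extract_introns(
    transcripts: Iterable[TranscriptModel], dedup: bool = True
) -> list[Intron]:
    """Introns between consecutive exons; unique by locus when ``dedup``.

    Gaps shorter than 4 nt (annotation artefacts) are skipped with a logged
    count rather than propagated.
    """
    introns: list[Intron] = []
    n_short = 0
    for tx in transcripts:
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            if s2 - e1 < 4:
                n_short += 1
                continue
            introns.append(Intron(tx.chrom, tx.strand, e1, s2))
    if n_short:
        log.warning("skipped %d inter-exon gaps shorter than 4 nt", n_short)
    if dedup:
        seen = set()
        unique = []
        for intron in introns:
            key = (intron.chrom, intron.strand, intron.start, intron.end)
            if key not in seen:
                seen.add(key)
                unique.append(intron)
        return unique
    return introns


@dataclass(frozen=True)
class SpliceSiteWindow:
    """Fixed-width boundary sequence at a donor or acceptor site.

    ``seq`` is in transcription sense over the RNA alphabet {A,C,G,U,N};
    ``origin`` records (chrom, strand, junction genomic coordinate), where the
    junction is the donor_pos for 5'SS windows and acceptor_pos for 3'SS.
    """

    site_kind: str
    seq: str
    origin: tuple[str, str, int] | None = None

    def __post_init__(self):
        if self.site_kind not in ("five_prime", "three_prime"):
            raise ValueError(f"bad site_kind {self.site_kind!r}")
        expected = len(self.positions)
        if len(self.seq) != expected:
            raise ValueError(
                f"{self.site_kind} window must be {expected} nt, got {len(self.seq)}"
            )
        if set(self.seq) - set("ACGUN"):
            raise ValueError(f"window seq has non-RNA characters: {self.seq!r}")

    @property
    def positions(self) -> tuple[int, ...]:
        return FIVE_PRIME_POSITIONS if self.site_kind == "five_prime" else THREE_PRIME_POSITIONS

    def base(self, position: int) -> str:
        try:
            idx = self.positions.index(position)
        except ValueError:
            raise KeyError(f"position {position} not in {self.site_kind} window") from None
        return self.seq[idx]

    def subseq(self, positions: Sequence[int]) -> str:
        return "".join(self.base(p) for p in positions)

    @property
    def notation(self) -> str:
        """Boundary notation, e.g. ``UC//GUGAG`` or ``UUGCAG\\\\CA``."""
        if self.site_kind == "five_prime":
            return f"{self.seq[:3]}//{self.seq[3:]}"
        return f"{self.seq[:5]}\\\\{self.seq[5:]}"


def donor_window(notation: str, origin=None) -> SpliceSiteWindow:
    """Build a 5'SS window from ``-3..+5`` sequence or ``XX//YYYYY`` notation.

    Two-base exonic prefixes (boundary notation like ``UC//GUGAG``) are padded with N
    at -3, which is never a scored or classed position.
    """
    seq = notation.upper().replace("T", "U")
    if "//" in seq:
        exonic, intronic = seq.split("//")
        if len(exonic) == 2:
            exonic = "N" + exonic
        seq = exonic + intronic
    return SpliceSiteWindow("five_prime", seq, origin)


def acceptor_window(notation: str, origin=None) -> SpliceSiteWindow:
    """Build a 3'SS window from ``-5..+2`` sequence or ``YYYYY\\\\XX`` notation."""
    seq = notation.upper().replace("T", "U")
    if "\\" in seq:
        intronic, exonic = seq.split("\\", 1)
        exonic = exonic.lstrip("\\")
        intronic = intronic[-5:].rjust(5, "N")
        seq = intronic + exonic
    return SpliceSiteWindow("three_prime", seq, origin)


def extract_window(intron: Intron, genome: Genome, site_kind: str) -> SpliceSiteWindow:
    """Extract the 5'SS or 3'SS window of an intron in transcription sense."""
    if site_kind not in ("five_prime", "three_prime"):
        raise ValueError(f"bad site_kind {site_kind!r}")
    if len(intron) < 5:
        raise ShortIntronError(
            f"intron [{intron.start},{intron.end}) shorter than the 5 nt intronic span"
        )
    s, e = intron.start, intron.end
    if site_kind == "five_prime":
        if intron.strand == "+":
            gstart, gend = s - 3, s + 5
        else:
            gstart, gend = e - 5, e + 3
        junction = intron.donor_pos
    else:
        if intron.strand == "+":
            gstart, gend = e - 5, e + 2
        else:
            gstart, gend = s - 2, s + 5
        junction = intron.acceptor_pos
    dna = genome.fetch(intron.chrom, gstart, gend, intron.strand)
    return SpliceSiteWindow(
        site_kind, dna_to_rna(dna), origin=(intron.chrom, intron.strand, junction)
    )


def extract_all_windows(
    introns: Iterable[Intron], genome: Genome, site_kind: str
) -> list[SpliceSiteWindow]:
    """Windows for all introns; boundary-violating windows are dropped (not
    padded) with a logged count; non-GU donors are counted, never dropped."""
    windows = []
    n_boundary = 0
    n_non_gu = 0
    for intron in introns:
        try:
            w = extract_window(intron, genome, site_kind)
        except ShortIntronError:
            n_boundary += 1
            continue
        except WindowError:
            n_boundary += 1
            continue
        if site_kind == "five_prime" and w.subseq((1, 2)) != "GU":
            n_non_gu += 1
        windows.append(w)
    if n_boundary:
        log.warning("dropped %d windows at chromosome boundaries / short introns", n_boundary)
    if n_non_gu:
        log.info("%d non-GU donors retained in the window set", n_non_gu)
    return windows


_TSV_FIELDS = ("chrom", "strand", "junction_pos", "site_kind", "seq")


def write_windows_tsv(windows: Iterable[SpliceSiteWindow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_FIELDS)
        for w in windows:
            chrom, strand, junction = w.origin if w.origin else ("", ".", -1)
            writer.writerow([chrom, strand, junction, w.site_kind, w.seq])


def read_windows_tsv(path: str | Path) -> list[SpliceSiteWindow]:
    windows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            origin = None
            if row["chrom"]:
                origin = (row["chrom"], row["strand"], int(row["junction_pos"]))
            windows.append(SpliceSiteWindow(row["site_kind"], row["seq"], origin))
    return windows


def write_windows_bed(windows: Iterable[SpliceSiteWindow], path: str | Path) -> None:
    """BED6 export of the genomic span of each window."""
    with open(path, "w") as fh:
        for w in windows:
            if w.origin is None:
                continue
            chrom, strand, junction = w.origin
            if w.site_kind == "five_prime":
                if strand == "+":
                    start, end = junction - 3, junction + 5
                else:
                    start, end = junction - 4, junction + 4
            else:
                if strand == "+":
                    start, end = junction - 4, junction + 3
                else:
                    start, end = junction - 2, junction + 5
            fh.write(f"{chrom}\t{start}\t{end}\t{w.seq}\t0\t{strand}\n")
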