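"""Local alternative-splicing events from transcript exon chains, and PSIs.

Events are detected pairwise from the exon chains of the transcripts of one
gene, in the local-event style of transcript-based PSI tools:

* A5 — two introns share an acceptor and differ in donor (alternative 5'SS);
* A3 — two introns share a donor and differ in acceptor (alternative 3'SS);
* RI — one transcript's exon spans another transcript's intact intron;
* SE — an internal exon with both flanking junctions in some transcripts is
  skipped by a direct junction in others.

Inclusion-form convention (deterministic and strand-symmetric): for A5/A3 the
inclusion form uses the shorter intron; for RI the intron-retained form; for
SE the exon-included form.  PSI = inclusion abundance / total event-form
abundance, missing when the total is below the expression floor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_annotation_io import (
    Genome,
    Intron,
    SpliceSiteWindow,
    TranscriptModel,
    extract_window,
)

log = logging.getLogger(__name__)

__all__ = [
    "ASEvent",
    "AltPair",
    "find_events",
    "compute_psi",
    "psi_matrix",
    "orient_pair",
    "flanking_donors",
    "write_events_tsv",
]

ANALYSED_EVENT_TYPES = ("A5", "A3", "RI", "SE")


@dataclass(frozen=True)
class ASEvent:
    """One local alternative-splicing event.

    ``coords`` per type: A5/A3 -> ((s1,e1),(s2,e2)) the two variant introns,
    sorted; RI -> (s,e) the retained intron; SE -> (p,a,b,q) with (p,a) the
    upstream-in-genome intron, [a,b) the skipped exon, (b,q) the downstream
    intron.
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    def __post_init__(self):
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion or exclusion form")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: a transcript supports both forms")


def _event_id(gene_id, etype, chrom, strand, coords) -> str:
    flat = ":".join(
        "-".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in coords
    )
    return f"{gene_id};{etype}:{chrom}:{flat}:{strand}"


def _junctions(tx: TranscriptModel) -> list[tuple[int, int]]:
    return [(e1, s2) for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:])]


def find_events(transcripts: Sequence[TranscriptModel]) -> list[ASEvent]:
    """Detect A5/A3/RI/SE events among the transcripts of each gene.

    Multi-way alternative sites are decomposed into all pairs.  Genes with a
    single transcript yield no events.
    """
    events: list[ASEvent] = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for gene_id in sorted(by_gene):
        events.extend(_gene_events(gene_id, by_gene[gene_id]))
    return events


def _gene_events(gene_id: str, txs: list[TranscriptModel]) -> list[ASEvent]:
    if len(txs) < 2:
        return []
    chrom, strand = txs[0].chrom, txs[0].strand
    junctions: dict[tuple[int, int], set[str]] = {}
    for tx in txs:
        for j in _junctions(tx):
            junctions.setdefault(j, set()).add(tx.transcript_id)

    events: dict[tuple, ASEvent] = {}

    def add(etype, coords, inclusion, exclusion):
        inclusion, exclusion = frozenset(inclusion), frozenset(exclusion)
        if not inclusion or not exclusion or (inclusion & exclusion):
            return
        key = (etype, coords)
        if key not in events:
            events[key] = ASEvent(
                _event_id(gene_id, etype, chrom, strand, coords),
                etype, gene_id, chrom, strand, coords, inclusion, exclusion,
            )

    def _is_skip_chain(short: tuple[int, int], long_: tuple[int, int], shared_start: bool) -> bool:
        """True when the long junction is the exon-skipping counterpart of the
        short one (an exon plus a second junction bridges the difference), in
        which case the pair is an SE event, not a genuine A5/A3 site shift."""
        for tx in txs:
            if short not in _junctions(tx):
                continue
            for a, b in tx.exons:
                if shared_start and a == short[1] and (b, long_[1]) in junctions:
                    return True
                if not shared_start and b == short[0] and (long_[0], a) in junctions:
                    return True
        return False

    juncs = sorted(junctions)
    # A5/A3: introns sharing one boundary
    for i, j1 in enumerate(juncs):
        for j2 in juncs[i + 1:]:
            shared_end = j1[1] == j2[1] and j1[0] != j2[0]
            shared_start = j1[0] == j2[0] and j1[1] != j2[1]
            if not (shared_end or shared_start):
                continue
            # shared acceptor boundary => alternative donor (A5)
            if strand == "+":
                etype = "A5" if shared_end else "A3"
            else:
                etype = "A3" if shared_end else "A5"
            short, long_ = sorted((j1, j2), key=lambda j: j[1] - j[0])
            if _is_skip_chain(short, long_, shared_start):
                continue
            add(etype, (short, long_), junctions[short], junctions[long_])

    # RI: an exon strictly spanning another transcript's intron
    for j in juncs:
        s, e = j
        retaining = {
            tx.transcript_id
            for tx in txs
            if any(a < s and b > e for a, b in tx.exons)
        }
        add("RI", (s, e), retaining, junctions[j])

    # SE: internal exon with both flanking junctions vs the direct skip junction
    for tx in txs:
        for k in range(1, len(tx.exons) - 1):
            p = tx.exons[k - 1][1]
            a, b = tx.exons[k]
            q = tx.exons[k + 1][0]
            skip = (p, q)
            if skip not in junctions:
                continue
            inclusion = junctions.get((p, a), set()) & junctions.get((b, q), set())
            inclusion = {
                tid for tid in inclusion
                for t in txs if t.transcript_id == tid and (a, b) in t.exons
            }
            add("SE", (p, a, b, q), inclusion, junctions[skip])

    return [events[k] for k in sorted(events)]


def compute_psi(
    event: ASEvent,
    tpm_by_transcript: Mapping[str, float],
    expression_floor: float = 1.0,
) -> float:
    """PSI = inclusion TPM / (inclusion + exclusion TPM); NaN below the floor.

    Transcripts absent from the abundance table count as unexpressed.
    """
    def total(tids):
        s = 0.0
        for tid in tids:
            v = float(tpm_by_transcript.get(tid, 0.0))
            if v < 0:
                raise ValueError(f"negative abundance for {tid}: {v}")
            s += v
        return s

    inc = total(event.inclusion_transcripts)
    exc = total(event.exclusion_transcripts)
    denom = inc + exc
    if denom < expression_floor:
        return float("nan")
    return inc / denom


def psi_matrix(
    events: Sequence[ASEvent],
    tpm: pd.DataFrame,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Event x sample PSI matrix from a transcript x sample TPM table."""
    data = {
        sample: [
            compute_psi(ev, tpm[sample], expression_floor) for ev in events
        ]
        for sample in tpm.columns
    }
    return pd.DataFrame(data, index=[ev.event_id for ev in events])


@dataclass(frozen=True)
class AltPair:
    """Two alternative donors (alt5) or acceptors (alt3), oriented by the
    strand of the parent gene; distance is in nt, transcription sense."""

    pair_id: str
    kind: str  # alt5 | alt3
    upstream_site: int  # genomic coordinate of the upstream junction
    downstream_site: int
    distance: int
    upstream_window: SpliceSiteWindow | None = None
    downstream_window: SpliceSiteWindow | None = None
    upstream_is_inclusion: bool | None = None


def _variant_introns(event: ASEvent) -> tuple[Intron, Intron]:
    (s1, e1), (s2, e2) = event.coords
    return (
        Intron(event.chrom, event.strand, s1, e1),
        Intron(event.chrom, event.strand, s2, e2),
    )


def orient_pair(event: ASEvent, genome: Genome | None = None) -> AltPair:
    """Order the two variant sites of an A5/A3 event as upstream/downstream
    relative to the strand of the parent gene and compute their distance."""
    if event.event_type not in ("A5", "A3"):
        raise ValueError(f"orient_pair expects an A5/A3 event, got {event.event_type}")
    inc_intron, exc_intron = _variant_introns(event)
    if event.event_type == "A5":
        sites = {inc_intron.donor_pos: inc_intron, exc_intron.donor_pos: exc_intron}
        site_kind = "five_prime"
        kind = "alt5"
    else:
        sites = {inc_intron.acceptor_pos: inc_intron, exc_intron.acceptor_pos: exc_intron}
        site_kind = "three_prime"
        kind = "alt3"
    lo, hi = sorted(sites)
    up, down = (lo, hi) if event.strand == "+" else (hi, lo)
    up_w = down_w = None
    if genome is not None:
        up_w = extract_window(sites[up], genome, site_kind)
        down_w = extract_window(sites[down], genome, site_kind)
    inc_site = inc_intron.donor_pos if event.event_type == "A5" else inc_intron.acceptor_pos
    return AltPair(
        pair_id=event.event_id,
        kind=kind,
        upstream_site=up,
        downstream_site=down,
        distance=hi - lo,
        upstream_window=up_w,
        downstream_window=down_w,
        upstream_is_inclusion=(up == inc_site),
    )


def flanking_donors(
    event: ASEvent, genome: Genome
) -> tuple[SpliceSiteWindow, SpliceSiteWindow]:
    """For an SE event, the 5'SS windows of the intron upstream of the skipped
    exon and of the intron whose donor sits at the exon's 3' end, in
    transcription sense."""
    if event.event_type != "SE":
        raise ValueError(f"flanking_donors expects an SE event, got {event.event_type}")
    p, a, b, q = event.coords
    left = Intron(event.chrom, event.strand, p, a)
    right = Intron(event.chrom, event.strand, b, q)
    upstream, downstream = (left, right) if event.strand == "+" else (right, left)
    return (
        extract_window(upstream, genome, "five_prime"),
        extract_window(downstream, genome, "five_prime"),
    )


def write_events_tsv(events: Iterable[ASEvent], path) -> None:
    """ioe-style event table: id, type, coordinates, form transcript lists."""
    with open(path, "w") as fh:
        fh.write(
            "event_id\tevent_type\tgene_id\tchrom\tstrand\tcoords\t"
            "inclusion_transcripts\texclusion_transcripts\n"
        )
        for ev in events:
            fh.write(
                f"{ev.event_id}\t{ev.event_type}\t{ev.gene_id}\t{ev.chrom}\t"
                f"{ev.strand}\t{ev.coords}\t"
                f"{','.join(sorted(ev.inclusion_transcripts))}\t"
                f"{','.join(sorted(ev.exclusion_transcripts))}\n"
            )
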