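"""Event detection, PSI arithmetic and alternative-pair orientation."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicegrammar.as_events import (
    compute_psi,
    find_events,
    flanking_donors,
    orient_pair,
    psi_matrix,
    write_events_tsv,
)
from splicegrammar.genome_annotation_io import Genome, GenomeSequence, TranscriptModel


def tx(tid, gene, strand, exons, chrom="c"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons))


def test_a5_event_detection():
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 120), (200, 300)]),
    ])
    (ev,) = events
    assert ev.event_type == "A5"
    assert set(ev.coords) == {(100, 200), (120, 200)}
    # donors at 100 and 120, shared acceptor boundary at 200
    pair = orient_pair(ev)
    assert {pair.upstream_site, pair.downstream_site} == {100, 120}


def test_ri_event_detection():
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 300)]),
    ])
    (ev,) = events
    assert ev.event_type == "RI"
    assert ev.coords == (100, 200)
    assert ev.inclusion_transcripts == frozenset({"T2"})  # retained form
    assert ev.exclusion_transcripts == frozenset({"T1"})


def test_se_event_detection_and_no_spurious_alt_sites():
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (150, 180), (200, 300)]),
        tx("T2", "G", "+", [(0, 100), (200, 300)]),
    ])
    (ev,) = events  # exactly one event: the skipped exon
    assert ev.event_type == "SE"
    assert ev.coords == (100, 150, 180, 200)
    assert ev.inclusion_transcripts == frozenset({"T1"})


def test_single_transcript_gene_yields_nothing():
    assert find_events([tx("T1", "G", "+", [(0, 100), (200, 300)])]) == []


def test_multiway_donors_decompose_into_pairs():
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 120), (200, 300)]),
        tx("T3", "G", "+", [(0, 140), (200, 300)]),
    ])
    assert sorted(e.event_type for e in events) == ["A5", "A5", "A5"]


def test_event_detection_invariant_to_order_and_translation():
    base = [
        tx("T1", "G", "+", [(0, 100), (150, 180), (200, 300)]),
        tx("T2", "G", "+", [(0, 100), (200, 300)]),
        tx("T3", "G", "+", [(0, 100), (160, 180), (200, 300)]),
    ]
    ids = sorted(e.event_id for e in find_events(base))
    shuffled = sorted(e.event_id for e in find_events(base[::-1]))
    assert ids == shuffled
    shifted = [
        tx(t.transcript_id, t.gene_id, t.strand, [(s + 10_000, e + 10_000) for s, e in t.exons])
        for t in base
    ]
    types = sorted(e.event_type for e in find_events(base))
    assert types == sorted(e.event_type for e in find_events(shifted))


def _a5_event():
    return find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 120), (200, 300)]),
    ])[0]


@pytest.mark.parametrize(
    "inc, exc, floor, expected",
    [(30.0, 10.0, 1.0, 0.75), (0.0, 5.0, 1.0, 0.0), (0.0, 0.0, 1.0, float("nan"))],
)
def test_compute_psi_arithmetic(inc, exc, floor, expected):
    ev = _a5_event()
    tpm = {next(iter(ev.inclusion_transcripts)): inc, next(iter(ev.exclusion_transcripts)): exc}
    psi = compute_psi(ev, tpm, expression_floor=floor)
    if math.isnan(expected):
        assert math.isnan(psi)
    else:
        assert psi == pytest.approx(expected)


def test_compute_psi_rejects_negative_abundance():
    ev = _a5_event()
    with pytest.raises(ValueError):
        compute_psi(ev, {t: -1.0 for t in ev.inclusion_transcripts | ev.exclusion_transcripts})


@settings(derandomize=True, max_examples=100)
@given(st.floats(0, 100), st.floats(0, 100))
def test_psi_complement_under_form_swap(a, b):
    ev = _a5_event()
    tpm = dict.fromkeys(ev.inclusion_transcripts, a) | dict.fromkeys(ev.exclusion_transcripts, b)
    psi = compute_psi(ev, tpm, expression_floor=1.0)
    swapped = type(ev)(
        ev.event_id, ev.event_type, ev.gene_id, ev.chrom, ev.strand, ev.coords,
        ev.exclusion_transcripts, ev.inclusion_transcripts,
    )
    psi_swapped = compute_psi(swapped, tpm, expression_floor=1.0)
    if math.isnan(psi):
        assert math.isnan(psi_swapped)
    else:
        assert psi + psi_swapped == pytest.approx(1.0)


def test_psi_matrix_shape_and_floor():
    ev = _a5_event()
    tpm = pd.DataFrame(
        {"s1": [30.0, 10.0], "s2": [0.2, 0.3]},
        index=["T2", "T1"],  # T2 = inclusion (shorter intron)
    )
    mat = psi_matrix([ev], tpm, expression_floor=1.0)
    assert mat.shape == (1, 2)
    assert mat.loc[ev.event_id, "s1"] == pytest.approx(0.75)
    assert math.isnan(mat.loc[ev.event_id, "s2"])


@pytest.mark.parametrize("strand, upstream", [("+", 100), ("-", 126)])
def test_orient_pair_strandedness(strand, upstream):
    if strand == "+":
        txs = [
            tx("T1", "G", "+", [(0, 100), (200, 300)]),
            tx("T2", "G", "+", [(0, 126), (200, 300)]),
        ]
    else:
        # donors on minus strand sit at intron end - 1: use introns sharing start
        txs = [
            tx("T1", "G", "-", [(0, 50), (101, 300)]),
            tx("T2", "G", "-", [(0, 50), (127, 300)]),
        ]
    (ev,) = find_events(txs)
    assert ev.event_type == "A5"
    pair = orient_pair(ev)
    assert pair.upstream_site == upstream
    assert pair.distance == 26


def test_nagnag_distance():
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 100), (203, 300)]),
    ])
    (ev,) = events
    assert ev.event_type == "A3"
    assert orient_pair(ev).distance == 3


def test_orient_pair_rejects_non_pair_events():
    (ri,) = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 300)]),
    ])
    with pytest.raises(ValueError):
        orient_pair(ri)


def _se_fixture_genome():
    # coordinates: exon [0,100) | intron [100,150) | exon [150,180) | intron [180,200) | exon [200,260)
    seq = (
        "A" * 97 + "TAA"                      # exon 1 ends ...UAA
        + "GTAAG" + "T" * 38 + "TTTGCAG"      # intron 1 (50 nt)
        + "C" * 27 + "GAA"                    # skipped exon ends ...GAA
        + "GTAAG" + "T" * 8 + "TTTGCAG"       # intron 2 (20 nt)
        + "G" * 60
    )
    return Genome([GenomeSequence("c", seq)])


def test_flanking_donors_of_skipped_exon():
    genome = _se_fixture_genome()
    (ev,) = find_events([
        tx("T1", "G", "+", [(0, 100), (150, 180), (200, 260)]),
        tx("T2", "G", "+", [(0, 100), (200, 260)]),
    ])
    up, down = flanking_donors(ev, genome)
    assert up.origin == ("c", "+", 100)
    assert down.origin == ("c", "+", 180)
    assert up.notation == "UAA//GUAAG"
    assert down.notation == "GAA//GUAAG"
    with pytest.raises(ValueError):
        flanking_donors(find_events([
            tx("T1", "G", "+", [(0, 100), (200, 260)]),
            tx("T2", "G", "+", [(0, 120), (200, 260)]),
        ])[0], genome)


def test_events_tsv_export(tmp_path):
    events = find_events([
        tx("T1", "G", "+", [(0, 100), (200, 300)]),
        tx("T2", "G", "+", [(0, 120), (200, 300)]),
    ])
    path = tmp_path / "events.tsv"
    write_events_tsv(events, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df["event_type"]) == ["A5"]
    assert df.loc[0, "inclusion_transcripts"] == "T2"
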