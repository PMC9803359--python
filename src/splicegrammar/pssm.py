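"""Log-transformed position-specific scoring matrices for splice sites.

A PSSM stores per-position log2 base frequencies over {A,C,G,U}.  The
log-likelihood of a site is the sum of log2 frequencies of its observed
bases over the scored positions.  Two scored regions matter here:

* U5 snRNA loop 1 contact: exonic positions -2..-1 of the 5'SS.
* U6 snRNA ACAGA box contact: intronic positions +3..+5 of the 5'SS.

For pairs of alternative donors, the log-odds ratio uses the downstream
site's log-likelihood as the denominator, so a positive ratio means the
upstream site has the greater PSSM score.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_annotation_io import SpliceSiteWindow

__all__ = [
    "BASES",
    "U5_POSITIONS",
    "U6_POSITIONS",
    "Pssm",
    "ScorePair",
    "PairLogOdds",
    "build_pssm",
    "score",
    "score_sites",
    "pair_log_odds",
    "score_pairs",
    "dedup_by_junction",
    "u5_pssm",
    "u6_pssm",
]

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

U5_POSITIONS: tuple[int, ...] = (-2, -1)
U6_POSITIONS: tuple[int, ...] = (3, 4, 5)


def _window_bases(window, positions: Sequence[int]) -> str:
    """Bases of a window at signed positions; plain strings must already be
    aligned to ``positions``."""
    if isinstance(window, SpliceSiteWindow):
        return window.subseq(positions)
    seq = str(window).upper().replace("T", "U")
    if len(seq) != len(positions):
        raise ValueError(
            f"string window of length {len(seq)} does not cover {len(positions)} positions"
        )
    return seq


@dataclass(frozen=True)
class Pssm:
    """Per-position log2 base frequencies over a signed position range."""

    positions: tuple[int, ...]
    log_freqs: np.ndarray  # shape (n_positions, 4), base order ACGU
    pseudocount: float
    n_sites: int

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(self.positions))
        lf = np.asarray(self.log_freqs, dtype=float)
        object.__setattr__(self, "log_freqs", lf)
        if lf.shape != (len(self.positions), 4):
            raise ValueError("log_freqs must be (n_positions, 4)")
        sums = np.exp2(lf).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-position frequencies must sum to 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def log_freq(self, position: int, base: str) -> float:
        return float(self.log_freqs[self.positions.index(position), _BASE_INDEX[base]])

    def freq(self, position: int, base: str) -> float:
        return float(2.0 ** self.log_freq(position, base))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pseudocount={self.pseudocount}\tn_sites={self.n_sites}\n")
            fh.write("position\t" + "\t".join(BASES) + "\n")
            for pos, row in zip(self.positions, self.log_freqs):
                fh.write(f"{pos}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pssm":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=") for kv in header.lstrip("# ").rstrip("\n").split("\t")
            )
            fh.readline()  # column names
            positions, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                positions.append(int(fields[0]))
                rows.append([float(v) for v in fields[1:5]])
        return cls(tuple(positions), np.array(rows), float(meta["pseudocount"]), int(meta["n_sites"]))


def dedup_by_junction(windows: Iterable[SpliceSiteWindow]) -> list[SpliceSiteWindow]:
    """One window per unique genomic junction (origin); order preserved.

    Windows without an origin are kept as-is.
    """
    seen = set()
    out = []
    for w in windows:
        if w.origin is None:
            out.append(w)
            continue
        if w.origin not in seen:
            seen.add(w.origin)
            out.append(w)
    return out


def build_pssm(
    windows: Iterable, positions: Sequence[int], pseudocount: float = 1.0
) -> Pssm:
    """Count bases per position and store log2 of pseudocounted frequencies.

    frequency(base, pos) = (count + pseudocount) / (n + 4 * pseudocount).
    Windows with N at any requested position are excluded from the counts so
    that ambiguous bases never bias frequencies.
    """
    positions = tuple(positions)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = np.zeros((len(positions), 4), dtype=float)
    n = 0
    n_skipped = 0
    for w in windows:
        bases = _window_bases(w, positions)
        if "N" in bases:
            n_skipped += 1
            continue
        for i, b in enumerate(bases):
            counts[i, _BASE_INDEX[b]] += 1
        n += 1
    if n == 0:
        raise ValueError("no usable windows to build a PSSM from")
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_freqs = np.log2(freqs)
    return Pssm(positions, log_freqs, pseudocount, n)


def score(pssm: Pssm, window) -> float:
    """Sum of log2 frequencies of observed bases; NaN if any scored base is N."""
    bases = _window_bases(window, pssm.positions)
    total = 0.0
    for i, b in enumerate(bases):
        if b == "N":
            return math.nan
        if b not in _BASE_INDEX:
            raise ValueError(f"non-RNA base {b!r} in window")
        total += pssm.log_freqs[i, _BASE_INDEX[b]]
    return float(total)


@dataclass(frozen=True)
class ScorePair:
    """U5 (-2..-1) and U6 (+3..+5) log2 likelihoods for one 5'SS."""

    u5_ll: float
    u6_ll: float
    origin: tuple | None = None


def score_sites(pssm_u5: Pssm, pssm_u6: Pssm, windows: Iterable[SpliceSiteWindow]) -> list[ScorePair]:
    """One ScorePair per window, order preserved; N at a scored position gives NaN."""
    out = []
    for w in windows:
        origin = w.origin if isinstance(w, SpliceSiteWindow) else None
        out.append(ScorePair(score(pssm_u5, w), score(pssm_u6, w), origin))
    return out


def pair_log_odds(pssm: Pssm, upstream_window, downstream_window) -> float:
    """log2-likelihood ratio upstream/downstream; positive means the upstream
    site has the greater PSSM score.  NaN propagates from unscoreable sites."""
    return score(pssm, upstream_window) - score(pssm, downstream_window)


@dataclass(frozen=True)
class PairLogOdds:
    pair_id: str
    u5_lor: float
    u6_lor: float


def score_pairs(pssm_u5: Pssm, pssm_u6: Pssm, pairs: Iterable) -> list[PairLogOdds]:
    """Pairs are (pair_id, upstream_window, downstream_window) triples or
    AltPair objects; returns U5 and U6 log-odds ratios per pair."""
    out = []
    for p in pairs:
        if hasattr(p, "upstream_window"):
            pid, up, down = p.pair_id, p.upstream_window, p.downstream_window
        else:
            pid, up, down = p
        out.append(
            PairLogOdds(pid, pair_log_odds(pssm_u5, up, down), pair_log_odds(pssm_u6, up, down))
        )
    return out


def u5_pssm(windows: Iterable[SpliceSiteWindow], pseudocount: float = 1.0) -> Pssm:
    """U5-contact PSSM (exonic -2..-1) from junction-deduplicated donors."""
    return build_pssm(dedup_by_junction(list(windows)), U5_POSITIONS, pseudocount)


def u6_pssm(windows: Iterable[SpliceSiteWindow], pseudocount: float = 1.0) -> Pssm:
    """U6 ACAGA-contact PSSM (intronic +3..+5) from junction-deduplicated donors."""
    return build_pssm(dedup_by_junction(list(windows)), U6_POSITIONS, pseudocount)
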