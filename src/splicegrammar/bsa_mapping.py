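"""Bulked-segregant mapping of an EMS-induced causal locus.

Two phenotype-selected sibling pools (e.g. early-flowering mutants vs their
phenotypically normal sisters from a backcross F2) are sequenced in bulk.
For every EMS-consistent SNP (G>A, plus C>T as the reverse-strand
representation of a G:C -> A:T transition), the per-pool ref/alt read depths
form a 2x2 pool x allele table tested with a G-test.  The per-SNP G values
are smoothed along each chromosome with a tri-cube kernel

    w(d) = (1 - (|d| / h)^3)^3  for |d| <= h, else 0,

with total window 2 Mb (half-width h = 1 Mb) by default, and the candidate
interval is the contiguous super-threshold region around the smoothed-G
maximum.  Under recessive segregation the causal SNP shows an allele
fraction near 1 in the mutant pool and near 1/3 in the normal pool.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "PoolVariant",
    "SmoothedTrack",
    "read_pool_vcf",
    "filter_ems",
    "pool_g_test",
    "tricube",
    "smooth_track",
    "call_interval",
    "write_track_tsv",
    "write_interval_bed",
]

EMS_STRICT = {("G", "A")}
EMS_WITH_REVERSE = {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class PoolVariant:
    """Biallelic site with per-pool allelic depths.

    ``pos`` is 0-based internally; VCF input/output converts at the boundary.
    Pool order is (normal/aphenotypic pool, mutant pool).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_depths: tuple[int, int]
    alt_depths: tuple[int, int]

    def __post_init__(self):
        if any(d < 0 for d in self.ref_depths + self.alt_depths):
            raise ValueError("depths must be non-negative")

    @property
    def pos1(self) -> int:
        return self.pos + 1

    def allele_fraction(self, pool: int) -> float:
        depth = self.ref_depths[pool] + self.alt_depths[pool]
        if depth == 0:
            return math.nan
        return self.alt_depths[pool] / depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and "," not in self.alt

    def is_ems_transition(self, include_ct: bool = True) -> bool:
        rules = EMS_WITH_REVERSE if include_ct else EMS_STRICT
        return self.is_snv and (self.ref, self.alt) in rules


def read_pool_vcf(path: str | Path, normal_pool: str, mutant_pool: str) -> list[PoolVariant]:
    """Load variants with per-sample AD fields for the two named pools."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        idx = (samples.index(normal_pool), samples.index(mutant_pool))
    except ValueError as exc:
        raise ValueError(f"pool sample not in VCF ({samples}): {exc}") from exc
    variants = []
    for rec in vcf:
        alts = rec.ALT or []
        alt = alts[0] if len(alts) == 1 else ",".join(alts)
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks AD")
        ref_depths = tuple(int(max(ad[i][0], 0)) for i in idx)
        alt_depths = tuple(int(max(ad[i][1], 0)) if ad.shape[1] > 1 else 0 for i in idx)
        variants.append(
            PoolVariant(rec.CHROM, rec.POS - 1, rec.REF, alt, ref_depths, alt_depths)
        )
    return variants


def filter_ems(variants: Iterable[PoolVariant], include_ct: bool = True) -> list[PoolVariant]:
    """Retain EMS-consistent transitions (G>A, and C>T unless strict mode).

    Multi-allelic and indel records are dropped with logged counts.
    """
    kept, n_non_snv, n_other = [], 0, 0
    for v in variants:
        if not v.is_snv:
            n_non_snv += 1
        elif v.is_ems_transition(include_ct):
            kept.append(v)
        else:
            n_other += 1
    log.info(
        "EMS filter: kept %d, dropped %d non-SNV and %d non-EMS records",
        len(kept), n_non_snv, n_other,
    )
    if not kept:
        log.warning("no EMS-consistent variants after filtering")
    return kept


def pool_g_test(variant: PoolVariant) -> float:
    """2x2 pool x allele G statistic; NaN when either pool has zero depth."""
    obs = np.array(
        [
            [variant.ref_depths[0], variant.alt_depths[0]],
            [variant.ref_depths[1], variant.alt_depths[1]],
        ],
        dtype=float,
    )
    if (obs.sum(axis=1) == 0).any():
        return math.nan
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        return 0.0
    n = obs.sum()
    expected = obs.sum(axis=1, keepdims=True) @ obs.sum(axis=0, keepdims=True) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    return 2.0 * float(terms.sum())


def tricube(distance, half_width: float):
    """Tri-cube kernel weight(s) for |d| <= h, 0 outside."""
    d = np.abs(np.asarray(distance, dtype=float)) / half_width
    return np.where(d <= 1.0, (1.0 - d**3) ** 3, 0.0)


@dataclass
class SmoothedTrack:
    """Per-SNP raw and tri-cube-smoothed G values along chromosomes."""

    chroms: np.ndarray
    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    window: float
    half_width: float


def smooth_track(
    variants: Sequence[PoolVariant],
    window: float = 2_000_000,
    window_is_half_width: bool = False,
) -> SmoothedTrack:
    """Tri-cube smoothed G statistic evaluated at SNP positions, per chromosome.

    ``window`` is the total kernel span (half-width = window / 2) unless
    ``window_is_half_width``.  Variants with undefined G (zero-depth pools)
    are excluded from both numerator and denominator.
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    chroms = np.array([v.chrom for v in variants])
    positions = np.array([v.pos for v in variants], dtype=float)
    raw = np.array([pool_g_test(v) for v in variants], dtype=float)
    h = float(window) if window_is_half_width else float(window) / 2.0
    smoothed = np.full_like(raw, np.nan)
    for chrom in np.unique(chroms):
        sel = np.where(chroms == chrom)[0]
        pos_c = positions[sel]
        raw_c = raw[sel]
        ok = ~np.isnan(raw_c)
        for local_i, i in enumerate(sel):
            if np.isnan(raw_c[local_i]):
                continue
            lo = np.searchsorted(pos_c, pos_c[local_i] - h, side="left")
            hi = np.searchsorted(pos_c, pos_c[local_i] + h, side="right")
            idx = slice(lo, hi)
            w = tricube(pos_c[idx] - pos_c[local_i], h)
            w = np.where(ok[idx], w, 0.0)
            denom = w.sum()
            smoothed[i] = float((w * np.nan_to_num(raw_c[idx])).sum() / denom)
    return SmoothedTrack(chroms, positions.astype(int), raw, smoothed, float(window), h)


def call_interval(track: SmoothedTrack, peak_fraction: float = 0.95) -> tuple[str, int, int]:
    """Contiguous region around the global smoothed-G maximum with smoothed
    G >= peak_fraction * maximum; ties at the maximum resolve to the widest
    such region.  A flat track returns the whole chromosome with a warning."""
    if track.smoothed.size == 0:
        raise ValueError("empty track")
    if not 0 < peak_fraction <= 1:
        raise ValueError("peak_fraction must be in (0, 1]")
    finite = ~np.isnan(track.smoothed)
    if not finite.any():
        raise ValueError("no finite smoothed values")
    gmax = np.nanmax(track.smoothed)
    threshold = peak_fraction * gmax
    gmin = np.nanmin(track.smoothed)
    if gmax - gmin < 1e-12:
        chrom = str(track.chroms[int(np.argmax(finite))])
        sel = track.chroms == chrom
        log.warning("flat smoothed track: returning whole chromosome %s", chrom)
        return (chrom, int(track.positions[sel].min()), int(track.positions[sel].max()) + 1)

    best = None
    n_max_runs = 0
    for chrom in np.unique(track.chroms):
        sel = np.where(track.chroms == chrom)[0]
        values = track.smoothed[sel]
        above = np.where(np.isnan(values), False, values >= threshold)
        has_max = np.where(np.isnan(values), False, values >= gmax - 1e-12)
        if not has_max.any():
            continue
        # contiguous runs of super-threshold SNPs
        run_start = None
        runs = []
        for i, flag in enumerate(above):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                runs.append((run_start, i - 1))
                run_start = None
        if run_start is not None:
            runs.append((run_start, len(above) - 1))
        for start, end in runs:
            if not has_max[start:end + 1].any():
                continue
            n_max_runs += 1
            width = track.positions[sel[end]] - track.positions[sel[start]]
            cand = (width, chrom, int(track.positions[sel[start]]), int(track.positions[sel[end]]) + 1)
            if best is None or cand[0] > best[0]:
                best = cand
    if n_max_runs > 1:
        log.warning("multiple tied smoothed-G peaks; reporting the widest region")
    return str(best[1]), best[2], best[3]


def write_track_tsv(track: SmoothedTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\traw_g\tsmoothed_g\n")
        for c, p, r, s in zip(track.chroms, track.positions, track.raw, track.smoothed):
            fh.write(f"{c}\t{int(p)}\t{r:.6g}\t{s:.6g}\n")


def write_interval_bed(interval: tuple[str, int, int], path: str | Path, name: str = "bsa_peak") -> None:
    chrom, start, end = interval
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_variants_tsv(variants: Iterable[PoolVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tnormal_ref\tnormal_alt\tmutant_ref\tmutant_alt\t"
            "normal_fraction\tmutant_fraction\tg\n"
        )
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos1}\t{v.ref}\t{v.alt}\t"
                f"{v.ref_depths[0]}\t{v.alt_depths[0]}\t{v.ref_depths[1]}\t{v.alt_depths[1]}\t"
                f"{v.allele_fraction(0):.4g}\t{v.allele_fraction(1):.4g}\t{pool_g_test(v):.6g}\n"
            )
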