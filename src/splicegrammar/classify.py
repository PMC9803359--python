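"""Discrete U5/U6 splice-site classes and +4-base switch categories.

Donor (5'SS) sequences fall into two major classes across eukaryotes:

* ``AG//GU`` sites, whose exonic -2..-1 bases match the U5 snRNA loop 1
  consensus AG;
* ``//GURAG`` sites, whose intronic +3..+5 bases match the U6 snRNA ACAGA
  box consensus RAG (R = A or G).

The U5 class of a site is the edit distance of its -2..-1 bases from AG
(0..2); the U6 class is the edit distance of its +3..+5 bases from RAG with
the degenerate R matching either purine (0..3).  N counts as one edit.

For a pair of alternative donors oriented lost -> gained (the site whose
usage decreases first), the switch category records the base change at a
position, grouped by IUPAC sets (R={A,G}, S={C,G}, B={C,G,U}, H={A,C,U});
e.g. a lost A+4 replaced by a gained U+4 is the ``A->U`` category.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome_annotation_io import SpliceSiteWindow, donor_window

__all__ = [
    "U5_CONSENSUS",
    "U6_CONSENSUS",
    "u5_class",
    "u6_class",
    "is_gurag",
    "is_aggu",
    "plus4_base",
    "major_class",
    "SwitchCategory",
    "switch_category",
    "order_classes_by_loglik",
]

U5_CONSENSUS = "AG"  # positions -2..-1
U6_CONSENSUS = "RAG"  # positions +3..+5, R = A or G

_IUPAC = {
    "R": set("AG"),
    "S": set("CG"),
    "B": set("CGU"),
    "H": set("ACU"),
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "U": {"U"},
}


def _as_donor(window) -> SpliceSiteWindow:
    if isinstance(window, SpliceSiteWindow):
        if window.site_kind != "five_prime":
            raise ValueError("expected a five_prime window")
        return window
    return donor_window(str(window))


def _edits(observed: str, consensus: str) -> int:
    dist = 0
    for base, cons in zip(observed, consensus):
        if base == "N" or base not in _IUPAC[cons]:
            dist += 1
    return dist


def u5_class(window) -> int:
    """Edit distance of 5'SS positions -2..-1 from the U5 consensus AG (0..2)."""
    return _edits(_as_donor(window).subseq((-2, -1)), U5_CONSENSUS)


def u6_class(window) -> int:
    """Edit distance of 5'SS positions +3..+5 from the U6 consensus RAG (0..3)."""
    return _edits(_as_donor(window).subseq((3, 4, 5)), U6_CONSENSUS)


def is_gurag(window) -> bool:
    """True when +1..+5 matches GURAG; not exclusive with ``is_aggu``."""
    w = _as_donor(window)
    return _edits(w.subseq((1, 2, 3, 4, 5)), "GURAG") == 0


def is_aggu(window) -> bool:
    """True when -2..-1 == AG and +1..+2 == GU."""
    w = _as_donor(window)
    return w.subseq((-2, -1)) == "AG" and w.subseq((1, 2)) == "GU"


def plus4_base(window) -> str:
    return _as_donor(window).base(4)


def major_class(window) -> str:
    """Assign a donor to the AG//GU-like or //GURAG-like major class.

    Compares the U5 and U6 edit distances on their normalised scales (max 2
    and 3 edits respectively); ties fall back to the exact is_aggu/is_gurag
    flags, and a doubly perfect AG//GURAG site counts as ``aggu``.
    """
    w = _as_donor(window)
    u5 = u5_class(w) / 2.0
    u6 = u6_class(w) / 3.0
    if u5 < u6:
        return "aggu"
    if u6 < u5:
        return "gurag"
    a, g = is_aggu(w), is_gurag(w)
    if a and not g:
        return "aggu"
    if g and not a:
        return "gurag"
    return "aggu" if u5 == 0 else "gurag"


@dataclass(frozen=True)
class SwitchCategory:
    """Base change at one position of a lost -> gained alternative-donor pair."""

    position: int
    from_base: str
    to_base: str
    group_label: str


# Ordered most-specific first; the first matching label is reported.
_SWITCH_RULES = {
    4: (("A", "U", "A->U"), ("A", "B", "A->B"), ("S", "U", "S->U"), ("B", "A", "B->A")),
    5: (("G", "H", "G->H"), ("H", "G", "H->G")),
    -1: (("G", "H", "G->H"), ("H", "G", "H->G")),
}


def switch_category(lost_window, gained_window, position: int = 4) -> SwitchCategory:
    """Categorise the base switch at ``position`` between a lost and a gained
    donor; supported positions are +4 (A/B/S groupings) and +5 / -1 (G/H)."""
    lost = _as_donor(lost_window)
    gained = _as_donor(gained_window)
    from_base = lost.base(position)
    to_base = gained.base(position)
    if position not in _SWITCH_RULES:
        raise ValueError(f"no switch grouping defined for position {position:+d}")
    if from_base == to_base:
        label = "same"
    else:
        label = "other"
        for src, dst, name in _SWITCH_RULES[position]:
            if from_base in _IUPAC[src] and to_base in _IUPAC[dst]:
                label = name
                break
    return SwitchCategory(position, from_base, to_base, label)


def order_classes_by_loglik(windows: Iterable, pssm, class_fn) -> list[int]:
    """Class values ordered by decreasing mean PSSM log-likelihood of their
    members (ties broken by class value), for contingency-table axes."""
    from . import pssm as pssm_mod

    by_class: dict[int, list[float]] = {}
    for w in windows:
        value = pssm_mod.score(pssm, w)
        by_class.setdefault(class_fn(w), []).append(value)
    means = {
        cls: sum(v for v in vals if v == v) / max(sum(1 for v in vals if v == v), 1)
        for cls, vals in by_class.items()
    }
    return sorted(means, key=lambda cls: (-means[cls], cls))
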