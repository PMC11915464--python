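"""Declarative montage construction recipes for 10-20 / 10-10 / 10-5 grids.

A :class:`CurveRecipe` encodes the whole construction as an ordered list of
entries.  Each entry names three already-placed labels (anchors); the curve is
the cross-section of the head through those anchors, and the arc runs from the
first anchor to the third, through the second.  New labels are placed at
stated arc-length fractions.  Fiducials (Nz, Iz, LPA, RPA) and the converged
vertex Cz count as placed from the start.

The 10-10 grid follows the modern standard nomenclature: reference sagittal
and coronal rows at 10% steps, the 10% horizontal ring (through Fpz, T7/T8,
Oz), and intermediate F/FC/CP/P rows subdivided in equal quarters per
half-arc, with sparse AF and PO rows.  The 10-5 grid extends it with
half-step positions on the reference rows and ring; intermediate ring names
use a systematic neighbor-concatenation scheme where no standard short name
exists.  Alternative grids can be supplied as custom recipes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["CurveRecipe", "RecipeEntry", "default_recipe", "SYSTEMS",
           "ALIASES", "canonical_label"]

SYSTEMS = ("10-20", "10-10", "10-5")

#: legacy 10-20 names accepted as aliases of the modern labels
ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def canonical_label(label: str) -> str:
    return ALIASES.get(label, label)


@dataclass(frozen=True)
class RecipeEntry:
    """One construction curve: section through three placed anchors, arc from
    anchors[0] to anchors[2] via anchors[1], labels at fractions."""

    anchors: tuple[str, str, str]
    placements: tuple[tuple[float, str], ...]

    def __post_init__(self):
        fracs = [f for f, _ in self.placements]
        if any(not (0.0 < f < 1.0) for f in fracs):
            raise ValidationError("recipe fractions must lie strictly in (0, 1)")
        if sorted(fracs) != fracs or len(set(fracs)) != len(fracs):
            raise ValidationError("recipe fractions must be strictly increasing")


@dataclass(frozen=True)
class CurveRecipe:
    entries: tuple[RecipeEntry, ...] = field(default_factory=tuple)

    def labels(self) -> list[str]:
        out = []
        for e in self.entries:
            out.extend(lbl for _, lbl in e.placements)
        return out


def _row(anchors, pairs):
    return RecipeEntry(tuple(anchors), tuple((float(f), l) for f, l in pairs))


def _merge(base_pairs, extra_pairs):
    return sorted(set(base_pairs) | set(extra_pairs))


# reference rows -------------------------------------------------------------

_SAG_1020 = [(0.1, "Fpz"), (0.3, "Fz"), (0.7, "Pz"), (0.9, "Oz")]
_SAG_1010 = _merge(_SAG_1020, [(0.2, "AFz"), (0.4, "FCz"), (0.6, "CPz"),
                               (0.8, "POz")])
_SAG_105 = _merge(_SAG_1010, [(0.05, "NFpz"), (0.15, "AFpz"), (0.25, "AFFz"),
                              (0.35, "FFCz"), (0.45, "FCCz"), (0.55, "CCPz"),
                              (0.65, "CPPz"), (0.75, "PPOz"), (0.85, "POOz"),
                              (0.95, "OIz")])

_COR_1020 = [(0.1, "T7"), (0.3, "C3"), (0.7, "C4"), (0.9, "T8")]
_COR_1010 = _merge(_COR_1020, [(0.2, "C5"), (0.4, "C1"), (0.6, "C2"),
                               (0.8, "C6")])
_COR_105 = _merge(_COR_1010, [(0.05, "T9h"), (0.15, "T7h"), (0.25, "C5h"),
                              (0.35, "C3h"), (0.45, "C1h"), (0.55, "C2h"),
                              (0.65, "C4h"), (0.75, "C6h"), (0.85, "T8h"),
                              (0.95, "T10h")])

# 10% horizontal ring: two half-arcs Fpz -> T7 -> Oz and Fpz -> T8 -> Oz -----

_RING_L_1020 = [(0.1, "Fp1"), (0.3, "F7"), (0.7, "P7"), (0.9, "O1")]
_RING_R_1020 = [(0.1, "Fp2"), (0.3, "F8"), (0.7, "P8"), (0.9, "O2")]
_RING_L_1010 = _merge(_RING_L_1020, [(0.2, "AF7"), (0.4, "FT7"), (0.6, "TP7"),
                                     (0.8, "PO7")])
_RING_R_1010 = _merge(_RING_R_1020, [(0.2, "AF8"), (0.4, "FT8"), (0.6, "TP8"),
                                     (0.8, "PO8")])


def _ring_half_steps(side_labels, anchor_mid):
    """Systematic names for 10-5 ring midpoints: neighbor concatenation."""
    # ordered stations along the half-arc at 0.0, 0.1, ..., 1.0
    stations = ["Fpz"] + [l for _, l in sorted(side_labels)] + ["Oz"]
    stations.insert(5, anchor_mid)  # T7 or T8 sits at fraction 0.5
    out = []
    for i in range(len(stations) - 1):
        frac = 0.05 + 0.1 * i
        out.append((frac, stations[i] + stations[i + 1]))
    return out


# intermediate rows ----------------------------------------------------------

def _quarter_row(prefix, left, mid, right, dense=False):
    """Standard intermediate row: equal quarters per half-arc."""
    pairs = [(0.125, f"{prefix}5"), (0.25, f"{prefix}3"),
             (0.375, f"{prefix}1"), (0.625, f"{prefix}2"),
             (0.75, f"{prefix}4"), (0.875, f"{prefix}6")]
    return _row((left, mid, right), pairs)


def _sparse_row(prefix, left, mid, right):
    pairs = [(0.25, f"{prefix}3"), (0.75, f"{prefix}4")]
    return _row((left, mid, right), pairs)


def default_recipe(system: str) -> CurveRecipe:
    """The built-in montage recipe for a landmark system."""
    if system not in SYSTEMS:
        raise ValidationError(f"unknown landmark system {system!r}")
    entries: list[RecipeEntry] = []
    if system == "10-20":
        entries.append(_row(("Nz", "Cz", "Iz"), _SAG_1020))
        entries.append(_row(("LPA", "Cz", "RPA"), _COR_1020))
        entries.append(_row(("Fpz", "T7", "Oz"), _RING_L_1020))
        entries.append(_row(("Fpz", "T8", "Oz"), _RING_R_1020))
        entries.append(_sparse_row("F", "F7", "Fz", "F8"))
        entries.append(_sparse_row("P", "P7", "Pz", "P8"))
        return CurveRecipe(tuple(entries))

    sag = _SAG_1010 if system == "10-10" else _SAG_105
    cor = _COR_1010 if system == "10-10" else _COR_105
    ring_l = _RING_L_1010
    ring_r = _RING_R_1010
    if system == "10-5":
        ring_l = _merge(ring_l, _ring_half_steps(_RING_L_1010, "T7"))
        ring_r = _merge(ring_r, _ring_half_steps(_RING_R_1010, "T8"))
    entries.append(_row(("Nz", "Cz", "Iz"), sag))
    entries.append(_row(("LPA", "Cz", "RPA"), cor))
    entries.append(_row(("Fpz", "T7", "Oz"), ring_l))
    entries.append(_row(("Fpz", "T8", "Oz"), ring_r))
    entries.append(_quarter_row("F", "F7", "Fz", "F8"))
    entries.append(_quarter_row("FC", "FT7", "FCz", "FT8"))
    entries.append(_quarter_row("CP", "TP7", "CPz", "TP8"))
    entries.append(_quarter_row("P", "P7", "Pz", "P8"))
    entries.append(_sparse_row("AF", "AF7", "AFz", "AF8"))
    entries.append(_sparse_row("PO", "PO7", "POz", "PO8"))
    return CurveRecipe(tuple(entries))
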