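"""Pairwise p-distances, barcode-gap detection, and diagnostic positions.

The barcode gap is the separation between the distribution of pairwise
p-distances *within* species and the (larger) distances *between* species;
its existence is what licenses threshold-based species assignment from a
short barcode.  The detector here is a single-pass check over labelled
sequences: with species labels known, the gap exists when the smallest
inter-specific distance exceeds the largest intra-specific one by the
relative gap width.  This deliberately replaces recursive de novo barcode
gap partitioning, which is unnecessary when labels are given.

A *diagnostic position* for a focal species is an alignment column where
the focal species is fixed for one base, every contrasted species is fixed,
and the focal base differs from all contrasted bases.  Columns carrying an
N or a gap in any involved record are disqualified (conservative: ambiguity
never counts as evidence).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .refpanel import (
    BASES,
    CoordinateError,
    FragmentDef,
    PanelError,
    ReferencePanel,
    extract_fragment,
)


class UndefinedDistanceError(ValueError):
    """No comparable columns between two sequences."""


class NoInterDistancesError(ValueError):
    """Fewer than two species: inter-specific distances undefined."""


@dataclass(frozen=True)
class DistanceSummary:
    """Intra/inter p-distance ranges and the gap decision."""

    intra_range: Optional[tuple[float, float]]
    inter_range: tuple[float, float]
    gap_detected: bool
    relative_gap_width: float = 1.5
    threshold: Optional[float] = None  # midpoint of the gap when detected


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


_COMPARABLE = np.frombuffer(BASES.encode("ascii"), dtype="S1")


def _comparable_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.isin(a, _COMPARABLE) & np.isin(b, _COMPARABLE)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing bases among comparable columns.

    Comparable columns are those where both characters are in {A,C,G,T};
    N and gap columns are excluded from numerator and denominator.
    """
    if len(a) != len(b):
        raise CoordinateError(
            f"p_distance: unequal lengths {len(a)} vs {len(b)}"
        )
    ea, eb = _encode(a), _encode(b)
    mask = _comparable_mask(ea, eb)
    n_comp = int(mask.sum())
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable columns between sequences")
    return float(np.count_nonzero(ea[mask] != eb[mask])) / n_comp


def distance_matrix(
    panel: ReferencePanel, frag: Optional[FragmentDef] = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise p-distances over the panel.

    ``frag`` restricts the computation to one fragment window; by default
    the full alignment is used.  Errors from individual pairs are re-raised
    with the offending record ids attached.
    """
    seqs = {
        r.id: extract_fragment(r.sequence, frag) if frag else r.sequence
        for r in panel.records
    }
    ids = list(seqs)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for ia, ib in itertools.combinations(ids, 2):
        try:
            d = p_distance(seqs[ia], seqs[ib])
        except ValueError as exc:
            raise type(exc)(f"pair ({ia!r}, {ib!r}): {exc}") from exc
        mat.loc[ia, ib] = d
        mat.loc[ib, ia] = d
    return mat


def distance_table(
    panel: ReferencePanel, frag: Optional[FragmentDef] = None
) -> pd.DataFrame:
    """Long-format pair table: id_a,id_b,species_a,species_b,dist,class."""
    species = {r.id: r.species for r in panel.records}
    mat = distance_matrix(panel, frag)
    rows = []
    for ia, ib in itertools.combinations(mat.index, 2):
        cls = "intra" if species[ia] == species[ib] else "inter"
        rows.append((ia, ib, species[ia], species[ib], mat.loc[ia, ib], cls))
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "species_a", "species_b", "dist", "class"]
    )


def barcode_gap_summary(
    panel: ReferencePanel,
    X: float = 1.5,
    frag: Optional[FragmentDef] = None,
) -> DistanceSummary:
    """Partition pairwise distances by species label and test for a gap.

    The gap is declared when ``inter.min > intra.max`` and the gap width
    exceeds ``(X - 1) * intra.max`` (relative gap width X, default 1.5).
    With no intra-specific pairs (one record per species) intra.max is
    taken as 0.
    """
    if len(panel.species) < 2:
        raise NoInterDistancesError(
            "need >=2 species for inter-specific distances"
        )
    table = distance_table(panel, frag)
    intra = table.loc[table["class"] == "intra", "dist"]
    inter = table.loc[table["class"] == "inter", "dist"]
    intra_range = (float(intra.min()), float(intra.max())) if len(intra) else None
    inter_range = (float(inter.min()), float(inter.max()))
    intra_max = intra_range[1] if intra_range else 0.0
    gap = inter_range[0] - intra_max
    detected = gap > 0 and gap > (X - 1.0) * intra_max
    threshold = (inter_range[0] + intra_max) / 2.0 if detected else None
    return DistanceSummary(
        intra_range=intra_range,
        inter_range=inter_range,
        gap_detected=bool(detected),
        relative_gap_width=X,
        threshold=threshold,
    )


def diagnostic_positions(
    panel: ReferencePanel,
    focal: str,
    frag: Optional[FragmentDef] = None,
    contrast: Optional[Sequence[str]] = None,
) -> list[int]:
    """Alignment columns (1-based, ascending) diagnostic for ``focal``.

    ``contrast`` defaults to every other species in the panel; passing a
    single species gives the pairwise mode.  A column qualifies when the
    focal species is fixed, every contrasted species is fixed, the focal
    base differs from each contrasted base, and no involved record carries
    N or a gap there.
    """
    if not any(r.species == focal for r in panel.records):
        raise PanelError(f"unknown species label {focal!r}")
    if contrast is None:
        contrast = [s for s in panel.species if s != focal]
    else:
        contrast = list(contrast)
        for sp in contrast:
            if not any(r.species == sp for r in panel.records):
                raise PanelError(f"unknown species label {sp!r}")
    if not contrast:
        raise PanelError("no contrast species")

    cols = frag.columns() if frag else range(1, panel.alignment_length + 1)
    groups = {sp: _species_matrix(panel, sp) for sp in [focal, *contrast]}

    out = []
    for col in cols:
        j = col - 1
        focal_col = groups[focal][:, j]
        base = _fixed_base(focal_col)
        if base is None:
            continue
        ok = True
        for sp in contrast:
            other = _fixed_base(groups[sp][:, j])
            if other is None or other == base:
                ok = False
                break
        if ok:
            out.append(col)
    return out


def _species_matrix(panel: ReferencePanel, species: str) -> np.ndarray:
    return np.vstack([_encode(r.sequence) for r in panel.records_of(species)])


def _fixed_base(column: np.ndarray):
    """The single {A,C,G,T} base a species is fixed for, else None."""
    vals = set(column.tobytes().decode("ascii"))
    if len(vals) == 1:
        (b,) = vals
        if b in BASES:
            return b
    return None


def diagnostic_table(
    panel: ReferencePanel, frag: Optional[FragmentDef] = None
) -> pd.DataFrame:
    """Per-species diagnostic positions in long format.

    Columns: species, fragment, column, focal_base, contrast_bases.
    """
    rows = []
    fragname = frag.name if frag else "full"
    for sp in panel.species:
        others = [s for s in panel.species if s != sp]
        for col in diagnostic_positions(panel, sp, frag):
            focal_base = panel.records_of(sp)[0].sequence[col - 1]
            contrast = ",".join(
                sorted({panel.records_of(o)[0].sequence[col - 1] for o in others})
            )
            rows.append((sp, fragname, col, focal_base, contrast))
    return pd.DataFrame(
        rows, columns=["species", "fragment", "column", "focal_base", "contrast_bases"]
    )
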