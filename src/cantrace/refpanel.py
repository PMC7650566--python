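"""Fixed-coordinate reference barcode alignment: data model, I/O, validation.

The reference panel is a pre-aligned set of mitochondrial cytochrome b
(Cyt b) barcode sequences, all sharing one coordinate frame anchored to the
*Thunnus thynnus* mitogenome (NC_004901, positions 14665-14901; 236 aligned
columns by default).  Three amplifiable fragments live inside that frame:
the full AB amplicon (236 bp) and the two mini-barcodes A (117 bp) and
B (109 bp) that remain amplifiable from degraded DNA.

All coordinates are 1-based and inclusive.  Gap characters are tolerated in
the alignment but columns containing a gap are excluded from distance and
diagnostic computations downstream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-")
BASES = "ACGT"

DEFAULT_ALIGNMENT_LENGTH = 236
#: mitogenome anchor: (genome id, 1-based start, 1-based end)
DEFAULT_ANCHOR = ("NC_004901", 14665, 14901)


class PanelError(ValueError):
    """Base class for panel construction / lookup failures."""


class AlignmentError(PanelError):
    """Sequences do not share a single alignment length."""


class MetadataError(PanelError):
    """FASTA/metadata mismatch or missing species label."""


class AlphabetError(PanelError):
    """Sequence contains a character outside {A,C,G,T,N,-}."""


class CoordinateError(PanelError):
    """Fragment or column coordinates fall outside the alignment."""


@dataclass(frozen=True)
class FragmentDef:
    """A named sub-window of the alignment, 1-based inclusive columns."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"fragment {self.name!r}: invalid window {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> range:
        """1-based alignment columns covered by this fragment."""
        return range(self.start, self.end + 1)

    def contains(self, other: "FragmentDef") -> bool:
        return self.start <= other.start and other.end <= self.end


def default_fragments() -> dict[str, FragmentDef]:
    """AB spans the frame; A is the 5' mini-barcode, B the 3' one.

    A = columns 1-117 and B = columns 128-236, leaving a 10-column
    inter-primer region (117 + 109 = 226 < 236).  This layout is a package
    convention; it is configurable wherever a panel is built.
    """
    return {
        "AB": FragmentDef("AB", 1, DEFAULT_ALIGNMENT_LENGTH),
        "A": FragmentDef("A", 1, 117),
        "B": FragmentDef("B", 128, DEFAULT_ALIGNMENT_LENGTH),
    }


@dataclass(frozen=True)
class RefRecord:
    """One aligned reference sequence with its species label."""

    id: str
    species: str
    sequence: str
    area: Optional[str] = None


@dataclass
class ReferencePanel:
    """Aligned reference sequences sharing one coordinate frame."""

    records: list[RefRecord]
    alignment_length: int = DEFAULT_ALIGNMENT_LENGTH
    anchor: tuple[str, int, int] = DEFAULT_ANCHOR
    fragments: dict[str, FragmentDef] = field(default_factory=default_fragments)

    def __post_init__(self) -> None:
        violations = validate_panel(self)
        if violations:
            _raise_first(violations)

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species, None)
        return list(seen)

    def records_of(self, species: str) -> list[RefRecord]:
        recs = [r for r in self.records if r.species == species]
        if not recs:
            raise PanelError(f"species {species!r} not present in panel")
        return recs

    def fragment(self, name: str) -> FragmentDef:
        try:
            return self.fragments[name]
        except KeyError:
            raise CoordinateError(f"fragment {name!r} not defined in panel") from None


def _raise_first(violations: list[str]) -> None:
    msg = violations[0]
    if "length" in msg:
        raise AlignmentError(msg)
    if "character" in msg:
        raise AlphabetError(msg)
    if "species" in msg or "metadata" in msg:
        raise MetadataError(msg)
    raise PanelError(msg)


def validate_panel(
    panel: ReferencePanel, expected_species: Optional[Iterable[str]] = None
) -> list[str]:
    """Return every invariant violation found (empty list means valid).

    ``expected_species`` lets callers check that a filtering step did not
    empty out a species: any expected label with zero records is reported.
    """
    violations: list[str] = []
    seen_ids: set[str] = set()
    for rec in panel.records:
        if rec.id in seen_ids:
            violations.append(f"duplicate id {rec.id!r}")
        seen_ids.add(rec.id)
        if len(rec.sequence) != panel.alignment_length:
            violations.append(
                f"record {rec.id!r}: length {len(rec.sequence)} != "
                f"alignment length {panel.alignment_length}"
            )
        bad = set(rec.sequence) - ALPHABET
        if bad:
            violations.append(
                f"record {rec.id!r}: illegal character(s) {sorted(bad)!r}"
            )
        if not rec.species:
            violations.append(f"record {rec.id!r}: empty species label")
    for name, frag in panel.fragments.items():
        if frag.end > panel.alignment_length:
            violations.append(
                f"fragment {name!r} end {frag.end} exceeds alignment length "
                f"{panel.alignment_length}"
            )
    present = {r.species for r in panel.records}
    for sp in expected_species or ():
        if sp not in present:
            violations.append(f"species {sp!r} has zero records")
    return violations


def extract_fragment(sequence: str, frag: FragmentDef) -> str:
    """Slice the fragment's columns (1-based inclusive) out of an aligned sequence."""
    if frag.end > len(sequence):
        raise CoordinateError(
            f"fragment {frag.name!r} ends at column {frag.end} but sequence "
            f"has only {len(sequence)} columns"
        )
    return sequence[frag.start - 1 : frag.end]


def load_panel(
    alignment_path: str | Path,
    metadata_path: str | Path,
    fragments: Optional[Mapping[str, FragmentDef]] = None,
    anchor: tuple[str, int, int] = DEFAULT_ANCHOR,
) -> ReferencePanel:
    """Read an aligned FASTA plus an ``id,species[,area]`` CSV into a panel.

    Every FASTA id must appear in the metadata with a non-empty species
    label.  All sequences must share one length; the panel's alignment
    length is taken from the sequences themselves.
    """
    seqs = list(SeqIO.parse(str(alignment_path), "fasta"))
    if not seqs:
        raise PanelError(f"no sequences found in {alignment_path}")
    meta = pd.read_csv(metadata_path, dtype=str)
    if "id" not in meta.columns or "species" not in meta.columns:
        raise MetadataError("metadata must have columns 'id' and 'species'")
    meta = meta.set_index("id")

    lengths = {len(s.seq) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(
            f"unequal sequence lengths in {alignment_path}: {sorted(lengths)}"
        )
    alignment_length = lengths.pop()

    records = []
    for s in seqs:
        if s.id not in meta.index:
            raise MetadataError(f"FASTA id {s.id!r} absent from metadata")
        row = meta.loc[s.id]
        species = row["species"]
        if not isinstance(species, str) or not species.strip():
            raise MetadataError(f"metadata lacks species for id {s.id!r}")
        area = row.get("area")
        if isinstance(area, float) or area in ("", None):  # NaN from pandas
            area = None
        seq = str(s.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {s.id!r}: illegal character(s) {sorted(bad)!r}"
            )
        records.append(RefRecord(id=s.id, species=species.strip(), sequence=seq, area=area))

    return ReferencePanel(
        records=records,
        alignment_length=alignment_length,
        anchor=anchor,
        fragments=dict(fragments) if fragments else default_fragments(),
    )


def write_panel(panel: ReferencePanel, alignment_path: str | Path, metadata_path: str | Path) -> None:
    """Write the panel back to single-line FASTA + ``id,species,area`` CSV."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in panel.records
    ]
    with open(alignment_path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(metadata_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "species", "area"])
        for r in panel.records:
            writer.writerow([r.id, r.species, r.area or ""])


def load_panel_config(path: str | Path) -> dict:
    """Read a JSON or YAML panel config (anchor + fragment coordinates)."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def fragments_from_config(cfg: Mapping) -> dict[str, FragmentDef]:
    frags = default_fragments()
    for name, window in cfg.get("fragments", {}).items():
        frags[name] = FragmentDef(name, int(window["start"]), int(window["end"]))
    return frags
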