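"""Synthetic study generator: reference panel, sampling design, degradation.

Emulates a traceability experiment on canned tuna: four tropical tuna
species (YFT yellowfin, BET bigeye, SKJ skipjack, LOT longtail) sampled
from their FAO fishing areas and tracked through five processing levels —
L1 frozen, L2 defrosted, L3 cooked, L4O canned in oil, L4B canned in brine.
Processing degrades DNA in two ways that are modelled separately:

* nucleotide substitutions accumulate level by level (Poisson counts with
  level-specific means, optionally biased toward species-diagnostic
  columns), and
* the amplifiable fragment shrinks (full AB amplicon early, mini-barcodes
  A/B or outright failure late), drawn from a per-level categorical table.

The synthetic reference panel plants its species structure explicitly:
a set of shared diagnostic columns inside the B mini-barcode where every
species carries a different base, plus per-species private columns that
push pairwise inter-specific p-distances into the target range while
intra-specific noise stays below the barcode gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .refpanel import (
    BASES,
    DEFAULT_ALIGNMENT_LENGTH,
    FragmentDef,
    RefRecord,
    ReferencePanel,
    default_fragments,
    extract_fragment,
)
from . import barcode_gap

#: processing levels in chain order
LEVELS = ("L1", "L2", "L3", "L4O", "L4B")

#: FAO-area short codes per species (AO Atlantic, IO Indian, EPO Eastern
#: Pacific, WCPO Western-Central Pacific)
DEFAULT_AREAS: dict[str, tuple[str, ...]] = {
    "YFT": ("AO", "IO", "EPO", "WCPO"),
    "SKJ": ("AO", "IO", "EPO", "WCPO"),
    "BET": ("IO", "EPO"),
    "LOT": ("IO",),
}

#: expected substitution counts per level (L1 is the reference: zero by
#: definition).  Calibrated so group-mean NS% rises monotonically through
#: the chain with the brine-canning step (L4B) highest.
DEFAULT_LAMBDA: dict[str, float] = {
    "L1": 0.0,
    "L2": 0.3,
    "L3": 1.2,
    "L4O": 2.5,
    "L4B": 4.5,
}

#: per-level fragment-availability distribution, matching the observed
#: pattern: AB amplifies through cooking (with occasional fallback to A or
#: failure at L3), only the B mini-barcode amplifies from cans.
DEFAULT_AMPLIFICATION: dict[str, dict[str, float]] = {
    "L1": {"AB": 1.0},
    "L2": {"AB": 1.0},
    "L3": {"AB": 24 / 33, "A": 7 / 33, "FAIL": 2 / 33},
    "L4O": {"B": 32 / 33, "A": 1 / 33},
    "L4B": {"B": 32 / 33, "FAIL": 1 / 33},
}

FAIL = "FAIL"


class FeasibilityError(ValueError):
    """Panel spec cannot be realised (after bounded retries)."""


class DesignError(ValueError):
    """Invalid study design."""


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Target structure of a synthetic reference panel."""

    n_species: int = 4
    seqs_per_species: int = 3
    intra_range: tuple[float, float] = (0.0, 0.05)
    inter_range: tuple[float, float] = (0.09, 0.14)
    n_diagnostic_in_b: int = 7
    alignment_length: int = DEFAULT_ALIGNMENT_LENGTH
    species_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.intra_range[1] >= self.inter_range[0]:
            raise FeasibilityError(
                "intra max must lie below inter min (barcode gap by construction)"
            )
        if self.n_species < 1 or self.seqs_per_species < 1:
            raise FeasibilityError("need >=1 species and >=1 sequence per species")
        if self.species_names is not None and len(self.species_names) != self.n_species:
            raise FeasibilityError("species_names length must equal n_species")

    def names(self) -> tuple[str, ...]:
        if self.species_names:
            return self.species_names
        if self.n_species == 4:
            return ("YFT", "BET", "SKJ", "LOT")
        return tuple(f"sp{i + 1}" for i in range(self.n_species))


@dataclass(frozen=True)
class StudyDesign:
    """Species x area x individual x level sampling layout."""

    areas: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AREAS)
    )
    individuals_per_cell: int = 3
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if not self.levels:
            raise DesignError("levels list must be non-empty")
        if self.levels[0] != "L1":
            raise DesignError("levels must start with L1 (the reference level)")
        if self.individuals_per_cell < 1:
            raise DesignError("need >=1 individual per species x area cell")
        if not self.areas:
            raise DesignError("need >=1 species")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.areas)

    @property
    def n_individuals(self) -> int:
        return sum(len(a) for a in self.areas.values()) * self.individuals_per_cell


@dataclass(frozen=True)
class DegradationParams:
    """Level-dependent substitution and amplification model."""

    lambda_by_level: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDA)
    )
    diagnostic_bias: float = 0.7
    amplification: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AMPLIFICATION.items()}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.diagnostic_bias <= 1.0:
            raise ValueError("diagnostic_bias must be in [0, 1]")
        for level, lam in self.lambda_by_level.items():
            if lam < 0:
                raise ValueError(f"lambda for {level} must be >= 0")
        if self.lambda_by_level.get("L1", 0.0) != 0.0:
            raise ValueError("lambda at L1 must be 0 (reference level)")
        for level, dist in self.amplification.items():
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"amplification probabilities for {level} sum to {total}"
                )


@dataclass(frozen=True)
class SpecimenSlot:
    """One individual at one processing level, before sequencing."""

    individual: str
    species: str
    area: str
    level: str


@dataclass(frozen=True)
class ProcessedSequence:
    """One specimen's sequence at one level for one fragment.

    ``truth_subs`` are the substituted alignment columns visible inside the
    recorded fragment; ``cumulative_subs`` tracks every column substituted
    so far across the whole alignment (degradation never reverts).
    """

    individual: str
    species_truth: str
    species_label: str
    area: str
    level: str
    fragment: str  # fragment name, or FAIL
    sequence: str  # fragment-length string; empty when FAIL
    frag: Optional[FragmentDef]
    truth_subs: frozenset[int] = frozenset()
    cumulative_subs: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.frag is not None and len(self.sequence) != self.frag.length:
            raise ValueError(
                f"{self.individual}/{self.level}: sequence length "
                f"{len(self.sequence)} != fragment length {self.frag.length}"
            )
        if self.frag is not None:
            window = set(self.frag.columns())
            if not set(self.truth_subs) <= window:
                raise ValueError("truth substitution columns outside fragment")


# ---------------------------------------------------------------------------
# panel synthesis


def synthesize_panel(
    spec: SyntheticPanelSpec,
    seed: int | np.random.Generator = 0,
    fragments: Optional[Mapping[str, FragmentDef]] = None,
    max_retries: int = 20,
) -> tuple[ReferencePanel, dict[str, tuple[int, ...]]]:
    """Build a panel with a planted barcode gap and diagnostic columns.

    Returns the panel plus a map species -> planted diagnostic columns
    (1-based, full alignment frame).  Realised pairwise distances are
    verified post hoc against the spec ranges and the construction is
    retried with a fresh stream on the (unexpected) event of a violation.
    """
    rng = np.random.default_rng(seed)
    frags = dict(fragments) if fragments else default_fragments()
    last_err: Optional[str] = None
    for _ in range(max_retries):
        try:
            panel, planted = _synthesize_once(spec, rng, frags)
        except FeasibilityError:
            raise
        err = _verify_panel(spec, panel, planted, frags)
        if err is None:
            return panel, planted
        last_err = err
    raise FeasibilityError(
        f"could not realise panel spec after {max_retries} attempts: {last_err}"
    )


def _synthesize_once(
    spec: SyntheticPanelSpec,
    rng: np.random.Generator,
    frags: Mapping[str, FragmentDef],
) -> tuple[ReferencePanel, dict[str, tuple[int, ...]]]:
    L = spec.alignment_length
    names = spec.names()
    S = spec.n_species
    b_frag = frags["B"]
    b_cols = list(b_frag.columns())

    if S > len(BASES):
        raise FeasibilityError(
            "shared diagnostic columns need a distinct base per species; "
            f"at most {len(BASES)} species supported"
        )
    d_shared = spec.n_diagnostic_in_b
    if b_frag.end > L:
        raise FeasibilityError(
            f"fragment B ends at column {b_frag.end} but alignment has {L} columns"
        )
    if d_shared > len(b_cols):
        raise FeasibilityError("more diagnostic columns requested than fragment B has")

    # target pairwise difference count: middle of the inter range
    lo = math.ceil(spec.inter_range[0] * L)
    mid = round((spec.inter_range[0] + spec.inter_range[1]) / 2.0 * L)
    # per-sequence intra noise budget: two noisy sequences must stay inside
    # the intra range, and noise on top of the planted differences must not
    # push any inter distance past the upper bound
    hi_total = math.floor(spec.inter_range[1] * L)
    n_private = max(0, (mid - d_shared + 1) // 2) if S > 1 else 0
    base_pair = d_shared + 2 * n_private
    if S > 1 and not (lo <= base_pair <= hi_total):
        raise FeasibilityError(
            f"cannot hit inter range: planted pairwise differences {base_pair} "
            f"outside [{lo}, {hi_total}] at alignment length {L}"
        )
    max_noise = min(
        math.floor(spec.intra_range[1] * L / 2.0),
        (hi_total - base_pair) // 2 if S > 1 else L,
        3,
    )
    max_noise = max(0, max_noise)

    n_planted = d_shared + S * n_private
    if n_planted + 1 > L:
        raise FeasibilityError(
            f"alignment length {L} too short for {n_planted} planted columns"
        )

    consensus = rng.choice(list(BASES), size=L)

    shared_cols = sorted(rng.choice(b_cols, size=d_shared, replace=False).tolist())
    outside_b = [c for c in range(1, L + 1) if c not in set(b_cols)]
    pool = outside_b if len(outside_b) >= S * n_private else [
        c for c in range(1, L + 1) if c not in set(shared_cols)
    ]
    if S * n_private > len(pool):
        raise FeasibilityError("not enough columns for private diagnostic sites")
    private_flat = rng.choice(pool, size=S * n_private, replace=False).tolist()
    private = {
        names[i]: sorted(private_flat[i * n_private : (i + 1) * n_private])
        for i in range(S)
    }

    planted_cols = set(shared_cols) | {c for cols in private.values() for c in cols}
    neutral = np.array(
        [c for c in range(1, L + 1) if c not in planted_cols], dtype=int
    )

    # species archetypes
    archetypes: dict[str, np.ndarray] = {}
    for i, sp in enumerate(names):
        seq = consensus.copy()
        for col in shared_cols:
            # all species mutually distinct at shared columns
            alts = [b for b in BASES]
            seq[col - 1] = alts[i]
        for col in private[sp]:
            alts = [b for b in BASES if b != consensus[col - 1]]
            seq[col - 1] = rng.choice(alts)
        archetypes[sp] = seq

    records: list[RefRecord] = []
    for sp in names:
        for j in range(spec.seqs_per_species):
            seq = archetypes[sp].copy()
            if j > 0 and max_noise > 0 and len(neutral) > 0:
                m = int(rng.integers(0, max_noise + 1))
                if m:
                    cols = rng.choice(neutral, size=m, replace=False)
                    for col in cols:
                        alts = [b for b in BASES if b != seq[col - 1]]
                        seq[col - 1] = rng.choice(alts)
            records.append(
                RefRecord(
                    id=f"{sp}_{j + 1}", species=sp, sequence="".join(seq)
                )
            )

    panel = ReferencePanel(
        records=records, alignment_length=L, fragments=dict(frags)
    )
    planted = {
        sp: tuple(sorted(set(shared_cols) | set(private[sp]))) for sp in names
    }
    return panel, planted


def _verify_panel(
    spec: SyntheticPanelSpec,
    panel: ReferencePanel,
    planted: dict[str, tuple[int, ...]],
    frags: Mapping[str, FragmentDef],
) -> Optional[str]:
    """Post-hoc check of realised distances and diagnostic columns."""
    if spec.n_species >= 2:
        table = barcode_gap.distance_table(panel)
        intra = table.loc[table["class"] == "intra", "dist"]
        inter = table.loc[table["class"] == "inter", "dist"]
        if len(intra) and not (
            spec.intra_range[0] <= intra.min() and intra.max() <= spec.intra_range[1]
        ):
            return f"intra distances [{intra.min()}, {intra.max()}] out of range"
        if not (
            spec.inter_range[0] <= inter.min() and inter.max() <= spec.inter_range[1]
        ):
            return f"inter distances [{inter.min()}, {inter.max()}] out of range"
        b = frags["B"]
        for sp in panel.species:
            diag_b = barcode_gap.diagnostic_positions(panel, sp, frag=b)
            if len(diag_b) < spec.n_diagnostic_in_b:
                return f"species {sp}: only {len(diag_b)} diagnostic columns in B"
    return None


# ---------------------------------------------------------------------------
# study design and degradation


def build_design(design: StudyDesign) -> list[SpecimenSlot]:
    """Expand the design into one slot per individual per level."""
    slots = []
    for sp, areas in design.areas.items():
        for area in areas:
            for i in range(1, design.individuals_per_cell + 1):
                ind = f"{sp}-{area}-{i}"
                for level in design.levels:
                    slots.append(SpecimenSlot(ind, sp, area, level))
    return slots


def apply_degradation(
    l1_sequence: str,
    level: str,
    params: DegradationParams,
    diagnostic_columns: Iterable[int],
    rng: np.random.Generator,
    columns: Optional[Iterable[int]] = None,
    exclude: Iterable[int] = (),
    ancestral: Optional[str] = None,
) -> tuple[str, frozenset[int]]:
    """Substitute Poisson(lambda_level) positions of a sequence.

    A fraction ``diagnostic_bias`` of the substitution mass targets
    diagnostic columns; the rest is uniform over the other eligible
    columns.  Substituted bases are drawn uniformly from the three
    alternatives to the ancestral base (default: the input sequence), so a
    substitution never silently restores the reference state.  ``columns``
    restricts eligibility (e.g. to the amplified fragment) and ``exclude``
    removes already-substituted columns; positions are 1-based.
    """
    lam = float(params.lambda_by_level.get(level, 0.0))
    seq = list(l1_sequence)
    anc = ancestral if ancestral is not None else l1_sequence
    if lam == 0.0:
        return l1_sequence, frozenset()

    eligible = set(columns) if columns is not None else set(range(1, len(seq) + 1))
    eligible -= set(exclude)
    diag_pool = sorted(eligible & set(diagnostic_columns))
    other_pool = sorted(eligible - set(diagnostic_columns))
    if not eligible:
        return l1_sequence, frozenset()

    n = min(int(rng.poisson(lam)), len(eligible))
    n_diag_target = int(rng.binomial(n, params.diagnostic_bias))
    # mass directed at a saturated pool is truncated, never redirected
    n_diag = min(n_diag_target, len(diag_pool))
    n_other = min(n - n_diag_target, len(other_pool))
    chosen: list[int] = []
    if n_diag:
        chosen += rng.choice(diag_pool, size=n_diag, replace=False).tolist()
    if n_other:
        chosen += rng.choice(other_pool, size=n_other, replace=False).tolist()

    for col in chosen:
        alts = [b for b in BASES if b != anc[col - 1]]
        seq[col - 1] = rng.choice(alts)
    return "".join(seq), frozenset(int(c) for c in chosen)


def _draw_fragment(
    level: str, params: DegradationParams, rng: np.random.Generator
) -> str:
    dist = params.amplification.get(level, {"AB": 1.0})
    names = list(dist)
    probs = np.array([dist[k] for k in names], dtype=float)
    return str(rng.choice(names, p=probs / probs.sum()))


def simulate_study(
    design: StudyDesign,
    panel: ReferencePanel,
    params: DegradationParams,
    seed: int | np.random.Generator = 0,
    planted_diagnostics: Optional[Mapping[str, Sequence[int]]] = None,
    cumulative: bool = True,
) -> list[ProcessedSequence]:
    """Run the study: per-individual haplotypes degraded level by level.

    Each individual receives an L1 haplotype (a panel sequence of its
    species plus a little intra-specific noise at non-diagnostic columns);
    subsequent levels accumulate substitutions on top of the previous
    level's state (set ``cumulative=False`` for independent per-level
    damage).  The amplified fragment at each level is drawn from the
    level's availability table.
    """
    rng = np.random.default_rng(seed)
    diag: dict[str, set[int]] = {}
    for sp in design.species:
        if planted_diagnostics and sp in planted_diagnostics:
            diag[sp] = set(planted_diagnostics[sp])
        else:
            diag[sp] = set(barcode_gap.diagnostic_positions(panel, sp))
    all_diag = set().union(*diag.values()) if diag else set()

    out: list[ProcessedSequence] = []
    full = FragmentDef("full", 1, panel.alignment_length)
    neutral = [c for c in range(1, panel.alignment_length + 1) if c not in all_diag]

    for sp, areas in design.areas.items():
        refs = panel.records_of(sp)
        for area in areas:
            for i in range(1, design.individuals_per_cell + 1):
                ind = f"{sp}-{area}-{i}"
                arch = refs[int(rng.integers(0, len(refs)))].sequence
                l1_seq = list(arch)
                m = int(rng.integers(0, 3))  # haplotype noise, 0-2 columns
                if m and neutral:
                    for col in rng.choice(neutral, size=m, replace=False):
                        alts = [b for b in BASES if b != l1_seq[col - 1]]
                        l1_seq[col - 1] = rng.choice(alts)
                l1 = "".join(l1_seq)

                current = l1
                cum: frozenset[int] = frozenset()
                for level in design.levels:
                    fragname = _draw_fragment(level, params, rng)
                    frag = panel.fragments.get(fragname, full) if fragname != FAIL else None
                    window = frag.columns() if frag else full.columns()
                    base = current if cumulative else l1
                    prior = cum if cumulative else frozenset()
                    mutated, new_cols = apply_degradation(
                        base,
                        level,
                        params,
                        diag[sp],
                        rng,
                        columns=window,
                        exclude=prior,
                        ancestral=l1,
                    )
                    if cumulative:
                        current = mutated
                        cum = frozenset(cum | new_cols)
                        subs_now = cum
                        seq_now = current
                    else:
                        subs_now = new_cols
                        seq_now = mutated
                    if frag is None:
                        out.append(
                            ProcessedSequence(
                                ind, sp, sp, area, level, FAIL, "", None,
                                frozenset(), subs_now,
                            )
                        )
                    else:
                        out.append(
                            ProcessedSequence(
                                ind, sp, sp, area, level, fragname,
                                extract_fragment(seq_now, frag), frag,
                                frozenset(c for c in subs_now if c in set(frag.columns())),
                                subs_now,
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# study I/O (FASTA per level + CSV manifest)

MANIFEST_COLUMNS = [
    "individual",
    "species_label",
    "species_truth",
    "area",
    "level",
    "fragment",
    "n_truth_subs",
]


def sample_id(rec: ProcessedSequence) -> str:
    sp, area, num = rec.individual.rsplit("-", 2)[-3:]
    return f"{sp}-{area}-{rec.level}-{num}"


def write_study(records: Sequence[ProcessedSequence], outdir: str | Path) -> None:
    """Write one FASTA per level plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    levels = sorted({r.level for r in records})
    for level in levels:
        with open(outdir / f"sequences_{level}.fasta", "w") as fh:
            for r in records:
                if r.level == level and r.fragment != FAIL:
                    fh.write(f">{sample_id(r)}\n{r.sequence}\n")
    rows = [
        {
            "individual": r.individual,
            "species_label": r.species_label,
            "species_truth": r.species_truth,
            "area": r.area,
            "level": r.level,
            "fragment": r.fragment,
            "n_truth_subs": len(r.truth_subs),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        outdir / "manifest.csv", index=False
    )


def read_study(
    indir: str | Path,
    fragments: Optional[Mapping[str, FragmentDef]] = None,
) -> list[ProcessedSequence]:
    """Read back a study written by :func:`write_study` (truth columns are
    not persisted; records come back with empty substitution sets)."""
    from Bio import SeqIO

    indir = Path(indir)
    frags = dict(fragments) if fragments else default_fragments()
    manifest = pd.read_csv(indir / "manifest.csv")
    seqs: dict[str, str] = {}
    for path in sorted(indir.glob("sequences_*.fasta")):
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
    out = []
    for _, row in manifest.iterrows():
        fragname = row["fragment"]
        if fragname == FAIL:
            out.append(
                ProcessedSequence(
                    row["individual"], row["species_truth"], row["species_label"],
                    row["area"], row["level"], FAIL, "", None,
                )
            )
            continue
        sp, area, num = row["individual"].rsplit("-", 2)[-3:]
        sid = f"{sp}-{area}-{row['level']}-{num}"
        out.append(
            ProcessedSequence(
                row["individual"], row["species_truth"], row["species_label"],
                row["area"], row["level"], fragname, seqs[sid], frags[fragname],
            )
        )
    return out
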