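"""Substitution accounting and species assignment for processed specimens.

The central statistic is NS: for each specimen at each processing level,
the number of nucleotide positions that differ from the *same specimen's*
frozen (L1) sequence over the fragment actually sequenced at that level,
expressed as a percentage of the fragment length (109, 117 or 236 bp).
Group means are unweighted arithmetic averages of per-specimen percentages.

Species are assigned by percent identity against every reference in the
panel, sliced to the query's fragment: the best identity wins when it
reaches the acceptance threshold (98% by default, mirroring common BLAST
practice for barcodes); several species tied at the best identity give a
TIE; a best identity below the threshold is AMBIGUOUS.  Assignments are
then compared with the morphological label to classify each specimen as
concordant, misidentified, ambiguous or failed, and tallied per fragment
and per level.

All displayed percentages use two decimals, rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

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
from .simulate import FAIL, ProcessedSequence

ASSIGNED = "ASSIGNED"
TIE = "TIE"
AMBIGUOUS = "AMBIGUOUS"
FAILED = "FAILED"

CONCORDANT = "CONCORDANT"
MISIDENTIFIED = "MISIDENTIFIED"

DEFAULT_THRESHOLD = 98.0


class PairingError(ValueError):
    """Query and reference records belong to different individuals."""


class GroupingError(ValueError):
    """Empty group in an averaging operation."""


def round2(x: float | Decimal) -> float:
    """Round to 2 decimals, half away from zero (display convention)."""
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _ratio_percent(numerator: int, denominator: int) -> float:
    """Exact-rational percentage rounded to 2 decimals half-up."""
    return float(
        (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class NSRecord:
    """Per-specimen, per-level substitution count and NS%."""

    individual: str
    species: str  # morphological label
    area: str
    level: str
    fragment: str
    fragment_length: int
    n_ns: int
    ns_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_ns <= self.fragment_length:
            raise ValueError("substitution count exceeds fragment length")


@dataclass(frozen=True)
class IdentificationResult:
    """Best-identity assignment for one query."""

    query_id: str
    best_identity: Optional[float]  # 2 decimals; None when FAILED
    species_set: frozenset[str]
    status: str  # ASSIGNED / TIE / AMBIGUOUS / FAILED


# ---------------------------------------------------------------------------
# substitution counting


def count_substitutions(
    query: ProcessedSequence, l1: ProcessedSequence
) -> tuple[int, frozenset[int]]:
    """Count columns of the query fragment differing from the L1 sequence.

    Both bases must be in {A,C,G,T} for a column to count; N or gap columns
    are excluded.  Returns the count plus the differing alignment columns
    (1-based).  The L1 record must cover the query's fragment (L1 carries
    the full AB amplicon, which contains both mini-barcodes).
    """
    if query.individual != l1.individual:
        raise PairingError(
            f"query {query.individual!r} paired with L1 of {l1.individual!r}"
        )
    if query.frag is None or l1.frag is None:
        raise CoordinateError("cannot count substitutions on a failed amplification")
    if not l1.frag.contains(query.frag):
        raise CoordinateError(
            f"fragment {query.frag.name!r} not contained in the L1 coverage "
            f"({l1.frag.name!r})"
        )
    offset = query.frag.start - l1.frag.start
    ref = l1.sequence[offset : offset + query.frag.length]
    qarr = np.frombuffer(query.sequence.encode("ascii"), dtype="S1")
    rarr = np.frombuffer(ref.encode("ascii"), dtype="S1")
    comparable_bases = np.frombuffer(BASES.encode("ascii"), dtype="S1")
    mask = np.isin(qarr, comparable_bases) & np.isin(rarr, comparable_bases)
    diff = mask & (qarr != rarr)
    cols = frozenset(int(i) + query.frag.start for i in np.flatnonzero(diff))
    return int(diff.sum()), cols


def ns_percent(n_ns: int, fragment_length: int) -> float:
    """100 * n_ns / fragment_length, to 2 decimals (half away from zero)."""
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    if not 0 <= n_ns <= fragment_length:
        raise ValueError("n_ns must lie in [0, fragment_length]")
    return _ratio_percent(n_ns, fragment_length)


def make_ns_records(
    records: Sequence[ProcessedSequence],
) -> list[NSRecord]:
    """Per-specimen NS relative to that specimen's own L1 sequence.

    Failed amplifications yield no NS record.  L1 records have NS = 0 by
    definition.
    """
    by_ind: dict[str, dict[str, ProcessedSequence]] = {}
    for rec in records:
        by_ind.setdefault(rec.individual, {})[rec.level] = rec
    out: list[NSRecord] = []
    for ind, levels in by_ind.items():
        l1 = levels.get("L1")
        for level, rec in levels.items():
            if rec.fragment == FAIL:
                continue
            if level == "L1":
                n = 0
            else:
                if l1 is None or l1.fragment == FAIL:
                    continue
                n, _ = count_substitutions(rec, l1)
            out.append(
                NSRecord(
                    individual=ind,
                    species=rec.species_label,
                    area=rec.area,
                    level=level,
                    fragment=rec.fragment,
                    fragment_length=rec.frag.length,
                    n_ns=n,
                    ns_percent=ns_percent(n, rec.frag.length),
                )
            )
    return out


def group_mean_ns(
    records: Iterable[NSRecord],
    by: Sequence[str] = ("level", "area", "species"),
) -> pd.DataFrame:
    """Unweighted arithmetic mean NS% per group, displayed to 2 decimals.

    The mean is taken over exact per-specimen percentages (before display
    rounding) and only the group mean is rounded.
    """
    rows = [
        {
            "individual": r.individual,
            "species": r.species,
            "area": r.area,
            "level": r.level,
            "fragment": r.fragment,
            # exact per-specimen percentage, pre-rounding
            "_pct": 100.0 * r.n_ns / r.fragment_length,
        }
        for r in records
    ]
    if not rows:
        raise GroupingError("no NS records to average")
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(list(by), sort=True)["_pct"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_ns_percent", "count": "n"})
    )
    grouped["mean_ns_percent"] = grouped["mean_ns_percent"].map(round2)
    return grouped


# ---------------------------------------------------------------------------
# identification


def percent_identity(query: str, reference: str) -> float:
    """100 * matches / comparable columns, to 2 decimals.

    Complementary to the p-distance: on fully comparable columns,
    percent_identity + 100 * p_distance = 100.
    """
    if len(query) != len(reference):
        raise CoordinateError(
            f"percent_identity: unequal lengths {len(query)} vs {len(reference)}"
        )
    qarr = np.frombuffer(query.encode("ascii"), dtype="S1")
    rarr = np.frombuffer(reference.encode("ascii"), dtype="S1")
    comparable_bases = np.frombuffer(BASES.encode("ascii"), dtype="S1")
    mask = np.isin(qarr, comparable_bases) & np.isin(rarr, comparable_bases)
    n_comp = int(mask.sum())
    if n_comp == 0:
        raise CoordinateError("no comparable columns between query and reference")
    matches = int(np.count_nonzero(qarr[mask] == rarr[mask]))
    return _ratio_percent(matches, n_comp)


def identify_species(
    query: ProcessedSequence,
    panel: ReferencePanel,
    threshold: float = DEFAULT_THRESHOLD,
) -> IdentificationResult:
    """Assign a species by best percent identity against the panel.

    Every panel record is sliced to the query's fragment; ties are resolved
    at the 2-decimal display precision.  Status is FAILED with no sequence,
    AMBIGUOUS below the threshold, TIE when several species share the best
    identity, otherwise ASSIGNED.
    """
    if not panel.records:
        raise PanelError("empty reference panel")
    qid = f"{query.individual}/{query.level}"
    if query.fragment == FAIL or not query.sequence:
        return IdentificationResult(qid, None, frozenset(), FAILED)
    frag = query.frag
    best = -1.0
    species_at_best: set[str] = set()
    for rec in panel.records:
        ref = extract_fragment(rec.sequence, frag)
        ident = percent_identity(query.sequence, ref)
        if ident > best:
            best = ident
            species_at_best = {rec.species}
        elif ident == best:
            species_at_best.add(rec.species)
    if best < threshold:
        status = AMBIGUOUS
    elif len(species_at_best) > 1:
        status = TIE
    else:
        status = ASSIGNED
    return IdentificationResult(qid, best, frozenset(species_at_best), status)


def classify_outcome(
    result: IdentificationResult,
    morphological: str,
    lenient_ties: bool = False,
) -> str:
    """Compare a genetic assignment with the morphological label.

    Strict mode (default) counts any multi-species tie as MISIDENTIFIED,
    even when the tie set contains the morphological species; lenient mode
    accepts such a tie as CONCORDANT.
    """
    if result.status == FAILED:
        return FAILED
    if result.status == AMBIGUOUS:
        return AMBIGUOUS
    if result.status == ASSIGNED:
        (sole,) = result.species_set
        return CONCORDANT if sole == morphological else MISIDENTIFIED
    # TIE
    if morphological not in result.species_set:
        return MISIDENTIFIED
    return CONCORDANT if lenient_ties else MISIDENTIFIED


@dataclass(frozen=True)
class OutcomeRecord:
    """One classified specimen, tagged for tabulation."""

    sample_id: str
    fragment: str
    level: str
    outcome: str


CONCORDANCE_COLUMNS = [
    "fragment",
    "level",
    "n_total",
    "n_concordant",
    "n_misidentified",
    "n_ambiguous",
    "n_failed",
    "percent_concordant",
]


def concordance_table(outcomes: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """Counts and percent concordant per fragment and per level.

    Each fragment also gets an ``ALL`` row aggregating over levels.
    Ambiguous and failed records count toward n_total (they are
    non-matches), so percent_concordant = n_concordant / n_total.
    """
    outcomes = list(outcomes)
    if not outcomes:
        return pd.DataFrame(columns=CONCORDANCE_COLUMNS)
    df = pd.DataFrame(
        [(o.fragment, o.level, o.outcome) for o in outcomes],
        columns=["fragment", "level", "outcome"],
    )
    rows = []
    for fragment, sub in df.groupby("fragment", sort=True):
        parts = [(lvl, g) for lvl, g in sub.groupby("level", sort=True)]
        parts.append(("ALL", sub))
        for level, g in parts:
            n = len(g)
            counts = g["outcome"].value_counts()
            n_con = int(counts.get(CONCORDANT, 0))
            rows.append(
                {
                    "fragment": fragment,
                    "level": level,
                    "n_total": n,
                    "n_concordant": n_con,
                    "n_misidentified": int(counts.get(MISIDENTIFIED, 0)),
                    "n_ambiguous": int(counts.get(AMBIGUOUS, 0)),
                    "n_failed": int(counts.get(FAILED, 0)),
                    "percent_concordant": _ratio_percent(n_con, n) if n else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)


# ---------------------------------------------------------------------------
# CSV serialisation


def ns_records_frame(records: Iterable[NSRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": r.individual,
                "species": r.species,
                "area": r.area,
                "level": r.level,
                "fragment": r.fragment,
                "fragment_length": r.fragment_length,
                "nNS": r.n_ns,
                "ns_percent": f"{r.ns_percent:.2f}",
            }
            for r in records
        ]
    )


def identification_frame(
    results: Iterable[tuple[IdentificationResult, ProcessedSequence, str]]
) -> pd.DataFrame:
    """Rows of (result, query, outcome) as the identification CSV layout."""
    return pd.DataFrame(
        [
            {
                "query": res.query_id,
                "fragment": q.fragment,
                "level": q.level,
                "best_identity": "" if res.best_identity is None else f"{res.best_identity:.2f}",
                "species_set": ";".join(sorted(res.species_set)),
                "status": res.status,
                "outcome": outcome,
            }
            for res, q, outcome in results
        ]
    )
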