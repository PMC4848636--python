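"""Kunitz/BPTI cysteine-framework motif and compensated-substitution analysis.

The Kunitz fold carries six conserved cysteines (Cys I-VI, N- to C-terminal)
forming three disulfide bridges.  In Kv-channel-blocking Kunitz toxins
(dendrotoxins, kalicludines and relatives), the residues flanking Cys I at
the N-terminus and spanning Cys V-Cys VI at the C-terminus form two short
surface patches,

    N-window  [Xa-2  Xa-1  CysI  Xa+1  Xa+2  Xa+3]
    C-window  [CysV  Xb+1  Xb+2  Xb+3  CysVI]

that concentrate the residues known to matter for channel block.  Only the
fully solvent-exposed window positions (by default Xa-2, Xa+1, Xa+3, Xb+1 and
Xb+2; relative accessible surface area > 50%) are compared between toxins,
each residue reduced to one of four physicochemical classes (negative,
positive, polar uncharged, hydrophobic).

Two toxins are predicted to share channel specificity when their exposed
window class vectors are identical, or when they differ only by "compensated"
substitutions: pairs of intra-window class swaps that preserve the window's
class composition.  A single uncompensated class change predicts altered
specificity.  This module detects the framework in a multiple sequence
alignment, extracts the windows in each record's own (published) residue
numbering, applies the exposure filter, builds class profiles, scores
pairwise compensation and partitions toxins into predicted specificity
groups.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

__all__ = [
    "ResidueClass",
    "RESIDUE_CLASS_TABLE",
    "ToxinRecord",
    "KunitzAlignment",
    "CysteineFramework",
    "WindowPosition",
    "MotifWindows",
    "ExposureResult",
    "ClassProfile",
    "CompensationVerdict",
    "CompensationReport",
    "SpecificityGrouping",
    "KeyResidueReport",
    "MotifError",
    "UnclassifiableResidueError",
    "N_WINDOW",
    "C_WINDOW",
    "WINDOW_POSITIONS",
    "DEFAULT_EXPOSED_POSITIONS",
    "classify_residue",
    "find_cysteine_framework",
    "extract_windows",
    "exposure_filter",
    "build_class_profiles",
    "detect_compensation",
    "group_specificities",
    "map_key_residues",
    "dendrotoxin_records",
    "reference_alignment",
    "synthetic_kalicludine_alignment",
]


class MotifError(ValueError):
    """Invalid input or non-canonical framework in motif analysis."""


class UnclassifiableResidueError(MotifError):
    """Raised for residues outside the 20-letter amino-acid alphabet."""


# Window position labels, N- to C-terminal.
N_WINDOW: tuple[str, ...] = ("Xa-2", "Xa-1", "CysI", "Xa+1", "Xa+2", "Xa+3")
C_WINDOW: tuple[str, ...] = ("CysV", "Xb+1", "Xb+2", "Xb+3", "CysVI")
WINDOW_POSITIONS: tuple[str, ...] = N_WINDOW + C_WINDOW

#: Positions that are fully solvent exposed in the Kunitz fold (relative
#: ASA > 50%); the remaining window positions are buried or only partially
#: exposed and are carried in reports but never enter class profiles.
DEFAULT_EXPOSED_POSITIONS: tuple[str, ...] = (
    "Xa-2", "Xa+1", "Xa+3", "Xb+1", "Xb+2"
)

_OFFSETS_N = (-2, -1, 0, 1, 2, 3)  # relative to Cys I (ungapped)
_OFFSETS_C = (0, 1, 2, 3, 4)  # relative to Cys V (ungapped)


class ResidueClass(str, Enum):
    negative = "negative"
    positive = "positive"
    polar_uncharged = "polar_uncharged"
    hydrophobic = "hydrophobic"


#: Physicochemical class of each amino acid.  His counts as positive and Pro,
#: Gly as hydrophobic; Cys and Tyr as polar uncharged.  Configurable: pass an
#: alternative mapping to the profile builders.
RESIDUE_CLASS_TABLE: dict[str, ResidueClass] = {
    **{aa: ResidueClass.negative for aa in "DE"},
    **{aa: ResidueClass.positive for aa in "KRH"},
    **{aa: ResidueClass.polar_uncharged for aa in "STNQCY"},
    **{aa: ResidueClass.hydrophobic for aa in "GAVLIPFMW"},
}


def classify_residue(
    aa: str, table: Mapping[str, ResidueClass] = RESIDUE_CLASS_TABLE
) -> ResidueClass:
    """Physicochemical class of a one-letter amino-acid code.

    Raises :class:`UnclassifiableResidueError` for X or any letter outside
    the 20-residue alphabet; callers must propagate the marker rather than
    silently assign a class.
    """
    key = aa.upper()
    if key not in table:
        raise UnclassifiableResidueError(f"unclassifiable residue {aa!r}")
    return table[key]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


_VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ToxinRecord:
    """One toxin sequence with its published residue numbering.

    ``numbering_offset`` maps 1-based sequence index i to the published
    (UniProt-style) residue number i + numbering_offset, so a mature chain
    numbered within its precursor gets a positive offset.
    """

    id: str
    sequence: str
    uniprot: str | None = None
    numbering_offset: int = 0
    key_residues: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _VALID_LETTERS
        if bad:
            raise MotifError(
                f"record {self.id!r}: invalid sequence letters {sorted(bad)}"
            )

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence.upper()

    def published_number(self, index1: int) -> int:
        """Published residue number of 1-based sequence index ``index1``."""
        return index1 + self.numbering_offset


@dataclass(frozen=True)
class KunitzAlignment:
    """A gapped multiple sequence alignment of toxin records.

    ``aligned_rows[i]`` is the gapped string for ``records[i]``; stripping
    gaps must reproduce each record's sequence exactly.  Column/position maps
    are derived, 0-based internally.
    """

    records: tuple[ToxinRecord, ...]
    aligned_rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.aligned_rows):
            raise MotifError("records/aligned_rows length mismatch")
        if not self.records:
            raise MotifError("empty alignment")
        lengths = {len(r) for r in self.aligned_rows}
        if len(lengths) != 1:
            raise MotifError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise MotifError("duplicate record ids in alignment")
        for rec, row in zip(self.records, self.aligned_rows):
            if row.replace("-", "").replace(".", "").upper() != rec.sequence.upper():
                raise MotifError(
                    f"record {rec.id!r}: aligned row does not degap to sequence"
                )

    @property
    def n_columns(self) -> int:
        return len(self.aligned_rows[0])

    def column_to_position(self, row_index: int, column: int) -> int | None:
        """0-based ungapped position at ``column`` of row ``row_index``.

        None when the row has a gap there.
        """
        row = self.aligned_rows[row_index]
        if row[column] in "-.":
            return None
        return len(row[: column + 1].replace("-", "").replace(".", "")) - 1

    def position_to_column(self, row_index: int, position: int) -> int:
        """Alignment column of 0-based ungapped ``position`` in a row."""
        row = self.aligned_rows[row_index]
        count = -1
        for col, ch in enumerate(row):
            if ch not in "-.":
                count += 1
                if count == position:
                    return col
        raise MotifError(
            f"position {position} out of range for row {row_index}"
        )


@dataclass(frozen=True)
class CysteineFramework:
    """The six framework cysteine columns of a Kunitz alignment."""

    framework_columns: tuple[int, int, int, int, int, int]  # 0-based, sorted
    per_record_positions: Mapping[str, tuple[int | None, ...]]  # 0-based ungapped
    flagged_records: Mapping[str, tuple[str, ...]]
    conservation: tuple[float, ...] = ()

    def positions_for(self, record_id: str) -> tuple[int | None, ...]:
        return tuple(self.per_record_positions[record_id])


@dataclass(frozen=True)
class WindowPosition:
    """One occupied window slot of one record."""

    label: str
    residue: str | None  # None when truncated / out of range
    published_number: int | None
    gap_flag: bool = False


@dataclass(frozen=True)
class MotifWindows:
    """Extracted N- and C-terminal windows for every record in an alignment."""

    per_record: Mapping[str, tuple[WindowPosition, ...]]
    record_flags: Mapping[str, tuple[str, ...]]

    def window(self, record_id: str) -> dict[str, WindowPosition]:
        return {wp.label: wp for wp in self.per_record[record_id]}

    def residue_at(self, record_id: str, label: str) -> str | None:
        return self.window(record_id)[label].residue


@dataclass(frozen=True)
class ExposureResult:
    """Exposure-filtered window position set.

    ``provenance`` is "asa-table" when derived from a per-residue relative
    ASA table and "fold-default" when the built-in fully-exposed set is
    used in the absence of ASA data.
    """

    exposed_positions: tuple[str, ...]
    provenance: str
    threshold: float
    per_record: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)
    unknown_positions: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClassProfile:
    """Physicochemical class vector of one toxin at exposed window positions.

    Classes are split by window; ``None`` marks an unclassifiable or missing
    residue, which is never silently assigned a class.
    """

    toxin_id: str
    n_window: tuple[tuple[str, ResidueClass | None], ...]
    c_window: tuple[tuple[str, ResidueClass | None], ...]

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.n_window + self.c_window)

    def classes(self, window: str) -> tuple[ResidueClass | None, ...]:
        pairs = self.n_window if window == "N" else self.c_window
        return tuple(c for _, c in pairs)


class CompensationVerdict(str, Enum):
    identical = "identical"
    compensated = "compensated"
    non_compensated = "non_compensated"


_VERDICT_ORDER = {
    CompensationVerdict.identical: 0,
    CompensationVerdict.compensated: 1,
    CompensationVerdict.non_compensated: 2,
}


@dataclass(frozen=True)
class CompensationReport:
    """Pairwise compensation analysis of two class profiles."""

    toxin_a: str
    toxin_b: str
    verdict: CompensationVerdict
    window_verdicts: Mapping[str, CompensationVerdict]
    substitutions: tuple[tuple[str, ResidueClass | None, ResidueClass | None], ...]
    compensated_pairs: tuple[tuple[str, str], ...]
    cross_window_multiset_preserving: bool = False


@dataclass(frozen=True)
class SpecificityGrouping:
    """Partition of toxins into predicted-specificity equivalence classes."""

    groups: tuple[tuple[str, ...], ...]
    mode: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class KeyResidueReport:
    """Location of annotated key residues relative to the two windows."""

    per_residue: tuple[tuple[str, int, str, str], ...]  # (toxin, number, note, location)
    counts: Mapping[str, Mapping[str, int]]
    errors: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Framework detection
# ---------------------------------------------------------------------------


def find_cysteine_framework(
    aln: KunitzAlignment, conservation_threshold: float = 0.9
) -> CysteineFramework:
    """Locate the six conserved cysteine columns (Cys I-VI) of an alignment.

    A column qualifies when the fraction of records carrying Cys there is at
    least ``conservation_threshold``.  Exactly six qualifying columns are
    required (else :class:`MotifError` listing the candidates); individual
    records lacking Cys at a framework column are flagged, not fatal.
    """
    if not (0.5 < conservation_threshold <= 1.0):
        raise MotifError("conservation_threshold must lie in (0.5, 1]")
    n = len(aln.records)
    candidates: list[tuple[int, float]] = []
    for col in range(aln.n_columns):
        frac = sum(
            1 for row in aln.aligned_rows if row[col].upper() == "C"
        ) / n
        if frac >= conservation_threshold:
            candidates.append((col, frac))
    if len(candidates) != 6:
        raise MotifError(
            f"non-canonical framework: {len(candidates)} cysteine columns at "
            f"conservation >= {conservation_threshold} "
            f"(candidates: {[c for c, _ in candidates]})"
        )
    columns = tuple(sorted(c for c, _ in candidates))
    conservation = tuple(f for _, f in sorted(candidates))

    per_record: dict[str, tuple[int | None, ...]] = {}
    flags: dict[str, tuple[str, ...]] = {}
    roman = ("I", "II", "III", "IV", "V", "VI")
    for i, rec in enumerate(aln.records):
        positions: list[int | None] = []
        rec_flags: list[str] = []
        for k, col in enumerate(columns):
            if aln.aligned_rows[i][col].upper() == "C":
                positions.append(aln.column_to_position(i, col))
            else:
                positions.append(None)
                rec_flags.append(f"missing Cys^{roman[k]} at column {col}")
        per_record[rec.id] = tuple(positions)
        if rec_flags:
            flags[rec.id] = tuple(rec_flags)
    return CysteineFramework(
        framework_columns=columns,  # type: ignore[arg-type]
        per_record_positions=per_record,
        flagged_records=flags,
        conservation=conservation,
    )


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def _row_has_gap_between(aln: KunitzAlignment, row: int, pos_a: int, pos_b: int) -> bool:
    """True when the aligned row contains gap columns between two ungapped
    positions (i.e. other records insert residues there)."""
    col_a = aln.position_to_column(row, pos_a)
    col_b = aln.position_to_column(row, pos_b)
    segment = aln.aligned_rows[row][col_a : col_b + 1]
    return any(ch in "-." for ch in segment)


def extract_windows(fw: CysteineFramework, aln: KunitzAlignment) -> MotifWindows:
    """Extract N- and C-terminal motif windows for every record.

    Windows are anchored on each record's own cysteines in ungapped sequence
    coordinates: the N-window runs from Cys I - 2 to Cys I + 3, the C-window
    from Cys V to Cys V + 4.  Residue numbers follow each record's published
    numbering.  Per-record flags: ``truncated N-window`` when Cys I sits
    within two residues of the start, ``non-canonical C-window`` when
    Cys VI - Cys V != 4 (an insertion between them), and ``non-canonical``
    when a required framework cysteine is absent.  Alignment gaps falling
    inside a window set the position's ``gap_flag``.
    """
    per_record: dict[str, tuple[WindowPosition, ...]] = {}
    record_flags: dict[str, tuple[str, ...]] = {}

    for i, rec in enumerate(aln.records):
        seq = rec.sequence.upper()
        positions = fw.per_record_positions[rec.id]
        flags: list[str] = list(fw.flagged_records.get(rec.id, ()))
        window_positions: list[WindowPosition] = []

        c1, c5, c6 = positions[0], positions[4], positions[5]

        def slot(label: str, pos0: int | None, anchor: int | None) -> WindowPosition:
            if pos0 is None or pos0 < 0 or pos0 >= len(seq):
                return WindowPosition(label, None, None, gap_flag=False)
            gap = False
            if anchor is not None and anchor != pos0:
                gap = _row_has_gap_between(aln, i, min(anchor, pos0), max(anchor, pos0))
            return WindowPosition(
                label, seq[pos0], rec.published_number(pos0 + 1), gap_flag=gap
            )

        # N-window around Cys I
        if c1 is None:
            flags.append("non-canonical: Cys^I absent")
            window_positions.extend(
                WindowPosition(lbl, None, None) for lbl in N_WINDOW
            )
        else:
            if c1 < 2:
                flags.append("truncated N-window")
            for lbl, off in zip(N_WINDOW, _OFFSETS_N):
                p = c1 + off
                window_positions.append(
                    slot(lbl, p if 0 <= p < len(seq) else None, c1)
                )

        # C-window Cys V .. Cys VI
        if c5 is None or c6 is None:
            flags.append("non-canonical: Cys^V or Cys^VI absent")
            window_positions.extend(
                WindowPosition(lbl, None, None) for lbl in C_WINDOW
            )
        elif c6 - c5 != 4:
            flags.append(
                f"non-canonical C-window: Cys^VI - Cys^V = {c6 - c5} != 4"
            )
            window_positions.extend(
                WindowPosition(lbl, None, None) for lbl in C_WINDOW
            )
        else:
            for lbl, off in zip(C_WINDOW, _OFFSETS_C):
                window_positions.append(slot(lbl, c5 + off, c5))

        # Canonicity check on the cysteine slots themselves.
        by_label = {wp.label: wp for wp in window_positions}
        for lbl in ("CysI", "CysV", "CysVI"):
            wp = by_label.get(lbl)
            if wp is not None and wp.residue is not None and wp.residue != "C":
                flags.append(f"non-canonical: {lbl} position holds {wp.residue}")

        per_record[rec.id] = tuple(window_positions)
        record_flags[rec.id] = tuple(flags)

    return MotifWindows(per_record=per_record, record_flags=record_flags)


# ---------------------------------------------------------------------------
# Exposure filtering
# ---------------------------------------------------------------------------


def exposure_filter(
    mw: MotifWindows,
    asa: Mapping[tuple[str, int], float] | None = None,
    threshold: float = 50.0,
) -> ExposureResult:
    """Restrict window positions to the solvent-exposed set.

    ``asa`` maps (toxin_id, published residue number) to relative ASA in
    percent (the relative scale may exceed 100).  A position label counts as
    exposed when its relative ASA is strictly greater than ``threshold`` in
    the majority of records with data.  Without an ASA table the built-in
    fully-exposed Kunitz set {Xa-2, Xa+1, Xa+3, Xb+1, Xb+2} is returned with
    provenance "fold-default".  Window positions absent from a supplied
    table are reported as exposure-unknown.
    """
    if asa is None:
        return ExposureResult(
            exposed_positions=DEFAULT_EXPOSED_POSITIONS,
            provenance="fold-default",
            threshold=threshold,
        )
    per_record: dict[str, dict[str, bool]] = {}
    votes: dict[str, list[bool]] = {lbl: [] for lbl in WINDOW_POSITIONS}
    unknown: set[str] = set()
    seen: set[str] = set()
    for rec_id, wps in mw.per_record.items():
        rec_table: dict[str, bool] = {}
        for wp in wps:
            if wp.published_number is None:
                continue
            key = (rec_id, wp.published_number)
            if key in asa:
                exposed = asa[key] > threshold
                rec_table[wp.label] = exposed
                votes[wp.label].append(exposed)
                seen.add(wp.label)
            else:
                unknown.add(wp.label)
        per_record[rec_id] = rec_table
    unknown -= seen
    exposed_positions = tuple(
        lbl for lbl in WINDOW_POSITIONS
        if votes[lbl] and sum(votes[lbl]) * 2 > len(votes[lbl])
    )
    return ExposureResult(
        exposed_positions=exposed_positions,
        provenance="asa-table",
        threshold=threshold,
        per_record=per_record,
        unknown_positions=tuple(sorted(unknown)),
    )


# ---------------------------------------------------------------------------
# Class profiles and compensation
# ---------------------------------------------------------------------------


def build_class_profiles(
    mw: MotifWindows,
    exposed_positions: Sequence[str] = DEFAULT_EXPOSED_POSITIONS,
    table: Mapping[str, ResidueClass] = RESIDUE_CLASS_TABLE,
) -> list[ClassProfile]:
    """Class vectors at the exposed window positions, one per record."""
    exposed = set(exposed_positions)
    profiles = []
    for rec_id, wps in mw.per_record.items():
        n_pairs: list[tuple[str, ResidueClass | None]] = []
        c_pairs: list[tuple[str, ResidueClass | None]] = []
        for wp in wps:
            if wp.label not in exposed:
                continue
            cls: ResidueClass | None
            if wp.residue is None:
                cls = None
            else:
                try:
                    cls = classify_residue(wp.residue, table)
                except UnclassifiableResidueError:
                    cls = None
            target = n_pairs if wp.label in N_WINDOW else c_pairs
            target.append((wp.label, cls))
        profiles.append(
            ClassProfile(toxin_id=rec_id, n_window=tuple(n_pairs),
                         c_window=tuple(c_pairs))
        )
    return profiles


def _window_verdict(
    pairs_a: Sequence[tuple[str, ResidueClass | None]],
    pairs_b: Sequence[tuple[str, ResidueClass | None]],
) -> tuple[CompensationVerdict, list, list]:
    """Verdict for one window plus substitutions and matched swap pairs."""
    diffs = [
        (lbl_a, ca, cb)
        for (lbl_a, ca), (lbl_b, cb) in zip(pairs_a, pairs_b)
        if ca != cb
    ]
    if not diffs:
        return CompensationVerdict.identical, [], []
    if any(ca is None or cb is None for _, ca, cb in diffs):
        return CompensationVerdict.non_compensated, diffs, []
    # Decompose the class changes into pairwise swaps: every a->b change must
    # be matched by a b->a change within the same window.
    unmatched: dict[tuple[ResidueClass, ResidueClass], list[str]] = {}
    swap_pairs: list[tuple[str, str]] = []
    for lbl, ca, cb in diffs:
        reverse = unmatched.get((cb, ca))
        if reverse:
            swap_pairs.append((reverse.pop(0), lbl))
        else:
            unmatched.setdefault((ca, cb), []).append(lbl)
    if any(v for v in unmatched.values()):
        return CompensationVerdict.non_compensated, diffs, swap_pairs
    return CompensationVerdict.compensated, diffs, swap_pairs


def detect_compensation(pA: ClassProfile, pB: ClassProfile) -> CompensationReport:
    """Score a toxin pair as identical / compensated / non-compensated.

    Each window is judged separately; compensation must be intra-window (the
    class swaps pair up within the N- or the C-window).  The overall verdict
    is the worse of the two windows.  Cross-window multiset preservation is
    reported separately and never upgrades the verdict.
    """
    if pA.positions != pB.positions:
        raise MotifError(
            f"profiles over different position sets: {pA.positions} vs "
            f"{pB.positions}"
        )
    vn, diffs_n, swaps_n = _window_verdict(pA.n_window, pB.n_window)
    vc, diffs_c, swaps_c = _window_verdict(pA.c_window, pB.c_window)
    overall = max((vn, vc), key=lambda v: _VERDICT_ORDER[v])

    cross = False
    if overall is not CompensationVerdict.identical:
        all_a = [c for _, c in pA.n_window + pA.c_window]
        all_b = [c for _, c in pB.n_window + pB.c_window]
        cross = Counter(all_a) == Counter(all_b)

    return CompensationReport(
        toxin_a=pA.toxin_id,
        toxin_b=pB.toxin_id,
        verdict=overall,
        window_verdicts={"N": vn, "C": vc},
        substitutions=tuple(diffs_n + diffs_c),
        compensated_pairs=tuple(swaps_n + swaps_c),
        cross_window_multiset_preserving=cross,
    )


# ---------------------------------------------------------------------------
# Specificity grouping
# ---------------------------------------------------------------------------


def group_specificities(
    profiles: Sequence[ClassProfile], mode: str = "compensated"
) -> SpecificityGrouping:
    """Partition toxins into predicted shared-specificity groups.

    ``strict`` mode groups toxins whose class vectors are identical
    position-wise in both windows (an equivalence relation).  ``compensated``
    mode links any pair whose :func:`detect_compensation` verdict is
    identical or compensated; the pairwise relation is not guaranteed
    transitive, so groups are its transitive closure, and a warning is
    attached whenever the closure merges a pair that is itself
    non-compensated.
    """
    if mode not in ("strict", "compensated"):
        raise MotifError(f"unknown grouping mode {mode!r}")
    if not profiles:
        raise MotifError("need at least one profile")
    ids = [p.toxin_id for p in profiles]
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    reports: dict[tuple[str, str], CompensationReport] = {}
    for pa, pb in itertools.combinations(profiles, 2):
        rep = detect_compensation(pa, pb)
        reports[(pa.toxin_id, pb.toxin_id)] = rep
        if mode == "strict":
            linked = rep.verdict is CompensationVerdict.identical
        else:
            linked = rep.verdict in (
                CompensationVerdict.identical, CompensationVerdict.compensated
            )
        if linked:
            union(pa.toxin_id, pb.toxin_id)

    groups_map: dict[str, list[str]] = {}
    for i in ids:
        groups_map.setdefault(find(i), []).append(i)
    groups = tuple(tuple(g) for g in groups_map.values())

    warnings: list[str] = []
    if mode == "compensated":
        for (a, b), rep in reports.items():
            if (find(a) == find(b)
                    and rep.verdict is CompensationVerdict.non_compensated):
                warnings.append(
                    f"non-transitive relation: {a} and {b} merged by closure "
                    "but are pairwise non-compensated"
                )
    return SpecificityGrouping(groups=groups, mode=mode,
                               warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Key-residue mapping
# ---------------------------------------------------------------------------


def map_key_residues(
    records: Sequence[ToxinRecord], mw: MotifWindows
) -> KeyResidueReport:
    """Locate annotated key residues relative to the N- and C-windows.

    Each (published residue number, note) annotation is labeled
    ``"N-window at <pos>"`` / ``"C-window at <pos>"`` / ``"outside"``; many
    experimentally-critical residues (e.g. the beta-sheet cluster near the
    protease-reactive loop) fall outside both windows.
    """
    rows: list[tuple[str, int, str, str]] = []
    counts: dict[str, dict[str, int]] = {}
    errors: list[str] = []
    for rec in records:
        window = mw.window(rec.id)
        by_number = {
            wp.published_number: wp.label
            for wp in window.values()
            if wp.published_number is not None
        }
        c = {"N-window": 0, "C-window": 0, "outside": 0}
        for number, note in rec.key_residues:
            idx1 = number - rec.numbering_offset
            if not (1 <= idx1 <= len(rec.sequence)):
                errors.append(
                    f"{rec.id}: key residue {number} outside sequence range"
                )
                continue
            label = by_number.get(number)
            if label is None:
                location = "outside"
                c["outside"] += 1
            elif label in N_WINDOW:
                location = f"N-window at {label}"
                c["N-window"] += 1
            else:
                location = f"C-window at {label}"
                c["C-window"] += 1
            rows.append((rec.id, number, note, location))
        counts[rec.id] = c
    return KeyResidueReport(
        per_residue=tuple(rows), counts=counts, errors=tuple(errors)
    )


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------

# Mature alpha-dendrotoxin (Dendroaspis angusticeps), numbered from 1.
_ALPHA_DTX_SEQ = (
    "QPRRKLCILHRNPGRCYDKIPAFYYNQKKKQCERFDWSGCGGNSNRFKTIEECRRTCIG"
)
# Mature dendrotoxin K (Dendroaspis polylepis); published numbering counts
# the precursor, so the mature chain starts at residue 23 (offset +22).
_DTX_K_SEQ = (
    "AAKYCKLPLRIGPCKRKIPSFYYKWKAKQCLPFDYSGCGGNANRFKTIEECRRTCVG"
)


def dendrotoxin_records() -> tuple[ToxinRecord, ToxinRecord]:
    """Hand-built alpha-DTX and DTX-K records with published numbering.

    Key-residue annotations follow the site-directed-mutagenesis literature
    in UniProt numbering (alpha-DTX P00980 mature chain from 1; DTX-K P00981
    precursor numbering, mature chain offset +22).
    """
    alpha = ToxinRecord(
        id="alpha-DTX",
        uniprot="P00980",
        sequence=_ALPHA_DTX_SEQ,
        numbering_offset=0,
        key_residues=(
            (3, "R3"), (4, "R4"), (5, "K5 dyad"), (6, "L6"),
            (8, "I8"), (9, "L9 dyad"),
        ),
    )
    dtxk = ToxinRecord(
        id="DTX-K",
        uniprot="P00981",
        sequence=_DTX_K_SEQ,
        numbering_offset=22,
        key_residues=(
            (25, "K25"), (26, "Y26"), (28, "K28"), (30, "P30"),
            (32, "R32"), (35, "P35"), (46, "K46"), (47, "W47"),
            (48, "K48"), (50, "K50"), (74, "R74"), (75, "R75"),
        ),
    )
    return alpha, dtxk


def reference_alignment() -> KunitzAlignment:
    """Pairwise alignment of alpha-DTX and DTX-K on their shared framework.

    The inter-cysteine segment lengths of the two toxins are identical, so
    the alignment only pads the shorter DTX-K N-terminus.
    """
    alpha, dtxk = dendrotoxin_records()
    return KunitzAlignment(
        records=(alpha, dtxk),
        aligned_rows=(alpha.sequence, "--" + dtxk.sequence),
    )


def synthetic_kalicludine_alignment() -> KunitzAlignment:
    """Synthetic stand-in for the kalicludines AsKC1/AsKC2/AsKC3.

    The real kalicludine window residues are only published as an alignment
    figure and the UniProt records are not bundled, so this fixture is a
    constructed (synthetic) sequence set on a Kunitz scaffold whose exposed
    window classes realise the reported relationship: AsKC1 and AsKC2 share
    identical class vectors (predicting shared specificity) while AsKC3
    carries a single uncompensated class change at Xa-2.
    """
    # Scaffold derived from the DTX-K fixture; window residues planted.
    #            Xa-2 Xa+1 Xa+3           Xb+1 Xb+2
    # AsKC1:      K    I    P              R    R
    # AsKC2:      R    L    G   (same classes as AsKC1)
    # AsKC3:      E    I    P   (positive -> negative at Xa-2)
    def scaffold(xa_m2: str, xa_p1: str, xa_p3: str, xb_1: str, xb_2: str) -> str:
        return (
            "AA" + xa_m2 + "YC" + xa_p1 + "L" + xa_p3
            + "LRIGPCKRKIPSFYYKWKAKQCLPFDYSGCGGNANRFKTIEEC"
            + xb_1 + xb_2 + "TCVG"
        )

    records = (
        ToxinRecord(id="AsKC1-syn", sequence=scaffold("K", "I", "P", "R", "R")),
        ToxinRecord(id="AsKC2-syn", sequence=scaffold("R", "L", "G", "R", "R")),
        ToxinRecord(id="AsKC3-syn", sequence=scaffold("E", "I", "P", "R", "R")),
    )
    return KunitzAlignment(
        records=records, aligned_rows=tuple(r.sequence for r in records)
    )
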