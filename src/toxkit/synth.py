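"""Seeded synthetic-data generators for every analysis stage.

These generators stand in for the wet-lab measurements the analyses were
designed for, with the statistical structure the fitters assume:
Morrison-shaped concave inhibition curves at the standard [E0]/Ki = 10
design, stoichiometric active-site titrations at [E0]/Ki >= 100, Hill
concentration-response curves with a 100% plateau, Boltzmann-gated IV/GV
families with voltage-independent block by construction, and Kunitz
alignments with a planted six-cysteine framework, planted window classes and
planted compensated/non-compensated substitutions (truth records included).

Noise is multiplicative Gaussian (sd as a fraction of the signal), the
error structure of spectrophotometric activity and TEVC current readings.
Every generator is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ephys import DoseResponse, IVSeries, boltzmann_po, hill_response
from .kinetics import (
    AssayCondition,
    InhibitionCurve,
    TitrationSeries,
    morrison_fraction,
)
from .motifs import (
    C_WINDOW,
    DEFAULT_EXPOSED_POSITIONS,
    N_WINDOW,
    KunitzAlignment,
    ResidueClass,
    ToxinRecord,
)

__all__ = [
    "SynthError",
    "gen_morrison_curve",
    "gen_titration",
    "gen_dose_response",
    "gen_gv_family",
    "PlantedMsa",
    "gen_kunitz_msa",
]


class SynthError(ValueError):
    """Inconsistent generator specification."""


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


def _mult_noise(rng: np.random.Generator, values: np.ndarray, sd: float
                ) -> np.ndarray:
    if sd < 0:
        raise SynthError("noise sd must be non-negative")
    if sd == 0:
        return values
    return values * (1.0 + rng.normal(0.0, sd, size=values.shape))


# ---------------------------------------------------------------------------
# Enzyme kinetics
# ---------------------------------------------------------------------------


def gen_morrison_curve(
    E0: float,
    Ki_app: float,
    n_points: int = 12,
    I_max_over_E0: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    enzyme_id: str = "synthetic-enzyme",
    S0: float = 0.0,
    KM: float | None = None,
) -> InhibitionCurve:
    """Inhibition curve on a log-spaced [I] grid (0 included) from the
    Morrison model, with multiplicative noise clipped to [0, 1.05]."""
    if n_points < 5:
        raise SynthError("need >= 5 points")
    rng = _rng(seed)
    grid = np.concatenate([
        [0.0],
        np.geomspace(I_max_over_E0 * E0 / 50.0, I_max_over_E0 * E0,
                     n_points - 1),
    ])
    fa = np.array([morrison_fraction(E0, i0, Ki_app) for i0 in grid])
    fa = np.clip(_mult_noise(rng, fa, noise_sd), 0.0, 1.05)
    cond = AssayCondition(enzyme_id=enzyme_id, E0=E0, S0=S0, KM=KM)
    return InhibitionCurve(
        condition=cond,
        I_grid=tuple(grid),
        fractional_activity=tuple(fa),
    )


def gen_titration(
    active_conc: float,
    E_total: float,
    n_points: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    E0_over_Ki: float = 1000.0,
    span_over_equivalence: float = 1.5,
) -> TitrationSeries:
    """Stoichiometric titration: activity declines linearly to zero at the
    equivalence point (added inhibitor = ``active_conc``), then stays flat.

    The grid is linear from 0 to ``span_over_equivalence`` times the
    equivalence concentration, so it always spans past the kink.
    """
    if n_points < 6:
        raise SynthError("need >= 6 titration points")
    rng = _rng(seed)
    x = np.linspace(0.0, span_over_equivalence * active_conc, n_points)
    fa = np.clip(1.0 - x / active_conc, 0.0, None)
    fa = np.clip(_mult_noise(rng, fa, noise_sd), 0.0, None)
    return TitrationSeries(
        E_total=E_total,
        inhibitor_amounts=tuple(x),
        fractional_activity=tuple(fa),
        E0_over_Ki=E0_over_Ki,
    )


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------


def gen_dose_response(
    IC50: float,
    h: float = 1.0,
    n_conc: int = 8,
    decades: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    channel_id: str = "synthetic-Kv",
) -> DoseResponse:
    """Hill concentration-response curve on a log grid centred on the IC50."""
    if decades < 2:
        raise SynthError("need >= 2 decades around the IC50")
    rng = _rng(seed)
    half = decades / 2.0
    conc = np.geomspace(IC50 * 10.0 ** (-half), IC50 * 10.0**half, n_conc)
    y = hill_response(conc, IC50, h)
    y = np.clip(_mult_noise(rng, y, noise_sd), 0.0, 100.0)
    return DoseResponse(
        channel_id=channel_id,
        conc=tuple(conc),
        percent_block=tuple(y),
    )


def gen_gv_family(
    V_half: float = 14.0,
    slope_k: float = 8.0,
    Erev: float = -80.0,
    V_grid: Sequence[float] | None = None,
    block_fraction: float = 0.5,
    Gmax: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[IVSeries, IVSeries]:
    """Paired control/toxin IV series from an ohmic Boltzmann-gated channel.

    I(V) = Gmax * Po(V) * (V - Erev) with the toxin series scaled by
    (1 - block_fraction) uniformly in V, so the block is voltage independent
    by construction.
    """
    if not (0.0 <= block_fraction <= 1.0):
        raise SynthError("block_fraction must lie in [0, 1]")
    if V_grid is None:
        V_grid = np.arange(-40.0, 41.0, 10.0)
    v = np.asarray(V_grid, dtype=float)
    rng = _rng(seed)
    i_control = Gmax * boltzmann_po(v, V_half, slope_k) * (v - Erev)
    i_toxin = (1.0 - block_fraction) * i_control
    i_control = _mult_noise(rng, i_control, noise_sd)
    i_toxin = _mult_noise(rng, i_toxin, noise_sd)
    control = IVSeries(V=tuple(v), I=tuple(i_control), condition="control",
                       Erev=Erev)
    toxin = IVSeries(V=tuple(v), I=tuple(i_toxin), condition="toxin",
                     Erev=Erev)
    return control, toxin


# ---------------------------------------------------------------------------
# Kunitz alignments with planted truth
# ---------------------------------------------------------------------------

# One representative residue per class, used when planting window classes.
_CLASS_RESIDUES: dict[ResidueClass, str] = {
    ResidueClass.negative: "DE",
    ResidueClass.positive: "KR",  # His excluded to keep plants unambiguous
    ResidueClass.polar_uncharged: "STNQ",
    ResidueClass.hydrophobic: "AVLIPF",
}

# Residues drawn for non-window scaffold columns: no Cys (so no spurious
# framework columns) and class-irrelevant.
_SCAFFOLD_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

_EXPOSED_N = tuple(p for p in DEFAULT_EXPOSED_POSITIONS if p in N_WINDOW)
_EXPOSED_C = tuple(p for p in DEFAULT_EXPOSED_POSITIONS if p in C_WINDOW)


@dataclass(frozen=True)
class PlantedMsa:
    """A generated alignment plus the ground truth used to build it."""

    alignment: KunitzAlignment
    asa: Mapping[tuple[str, int], float]
    planted_classes: Mapping[str, Mapping[str, ResidueClass]]
    strict_groups: tuple[tuple[str, ...], ...]
    compensated_groups: tuple[tuple[str, ...], ...]
    cys_positions: tuple[int, ...]  # 1-based


def _groups_from_classes(
    classes: Mapping[str, Mapping[str, ResidueClass]], mode: str
) -> tuple[tuple[str, ...], ...]:
    """Independent grouping of planted class vectors (simple closure)."""
    ids = list(classes)

    def window_vec(i: str, labels: Sequence[str]) -> tuple:
        return tuple(classes[i][lbl] for lbl in labels)

    def linked(a: str, b: str) -> bool:
        if mode == "strict":
            return (window_vec(a, _EXPOSED_N) == window_vec(b, _EXPOSED_N)
                    and window_vec(a, _EXPOSED_C) == window_vec(b, _EXPOSED_C))
        for labels in (_EXPOSED_N, _EXPOSED_C):
            va, vb = window_vec(a, labels), window_vec(b, labels)
            if sorted(c.value for c in va) != sorted(c.value for c in vb):
                return False
        return True

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a in ids:
        for b in ids:
            if a < b and linked(a, b):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    out: dict[str, list[str]] = {}
    for i in ids:
        out.setdefault(find(i), []).append(i)
    return tuple(tuple(g) for g in out.values())


def gen_kunitz_msa(
    n_seqs: int = 6,
    scaffold_length: int = 58,
    planted_cys_positions: Sequence[int] = (5, 14, 30, 38, 51, 55),
    planted_window_classes: Mapping[str, ResidueClass] | None = None,
    n_compensated_pairs: int = 1,
    n_noncompensated: int = 1,
    seed: int = 0,
) -> PlantedMsa:
    """Generate an ungapped Kunitz-like alignment with planted truth.

    The first ``1 + n_compensated_pairs`` sequences form the base specificity
    group: sequence 0 carries the base window classes and each "compensated"
    sequence swaps the classes of two exposed N-window positions (an
    intra-window compensated substitution pair).  The next
    ``n_noncompensated`` sequences each carry one distinct uncompensated
    class change, forming singleton groups.  Any remaining sequences repeat
    the base classes.  A relative-ASA table marks the exposed window
    positions at 50-100% and the rest of the windows at <= 50%.  The truth
    record lists the intended strict- and compensated-mode groupings,
    recomputed independently from the planted class vectors (an inconsistent
    plant specification raises :class:`SynthError`).
    """
    cys = tuple(int(c) for c in planted_cys_positions)  # 1-based
    if len(cys) != 6 or sorted(cys) != list(cys):
        raise SynthError("exactly six increasing cysteine positions required")
    if cys[5] - cys[4] != 4:
        raise SynthError("Cys VI must sit at Cys V + 4")
    if cys[0] < 3:
        raise SynthError("Cys I must leave room for the Xa-2 position")
    if cys[5] + 2 > scaffold_length:
        raise SynthError("scaffold too short for the planted framework")
    if n_seqs < 1 + n_compensated_pairs + n_noncompensated:
        raise SynthError("n_seqs too small for the requested plants")

    rng = _rng(seed)
    if planted_window_classes is None:
        planted_window_classes = {
            "Xa-2": ResidueClass.positive,
            "Xa+1": ResidueClass.hydrophobic,
            "Xa+3": ResidueClass.positive,
            "Xb+1": ResidueClass.positive,
            "Xb+2": ResidueClass.positive,
        }
    missing = set(DEFAULT_EXPOSED_POSITIONS) - set(planted_window_classes)
    if missing:
        raise SynthError(f"planted classes missing positions {sorted(missing)}")

    # Per-sequence class vectors.
    base = dict(planted_window_classes)
    classes: dict[str, dict[str, ResidueClass]] = {}
    ids: list[str] = []
    other = [c for c in ResidueClass]

    def seq_id(i: int) -> str:
        return f"syn{i:02d}"

    k = 0
    classes[seq_id(k)] = dict(base)
    ids.append(seq_id(k))
    k += 1
    # Compensated variants: swap two exposed N-window positions whose base
    # classes differ (guaranteed by the default plant; checked otherwise).
    swap_candidates = [
        (a, b)
        for ai, a in enumerate(_EXPOSED_N)
        for b in _EXPOSED_N[ai + 1:]
        if base[a] != base[b]
    ]
    if n_compensated_pairs and not swap_candidates:
        raise SynthError(
            "cannot plant compensated swaps: all exposed N-window classes equal"
        )
    for j in range(n_compensated_pairs):
        a, b = swap_candidates[j % len(swap_candidates)]
        v = dict(base)
        v[a], v[b] = v[b], v[a]
        classes[seq_id(k)] = v
        ids.append(seq_id(k))
        k += 1
    # Non-compensated variants: one distinct class change each.
    for j in range(n_noncompensated):
        pos = _EXPOSED_N[j % len(_EXPOSED_N)]
        v = dict(base)
        replacement = [c for c in other if c != base[pos]][j % 3]
        v[pos] = replacement
        classes[seq_id(k)] = v
        ids.append(seq_id(k))
        k += 1
    while k < n_seqs:
        classes[seq_id(k)] = dict(base)
        ids.append(seq_id(k))
        k += 1

    strict_groups = _groups_from_classes(classes, "strict")
    compensated_groups = _groups_from_classes(classes, "compensated")
    # Sanity: every non-compensated plant must be a singleton in both modes.
    planted_singletons = set(
        seq_id(1 + n_compensated_pairs + j) for j in range(n_noncompensated)
    )
    for g in compensated_groups:
        if len(g) > 1 and planted_singletons & set(g):
            raise SynthError(
                "inconsistent plant spec: a non-compensated variant collides "
                f"with another group ({g})"
            )

    # Window layout in 1-based sequence coordinates.
    label_pos: dict[str, int] = {}
    for lbl, off in zip(N_WINDOW, (-2, -1, 0, 1, 2, 3)):
        label_pos[lbl] = cys[0] + off
    for lbl, off in zip(C_WINDOW, (0, 1, 2, 3, 4)):
        label_pos[lbl] = cys[4] + off
    window_cols = set(label_pos.values())
    cys_set = set(cys)

    # A shared scaffold keeps non-window columns conserved enough to look
    # like an alignment while carrying no second framework.
    scaffold = rng.choice(list(_SCAFFOLD_ALPHABET), size=scaffold_length)
    buried_window = [
        lbl for lbl in N_WINDOW + C_WINDOW
        if lbl not in DEFAULT_EXPOSED_POSITIONS
        and lbl not in ("CysI", "CysV", "CysVI")
    ]
    buried_residues = {lbl: rng.choice(list("STNQ")) for lbl in buried_window}

    records: list[ToxinRecord] = []
    asa: dict[tuple[str, int], float] = {}
    for rid in ids:
        chars = list(scaffold)
        for c in cys:
            chars[c - 1] = "C"
        for lbl, pos in label_pos.items():
            if pos in cys_set:
                continue
            if lbl in DEFAULT_EXPOSED_POSITIONS:
                pool = _CLASS_RESIDUES[classes[rid][lbl]]
                chars[pos - 1] = pool[rng.integers(len(pool))]
            else:
                chars[pos - 1] = buried_residues[lbl]
        seq = "".join(chars)
        records.append(ToxinRecord(id=rid, sequence=seq))
        for lbl, pos in label_pos.items():
            if lbl in DEFAULT_EXPOSED_POSITIONS:
                asa[(rid, pos)] = float(rng.uniform(55.0, 100.0))
            else:
                asa[(rid, pos)] = float(rng.uniform(5.0, 45.0))

    alignment = KunitzAlignment(
        records=tuple(records),
        aligned_rows=tuple(r.sequence for r in records),
    )
    return PlantedMsa(
        alignment=alignment,
        asa=asa,
        planted_classes=classes,
        strict_groups=strict_groups,
        compensated_groups=compensated_groups,
        cys_positions=cys,
    )
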