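"""Mining of ATP·Mg2+ instances from PDB coordinate files.

This module locates ATP (and, optionally, non-hydrolysable analogues) bound
to a single Mg2+ ion in PDB-format structure files, applies the two
selection rules used to build the reference set — no second divalent cation
within 8 Å of the nucleotide, and the Mg2+ within 3 Å of at least one
phosphate oxygen — and classifies the Mg2+–phosphate coordination geometry
into the seven single/double/triple permutations over the alpha-, beta- and
gamma-phosphate groups.

Coordination nomenclature
-------------------------
A group (alpha, beta, gamma) counts as coordinated when the Mg2+ ion lies
within a distance cutoff (default 3.0 Å) of any of the group's non-bridging
oxygens.  Two composite labels matter downstream:

``C3``
    tridentate coordination, all three groups bound (mode ``ABG``).
``C2``
    bidentate beta–gamma coordination (mode ``BG``) with the Mg2+ ion more
    than 3.75 Å from the alpha-phosphorus.

Everything else is labelled ``OTHER``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "LigandComplex",
    "CoordinationAssignment",
    "TransitionCounts",
    "StructureFormatError",
    "ClassificationError",
    "DIVALENT_CATIONS",
    "NON_BRIDGING_OXYGENS",
    "read_structures",
    "filter_complexes",
    "classify_coordination",
    "distance_only_c2",
    "tabulate_modes",
    "count_transitions",
    "mining_table",
]

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed as PDB."""


class ClassificationError(ValueError):
    """Raised when a complex lacks the atoms needed for classification."""


#: Residue names treated as divalent cations for the exclusion rule.
DIVALENT_CATIONS = frozenset(
    {"MG", "CA", "MN", "ZN", "FE2", "CO", "NI", "CU", "CD", "SR", "BA"}
)

#: Non-bridging oxygens per phosphate group (PDB v3 naming).
NON_BRIDGING_OXYGENS = {
    "alpha": ("O1A", "O2A"),
    "beta": ("O1B", "O2B"),
    "gamma": ("O1G", "O2G", "O3G"),
}

#: Bridging oxygens optionally counted towards each group.
BRIDGING_OXYGENS = {
    "alpha": ("O3A",),
    "beta": ("O3A", "O3B"),
    "gamma": ("O3B",),
}

#: Atoms that must be present for an instance to be usable at all.
REQUIRED_ATOMS = ("PA", "PB", "PG", "O3A", "O3B")

#: Atom-name aliases mapping analogue naming onto ATP naming.
ANALOGUE_ALIASES = {
    "ANP": {"N3B": "O3B"},  # AMP-PNP: imido bridge
    "ACP": {"C3B": "O3B"},  # AMP-PCP: methylene bridge
    "AGS": {"S1G": "O1G"},  # ATP-gamma-S
}

_GROUP_ORDER = ("alpha", "beta", "gamma")
_MODE_FROM_GROUPS = {
    frozenset(): "NONE",
    frozenset({"alpha"}): "A",
    frozenset({"beta"}): "B",
    frozenset({"gamma"}): "G",
    frozenset({"alpha", "beta"}): "AB",
    frozenset({"alpha", "gamma"}): "AG",
    frozenset({"beta", "gamma"}): "BG",
    frozenset({"alpha", "beta", "gamma"}): "ABG",
}


@dataclass
class AtomRecord:
    """One atom read from a structure file."""

    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    model_index: int
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"invalid position for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy out of [0, 1] for atom {self.atom_name}")


@dataclass
class LigandComplex:
    """One ATP(-analogue)·Mg2+ instance extracted from a structure."""

    source_id: str
    atp_atoms: list[AtomRecord]
    mg: AtomRecord
    nearby_divalent_cations: list[AtomRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atp_atoms:
            if a.atom_name == name:
                return a
        raise KeyError(name)

    def has_atom(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atp_atoms)


@dataclass
class CoordinationAssignment:
    """Coordination classification of one complex."""

    coordinated_groups: frozenset[str]
    mode_label: str
    c2c3_label: str
    mg_pa_distance: float
    group_distances: dict[str, float] = field(default_factory=dict)


class TransitionCounts(NamedTuple):
    total: int
    c3_to_c2: int
    c2_to_c3: int


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _iter_pdb_paths(path_or_dir: str | Path) -> list[Path]:
    p = Path(path_or_dir)
    if p.is_dir():
        files = sorted(p.glob("*.pdb")) + sorted(p.glob("*.ent"))
        if not files:
            raise StructureFormatError(f"no PDB files found in directory {p}")
        return files
    return [p]


def _load_models(path: Path):
    """Parse a PDB file with biotite, altlocs resolved by highest occupancy."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(
            model=None, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # biotite raises a zoo of exceptions
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureFormatError(f"{path}: no ATOM/HETATM records (line 1)")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    return stack


def read_structures(
    path_or_dir: str | Path,
    residue_whitelist: Sequence[str] = ("ATP",),
    capture_radius: float = 12.0,
) -> list[LigandComplex]:
    """Extract one :class:`LigandComplex` per (model, nucleotide copy) pair.

    Every model of every file yields independent instances; a nucleotide
    copy is kept when at least one Mg2+ ion lies within ``capture_radius``
    of any of its atoms.  Analogue atom names are mapped onto ATP naming.
    Instances missing any of PA, PB, PG, O3A, O3B are skipped with a
    warning.
    """
    whitelist = set(residue_whitelist)
    complexes: list[LigandComplex] = []
    for path in _iter_pdb_paths(path_or_dir):
        stack = _load_models(path)
        for model_idx in range(stack.stack_depth()):
            atoms = stack[model_idx]
            complexes.extend(
                _extract_from_model(atoms, path.stem, model_idx + 1, whitelist,
                                    capture_radius)
            )
    return complexes


def _extract_from_model(atoms, source: str, model_index: int,
                        whitelist: set[str], capture_radius: float
                        ) -> list[LigandComplex]:
    import biotite.structure as struc

    res_names = atoms.res_name
    occupancy = (atoms.occupancy if "occupancy" in atoms.get_annotation_categories()
                 else np.ones(atoms.array_length()))

    def record(i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(atoms.atom_name[i]),
            element=str(atoms.element[i]).capitalize(),
            residue_name=str(res_names[i]),
            chain_id=str(atoms.chain_id[i]),
            model_index=model_index,
            position=np.array(atoms.coord[i], dtype=float),
            occupancy=float(np.clip(occupancy[i], 0.0, 1.0)),
        )

    mg_idx = np.where((res_names == "MG") & (atoms.atom_name == "MG"))[0]
    cation_idx = np.where(np.isin(res_names, sorted(DIVALENT_CATIONS)))[0]

    out: list[LigandComplex] = []
    # one instance per nucleotide residue copy
    starts = struc.get_residue_starts(atoms)
    for s_i, start in enumerate(starts):
        stop = starts[s_i + 1] if s_i + 1 < len(starts) else atoms.array_length()
        rname = str(res_names[start])
        if rname not in whitelist:
            continue
        aliases = ANALOGUE_ALIASES.get(rname, {})
        atp_records = []
        for i in range(start, stop):
            rec = record(i)
            rec.atom_name = aliases.get(rec.atom_name, rec.atom_name)
            atp_records.append(rec)
        names = {a.atom_name for a in atp_records}
        missing = [n for n in REQUIRED_ATOMS if n not in names]
        if missing:
            logger.warning("%s model %d %s: skipping instance, missing %s",
                           source, model_index, rname, ",".join(missing))
            continue
        atp_coords = np.array([a.position for a in atp_records])
        if len(mg_idx) == 0:
            continue
        mg_d = np.array([
            np.min(np.linalg.norm(atp_coords - atoms.coord[i], axis=1))
            for i in mg_idx
        ])
        within = mg_idx[mg_d <= capture_radius]
        if len(within) == 0:
            continue
        chosen = within[np.argmin(mg_d[mg_d <= capture_radius])]
        cations = [
            record(i) for i in cation_idx
            if i != chosen
            and np.min(np.linalg.norm(atp_coords - atoms.coord[i], axis=1))
            <= capture_radius
        ]
        chain = str(atoms.chain_id[start])
        out.append(LigandComplex(
            source_id=f"{source}/m{model_index}/{chain}/{rname}",
            atp_atoms=atp_records,
            mg=record(chosen),
            nearby_divalent_cations=cations,
            metadata={"model": str(model_index), "chain": chain,
                      "residue": rname},
        ))
    return out


# ---------------------------------------------------------------------------
# Selection filters
# ---------------------------------------------------------------------------

def _phosphate_oxygen_positions(cx: LigandComplex) -> np.ndarray:
    names = [n for names in NON_BRIDGING_OXYGENS.values() for n in names]
    names += ["O3A", "O3B"]
    pos = [a.position for a in cx.atp_atoms if a.atom_name in names]
    return np.array(pos)


def filter_complexes(
    complexes: Iterable[LigandComplex],
    exclusion_radius: float = 8.0,
    coordination_radius: float = 3.0,
) -> tuple[list[LigandComplex], pd.DataFrame]:
    """Apply the two selection rules of the reference-set construction.

    A complex is retained when (a) no *second* divalent cation lies within
    ``exclusion_radius`` of any nucleotide atom, and (b) its Mg2+ ion lies
    within ``coordination_radius`` of at least one phosphate oxygen.

    Returns the retained complexes (input order preserved) and a per-complex
    table of pass/fail with rejection reasons.
    """
    if exclusion_radius <= 0 or coordination_radius <= 0:
        raise ValueError("radii must be positive")
    kept: list[LigandComplex] = []
    rows = []
    for cx in complexes:
        atp = np.array([a.position for a in cx.atp_atoms])
        reason = ""
        for cat in cx.nearby_divalent_cations:
            if np.min(np.linalg.norm(atp - cat.position, axis=1)) <= exclusion_radius:
                reason = (f"second divalent cation ({cat.residue_name}) within "
                          f"{exclusion_radius:g} A")
                break
        if not reason:
            oxy = _phosphate_oxygen_positions(cx)
            if oxy.size == 0:
                reason = "no phosphate oxygens present"
            else:
                dmin = float(np.min(np.linalg.norm(oxy - cx.mg.position, axis=1)))
                if dmin > coordination_radius:
                    reason = (f"nearest phosphate oxygen {dmin:.2f} A > "
                              f"{coordination_radius:g} A")
        passed = reason == ""
        rows.append({"source_id": cx.source_id, "passed": passed,
                     "reason": reason})
        if passed:
            kept.append(cx)
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coordination classification
# ---------------------------------------------------------------------------

def classify_coordination(
    cx: LigandComplex,
    cutoff: float = 3.0,
    c2_pa_threshold: float = 3.75,
    include_bridging: bool = False,
) -> CoordinationAssignment:
    """Assign the coordination mode of one complex.

    Group membership is decided from the minimum Mg2+ distance to the
    group's non-bridging oxygens (bridging O3A/O3B optionally included).
    """
    mg = cx.mg.position
    groups: set[str] = set()
    group_distances: dict[str, float] = {}
    for group in _GROUP_ORDER:
        names = list(NON_BRIDGING_OXYGENS[group])
        if include_bridging:
            names += list(BRIDGING_OXYGENS[group])
        pos = [a.position for a in cx.atp_atoms if a.atom_name in names]
        present = {a.atom_name for a in cx.atp_atoms} & set(NON_BRIDGING_OXYGENS[group])
        if not present:
            raise ClassificationError(
                f"{cx.source_id}: no non-bridging oxygens of group {group}")
        d = float(np.min(np.linalg.norm(np.array(pos) - mg, axis=1)))
        group_distances[group] = d
        if d <= cutoff:
            groups.add(group)
    try:
        pa = cx.atom("PA").position
    except KeyError:
        raise ClassificationError(f"{cx.source_id}: missing PA") from None
    mg_pa = float(np.linalg.norm(pa - mg))
    mode = _MODE_FROM_GROUPS[frozenset(groups)]
    if groups == {"alpha", "beta", "gamma"}:
        c2c3 = "C3"
    elif groups == {"beta", "gamma"} and mg_pa > c2_pa_threshold:
        c2c3 = "C2"
    else:
        c2c3 = "OTHER"
    return CoordinationAssignment(
        coordinated_groups=frozenset(groups),
        mode_label=mode,
        c2c3_label=c2c3,
        mg_pa_distance=mg_pa,
        group_distances=group_distances,
    )


def distance_only_c2(mg_pa_distance: float | np.ndarray,
                     threshold: float = 3.75) -> bool | np.ndarray:
    """Pure distance rule: Mg–Palpha beyond the threshold counts as C2.

    Used as a per-frame mask when reweighting simulation ensembles, where
    the full group-membership rule is unnecessarily strict.
    """
    return np.asarray(mg_pa_distance) > threshold if isinstance(
        mg_pa_distance, np.ndarray) else mg_pa_distance > threshold


def tabulate_modes(assignments: Sequence[CoordinationAssignment]) -> pd.DataFrame:
    """Count and fraction per coordination mode label."""
    if len(assignments) == 0:
        raise ValueError("no assignments to tabulate")
    labels = pd.Series([a.mode_label for a in assignments])
    counts = labels.value_counts()
    table = pd.DataFrame({"count": counts, "fraction": counts / len(labels)})
    table.index.name = "mode_label"
    assert math.isclose(table["fraction"].sum(), 1.0, abs_tol=1e-12)
    return table


def count_transitions(mode_series: Sequence[str]) -> TransitionCounts:
    """Count adjacent C2<->C3 changes in a label series, ignoring OTHER.

    OTHER frames are removed before counting, so a C3 ... OTHER ... C2
    excursion still counts as one transition.
    """
    cleaned = [m for m in mode_series if m != "OTHER"]
    bad = {m for m in mode_series} - {"C2", "C3", "OTHER"}
    if bad:
        raise ValueError(f"unknown labels in series: {sorted(bad)}")
    c3_to_c2 = c2_to_c3 = 0
    for a, b in zip(cleaned, cleaned[1:]):
        if a == "C3" and b == "C2":
            c3_to_c2 += 1
        elif a == "C2" and b == "C3":
            c2_to_c3 += 1
    return TransitionCounts(c3_to_c2 + c2_to_c3, c3_to_c2, c2_to_c3)


def mining_table(
    complexes: Sequence[LigandComplex],
    assignments: Sequence[CoordinationAssignment | None],
    filter_report: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per instance: identity, mode, C2/C3 label, Mg–Palpha distance."""
    rows = []
    report = (filter_report.set_index("source_id")
              if filter_report is not None else None)
    for cx, asn in zip(complexes, assignments):
        row = {
            "source_id": cx.source_id,
            "model": cx.metadata.get("model", ""),
            "chain": cx.metadata.get("chain", ""),
            "mode_label": asn.mode_label if asn else "",
            "c2c3": asn.c2c3_label if asn else "",
            "mg_pa_distance": asn.mg_pa_distance if asn else np.nan,
        }
        if report is not None and cx.source_id in report.index:
            row["passed"] = bool(report.loc[cx.source_id, "passed"])
            row["reason"] = str(report.loc[cx.source_id, "reason"])
        rows.append(row)
    return pd.DataFrame(rows)
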