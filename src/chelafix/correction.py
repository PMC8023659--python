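"""PDB-consistency offset correction of coordination free energies.

A force field's computed C3→C2 free-energy difference for an
ATP·Mg2+–protein complex predicts the coordination mode observed in the
crystal structure: positive favours C3, negative favours C2.  Systematic
force-field bias is modelled as a single additive offset applied to all
computed differences; the offset is fitted by maximizing the number of
complexes whose predicted sign matches the observed mode.  Because the
accuracy is piecewise constant in the offset, with breakpoints at −ΔG_i,
the optimum is a union of open intervals that can be found exactly.

Conventions: corrected ΔG(C3→C2) = uncorrected + offset.  When applied to
ensemble weights, a positive offset raises the free energy of C2 frames,
i.e. multiplies their weights by exp(−offset/kT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .mbar import TargetWeights

__all__ = [
    "ComplexDeltaG",
    "OffsetFit",
    "predict_mode",
    "fit_offset",
    "prediction_accuracy",
    "corrected_solution_dg",
    "apply_offset_to_weights",
    "records_to_table",
    "records_from_table",
    "load_reference_values",
]


@dataclass
class ComplexDeltaG:
    """Computed C3→C2 free energy for one complex with its observed mode."""

    complex_id: str
    delta_g_c3_to_c2: float          # kcal/mol
    uncertainty: float = 0.0         # kcal/mol
    observed_mode: str = "C3"        # "C2" or "C3"
    force_field_tag: str = ""

    def __post_init__(self) -> None:
        if self.observed_mode not in ("C2", "C3"):
            raise ValueError("observed_mode must be 'C2' or 'C3'")
        if not np.isfinite(self.delta_g_c3_to_c2):
            raise ValueError("delta_g must be finite")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass
class OffsetFit:
    """Result of the sign-consistency offset fit."""

    optimal_intervals: list[tuple[float, float]]
    chosen_interval: tuple[float, float]
    mean_offset: float
    n_correct: int
    n_total: int
    violations: dict[str, float] = field(default_factory=dict)
    tie_flagged: bool = False


def predict_mode(record: ComplexDeltaG, offset: float
                 ) -> tuple[str, bool]:
    """Sign rule: corrected ΔG > 0 predicts C3, < 0 predicts C2.

    Exact zeros are tie-broken to C3 and flagged (second return value).
    """
    corrected = record.delta_g_c3_to_c2 + offset
    if corrected > 0:
        return "C3", False
    if corrected < 0:
        return "C2", False
    return "C3", True


def prediction_accuracy(
    records: Sequence[ComplexDeltaG],
    offset: float,
    within_uncertainty: bool = False,
) -> tuple[int, int, dict[str, float]]:
    """Count sign-correct predictions at a given offset.

    Returns (n_correct, n_total, violations), where violations maps the
    id of each mispredicted complex to its signed corrected ΔG (the
    margin by which the sign rule fails).  With ``within_uncertainty``,
    a misprediction inside the record's own uncertainty of the boundary
    still counts as correct.
    """
    n_correct = 0
    violations: dict[str, float] = {}
    for rec in records:
        predicted, _tie = predict_mode(rec, offset)
        corrected = rec.delta_g_c3_to_c2 + offset
        ok = predicted == rec.observed_mode
        if not ok and within_uncertainty and abs(corrected) <= rec.uncertainty:
            ok = True
        if ok:
            n_correct += 1
        else:
            violations[rec.complex_id] = corrected
    return n_correct, len(records), violations


def fit_offset(records: Sequence[ComplexDeltaG],
               within_uncertainty: bool = False) -> OffsetFit:
    """Exact maximization of sign-prediction accuracy over the offset.

    Accuracy is piecewise constant with breakpoints at {−ΔG_i}; it is
    evaluated on every open segment between sorted breakpoints (and at
    the breakpoints themselves, where exact zeros tie-break to C3).
    All maximal open intervals of optimal accuracy are returned; the
    widest is chosen, ties going to the interval whose midpoint is
    smallest in absolute value.  Unbounded optimal intervals are kept,
    with a pseudo-midpoint one kcal/mol beyond the finite endpoint.
    """
    if len(records) == 0:
        raise ValueError("cannot fit an offset to an empty record list")
    labels = {r.observed_mode for r in records}
    if len(labels) < 2:
        import warnings
        warnings.warn("only one observed mode present; offset fit is "
                      "one-sided", stacklevel=2)

    breakpoints = np.unique([-r.delta_g_c3_to_c2 for r in records])
    # candidate offsets: one per open segment, plus each breakpoint
    seg_points = []
    lo_probe = breakpoints[0] - 1.0
    seg_points.append(lo_probe)
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        seg_points.append(0.5 * (a + b))
    seg_points.append(breakpoints[-1] + 1.0)

    def acc(off: float) -> int:
        return prediction_accuracy(records, off, within_uncertainty)[0]

    seg_acc = [acc(p) for p in seg_points]
    bp_acc = [acc(b) for b in breakpoints]
    best = max(seg_acc)

    # segments: (-inf, b0), (b0, b1), ..., (b(m-1), +inf)
    bounds = [(-np.inf, breakpoints[0])]
    bounds += list(zip(breakpoints[:-1], breakpoints[1:]))
    bounds.append((breakpoints[-1], np.inf))

    intervals: list[tuple[float, float]] = []
    i = 0
    m = len(bounds)
    while i < m:
        if seg_acc[i] == best:
            lo = bounds[i][0]
            j = i
            # merge across breakpoints that are themselves optimal
            while (j + 1 < m and seg_acc[j + 1] == best
                   and bp_acc[j] == best):
                j += 1
            intervals.append((lo, bounds[j][1]))
            i = j + 1
        else:
            i += 1

    def width(iv: tuple[float, float]) -> float:
        return iv[1] - iv[0]

    def midpoint(iv: tuple[float, float]) -> float:
        lo, hi = iv
        if np.isinf(lo) and np.isinf(hi):
            return 0.0
        if np.isinf(lo):
            return hi - 1.0
        if np.isinf(hi):
            return lo + 1.0
        return 0.5 * (lo + hi)

    chosen = min(intervals, key=lambda iv: (-width(iv), abs(midpoint(iv))))
    mid = midpoint(chosen)
    n_correct, n_total, violations = prediction_accuracy(
        records, mid, within_uncertainty)
    tie = any(predict_mode(r, mid)[1] for r in records)
    return OffsetFit(
        optimal_intervals=intervals,
        chosen_interval=chosen,
        mean_offset=mid,
        n_correct=n_correct,
        n_total=n_total,
        violations=violations,
        tie_flagged=tie,
    )


def corrected_solution_dg(uncorrected: float, offset: float) -> float:
    """Corrected solution ΔG(C3→C2) = uncorrected + offset (kcal/mol)."""
    return uncorrected + offset


def apply_offset_to_weights(
    weights: TargetWeights,
    c2_mask: np.ndarray,
    offset: float,
    kT: float,
) -> TargetWeights:
    """Reweight C2-labelled frames by exp(−offset/kT) and renormalize.

    ``c2_mask`` marks frames in C2 coordination (conventionally by the
    Mg–Palpha > 3.75 Å distance rule).  A positive offset raises the C2
    free energy, consistent with :func:`corrected_solution_dg`.
    """
    mask = np.asarray(c2_mask, dtype=bool)
    if mask.shape != weights.w_n.shape:
        raise ValueError("mask length does not match the weight vector")
    w = weights.w_n.copy()
    w[mask] *= np.exp(-offset / kT)
    w /= w.sum()
    return TargetWeights(w, target_state=weights.target_state + "+offset")


# ---------------------------------------------------------------------------
# Tables and packaged reference values
# ---------------------------------------------------------------------------

def records_to_table(records: Sequence[ComplexDeltaG]) -> pd.DataFrame:
    return pd.DataFrame([{
        "complex_id": r.complex_id,
        "dg": r.delta_g_c3_to_c2,
        "se": r.uncertainty,
        "observed_mode": r.observed_mode,
        "force_field": r.force_field_tag,
    } for r in records])


def records_from_table(table: pd.DataFrame) -> list[ComplexDeltaG]:
    return [
        ComplexDeltaG(
            complex_id=str(row["complex_id"]),
            delta_g_c3_to_c2=float(row["dg"]),
            uncertainty=float(row.get("se", 0.0) or 0.0),
            observed_mode=str(row["observed_mode"]),
            force_field_tag=str(row.get("force_field", "") or ""),
        )
        for _, row in table.iterrows()
    ]


def load_reference_values() -> dict:
    """Published solution ΔGs and fitted offset bounds for Amber/CHARMM."""
    text = resources.files("chelafix").joinpath("reference_values.yml").read_text()
    return yaml.safe_load(text)
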