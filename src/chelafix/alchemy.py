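"""Alchemical state construction for the extended-ensemble protocol.

The sampling problem for ATP4−·Mg2+ coordination is circumvented with a
nonphysical reduced-charge analogue, ATP2.5−·Mg0.5+: the cation charge is
lowered from +2 to +0.5 and the removed +1.5 is spread uniformly over the
13 phosphorus/oxygen atoms of the triphosphate, preserving the net charge
while flattening the electrostatic barriers between coordination modes.
Native, geometrically restrained subensembles are coupled to the common
reduced-charge state by a chain of lambda intermediates whose spacing is
tuned to equalize neighbour phase-space overlap (target: exchange
acceptance around one half along the chain).

This module builds charge sets, linear lambda interpolations, flat-bottom
coordination restraints, and the schedule-equalization loop.  It does not
run molecular dynamics; samples come from any object satisfying the small
sampler protocol (see :func:`equalize_schedule`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "ChargeSet",
    "FlatBottomTerm",
    "RestraintSpec",
    "StateSpec",
    "LambdaSchedule",
    "build_reduced_charge_state",
    "interpolate_state",
    "restraint_energy",
    "estimate_pair_acceptance",
    "equalize_schedule",
    "coordination_restraint",
    "charge_table",
    "NATIVE_TRIPHOSPHATE_CHARGES",
    "TRIPHOSPHATE_ATOMS",
]

#: The 13 phosphorus and oxygen atoms of the ATP triphosphate group.
TRIPHOSPHATE_ATOMS = (
    "PA", "O1A", "O2A", "O3A", "O5'",
    "PB", "O1B", "O2B", "O3B",
    "PG", "O1G", "O2G", "O3G",
)

#: Nominal point charges (e) for ATP4− triphosphate + Mg2+.  These are
#: illustrative partial charges summing to the formal values, not any
#: specific force field's parameters.
NATIVE_TRIPHOSPHATE_CHARGES: dict[str, float] = {
    "PA": 1.30, "PB": 1.30, "PG": 1.30,
    "O5'": -0.60, "O3A": -0.60, "O3B": -0.60,
    "O1A": -0.85, "O2A": -0.85, "O1B": -0.85, "O2B": -0.85,
    "O1G": -0.90, "O2G": -0.90, "O3G": -0.90,
    "MG": 2.00,
}


@dataclass
class ChargeSet:
    """Atom-id -> partial charge map (elementary charge units)."""

    charges: dict[str, float]

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges.values()))

    def __getitem__(self, atom_id: str) -> float:
        return self.charges[atom_id]


@dataclass(frozen=True)
class FlatBottomTerm:
    """Half-harmonic flat-bottom restraint on one distance coordinate.

    ``coordinate`` names the distance to evaluate: ``("group_min", g)`` is
    the minimum Mg distance to group g's non-bridging oxygens on a tail
    frame, ``("mg_pa",)`` the Mg–Palpha distance, and ``("scalar", key)``
    reads a precomputed coordinate from a mapping (the surrogate sampler's
    ``{"r": ...}``).
    """

    coordinate: tuple
    lower: float | None = None      # Å; None = no lower wall
    upper: float | None = None      # Å; None = no upper wall
    force_constant: float = 1000.0  # kcal/mol/Å^2

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None \
                and not self.lower < self.upper:
            raise ValueError("lower wall must be below upper wall")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")

    def energy(self, d):
        d = np.asarray(d, dtype=float)
        e = np.zeros_like(d)
        if self.lower is not None:
            dev = np.clip(self.lower - d, 0.0, None)
            e = e + 0.5 * self.force_constant * dev**2
        if self.upper is not None:
            dev = np.clip(d - self.upper, 0.0, None)
            e = e + 0.5 * self.force_constant * dev**2
        return e if e.ndim else float(e)


@dataclass(frozen=True)
class RestraintSpec:
    """A named set of flat-bottom terms confining one coordination mode."""

    mode: str
    terms: tuple[FlatBottomTerm, ...] = ()


@dataclass(frozen=True)
class StateSpec:
    """One extended-ensemble state: lambda plus optional restraint."""

    lam: float
    restraint: RestraintSpec | None = None
    charges: ChargeSet | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if not self.name:
            tag = self.restraint.mode if self.restraint else "free"
            object.__setattr__(self, "name", f"{tag}@{self.lam:.4f}")


@dataclass
class LambdaSchedule:
    """Sorted lambda values with predicted neighbour exchange acceptances."""

    lambdas: np.ndarray
    neighbor_acceptance: np.ndarray | None = None
    converged: bool = True
    rounds: int = 0

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("schedule endpoints must be exactly 0 and 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        self.lambdas = lam

    def to_json(self) -> str:
        return json.dumps({
            "lambdas": self.lambdas.tolist(),
            "neighbor_acceptance": (None if self.neighbor_acceptance is None
                                    else np.asarray(self.neighbor_acceptance).tolist()),
            "converged": bool(self.converged),
            "rounds": int(self.rounds),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LambdaSchedule":
        d = json.loads(text)
        acc = d.get("neighbor_acceptance")
        return cls(np.asarray(d["lambdas"]),
                   None if acc is None else np.asarray(acc),
                   d.get("converged", True), d.get("rounds", 0))


# ---------------------------------------------------------------------------
# Charge construction and interpolation
# ---------------------------------------------------------------------------

def build_reduced_charge_state(
    native: ChargeSet,
    triphosphate_atom_ids: Sequence[str] = TRIPHOSPHATE_ATOMS,
    cation_id: str = "MG",
    cation_target: float = 0.5,
    redistributed: float = 1.5,
) -> ChargeSet:
    """Reduce the cation charge and spread the remainder over the tail.

    The cation is set to ``cation_target`` (+0.5 by default) and
    ``redistributed`` (+1.5) is added uniformly over the 13 triphosphate
    atoms, so the net charge of the complex is preserved exactly.
    """
    ids = list(triphosphate_atom_ids)
    if len(ids) != 13:
        raise ValueError(f"expected 13 triphosphate atoms, got {len(ids)}")
    if cation_id in ids:
        raise ValueError("cation cannot be part of the triphosphate group")
    if cation_id not in native.charges:
        raise ValueError(f"cation {cation_id!r} not in charge set")
    missing = [i for i in ids if i not in native.charges]
    if missing:
        raise ValueError(f"atoms missing from charge set: {missing}")
    removed = native.charges[cation_id] - cation_target
    if not np.isclose(removed, redistributed):
        # the spread charge must exactly compensate the cation reduction
        raise ValueError(
            f"cation reduction ({removed:g}) != redistributed ({redistributed:g})")
    per_atom = redistributed / 13.0
    new = dict(native.charges)
    new[cation_id] = cation_target
    for i in ids:
        new[i] += per_atom
    return ChargeSet(new)


def interpolate_state(native: ChargeSet, reduced: ChargeSet,
                      lam: float) -> ChargeSet:
    """Linear charge interpolation q(lambda) = (1−λ) q_native + λ q_reduced."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if set(native.charges) != set(reduced.charges):
        raise ValueError("charge sets cover different atoms")
    if lam == 0.0:
        return ChargeSet(dict(native.charges))
    if lam == 1.0:
        return ChargeSet(dict(reduced.charges))
    return ChargeSet({
        k: (1.0 - lam) * native.charges[k] + lam * reduced.charges[k]
        for k in native.charges
    })


def charge_table(native: ChargeSet, reduced: ChargeSet):
    """Per-atom charge comparison as a DataFrame (atom_id, q_native, q_reduced)."""
    import pandas as pd

    return pd.DataFrame({
        "atom_id": list(native.charges),
        "q_native": [native.charges[k] for k in native.charges],
        "q_reduced": [reduced.charges[k] for k in native.charges],
    })


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

_GROUP_NONBRIDGING = {
    "alpha": ("O1A", "O2A"),
    "beta": ("O1B", "O2B"),
    "gamma": ("O1G", "O2G", "O3G"),
}


def coordination_restraint(
    mode: str,
    coordinated: Sequence[str],
    uncoordinated: Sequence[str] = (),
    upper_wall: float = 3.0,
    lower_wall: float = 3.75,
    force_constant: float = 1000.0,
) -> RestraintSpec:
    """Flat-bottom restraint confining a coordination permutation.

    Each coordinated group gets an upper wall on its minimum Mg–oxygen
    distance (default 3.0 Å); each explicitly uncoordinated group gets a
    lower wall (default 3.75 Å).
    """
    terms = [FlatBottomTerm(("group_min", g), upper=upper_wall,
                            force_constant=force_constant)
             for g in coordinated]
    terms += [FlatBottomTerm(("group_min", g), lower=lower_wall,
                             force_constant=force_constant)
              for g in uncoordinated]
    return RestraintSpec(mode=mode, terms=tuple(terms))


def _eval_coordinate(coord: tuple, frame) -> float | np.ndarray:
    kind = coord[0]
    if kind == "scalar":
        return frame[coord[1]]
    # tail-frame coordinates
    mg = frame.atom("MG")
    if kind == "mg_pa":
        return float(np.linalg.norm(mg - frame.atom("PA")))
    if kind == "group_min":
        names = _GROUP_NONBRIDGING[coord[1]]
        pos = [frame.all_phosphate_oxygens[n]
               for n in names if n in frame.all_phosphate_oxygens]
        if not pos:
            raise ValueError(f"frame lacks oxygens of group {coord[1]}")
        return float(np.min(np.linalg.norm(np.array(pos) - mg, axis=1)))
    raise ValueError(f"unknown coordinate kind {kind!r}")


def restraint_energy(spec: RestraintSpec | None, frame) -> float | np.ndarray:
    """Total flat-bottom energy of a restraint on one frame (kcal/mol).

    ``frame`` is a :class:`~chelafix.pca_landscape.TailFrame` or any
    mapping providing scalar coordinates (arrays allowed for vectorized
    evaluation of ``("scalar", ...)`` terms).
    """
    if spec is None or not spec.terms:
        return 0.0
    total = None
    for term in spec.terms:
        e = term.energy(_eval_coordinate(term.coordinate, frame))
        total = e if total is None else total + e
    return total


# ---------------------------------------------------------------------------
# Exchange acceptance and schedule equalization
# ---------------------------------------------------------------------------

def estimate_pair_acceptance(
    samples_i: np.ndarray,
    samples_j: np.ndarray,
    u_i: Callable[[np.ndarray], np.ndarray],
    u_j: Callable[[np.ndarray], np.ndarray],
    beta: float = 1.0,
) -> float:
    """Mean Metropolis exchange acceptance between two sampled states.

    Samples are paired (truncated to the shorter set) and the standard
    swap criterion min(1, exp(−β Δ)) is averaged, with
    Δ = u_i(x_j) + u_j(x_i) − u_i(x_i) − u_j(x_j).
    """
    xi = np.asarray(samples_i, dtype=float)
    xj = np.asarray(samples_j, dtype=float)
    if xi.shape[0] == 0 or xj.shape[0] == 0:
        raise ValueError("need at least one sample per state")
    m = min(xi.shape[0], xj.shape[0])
    xi, xj = xi[:m], xj[:m]
    delta = (np.asarray(u_i(xj)) + np.asarray(u_j(xi))
             - np.asarray(u_i(xi)) - np.asarray(u_j(xj)))
    return float(np.mean(np.minimum(1.0, np.exp(-beta * np.clip(delta, -700, 700)))))


class LambdaSampler(Protocol):
    """Protocol for objects that can sample and score arbitrary lambdas."""

    def sample(self, lam: float, n: int, rng: np.random.Generator
               ) -> np.ndarray: ...

    def reduced_energy(self, lam: float, samples: np.ndarray
                       ) -> np.ndarray: ...


def equalize_schedule(
    initial: LambdaSchedule,
    sampler: LambdaSampler,
    target_states: int = 21,
    tol: float = 0.05,
    max_rounds: int = 10,
    n_samples: int = 1000,
    seed: int | None = None,
) -> LambdaSchedule:
    """Iteratively re-space lambdas to equalize neighbour overlap.

    Each round samples every state, measures neighbour exchange
    acceptances a_i, and re-spaces the schedule by inverse interpolation
    of the cumulative resistance sum(1 − a_i), so every gap carries equal
    resistance.  Stops when the coefficient of variation of the neighbour
    acceptances drops to ``tol`` or after ``max_rounds``.
    """
    rng = np.random.default_rng(seed)
    lams = np.asarray(initial.lambdas, dtype=float)
    if target_states < 2:
        raise ValueError("need at least the two endpoint states")
    if target_states == 2:
        acc = _neighbor_acceptances(np.array([0.0, 1.0]), sampler, n_samples, rng)
        return LambdaSchedule(np.array([0.0, 1.0]), acc, True, 0)
    if len(lams) != target_states:
        frac = np.linspace(0.0, 1.0, target_states)
        lams = np.interp(frac, np.linspace(0.0, 1.0, len(lams)), lams)
        lams[0], lams[-1] = 0.0, 1.0
    acc = _neighbor_acceptances(lams, sampler, n_samples, rng)
    converged = _cv(acc) <= tol
    rounds = 0
    while not converged and rounds < max_rounds:
        rounds += 1
        resistance = np.clip(1.0 - acc, 1e-6, None)
        cum = np.concatenate([[0.0], np.cumsum(resistance)])
        targets = np.linspace(0.0, cum[-1], target_states)
        lams = np.interp(targets, cum, lams)
        lams[0], lams[-1] = 0.0, 1.0
        lams = np.maximum.accumulate(lams)  # guard against numerical ties
        if np.any(np.diff(lams) <= 0):
            eps = 1e-9
            lams = np.linspace(0, 1, target_states) * eps + lams * (1 - eps)
            lams[0], lams[-1] = 0.0, 1.0
        acc = _neighbor_acceptances(lams, sampler, n_samples, rng)
        converged = _cv(acc) <= tol
    return LambdaSchedule(lams, acc, converged, rounds)


def _cv(acc: np.ndarray) -> float:
    return float(np.std(acc) / np.mean(acc)) if np.mean(acc) > 0 else np.inf


def _neighbor_acceptances(lams: np.ndarray, sampler: LambdaSampler,
                          n: int, rng: np.random.Generator) -> np.ndarray:
    samples = [sampler.sample(l, n, rng) for l in lams]
    out = []
    for a, b, sa, sb in zip(lams[:-1], lams[1:], samples[:-1], samples[1:]):
        out.append(estimate_pair_acceptance(
            sa, sb,
            lambda x, l=a: sampler.reduced_energy(l, x),
            lambda x, l=b: sampler.reduced_energy(l, x),
            beta=1.0,
        ))
    return np.asarray(out)
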