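"""Synthetic inputs for the full coordination-analysis pipeline.

Three generators cover everything the pipeline consumes, with exactly
known ground truth throughout:

* idealized ATP·Mg2+ structures in each of the seven coordination
  permutations, written as PDB files (tetrahedral phosphate geometry,
  P–O 1.5/1.6 Å, target Mg–O 2.05 Å — construction constants, not claims
  about real structures);
* a surrogate extended-ensemble sampler over a 2D reaction coordinate
  (r = Mg–Palpha-like distance, theta = alpha–beta–gamma phosphate angle)
  plus a harmonic solvent-bath coordinate, with Hamiltonian replica
  exchange across the lambda chain and an exact quadrature oracle for all
  state free energies;
* C3→C2 free-energy datasets with observed coordination labels, an
  injected additive force-field bias and Gaussian noise, for exercising
  the offset-correction fit.

The surrogate emulates the *structure* of the sampling problem: at
lambda=0 (native charges) a high barrier separates the C3-like well near
r=3.3 Å from the C2-like well near 4.2 Å, so unbiased sampling stalls; at
lambda=1 (reduced charges) the barrier is low and both wells mix.  The
bath coordinate shifts linearly with lambda at fixed stiffness, standing
in for the solvent's response to charge scaling: it gives the chain a
realistic neighbour-overlap structure while contributing exactly zero to
every free-energy difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .alchemy import FlatBottomTerm, RestraintSpec, StateSpec, restraint_energy
from .correction import ComplexDeltaG
from .mbar import ReducedPotentialMatrix
from .pca_landscape import TailFrame
from .structure_mining import (
    AtomRecord,
    LigandComplex,
    classify_coordination,
)

__all__ = [
    "COORDINATION_MODES",
    "SurrogateSpec",
    "SampleArchive",
    "generate_toy_complex_pdb",
    "toy_ligand_complex",
    "toy_tail_frame",
    "generate_configuration_cloud",
    "surrogate_potential",
    "surrogate_reduced_energy",
    "default_state_chain",
    "default_swap_pairs",
    "sample_surrogate_ensemble",
    "quadrature_free_energies",
    "quadrature_bin_masses",
    "GridSampler",
    "generate_deltaG_dataset",
    "gaussian_pair_matrix",
]

COORDINATION_MODES = ("A", "B", "G", "AB", "AG", "BG", "ABG")

_MODE_GROUPS = {
    "A": {"alpha"}, "B": {"beta"}, "G": {"gamma"},
    "AB": {"alpha", "beta"}, "AG": {"alpha", "gamma"},
    "BG": {"beta", "gamma"}, "ABG": {"alpha", "beta", "gamma"},
}

#: Backbone alpha-beta-gamma phosphate angle used per mode (degrees).
#: Tridentate coordination requires a folded tail; bidentate beta-gamma is
#: built extended, mirroring the geometric trend of observed structures.
_MODE_PPP_ANGLE = {
    "ABG": 112.0, "BG": 155.0, "AB": 125.0, "AG": 105.0,
    "A": 140.0, "B": 140.0, "G": 140.0,
}

_NONBRIDGING = {
    "alpha": ("O1A", "O2A"),
    "beta": ("O1B", "O2B"),
    "gamma": ("O1G", "O2G", "O3G"),
}

_P_O_BRIDGE = 1.60   # Å
_P_O_TERM = 1.50     # Å
_P_P = 2.90          # Å
_MG_O = 2.05         # Å target coordination distance
_TETRA = np.degrees(np.arccos(-1.0 / 3.0))  # 109.47°


# ---------------------------------------------------------------------------
# Idealized ATP·Mg2+ structures
# ---------------------------------------------------------------------------

def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(v @ ref) > 0.9 * np.linalg.norm(v):
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _tetra_completion_2(b1: np.ndarray, b2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit directions completing a tetrahedron given two bond dirs."""
    u = -(b1 + b2)
    u /= np.linalg.norm(u)
    v = np.cross(b1, b2)
    v /= np.linalg.norm(v)
    h = np.radians(_TETRA / 2.0)
    return (u * np.cos(h) + v * np.sin(h), u * np.cos(h) - v * np.sin(h))


def _tetra_completion_1(b: np.ndarray) -> list[np.ndarray]:
    """Three unit directions completing a tetrahedron given one bond dir."""
    b = b / np.linalg.norm(b)
    p = _perp(b)
    q = np.cross(b, p)
    out = []
    for phi in (0.0, 120.0, 240.0):
        ang = np.radians(phi)
        lateral = np.cos(ang) * p + np.sin(ang) * q
        out.append(np.cos(np.radians(_TETRA)) * b
                   + np.sin(np.radians(_TETRA)) * lateral)
    return out


def _bridge_oxygen(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    mid = 0.5 * (p1 + p2)
    half = 0.5 * np.linalg.norm(p2 - p1)
    lift = np.sqrt(max(_P_O_BRIDGE**2 - half**2, 1e-9))
    return mid + np.array([0.0, 0.0, lift])


def triphosphate_template(ppp_angle_deg: float) -> dict[str, np.ndarray]:
    """Idealized triphosphate coordinates for a given P–P–P angle."""
    pb = np.zeros(3)
    pa = np.array([_P_P, 0.0, 0.0])
    ang = np.radians(ppp_angle_deg)
    pg = _P_P * np.array([np.cos(ang), np.sin(ang), 0.0])
    o3a = _bridge_oxygen(pa, pb)
    o3b = _bridge_oxygen(pb, pg)
    atoms = {"PA": pa, "PB": pb, "PG": pg, "O3A": o3a, "O3B": o3b}
    # O5' on PA: tetrahedral from the O3A bond, tilted away from PB
    b1 = (o3a - pa) / np.linalg.norm(o3a - pa)
    away = pa - pb
    away -= (away @ b1) * b1
    away /= np.linalg.norm(away)
    d_o5 = np.cos(np.radians(_TETRA)) * b1 + np.sin(np.radians(_TETRA)) * away
    atoms["O5'"] = pa + _P_O_BRIDGE * d_o5
    # PA non-bridging oxygens complete the {O3A, O5'} bonds
    b2 = (atoms["O5'"] - pa) / _P_O_BRIDGE
    d1, d2 = _tetra_completion_2(b1, b2)
    atoms["O1A"] = pa + _P_O_TERM * d1
    atoms["O2A"] = pa + _P_O_TERM * d2
    # PB non-bridging oxygens complete the two bridges
    c1 = (o3a - pb) / np.linalg.norm(o3a - pb)
    c2 = (o3b - pb) / np.linalg.norm(o3b - pb)
    d1, d2 = _tetra_completion_2(c1, c2)
    atoms["O1B"] = pb + _P_O_TERM * d1
    atoms["O2B"] = pb + _P_O_TERM * d2
    # PG terminal oxygens complete the single O3B bond
    g = (o3b - pg) / np.linalg.norm(o3b - pg)
    for name, d in zip(("O1G", "O2G", "O3G"), _tetra_completion_1(g)):
        atoms[name] = pg + _P_O_TERM * d
    return atoms


def _mg_objective(mg: np.ndarray, atoms: dict[str, np.ndarray],
                  coordinated: set[str], mode: str) -> float:
    cost = 0.0
    for group in ("alpha", "beta", "gamma"):
        pos = np.array([atoms[n] for n in _NONBRIDGING[group]])
        d = np.min(np.linalg.norm(pos - mg, axis=1))
        if group in coordinated:
            cost += (d - _MG_O) ** 2
        else:
            cost += 6.0 * max(0.0, 3.6 - d) ** 2
    if mode == "BG":
        cost += 6.0 * max(0.0, 4.1 - np.linalg.norm(mg - atoms["PA"])) ** 2
    # steric: keep Mg off phosphorus and bridging oxygens
    for name in ("PA", "PB", "PG", "O3A", "O3B", "O5'"):
        cost += 2.0 * max(0.0, 2.4 - np.linalg.norm(mg - atoms[name])) ** 2
    return cost


_MG_CACHE: dict[str, np.ndarray] = {}


def _place_mg(atoms: dict[str, np.ndarray], mode: str) -> np.ndarray:
    if mode in _MG_CACHE:
        return _MG_CACHE[mode]
    coordinated = _MODE_GROUPS[mode]
    targets = np.array([atoms[n] for g in coordinated for n in _NONBRIDGING[g]])
    center = targets.mean(axis=0)
    starts = [center + d for d in (
        np.array([0.0, 0.0, -2.0]), np.array([0.0, 0.0, 2.0]),
        np.array([0.0, -2.0, 0.0]), np.array([0.0, 2.0, 0.0]),
        np.array([-2.0, 0.0, 0.0]), np.array([2.0, 0.0, 0.0]),
        np.zeros(3),
    )]
    best, best_val = None, np.inf
    for s in starts:
        res = minimize(_mg_objective, s, args=(atoms, coordinated, mode),
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12})
        if res.fun < best_val - 1e-12:
            best, best_val = res.x, res.fun
    _MG_CACHE[mode] = np.asarray(best)
    return _MG_CACHE[mode]


def _toy_coordinates(mode: str) -> dict[str, np.ndarray]:
    if mode not in COORDINATION_MODES:
        raise ValueError(f"unknown coordination mode {mode!r}")
    atoms = triphosphate_template(_MODE_PPP_ANGLE[mode])
    atoms = dict(atoms)
    atoms["MG"] = _place_mg({k: v for k, v in atoms.items()}, mode)
    return atoms


def toy_ligand_complex(mode: str, jitter_sd: float = 0.0,
                       rng: np.random.Generator | None = None,
                       source_id: str | None = None) -> LigandComplex:
    """In-memory ATP·Mg2+ instance realizing one coordination mode."""
    atoms = _toy_coordinates(mode)
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        atoms = {k: v + rng.normal(0.0, jitter_sd, 3) for k, v in atoms.items()}
    atp = [
        AtomRecord(atom_name=n, element="P" if n.startswith("P") else "O",
                   residue_name="ATP", chain_id="A", model_index=1,
                   position=p)
        for n, p in atoms.items() if n != "MG"
    ]
    mg = AtomRecord(atom_name="MG", element="Mg", residue_name="MG",
                    chain_id="A", model_index=1, position=atoms["MG"])
    return LigandComplex(
        source_id=source_id or f"toy-{mode}", atp_atoms=atp, mg=mg,
        metadata={"mode": mode, "jitter_sd": f"{jitter_sd:g}"},
    )


def toy_tail_frame(mode: str, jitter_sd: float = 0.0,
                   rng: np.random.Generator | None = None,
                   rigid_motion: bool = False) -> TailFrame:
    """Tail frame of a toy complex, optionally under a random rigid motion."""
    from .pca_landscape import extract_tail_frame

    frame = extract_tail_frame(toy_ligand_complex(mode, jitter_sd, rng))
    if rigid_motion:
        if rng is None:
            rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        t = rng.uniform(-20.0, 20.0, 3)
        frame = TailFrame(
            frame.six_atom_coords @ R.T + t,
            {k: v @ R.T + t for k, v in frame.all_phosphate_oxygens.items()},
            frame.weight,
        )
    return frame


def generate_toy_complex_pdb(mode: str, jitter_sd: float = 0.0,
                             seed: int = 0, path: str | Path = "toy.pdb"
                             ) -> Path:
    """Write a valid PDB file realizing one coordination mode.

    At ``jitter_sd=0`` the file round-trips exactly through reading and
    classification; Gaussian positional noise (same seed, same bytes) may
    break the mode at large amplitudes.
    """
    import biotite.structure as struc
    from biotite.structure.io import pdb as pdbio

    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    atoms = _toy_coordinates(mode)
    atoms = {k: v + (rng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else 0.0)
             for k, v in atoms.items()}
    names = [n for n in atoms if n != "MG"]
    arr = struc.AtomArray(len(names) + 1)
    for i, n in enumerate(names):
        arr.coord[i] = atoms[n]
        arr.atom_name[i] = n
        arr.res_name[i] = "ATP"
        arr.res_id[i] = 1
        arr.chain_id[i] = "A"
        arr.element[i] = "P" if n.startswith("P") else "O"
        arr.hetero[i] = True
    arr.coord[-1] = atoms["MG"]
    arr.atom_name[-1] = "MG"
    arr.res_name[-1] = "MG"
    arr.res_id[-1] = 2
    arr.chain_id[-1] = "A"
    arr.element[-1] = "MG"
    arr.hetero[-1] = True
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    path = Path(path)
    pdb_file.write(str(path))
    return path


def generate_configuration_cloud(
    n_per_mode: int = 500,
    modes: Sequence[str] = ("BG", "ABG"),
    jitter_sd: float = 0.15,
    seed: int = 0,
) -> tuple[list[TailFrame], list[str]]:
    """Mixed cloud of jittered, rigidly scattered tail frames with labels.

    Labels are the C2/C3 class of the generating mode (``BG`` → C2,
    ``ABG`` → C3, anything else OTHER).
    """
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    label_of = {"BG": "C2", "ABG": "C3"}
    for mode in modes:
        for _ in range(n_per_mode):
            frames.append(toy_tail_frame(mode, jitter_sd, rng,
                                         rigid_motion=True))
            labels.append(label_of.get(mode, "OTHER"))
    return frames, labels


# ---------------------------------------------------------------------------
# Surrogate extended ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of the 2D double-well surrogate plus solvent bath.

    Distances in Å, angles in degrees, energies in kcal/mol.  The barrier
    scales with lambda as B(λ) = barrier_native (1 − λ s), where
    s = 1 − barrier_reduced/barrier_native is the effective
    charge-reduction factor; the bath center shifts by bath_shift·λ at
    constant stiffness kT/bath_sigma², so the bath changes neighbour
    overlap but no free-energy difference.
    """

    r_c3: float = 3.3
    r_c2: float = 4.2
    r_barrier: float = 3.75
    well_depth_c3: float = 2.0
    well_depth_c2: float = 2.0
    barrier_native: float = 8.0
    barrier_reduced: float = 1.0
    well_width: float = 0.18
    barrier_width: float = 0.14
    switch_width: float = 0.10
    theta_c3: float = 112.0
    theta_c2: float = 155.0
    k_theta: float = 0.004          # kcal/mol/deg^2
    temperature: float = 300.0      # K
    bath_sigma: float = 1.0
    bath_shift: float = 19.1
    wall_height: float = 60.0
    wall_halfwidth: float = 1.7     # Å from r_barrier where the wall bites

    @property
    def kT(self) -> float:
        return 0.0019872041 * self.temperature

    @property
    def charge_reduction_factor(self) -> float:
        return 1.0 - self.barrier_reduced / self.barrier_native

    def barrier(self, lam) -> np.ndarray | float:
        return self.barrier_native * (1.0 - np.asarray(lam)
                                      * self.charge_reduction_factor)

    def __post_init__(self) -> None:
        if self.barrier_native < self.barrier_reduced:
            raise ValueError("reduced-charge barrier must be the lower one")
        if self.barrier_reduced < 0:
            raise ValueError("barrier height must be non-negative")


def _switch(spec: SurrogateSpec, r) -> np.ndarray:
    """0 in the C3 well, 1 in the C2 well, smooth across the barrier."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(r, dtype=float)
                                 - spec.r_barrier) / spec.switch_width))


def surrogate_potential(spec: SurrogateSpec, r, theta, lam=0.0):
    """2D potential U(r, theta; lambda) in kcal/mol (bath excluded)."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    u = (-spec.well_depth_c3
         * np.exp(-((r - spec.r_c3) ** 2) / (2 * spec.well_width**2))
         - spec.well_depth_c2
         * np.exp(-((r - spec.r_c2) ** 2) / (2 * spec.well_width**2))
         + spec.barrier(lam)
         * np.exp(-((r - spec.r_barrier) ** 2) / (2 * spec.barrier_width**2)))
    u = u + spec.wall_height * ((r - spec.r_barrier) / spec.wall_halfwidth) ** 10
    w = _switch(spec, r)
    theta0 = spec.theta_c3 + (spec.theta_c2 - spec.theta_c3) * w
    u = u + 0.5 * spec.k_theta * (theta - theta0) ** 2
    return u


def _bath_reduced(spec: SurrogateSpec, h, lam):
    mu = spec.bath_shift * np.asarray(lam, dtype=float)
    return ((np.asarray(h, dtype=float) - mu) ** 2) / (2 * spec.bath_sigma**2)


def surrogate_reduced_energy(spec: SurrogateSpec, state: StateSpec,
                             r, theta, h=None):
    """Dimensionless reduced potential of one state (restraint + bath)."""
    u = surrogate_potential(spec, r, theta, state.lam) / spec.kT
    if state.restraint is not None:
        u = u + restraint_energy(state.restraint, {"r": np.asarray(r)}) / spec.kT
    if h is not None:
        u = u + _bath_reduced(spec, h, state.lam)
    return u


def default_state_chain(spec: SurrogateSpec | None = None,
                        n_lambda: int = 21,
                        restrained_ends: bool = True,
                        restraint_k: float = 100.0
                        ) -> list[StateSpec]:
    """The standard extended ensemble: lambda chain + restrained ends.

    States 0..n_lambda−1 are the unrestrained chain from native (λ=0) to
    reduced-charge (λ=1); two geometrically restrained native states (C3:
    r upper wall 3.6 Å; C2: r lower wall 3.9 Å) are appended.
    """
    lams = np.linspace(0.0, 1.0, n_lambda)
    states = [StateSpec(lam=float(l)) for l in lams]
    if restrained_ends:
        c3 = RestraintSpec("C3", (FlatBottomTerm(("scalar", "r"), upper=3.6,
                                                 force_constant=restraint_k),))
        c2 = RestraintSpec("C2", (FlatBottomTerm(("scalar", "r"), lower=3.9,
                                                 force_constant=restraint_k),))
        states.append(StateSpec(lam=0.0, restraint=c3))
        states.append(StateSpec(lam=0.0, restraint=c2))
    return states


def default_swap_pairs(states: Sequence[StateSpec]) -> list[tuple[int, int]]:
    """Replica-exchange pairs: the lambda chain plus restrained attachments.

    Unrestrained states are chained in lambda order; every restrained
    state is paired with the unrestrained state closest in lambda.
    """
    free = [(i, s.lam) for i, s in enumerate(states) if s.restraint is None]
    free.sort(key=lambda t: t[1])
    pairs = [(free[i][0], free[i + 1][0]) for i in range(len(free) - 1)]
    for i, s in enumerate(states):
        if s.restraint is not None:
            j = min(free, key=lambda t: abs(t[1] - s.lam))[0]
            pairs.append((i, j))
    return pairs


@dataclass
class SampleArchive:
    """Per-state samples plus the reduced-potential matrix across states."""

    spec: SurrogateSpec
    states: list[StateSpec]
    coords: np.ndarray          # (K, n, 3): r, theta, h
    u_kn: np.ndarray            # (K, K*n)
    seed: int
    move_acceptance: np.ndarray
    swap_acceptance: dict[tuple[int, int], float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.coords.shape[0]

    @property
    def n_per_state(self) -> int:
        return self.coords.shape[1]

    @property
    def samples_flat(self) -> np.ndarray:
        """All samples in state-block order, shape (K*n, 3)."""
        return self.coords.reshape(-1, 3)

    def matrix(self) -> ReducedPotentialMatrix:
        names = [s.name for s in self.states]
        N_k = np.full(self.n_states, self.n_per_state)
        return ReducedPotentialMatrix(self.u_kn, N_k, names)

    def recompute_u_kn(self) -> np.ndarray:
        x = self.samples_flat
        u = np.empty((self.n_states, x.shape[0]))
        for k, s in enumerate(self.states):
            u[k] = surrogate_reduced_energy(self.spec, s, x[:, 0], x[:, 1],
                                            x[:, 2])
        return u

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, coords=self.coords, u_kn=self.u_kn,
                            move_acceptance=self.move_acceptance)
        sidecar = {
            "seed": int(self.seed),
            "spec": {k: getattr(self.spec, k)
                     for k in self.spec.__dataclass_fields__},
            "states": [{"lam": s.lam, "name": s.name,
                        "restraint": None if s.restraint is None else {
                            "mode": s.restraint.mode,
                            "terms": [{"coordinate": list(t.coordinate),
                                       "lower": t.lower, "upper": t.upper,
                                       "k": t.force_constant}
                                      for t in s.restraint.terms]}}
                       for s in self.states],
            "warnings": self.warnings_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SampleArchive":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz"
                       else path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = SurrogateSpec(**sidecar["spec"])
        states = []
        for sd in sidecar["states"]:
            restraint = None
            if sd["restraint"] is not None:
                terms = tuple(
                    FlatBottomTerm(tuple(t["coordinate"]), lower=t["lower"],
                                   upper=t["upper"], force_constant=t["k"])
                    for t in sd["restraint"]["terms"])
                restraint = RestraintSpec(sd["restraint"]["mode"], terms)
            states.append(StateSpec(lam=sd["lam"], restraint=restraint,
                                    name=sd["name"]))
        return cls(spec=spec, states=states, coords=data["coords"],
                   u_kn=data["u_kn"], seed=sidecar["seed"],
                   move_acceptance=data["move_acceptance"],
                   warnings_=list(sidecar.get("warnings", [])))


def _state_arrays(spec: SurrogateSpec, states: Sequence[StateSpec]):
    lam = np.array([s.lam for s in states])
    lower = np.full(len(states), -np.inf)
    upper = np.full(len(states), np.inf)
    kres = np.zeros(len(states))
    for i, s in enumerate(states):
        if s.restraint is None:
            continue
        for t in s.restraint.terms:
            if t.coordinate != ("scalar", "r"):
                raise ValueError("surrogate restraints must act on r")
            if t.lower is not None:
                lower[i] = t.lower
            if t.upper is not None:
                upper[i] = t.upper
            kres[i] = t.force_constant
    return lam, lower, upper, kres


def _u_vec(spec: SurrogateSpec, lam, lower, upper, kres, r, theta, h):
    """Vectorized reduced energy; state parameters broadcast against coords."""
    u = surrogate_potential(spec, r, theta, lam) / spec.kT
    dev_lo = np.clip(lower - r, 0.0, None)
    dev_hi = np.clip(r - upper, 0.0, None)
    dev_lo = np.where(np.isfinite(dev_lo), dev_lo, 0.0)
    dev_hi = np.where(np.isfinite(dev_hi), dev_hi, 0.0)
    u = u + 0.5 * kres * (dev_lo**2 + dev_hi**2) / spec.kT
    return u + _bath_reduced(spec, h, lam)


def sample_surrogate_ensemble(
    spec: SurrogateSpec,
    states: Sequence[StateSpec],
    n_per_state: int,
    seed: int = 0,
    n_equil_sweeps: int = 2000,
    thin: int = 10,
    step_r: float = 0.18,
    step_theta: float = 9.0,
    step_h: float = 0.8,
    swap_pairs: Sequence[tuple[int, int]] | None = None,
    swap_rounds: int = 3,
) -> SampleArchive:
    """Hamiltonian-replica-exchange Metropolis sampling of all states.

    Every sweep proposes one Gaussian move per replica (accepted by the
    Metropolis rule under that replica's own reduced potential) and then
    attempts one partition of neighbour swaps, cycling through a conflict-
    free partition of the swap-pair list.  Samples are recorded every
    ``thin`` sweeps after ``n_equil_sweeps``; u_kn is then evaluated for
    every sample under every state.
    """
    if n_per_state < 100:
        raise ValueError("n_per_state must be at least 100")
    states = list(states)
    K = len(states)
    rng = np.random.default_rng(seed)
    lam, lower, upper, kres = _state_arrays(spec, states)
    if swap_pairs is None:
        swap_pairs = default_swap_pairs(states)
    partitions = _partition_pairs(swap_pairs)

    # initial configuration: alternate wells along the chain to halve the
    # equilibration burden; restrained states start inside their window
    r = np.where(np.arange(K) % 2 == 0, spec.r_c3, spec.r_c2)
    r[np.isfinite(upper)] = spec.r_c3
    r[np.isfinite(lower)] = spec.r_c2
    theta = np.where(r > spec.r_barrier, spec.theta_c2, spec.theta_c3)
    h = spec.bath_shift * lam
    u_cur = _u_vec(spec, lam, lower, upper, kres, r, theta, h)

    n_sweeps = n_equil_sweeps + n_per_state * thin
    coords = np.empty((K, n_per_state, 3))
    n_acc = np.zeros(K)
    swap_att: dict[tuple[int, int], list[int]] = {tuple(p): [0, 0]
                                                 for p in swap_pairs}
    rec = 0
    for sweep in range(n_sweeps):
        # Metropolis displacement move, all replicas at once
        r_new = r + rng.normal(0.0, step_r, K)
        th_new = theta + rng.normal(0.0, step_theta, K)
        h_new = h + rng.normal(0.0, step_h, K)
        u_new = _u_vec(spec, lam, lower, upper, kres, r_new, th_new, h_new)
        accept = np.log(rng.random(K)) < -(u_new - u_cur)
        r = np.where(accept, r_new, r)
        theta = np.where(accept, th_new, theta)
        h = np.where(accept, h_new, h)
        u_cur = np.where(accept, u_new, u_cur)
        n_acc += accept

        # replica exchange over every conflict-free partition; several
        # rounds per sweep speed up replica diffusion along the ladder
        for part in partitions * swap_rounds:
            if not part:
                continue
            ia = np.array([p[0] for p in part])
            ib = np.array([p[1] for p in part])
            ua_xb = _u_vec(spec, lam[ia], lower[ia], upper[ia], kres[ia],
                           r[ib], theta[ib], h[ib])
            ub_xa = _u_vec(spec, lam[ib], lower[ib], upper[ib], kres[ib],
                           r[ia], theta[ia], h[ia])
            delta = ua_xb + ub_xa - u_cur[ia] - u_cur[ib]
            do_swap = np.log(rng.random(len(part))) < -delta
            for p, sw in zip(part, do_swap):
                swap_att[tuple(p)][0] += int(sw)
                swap_att[tuple(p)][1] += 1
            sa, sb = ia[do_swap], ib[do_swap]
            r[sa], r[sb] = r[sb].copy(), r[sa].copy()
            theta[sa], theta[sb] = theta[sb].copy(), theta[sa].copy()
            h[sa], h[sb] = h[sb].copy(), h[sa].copy()
            u_cur[sa], u_cur[sb] = ua_xb[do_swap], ub_xa[do_swap]

        if sweep >= n_equil_sweeps and (sweep - n_equil_sweeps) % thin == 0 \
                and rec < n_per_state:
            coords[:, rec, 0] = r
            coords[:, rec, 1] = theta
            coords[:, rec, 2] = h
            rec += 1

    move_acc = n_acc / n_sweeps
    warn: list[str] = []
    if np.any(move_acc < 0.01):
        bad = [states[i].name for i in np.where(move_acc < 0.01)[0]]
        warn.append(f"move acceptance below 1% for states: {bad}")
        warnings.warn(warn[-1], stacklevel=2)

    archive = SampleArchive(
        spec=spec, states=states, coords=coords,
        u_kn=np.empty((K, K * n_per_state)), seed=seed,
        move_acceptance=move_acc,
        swap_acceptance={p: (a / t if t else np.nan)
                         for p, (a, t) in swap_att.items()},
        warnings_=warn,
    )
    archive.u_kn = archive.recompute_u_kn()
    return archive


def _partition_pairs(pairs: Sequence[tuple[int, int]]
                     ) -> list[list[tuple[int, int]]]:
    """Greedy conflict-free partition of swap pairs (shared-state safe)."""
    remaining = [tuple(p) for p in pairs]
    partitions: list[list[tuple[int, int]]] = []
    while remaining:
        used: set[int] = set()
        group: list[tuple[int, int]] = []
        rest: list[tuple[int, int]] = []
        for p in remaining:
            if p[0] in used or p[1] in used:
                rest.append(p)
            else:
                group.append(p)
                used.update(p)
        partitions.append(group)
        remaining = rest
    return partitions


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------

def _quadrature_grid(spec: SurrogateSpec, n_r: int, n_theta: int,
                     r_range: tuple[float, float],
                     theta_range: tuple[float, float]):
    r = np.linspace(*r_range, n_r)
    th = np.linspace(*theta_range, n_theta)
    return np.meshgrid(r, th, indexing="ij")


def quadrature_free_energies(
    spec: SurrogateSpec,
    states: Sequence[StateSpec],
    n_r: int = 801,
    n_theta: int = 601,
    r_range: tuple[float, float] = (2.0, 6.2),
    theta_range: tuple[float, float] = (20.0, 260.0),
    check_convergence: bool = False,
) -> np.ndarray:
    """Exact dimensionless state free energies by 2D midpoint quadrature.

    f_k = −ln Σ exp(−u_k) ΔA relative to state 0.  The bath coordinate
    integrates to the same constant in every state and is omitted.  Raises
    if the Boltzmann density does not vanish at the grid boundary; with
    ``check_convergence`` the resolution is doubled and agreement to 1e-6
    is enforced.
    """
    def compute(nr: int, nth: int) -> np.ndarray:
        gr, gth = _quadrature_grid(spec, nr, nth, r_range, theta_range)
        dA = (gr[1, 0] - gr[0, 0]) * (gth[0, 1] - gth[0, 0])
        f = np.empty(len(states))
        for k, s in enumerate(states):
            u = surrogate_reduced_energy(spec, s, gr, gth)
            u_min = u.min()
            boltz = np.exp(-(u - u_min))
            edge = max(boltz[0].max(), boltz[-1].max(),
                       boltz[:, 0].max(), boltz[:, -1].max())
            if edge > 1e-12 * boltz.max():
                raise ValueError(
                    f"quadrature support truncated for state {s.name}")
            f[k] = -(np.log(boltz.sum() * dA) - u_min)
        return f - f[0]

    f = compute(n_r, n_theta)
    if check_convergence:
        f2 = compute(2 * n_r - 1, 2 * n_theta - 1)
        if np.max(np.abs(f2 - f)) >= 1e-6:
            raise ValueError("quadrature not converged at this resolution")
        f = f2
    return f


def quadrature_bin_masses(
    spec: SurrogateSpec,
    state: StateSpec,
    r_edges: np.ndarray,
    theta_edges: np.ndarray,
    oversample: int = 8,
) -> np.ndarray:
    """Exact normalized Boltzmann mass of ``state`` in each 2D bin."""
    r_fine = _subdivide(r_edges, oversample)
    th_fine = _subdivide(theta_edges, oversample)
    gr, gth = np.meshgrid(r_fine, th_fine, indexing="ij")
    u = surrogate_reduced_energy(spec, state, gr, gth)
    boltz = np.exp(-(u - u.min()))
    mass, _, _ = np.histogram2d(gr.ravel(), gth.ravel(),
                                bins=[r_edges, theta_edges],
                                weights=boltz.ravel())
    total = boltz.sum()
    return mass / total


def _subdivide(edges: np.ndarray, oversample: int) -> np.ndarray:
    pts = []
    for a, b in zip(edges[:-1], edges[1:]):
        step = (b - a) / oversample
        pts.append(a + step * (np.arange(oversample) + 0.5))
    return np.concatenate(pts)


class GridSampler:
    """Exact independent sampler of the surrogate at arbitrary lambda.

    Draws (r, theta) from the 2D Boltzmann density on a fine grid (with
    uniform in-cell placement) and the bath coordinate from its exact
    Gaussian.  Satisfies the sampler protocol of
    :func:`chelafix.alchemy.equalize_schedule`.
    """

    def __init__(self, spec: SurrogateSpec, n_r: int = 481, n_theta: int = 321,
                 r_range: tuple[float, float] = (2.0, 6.2),
                 theta_range: tuple[float, float] = (20.0, 260.0)):
        self.spec = spec
        self.r = np.linspace(*r_range, n_r)
        self.theta = np.linspace(*theta_range, n_theta)
        self.dr = self.r[1] - self.r[0]
        self.dth = self.theta[1] - self.theta[0]
        self._gr, self._gth = np.meshgrid(self.r, self.theta, indexing="ij")
        self._cache: dict[float, np.ndarray] = {}

    def _probs(self, lam: float) -> np.ndarray:
        key = round(float(lam), 12)
        if key not in self._cache:
            u = surrogate_potential(self.spec, self._gr, self._gth, lam) \
                / self.spec.kT
            p = np.exp(-(u - u.min())).ravel()
            self._cache[key] = p / p.sum()
        return self._cache[key]

    def sample(self, lam: float, n: int, rng: np.random.Generator
               ) -> np.ndarray:
        p = self._probs(lam)
        idx = rng.choice(p.size, size=n, p=p)
        i, j = np.unravel_index(idx, self._gr.shape)
        r = self.r[i] + rng.uniform(-0.5, 0.5, n) * self.dr
        th = self.theta[j] + rng.uniform(-0.5, 0.5, n) * self.dth
        h = self.spec.bath_shift * lam \
            + rng.normal(0.0, self.spec.bath_sigma, n)
        return np.column_stack([r, th, h])

    def reduced_energy(self, lam: float, samples: np.ndarray) -> np.ndarray:
        x = np.asarray(samples)
        u = surrogate_potential(self.spec, x[:, 0], x[:, 1], lam) / self.spec.kT
        return u + _bath_reduced(self.spec, x[:, 2], lam)


# ---------------------------------------------------------------------------
# ΔG-vs-label datasets and analytic test matrices
# ---------------------------------------------------------------------------

def generate_deltaG_dataset(
    n: int = 30,
    true_bias: float = 6.1,
    margin_range: tuple[float, float] = (0.5, 8.0),
    noise_sd: float = 1.0,
    c2_fraction: float = 13.0 / 30.0,
    seed: int | None = None,
) -> tuple[list[ComplexDeltaG], "pd.DataFrame"]:
    """Label-consistent ΔG dataset with an injected additive bias.

    Each complex gets a base ΔG(C3→C2) of +margin (C3-labelled) or
    −margin (C2-labelled), margin ~ Uniform(margin_range); the observed
    value adds ``true_bias`` and Gaussian noise.  Fitting the offset on
    the result should recover approximately −true_bias.  The number of
    C2 labels is fixed by deterministic rounding of ``c2_fraction``.
    """
    import pandas as pd

    if n < 2:
        raise ValueError("need at least two complexes")
    if not 0.0 < c2_fraction < 1.0:
        raise ValueError("c2_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_c2 = int(round(n * c2_fraction))
    labels = np.array(["C2"] * n_c2 + ["C3"] * (n - n_c2))
    labels = labels[rng.permutation(n)]
    margins = rng.uniform(*margin_range, n)
    base = np.where(labels == "C3", margins, -margins)
    noise = rng.normal(0.0, noise_sd, n)
    observed = base + true_bias + noise
    records = [
        ComplexDeltaG(complex_id=f"syn{i:03d}",
                      delta_g_c3_to_c2=float(observed[i]),
                      uncertainty=noise_sd,
                      observed_mode=str(labels[i]),
                      force_field_tag="synthetic")
        for i in range(n)
    ]
    truth = pd.DataFrame({
        "complex_id": [r.complex_id for r in records],
        "observed_mode": labels,
        "base_dg": base,
        "margin": margins,
        "true_bias": true_bias,
        "noise": noise,
    })
    return records, truth


def gaussian_pair_matrix(n_per_state: int = 10000,
                         sigmas: tuple[float, float] = (1.0, 2.0),
                         seed: int = 0
                         ) -> tuple[ReducedPotentialMatrix, float]:
    """Two harmonic states with widths sigma1, sigma2; exact Δf known.

    u_k(x) = x² / (2 σ_k²), so Δf = f_2 − f_1 = −ln(σ2/σ1).
    Returns the reduced-potential matrix and the exact Δf.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = sigmas
    x = np.concatenate([rng.normal(0.0, s1, n_per_state),
                        rng.normal(0.0, s2, n_per_state)])
    u_kn = np.vstack([x**2 / (2 * s1**2), x**2 / (2 * s2**2)])
    mat = ReducedPotentialMatrix(u_kn, np.array([n_per_state, n_per_state]),
                                 ["narrow", "wide"])
    return mat, float(-np.log(s2 / s1))
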