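"""Synthetic ensembles with analytically known ground truth.

Everything the analysis pipeline consumes can be generated here: a
parameterized toy chain topology, Cartesian coordinates built from
internal coordinates (fixed bond lengths and angles, free torsions),
i.i.d. ensembles whose per-torsion distributions are prescribed (fixed /
uniform / von Mises), a metal-ion site with a controlled expected count of
in-shell waters, and two-state systems whose entropy difference is known
in closed form.

Torsions are sampled independently, matching the independence assumption
of the histogram entropy estimator, so analytic totals are exact sums of
per-torsion closed forms:

    uniform:        S = ln 2*pi
    von Mises(k):   S = ln(2*pi I0(k)) - k I1(k)/I0(k)
    fixed:          S = -inf (differential) / 0 (discrete)

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .exceptions import ConfeError, GeometryError
from .entropy import KB_KCAL
from .structure import (
    Atom,
    AngleTerm,
    BondTerm,
    ConformationEnsemble,
    Topology,
    TorsionTerm,
)

TOY_BOND_LENGTH = 1.5    # A
TOY_BOND_ANGLE = 111.0   # degrees

_CHAIN_PARAMS = {
    # name: (element, charge, rmin_half, epsilon, gb_radius, gb_screen)
    "N": ("N", -0.40, 1.824, 0.17, 1.55, 0.79),
    "CA": ("C", +0.20, 1.908, 0.1094, 1.70, 0.72),
    "C": ("C", +0.60, 1.908, 0.1094, 1.70, 0.72),
    "O": ("O", -0.40, 1.661, 0.21, 1.50, 0.85),
}


def von_mises_entropy(kappa: float) -> float:
    """Differential entropy (nats) of the von Mises distribution."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return float(np.log(2.0 * np.pi))
    log_i0 = np.log(special.ive(0, kappa)) + kappa
    ratio = special.ive(1, kappa) / special.ive(0, kappa)
    return float(np.log(2.0 * np.pi) + log_i0 - kappa * ratio)


@dataclass
class TorsionDistributionSpec:
    """Per-torsion sampling distributions with analytic entropies.

    Each entry is ``("fixed", theta0)``, ``("uniform",)`` or
    ``("vonmises", mu, kappa)`` with angles in degrees.  Closed-form
    entropies are validated at construction against scipy's independent
    evaluation.
    """

    entries: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            kind = e[0]
            if kind == "vonmises":
                _, _, kappa = e
                if kappa < 0:
                    raise ValueError("kappa must be >= 0")
                if kappa > 0:
                    closed = von_mises_entropy(kappa)
                    ref = float(stats.vonmises(kappa).entropy())
                    if abs(closed - ref) > 1e-9:
                        raise ConfeError(
                            "von Mises entropy closed form failed validation")
            elif kind not in ("fixed", "uniform"):
                raise ValueError(f"unknown distribution kind {kind!r}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def uniform(cls, n: int) -> "TorsionDistributionSpec":
        return cls([("uniform",)] * n)

    @classmethod
    def fixed(cls, angles) -> "TorsionDistributionSpec":
        return cls([("fixed", float(a)) for a in np.atleast_1d(angles)])

    @classmethod
    def von_mises(cls, mu: float, kappa: float,
                  n: int) -> "TorsionDistributionSpec":
        return cls([("vonmises", float(mu), float(kappa))] * n)

    def __len__(self) -> int:
        return len(self.entries)

    # -- analytic entropies ------------------------------------------------
    def analytic_entropy_per_torsion(self,
                                     mode: str = "differential") -> np.ndarray:
        out = np.zeros(len(self.entries))
        for k, e in enumerate(self.entries):
            if e[0] == "fixed":
                out[k] = -np.inf if mode == "differential" else 0.0
            elif e[0] == "uniform":
                out[k] = np.log(2.0 * np.pi)
            else:
                out[k] = von_mises_entropy(e[2])
        return out

    def analytic_entropy_total(self, mode: str = "differential") -> float:
        return float(np.sum(self.analytic_entropy_per_torsion(mode)))


@dataclass
class TwoStateGroundTruth:
    """Analytic entropy contrast between two constructed states.

    ``delta_s`` is state A minus state B (nats); ``delta_ts`` is
    k_B T delta_s (kcal/mol); ``delta_offset`` is the constructed enthalpy
    difference (A minus B) injected through the topology energy offsets.
    """

    spec_a: TorsionDistributionSpec
    spec_b: TorsionDistributionSpec
    delta_s: float
    delta_ts: float
    temperature: float
    delta_offset: float
    seed: int

    def __post_init__(self) -> None:
        if abs(self.delta_ts - KB_KCAL * self.temperature * self.delta_s) \
                > 1e-9:
            raise ConfeError("delta_ts != kB T delta_s")


# ---------------------------------------------------------------------------
# Toy topologies
# ---------------------------------------------------------------------------

def make_toy_topology(n_residues: int, atoms_per_residue: int = 4,
                      seed: int = 0,
                      interacting: bool = True) -> Topology:
    """Serial toy chain with full force-field parameters.

    ``atoms_per_residue = 4`` builds the main-chain-like pattern N-CA-C(=O)
    per residue (bonds N-CA, CA-C, C-O within a residue and C-N between
    residues); ``1`` builds a plain linear chain of CA atoms.  Charges sum
    to zero by construction.  With ``interacting=False`` charges and LJ
    well depths are zeroed (radii kept, so surface areas remain defined) —
    the configuration used by the two-state generator to isolate the
    entropy signal.  The topology is identical for any given arguments;
    ``seed`` is recorded for provenance only.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if atoms_per_residue not in (1, 4):
        raise ValueError("atoms_per_residue must be 1 or 4")
    atoms: list[Atom] = []
    bonds: list[BondTerm] = []
    if atoms_per_residue == 4:
        for r in range(n_residues):
            base = 4 * r
            for name in ("N", "CA", "C", "O"):
                el, q, rmh, eps, gbr, scr = _CHAIN_PARAMS[name]
                atoms.append(Atom(
                    name=name, element=el, resname="GLY", resid=r + 1,
                    charge=q if interacting else 0.0,
                    rmin_half=rmh,
                    epsilon=eps if interacting else 0.0,
                    gb_radius=gbr, gb_screen=scr))
            bonds.append(BondTerm(base, base + 1, 300.0, TOY_BOND_LENGTH))
            bonds.append(BondTerm(base + 1, base + 2, 300.0, TOY_BOND_LENGTH))
            bonds.append(BondTerm(base + 2, base + 3, 300.0, TOY_BOND_LENGTH))
            if r + 1 < n_residues:
                bonds.append(BondTerm(base + 2, base + 4, 300.0,
                                      TOY_BOND_LENGTH))
    else:
        for r in range(n_residues):
            el, _, rmh, eps, gbr, scr = _CHAIN_PARAMS["CA"]
            q = 0.1 if r % 2 == 0 else -0.1
            if n_residues % 2 == 1 and r == n_residues - 1:
                q = 0.0
            atoms.append(Atom(
                name="CA", element=el, resname="GLY", resid=r + 1,
                charge=q if interacting else 0.0,
                rmin_half=rmh,
                epsilon=eps if interacting else 0.0,
                gb_radius=gbr, gb_screen=scr))
            if r + 1 < n_residues:
                bonds.append(BondTerm(r, r + 1, 300.0, TOY_BOND_LENGTH))

    topo = Topology(atoms, bonds)
    adj = topo.bonded_neighbors()
    angles = []
    for j in range(len(atoms)):
        for i in adj[j]:
            for k in adj[j]:
                if i < k:
                    angles.append(AngleTerm(i, j, k, 50.0, TOY_BOND_ANGLE))
    from .geometry import enumerate_torsions

    torsions = [TorsionTerm(*q, barrier=0.0, periodicity=3, phase=0.0)
                for q in enumerate_torsions(topo).quads.tolist()]
    return Topology(atoms, bonds, angles, torsions)


# ---------------------------------------------------------------------------
# Internal -> Cartesian chain building
# ---------------------------------------------------------------------------

def _build_plan(topology: Topology) -> list[tuple[int, int, int, int, float]]:
    """Placement plan: (atom, a, b, c, extra_phase_deg) per atom >= 3.

    Atom d is placed about bond b-c (c = lowest-index bonded neighbor of d)
    with the torsion value assigned to that bond; second children of the
    same bond are offset by 180 degrees so every enumerated torsion,
    re-measured with its lowest-index flanking atoms, returns exactly the
    input value.
    """
    adj = topology.bonded_neighbors()
    plan = []
    child_rank: dict[tuple[int, int], int] = {}
    for d in range(3, topology.n_atoms):
        placed = [x for x in adj[d] if x < d]
        if not placed:
            raise GeometryError(
                f"atom {d} is not bonded to any earlier atom; cannot build")
        c = placed[0]
        b_opts = [x for x in adj[c] if x < d and x != d]
        b_opts = [x for x in b_opts if x != c]
        if not b_opts:
            raise GeometryError(f"no reference atom for placing atom {d}")
        b = b_opts[0]
        a_opts = [x for x in adj[b] if x != c and x < d]
        if not a_opts:
            raise GeometryError(f"no torsion reference for atom {d}")
        a = a_opts[0]
        rank = child_rank.get((b, c), 0)
        child_rank[(b, c)] = rank + 1
        if rank > 1:
            raise GeometryError(
                f"bond ({b}, {c}) has more than two dependent branches")
        plan.append((d, a, b, c, 180.0 * rank))
    return plan


def build_coordinates_from_torsions(topology: Topology,
                                    torsion_values: np.ndarray,
                                    bond_length: float = TOY_BOND_LENGTH,
                                    bond_angle: float = TOY_BOND_ANGLE
                                    ) -> np.ndarray:
    """Cartesian coordinates from torsion values (degrees).

    ``torsion_values`` has one value per torsion of
    ``geometry.enumerate_torsions(topology)`` in that order, shape (Nd,)
    or (frames, Nd); bond lengths and bond angles are fixed constants.
    Re-measuring the enumerated torsions on the result reproduces the
    inputs.  Returns (atoms, 3) or (frames, atoms, 3).
    """
    from .geometry import enumerate_torsions

    if not (1e-6 < bond_angle % 360.0 < 180.0 - 1e-6):
        raise GeometryError(
            "bond angle must lie strictly between 0 and 180 degrees")
    torsions = enumerate_torsions(topology)
    vals = np.asarray(torsion_values, dtype=float)
    single = vals.ndim == 1
    vals = np.atleast_2d(vals)
    if vals.shape[1] != torsions.nd:
        raise GeometryError(
            f"expected {torsions.nd} torsion values, got {vals.shape[1]}")
    bond_of = {}
    for t, (a, b, c, d) in enumerate(torsions.quads):
        bond_of[(min(b, c), max(b, c))] = t

    nf = vals.shape[0]
    n = topology.n_atoms
    coords = np.zeros((nf, n, 3))
    theta = np.radians(bond_angle)
    coords[:, 1] = [bond_length, 0.0, 0.0]
    if n > 2:
        coords[:, 2] = coords[:, 1] + bond_length * np.array(
            [-np.cos(theta), np.sin(theta), 0.0])
    for d, a, b, c, extra in _build_plan(topology):
        key = (min(b, c), max(b, c))
        if key not in bond_of:
            raise GeometryError(
                f"placement bond {key} is not an enumerated torsion")
        phi = np.radians(vals[:, bond_of[key]] + extra)
        pa, pb, pc = coords[:, a], coords[:, b], coords[:, c]
        bc = pc - pb
        bc_u = bc / np.linalg.norm(bc, axis=1, keepdims=True)
        ab = pb - pa
        nvec = np.cross(ab, bc_u)
        nn = np.linalg.norm(nvec, axis=1, keepdims=True)
        if np.any(nn < 1e-10):
            raise GeometryError("collinear reference atoms during build")
        n_u = nvec / nn
        m_u = np.cross(n_u, bc_u)
        d2 = np.stack([
            -bond_length * np.cos(theta) * np.ones(nf),
            bond_length * np.sin(theta) * np.cos(phi),
            bond_length * np.sin(theta) * np.sin(phi),
        ], axis=1)
        coords[:, d] = (pc + d2[:, :1] * bc_u
                        + d2[:, 1:2] * m_u + d2[:, 2:3] * n_u)
    return coords[0] if single else coords


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def sample_torsions(spec: TorsionDistributionSpec, n_frames: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_frames, n_torsions) i.i.d. torsion angles in degrees."""
    cols = []
    for e in spec.entries:
        if e[0] == "fixed":
            cols.append(np.full(n_frames, e[1]))
        elif e[0] == "uniform":
            cols.append(rng.uniform(-180.0, 180.0, n_frames))
        else:
            _, mu, kappa = e
            if kappa == 0:
                cols.append(rng.uniform(-180.0, 180.0, n_frames))
            else:
                cols.append(np.degrees(
                    rng.vonmises(np.radians(mu), kappa, n_frames)))
    return np.column_stack(cols)


def sample_ensemble(topology: Topology, spec: TorsionDistributionSpec,
                    n_frames: int, seed: int,
                    run_id: int = 0) -> ConformationEnsemble:
    """I.i.d. frames with torsions drawn independently per the spec."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    angles = sample_torsions(spec, n_frames, rng)
    coords = build_coordinates_from_torsions(topology, angles)
    from .structure import config_hash

    spec_hash = config_hash(spec.entries)
    meta = [{"seed": seed, "run_id": run_id, "spec_hash": spec_hash,
             "frame": f} for f in range(n_frames)]
    return ConformationEnsemble(topology, coords, meta)


def make_metal_site(n_water_mean: float, n_frames: int, seed: int,
                    shell_distance: float = 2.5,
                    cutoff: float = 3.0) -> ConformationEnsemble:
    """A Zn ion with waters whose expected in-shell count is controlled.

    K = max(4, ceil(mean)) water oxygens; each is independently placed
    inside the shell (uniform distance in [shell_distance - 0.4,
    min(shell_distance + 0.4, cutoff - 0.05)]) with probability mean / K,
    otherwise well outside (5-8 A), so the expected number of waters within
    ``cutoff`` of the Zn equals ``n_water_mean`` exactly.
    """
    if n_water_mean < 0 or n_frames < 1:
        raise ValueError("parameters must be positive")
    k = max(4, int(np.ceil(n_water_mean))) if n_water_mean > 0 else 4
    p = n_water_mean / k
    if p > 1:
        raise ValueError("n_water_mean too large for water count")
    atoms = [Atom(name="ZN", element="Zn", resname="ZN", resid=1,
                  charge=2.0, rmin_half=1.10, epsilon=0.0125,
                  gb_radius=1.45, gb_screen=0.8)]
    for w in range(k):
        atoms.append(Atom(name="O", element="O", resname="WAT",
                          resid=w + 2, charge=-0.834, rmin_half=1.7683,
                          epsilon=0.152, gb_radius=1.5, gb_screen=0.85))
    topo = Topology(atoms)
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_frames, k + 1, 3))
    hi = min(shell_distance + 0.4, cutoff - 0.05)
    lo = min(shell_distance - 0.4, hi - 0.1)
    for f in range(n_frames):
        inside = rng.random(k) < p
        dist = np.where(inside, rng.uniform(lo, hi, k),
                        rng.uniform(5.0, 8.0, k))
        vec = rng.normal(size=(k, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        coords[f, 1:] = vec * dist[:, None]
    meta = [{"seed": seed, "frame": f} for f in range(n_frames)]
    return ConformationEnsemble(topo, coords, meta)


def make_two_state_system(kappa_a: float, kappa_b: float,
                          n_torsions: int = 50, n_frames: int = 10_000,
                          temperature: float = 300.0, seed: int = 0,
                          enthalpy_offsets: tuple[float, float] = (0.0, 0.0)
                          ) -> tuple[ConformationEnsemble,
                                     ConformationEnsemble,
                                     TwoStateGroundTruth]:
    """Two ensembles over one chain differing only in torsion concentration.

    kappa = 0 means uniform torsions.  The chain is non-interacting (zero
    charges and LJ well depths) so the enthalpy of the two states is
    matched by construction; ``enthalpy_offsets`` (state A, state B;
    kcal/mol) are constant shifts applied through the topology to set an
    enthalpy difference exactly.  The ground truth carries
    delta_s = n_torsions * (S(kappa_a) - S(kappa_b)) (A minus B).
    """
    base = make_toy_topology(n_torsions + 3, atoms_per_residue=1,
                             interacting=False)
    import copy

    topo_a = copy.deepcopy(base)
    topo_a.energy_offset = float(enthalpy_offsets[0])
    topo_b = copy.deepcopy(base)
    topo_b.energy_offset = float(enthalpy_offsets[1])
    spec_a = (TorsionDistributionSpec.uniform(n_torsions) if kappa_a == 0
              else TorsionDistributionSpec.von_mises(0.0, kappa_a, n_torsions))
    spec_b = (TorsionDistributionSpec.uniform(n_torsions) if kappa_b == 0
              else TorsionDistributionSpec.von_mises(0.0, kappa_b, n_torsions))
    rng = np.random.default_rng(seed)
    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
    ens_a = sample_ensemble(topo_a, spec_a, n_frames, int(seed_a))
    ens_b = sample_ensemble(topo_b, spec_b, n_frames, int(seed_b))
    s_a = (np.log(2 * np.pi) if kappa_a == 0 else von_mises_entropy(kappa_a))
    s_b = (np.log(2 * np.pi) if kappa_b == 0 else von_mises_entropy(kappa_b))
    delta_s = n_torsions * (s_a - s_b)
    truth = TwoStateGroundTruth(
        spec_a=spec_a, spec_b=spec_b, delta_s=delta_s,
        delta_ts=KB_KCAL * temperature * delta_s,
        temperature=temperature,
        delta_offset=float(enthalpy_offsets[0] - enthalpy_offsets[1]),
        seed=seed)
    return ens_a, ens_b, truth
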