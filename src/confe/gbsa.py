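"""Per-snapshot GBSA energies.

The "enthalpy" side of the free energy is evaluated on solvent-stripped
snapshots as

    E_MM  = E_bond + E_angle + E_torsion + E_LJ + E_Coulomb + E_GB
    E_ASA = gamma * SASA + b

with the generalized-Born polar solvation term in the Hawkins
pairwise-descreening (HCT) flavor and the Still pairwise energy form, and
the nonpolar term proportional to the Shrake-Rupley solvent-accessible
surface area (probe radius 1.4 A).

Units: kcal/mol, Angstrom, elementary charges.  The electrostatic constant
k_e = 332.06 kcal*A/mol/e^2 and solvent dielectric 78.5 are configurable;
there are no cutoffs — all pairs are summed, which is the appropriate
regime for snapshot re-evaluation of desk-scale systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EnergyError
from .structure import ConformationEnsemble, Topology


@dataclass
class GBParameters:
    """Generalized-Born model constants (per-atom radii live on the topology)."""

    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    coulomb_constant: float = 332.06     # kcal*A/mol/e^2
    dielectric_offset: float = 0.09      # A, subtracted from intrinsic radii

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectrics must be positive")
        if self.solvent_dielectric <= self.interior_dielectric:
            raise ValueError("solvent dielectric must exceed interior")


@dataclass
class SASAParameters:
    """Shrake-Rupley surface-area term parameters."""

    probe_radius: float = 1.4            # A
    n_points: int = 960                  # sphere sample points per atom
    gamma: float = 0.005                 # kcal/mol/A^2
    offset: float = 0.0                  # b, kcal/mol

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 92:
            raise ValueError("need at least 92 sphere points")


@dataclass
class EnergyDecomposition:
    """Per-snapshot energy components (kcal/mol; SASA in A^2).

    ``e_mm`` is by construction the sum of bond, angle, torsion, LJ,
    Coulomb and GB components plus the topology's constant offset.
    """

    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    gb: float = 0.0
    offset: float = 0.0
    sasa_total: float = 0.0
    e_asa: float = 0.0
    born_radii_clamped: int = 0

    @property
    def e_mm(self) -> float:
        return (self.bond + self.angle + self.torsion + self.lj
                + self.coulomb + self.gb + self.offset)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("bond", "angle", "torsion", "lj", "coulomb", "gb", "offset")}
        d["e_mm"] = self.e_mm
        d["sasa_total"] = self.sasa_total
        d["e_asa"] = self.e_asa
        d["born_radii_clamped"] = self.born_radii_clamped
        return d


# ---------------------------------------------------------------------------
# Effective Born radii (Hawkins-Cramer-Truhlar pairwise descreening)
# ---------------------------------------------------------------------------

def effective_born_radii(topology: Topology, frame: np.ndarray,
                         params: GBParameters | None = None,
                         with_flags: bool = False):
    """Per-atom effective Born radii by HCT pairwise descreening.

    The inverse effective radius of atom i is the inverse of its reduced
    intrinsic radius (intrinsic minus the dielectric offset) minus the sum
    over all other atoms of the analytic Coulomb-field descreening integral
    of each neighbor's screened sphere.  Non-positive inverse radii
    (pathological overlaps) are clamped with a warning.
    """
    params = params or GBParameters()
    frame = np.asarray(frame, dtype=float)
    rho = topology.gb_radii() - params.dielectric_offset
    if np.any(~(rho > 0)):
        raise EnergyError(
            "every intrinsic GB radius must exceed the dielectric offset")
    scr = topology.gb_screens()
    n = topology.n_atoms
    if frame.shape != (n, 3):
        raise EnergyError(f"frame shape {frame.shape} != ({n}, 3)")
    diff = frame[:, None, :] - frame[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    s = scr * rho                               # scaled neighbor radii
    ri = rho[:, None]
    sj = s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r + sj
        l = np.maximum(ri, np.abs(r - sj))
        term = 0.5 * (1.0 / l - 1.0 / u
                      + 0.25 * (r - sj * sj / np.where(r > 0, r, 1.0))
                      * (1.0 / (u * u) - 1.0 / (l * l))
                      + 0.5 / np.where(r > 0, r, 1.0) * np.log(l / u))
        # neighbor sphere engulfs atom i entirely
        engulf = sj >= r + ri
        term = term + np.where(engulf, 2.0 * (1.0 / ri - 1.0 / l), 0.0)
        # neighbor entirely inside atom i's own radius: no descreening
        term = np.where(u <= ri, 0.0, term)
    np.fill_diagonal(term, 0.0)
    inv = 1.0 / rho - term.sum(axis=1)
    bad = inv <= 0
    n_clamped = int(bad.sum())
    if n_clamped:
        warnings.warn(
            "some effective Born radii were non-positive and were clamped; "
            "geometry has pathological overlaps (count flagged in output)")
        inv = np.where(bad, 1.0 / (1e3 * rho), inv)
    radii = 1.0 / inv
    if with_flags:
        return radii, n_clamped
    return radii


def gb_polar_energy(topology: Topology, frame: np.ndarray,
                    radii: np.ndarray,
                    params: GBParameters | None = None) -> float:
    """Still-form pairwise GB polar solvation energy (kcal/mol).

    E = -(k_e/2) (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB(r, R_i, R_j)
    with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the i = j self
    terms (f = R_i) give the Born self-energies.
    """
    params = params or GBParameters()
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    q = topology.charges()
    if len(radii) != topology.n_atoms:
        raise EnergyError("radii length does not match atom count")
    diff = frame[:, None, :] - frame[None, :, :]
    r2 = np.sum(diff * diff, axis=-1)
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    qq = q[:, None] * q[None, :]
    prefac = -0.5 * params.coulomb_constant * (
        1.0 / params.interior_dielectric - 1.0 / params.solvent_dielectric)
    return float(prefac * np.sum(qq / f))


# ---------------------------------------------------------------------------
# Surface area (Shrake-Rupley with a deterministic Fibonacci sphere)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (deterministic, no RNG)."""
    k = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(topology: Topology, frame: np.ndarray,
         params: SASAParameters | None = None) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Per atom: the fraction of sphere points (radius = vdW + probe) not
    buried inside any neighbor's expanded sphere, times the sphere area.
    Returns (per-atom areas, total), in A^2.
    """
    params = params or SASAParameters()
    frame = np.asarray(frame, dtype=float)
    radii = topology.vdw_radii() + params.probe_radius
    if np.isnan(radii).any():
        raise EnergyError("van der Waals radii missing for some atoms")
    n = topology.n_atoms
    pts = fibonacci_sphere(params.n_points)
    areas = np.zeros(n)
    diff = frame[:, None, :] - frame[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    for i in range(n):
        neigh = np.nonzero((dist[i] < radii[i] + radii) &
                           (np.arange(n) != i))[0]
        sphere = frame[i] + radii[i] * pts
        exposed = np.ones(params.n_points, dtype=bool)
        for j in neigh:
            d = sphere - frame[j]
            exposed &= np.sum(d * d, axis=1) > radii[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


def asa_energy(sasa_total: float,
               params: SASAParameters | None = None) -> float:
    """Nonpolar solvation term: gamma * SASA + b (kcal/mol)."""
    params = params or SASAParameters()
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return params.gamma * sasa_total + params.offset


# ---------------------------------------------------------------------------
# Molecular-mechanics vacuum terms
# ---------------------------------------------------------------------------

def mm_energy(topology: Topology, frame: np.ndarray,
              scale14_elec: float = 1.0 / 1.2,
              scale14_lj: float = 0.5,
              coulomb_constant: float = 332.06) -> EnergyDecomposition:
    """Classical force-field terms of one snapshot.

    Harmonic bonds and angles, cosine torsion series, 12-6 Lennard-Jones
    (Lorentz-like Rmin/2 addition, geometric-mean epsilon) and Coulomb;
    1-2/1-3 pairs excluded, 1-4 pairs scaled (AMBER-style defaults 1/1.2
    electrostatic, 1/2 LJ, configurable).
    """
    frame = np.asarray(frame, dtype=float)
    out = EnergyDecomposition(offset=topology.energy_offset)

    for b in topology.bonds:
        if b.k is None or b.b0 is None:
            raise EnergyError(f"bond ({b.i}, {b.j}) lacks parameters")
        d = np.linalg.norm(frame[b.i] - frame[b.j])
        out.bond += b.k * (d - b.b0) ** 2
    for a in topology.angles:
        if a.force is None or a.theta0 is None:
            raise EnergyError(f"angle ({a.i}, {a.j}, {a.k}) lacks parameters")
        v1 = frame[a.i] - frame[a.j]
        v2 = frame[a.k] - frame[a.j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        out.angle += a.force * (theta - np.radians(a.theta0)) ** 2
    if topology.torsions:
        from .geometry import dihedrals

        quads = np.array([[t.i, t.j, t.k, t.l] for t in topology.torsions])
        phis = np.radians(dihedrals(frame, quads))
        for t, phi in zip(topology.torsions, phis):
            if t.barrier is None or t.periodicity is None or t.phase is None:
                raise EnergyError(
                    f"torsion ({t.i}, {t.j}, {t.k}, {t.l}) lacks parameters")
            out.torsion += 0.5 * t.barrier * (
                1.0 + np.cos(t.periodicity * phi - np.radians(t.phase)))

    # nonbonded
    q = topology.charges()
    rmh = topology.vdw_radii()
    eps = np.array([a.epsilon for a in topology.atoms], dtype=float)
    if np.isnan(q).any() or np.isnan(rmh).any() or np.isnan(eps).any():
        raise EnergyError("nonbonded parameters missing for some atoms")
    n = topology.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    excl = topology.exclusions()
    p14 = topology.pairs14()
    mask = np.ones(len(iu), dtype=bool)
    w_lj = np.ones(len(iu))
    w_el = np.ones(len(iu))
    for idx, (i, j) in enumerate(zip(iu, ju)):
        pair = (int(i), int(j))
        if pair in excl:
            mask[idx] = False
        elif pair in p14:
            w_lj[idx] = scale14_lj
            w_el[idx] = scale14_elec
    iu, ju = iu[mask], ju[mask]
    w_lj, w_el = w_lj[mask], w_el[mask]
    if len(iu):
        d = np.linalg.norm(frame[iu] - frame[ju], axis=1)
        rmin = rmh[iu] + rmh[ju]
        epsij = np.sqrt(eps[iu] * eps[ju])
        sr6 = (rmin / d) ** 6
        out.lj = float(np.sum(w_lj * epsij * (sr6 * sr6 - 2.0 * sr6)))
        out.coulomb = float(np.sum(
            w_el * coulomb_constant * q[iu] * q[ju] / d))
    return out


# ---------------------------------------------------------------------------
# Snapshot and ensemble evaluation
# ---------------------------------------------------------------------------

def snapshot_energy(topology: Topology, frame: np.ndarray,
                    gb: GBParameters | None = None,
                    sa: SASAParameters | None = None,
                    scale14_elec: float = 1.0 / 1.2,
                    scale14_lj: float = 0.5) -> EnergyDecomposition:
    """Full GBSA decomposition of one (solvent-stripped) snapshot."""
    gb = gb or GBParameters()
    sa = sa or SASAParameters()
    out = mm_energy(topology, frame, scale14_elec, scale14_lj,
                    gb.coulomb_constant)
    radii, n_clamped = effective_born_radii(topology, frame, gb,
                                            with_flags=True)
    out.born_radii_clamped = n_clamped
    out.gb = gb_polar_energy(topology, frame, radii, gb)
    _, total = sasa(topology, frame, sa)
    out.sasa_total = total
    out.e_asa = asa_energy(total, sa)
    return out


def ensemble_average(ensemble: ConformationEnsemble,
                     gb: GBParameters | None = None,
                     sa: SASAParameters | None = None,
                     stride: int = 1,
                     scale14_elec: float = 1.0 / 1.2,
                     scale14_lj: float = 0.5
                     ) -> tuple[float, float, pd.DataFrame]:
    """Arithmetic means <E_MM> and <E_ASA> over frames.

    ``stride`` evaluates every stride-th frame (energy means converge much
    faster than the torsion histograms, so pipelines may subsample here).
    Returns (mean E_MM, mean E_ASA, per-frame DataFrame) for convergence
    diagnostics.
    """
    if ensemble.n_frames == 0:
        raise EnergyError("cannot average over an empty ensemble")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = []
    idx = range(0, ensemble.n_frames, stride)
    for f in idx:
        dec = snapshot_energy(ensemble.topology, ensemble.coordinates[f],
                              gb, sa, scale14_elec, scale14_lj)
        row = dec.as_dict()
        row["frame"] = f
        rows.append(row)
    df = pd.DataFrame(rows).set_index("frame")
    return float(df["e_mm"].mean()), float(df["e_asa"].mean()), df
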