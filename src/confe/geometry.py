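"""Superposition, RMSD, dihedrals, torsion enumeration and contacts.

These are the measurements behind trajectory stability tables: main-chain
RMSD of a trajectory against its own start and against the other state's
start, per-region (loop / arginine) RMSD after a global main-chain fit,
and the count of water oxygens in contact with a catalytic metal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeometryError, SelectionError
from .structure import AtomSelection, ConformationEnsemble, Topology


@dataclass
class SuperpositionResult:
    """Least-squares rigid fit: ``x @ rotation.T + translation`` maps the
    mobile coordinates onto the reference frame."""

    rotation: np.ndarray      # (3, 3), orthonormal, det = +1
    translation: np.ndarray   # (3,), Angstrom
    rmsd: float               # over the fit atoms, Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TorsionSet:
    """Torsion quadruples (atom index 4-tuples) with labels; Nd = len."""

    quads: np.ndarray                 # (Nd, 4) int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.quads = np.asarray(self.quads, dtype=int).reshape(-1, 4)
        if not self.labels:
            self.labels = [f"t{k}" for k in range(len(self.quads))]
        seen = set()
        for q in self.quads:
            key = tuple(q)
            if key in seen:
                raise GeometryError(f"duplicate torsion quadruple {key}")
            seen.add(key)

    @property
    def nd(self) -> int:
        return len(self.quads)

    def __len__(self) -> int:
        return len(self.quads)


@dataclass
class ContactSeries:
    """Per-frame contact counts of partner atoms near a center selection."""

    counts: np.ndarray
    cutoff: float
    center_label: str = ""
    partner_label: str = ""

    @property
    def average(self) -> float:
        return float(np.mean(self.counts))


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit: AtomSelection | None = None) -> SuperpositionResult:
    """Kabsch least-squares superposition of ``mobile`` onto ``reference``.

    Reflections are excluded (det(R) = +1).  Raises GeometryError for fewer
    than 3 fit atoms or a collinear fit set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit is not None:
        mfit = mobile[fit.indices]
        rfit = reference[fit.indices]
    else:
        mfit, rfit = mobile, reference
    if mfit.shape != rfit.shape:
        raise GeometryError(
            f"fit coordinate shapes differ: {mfit.shape} vs {rfit.shape}")
    if len(mfit) < 3:
        raise GeometryError("superposition needs at least 3 fit atoms")
    mc = mfit.mean(axis=0)
    rc = rfit.mean(axis=0)
    a = mfit - mc
    b = rfit - rc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise GeometryError("fit atoms are collinear; rotation is degenerate")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = a @ rot.T + rc
    rmsd_val = float(np.sqrt(np.mean(np.sum((fitted - rfit) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd_val)


def rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
         measure: AtomSelection | None = None,
         fit: AtomSelection | None = None) -> float:
    """RMSD between two frames after superposition.

    ``frame_a`` is superposed onto ``frame_b`` over the ``fit`` selection
    (default: the ``measure`` selection, giving the standard global RMSD);
    the deviation is then measured over ``measure`` (default: all atoms).
    With ``fit != measure`` this is a "position in the global frame" RMSD,
    as used for loops and individual residues after a global main-chain fit.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if measure is not None and len(measure) == 0:
        raise SelectionError("empty measure selection")
    if fit is None:
        fit = measure
    sup = kabsch_superpose(frame_a, frame_b, fit)
    moved = sup.apply(frame_a)
    if measure is not None:
        moved = moved[measure.indices]
        ref = frame_b[measure.indices]
    else:
        ref = frame_b
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Dihedral angles
# ---------------------------------------------------------------------------

def dihedrals(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angles in degrees, vectorized.

    ``coords`` is (atoms, 3) or (frames, atoms, 3); ``quads`` is (M, 4).
    Returns (M,) or (frames, M) in (-180, 180] with the IUPAC convention:
    cis = 0, trans = 180, positive = clockwise rotation of the far bond
    viewed along atom2 -> atom3.
    """
    coords = np.asarray(coords, dtype=float)
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    p0 = coords[:, quads[:, 0]]
    p1 = coords[:, quads[:, 1]]
    p2 = coords[:, quads[:, 2]]
    p3 = coords[:, quads[:, 3]]
    b0 = p0 - p1
    bc = p2 - p1
    b2 = p3 - p2
    bcn = np.linalg.norm(bc, axis=-1)
    if np.any(bcn < 1e-10):
        raise GeometryError("undefined dihedral: central bond has zero length")
    bch = bc / bcn[..., None]
    v = b0 - np.sum(b0 * bch, axis=-1, keepdims=True) * bch
    w = b2 - np.sum(b2 * bch, axis=-1, keepdims=True) * bch
    if np.any(np.linalg.norm(v, axis=-1) < 1e-10) or \
       np.any(np.linalg.norm(w, axis=-1) < 1e-10):
        raise GeometryError(
            "undefined dihedral: three consecutive atoms are collinear")
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(bch, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 to +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0 + 1e-12, ang + 360.0, ang)
    return ang[0] if single else ang


def dihedral(coords: np.ndarray, quad) -> float:
    """Single signed dihedral (degrees, IUPAC sign, range (-180, 180])."""
    q = np.asarray(quad, dtype=int)
    if len(np.unique(q)) != 4:
        raise GeometryError("dihedral needs four distinct atom indices")
    return float(dihedrals(np.asarray(coords, dtype=float), q[None])[0])


# ---------------------------------------------------------------------------
# Torsion enumeration
# ---------------------------------------------------------------------------

def enumerate_torsions(topology: Topology,
                       policy: str = "all-rotatable") -> TorsionSet:
    """Enumerate torsion quadruples.

    ``all-rotatable`` (default) emits exactly one quadruple per non-terminal
    heavy-atom bond b-c (both ends bonded to at least one further atom),
    with flanking atoms a, d chosen as the lowest-index neighbors; ordering
    is deterministic by (b, c).  ``backbone-only`` keeps quadruples whose
    four atoms are all main-chain atoms; ``forcefield-terms`` returns the
    torsion terms stored in the topology.
    """
    if policy == "forcefield-terms":
        quads = np.array([[t.i, t.j, t.k, t.l] for t in topology.torsions],
                         dtype=int).reshape(-1, 4)
        return TorsionSet(quads)
    if policy not in ("all-rotatable", "backbone-only"):
        raise ValueError(f"unknown torsion policy {policy!r}")
    if not topology.bonds:
        warnings.warn("topology has no bonds; empty torsion set")
        return TorsionSet(np.empty((0, 4), dtype=int))
    adj = topology.bonded_neighbors()
    hydrogens = {k for k, a in enumerate(topology.atoms)
                 if a.element.upper() == "H"}
    quads = []
    labels = []
    bonds = sorted({(min(b.i, b.j), max(b.i, b.j)) for b in topology.bonds})
    mc = {k for k, a in enumerate(topology.atoms)
          if a.name.upper() in ("N", "CA", "C", "O")}
    for b, c in bonds:
        if b in hydrogens or c in hydrogens:
            continue
        a_opts = [x for x in adj[b] if x != c and x not in hydrogens]
        d_opts = [x for x in adj[c] if x != b and x not in hydrogens]
        if not a_opts or not d_opts:
            continue  # terminal bond
        a, d = a_opts[0], d_opts[0]
        if policy == "backbone-only" and not {a, b, c, d} <= mc:
            continue
        quads.append((a, b, c, d))
        labels.append(f"{b}-{c}")
    return TorsionSet(np.array(quads, dtype=int).reshape(-1, 4), labels)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def count_contacts(ensemble: ConformationEnsemble, center: AtomSelection,
                   partners: AtomSelection, cutoff: float = 3.0
                   ) -> ContactSeries:
    """Per-frame count of partner atoms within ``cutoff`` of any center atom.

    The time average of the counts is the "ligand water" statistic reported
    for metal sites (default 3.0 A, a typical Zn(2+)-O first-shell
    coordination distance).
    """
    if len(center) == 0:
        raise SelectionError("center selection is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ccoords = ensemble.coordinates[:, center.indices, :]
    pcoords = ensemble.coordinates[:, partners.indices, :]
    # (F, P, C) distances; partner counts if within cutoff of any center
    diff = pcoords[:, :, None, :] - ccoords[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    within = (dist <= cutoff).any(axis=2)
    counts = within.sum(axis=1).astype(int)
    return ContactSeries(counts, cutoff, center.label, partners.label)


# ---------------------------------------------------------------------------
# Region RMSD tables
# ---------------------------------------------------------------------------

def region_rmsd_table(traj: ConformationEnsemble,
                      refs: dict[str, np.ndarray],
                      regions: list[AtomSelection],
                      fit: AtomSelection,
                      reduce: str = "mean") -> pd.DataFrame:
    """Time-averaged per-region RMSD of a trajectory against references.

    For every frame and reference: global superposition on ``fit`` (the
    main chain, conventionally), then RMSD over each region's atoms in that
    global frame.  ``reduce`` is ``mean`` over frames or ``last`` (final
    snapshot only).  Rows: region labels; columns: reference labels.
    """
    if reduce not in ("mean", "last"):
        raise ValueError("reduce must be 'mean' or 'last'")
    for region in regions:
        if len(region) == 0:
            raise SelectionError(
                f"region {region.label!r} selects no atoms in this topology")
    frames = (traj.coordinates if reduce == "mean"
              else traj.coordinates[-1:])
    out = {}
    for ref_label, ref in refs.items():
        ref = np.asarray(ref, dtype=float)
        col = []
        per_region = np.zeros((len(frames), len(regions)))
        for fi, frame in enumerate(frames):
            sup = kabsch_superpose(frame, ref, fit)
            moved = sup.apply(frame)
            for ri, region in enumerate(regions):
                d = moved[region.indices] - ref[region.indices]
                per_region[fi, ri] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
        col = per_region.mean(axis=0)
        out[ref_label] = col
    return pd.DataFrame(out, index=[r.label for r in regions])
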