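"""PCA of conformational ensembles and pathway waypoint selection.

Intermediate structures along a conformational transition are projected
onto the leading principal components of their (aligned) coordinates; a
fixed number of waypoints is then picked at equal arc-length intervals
along the projected path, and a linear Cartesian morph provides a
geometric stand-in path between two endpoint conformations.  The morph is
explicitly labeled "interpolated": it exercises profile machinery and
makes no physical claim about transition ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfeError, GeometryError
from .geometry import kabsch_superpose
from .structure import AtomSelection, ConformationEnsemble


@dataclass
class PCAModel:
    """Principal components of aligned coordinates over a selection.

    Eigenvalues are variances (A^2, sample convention n-1) in
    non-increasing order; eigenvectors are orthonormal rows over the
    flattened 3N selected coordinates; projections are mean-centered
    scores of the analyzed frames (the mean structure maps to the origin).
    """

    mean: np.ndarray          # (3m,)
    eigenvalues: np.ndarray   # (k,)
    eigenvectors: np.ndarray  # (k, 3m), rows orthonormal
    projections: np.ndarray   # (frames, k)
    selection: AtomSelection

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def to_frame(self) -> pd.DataFrame:
        k = min(self.projections.shape[1], 5)
        return pd.DataFrame(
            self.projections[:, :k],
            columns=[f"pc{j + 1}" for j in range(k)])


def align_ensemble(ensemble: ConformationEnsemble, fit: AtomSelection,
                   mode: str = "to-first", tol: float = 1e-6,
                   max_iter: int = 50) -> ConformationEnsemble:
    """Superpose every frame onto a common reference.

    ``to-first`` fits each frame onto frame 0; ``iterative-mean`` fits to
    the converged mean structure (fixed point of align-then-average, which
    can only lower the total coordinate variance).
    """
    if ensemble.n_frames < 2:
        raise ConfeError("alignment needs at least 2 frames")
    if mode not in ("to-first", "iterative-mean"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    coords = ensemble.coordinates.copy()

    def align_to(ref):
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            sup = kabsch_superpose(coords[f], ref, fit)
            out[f] = sup.apply(coords[f])
        return out

    if mode == "to-first":
        aligned = align_to(coords[0])
    else:
        ref = coords[0]
        aligned = coords
        for _ in range(max_iter):
            aligned = align_to(ref)
            new_ref = aligned.mean(axis=0)
            shift = float(np.abs(new_ref - ref).max())
            ref = new_ref
            if shift < tol:
                break
        else:
            warnings.warn("iterative-mean alignment did not converge; "
                          "returning best iterate")
    return ensemble.with_coordinates(aligned)


def pca(ensemble: ConformationEnsemble, selection: AtomSelection) -> PCAModel:
    """PCA of the flattened selected coordinates of an aligned ensemble."""
    if ensemble.n_frames < 2:
        raise ConfeError("PCA needs at least 2 frames")
    if len(selection) == 0:
        raise ConfeError("PCA selection is empty")
    x = ensemble.coordinates[:, selection.indices, :].reshape(
        ensemble.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s * s / (ensemble.n_frames - 1)
    # deterministic sign: largest-magnitude component of each axis positive
    for k in range(vt.shape[0]):
        imax = int(np.argmax(np.abs(vt[k])))
        if vt[k, imax] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    projections = u * s
    return PCAModel(mean, eigvals, vt, projections, selection)


def project(model: PCAModel, frame: np.ndarray) -> np.ndarray:
    """Scores of one frame (already aligned to the model's reference)."""
    frame = np.asarray(frame, dtype=float)
    x = frame[model.selection.indices].reshape(-1)
    if x.shape[0] != model.mean.shape[0]:
        raise ConfeError(
            f"frame selection dimension {x.shape[0]} != model "
            f"{model.mean.shape[0]}")
    return model.eigenvectors @ (x - model.mean)


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Selected coordinates (m, 3) rebuilt from component scores."""
    x = model.mean + np.asarray(scores, dtype=float) @ model.eigenvectors
    return x.reshape(-1, 3)


def select_waypoints(projections: np.ndarray, n: int = 10) -> np.ndarray:
    """Indices at equal arc length along a projected path.

    Arc length is accumulated in the first two component dimensions;
    endpoints are always included; chosen indices are strictly monotone
    with ties broken toward the smaller index.  A path of zero length
    falls back to equal index spacing.
    """
    proj = np.atleast_2d(np.asarray(projections, dtype=float))
    if proj.shape[0] < n:
        raise ConfeError(f"path has {proj.shape[0]} points, need >= {n}")
    if n < 2:
        raise ConfeError("need at least 2 waypoints")
    xy = proj[:, : min(2, proj.shape[1])]
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    npts = len(cum)
    if total == 0:
        return np.round(np.linspace(0, npts - 1, n)).astype(int)
    targets = np.linspace(0.0, total, n)
    chosen = [0]
    for t in targets[1:-1]:
        lo = chosen[-1] + 1
        hi = npts - (n - len(chosen) - 1)  # leave room for the rest
        cand = np.arange(lo, hi)
        dist = np.abs(cum[cand] - t)
        chosen.append(int(cand[np.argmin(dist)]))
    chosen.append(npts - 1)
    return np.array(chosen, dtype=int)


def morph(conf_a: np.ndarray, conf_b: np.ndarray, n_frames: int,
          topology=None, superpose: bool = True) -> ConformationEnsemble:
    """Linear Cartesian interpolation between two conformations.

    ``conf_b`` is first superposed onto ``conf_a`` (all atoms) so the
    morph contains no rigid-body drift; frames run from A to B inclusive.
    Frame metadata is labeled ``interpolated`` — this is a geometric
    stand-in for a biased transition simulation, not a reproduction of one.
    """
    conf_a = np.asarray(conf_a, dtype=float)
    conf_b = np.asarray(conf_b, dtype=float)
    if conf_a.shape != conf_b.shape:
        raise GeometryError(
            f"endpoint shapes differ: {conf_a.shape} vs {conf_b.shape}")
    if n_frames < 2:
        raise ValueError("morph needs at least 2 frames")
    if superpose:
        sup = kabsch_superpose(conf_b, conf_a)
        conf_b = sup.apply(conf_b)
    t = np.linspace(0.0, 1.0, n_frames)[:, None, None]
    coords = (1.0 - t) * conf_a[None] + t * conf_b[None]
    if topology is None:
        raise ValueError("morph requires the shared topology")
    meta = [{"interpolated": True, "t": float(tt)} for tt in t[:, 0, 0]]
    return ConformationEnsemble(topology, coords, meta)
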