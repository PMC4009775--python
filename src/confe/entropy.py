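"""Conformational entropy from dihedral-angle distributions.

The estimator treats each torsion independently: over an ensemble of
snapshots the angle of torsion i is histogrammed on the circle (bins of
width w anchored at -180 deg, +180 identified with -180) and the entropy
is summed over torsions,

    discrete:       S_i = -sum_b P_b ln P_b          (0 <= S_i <= ln nbins)
    differential:   S_i = -sum_b P_b ln(P_b / w_rad) (S_i <= ln 2*pi)

with 0 ln 0 = 0.  The differential reading approximates the continuous
entropy of the angle density in radian measure and is bin-width independent
for smooth distributions; the discrete reading shifts by the log bin count.
Both are first-class — see the bin-width sensitivity report.

The entropic free-energy term is TS = k_B T S with
k_B = 0.0019872041 kcal/mol/K (T defaults to 300 K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfeError
from .geometry import TorsionSet, dihedrals
from .structure import ConformationEnsemble

KB_KCAL = 0.0019872041  # kcal/mol/K


@dataclass
class DihedralHistogram:
    """Normalized occupancy of one torsion over an ensemble."""

    torsion_index: int
    label: str
    bin_width: float              # degrees; must divide 360
    probabilities: np.ndarray     # (360/width,), sums to 1
    n_samples: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        nbins = int(round(360.0 / self.bin_width))
        if abs(nbins * self.bin_width - 360.0) > 1e-9:
            raise ConfeError(f"bin width {self.bin_width} must divide 360")
        if len(self.probabilities) != nbins:
            raise ConfeError("probability vector length != 360/width")
        if np.any(self.probabilities < 0):
            raise ConfeError("negative occupancy")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ConfeError("occupancies do not sum to 1")

    @property
    def edges(self) -> np.ndarray:
        nbins = len(self.probabilities)
        return -180.0 + self.bin_width * np.arange(nbins + 1)


@dataclass
class EntropyResult:
    """Per-torsion and total entropy of one ensemble ("form")."""

    s_per_torsion: np.ndarray     # nats
    mode: str                     # "discrete" | "differential"
    bin_width: float              # degrees
    nd: int
    labels: list[str]

    @property
    def s_total(self) -> float:
        return float(np.sum(self.s_per_torsion))

    def ts(self, temperature: float = 300.0) -> float:
        return ts_term(self, temperature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "torsion": np.arange(self.nd),
            "label": self.labels,
            "bin_width_deg": self.bin_width,
            "mode": self.mode,
            "s_nats": self.s_per_torsion,
        })


def bin_angles(angles: np.ndarray, bin_width: float) -> np.ndarray:
    """Circular bin indices for angles in degrees.

    Bins are half-open [-180 + k*w, -180 + (k+1)*w) anchored at -180; an
    angle of exactly +180 wraps into the first bin (the circle identifies
    +180 with -180).  ``bin_width`` must divide 360.
    """
    nbins = int(round(360.0 / bin_width))
    if abs(nbins * bin_width - 360.0) > 1e-9:
        raise ConfeError(f"bin width {bin_width} must divide 360")
    return np.floor((np.asarray(angles, dtype=float) + 180.0)
                    / bin_width).astype(int) % nbins


def histogram_torsions(ensemble: ConformationEnsemble, torsions: TorsionSet,
                       bin_width: float = 30.0) -> list[DihedralHistogram]:
    """Histogram every torsion of the set over all frames.

    Binning follows :func:`bin_angles` (half-open bins anchored at -180,
    +180 identified with -180).
    """
    nbins = int(round(360.0 / bin_width))
    if ensemble.n_frames < 1:
        raise ConfeError("ensemble has no frames")
    angles = dihedrals(ensemble.coordinates, torsions.quads)  # (F, Nd)
    angles = np.atleast_2d(angles)
    idx = bin_angles(angles, bin_width)
    out = []
    for t in range(torsions.nd):
        counts = np.bincount(idx[:, t], minlength=nbins).astype(float)
        out.append(DihedralHistogram(
            torsion_index=t, label=torsions.labels[t], bin_width=bin_width,
            probabilities=counts / counts.sum(),
            n_samples=ensemble.n_frames))
    return out


def entropy(histograms: list[DihedralHistogram], mode: str = "differential",
            miller_madow: bool = False) -> EntropyResult:
    """Entropy summed over independent torsions (nats).

    ``miller_madow`` adds the (m-1)/(2n) occupancy-count bias correction
    per torsion (off by default).
    """
    if mode not in ("discrete", "differential"):
        raise ValueError(f"unknown entropy mode {mode!r}")
    if not histograms:
        raise ConfeError("no histograms given")
    widths = {h.bin_width for h in histograms}
    if len(widths) != 1:
        raise ConfeError(f"mixed bin widths {sorted(widths)}")
    w = histograms[0].bin_width
    w_rad = np.radians(w)
    s = np.zeros(len(histograms))
    for k, h in enumerate(histograms):
        p = h.probabilities[h.probabilities > 0]
        sk = float(-np.sum(p * np.log(p)))
        if miller_madow:
            sk += (len(p) - 1) / (2.0 * h.n_samples)
        if mode == "differential":
            sk += np.log(w_rad)
        s[k] = sk
    return EntropyResult(s, mode, w, len(histograms),
                         [h.label for h in histograms])


def ts_term(result: EntropyResult, temperature: float = 300.0) -> float:
    """TS in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_KCAL * temperature * result.s_total


def bin_sensitivity(ensemble: ConformationEnsemble, torsions: TorsionSet,
                    widths: tuple[float, ...] = (12.0, 30.0, 60.0, 120.0),
                    mode: str = "differential",
                    temperature: float = 300.0) -> pd.DataFrame:
    """TS as a function of histogram bin width.

    Reports S (nats), TS (kcal/mol) and the deviation of each width's TS
    from the mean TS of the other widths, as a fraction.  On smooth torsion
    distributions the differential-mode TS is nearly flat for moderate
    widths and drifts for very coarse bins.
    """
    rows = []
    for w in widths:
        hists = histogram_torsions(ensemble, torsions, w)
        res = entropy(hists, mode)
        rows.append({"bin_width_deg": w, "s_nats": res.s_total,
                     "ts_kcal_mol": res.ts(temperature)})
    df = pd.DataFrame(rows)
    ts = df["ts_kcal_mol"].to_numpy()
    rel = np.zeros(len(ts))
    for k in range(len(ts)):
        others = np.delete(ts, k)
        ref = np.mean(others)
        rel[k] = (ts[k] - ref) / abs(ref) if ref != 0 else 0.0
    df["relative_deviation"] = rel
    return df


def entropy_parameter_recovery(spec, n_frames: int, seed: int,
                               bin_width: float = 30.0,
                               mode: str = "differential",
                               n_torsions_topology: int | None = None):
    """Estimator-validation harness against an analytic ground truth.

    Samples an ensemble from a synthetic torsion-distribution spec, runs the
    histogram estimator, and reports (estimated S, analytic S, error), all
    in nats summed over torsions.  Fixed-angle torsions have differential
    entropy -inf; compare those in discrete mode, where the truth is 0.
    """
    from . import synthetic
    from .geometry import enumerate_torsions

    topo = synthetic.make_toy_topology(
        n_residues=len(spec) + 3, atoms_per_residue=1)
    torsions = enumerate_torsions(topo)
    ens = synthetic.sample_ensemble(topo, spec, n_frames, seed)
    hists = histogram_torsions(ens, torsions, bin_width)
    res = entropy(hists, mode)
    analytic = spec.analytic_entropy_total(mode=mode)
    return res.s_total, analytic, res.s_total - analytic
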