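"""Ensemble free energies G1/G2, replicate statistics, and profiles.

The free energy of a conformational state ("form") a observed as an
ensemble of snapshots is

    G1_a = <E_MM>_a + <E_ASA>_a - T S_a        (with protein entropy)
    G2_a = <E_MM>_a + <E_ASA>_a                (without)

where the averages are arithmetic means of per-snapshot GBSA energies and
S_a is the dihedral-distribution entropy of the ensemble.  G2 - G1 = TS
identically.  Replicate runs (independent seeds) are summarized as mean
and sample standard deviation; two states are compared by the difference
of replicate means with a one-sigma significance flag.

The main entry point follows the model/results idiom:

>>> model = EnsembleFreeEnergy(ensemble, temperature=300.0)
>>> res = model.fit()
>>> res.record.g1, res.record.g2
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entropy as ent
from . import gbsa
from .exceptions import ConfeError, EnsembleError
from .geometry import TorsionSet, enumerate_torsions
from .structure import ConformationEnsemble


@dataclass
class FreeEnergyRecord:
    """G1/G2 bookkeeping for one ensemble.

    Sign convention: ``ts`` is the entropic term T*S (>= 0 whenever S >= 0)
    that is *subtracted* from the enthalpy, so g1 = g2 - ts.  Tabular
    output prints a "-TS" column (negated) to match the common layout of
    replicate free-energy tables.
    """

    label: str
    e_mm: float
    e_asa: float
    s_nats: float
    ts: float
    g2: float
    g1: float
    n_frames: int = 0
    n_energy_frames: int = 0
    run_id: int = 0
    temperature: float = 300.0
    entropy_mode: str = "differential"
    bin_width: float = 30.0
    nd: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.ts) and abs((self.g2 - self.g1) - self.ts) > \
                1e-9 * max(1.0, abs(self.g2)):
            raise ConfeError("record violates G2 - G1 = TS")

    @classmethod
    def from_components(cls, label: str, g2: float, ts: float,
                        run_id: int = 0, temperature: float = 300.0,
                        **kw) -> "FreeEnergyRecord":
        """Build a record from an enthalpy total and an entropic term.

        Used to recombine externally tabulated G2 and TS columns; the
        entropy in nats is back-computed from TS.
        """
        s = ts / (ent.KB_KCAL * temperature)
        return cls(label=label, e_mm=g2, e_asa=0.0, s_nats=s, ts=ts,
                   g2=g2, g1=g2 - ts, run_id=run_id,
                   temperature=temperature, **kw)


class FreeEnergyResults:
    """Fitted free-energy estimate with diagnostics."""

    def __init__(self, record: FreeEnergyRecord,
                 energy_frame: pd.DataFrame | None,
                 entropy_result: ent.EntropyResult | None,
                 histograms: list | None):
        self.record = record
        self.energy_frame = energy_frame
        self.entropy_result = entropy_result
        self.histograms = histograms

    def summary(self) -> str:
        r = self.record
        lines = [
            "Ensemble free energy",
            "=" * 46,
            f"{'label':<22}{r.label}",
            f"{'frames (entropy)':<22}{r.n_frames}",
            f"{'frames (energy)':<22}{r.n_energy_frames}",
            f"{'torsions Nd':<22}{r.nd}",
            f"{'entropy mode':<22}{r.entropy_mode}",
            f"{'bin width (deg)':<22}{r.bin_width:g}",
            f"{'temperature (K)':<22}{r.temperature:g}",
            "-" * 46,
            f"{'<E_MM>  (kcal/mol)':<22}{r.e_mm:14.4f}",
            f"{'<E_ASA> (kcal/mol)':<22}{r.e_asa:14.4f}",
            f"{'S (nats)':<22}{r.s_nats:14.4f}",
            f"{'TS (kcal/mol)':<22}{r.ts:14.4f}",
            f"{'G2 = <E> (kcal/mol)':<22}{r.g2:14.4f}",
            f"{'G1 = G2 - TS':<22}{r.g1:14.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


class EnsembleFreeEnergy:
    """Free-energy model for one conformational ensemble.

    Parameters
    ----------
    ensemble : ConformationEnsemble
        Snapshots of one form, solvent already stripped.
    gb, sa : GBParameters / SASAParameters
        GBSA model constants (standard defaults).
    torsions : TorsionSet, optional
        Defaults to all rotatable heavy-atom torsions of the topology.
    bin_width : float
        Histogram bin width in degrees (must divide 360).
    entropy_mode : {"differential", "discrete"}
    temperature : float, K
    energy_stride : int
        Evaluate GBSA energies on every stride-th frame only; entropy always
        uses all frames.
    skip_entropy : bool
        Allow single-frame ensembles; TS is reported as NaN and G1 = NaN.
    """

    def __init__(self, ensemble: ConformationEnsemble,
                 gb: gbsa.GBParameters | None = None,
                 sa: gbsa.SASAParameters | None = None,
                 torsions: TorsionSet | None = None,
                 bin_width: float = 30.0,
                 entropy_mode: str = "differential",
                 temperature: float = 300.0,
                 energy_stride: int = 1,
                 skip_entropy: bool = False,
                 label: str = "", run_id: int = 0):
        self.ensemble = ensemble
        self.gb = gb or gbsa.GBParameters()
        self.sa = sa or gbsa.SASAParameters()
        self.torsions = torsions
        self.bin_width = bin_width
        self.entropy_mode = entropy_mode
        self.temperature = temperature
        self.energy_stride = energy_stride
        self.skip_entropy = skip_entropy
        self.label = label
        self.run_id = run_id

    def fit(self) -> FreeEnergyResults:
        ens = self.ensemble
        if ens.n_frames < 2 and not self.skip_entropy:
            raise EnsembleError(
                "entropy needs at least 2 frames; pass skip_entropy=True "
                "to compute G2 only")
        e_mm, e_asa, frame = gbsa.ensemble_average(
            ens, self.gb, self.sa, stride=self.energy_stride)
        torsions = self.torsions
        if torsions is None:
            torsions = enumerate_torsions(ens.topology)
        if ens.n_frames >= 2 and torsions.nd > 0:
            hists = ent.histogram_torsions(ens, torsions, self.bin_width)
            eres = ent.entropy(hists, self.entropy_mode)
            s = eres.s_total
            ts = eres.ts(self.temperature)
        else:
            hists, eres = None, None
            s, ts = float("nan"), float("nan")
        g2 = e_mm + e_asa
        g1 = g2 - ts if np.isfinite(ts) else float("nan")
        record = FreeEnergyRecord(
            label=self.label, e_mm=e_mm, e_asa=e_asa, s_nats=s, ts=ts,
            g2=g2, g1=g1, n_frames=ens.n_frames, n_energy_frames=len(frame),
            run_id=self.run_id, temperature=self.temperature,
            entropy_mode=self.entropy_mode, bin_width=self.bin_width,
            nd=torsions.nd)
        return FreeEnergyResults(record, frame, eres, hists)


def free_energy_of_ensemble(ensemble: ConformationEnsemble,
                            **kwargs) -> FreeEnergyRecord:
    """Functional wrapper: fit an EnsembleFreeEnergy model, return the record."""
    return EnsembleFreeEnergy(ensemble, **kwargs).fit().record


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSummary:
    """Replicate-run statistics: mean and sample std (n-1) of G1, G2, TS."""

    records: list[FreeEnergyRecord]
    label: str = ""
    allow_single: bool = False

    def __post_init__(self) -> None:
        if len(self.records) < 2 and not self.allow_single:
            raise ConfeError("replicate summary needs at least 2 records")
        modes = {r.entropy_mode for r in self.records}
        temps = {r.temperature for r in self.records}
        if len(modes) != 1 or len(temps) != 1:
            raise ConfeError("records mix entropy modes or temperatures")
        if not self.label:
            self.label = self.records[0].label

    @property
    def entropy_mode(self) -> str:
        return self.records[0].entropy_mode

    @property
    def temperature(self) -> float:
        return self.records[0].temperature

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records])

    def mean(self, attr: str) -> float:
        return float(np.mean(self._values(attr)))

    def std(self, attr: str) -> float:
        if len(self.records) < 2:
            return 0.0
        return float(np.std(self._values(attr), ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Replicate table: run, G2, -TS, G1 plus Average and sigma rows.

        The entropic column is printed negated ("-TS", the quantity that is
        *added* to G2 to obtain G1), matching the common published layout.
        """
        rows = [{"run": r.run_id, "G2": r.g2, "-TS": -r.ts, "G1": r.g1}
                for r in self.records]
        df = pd.DataFrame(rows)
        avg = {"run": "Average", "G2": self.mean("g2"),
               "-TS": -self.mean("ts"), "G1": self.mean("g1")}
        sig = {"run": "sigma", "G2": self.std("g2"),
               "-TS": self.std("ts"), "G1": self.std("g1")}
        return pd.concat([df, pd.DataFrame([avg, sig])], ignore_index=True)


def summarize_replicates(records: list[FreeEnergyRecord],
                         label: str = "") -> ReplicateSummary:
    return ReplicateSummary(list(records), label)


@dataclass
class StateComparison:
    """Differences (state b minus state a) of replicate means.

    ``sigma_*`` is the quadrature-propagated standard deviation; a
    difference is flagged significant when it exceeds the larger of the two
    state deviations (the loose one-sigma criterion).
    """

    dg1: float
    dg2: float
    dts: float
    sigma_g1: float
    sigma_g2: float
    sigma_ts: float
    g1_significant: bool
    g2_significant: bool
    label_a: str = ""
    label_b: str = ""


def compare_states(a: ReplicateSummary, b: ReplicateSummary
                   ) -> StateComparison:
    """Compare two states' replicate summaries (b minus a)."""
    if a.entropy_mode != b.entropy_mode:
        raise ConfeError("entropy mode mismatch between states")
    if a.temperature != b.temperature:
        raise ConfeError("temperature mismatch between states")

    def delta(attr):
        return b.mean(attr) - a.mean(attr)

    def sig(attr):
        return float(np.hypot(a.std(attr), b.std(attr)))

    def flag(attr):
        return abs(delta(attr)) > max(a.std(attr), b.std(attr))

    return StateComparison(
        dg1=delta("g1"), dg2=delta("g2"), dts=delta("ts"),
        sigma_g1=sig("g1"), sigma_g2=sig("g2"), sigma_ts=sig("ts"),
        g1_significant=flag("g1"), g2_significant=flag("g2"),
        label_a=a.label, label_b=b.label)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """Ordered waypoints along a pathway with per-waypoint replicates."""

    labels: list[str]
    summaries: list[ReplicateSummary]
    direction: str = "A->B"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.summaries):
            raise ConfeError("labels and summaries differ in length")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, (lab, summ) in enumerate(zip(self.labels, self.summaries)):
            for r in summ.records:
                rows.append({"waypoint": w + 1, "label": lab,
                             "replicate": r.run_id, "G1": r.g1, "G2": r.g2,
                             "TS": r.ts})
        return pd.DataFrame(rows)

    def series(self, which: str = "g1") -> np.ndarray:
        return np.array([s.mean(which) for s in self.summaries])

    def reversed(self) -> "FreeEnergyProfile":
        direction = "B->A" if self.direction == "A->B" else "A->B"
        return FreeEnergyProfile(list(reversed(self.labels)),
                                 list(reversed(self.summaries)), direction)


def build_profile(waypoint_ensembles: list[tuple[str, list]],
                  direction: str = "A->B",
                  **model_kwargs) -> FreeEnergyProfile:
    """Free-energy profile from replicate ensembles at ordered waypoints.

    ``waypoint_ensembles`` is an ordered list of (label, [ensembles]) with
    at least one replicate ensemble per waypoint; model keyword arguments
    are passed to :class:`EnsembleFreeEnergy`.
    """
    if len(waypoint_ensembles) < 2:
        raise ConfeError("a profile needs at least 2 waypoints")
    labels = []
    summaries = []
    for w, (label, replicates) in enumerate(waypoint_ensembles):
        if not replicates:
            raise ConfeError(f"waypoint {label!r} has no ensembles")
        records = []
        for k, ens in enumerate(replicates):
            records.append(EnsembleFreeEnergy(
                ens, label=label, run_id=k + 1, **model_kwargs).fit().record)
        labels.append(label)
        summaries.append(ReplicateSummary(records, label, allow_single=True))
    return FreeEnergyProfile(labels, summaries, direction)
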