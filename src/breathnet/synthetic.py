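"""Synthetic cohorts of coupled breath-sampled cardiorespiratory series.

The generator emulates a three-arm cross-over hypoxia study: ~12
participants x 3 conditions (normoxic control CTR, ~2500 m simulated
altitude HY1, ~3500 m HY2) x 2 phases (rest, isometric exercise), each
recording a 5-min window sampled once per breath.  Channels follow a
stable vector-autoregressive scheme with explicit cross-lags, so the
directed couplings — the ground truth that TE estimation and surrogate
testing are validated against — are known exactly and tunable per
condition and phase.  Hypoxia at ~2500 m is emulated as globally weakened
coupling at rest and a rewired (decoupled) edge set during exercise,
which is the planted effect the similarity analysis should recover as the
lowest rest-exercise network similarity.

Everything is reproducible: one cohort seed expands into independent
per-recording and per-draw substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import MAD_SCALE
from .series import CHANNELS, BreathSeries, ParticipantRecording

__all__ = [
    "Edge", "CouplingSpec", "CohortSpec", "Cohort", "DEFAULT_EDGES",
    "generate_participant_recording", "generate_cohort", "inject_artifacts",
    "rewire_edges",
]


@dataclass(frozen=True)
class Edge:
    """Directed lagged coupling: source drives target ``lag`` breaths later."""

    source: str
    target: str
    lag: int
    strength: float


def _distributed(source: str, target: str, strength: float,
                 lags: tuple[int, ...] = (5, 4)) -> tuple[Edge, ...]:
    """One physiological link, smeared over a short window of breaths.

    Cardiorespiratory influences (chemoreflex and mechanical feedback) act
    over roughly 12-15 s rather than one exact breath, so each conceptual
    link contributes at two adjacent lags around the ~5-breath horizon.
    """
    return tuple(Edge(source, target, lag, strength) for lag in lags)


#: Default coupling structure: a plausible resting cardiorespiratory web.
#: Breathing pattern (VT, RF) drives ventilation, ventilation and pattern
#: drive the end-tidal gas tensions, gas tensions drive HR, HR drives
#: oxygen uptake.  The wiring is acyclic, which keeps the lagged-linear
#: system stationary for any coupling strengths in [0, 1] (the companion
#: spectrum reduces to the per-channel AR coefficients).
DEFAULT_EDGES: tuple[Edge, ...] = (
    _distributed("VT", "RF", 0.35)
    + _distributed("VT", "VE", 0.35)
    + _distributed("RF", "VE", 0.40)
    + _distributed("VE", "PETO2", 0.45)
    + _distributed("VT", "PETO2", 0.35)
    + _distributed("VE", "PETCO2", 0.35)
    + _distributed("RF", "PETCO2", 0.40)
    + _distributed("PETO2", "HR", 0.45)
    + _distributed("PETCO2", "HR", 0.40)
    + _distributed("HR", "VO2", 0.35)
)

#: Plausible channel means and scales (SDs) in physiological units.  TE is
#: invariant under monotone rescaling with quantile binning, so these set
#: realistic magnitudes without affecting estimation tests.
DEFAULT_MEANS: dict[str, float] = {
    "HR": 80.0, "RF": 16.0, "VE": 12.0, "VT": 0.75,
    "VO2": 0.35, "PETO2": 100.0, "PETCO2": 38.0,
}
DEFAULT_SCALES: dict[str, float] = {
    "HR": 4.0, "RF": 2.0, "VE": 1.5, "VT": 0.08,
    "VO2": 0.04, "PETO2": 3.0, "PETCO2": 1.5,
}


@dataclass(frozen=True)
class CouplingSpec:
    """A stationary lagged-linear system over the seven channels.

    Each channel follows, in standardised deviations ``z = (x - mean)/scale``,

        z_j[t] = ar_j * z_j[t-1] + sum_edges strength * z_src[t-lag] + noise,

    then is mapped back to physiological units.  Stationarity (spectral
    radius of the companion matrix < 1) is checked before any generation.
    """

    channels: tuple[str, ...] = CHANNELS
    edges: tuple[Edge, ...] = DEFAULT_EDGES
    ar_coefficient: float = 0.55
    noise_sd_z: float = 0.8  # innovation SD in standardised units
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALES))

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd_z <= 0:
            raise ValueError("noise_sd_z must be positive")
        for e in self.edges:
            if e.source not in self.channels or e.target not in self.channels:
                raise ValueError(f"edge {e} references unknown channel")
            if e.lag < 1:
                raise ValueError(f"edge {e}: lag must be a positive integer "
                                 "(instantaneous self-loops are not allowed)")
            if not 0 <= e.strength <= 1:
                raise ValueError(f"edge {e}: strength must lie in [0, 1]")
        rho = self.spectral_radius()
        if rho >= 1:
            raise ValueError(
                f"non-stationary coupling spec: companion spectral radius "
                f"{rho:.3f} >= 1; reduce strengths or ar_coefficient")

    @property
    def max_lag(self) -> int:
        return max([e.lag for e in self.edges], default=1)

    def scaled(self, multiplier: float) -> "CouplingSpec":
        """Copy with every coupling strength multiplied (clipped to [0, 1])."""
        edges = tuple(Edge(e.source, e.target, e.lag,
                           float(np.clip(e.strength * multiplier, 0, 1)))
                      for e in self.edges)
        return CouplingSpec(self.channels, edges, self.ar_coefficient,
                            self.noise_sd_z, dict(self.means), dict(self.scales))

    def with_edges(self, edges: tuple[Edge, ...]) -> "CouplingSpec":
        return CouplingSpec(self.channels, edges, self.ar_coefficient,
                            self.noise_sd_z, dict(self.means), dict(self.scales))

    def coefficient_tensor(self) -> np.ndarray:
        """(max_lag, k, k) array A with z[t] = sum_l A[l-1] z[t-l] + noise."""
        k = len(self.channels)
        idx = {c: i for i, c in enumerate(self.channels)}
        A = np.zeros((self.max_lag, k, k))
        for i in range(k):
            A[0, i, i] = self.ar_coefficient
        for e in self.edges:
            A[e.lag - 1, idx[e.target], idx[e.source]] += e.strength
        return A

    def companion_matrix(self) -> np.ndarray:
        A = self.coefficient_tensor()
        p, k, _ = A.shape
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = np.concatenate(list(A), axis=1)
        if p > 1:
            comp[k:, :-k] = np.eye(k * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def total_coupling(self) -> float:
        """Ground-truth total coupling: sum of edge strengths."""
        return float(sum(e.strength for e in self.edges))


def _topological_order(edges: tuple[Edge, ...],
                       channels: tuple[str, ...]) -> list[str] | None:
    """Kahn's algorithm with ties broken by channel order; None if cyclic."""
    links = {(e.source, e.target) for e in edges}
    indeg = {c: 0 for c in channels}
    for _, t in links:
        indeg[t] += 1
    order: list[str] = []
    ready = [c for c in channels if indeg[c] == 0]
    while ready:
        node = ready.pop(0)
        order.append(node)
        for s, t in sorted(links):
            if s == node:
                indeg[t] -= 1
                if indeg[t] == 0 and t not in ready:
                    ready.append(t)
        ready.sort(key=channels.index)
    return order if len(order) == len(channels) else None


def rewire_edges(edges: tuple[Edge, ...],
                 channels: tuple[str, ...] = CHANNELS,
                 shift: int = 1) -> tuple[Edge, ...]:
    """Deterministically redirect every link to a different target.

    Produces a same-sized, same-strength edge set with mostly disjoint
    wiring — the "decoupled" network used to plant a rest-exercise
    dissimilarity.  Each link's target rotates ``shift`` positions among
    the channels downstream of its source in a topological order of the
    original wiring, so an acyclic (hence stationary-for-any-strengths)
    coupling stays acyclic.  All lag components of one link move
    together; a link whose source has a single downstream channel keeps
    its target.
    """
    order = _topological_order(edges, channels) or list(channels)
    pos = {c: i for i, c in enumerate(order)}
    remap: dict[tuple[str, str], str] = {}
    taken: set[tuple[str, str]] = set()
    out = []
    for e in edges:
        link = (e.source, e.target)
        if link not in remap:
            segment = order[pos[e.source] + 1:]
            j = segment.index(e.target) if e.target in segment else 0
            for extra in range(len(segment)):
                cand = segment[(j + shift + extra) % len(segment)]
                if (e.source, cand) not in taken:
                    remap[link] = cand
                    taken.add((e.source, cand))
                    break
            else:
                remap[link] = e.target
        out.append(Edge(e.source, remap[link], e.lag, e.strength))
    return tuple(out)


def generate_participant_recording(spec: CouplingSpec, rf: float,
                                   window_minutes: float, seed, *,
                                   participant_id: str = "P00",
                                   condition: str = "CTR",
                                   phase: str = "rest",
                                   ibi_jitter_shape: float | None = None,
                                   ) -> ParticipantRecording:
    """Simulate one recording of ``round(rf * window_minutes)`` breaths.

    A burn-in of at least ``10 * max_lag`` samples is discarded so the
    series start near the stationary distribution.  ``ibi_jitter_shape``
    optionally attaches Gamma-distributed inter-breath times (the analysis
    itself stays event-indexed, so this is off by default).
    """
    if rf <= 0:
        raise ValueError("breathing frequency must be positive")
    n = int(round(rf * window_minutes))
    if n < 30:
        raise ValueError(f"window of {n} breaths is too short for TE "
                         "estimation (need >= 30)")
    p = spec.max_lag
    if n <= 2 * p:
        raise ValueError(f"window of {n} breaths too short for max lag {p}")
    burn = max(10 * p, 50)
    total = burn + n
    k = len(spec.channels)
    A = spec.coefficient_tensor()
    rng = np.random.default_rng(seed)
    z = np.zeros((total, k))
    eps = rng.normal(0.0, spec.noise_sd_z, size=(total, k))
    for t in range(p, total):
        acc = eps[t].copy()
        for l in range(p):
            acc += A[l] @ z[t - l - 1]
        z[t] = acc
    z = z[burn:]
    channels = {}
    for i, name in enumerate(spec.channels):
        values = spec.means[name] + spec.scales[name] * z[:, i]
        channels[name] = BreathSeries(name, values)
    times = None
    if ibi_jitter_shape is not None:
        mean_ibi = 60.0 / rf
        intervals = rng.gamma(ibi_jitter_shape,
                              mean_ibi / ibi_jitter_shape, size=n)
        times = np.cumsum(intervals)
    return ParticipantRecording(participant_id=participant_id,
                                condition=condition, phase=phase,
                                channels=channels, times=times)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cross-over cohort.

    Defaults mirror the emulated study: 12 participants (six F, six M),
    three inspired-oxygen conditions, rest (~15 breaths/min) and exercise
    (~25 breaths/min) phases of 5 min each, condition- and phase-specific
    coupling multipliers with a decoupled (rewired) edge set for the
    low-grade-hypoxia exercise phase, and symptom flags drawn from a
    logistic model on ground-truth total coupling (slope 0 by default: no
    true symptom-coupling association).
    """

    n_participants: int = 12
    conditions: tuple[str, ...] = ("CTR", "HY1", "HY2")
    phases: tuple[str, ...] = ("rest", "exercise")
    base_coupling: CouplingSpec = field(default_factory=CouplingSpec)
    multipliers: dict = field(default_factory=lambda: {
        ("CTR", "rest"): 1.0, ("CTR", "exercise"): 1.0,
        ("HY1", "rest"): 0.35, ("HY1", "exercise"): 0.8,
        ("HY2", "rest"): 0.9, ("HY2", "exercise"): 1.0,
    })
    decoupled: tuple = (("HY1", "exercise"),)
    rf_mean: float = 15.0
    rf_sd: float = 2.5
    exercise_rf_mean: float = 25.0
    exercise_rf_sd: float = 3.0
    window_minutes: float = 5.0
    symptom_intercept: float = -0.6931  # logit(1/3): control-arm prevalence
    symptom_slope: float = 0.0
    headache_rate: float = 0.17
    fio2: dict = field(default_factory=lambda: {
        "CTR": 0.209, "HY1": 0.151, "HY2": 0.135})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.rf_mean * self.window_minutes < 30:
            raise ValueError("rf_mean * window_minutes must allow >= 30 samples")
        for cond in self.conditions:
            for phase in self.phases:
                if (cond, phase) not in self.multipliers:
                    raise ValueError(f"no coupling multiplier for {(cond, phase)}")

    def coupling_for(self, condition: str, phase: str) -> CouplingSpec:
        """Effective coupling spec for one cell of the design."""
        spec = self.base_coupling.scaled(self.multipliers[(condition, phase)])
        if (condition, phase) in self.decoupled:
            spec = spec.with_edges(rewire_edges(spec.edges, spec.channels))
        return spec


@dataclass
class Cohort:
    """Generated recordings plus the per-participant cohort table."""

    spec: CohortSpec
    recordings: dict  # (participant_id, condition, phase) -> ParticipantRecording
    table: pd.DataFrame  # one row per participant x condition

    def recording(self, participant: str, condition: str,
                  phase: str) -> ParticipantRecording:
        return self.recordings[(participant, condition, phase)]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate all ``n x conditions x phases`` recordings and cohort table.

    Every recording and every Bernoulli draw uses its own substream keyed
    on (cohort seed, participant, condition, phase), so any single element
    is reproducible in isolation and the whole cohort is reproducible
    from ``spec.seed`` alone.
    """
    recordings = {}
    rows = []
    for p_idx in range(spec.n_participants):
        pid = f"P{p_idx + 1:02d}"
        sex = "F" if p_idx < spec.n_participants / 2 else "M"
        for c_idx, cond in enumerate(spec.conditions):
            truth_total = 0.0
            for ph_idx, phase in enumerate(spec.phases):
                coupling = spec.coupling_for(cond, phase)
                truth_total += coupling.total_coupling()
                rf_mean, rf_sd = ((spec.exercise_rf_mean, spec.exercise_rf_sd)
                                  if phase == "exercise"
                                  else (spec.rf_mean, spec.rf_sd))
                ss = np.random.SeedSequence((spec.seed, 1, p_idx, c_idx, ph_idx))
                rng = np.random.default_rng(ss)
                rf = float(np.clip(rng.normal(rf_mean, rf_sd), 8.0, 40.0))
                rec = generate_participant_recording(
                    coupling, rf, spec.window_minutes, rng,
                    participant_id=pid, condition=cond, phase=phase)
                recordings[(pid, cond, phase)] = rec
            draw = np.random.default_rng(
                np.random.SeedSequence((spec.seed, 2, p_idx, c_idx)))
            p_sym = _sigmoid(spec.symptom_intercept
                             + spec.symptom_slope * truth_total)
            symptom = bool(draw.random() < p_sym)
            headache = bool(draw.random() < spec.headache_rate)
            fio2 = spec.fio2.get(cond, 0.209)
            spo2 = float(np.clip(1.416 * fio2 * 100 + 68.83
                                 + draw.normal(0.0, 1.73), 50.0, 100.0))
            rows.append({"participant_id": pid, "sex": sex, "condition": cond,
                         "symptom": symptom, "headache": headache,
                         "spo2": spo2, "fio2": fio2,
                         "truth_total_coupling": truth_total})
    table = pd.DataFrame(rows)
    return Cohort(spec=spec, recordings=recordings, table=table)


def inject_artifacts(recording: ParticipantRecording, artifact_rate: float,
                     magnitude: float, seed) -> tuple[ParticipantRecording, dict]:
    """Corrupt a fraction of samples per channel with +/- magnitude spikes.

    Each channel gets ``round(rate * n)`` random breaths replaced by
    ``value +/- magnitude * robust sigma`` (1.4826 x the channel's MAD),
    emulating isolated breath-by-breath artifacts.  Returns the corrupted
    recording and the ground-truth indices per channel, for validating
    outlier detection and interpolation.
    """
    if not 0 <= artifact_rate < 0.2:
        raise ValueError("artifact_rate must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    n_bad = int(round(artifact_rate * n))
    truth: dict[str, np.ndarray] = {}
    new_channels = {}
    for name, series in recording.channels.items():
        values = series.values.copy()
        idx = np.sort(rng.choice(n, size=n_bad, replace=False))
        if n_bad:
            med = np.median(values)
            sigma = MAD_SCALE * np.median(np.abs(values - med))
            signs = rng.choice([-1.0, 1.0], size=n_bad)
            values[idx] = values[idx] + signs * magnitude * sigma
        truth[name] = idx
        new_channels[name] = series.with_values(values)
    corrupted = ParticipantRecording(
        participant_id=recording.participant_id,
        condition=recording.condition, phase=recording.phase,
        channels=new_channels,
        times=None if recording.times is None else recording.times.copy())
    return corrupted, truth
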