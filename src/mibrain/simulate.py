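"""Seeded synthetic EEG with known coupling structure.

Two generators are provided:

* :func:`simulate_ar_network` — a multichannel autoregressive system in which
  each channel follows the same stable AR(p) recursion and selected channel
  pairs are tied by lagged linear cross-terms. A single lagged coupling between
  two channels (e.g. C3 -> C4) is the classic surrogate for a genuine
  time-lagged interhemispheric interaction, against which connectivity
  estimators are benchmarked.
* :func:`simulate_cohort` — group-structured cohorts (HC, PSND, PSMD, PSD) in
  which interhemispheric, fronto-parieto-occipital and intrahemispheric
  coupling strengths are generative knobs, so group contrasts in downstream
  network metrics are known by construction.

Volume conduction (instantaneous linear mixing of sources into electrodes) is
modelled separately by :func:`apply_mixing` so that parameter-recovery studies
can switch it on and off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .recording import (
    EEGRecording,
    HOMOLOGOUS_PAIRS,
    MONTAGE_16,
    hemisphere_of,
)

logger = logging.getLogger(__name__)

#: Default per-channel AR(2) coefficients: characteristic roots 0.6 and 0.5,
#: a smooth low-pass process with substantial short-lag autocorrelation. The
#: autocorrelation matters twice over: a lagged cross-channel coupling is only
#: visible to a zero-lag dependence measure through the signals' own
#: autocorrelation at that lag, while excessive autocorrelation shrinks the
#: effective sample count per epoch and inflates the plug-in MI bias floor
#: until genuine couplings drown in it.
DEFAULT_AR_COEFFICIENTS = (1.1, -0.3)

#: Per-channel output standard deviation after standardisation, in the
#: microvolt-scale units of the recording.
DEFAULT_OUTPUT_SD = 10.0

#: Samples generated before the retained stretch, to wash out the transient.
BURN_IN_SAMPLES = 1000

GROUP_LABELS = ("HC", "PSND", "PSMD", "PSD")


@dataclass(frozen=True)
class ARCouplingSpec:
    """A lagged linear influence of one channel on another.

    ``target[t] += strength * source[t - lag]``
    """

    source_channel: int
    target_channel: int
    lag: int
    strength: float

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError(f"coupling lag must be >= 1, got {self.lag}")
        if self.source_channel == self.target_channel:
            raise ValueError("coupling source and target must differ")
        if not np.isfinite(self.strength):
            raise ValueError("coupling strength must be finite")


@dataclass(frozen=True)
class CohortScenario:
    """Generative parameters for one subject group.

    The three strength knobs scale fixed coupling templates: homologous
    left->right pairs (interhemispheric), contralateral frontal->
    parieto-occipital links (fronto_parietal), and anterior->posterior links
    within the left hemisphere (intrahemispheric).
    """

    group_label: str
    n_subjects: int
    interhemispheric_strength: float
    fronto_parietal_strength: float
    intrahemispheric_strength: float = 0.3
    noise_sd: float = 1.0
    mixing: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("interhemispheric_strength", "fronto_parietal_strength",
                     "intrahemispheric_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("mixing matrix must be square")
            if np.linalg.matrix_rank(m) < m.shape[0]:
                raise ValueError("mixing matrix must have full rank")


def _var_coefficient_matrices(n_channels, ar_coefficients, couplings):
    """Stack the VAR lag matrices A_1..A_p implied by per-channel AR
    coefficients plus cross-channel couplings."""
    ar = tuple(float(a) for a in ar_coefficients)
    max_lag = len(ar)
    for c in couplings:
        max_lag = max(max_lag, c.lag)
        for idx in (c.source_channel, c.target_channel):
            if not 0 <= idx < n_channels:
                raise ValueError(f"coupling channel index {idx} out of range for {n_channels} channels")
    if max_lag == 0:
        return np.zeros((0, n_channels, n_channels))
    A = np.zeros((max_lag, n_channels, n_channels))
    for lag_idx, a in enumerate(ar):
        A[lag_idx] += a * np.eye(n_channels)
    for c in couplings:
        A[c.lag - 1, c.target_channel, c.source_channel] += c.strength
    return A


def _topological_order(n_channels, couplings):
    """Kahn's algorithm on the coupling digraph; None if it has a cycle."""
    indeg = [0] * n_channels
    out_edges = [[] for _ in range(n_channels)]
    for c in couplings:
        out_edges[c.source_channel].append(c.target_channel)
        indeg[c.target_channel] += 1
    queue = [i for i in range(n_channels) if indeg[i] == 0]
    order = []
    while queue:
        u = queue.pop()
        order.append(u)
        for v in out_edges[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    return order if len(order) == n_channels else None


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR with lag matrices ``A``
    (shape (p, n, n)). Radius < 1 iff the process is stable."""
    p, n, _ = A.shape
    if p == 0:
        return 0.0
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(A, axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_ar_network(
    n_channels: int,
    duration_s: float,
    sampling_rate: float,
    ar_coefficients: Sequence[float] = DEFAULT_AR_COEFFICIENTS,
    couplings: Sequence[ARCouplingSpec] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    channel_labels: Optional[Sequence[str]] = None,
    standardize: bool = True,
) -> EEGRecording:
    """Simulate a coupled-AR multichannel recording.

    Every channel follows ``x[t] = sum_l a_l x[t-l] + noise`` with the shared
    ``ar_coefficients``; each :class:`ARCouplingSpec` adds a lagged cross-term.
    The full VAR must be stable (companion spectral radius < 1) or a
    ``ValueError`` naming the radius is raised. A burn-in stretch of
    ``BURN_IN_SAMPLES`` is generated and discarded, and identical arguments
    (including ``seed``) give bit-identical output.

    With ``standardize`` (default), each channel is rescaled to a common
    standard deviation of ``DEFAULT_OUTPUT_SD`` microvolts, emulating the
    roughly uniform amplitude of scalp EEG: a strongly driven channel would
    otherwise dominate any cross-channel average (e.g. the average reference).
    Per-channel affine rescaling leaves the histogram MI between channels
    unchanged, because equal-width binning over each signal's own range is
    affine-invariant.
    """
    n_samples = int(round(duration_s * sampling_rate))
    if n_samples < 2:
        raise ValueError("duration too short")
    A = _var_coefficient_matrices(n_channels, ar_coefficients, couplings)
    p = A.shape[0]
    if p >= n_samples:
        raise ValueError(f"maximum lag {p} must be smaller than the {n_samples}-sample recording")
    if couplings and n_samples < 10 * max(c.lag for c in couplings):
        raise ValueError("recording must be at least 10x the maximum coupling lag")
    radius = companion_spectral_radius(A)
    if radius >= 1.0:
        raise ValueError(
            f"unstable AR system: companion spectral radius {radius:.4f} >= 1"
        )

    rng = np.random.default_rng(seed)
    total = n_samples + BURN_IN_SAMPLES
    noise = rng.standard_normal((total, n_channels)) * noise_sd

    order = _topological_order(n_channels, couplings)
    if order is not None:
        # acyclic coupling graph: each channel is its own AR filter driven by
        # noise plus lagged, already-generated source channels — fully
        # vectorised per channel
        import scipy.signal

        ar = np.asarray(ar_coefficients, dtype=float)
        denom = np.concatenate([[1.0], -ar]) if ar.size else np.array([1.0])
        by_target = {}
        for c in couplings:
            by_target.setdefault(c.target_channel, []).append(c)
        xT = np.zeros((n_channels, total))
        for ch in order:
            drive = noise[:, ch].copy()
            for c in by_target.get(ch, ()):
                drive[c.lag:] += c.strength * xT[c.source_channel, : total - c.lag]
            xT[ch] = scipy.signal.lfilter([1.0], denom, drive)
        data = xT[:, BURN_IN_SAMPLES:].copy()
    else:
        x = np.zeros((total, n_channels))
        for t in range(total):
            acc = noise[t]
            for lag in range(1, min(p, t) + 1):
                acc = acc + A[lag - 1] @ x[t - lag]
            x[t] = acc
        data = x[BURN_IN_SAMPLES:].T.copy()
    if standardize:
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = data / sd * DEFAULT_OUTPUT_SD

    if channel_labels is None:
        if n_channels == 16:
            channel_labels = MONTAGE_16
        else:
            channel_labels = tuple(f"ch{i}" for i in range(n_channels))
    return EEGRecording(
        data=data,
        sampling_rate=sampling_rate,
        channel_labels=channel_labels,
        reference="simulated",
    )


def apply_mixing(recording: EEGRecording, mixing_matrix: np.ndarray) -> EEGRecording:
    """Instantaneously mix channels: ``output = M @ data``.

    Models volume conduction — linear zero-lag leakage of sources into several
    electrodes, the classic source of spurious connectivity. A singular mixing
    matrix is accepted but logged with its rank.
    """
    M = np.asarray(mixing_matrix, dtype=float)
    n = recording.n_channels
    if M.shape != (n, n):
        raise ValueError(f"mixing matrix shape {M.shape} does not match {n} channels")
    if not np.all(np.isfinite(M)):
        raise ValueError("mixing matrix contains non-finite values")
    rank = int(np.linalg.matrix_rank(M))
    if rank < n:
        logger.warning("mixing matrix is singular (rank %d of %d); channels will be linearly dependent", rank, n)
        warnings.warn(f"mixing matrix is singular (rank {rank} of {n})", stacklevel=2)
    return recording.copy_with(data=M @ recording.data, reference=recording.reference + "+mixed")


#: Anterior->posterior coupling pairs of the cohort template. The
#: fronto-parieto-occipital links run contralaterally (right frontal to left
#: posterior), so they are both anterior-posterior and hemisphere-crossing;
#: the remaining intrahemispheric links stay within the left hemisphere.
COHORT_FRONTO_PARIETAL_PAIRS = (("F4", "P3"), ("Fp2", "O1"))
COHORT_INTRAHEMISPHERIC_PAIRS = (("C3", "T3"), ("P3", "T5"))

#: Scenario strengths are dimensionless knobs in [0, 1]; this gain converts
#: them into AR cross-coefficients sized so that the weakest group's couplings
#: sit at the connectivity floor while the strongest group's are reliably
#: detected — i.e. the group contrast spans the estimator's dynamic range.
COHORT_COUPLING_GAIN = 0.2

#: Per-channel total injected coupling power (scenario coupling plus hidden
#: background source) is held at this constant amplitude, so every channel has
#: an identical spectrum regardless of the scenario strengths. Without this,
#: channels receiving strong couplings become spectrally slower than pure
#: channels, and pairs of such channels acquire inflated plug-in MI (the
#: histogram estimator's bias grows with autocorrelation) — a floor
#: heterogeneity that would masquerade as connectivity.
COHORT_TOTAL_INJECTION = 0.85

#: Fixed per-homologous-pair multipliers on the interhemispheric coupling — a
#: topographic profile (strongest prefrontal, weakest posterior-temporal) that
#: spreads the eight pairs across the detection transition, so group strength
#: differences translate into graded rather than all-or-nothing edge counts.
COHORT_PAIR_PROFILE = dict(zip(HOMOLOGOUS_PAIRS, (1.6, 1.3, 1.05, 0.85, 0.68, 0.55, 0.44, 0.36)))

#: One lag (in samples) for every cohort coupling and hidden injection.
COHORT_COUPLING_LAG = 2


def _cohort_couplings(
    montage: Sequence[str],
    interhemispheric: float,
    fronto_parietal: float,
    intrahemispheric: float,
) -> tuple:
    """Build the coupling set for one cohort subject.

    Returns ``(couplings, n_total_channels)`` where channels beyond the
    montage are hidden background sources, one per scalp channel: each scalp
    channel receives its scenario coupling (if any) plus a hidden injection
    topping total injected power up to ``COHORT_TOTAL_INJECTION``. Every
    scalp channel receives at most one scenario coupling, so no two channels
    share a lagged driver (which would create spurious near-duplicate pairs),
    and the digraph is acyclic (left->right, anterior->posterior), so the VAR
    is stable for any strengths.
    """
    index = {label: i for i, label in enumerate(montage)}
    n = len(montage)
    S = COHORT_TOTAL_INJECTION

    incoming = {}
    if interhemispheric > 0:
        for pair in HOMOLOGOUS_PAIRS:
            left, right = pair
            incoming[right] = (left, interhemispheric * COHORT_COUPLING_GAIN * COHORT_PAIR_PROFILE[pair])
    if fronto_parietal > 0:
        for src, dst in COHORT_FRONTO_PARIETAL_PAIRS:
            incoming[dst] = (src, fronto_parietal * COHORT_COUPLING_GAIN)
    if intrahemispheric > 0:
        for src, dst in COHORT_INTRAHEMISPHERIC_PAIRS:
            incoming[dst] = (src, intrahemispheric * COHORT_COUPLING_GAIN)

    couplings = []
    for i, channel in enumerate(montage):
        entry = incoming.get(channel)
        c = entry[1] if entry else 0.0
        c = min(c, S)  # power budget cap
        if entry and c > 0:
            couplings.append(ARCouplingSpec(index[entry[0]], i, COHORT_COUPLING_LAG, c))
        b = np.sqrt(max(S * S - c * c, 0.0))
        if b > 1e-12:
            couplings.append(ARCouplingSpec(n + i, i, COHORT_COUPLING_LAG, b))
    return couplings, 2 * n


def subject_seed(scenario_seed: int, subject_index: int) -> int:
    """Deterministic, collision-free per-subject seed."""
    return scenario_seed * 10007 + subject_index


def simulate_cohort(
    scenarios: Sequence[CohortScenario],
    montage: Sequence[str] = MONTAGE_16,
    duration_s: float = 300.0,
    sampling_rate: float = 250.0,
) -> list:
    """Generate per-subject recordings for each group scenario.

    Returns a list of ``(group_label, EEGRecording)`` in scenario order, with
    ``n_subjects`` recordings per scenario. Subject seeds derive
    deterministically from the scenario seed and subject index.
    """
    montage = tuple(montage)
    for label in montage:
        hemisphere_of(label)  # raises KeyError listing valid names
    n_left = sum(1 for m in montage if hemisphere_of(m) == "left")
    if n_left != len(montage) - n_left:
        raise ValueError("montage must have equal left and right electrode counts")

    out = []
    for scenario in scenarios:
        couplings, n_total = _cohort_couplings(
            montage,
            scenario.interhemispheric_strength,
            scenario.fronto_parietal_strength,
            scenario.intrahemispheric_strength,
        )
        hidden_labels = tuple(f"src{i}" for i in range(n_total - len(montage)))
        for subject in range(scenario.n_subjects):
            full = simulate_ar_network(
                n_channels=n_total,
                duration_s=duration_s,
                sampling_rate=sampling_rate,
                couplings=couplings,
                noise_sd=scenario.noise_sd,
                seed=subject_seed(scenario.seed, subject),
                channel_labels=montage + hidden_labels,
            )
            # keep only the scalp montage; the rest are hidden background sources
            rec = EEGRecording(
                data=full.data[: len(montage)],
                sampling_rate=sampling_rate,
                channel_labels=montage,
                reference="simulated",
            )
            if scenario.mixing is not None:
                rec = apply_mixing(rec, scenario.mixing)
            out.append((scenario.group_label, rec))
    return out


def default_cohort_scenarios(
    n_subjects: int = 15,
    seed: int = 0,
    strengths: Sequence[float] = (0.8, 0.6, 0.4, 0.2),
    fronto_parietal: Sequence[float] = (0.7, 0.55, 0.4, 0.25),
    intrahemispheric: Sequence[float] = (0.2, 0.45, 0.6, 0.75),
    noise_sd: float = 1.0,
) -> list:
    """Four-group scenario set encoding the qualitative group ordering the
    analysis is meant to recover: interhemispheric and fronto-parieto-
    occipital coupling decrease monotonically from HC to PSD, while other
    within-hemisphere coupling increases correspondingly (weakened
    left-right communication with relatively enhanced hemisphere-internal
    connections as depression severity grows)."""
    scenarios = []
    for i, group in enumerate(GROUP_LABELS):
        scenarios.append(
            CohortScenario(
                group_label=group,
                n_subjects=n_subjects,
                interhemispheric_strength=float(strengths[i]),
                fronto_parietal_strength=float(fronto_parietal[i]),
                intrahemispheric_strength=float(intrahemispheric[i]),
                noise_sd=noise_sd,
                seed=seed * 4 + i,
            )
        )
    return scenarios
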