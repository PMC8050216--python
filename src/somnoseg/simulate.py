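"""Synthetic multi-cohort polysomnography.

The generator emits Markov-chain hypnograms at 30-s resolution and
stage-conditioned oscillatory EEG/EOG signals so the whole pipeline —
EDF ingestion, preprocessing, sampling, training, inference, and the
high-frequency triplet analysis — can be exercised without any real
recordings.  Signal realism targets learnability, not physiology: each
stage carries a distinct spectral/amplitude signature (alpha-band wake,
low-amplitude mixed N1, spindle-band N2, high-amplitude slow-wave N3,
REM marked by large slow EOG deflections), with MASK epochs rendered as
artifact-like high-variance noise.

Two default montages mirror a heterogeneous multi-cohort setting: cohort
A uses {C3-M2, C4-M1, ROC-M1, LOC-M2} at 256 Hz, cohort B uses
{Fpz-Cz, EOG horizontal} at 100 Hz.

For the downstream classification experiment,
:func:`generate_two_population_cohort` contrasts a consolidated-sleep
control population with a fast-transition ("OSA-like") population whose
N2/N3/REM → W/N1 arousal probabilities are multiplied by a configurable
factor; at multiplier 1 the populations are identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._stages import MASK_CODE, N_STAGES, STAGES
from .io import Channel, Hypnogram, PSGRecord, infer_channel_role

__all__ = [
    "CohortSpec",
    "MONTAGE_A",
    "MONTAGE_B",
    "CONTROL_TRANSITIONS",
    "arousal_matrix",
    "generate_hypnogram",
    "generate_psg",
    "generate_record",
    "generate_collection_datasets",
    "generate_two_population_cohort",
]

MONTAGE_A: tuple[str, ...] = ("C3-M2", "C4-M1", "ROC-M1", "LOC-M2")
MONTAGE_B: tuple[str, ...] = ("Fpz-Cz", "EOG horizontal")

#: 30-s stage transition probabilities of a consolidated ("control")
#: sleeper, rows/columns ordered W, N1, N2, N3, REM.
CONTROL_TRANSITIONS: np.ndarray = np.array(
    [
        [0.85, 0.12, 0.03, 0.00, 0.00],
        [0.05, 0.60, 0.32, 0.01, 0.02],
        [0.02, 0.03, 0.85, 0.07, 0.03],
        [0.01, 0.01, 0.08, 0.88, 0.02],
        [0.03, 0.05, 0.07, 0.00, 0.85],
    ]
)

#: Per-stage oscillation/noise settings: (EEG osc Hz, EEG osc amplitude,
#: EEG noise SD, EOG osc Hz, EOG osc amplitude, EOG noise SD), amplitudes
#: in arbitrary microvolt-like units.
DEFAULT_STAGE_SIGNALS: dict[str, tuple[float, float, float, float, float, float]] = {
    "W": (10.0, 30.0, 10.0, 0.8, 8.0, 8.0),
    "N1": (5.0, 12.0, 8.0, 0.3, 10.0, 5.0),
    "N2": (13.0, 28.0, 8.0, 0.3, 6.0, 5.0),
    "N3": (1.0, 75.0, 10.0, 0.2, 5.0, 5.0),
    "REM": (6.0, 10.0, 8.0, 0.35, 55.0, 5.0),
}

_MASK_NOISE_SD = 150.0


@dataclass
class CohortSpec:
    n_subjects: int = 4
    montage: tuple[str, ...] = MONTAGE_A
    native_rate: float = 256.0
    record_hours: float = 8.0
    transition_matrix: np.ndarray = field(default_factory=lambda: CONTROL_TRANSITIONS.copy())
    mask_rate: float = 0.02
    stage_signal_params: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_SIGNALS))
    dataset_id: str = "cohortA"
    seed: int = 0

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=np.float64)
        if P.shape != (N_STAGES, N_STAGES) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 5×5 row-stochastic")
        self.transition_matrix = P
        if not 0.0 <= self.mask_rate <= 0.2:
            raise ValueError("mask_rate must lie in [0, 0.2]")

    @property
    def n_epochs(self) -> int:
        return int(round(self.record_hours * 3600.0 / 30.0))


def arousal_matrix(base: np.ndarray = CONTROL_TRANSITIONS, multiplier: float = 4.0
                   ) -> np.ndarray:
    """A fast-transition variant of ``base``: probabilities of leaving N2,
    N3 and REM toward W or N1 are scaled by ``multiplier`` and each row is
    rebalanced through its self-transition.  Multiplier 1 is the identity.
    """
    P = np.asarray(base, dtype=np.float64).copy()
    for row in (2, 3, 4):  # N2, N3, REM
        for col in (0, 1):  # → W, → N1
            P[row, col] *= multiplier
        off = P[row].copy()
        off[row] = 0.0
        total = off.sum()
        if total >= 1.0:  # keep the row stochastic even for extreme multipliers
            P[row] = off / total
        else:
            P[row] = off
            P[row, row] = 1.0 - total
    return P


def generate_hypnogram(spec: CohortSpec, rng: np.random.Generator) -> Hypnogram:
    """A 30-s Markov-chain stage sequence started in Wake, with MASK epochs
    injected independently at ``spec.mask_rate``."""
    P = spec.transition_matrix
    labels = np.empty(spec.n_epochs, dtype=np.int8)
    state = 0  # W
    for t in range(spec.n_epochs):
        labels[t] = state
        state = int(rng.choice(N_STAGES, p=P[state]))
    masked = rng.random(spec.n_epochs) < spec.mask_rate
    labels[masked] = MASK_CODE
    return Hypnogram(labels)


def _epoch_signal(stage_code: int, role: str, n: int, rate: float,
                  params: dict, rng: np.random.Generator) -> np.ndarray:
    if stage_code == MASK_CODE:
        return rng.normal(0.0, _MASK_NOISE_SD, n)
    f_eeg, a_eeg, s_eeg, f_eog, a_eog, s_eog = params[STAGES[stage_code]]
    freq, amp, noise = (f_eog, a_eog, s_eog) if role == "EOG" else (f_eeg, a_eeg, s_eeg)
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    return amp * np.sin(2 * np.pi * freq * t + phase) + rng.normal(0.0, noise, n)


def generate_psg(hyp: Hypnogram, spec: CohortSpec, rng: np.random.Generator,
                 subject_id: str = "S000") -> PSGRecord:
    """Stage-conditioned signals for every channel of the montage."""
    n_epoch_samples = int(round(30.0 * spec.native_rate))
    channels = []
    for label in spec.montage:
        role = infer_channel_role(label)
        x = np.empty(len(hyp) * n_epoch_samples)
        for e, code in enumerate(hyp.labels):
            x[e * n_epoch_samples : (e + 1) * n_epoch_samples] = _epoch_signal(
                int(code), role, n_epoch_samples, spec.native_rate,
                spec.stage_signal_params, rng)
        channels.append(Channel(label, role, spec.native_rate, x))
    return PSGRecord(subject_id, spec.dataset_id, channels)


def generate_record(spec: CohortSpec, rng: np.random.Generator,
                    subject_id: str = "S000") -> tuple[PSGRecord, Hypnogram]:
    hyp = generate_hypnogram(spec, rng)
    return generate_psg(hyp, spec, rng, subject_id), hyp


def generate_collection_datasets(specs, seed: int = 0):
    """Materialize ``[(dataset_id, [(record, hypnogram), ...]), ...]`` for a
    list of cohort specs (input to the training sampler after preprocessing)."""
    out = []
    for k, spec in enumerate(specs):
        rng = np.random.default_rng([seed, spec.seed, k])
        records = []
        for s in range(spec.n_subjects):
            subject_id = f"{spec.dataset_id}-{s:03d}"
            records.append(generate_record(spec, rng, subject_id))
        out.append((spec.dataset_id, records))
    return out


def generate_two_population_cohort(n_control: int = 25, n_case: int = 55,
                                   rng: np.random.Generator | None = None,
                                   arousal_multiplier: float = 4.0,
                                   record_hours: float = 8.0,
                                   with_signals: bool = False):
    """A labeled control-vs-fast-transition cohort for the classification
    experiment (defaults mirror the 25-control / 55-case population).

    Returns ``(hypnograms, labels)`` — dicts keyed by subject id, labels
    0 = control, 1 = case — or ``(records, hypnograms, labels)`` when
    ``with_signals`` is set.
    """
    if min(n_control, n_case) < 2:
        raise ValueError("need at least 2 subjects per class")
    rng = rng if rng is not None else np.random.default_rng(0)
    case_P = arousal_matrix(CONTROL_TRANSITIONS, arousal_multiplier)
    hyps: dict[str, Hypnogram] = {}
    labels: dict[str, int] = {}
    records: dict[str, PSGRecord] = {}
    for group, n, P in (("ctl", n_control, CONTROL_TRANSITIONS), ("osa", n_case, case_P)):
        spec = CohortSpec(n_subjects=n, record_hours=record_hours,
                          transition_matrix=P, mask_rate=0.0, dataset_id=group)
        for s in range(n):
            sid = f"{group}-{s:03d}"
            hyp = generate_hypnogram(spec, rng)
            hyps[sid] = hyp
            labels[sid] = 0 if group == "ctl" else 1
            if with_signals:
                records[sid] = generate_psg(hyp, spec, rng, sid)
    if with_signals:
        return records, hyps, labels
    return hyps, labels
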