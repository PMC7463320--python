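"""Synthetic 450K-style beta matrices for paired and case/control designs.

The generator emulates the statistical structure the downstream analysis
relies on, without any array-level physics: per-probe baseline methylation,
a shared subject effect inducing within-pair correlation, and additive
tumor (or case) effects, all on the logit scale so that beta values stay
strictly inside (0, 1) with no clipping.

Generative model, probe j and subject i::

    logit(beta) = logit(m_j) + u_ij + delta_j * [tumor/case] + eps

with m_j ~ Beta(baseline_alpha, baseline_beta) drawn once per probe,
u_ij ~ N(0, subject_sd^2) shared by both samples of a subject,
delta_j the configured logit-scale shift (0 for unlisted probes), and
eps ~ N(0, noise_sd^2) independent per entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import BetaMatrix, SampleSheet

# distinct stream tags so the two designs give unrelated draws under one seed
_PAIRED_STREAM = 1
_CASE_CONTROL_STREAM = 2

#: age range (years) of the emulated blood case/control recruitment
AGE_RANGE = (55.0, 75.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic beta-matrix generator.

    ``probes`` should include every CpG of any clock under test plus
    background filler probes.  ``effects`` maps probe id to the logit-scale
    shift applied in tumor (paired design) or case (blood design) samples;
    positive means hypermethylated in tumor/case.
    """

    n_subjects: int
    probes: list[str]
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    subject_sd: float = 0.5
    effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    detection_fail_rate: float = 0.0
    n_cases: int | None = None
    n_controls: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not self.probes:
            raise ValueError("probe list must not be empty")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probe ids in simulation config")
        if self.baseline_alpha <= 0 or self.baseline_beta <= 0:
            raise ValueError("baseline Beta shape parameters must be positive")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        unknown = set(self.effects) - set(self.probes)
        if unknown:
            raise ValueError(f"effect probes not in probe list: {sorted(unknown)}")
        if not 0.0 <= self.detection_fail_rate <= 1.0:
            raise ValueError("detection_fail_rate must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def default_probes(clock_probes: list[str] | None = None, n_background: int = 200) -> list[str]:
    """Probe list combining clock CpGs with synthetic background probes."""
    clock_probes = list(clock_probes or [])
    background = [f"bg{i:05d}" for i in range(n_background)]
    return clock_probes + background


def _effect_vector(config: SimulationConfig) -> np.ndarray:
    return np.array([config.effects.get(p, 0.0) for p in config.probes], dtype=float)


def _detection_p(
    rng: np.random.Generator, shape: tuple[int, int], fail_rate: float, threshold: float = 0.01
) -> pd.DataFrame | None:
    """Per-entry detection p-values; a ``fail_rate`` fraction lands above
    ``threshold`` (flagged as unreliable), the rest well below it."""
    if fail_rate == 0.0:
        return None
    flagged = rng.random(shape) < fail_rate
    low = rng.uniform(0.0, threshold / 2.0, size=shape)
    high = rng.uniform(threshold * 1.1, 1.0, size=shape)
    return pd.DataFrame(np.where(flagged, high, low))


def simulate_paired(config: SimulationConfig) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate one tumor and one adjacent-normal sample per subject.

    Deterministic for a fixed ``config.seed``.  Stage is assigned uniformly
    from {I, II, III, IV} per subject; ages uniform over the emulated
    recruitment range; effects apply to tumor columns only.
    """
    rng = np.random.default_rng([_PAIRED_STREAM, config.seed])
    n_probes = len(config.probes)
    n_sub = config.n_subjects

    m = rng.beta(config.baseline_alpha, config.baseline_beta, size=n_probes)
    base = logit(m)[:, None]  # (probes, 1)
    u = rng.normal(0.0, config.subject_sd, size=(n_probes, n_sub))
    delta = _effect_vector(config)[:, None]

    eps_normal = rng.normal(0.0, config.noise_sd, size=(n_probes, n_sub))
    eps_tumor = rng.normal(0.0, config.noise_sd, size=(n_probes, n_sub))
    beta_normal = expit(base + u + eps_normal)
    beta_tumor = expit(base + u + delta + eps_tumor)

    subjects = [f"s{i + 1:04d}" for i in range(n_sub)]
    sample_ids: list[str] = []
    rows = []
    stages = rng.choice(["I", "II", "III", "IV"], size=n_sub)
    ages = rng.uniform(*AGE_RANGE, size=n_sub)
    sexes = rng.choice(["M", "F"], size=n_sub)
    values = np.empty((n_probes, 2 * n_sub))
    for i, subj in enumerate(subjects):
        for role, col in (("normal", beta_normal[:, i]), ("tumor", beta_tumor[:, i])):
            sid = f"{subj}_{role[0].upper()}"
            values[:, len(sample_ids)] = col
            sample_ids.append(sid)
            rows.append(
                dict(
                    sample_id=sid,
                    subject_id=subj,
                    tissue_role=role,
                    group="none",
                    stage=stages[i],
                    age=ages[i],
                    sex=sexes[i],
                )
            )
    frame = pd.DataFrame(values, index=pd.Index(config.probes, name="probe_id"), columns=sample_ids)
    dp = _detection_p(rng, frame.shape, config.detection_fail_rate)
    if dp is not None:
        dp.index, dp.columns = frame.index, frame.columns
    sheet = SampleSheet(pd.DataFrame(rows))
    return BetaMatrix(frame, dp), sheet


def simulate_case_control(config: SimulationConfig) -> tuple[BetaMatrix, SampleSheet]:
    """Simulate one blood sample per subject, split into cases and controls.

    ``n_cases``/``n_controls`` default to a balanced split of ``n_subjects``
    (controls get the extra subject when odd).  Effects apply to cases.
    """
    rng = np.random.default_rng([_CASE_CONTROL_STREAM, config.seed])
    n_cases = config.n_cases if config.n_cases is not None else config.n_subjects // 2
    n_controls = (
        config.n_controls if config.n_controls is not None else config.n_subjects - n_cases
    )
    n_sub = n_cases + n_controls
    n_probes = len(config.probes)

    m = rng.beta(config.baseline_alpha, config.baseline_beta, size=n_probes)
    base = logit(m)[:, None]
    u = rng.normal(0.0, config.subject_sd, size=(n_probes, n_sub))
    eps = rng.normal(0.0, config.noise_sd, size=(n_probes, n_sub))
    is_case = np.array([True] * n_cases + [False] * n_controls)
    delta = _effect_vector(config)[:, None] * is_case[None, :]
    values = expit(base + u + delta + eps)

    subjects = [f"s{i + 1:04d}" for i in range(n_sub)]
    sample_ids = [f"{s}_B" for s in subjects]
    stages = rng.choice(["I", "II", "III", "IV"], size=n_sub)
    ages = rng.uniform(*AGE_RANGE, size=n_sub)
    sexes = rng.choice(["M", "F"], size=n_sub)
    rows = [
        dict(
            sample_id=sample_ids[i],
            subject_id=subjects[i],
            tissue_role="blood",
            group="case" if is_case[i] else "control",
            stage=stages[i] if is_case[i] else "unknown",
            age=ages[i],
            sex=sexes[i],
        )
        for i in range(n_sub)
    ]
    frame = pd.DataFrame(values, index=pd.Index(config.probes, name="probe_id"), columns=sample_ids)
    dp = _detection_p(rng, frame.shape, config.detection_fail_rate)
    if dp is not None:
        dp.index, dp.columns = frame.index, frame.columns
    sheet = SampleSheet(pd.DataFrame(rows))
    return BetaMatrix(frame, dp), sheet
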