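"""Synthetic study cohort with known ground-truth effect structure.

Emulates a placebo-controlled, within-subject psilocybin design: 19-channel
10-20 EEG at 300 Hz recorded at baseline and 1 h / 2 h / 4.5 h post-dose
under a 1 mg (inactive) and a 25 mg (active) condition; behavioral scores
(psychological insight, well-being) tied to a per-subject latent "entropy
responsiveness"; 200-region parcellated timeseries with block-modular
covariance; and a 7-outcome change-score table with a planted correlated
cluster.  Every generator is a pure function of its arguments and seed, so
each downstream analysis stage can be tested against the planted truth
without any external data.

The active condition thins the 10 Hz alpha rhythm and boosts broadband
irregularity at 1 h and 2 h (maximal at 2 h, back near baseline by 4.5 h),
scaled by the subject latent — reproducing the canonical psychedelic EEG
signature of decreased alpha power and increased Lempel-Ziv complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .eeg import CHANNELS_1020, EegRecording

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "OUTCOME_NAMES",
    "OUTCOME_SIGNS",
    "generate_eeg_recording",
    "generate_behavior",
    "generate_parcel_timeseries",
    "generate_outcome_changes",
    "generate_latents",
]

TIMEPOINTS: tuple[str, ...] = ("baseline", "1h", "2h", "4.5h")
CONDITIONS: tuple[str, ...] = ("1mg", "25mg")

#: The seven change-score outcomes of the long-term correlation matrix.
OUTCOME_NAMES: tuple[str, ...] = (
    "EDS_errors",   # extradimensional-shift errors (fewer = more flexible)
    "amg_RSFC",     # amygdala resting-state functional connectivity
    "wellbeing",    # WEMWBS change
    "emo_fMRI",     # BOLD response to emotional faces
    "modularity",   # normalized network modularity Q change
    "DTI_AD",       # axial diffusivity in merged prefrontal-subcortical tracts
    "insight",      # psychological insight (PIS)
)

#: Planted direction of each outcome's change after the active dose, so a
#: shared improvement factor yields the observed mixed-sign correlations.
OUTCOME_SIGNS: dict[str, int] = {
    "EDS_errors": -1,
    "amg_RSFC": -1,
    "wellbeing": +1,
    "emo_fMRI": -1,
    "modularity": -1,
    "DTI_AD": -1,
    "insight": +1,
}

# Condition modulation of the EEG generator per post-dose timepoint: how
# strongly the active dose suppresses alpha and boosts broadband noise.
_DOSE_MODULATION: dict[str, float] = {"baseline": 0.0, "1h": 0.8, "2h": 1.0, "4.5h": 0.15}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    The defaults are the emulated study's conditions: n=28 subjects,
    4-minute 19-channel EEG at 300 Hz, standardized mediation slopes
    (entropy -> insight 0.55, insight -> well-being 0.50, direct entropy ->
    well-being 0.20), 200 regions in 4 modules, and a target modularity /
    well-being change correlation of -0.4.
    """

    n_subjects: int = 28
    sampling_rate: float = 300.0
    recording_duration: float = 240.0
    channel_labels: tuple[str, ...] = CHANNELS_1020
    timepoints: tuple[str, ...] = TIMEPOINTS
    conditions: tuple[str, ...] = CONDITIONS
    entropy_effect_insight: float = 0.55
    insight_effect_wellbeing: float = 0.50
    direct_entropy_wellbeing: float = 0.20
    insight_noise_sd: float | None = None     # None -> unit-variance closure
    wellbeing_noise_sd: float | None = None
    n_regions: int = 200
    n_modules: int = 4
    rho_within: float = 0.30
    rho_between: float = 0.05
    modularity_wellbeing_r: float = -0.4
    alpha_amplitude: float = 1.0
    noise_amplitude: float = 0.4
    latent_gain: float = 0.3  # how strongly the subject latent scales dosing effects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        for name in ("rho_within", "rho_between", "modularity_wellbeing_r"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.rho_within <= self.rho_between:
            raise ValueError(
                "rho_within must exceed rho_between for identifiable modules "
                f"(got {self.rho_within} <= {self.rho_between})"
            )

    def module_assignment(self) -> np.ndarray:
        """Planted region -> module labels; remainder goes to the last module."""
        per = self.n_regions // self.n_modules
        labels = np.repeat(np.arange(self.n_modules), per)
        if labels.size < self.n_regions:
            labels = np.concatenate(
                [labels, np.full(self.n_regions - labels.size, self.n_modules - 1)]
            )
        return labels


@dataclass
class GroundTruth:
    """Planted per-subject effects, for downstream recovery tests."""

    latents: np.ndarray                  # per-subject entropy z-scores
    insight_std: np.ndarray              # standardized planted insight
    wellbeing_change_std: np.ndarray     # standardized planted well-being change
    module_assignment: np.ndarray        # region -> module partition
    cluster_members: tuple[str, ...] = field(default_factory=tuple)


def generate_latents(config: CohortConfig, seed: int | None = None) -> np.ndarray:
    """Per-subject latent entropy-responsiveness z-scores."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return rng.standard_normal(config.n_subjects)


def _check_labels(condition: str, timepoint: str, config: CohortConfig) -> None:
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; expected one of {config.conditions}")
    if timepoint not in config.timepoints:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {config.timepoints}")


def generate_eeg_recording(
    subject_latent: float,
    condition: str,
    timepoint: str,
    config: CohortConfig,
    seed: int,
    subject: str = "sub-00",
) -> EegRecording:
    """One synthetic resting-state EEG recording.

    The signal is a 10 Hz alpha sinusoid (random phase per channel, center
    of the 8-13 Hz alpha band) plus broadband white noise band-limited to
    1-45 Hz.  Under the active dose at 1 h / 2 h the alpha amplitude is
    reduced and the noise amplitude increased, scaled by the subject latent;
    the placebo dose and baseline are unmodulated.  Deterministic given the
    seed: the phase and noise draws are identical across conditions, so
    paired contrasts isolate the amplitude modulation.
    """
    _check_labels(condition, timepoint, config)
    rng = np.random.default_rng(seed)
    n_ch = len(config.channel_labels)
    n_samp = int(round(config.recording_duration * config.sampling_rate))
    t = np.arange(n_samp) / config.sampling_rate
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    raw_noise = rng.standard_normal((n_ch, n_samp))
    sos = scipy.signal.butter(4, [1.0, 45.0], btype="bandpass", fs=config.sampling_rate, output="sos")
    noise = scipy.signal.sosfiltfilt(sos, raw_noise, axis=1)
    noise /= noise.std(axis=1, keepdims=True)

    modulation = 0.0
    if condition == "25mg":
        modulation = _DOSE_MODULATION.get(timepoint, 0.0) * max(
            0.0, 1.0 + config.latent_gain * subject_latent
        )
    w_alpha = config.alpha_amplitude * max(0.0, 1.0 - 0.55 * modulation)
    w_noise = config.noise_amplitude * (1.0 + 0.5 * modulation)

    data = w_alpha * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None]) + w_noise * noise
    return EegRecording(
        subject=subject,
        dose=condition,
        timepoint=timepoint,
        channels=config.channel_labels,
        sampling_rate=config.sampling_rate,
        data=data,
    )


def generate_behavior(
    latents: np.ndarray,
    config: CohortConfig,
    seed: int,
) -> pd.DataFrame:
    """Behavioral score table with the planted mediation chain.

    Standardized structure: ``insight* = a z + e1`` and
    ``wellbeing_change* = b insight* + c' z + e2`` with slopes
    ``a = entropy_effect_insight``, ``b = insight_effect_wellbeing`` and
    ``c' = direct_entropy_wellbeing``.  Noise SDs default to the values that
    make both standardized variables unit-variance.  Scores are then
    affine-mapped into instrument ranges: insight as a continuous PIS sum
    score (6 VAS items, 0-100 each, total 0-600), well-being as WEMWBS
    totals clipped to [14, 70] (population norm 51 +/- 9).  Placebo (1 mg)
    rows carry zero planted effect.

    Returns one row per subject x condition with columns ``subject``,
    ``condition``, ``insight``, ``wellbeing_pre``, ``wellbeing_post``,
    ``wellbeing_change`` plus the standardized latents.
    """
    z = np.asarray(latents, dtype=float)
    n = z.size
    a = config.entropy_effect_insight
    b = config.insight_effect_wellbeing
    cp = config.direct_entropy_wellbeing
    for v in (a, b, cp):
        if not np.isfinite(v):
            raise ValueError("mediation slopes must be finite")
    sd1 = config.insight_noise_sd
    if sd1 is None:
        sd1 = float(np.sqrt(max(0.0, 1.0 - a**2)))
    sd2 = config.wellbeing_noise_sd
    if sd2 is None:
        var_expl = b**2 + cp**2 + 2 * b * cp * a
        sd2 = float(np.sqrt(max(0.0, 1.0 - var_expl)))
    rng = np.random.default_rng(seed)

    rows = []
    truth = {}
    for condition in config.conditions:
        e1 = rng.standard_normal(n) * sd1
        e2 = rng.standard_normal(n) * sd2
        if condition == "25mg":
            insight_std = a * z + e1
            wb_std = b * insight_std + cp * z + e2
        else:
            insight_std = e1
            wb_std = e2
        # Instrument mapping: active condition shows the large group effects
        # (next-day insight strongly elevated; well-being up ~5 points).
        if condition == "25mg":
            insight_score = 250.0 + 80.0 * insight_std
            wb_change = 4.7 + 6.0 * wb_std
        else:
            insight_score = 40.0 + 20.0 * insight_std
            wb_change = 0.0 + 6.0 * wb_std
        insight_score = np.clip(insight_score, 0.0, 600.0)
        wb_pre = np.clip(51.0 + 9.0 * rng.standard_normal(n), 14.0, 70.0)
        wb_post = np.clip(wb_pre + wb_change, 14.0, 70.0)
        wb_change = wb_post - wb_pre
        if condition == "25mg":
            truth["insight_std"] = insight_std
            truth["wellbeing_change_std"] = wb_std
        for i in range(n):
            rows.append(
                {
                    "subject": f"sub-{i:02d}",
                    "condition": condition,
                    "latent_entropy": z[i],
                    "insight": insight_score[i],
                    "wellbeing_pre": wb_pre[i],
                    "wellbeing_post": wb_post[i],
                    "wellbeing_change": wb_change[i],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = truth
    return df


def _block_covariance(config: CohortConfig, modularity_shift: float) -> np.ndarray:
    labels = config.module_assignment()
    same = labels[:, None] == labels[None, :]
    rho_b = config.rho_between + modularity_shift
    cov = np.where(same, config.rho_within, rho_b)
    np.fill_diagonal(cov, 1.0)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-10:
        raise ValueError(
            "block covariance not positive semi-definite for "
            f"rho_within={config.rho_within}, rho_between={rho_b} "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return cov


def generate_parcel_timeseries(
    config: CohortConfig,
    modularity_shift: float = 0.0,
    seed: int = 0,
    n_samples: int = 384,
) -> np.ndarray:
    """Region x time matrix drawn from a block-modular covariance.

    Within-module correlation is ``rho_within``; between-module correlation
    is ``rho_between + modularity_shift`` (a positive shift raises
    between-module coupling and therefore lowers modularity Q).  The default
    384 samples emulate an 8-minute scan at TR = 1.25 s.
    """
    cov = _block_covariance(config, modularity_shift)
    rng = np.random.default_rng(seed)
    # eigh-based square root: tolerant of the semi-definite boundary
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    ts = root @ rng.standard_normal((config.n_regions, n_samples))
    return ts


def generate_outcome_changes(
    config: CohortConfig,
    cluster_members: tuple[str, ...] = ("wellbeing", "modularity", "DTI_AD", "insight"),
    cluster_r: float = 0.6,
    seed: int = 0,
    n_subjects: int | None = None,
) -> pd.DataFrame:
    """Seven-outcome change-score table with one planted correlated cluster.

    Cluster members load on a shared improvement factor so that each pair of
    members correlates at about ``cluster_r``, with signs given by the
    outcome's planted direction of change (well-being and insight increase;
    modularity, axial diffusivity, EDS errors, amygdala RSFC and the
    emotional-faces BOLD response decrease).  Non-members are independent
    noise.  Outcomes are left standardized; the test statistic is
    scale-free.
    """
    if not 0.0 <= cluster_r < 1.0:
        raise ValueError(f"cluster_r={cluster_r} outside [0, 1)")
    unknown = set(cluster_members) - set(OUTCOME_NAMES)
    if unknown:
        raise ValueError(f"unknown outcomes {sorted(unknown)}; expected {OUTCOME_NAMES}")
    n = config.n_subjects if n_subjects is None else n_subjects
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n)
    data = {}
    for name in OUTCOME_NAMES:
        noise = rng.standard_normal(n)
        if name in cluster_members:
            load = np.sqrt(cluster_r)
            x = load * factor + np.sqrt(1.0 - cluster_r) * noise
            data[name] = OUTCOME_SIGNS[name] * x
        else:
            data[name] = noise
    df = pd.DataFrame(data, index=[f"sub-{i:02d}" for i in range(n)])
    df.index.name = "subject"
    df.attrs["contrast"] = "post-25mg vs post-1mg"
    df.attrs["cluster_members"] = tuple(cluster_members)
    return df


def _derived_seed(*entropy: int) -> int:
    """Stable per-item seed below 2**31, derived from integer coordinates."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass
class Cohort:
    """A fully materialized-on-demand synthetic cohort.

    Behavioral scores and the outcome change table are generated eagerly;
    EEG recordings and parcellated timeseries are produced lazily (their
    seeds are a pure function of the cohort seed and the recording
    coordinates), so a 28-subject cohort never needs to hold hours of
    signal in memory at once.
    """

    config: CohortConfig
    latents: np.ndarray
    behavior: pd.DataFrame
    outcome_changes: pd.DataFrame
    parcel_shifts: np.ndarray  # per-subject post-session between-module shift
    truth: GroundTruth

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"sub-{i:02d}" for i in range(self.config.n_subjects))

    def eeg_recording(self, subject_idx: int, condition: str, timepoint: str) -> EegRecording:
        c = self.config.conditions.index(condition)
        t = self.config.timepoints.index(timepoint)
        seed = _derived_seed(self.config.seed, 1, subject_idx, c, t)
        return generate_eeg_recording(
            float(self.latents[subject_idx]),
            condition,
            timepoint,
            self.config,
            seed=seed,
            subject=f"sub-{subject_idx:02d}",
        )

    def parcel_timeseries(self, subject_idx: int, session: str, n_samples: int = 384) -> np.ndarray:
        if session == "pre":
            shift = 0.0
        elif session == "post":
            shift = float(self.parcel_shifts[subject_idx])
        else:
            raise ValueError("session must be 'pre' or 'post'")
        seed = _derived_seed(self.config.seed, 2, subject_idx, 0 if session == "pre" else 1)
        return generate_parcel_timeseries(self.config, modularity_shift=shift, seed=seed, n_samples=n_samples)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the cohort-level structure for all downstream stages.

    The per-subject post-session between-module shift is built to correlate
    with the planted well-being change at ``-modularity_wellbeing_r`` (a
    larger shift raises between-module coupling and so *lowers* Q, giving
    the target negative modularity-change vs well-being-change
    correlation).  Shifts are clipped to keep the block covariance valid.
    """
    latents = generate_latents(config)
    behavior = generate_behavior(latents, config, seed=_derived_seed(config.seed, 3))
    truth_b = behavior.attrs["ground_truth"]
    outcome_changes = generate_outcome_changes(config, seed=_derived_seed(config.seed, 4))

    rho = config.modularity_wellbeing_r
    rng = np.random.default_rng(_derived_seed(config.seed, 5))
    wb = np.asarray(truth_b["wellbeing_change_std"], dtype=float)
    wb_z = (wb - wb.mean()) / wb.std() if wb.std() > 0 else wb
    u = -rho * wb_z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(config.n_subjects)
    # operating point: mid-range between-module shifts, where the normalized
    # Q statistic responds steeply, so the planted correlation survives the
    # Louvain/null estimation noise
    max_shift = max(0.0, config.rho_within - config.rho_between - 0.05)
    shifts = np.clip((0.6 + 0.25 * u) * max_shift, 0.0, 0.95 * max_shift)

    truth = GroundTruth(
        latents=latents,
        insight_std=np.asarray(truth_b["insight_std"]),
        wellbeing_change_std=wb,
        module_assignment=config.module_assignment(),
        cluster_members=outcome_changes.attrs["cluster_members"],
    )
    return Cohort(
        config=config,
        latents=latents,
        behavior=behavior,
        outcome_changes=outcome_changes,
        parcel_shifts=shifts,
        truth=truth,
    )
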