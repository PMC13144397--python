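"""Pipeline orchestration and on-disk formats.

Artifacts are plain text or numpy containers: EEG as a ``.npy`` array plus
a ``.json`` sidecar (subject, dose, timepoint, channel labels, Hz),
behavioral and change tables as CSV with a header row, parcel timeseries as
TSV (regions x time), and every stage report as JSON.  ``run_pipeline``
executes the enabled stages in dependency order; all randomness is seeded
from the global seed via per-stage derived seeds, so a fixed config and
seed reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortConfig, _derived_seed, generate_cohort
from .eeg import EegRecording, FeatureTensor, band_power, lzc_channel, preprocess
from .mediation import fit_mediation
from .modularity import fc_matrix, modularity_score
from .outcomes import adjusted_change_correlation, correlation_cluster_test
from .predictor import fit_final_predictor

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_table",
    "write_table",
    "read_eeg",
    "write_eeg",
    "read_matrix",
    "write_matrix",
    "read_features",
    "write_features",
]

ALL_STAGES = ("simulate", "features", "predict", "mediate", "modularity", "corrcluster")

BEHAVIOR_COLUMNS = [
    "subject", "condition", "latent_entropy", "insight",
    "wellbeing_pre", "wellbeing_post", "wellbeing_change",
]
FEATURE_COLUMNS = ["subject", "electrode", "timepoint", "feature", "value"]


# ---------------------------------------------------------------------------
# readers / writers

def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    path = Path(path)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"table is missing required columns {missing}")
        df = df[columns]
    df.to_csv(path, index=False)


def read_table(path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        unexpected = [c for c in df.columns if c not in columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}; unexpected {unexpected}")
    return df


def write_eeg(recording: EegRecording, directory, stem: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"{recording.subject}_{recording.dose}_{recording.timepoint.replace('.', 'p')}"
    np.save(directory / f"{stem}.npy", recording.data)
    sidecar = {
        "subject": recording.subject,
        "dose": recording.dose,
        "timepoint": recording.timepoint,
        "channels": list(recording.channels),
        "sampling_rate": recording.sampling_rate,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{stem}.npy"


def read_eeg(path) -> EegRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path)
    return EegRecording(
        subject=sidecar["subject"],
        dose=sidecar["dose"],
        timepoint=sidecar["timepoint"],
        channels=tuple(sidecar["channels"]),
        sampling_rate=float(sidecar["sampling_rate"]),
        data=data,
    )


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t")


def read_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    return np.atleast_2d(m)


def write_features(tensor: FeatureTensor, path) -> None:
    """FeatureTensor -> tidy CSV (subject, electrode, timepoint, feature, value)."""
    rows = []
    for si, s in enumerate(tensor.subjects):
        for ei, e in enumerate(tensor.electrodes):
            for ti, t in enumerate(tensor.timepoints):
                rows.append((s, e, t, tensor.feature_name, tensor.values[si, ei, ti]))
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_features(path, feature_name: str | None = None) -> FeatureTensor:
    df = read_table(path, FEATURE_COLUMNS)
    if feature_name is not None:
        df = df[df["feature"] == feature_name]
    else:
        feature_name = df["feature"].iloc[0]
        df = df[df["feature"] == feature_name]
    subjects = tuple(dict.fromkeys(df["subject"]))
    electrodes = tuple(dict.fromkeys(df["electrode"]))
    timepoints = tuple(dict.fromkeys(df["timepoint"]))
    values = np.full((len(subjects), len(electrodes), len(timepoints)), np.nan)
    s_ix = {s: i for i, s in enumerate(subjects)}
    e_ix = {e: i for i, e in enumerate(electrodes)}
    t_ix = {t: i for i, t in enumerate(timepoints)}
    for row in df.itertuples(index=False):
        values[s_ix[row.subject], e_ix[row.electrode], t_ix[row.timepoint]] = row.value
    return FeatureTensor(
        values=values,
        feature_name=str(feature_name),
        subjects=subjects,
        electrodes=electrodes,
        timepoints=timepoints,
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Serialized pipeline configuration (round-trippable to YAML).

    The cohort block carries the scientific study conditions; the stage
    parameters default to a demonstration profile sized to run the full
    chain in minutes (shorter recordings, reduced permutation and Louvain
    counts).  Study-scale analyses raise the counts explicitly.
    """

    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    out_dir: str = "entropath_run"
    # cohort block
    n_subjects: int = 28
    recording_duration: float = 40.0
    n_regions: int = 100
    n_modules: int = 4
    # stage parameters
    epoch_length: float = 2.0
    lzc_timepoints: tuple[str, ...] = ("1h", "2h", "4.5h")
    n_shuffles: int = 20
    theta_grid_max: float = 0.90
    theta_grid_step: float = 0.05
    predict_target: str = "insight"
    n_perm_predict: int = 500
    n_boot: int = 1000
    n_louvain: int = 20
    n_null: int = 20
    gamma: float = 1.0
    parcel_samples: int = 200
    n_perm_cluster: int = 1000
    alpha_cell: float = 0.05
    log_level: str = "INFO"

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_subjects=self.n_subjects,
            recording_duration=self.recording_duration,
            n_regions=self.n_regions,
            n_modules=self.n_modules,
            seed=_derived_seed(self.seed, 10),
        )

    def theta_grid(self) -> np.ndarray:
        return np.round(
            np.arange(0.0, self.theta_grid_max + 1e-9, self.theta_grid_step), 10
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("stages", "lzc_timepoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: RunConfig, out: Path, report: dict) -> Cohort:
    cohort = generate_cohort(cfg.cohort_config())
    sim_dir = out / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.behavior, sim_dir / "behavior.csv", BEHAVIOR_COLUMNS)
    cohort.outcome_changes.reset_index().to_csv(sim_dir / "outcome_changes.csv", index=False)
    report["simulate"] = {
        "n_subjects": cfg.n_subjects,
        "behavior_rows": int(len(cohort.behavior)),
        "outcomes": list(cohort.outcome_changes.columns),
    }
    return cohort


def _stage_features(cfg: RunConfig, cohort: Cohort, out: Path, report: dict) -> FeatureTensor:
    config = cohort.config
    timepoints = tuple(cfg.lzc_timepoints)
    n = config.n_subjects
    lzc = np.zeros((n, len(config.channel_labels), len(timepoints)))
    alpha = np.zeros_like(lzc)
    for si in range(n):
        for ti, tp in enumerate(timepoints):
            rec = cohort.eeg_recording(si, "25mg", tp)
            ep = preprocess(rec, epoch_length=cfg.epoch_length)
            # one shared seed: the surrogate normalizer is then a common
            # constant per epoch composition across subjects and timepoints
            lzc[si, :, ti] = lzc_channel(ep, n_shuffles=cfg.n_shuffles, seed=_derived_seed(cfg.seed, 20))
            alpha[si, :, ti] = band_power(ep)["alpha"]
    subjects = cohort.subjects
    tensor = FeatureTensor(lzc, "LZc", subjects, config.channel_labels, timepoints)
    alpha_t = FeatureTensor(alpha, "band:alpha", subjects, config.channel_labels, timepoints)
    write_features(tensor, out / "features_lzc.csv")
    write_features(alpha_t, out / "features_alpha.csv")
    report["features"] = {
        "n_recordings": int(n * len(timepoints)),
        "mean_lzc": float(lzc.mean()),
        "mean_alpha_power": float(alpha.mean()),
    }
    return tensor


def _stage_predict(cfg: RunConfig, cohort: Cohort, tensor: FeatureTensor, out: Path, report: dict) -> None:
    active = cohort.behavior[cohort.behavior["condition"] == "25mg"].set_index("subject")
    target = active.loc[list(tensor.subjects), cfg.predict_target].to_numpy()
    model = fit_final_predictor(
        tensor,
        target,
        theta_grid=cfg.theta_grid(),
        n_perm=cfg.n_perm_predict,
        seed=_derived_seed(cfg.seed, 30),
    )
    report["predict"] = {
        "target": cfg.predict_target,
        "theta_star": model.theta_star,
        "n_selected": len(model.selected_features),
        "selected_features": [list(f) for f in model.selected_features[:10]],
        "out_of_sample_r2": model.out_of_sample_r2,
        "spearman_rs": model.spearman_rs,
        "surrogate_p": model.surrogate_p,
        "n_perm": model.n_perm,
    }
    pd.DataFrame(
        {"subject": tensor.subjects, "observed": target, "predicted": model.predictions}
    ).to_csv(out / "predictions.csv", index=False)


def _stage_mediate(cfg: RunConfig, cohort: Cohort, tensor: FeatureTensor, out: Path, report: dict) -> None:
    active = cohort.behavior[cohort.behavior["condition"] == "25mg"].set_index("subject")
    ti = tensor.timepoints.index("2h")
    x = tensor.values[:, :, ti].mean(axis=1)  # whole-sensor-average LZc at 2 h
    m = active.loc[list(tensor.subjects), "insight"].to_numpy()
    y = active.loc[list(tensor.subjects), "wellbeing_change"].to_numpy()
    res = fit_mediation(x, m, y, n_boot=cfg.n_boot, seed=_derived_seed(cfg.seed, 40))
    report["mediate"] = res.to_dict()


def _stage_modularity(cfg: RunConfig, cohort: Cohort, out: Path, report: dict) -> None:
    n = cohort.config.n_subjects
    rows = []
    for si in range(n):
        entry = {"subject": f"sub-{si:02d}"}
        for session in ("pre", "post"):
            ts = cohort.parcel_timeseries(si, session, n_samples=cfg.parcel_samples)
            res = modularity_score(
                fc_matrix(ts),
                n_louvain=cfg.n_louvain,
                n_null=cfg.n_null,
                gamma=cfg.gamma,
                seed=_derived_seed(cfg.seed, 50, si, 0 if session == "pre" else 1),
            )
            entry[f"q_raw_{session}"] = res.q_raw
            entry[f"q_null_mean_{session}"] = res.q_null_mean
            entry[f"q_norm_{session}"] = res.q_norm
        entry["q_norm_change"] = entry["q_norm_post"] - entry["q_norm_pre"]
        rows.append(entry)
    df = pd.DataFrame(rows)
    df.to_csv(out / "modularity.csv", index=False)

    active = cohort.behavior[cohort.behavior["condition"] == "25mg"].set_index("subject")
    wb_change = active.loc[df["subject"], "wellbeing_change"].to_numpy()
    wb_pre = active.loc[df["subject"], "wellbeing_pre"].to_numpy()
    r, p = adjusted_change_correlation(df["q_norm_change"].to_numpy(), wb_change, wb_pre)
    report["modularity"] = {
        "mean_q_norm_pre": float(df["q_norm_pre"].mean()),
        "mean_q_norm_post": float(df["q_norm_post"].mean()),
        "modularity_wellbeing_partial_r": r,
        "modularity_wellbeing_p": p,
    }


def _stage_corrcluster(cfg: RunConfig, cohort: Cohort, out: Path, report: dict) -> None:
    res = correlation_cluster_test(
        cohort.outcome_changes,
        alpha_cell=cfg.alpha_cell,
        n_perm=cfg.n_perm_cluster,
        seed=_derived_seed(cfg.seed, 60),
    )
    np.savetxt(out / "corr_matrix.tsv", res.r, delimiter="\t")
    report["corrcluster"] = {
        "clusters": res.clusters,
        "cluster_masses": [float(m) for m in res.cluster_masses],
        "cluster_p": [float(p) for p in res.cluster_p],
        "n_perm": res.n_perm,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The report embeds the config verbatim and is written to
    ``<out_dir>/report.json`` with sorted keys and no timestamps, so equal
    config + seed give byte-identical output.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        sort_keys=True,
    )
    report: dict = {
        "version": __version__,
        "config": json.loads(config_json),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
    }
    stages = [s for s in ALL_STAGES if s in config.stages]
    needs_cohort = bool(stages)
    cohort = None
    tensor = None
    if needs_cohort:
        downstream = set(stages) - {"simulate"}
        if downstream and "simulate" not in stages:
            raise ValueError(
                f"stages {sorted(downstream)} need the 'simulate' stage enabled "
                "(no upstream artifacts were supplied)"
            )
    for stage in stages:
        if stage == "simulate":
            cohort = _stage_simulate(config, out, report)
        elif stage == "features":
            tensor = _stage_features(config, cohort, out, report)
        elif stage == "predict":
            if tensor is None:
                raise ValueError("'predict' needs the 'features' stage enabled")
            _stage_predict(config, cohort, tensor, out, report)
        elif stage == "mediate":
            if tensor is None:
                raise ValueError("'mediate' needs the 'features' stage enabled")
            _stage_mediate(config, cohort, tensor, out, report)
        elif stage == "modularity":
            _stage_modularity(config, cohort, out, report)
        elif stage == "corrcluster":
            _stage_corrcluster(config, cohort, out, report)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
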