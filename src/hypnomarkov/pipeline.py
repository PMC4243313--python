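"""End-to-end orchestration: simulate -> segment -> fit -> metrics -> spectra.

The pipeline reproduces a complete hypnogram analysis with deterministic,
provenance-stamped outputs:

* sleep-onset phase (first ~30 min by default) fitted with a two-state
  WAKE/SLEEP Markov model — REM is too rare there for a three-state fit;
* steady phase (remainder of the recording) fitted with a three-state
  WAKE/NREM/REM model;
* per-subject standard sleep metrics with group mean +/- SEM and two-way
  ANOVA + Tukey HSD;
* per-stage EEG spectra aggregated to group mean +/- SEM per 1-Hz bin.

All randomness flows from the single configuration seed.  Every output
table carries a provenance header (config hash, seed, package version), so
reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hypnogram_io import (
    FINE_TO_THREE_STATE,
    FINE_TO_TWO_STATE,
    THREE_TO_TWO_STATE,
    Hypnogram,
    collapse_stages,
    read_hypnogram,
    segment_hypnogram,
    write_hypnogram,
)
from .markov_model import (
    FitResult,
    ModelSpec,
    fit_ctmc,
    normalized_transition_rates,
    sojourn_times,
)
from .sleep_metrics import aggregate_metrics, compare_groups, metrics_frame
from .spectra import BANDS, epoch_psd, stage_average_spectrum
from .synthetic_data import (
    StageSpectralProfile,
    default_fine_design,
    default_spectral_profile,
    simulate_group_study,
    simulate_stage_eeg,
    subject_rng,
)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "run_simulate",
    "run_markov_analysis",
    "run_metrics",
    "run_spectra",
    "run_report",
]

logger = logging.getLogger(__name__)

_NUMERIC_METRICS = (
    "wake_time", "wake_episode_count", "wake_mean_duration",
    "nrem_time", "nrem_episode_count", "nrem_mean_duration",
    "rem_time", "rem_episode_count", "rem_mean_duration",
    "sleep_time", "sleep_episode_count", "sleep_mean_duration",
    "sleep_fragmentation", "rem_latency", "sws1_latency", "sws2_latency",
    "first_rem_item",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration or inputs (caught before any fitting)."""


@dataclass
class PipelineConfig:
    """Pipeline settings; everything is reproducible from ``seed``.

    With no ``hypnogram_paths`` the bundled four-group fine-vocabulary
    simulation (6-7 subjects per group, 2-h recordings at 4-s epochs) is
    generated and analysed.
    """

    out_dir: str = "hypnomarkov_out"
    seed: int = 0
    hypnogram_paths: tuple[str, ...] | None = None
    phase_boundaries: tuple[float, ...] = (2000.0,)
    reference_group: str = "HC-VEH"
    duration: float = 7200.0
    epoch_length: float = 4.0
    metrics: tuple[str, ...] | None = None
    simulate_eeg: bool = True
    sampling_rate: float = 128.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hypnogram_paths", "phase_boundaries", "metrics"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("hypnogram_paths", "phase_boundaries", "metrics"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(cfg: PipelineConfig) -> list[str]:
    return [
        f"# hypnomarkov_version\t{__version__}",
        f"# config_hash\t{cfg.config_hash()}",
        f"# seed\t{cfg.seed}",
    ]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    path.write_text("\n".join(_provenance(cfg)) + "\n" + body, encoding="utf-8")


def _load_or_simulate(cfg: PipelineConfig) -> list[Hypnogram]:
    if cfg.hypnogram_paths:
        data = [read_hypnogram(p) for p in cfg.hypnogram_paths]
    else:
        design = default_fine_design(seed=cfg.seed, duration=cfg.duration)
        data = simulate_group_study(design)
    if not data:
        raise ConfigError("no hypnograms to analyse")
    vocabs = {h.vocabulary for h in data}
    if len(vocabs) > 1:
        raise ConfigError(f"hypnograms mix vocabularies: {sorted(vocabs)}")
    return data


def run_simulate(cfg: PipelineConfig) -> list[Path]:
    """Generate the default synthetic study and write hypnogram TSV files."""
    design = default_fine_design(seed=cfg.seed, duration=cfg.duration)
    out = Path(cfg.out_dir) / "hypnograms"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for h in simulate_group_study(design):
        p = out / f"{h.subject_id}.tsv"
        write_hypnogram(h, p)
        paths.append(p)
    logger.info("simulated %d hypnograms into %s", len(paths), out)
    return paths


def _collapse_to(h: Hypnogram, target: str) -> Hypnogram:
    if h.vocabulary == target:
        return h
    key = (h.vocabulary, target)
    cmap = {
        ("fine", "three_state"): FINE_TO_THREE_STATE,
        ("fine", "two_state"): FINE_TO_TWO_STATE,
        ("three_state", "two_state"): THREE_TO_TWO_STATE,
    }.get(key)
    if cmap is None:
        raise ConfigError(
            f"cannot collapse {h.vocabulary!r} hypnograms to {target!r}"
        )
    return collapse_stages(h, cmap)


def _model_spec(states: tuple[str, ...], groups: Sequence[str], cfg: PipelineConfig) -> ModelSpec:
    if cfg.reference_group not in groups:
        raise ConfigError(
            f"reference group {cfg.reference_group!r} absent from data groups {sorted(groups)}"
        )
    covariates = tuple(sorted(g for g in groups if g != cfg.reference_group))
    return ModelSpec(
        states=states,
        reference_group=cfg.reference_group,
        covariate_groups=covariates,
        delta=cfg.epoch_length,
    )


def _fit_tables(fit: FitResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    soj = pd.DataFrame(
        [
            {
                "group": e.group,
                "state": e.state,
                "sojourn_s": e.sojourn,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in sojourn_times(fit)
        ]
    )
    ntr = pd.DataFrame(
        [
            {
                "group": e.group,
                "transition": f"{e.from_state}->{e.to_state}",
                "ntr": e.ntr,
                "ci_low": np.nan if e.ci_low is None else e.ci_low,
                "ci_high": np.nan if e.ci_high is None else e.ci_high,
                "significant_vs_reference": e.significant_vs_reference,
            }
            for e in normalized_transition_rates(fit)
        ]
    )
    return soj, ntr


def run_markov_analysis(
    cfg: PipelineConfig, data: Sequence[Hypnogram] | None = None
) -> dict[str, FitResult]:
    """Fit the onset (two-state) and steady (three-state) phase models.

    Writes ``onset_sojourns.tsv``/``onset_ntr.tsv``, the steady-phase
    counterparts, and ``fit_report.json`` with full parameter covariance.
    Returns the fits keyed by phase name.
    """
    data = list(data) if data is not None else _load_or_simulate(cfg)
    end = min(h.end_time for h in data)
    for b in cfg.phase_boundaries:
        if b >= end:
            raise ConfigError(
                f"phase boundary {b} s is beyond the recording end ({end} s)"
            )
    groups = sorted({h.group for h in data})
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    segments: dict[str, list[Hypnogram]] = {"onset": [], "steady": []}
    for h in data:
        segs = segment_hypnogram(h, cfg.phase_boundaries) if cfg.phase_boundaries else [h]
        segments["onset"].append(segs[0])
        for s in segs[1:]:
            segments["steady"].append(s)
    if not segments["steady"]:
        segments.pop("steady")

    phase_states = {"onset": ("WAKE", "SLEEP"), "steady": ("WAKE", "NREM", "REM")}
    fits: dict[str, FitResult] = {}
    report: dict[str, dict] = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "phases": {},
    }
    for phase, seqs in segments.items():
        states = phase_states[phase]
        target = "two_state" if len(states) == 2 else "three_state"
        collapsed = [_collapse_to(h, target) for h in seqs]
        spec = _model_spec(states, groups, cfg)
        logger.info(
            "phase %s: fitting %d-state model, %d free parameters "
            "(%d descriptive parameters per group)",
            phase, spec.n_states, spec.n_free_parameters,
            spec.descriptive_parameter_count,
        )
        fit = fit_ctmc(collapsed, spec)
        fits[phase] = fit
        soj, ntr = _fit_tables(fit)
        _write_table(soj, out / f"{phase}_sojourns.tsv", cfg)
        _write_table(ntr, out / f"{phase}_ntr.tsv", cfg)
        report["phases"][phase] = fit.summary()
    (out / "fit_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return fits


def run_metrics(
    cfg: PipelineConfig, data: Sequence[Hypnogram] | None = None
) -> pd.DataFrame:
    """Per-subject standard sleep metrics plus group summary and ANOVA tables.

    Requires fine-vocabulary hypnograms.  Returns the per-subject table;
    writes ``metrics_subjects.tsv``, ``metrics_summary.tsv`` and
    ``metrics_anova.tsv``.
    """
    data = list(data) if data is not None else _load_or_simulate(cfg)
    if any(h.vocabulary != "fine" for h in data):
        raise ConfigError("sleep metrics require fine-vocabulary hypnograms")
    rows = [aggregate_metrics(h) for h in data]
    df = metrics_frame(rows)
    out = Path(cfg.out_dir)
    _write_table(df, out / "metrics_subjects.tsv", cfg)

    wanted = cfg.metrics or _NUMERIC_METRICS
    unknown = [m for m in wanted if m not in _NUMERIC_METRICS]
    if unknown:
        raise ConfigError(f"unknown metrics requested: {unknown}")

    summary_records = []
    anova_records = []
    for metric in wanted:
        vals = df[["group", metric]].copy()
        vals[metric] = pd.to_numeric(vals[metric])
        grp = vals.groupby("group")[metric]
        for g, mean, sem, n in zip(
            grp.mean().index, grp.mean(), grp.sem(), grp.count()
        ):
            summary_records.append(
                {"metric": metric, "group": g, "mean": mean, "sem": sem, "n": int(n)}
            )
        try:
            cmp = compare_groups(df, metric)
        except ValueError as exc:
            logger.info("metric %s: ANOVA skipped (%s)", metric, exc)
            continue
        if cmp.n_dropped:
            logger.info(
                "metric %s: %d subjects had undefined values and were dropped",
                metric, cmp.n_dropped,
            )
        for label, effect in (
            ("treatment", "C(treatment)"),
            ("rebound", "C(rebound)"),
            ("interaction", "C(treatment):C(rebound)"),
        ):
            anova_records.append(
                {
                    "metric": metric,
                    "effect": label,
                    "F": cmp.f_statistic(effect) if not cmp.note else np.nan,
                    "p": cmp.p_value(effect) if not cmp.note else np.nan,
                    "n_used": cmp.n_used,
                    "n_dropped": cmp.n_dropped,
                    "note": cmp.note,
                }
            )
    _write_table(pd.DataFrame(summary_records), out / "metrics_summary.tsv", cfg)
    _write_table(pd.DataFrame(anova_records), out / "metrics_anova.tsv", cfg)
    return df


def run_spectra(
    cfg: PipelineConfig,
    data: Sequence[Hypnogram] | None = None,
    waveforms: Sequence[np.ndarray] | None = None,
    profile: StageSpectralProfile | None = None,
) -> pd.DataFrame | None:
    """Group-level stage spectra: mean +/- SEM per group x stage x 1-Hz bin.

    Waveforms may be passed explicitly (one per hypnogram); otherwise, when
    ``simulate_eeg`` is enabled, stage-conditional EEG is synthesized from
    the default spectral profile.  With neither, the step is skipped with a
    warning and ``None`` is returned (exit remains successful).
    """
    data = list(data) if data is not None else _load_or_simulate(cfg)
    if waveforms is None:
        if not cfg.simulate_eeg:
            logger.warning("no waveforms available; spectra step skipped")
            return None
        prof = profile or default_spectral_profile()
        waveforms = [
            simulate_stage_eeg(h, prof, fs=cfg.sampling_rate,
                               seed=subject_rng(cfg.seed ^ 0x5EEC, gi, 0))
            for gi, h in enumerate(data)
        ]
    if len(waveforms) != len(data):
        raise ConfigError("need exactly one waveform per hypnogram")
    spe = int(round(cfg.sampling_rate * cfg.epoch_length))
    frames = []
    for h, wave in zip(data, waveforms):
        wave = np.asarray(wave, dtype=float)
        if wave.size != h.n_epochs * spe:
            raise ConfigError(
                f"waveform for {h.subject_id!r} has {wave.size} samples, "
                f"expected {h.n_epochs * spe}"
            )
        psds = [epoch_psd(wave[i * spe : (i + 1) * spe], cfg.sampling_rate)
                for i in range(h.n_epochs)]
        frames.append(stage_average_spectrum(psds, h).to_frame())
    long = pd.concat(frames, ignore_index=True)
    agg = (
        long.groupby(["group", "stage", "bin_hz"], sort=True)
        .agg(
            mean_power=("power", "mean"),
            sem_power=("power", "sem"),
            n_subjects=("power", "size"),
        )
        .reset_index()
    )
    out = Path(cfg.out_dir)
    _write_table(agg, out / "spectra_group.tsv", cfg)

    def band_of(bin_hz: int) -> str:
        for name, (lo, hi) in BANDS.items():
            if lo <= bin_hz <= hi:
                return name
        raise AssertionError(bin_hz)

    long["band"] = [band_of(b) for b in long["bin_hz"]]
    per_subject_band = (
        long.groupby(["group", "subject_id", "stage", "band"], sort=True)["power"]
        .sum()
        .reset_index()
    )
    band_agg = (
        per_subject_band.groupby(["group", "stage", "band"], sort=True)
        .agg(mean_power=("power", "mean"), sem_power=("power", "sem"),
             n_subjects=("power", "size"))
        .reset_index()
    )
    _write_table(band_agg, out / "spectra_bands.tsv", cfg)
    return agg


def run_report(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a status dictionary per step."""
    data = _load_or_simulate(cfg)
    fits = run_markov_analysis(cfg, data)
    metrics = run_metrics(cfg, data) if data[0].vocabulary == "fine" else None
    spectra = run_spectra(cfg, data) if data[0].vocabulary == "fine" else None
    return {
        "fits": fits,
        "converged": all(f.converged for f in fits.values()),
        "metrics": metrics,
        "spectra": spectra,
    }
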