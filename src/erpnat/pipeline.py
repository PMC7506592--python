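"""End-to-end orchestration: simulate → preprocess → average → extract → stats.

The statistical routing mirrors the design: a Shapiro–Wilk gate per measure
family decides between the parametric path (paired t) and the Wilcoxon
signed-rank test for the rating instruments; component amplitudes go to the
2×2 within-subjects ANOVA with partial η², with Bonferroni-corrected planned
simple-effect contrasts whenever the interaction is significant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ArtifactCriteria, ContinuousEEG, Epochs
from .edf import read_edf, write_edf
from .erp import (DEFAULT_WINDOWS, ComponentWindow, SubjectAverage,
                  component_table, grand_average, subject_average)
from .exceptions import ConfigurationError, PipelineError
from .io import (read_events_tsv, read_ratings_csv, write_amplitudes_csv,
                 write_events_tsv, write_json, write_ratings_csv)
from .montage import Montage, build_montage
from .preprocessing import (bandpass_filter, baseline_correct,
                            detect_artifacts, rereference_average,
                            replace_bad_channels, segment)
from .stats import (PairedSample, bonferroni_posthoc, effect_size_label,
                    paired_t, partial_eta_sq, rm_anova_2x2, shapiro_wilk,
                    wilcoxon_signed_rank)
from .synth import (CohortModel, ParadigmSpec, rating_means_table,
                    simulate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, hashable for provenance."""

    data_dir: str = "."
    out_dir: str = "results"
    low_hz: float = 0.3
    high_hz: float = 30.0
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    offset_ms: float = 11.0
    criteria: ArtifactCriteria = field(default_factory=ArtifactCriteria)
    component_halfwidth_ms: float = 10.0
    alpha: float = 0.05
    wilcoxon_method: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0,1)")

    def windows(self) -> tuple[ComponentWindow, ...]:
        return tuple(dataclasses.replace(w, halfwidth_ms=self.component_halfwidth_ms)
                     for w in DEFAULT_WINDOWS)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["criteria"] = dataclasses.asdict(self.criteria)
        return payload

    def analysis_dict(self) -> dict:
        """Config without file locations: what the numbers depend on."""
        payload = self.to_dict()
        payload.pop("data_dir", None)
        payload.pop("out_dir", None)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        crit = payload.pop("criteria", {})
        cfg = cls(**{k: v for k, v in payload.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.criteria = ArtifactCriteria(**crit) if isinstance(crit, dict) else crit
        return cfg

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-subject processing
# ---------------------------------------------------------------------------

def preprocess_subject(eeg: ContinuousEEG, events: pd.DataFrame,
                       montage: Montage, config: RunConfig) -> tuple[Epochs, object]:
    """Filter → segment → detect → replace → baseline → re-reference."""
    filtered = bandpass_filter(eeg, config.low_hz, config.high_hz)
    epochs = segment(filtered, events, window_ms=config.window_ms,
                     offset_ms=config.offset_ms)
    if epochs.n_epochs == 0:
        raise PipelineError("no condition-concordant epochs in record")
    report = detect_artifacts(epochs, config.criteria, montage)
    epochs = replace_bad_channels(epochs, report, montage)
    epochs = baseline_correct(epochs, config.baseline_ms)
    epochs = rereference_average(epochs)
    return epochs, report


def process_subject(eeg: ContinuousEEG, events: pd.DataFrame,
                    montage: Montage, config: RunConfig,
                    subject: str = "subject") -> tuple[SubjectAverage, object]:
    epochs, report = preprocess_subject(eeg, events, montage, config)
    if not epochs.clean_mask.any():
        raise PipelineError(f"subject {subject}: no epochs retained")
    return subject_average(epochs, subject=subject), report


# ---------------------------------------------------------------------------
# Statistics layer
# ---------------------------------------------------------------------------

def run_stats(amplitudes: pd.DataFrame, rating_means: pd.DataFrame,
              alpha: float = 0.05, wilcoxon_method: str = "auto") -> dict:
    """Full inferential report on an amplitude table and rating means.

    Returns a JSON-serialisable dict: per rating instrument the normality
    gate and the routed paired test; per ERP component the 2×2 RM-ANOVA
    with η²p labels, cell statistics, and planned Bonferroni post hocs when
    the interaction is significant.
    """
    out: dict = {"alpha": alpha, "ratings": {}, "erp": {}}

    for instrument, chunk in rating_means.groupby("instrument"):
        wide = chunk.pivot_table(index="subject", columns="agent",
                                 values="mean_score")
        if not {"human", "AI"}.issubset(wide.columns):
            raise ConfigurationError(f"{instrument}: need human and AI columns")
        pair = PairedSample(wide["human"].to_numpy(), wide["AI"].to_numpy(),
                            "human", "AI")
        d = pair.differences
        try:
            w, p_norm = shapiro_wilk(d)
            gate = {"W": w, "p": p_norm, "normal": bool(p_norm >= alpha)}
        except ConfigurationError:
            gate = {"W": None, "p": None, "normal": False}
        entry: dict = {"shapiro": gate, "n": pair.n,
                       "mean_human": float(wide["human"].mean()),
                       "sd_human": float(wide["human"].std(ddof=1)),
                       "mean_AI": float(wide["AI"].mean()),
                       "sd_AI": float(wide["AI"].std(ddof=1))}
        if gate["normal"]:
            t, df, p = paired_t(pair)
            entry["test"] = "paired_t"
            entry["result"] = {"t": t, "df": df, "p": p}
        else:
            res = wilcoxon_signed_rank(pair, method=wilcoxon_method)
            entry["test"] = "wilcoxon"
            entry["result"] = dataclasses.asdict(res)
        entry["significant"] = bool(entry["result"]["p"] < alpha)
        out["ratings"][instrument] = entry

    for component, chunk in amplitudes.groupby("component"):
        gates = {}
        for (identity, site), cell in chunk.groupby(["identity", "site"]):
            try:
                w, p_norm = shapiro_wilk(cell["amplitude_uv"].to_numpy())
                gates[f"{identity}/{site}"] = {"W": w, "p": p_norm,
                                               "normal": bool(p_norm >= alpha)}
            except ConfigurationError:
                gates[f"{identity}/{site}"] = {"W": None, "p": None,
                                               "normal": False}
        anova = rm_anova_2x2(chunk)
        effects = {}
        for name, eff in anova.effects.items():
            eta_direct = partial_eta_sq(eff.F, *eff.df)
            effects[name] = {
                "F": eff.F, "df": list(eff.df), "p": eff.p,
                "eta_p_sq": eff.eta_p_sq,
                "eta_p_sq_from_F": eta_direct,
                "label": effect_size_label(eff.eta_p_sq),
                "significant": bool(eff.p < alpha),
            }
        entry = {
            "shapiro": gates,
            "n_subjects": anova.n_subjects,
            "cell_means": {f"{a}/{b}": float(anova.cell_means.loc[a, b])
                           for a in anova.cell_means.index
                           for b in anova.cell_means.columns},
            "cell_ses": {f"{a}/{b}": float(anova.cell_ses.loc[a, b])
                         for a in anova.cell_ses.index
                         for b in anova.cell_ses.columns},
            "effects": effects,
        }
        if effects["interaction"]["significant"]:
            posthoc = bonferroni_posthoc(chunk, alpha=alpha)
            entry["posthoc"] = [dataclasses.asdict(c) for c in posthoc.contrasts]
            entry["posthoc_alpha_bonf"] = posthoc.alpha_bonf
        out["erp"][component] = entry
    return out


def format_summary(stats: dict) -> str:
    """Human-readable text mirroring the report structure."""
    lines = [f"erpnat {__version__} — statistical summary",
             f"alpha = {stats['alpha']}", ""]
    lines.append("Subjective ratings (higher = more negative/unnatural)")
    for instrument, entry in stats["ratings"].items():
        res = entry["result"]
        lines.append(f"  {instrument}: human M={entry['mean_human']:.2f} "
                     f"SD={entry['sd_human']:.2f}; AI M={entry['mean_AI']:.2f} "
                     f"SD={entry['sd_AI']:.2f} (n={entry['n']})")
        if entry["test"] == "wilcoxon":
            lines.append(f"    Wilcoxon signed-rank: Z={res['Z']:.2f}, "
                         f"p={res['p']:.4g} ({res['method']}); mean rank "
                         f"+={res['mean_rank_pos']:.2f} -={res['mean_rank_neg']:.2f}")
        else:
            lines.append(f"    paired t: t({res['df']})={res['t']:.2f}, "
                         f"p={res['p']:.4g}")
    lines.append("")
    lines.append("ERP amplitudes (adaptive mean, μV)")
    for component, entry in stats["erp"].items():
        lines.append(f"  {component} (n={entry['n_subjects']}):")
        for cell, m in entry["cell_means"].items():
            se = entry["cell_ses"][cell]
            lines.append(f"    {cell}: M={m:.2f}, SE={se:.2f}")
        for name, eff in entry["effects"].items():
            lines.append(
                f"    {name}: F({eff['df'][0]},{eff['df'][1]})={eff['F']:.2f}, "
                f"p={eff['p']:.3g}, eta_p^2={eff['eta_p_sq']:.2f} ({eff['label']})"
                + (" *" if eff["significant"] else ""))
        for c in entry.get("posthoc", []):
            flag = "significant" if c["significant"] else "n.s."
            lines.append(f"    post hoc {c['name']}: diff={c['mean_diff']:.2f}, "
                         f"t({c['df']})={c['t']:.2f}, p={c['p']:.3g} vs "
                         f"alpha_bonf={c['alpha_bonf']:.4g} → {flag}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Disk-level orchestration
# ---------------------------------------------------------------------------

def simulate_to_dir(out_dir, n_subjects: int, seed: int,
                    paradigm: ParadigmSpec | None = None,
                    model: CohortModel | None = None,
                    n_channels: int = 16) -> Path:
    """Simulate a cohort and write EDF + events TSV + montage + ratings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = build_montage(n_channels)
    records, ratings = simulate_cohort(n_subjects, seed, paradigm=paradigm,
                                       montage=montage, model=model)
    montage.to_json(out / "montage.json")
    write_ratings_csv(out / "ratings.csv", ratings)
    truth = {}
    for rec in records:
        sub = rec["subject"]
        write_edf(out / f"{sub}_eeg.edf", rec["eeg"])
        write_events_tsv(out / f"{sub}_events.tsv", rec["events"])
        profile = rec["profile"]
        truth[sub] = {
            "p1": {f"{i}/{s}": v for (i, s), v in profile.p1_amp_by_cell.items()},
            "n170": {f"{i}/{s}": v for (i, s), v in profile.n170_amp_by_cell.items()},
            "bad_channels": sorted(profile.bad_channel_ids),
        }
    write_json(out / "ground_truth.json", truth)
    logger.info("simulated %d subjects into %s", n_subjects, out)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis over a simulated/recorded data directory.

    Expects ``montage.json``, ``ratings.csv`` and per-subject
    ``sub-XX_eeg.edf`` / ``sub-XX_events.tsv`` under ``config.data_dir``.
    Writes the artifact report, the amplitude table, the stats JSON and a
    text summary under ``config.out_dir``; outputs embed the config hash.
    Deterministic for fixed inputs and configuration.
    """
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    montage_path = data_dir / "montage.json"
    if not montage_path.exists():
        raise ConfigurationError(f"missing {montage_path}")
    montage = Montage.from_json(montage_path)

    averages, report_frames = [], []
    edf_files = sorted(data_dir.glob("sub-*_eeg.edf"))
    if not edf_files:
        raise ConfigurationError(f"no sub-*_eeg.edf files in {data_dir}")
    for edf_path in edf_files:
        sub = edf_path.name.replace("_eeg.edf", "")
        eeg = read_edf(edf_path)
        events = read_events_tsv(data_dir / f"{sub}_events.tsv")
        try:
            avg, report = process_subject(eeg, events, montage, config,
                                          subject=sub)
        except PipelineError as exc:
            logger.warning("%s", exc)
            raise
        frame = report.to_frame()
        frame.insert(0, "subject", sub)
        report_frames.append(frame)
        averages.append(avg)

    complete = [a for a in averages if a.complete]
    if not complete:
        raise PipelineError("no subject has retained epochs in both conditions")
    amplitudes = component_table(complete, windows=config.windows(),
                                 montage=montage)
    grand = grand_average(complete)

    ratings = read_ratings_csv(data_dir / "ratings.csv")
    means = rating_means_table(ratings)
    stats = run_stats(amplitudes, means, alpha=config.alpha,
                      wilcoxon_method=config.wilcoxon_method)
    stats["meta"] = {
        "config": config.analysis_dict(),
        "config_hash": config.config_hash,
        "erpnat_version": __version__,
        "n_subjects_processed": len(averages),
        "n_subjects_complete": len(complete),
        "grand_average_n": grand.meta.get("n_subjects"),
    }

    reports = pd.concat(report_frames, ignore_index=True)
    with open(out_dir / "artifact_report.csv", "w") as fh:
        fh.write(f"# config_hash: {config.config_hash}\n")
        reports.to_csv(fh, index=False)
    write_amplitudes_csv(out_dir / "amplitudes.csv", amplitudes,
                         config_hash=config.config_hash)
    write_json(out_dir / "stats.json", stats)
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(format_summary(stats))
    logger.info("pipeline complete: %s", out_dir)
    return stats
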