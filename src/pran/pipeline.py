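"""Experiment recipes: competition scoring and the full statistical report.

Three presets encode the studies' montages, analysis windows, follow-up ROI
subsets and standardization parameters.  ``run_competition`` turns a lexicon
plus frequency list into a competition table for the stimulus WIFs;
``run_analysis`` reduces an epoch set and produces, in order, the
median-split summary, the omnibus Competitors x Antpost x Laterality ANOVA,
ROI-subset follow-ups, the two-predictor regression (competition +
frequency, long format over WIF x ROI) and the single-predictor regression
(ROI-averaged per WIF), together with a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .erp import (
    MONTAGES,
    EpochSet,
    baseline_correct,
    item_erps,
    reject_artifacts,
    subject_wif_erps,
    window_roi_amplitudes,
)
from .lexicon import (
    CompetitionRecord,
    Constraints,
    ParseReport,
    WIFKey,
    apply_frequency_filter,
    competition_table,
    parse_frequency_table,
    parse_lexicon,
    wif_token_frequency,
)
from .simulate import ErpSimConfig, simulate_epochs
from .stats import (
    RegressionFit,
    SplitAssignment,
    median_split,
    pran_regression,
    rm_anova,
    standardize_amplitudes,
    subset_anova,
)

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "CompetitionResult",
    "AnalysisReport",
    "run_competition",
    "run_analysis",
    "simulate_and_estimate",
]

logger = logging.getLogger("pran")


@dataclass(frozen=True)
class ExperimentConfig:
    """All analysis choices for one experiment recipe."""

    name: str
    montage: str = "exp1_3"
    analysis_window: tuple[float, float] = (136.0, 280.0)
    baseline_window: tuple[float, float] = (-200.0, 0.0)
    rejection_threshold: float = 100.0
    frequency_threshold: int = 2
    regression_rois: tuple[str, ...] = ("left central", "left posterior")
    standardization: tuple[float, float] | None = None  # (study mean, SD) in uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis_window[0] >= self.analysis_window[1]:
            raise ValueError("analysis window must be ordered")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline window must be ordered")
        names = {r.name for r in MONTAGES[self.montage]}
        unknown = set(self.regression_rois) - names
        if unknown:
            raise ValueError(f"ROI(s) not in montage: {', '.join(sorted(unknown))}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


PRESETS: dict[str, ExperimentConfig] = {
    "exp1": ExperimentConfig(
        name="exp1",
        montage="exp1_3",
        analysis_window=(136.0, 280.0),
        regression_rois=("left central", "left posterior"),
        standardization=(-2.44, 0.91),
    ),
    "exp2": ExperimentConfig(
        name="exp2",
        montage="exp2",
        analysis_window=(136.0, 280.0),
        regression_rois=("left anterior", "left central", "left posterior"),
        standardization=(-1.46, 1.36),
    ),
    "exp3": ExperimentConfig(
        name="exp3",
        montage="exp1_3",
        analysis_window=(220.0, 280.0),
        regression_rois=("left anterior", "left central"),
        standardization=(-2.15, 1.42),
    ),
}


@dataclass
class CompetitionResult:
    records: list[CompetitionRecord]
    table: pd.DataFrame
    parse_report: ParseReport
    n_entries_after_frequency_filter: int

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_competition(
    config: ExperimentConfig,
    lexicon_path: str | Path,
    frequency_path: str | Path,
    stimulus_wifs: Sequence[WIFKey],
    constraints: Constraints = Constraints(),
    column_map=None,
) -> CompetitionResult:
    """Lexicon + frequency list -> competition table for the stimulus WIFs.

    The table carries counts, log counts, z-scores and the per-WIF mean
    cohort token frequency with its z-scored log.
    """
    entries, report = parse_lexicon(lexicon_path, column_map=column_map)
    logger.info("parsed %d lexicon entries (%d skipped)", report.n_parsed, report.n_skipped)
    freq = parse_frequency_table(frequency_path, min_frequency=config.frequency_threshold)
    entries = apply_frequency_filter(entries, freq)
    logger.info("%d entries survive the frequency threshold %d",
                len(entries), config.frequency_threshold)
    records = competition_table(stimulus_wifs, entries, constraints)
    median_split(records)
    tok = wif_token_frequency([r.wif for r in records], entries, constraints)
    log_tok = np.log([max(tok[r.wif], 1) for r in records])
    sd = float(np.std(log_tok, ddof=1)) if len(log_tok) > 1 else 0.0
    z_tok = (log_tok - log_tok.mean()) / sd if sd > 0 else np.zeros_like(log_tok)
    table = pd.DataFrame(
        {
            "wif_segments": [" ".join(r.wif.segments) for r in records],
            "accent": [r.wif.accent for r in records],
            "count": [r.count for r in records],
            "log_count": [r.log_count for r in records],
            "z_log_count": [r.z_log_count for r in records],
            "group": [r.group for r in records],
            "token_frequency": [tok[r.wif] for r in records],
            "z_log_frequency": z_tok,
        }
    )
    return CompetitionResult(records, table, report, len(entries))


@dataclass
class AnalysisReport:
    config: ExperimentConfig
    split: SplitAssignment
    rejection_log: pd.DataFrame
    omnibus_anova: pd.DataFrame
    followup_anovas: dict[str, pd.DataFrame]
    regression_two_predictor: RegressionFit | None
    regression_simple: RegressionFit
    group_means_uv: dict[str, float]
    manifest: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = [f"# PrAN analysis report — {self.config.name}", ""]
        lines.append("## Median split (raw competitor counts)")
        lines.append(
            f"low group:  n={len(self.split.low_wifs)} mean={self.split.low_mean:.1f} "
            f"SD={self.split.low_sd:.1f}"
        )
        lines.append(
            f"high group: n={len(self.split.high_wifs)} mean={self.split.high_mean:.1f} "
            f"SD={self.split.high_sd:.1f}"
        )
        lines.append("")
        lines.append("## Windowed group mean amplitudes (uV, regression ROIs)")
        for g, v in self.group_means_uv.items():
            lines.append(f"{g}: {v:.3f}")
        lines.append("")
        lines.append("## Omnibus ANOVA")
        lines.append(self.omnibus_anova.to_string(index=False))
        for name, tab in self.followup_anovas.items():
            lines.append("")
            lines.append(f"## Follow-up ANOVA — {name}")
            lines.append(tab.to_string(index=False))
        if self.regression_two_predictor is not None:
            r = self.regression_two_predictor
            lines.append("")
            lines.append("## Regression: competition + frequency (WIF x ROI)")
            lines.append(
                f"F({r.df_model},{r.df_resid}) = {r.f_value:.3f}, R^2 = {r.r_squared:.3f}, "
                f"n = {r.n_obs}"
            )
            for name in r.predictors:
                lines.append(
                    f"  {name}: b = {r.coefficients[name]:.3f}, t = {r.t_values[name]:.3f}, "
                    f"p(two-tailed) = {r.p_two_tailed[name]:.4f}"
                )
            lines.append(
                f"  competition one-tailed p = {r.p_competition_one_tailed:.4f}"
            )
        r = self.regression_simple
        lines.append("")
        lines.append("## Regression: competition only (ROI-averaged per WIF)")
        lines.append(
            f"F({r.df_model},{r.df_resid}) = {r.f_value:.3f}, R^2 = {r.r_squared:.3f}, "
            f"n = {r.n_obs}"
        )
        b = r.coefficients["lexical_competition"]
        lines.append(
            f"  lexical_competition: b = {b:.3f}, t = {r.t_values['lexical_competition']:.3f}, "
            f"one-tailed p = {r.p_competition_one_tailed:.4f}"
        )
        lines.append("")
        lines.append("## Manifest")
        lines.append(json.dumps(self.manifest, indent=2, sort_keys=True))
        return "\n".join(lines) + "\n"

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "report.txt").write_text(self.render(), encoding="utf-8")
        self.omnibus_anova.to_csv(d / "anova_omnibus.tsv", sep="\t", index=False)
        for name, tab in self.followup_anovas.items():
            safe = name.replace(" ", "_")
            tab.to_csv(d / f"anova_{safe}.tsv", sep="\t", index=False)
        self.rejection_log.to_csv(d / "rejection_log.tsv", sep="\t", index=False)
        (d / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )


def _check_wif_match(epochs: EpochSet, records: Sequence[CompetitionRecord]) -> None:
    epoch_wifs = {epochs.item_wif[i] for i in epochs.items}
    table_wifs = {r.wif for r in records}
    if epoch_wifs != table_wifs:
        only_e = sorted(w.label for w in epoch_wifs - table_wifs)
        only_t = sorted(w.label for w in table_wifs - epoch_wifs)
        raise ValueError(
            "WIF sets differ between epochs and competition table; "
            f"epochs only: [{', '.join(only_e)}]; table only: [{', '.join(only_t)}]"
        )


def run_analysis(
    config: ExperimentConfig,
    epochs: EpochSet,
    competition: Sequence[CompetitionRecord],
    z_log_frequency: Sequence[float] | None = None,
) -> AnalysisReport:
    """Full statistical report for one experiment.

    ``competition`` records must cover exactly the WIFs present in the
    epochs.  ``z_log_frequency`` (aligned with the sorted WIF order) enables
    the two-predictor regression; without it only the simple regression is
    fitted.
    """
    records = sorted(competition, key=lambda r: r.wif)
    _check_wif_match(epochs, records)
    montage = MONTAGES[config.montage]

    split = median_split(records)
    corrected = baseline_correct(epochs, config.baseline_window)
    corrected, rej_log = reject_artifacts(corrected, config.rejection_threshold)
    logger.info("rejected %d of %d epochs", int(corrected.rejected.sum()),
                corrected.rejected.size)

    subj = subject_wif_erps(corrected)
    subj_amp = window_roi_amplitudes(subj, montage, config.analysis_window)
    wif_group = {(" ".join(r.wif.segments), r.wif.accent): r.group for r in records}
    subj_amp["competitors"] = [
        "few" if wif_group[(s, a)] == "low" else "many"
        for s, a in zip(subj_amp["wif_segments"], subj_amp["accent"])
    ]
    cells = (
        subj_amp.groupby(["subject", "competitors", "roi"], as_index=False)["amplitude"]
        .mean()
    )
    if cells["amplitude"].isna().any():
        raise ValueError("missing subject x group x ROI cells after rejection")
    by_name = {r.name: r for r in montage}
    cells["antpost"] = cells["roi"].map(lambda n: by_name[n].antpost)
    cells["laterality"] = cells["roi"].map(lambda n: by_name[n].laterality)
    cell_means = cells.groupby(
        ["subject", "competitors", "antpost", "laterality"], as_index=False
    )["amplitude"].mean()
    omnibus = rm_anova(cell_means, within=["competitors", "antpost", "laterality"])

    followups: dict[str, pd.DataFrame] = {}
    followups["regression ROIs pooled"] = subset_anova(
        cells, montage, list(config.regression_rois), collapse=True
    )
    for roi in config.regression_rois:
        followups[roi] = subset_anova(cells, montage, [roi], collapse=True)

    grand = item_erps(corrected)
    item_amp = window_roi_amplitudes(
        grand, [by_name[n] for n in config.regression_rois], config.analysis_window
    )
    mean_sd = config.standardization
    z_kwargs = (
        {"study_mean": mean_sd[0], "study_sd": mean_sd[1]} if mean_sd else {}
    )
    # group means on the raw uV scale over the regression ROIs
    item_amp["group"] = [
        wif_group[(s, a)] for s, a in zip(item_amp["wif_segments"], item_amp["accent"])
    ]
    group_means = {
        g: float(v) for g, v in item_amp.groupby("group")["amplitude"].mean().items()
    }

    key_order = {(" ".join(r.wif.segments), r.wif.accent): k for k, r in enumerate(records)}
    z_comp = np.array([r.z_log_count for r in records])

    two_fit: RegressionFit | None = None
    long = item_amp.copy()
    long["z_amplitude"] = standardize_amplitudes(long["amplitude"].to_numpy(), **z_kwargs)
    pos = [key_order[(s, a)] for s, a in zip(long["wif_segments"], long["accent"])]
    long["z_log_count"] = z_comp[pos]
    if z_log_frequency is not None:
        zf = np.asarray(z_log_frequency, dtype=float)
        long["z_log_frequency"] = zf[pos]
        two_fit = pran_regression(
            long["z_amplitude"], long["z_log_count"], long["z_log_frequency"]
        )

    wide = (
        item_amp.groupby(["wif_segments", "accent"], as_index=False)["amplitude"].mean()
    )
    wide["z_amplitude"] = standardize_amplitudes(wide["amplitude"].to_numpy(), **z_kwargs)
    pos = [key_order[(s, a)] for s, a in zip(wide["wif_segments"], wide["accent"])]
    simple_fit = pran_regression(wide["z_amplitude"], z_comp[pos])

    manifest = {
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_hash": config.config_hash(),
        "pran_version": __version__,
        "n_subjects": len(epochs.subjects),
        "n_items": len(epochs.items),
        "n_wifs": len(records),
        "n_epochs_rejected": int(corrected.rejected.sum()),
        "n_obs_simple_regression": simple_fit.n_obs,
        "n_obs_two_predictor_regression": two_fit.n_obs if two_fit else None,
        "seed": config.seed,
    }
    return AnalysisReport(
        config=config,
        split=split,
        rejection_log=rej_log,
        omnibus_anova=omnibus,
        followup_anovas=followups,
        regression_two_predictor=two_fit,
        regression_simple=simple_fit,
        group_means_uv=group_means,
        manifest=manifest,
    )


def simulate_and_estimate(
    sim_config: ErpSimConfig,
    competition: Sequence[CompetitionRecord],
    exp_config: ExperimentConfig,
) -> dict[str, float]:
    """One simulate -> reduce -> regress replicate (the light path used for
    calibration and recovery studies; no omnibus ANOVA).

    Returns the simple-regression slope, its one-tailed p, R^2, and the
    low-minus-high median-split group difference in microvolts.
    """
    records = sorted(competition, key=lambda r: r.wif)
    sim = simulate_epochs(sim_config, records)
    corrected = baseline_correct(sim.epochs, exp_config.baseline_window)
    corrected, _ = reject_artifacts(corrected, exp_config.rejection_threshold)
    grand = item_erps(corrected)
    by_name = {r.name: r for r in MONTAGES[exp_config.montage]}
    item_amp = window_roi_amplitudes(
        grand, [by_name[n] for n in exp_config.regression_rois],
        exp_config.analysis_window,
    )
    wide = item_amp.groupby(["wif_segments", "accent"], as_index=False)["amplitude"].mean()
    mean_sd = exp_config.standardization
    z_kwargs = {"study_mean": mean_sd[0], "study_sd": mean_sd[1]} if mean_sd else {}
    z_amp = standardize_amplitudes(wide["amplitude"].to_numpy(), **z_kwargs)
    key_order = {(" ".join(r.wif.segments), r.wif.accent): k for k, r in enumerate(records)}
    pos = [key_order[(s, a)] for s, a in zip(wide["wif_segments"], wide["accent"])]
    z_comp = np.array([r.z_log_count for r in records])[pos]
    fit = pran_regression(z_amp, z_comp)
    split = median_split(records)
    group = np.array(
        [split.assignment[WIFKey(tuple(s.split()), a)]
         for s, a in zip(wide["wif_segments"], wide["accent"])]
    )
    amp = wide["amplitude"].to_numpy()
    low = float(amp[group == "low"].mean())
    high = float(amp[group == "high"].mean())
    return {
        "slope": fit.coefficients["lexical_competition"],
        "p_one_tailed": fit.p_competition_one_tailed,
        "r_squared": fit.r_squared,
        "group_diff_uv": low - high,
        "low_mean_uv": low,
        "high_mean_uv": high,
    }
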