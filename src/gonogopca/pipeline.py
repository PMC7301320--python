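"""End-to-end pipeline: simulate -> preprocess -> 4 x PCA -> match -> stats.

`PipelineConfig` fully determines a run together with the input data (or
the simulate directive): it carries the generator settings, preprocessing
parameters, PCA floors and rotation options, the grid policy, alpha and
the seed.  `run_pipeline` writes a result directory containing the config
copy, the behavioral table, variance tables, loadings, match tables and
the Tables-style contrast CSVs, all with fixed float formatting so that a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .contrasts import (
    behavioral_tests, results_table, run_contrast_battery,
)
from .data import AverageSet, EpochSet
from .decompose import (
    Decomposition, SelectionRule, component_amplitude_map, decompose_dataset,
    reconstitute,
)
from .match import ComponentMatch, match_components, match_table
from .montage import Montage, default_montage
from .preprocess import (
    average_and_downsample, behavior_summary, preprocess_epochs,
)
from .simulate import GeneratorConfig, simulate_session
from .templates import ComponentTemplate, make_default_templates

logger = logging.getLogger(__name__)

DRUGS = ("placebo", "caffeine")
CONDITIONS = ("go", "nogo")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (with the input data)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    drugs: tuple[str, ...] = DRUGS
    lowpass_hz: float = 25.0
    artifact_threshold_uv: float = 75.0
    primary_floor_pct: float = 2.0
    fallback_floor_pct: float = 1.0
    kaiser: bool = True
    rotation_max_iter: int = 1000
    alpha: float = 0.05
    pn_uses_temporal_grid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.drugs) != DRUGS:
            raise ValueError(
                "the design is a 2-level placebo/caffeine crossover; "
                f"got drugs={self.drugs!r}")
        self.generator.seed = self.seed

    @property
    def selection_rule(self) -> SelectionRule:
        return SelectionRule(self.primary_floor_pct, self.fallback_floor_pct)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["drugs"] = list(self.drugs)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    averages: AverageSet
    behavior: pd.DataFrame
    behavior_tests: pd.DataFrame
    decompositions: dict[tuple[str, str], Decomposition]   # (condition, drug)
    matches: dict[str, list[ComponentMatch]]               # per condition
    placebo_stats: dict[tuple[str, str], pd.DataFrame]     # (condition, label)
    drug_stats: dict[tuple[str, str], pd.DataFrame]
    reconstitution: dict[tuple[str, str], pd.DataFrame]    # per-site fit r


def simulate_and_preprocess(
    config: PipelineConfig,
    templates: tuple[ComponentTemplate, ...] | None = None,
    montage: Montage | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> tuple[AverageSet, pd.DataFrame, dict]:
    """Generate both drug arms and reduce them to average ERPs.

    Arms are processed one at a time so only one session's raw epochs are
    held in memory.  Returns the combined AverageSet, the behavioral
    summary per subject x drug, and the generator ground truth per drug.
    """
    montage = montage or default_montage()
    if templates is None:
        templates = make_default_templates(montage)
    avg_parts, behav_parts, truth = [], [], {}
    for drug in config.drugs:
        epochs, log = simulate_session(config.generator, templates, drug, montage)
        epochs = preprocess_epochs(
            epochs, cutoff=config.lowpass_hz,
            threshold_uv=config.artifact_threshold_uv)
        avg = average_and_downsample(epochs)
        if tuple(conditions) != CONDITIONS:
            keep = avg.meta["condition"].isin(conditions).to_numpy()
            avg = AverageSet(avg.data[keep], avg.channels, avg.times,
                             avg.sfreq, avg.meta.loc[keep].reset_index(drop=True),
                             montage, avg.ground_truth)
        avg_parts.append(avg)
        behav_parts.append(behavior_summary(log))
        truth[drug] = epochs.ground_truth
        del epochs
    first = avg_parts[0]
    averages = AverageSet(
        data=np.concatenate([a.data for a in avg_parts]),
        channels=first.channels,
        times=first.times,
        sfreq=first.sfreq,
        meta=pd.concat([a.meta for a in avg_parts], ignore_index=True),
        montage=montage,
        ground_truth=truth,
    )
    behavior = pd.concat(behav_parts, ignore_index=True)
    return averages, behavior, truth


def decompose_all(
    averages: AverageSet, config: PipelineConfig,
    templates: tuple[ComponentTemplate, ...] | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> dict[tuple[str, str], Decomposition]:
    """Four separate PCAs; the placebo solution of each condition is the
    reference for the caffeine fallback selection."""
    rule = config.selection_rule
    out: dict[tuple[str, str], Decomposition] = {}
    for condition in conditions:
        plac = decompose_dataset(
            averages, "placebo", condition, rule, templates,
            kaiser=config.kaiser, max_iter=config.rotation_max_iter)
        caff = decompose_dataset(
            averages, "caffeine", condition, rule, templates,
            reference=plac, kaiser=config.kaiser,
            max_iter=config.rotation_max_iter)
        out[(condition, "placebo")] = plac
        out[(condition, "caffeine")] = caff
    return out


def component_amplitudes(
    plac: Decomposition, caff: Decomposition, match: ComponentMatch,
    grid,
) -> pd.DataFrame:
    """Tidy subject x drug x channel amplitude table for one matched
    component, restricted to the 9 grid sites."""
    parts = []
    for dec, drug, fac in ((plac, "placebo", match.placebo_factor),
                           (caff, "caffeine", match.caffeine_factor)):
        amp = component_amplitude_map(dec, fac, sites=grid.channels)
        amp["drug"] = drug
        parts.append(amp)
    return pd.concat(parts, ignore_index=True)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    templates: tuple[ComponentTemplate, ...] | None = None,
    montage: Montage | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> PipelineResult:
    """Execute the full chain and (optionally) write the result directory."""
    montage = montage or default_montage()
    if templates is None:
        templates = make_default_templates(montage)

    averages, behavior, _ = simulate_and_preprocess(
        config, templates, montage, conditions)
    behavior_stats = behavioral_tests(behavior)
    decs = decompose_all(averages, config, templates, conditions)

    matches: dict[str, list[ComponentMatch]] = {}
    placebo_stats: dict[tuple[str, str], pd.DataFrame] = {}
    drug_stats: dict[tuple[str, str], pd.DataFrame] = {}
    recon: dict[tuple[str, str], pd.DataFrame] = {}

    for condition in conditions:
        plac = decs[(condition, "placebo")]
        caff = decs[(condition, "caffeine")]
        matches[condition] = match_components(plac, caff)
        for key, dec in ((("placebo"), plac), (("caffeine"), caff)):
            _, fit = reconstitute(dec, selected_only=True)
            recon[(condition, key)] = fit
        for m in matches[condition]:
            if m.match_class == "unmatched":
                logger.info("%s %s unmatched (r_c=%.2f); excluded from drug stats",
                            condition, m.label, min(m.temporal_congruence,
                                                    m.topographic_congruence))
                continue
            grid = montage.grid(
                "temporal" if (m.label == "PN" and config.pn_uses_temporal_grid)
                else "core")
            amps = component_amplitudes(plac, caff, m, grid)
            p_res, d_res = run_contrast_battery(amps, grid, alpha=config.alpha)
            placebo_stats[(condition, m.label)] = results_table(p_res)
            drug_stats[(condition, m.label)] = results_table(d_res)

    result = PipelineResult(
        config=config, averages=averages, behavior=behavior,
        behavior_tests=behavior_stats, decompositions=decs, matches=matches,
        placebo_stats=placebo_stats, drug_stats=drug_stats,
        reconstitution=recon,
    )
    if out_dir is not None:
        write_result_dir(result, Path(out_dir))
    return result


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_result_dir(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    gio.write_json(result.config.to_dict(), out_dir / "config.json")
    _write_csv(result.behavior, out_dir / "behavior_summary.csv")
    _write_csv(result.behavior_tests, out_dir / "behavior_tests.csv")
    for (condition, drug), dec in result.decompositions.items():
        stem = f"{condition}-{drug}"
        _write_csv(dec.variance_table(), out_dir / f"variance_{stem}.csv")
        loadings = pd.DataFrame(
            dec.loadings[:, dec.selected],
            columns=[f"{lab}" for lab, s in zip(dec.labels, dec.selected) if s])
        loadings.insert(0, "time_s", dec.times)
        _write_csv(loadings, out_dir / f"loadings_{stem}.csv")
        _write_csv(result.reconstitution[(condition, drug)],
                   out_dir / f"reconstitution_{stem}.csv")
    for condition, mlist in result.matches.items():
        _write_csv(match_table(mlist), out_dir / f"match_{condition}.csv")
    for (condition, label), df in result.placebo_stats.items():
        safe = label.replace("/", "_")
        _write_csv(df, out_dir / f"topography_{condition}_{safe}.csv")
    for (condition, label), df in result.drug_stats.items():
        safe = label.replace("/", "_")
        _write_csv(df, out_dir / f"drug_effects_{condition}_{safe}.csv")
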