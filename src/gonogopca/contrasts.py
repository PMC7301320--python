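"""Planned-contrast repeated-measures topographic statistics.

Component amplitudes are analyzed on a 3 x 3 site grid (sagittal: frontal /
central / parietal rows; lateral: left / midline / right columns) with
planned single-df contrasts: F > P, C > F/P, L > R, M > L/R, their four
sagittal x lateral products, and — in the drug step — the Drug main effect
and Drug x each topographic term.  Every contrast reduces to a one-sample
t on per-subject contrast scores: F = t^2 with df = (1, n - 1), and the
effect size is partial eta squared, F / (F + df_error).

The analysis is two-step.  Step 1 establishes each component's topography
in the placebo condition; its significant contrasts form the component's
"defining topography".  Step 2 tests caffeine effects: observed increases
of the global (Drug main) effect or of Drug x defining-topography terms
are tested one-sided (the amplifier prediction); unpredicted decreases and
non-defining terms keep two-sided probability.  No multiplicity
correction is applied — the contrasts are planned and do not exceed the
effect degrees of freedom.

The behavioral battery is six paired one-tailed t-tests (Go omission %,
fast-RT %, delayed-RT %, NoGo commission %, Go mean RT, RT variability),
each predicting a reduction under caffeine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .montage import SiteGrid

ALPHA = 0.05

_SAGITTAL = {
    "F>P": np.array([1.0, 0.0, -1.0]) / 3.0,
    "C>F/P": np.array([-0.5, 1.0, -0.5]) / 3.0,
}
_LATERAL = {
    "L>R": np.array([1.0, 0.0, -1.0]) / 3.0,
    "M>L/R": np.array([-0.5, 1.0, -0.5]) / 3.0,
}


@dataclass(frozen=True)
class ContrastSpec:
    """Coefficients of one planned contrast over the 3 x 3 grid.

    ``drug`` marks Drug-step terms: per-subject scores are computed on the
    caffeine-minus-placebo cell differences (the Drug main effect uses the
    uniform 1/9 topographic weighting).
    """

    name: str
    cells: np.ndarray            # (3, 3) coefficients, rows sagittal
    drug: bool = False
    predicted: str = "none"      # increase | decrease | none
    sided: int = 2

    def __post_init__(self) -> None:
        if self.cells.shape != (3, 3):
            raise ValueError("cell coefficients must be 3 x 3")


def build_contrasts(include_drug: bool = False) -> list[ContrastSpec]:
    """The planned contrast set: 4 topographic mains, their 4 products,
    and optionally the Drug main plus Drug x each topographic term."""
    specs: list[ContrastSpec] = []
    for sname, srow in _SAGITTAL.items():
        specs.append(ContrastSpec(sname, np.outer(srow, np.ones(3))))
    for lname, lcol in _LATERAL.items():
        specs.append(ContrastSpec(lname, np.outer(np.ones(3), lcol)))
    for sname, srow in _SAGITTAL.items():
        for lname, lcol in _LATERAL.items():
            # elementwise product of the two main-effect coefficient grids
            specs.append(ContrastSpec(f"{sname} x {lname}",
                                      np.outer(srow, lcol)))
    if include_drug:
        topo_specs = list(specs)
        specs.append(ContrastSpec("Drug", np.full((3, 3), 1.0 / 9.0),
                                  drug=True, predicted="increase", sided=2))
        for t in topo_specs:
            specs.append(ContrastSpec(f"Drug x {t.name}", t.cells.copy(),
                                      drug=True, predicted="increase", sided=2))
    return specs


@dataclass(frozen=True)
class ContrastResult:
    name: str
    scores: np.ndarray           # per-subject contrast scores
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    sided: int = 2
    rule: str = ""               # sidedness rule trace

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))


def _amplitude_grid(amplitudes: pd.DataFrame, grid: SiteGrid) -> np.ndarray:
    """(n_subjects, n_drugs, 3, 3) array from a tidy amplitude table with
    columns subject, drug, channel, amplitude_uv.  Raises on missing cells."""
    subjects = sorted(amplitudes["subject"].unique().tolist())
    drugs = sorted(amplitudes["drug"].unique().tolist())
    lut = {(r.subject, r.drug, r.channel): r.amplitude_uv
           for r in amplitudes.itertuples()}
    out = np.empty((len(subjects), len(drugs), 3, 3))
    missing = []
    for si, s in enumerate(subjects):
        for di, d in enumerate(drugs):
            for i, row in enumerate(grid.cells):
                for j, ch in enumerate(row):
                    key = (s, d, ch)
                    if key not in lut:
                        missing.append(key)
                    else:
                        out[si, di, i, j] = lut[key]
    if missing:
        raise ValueError(f"missing amplitude cells: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return out


def contrast_scores(table: np.ndarray, spec: ContrastSpec,
                    drug_axis: tuple[int, int] | None = None) -> np.ndarray:
    """Per-subject contrast scores.

    ``table`` is (n_subjects, 3, 3) for topographic contrasts, or
    (n_subjects, n_drugs, 3, 3) for drug contrasts; ``drug_axis`` gives the
    (caffeine, placebo) indices along the drug axis.
    """
    if spec.drug:
        if table.ndim != 4 or drug_axis is None:
            raise ValueError("drug contrast needs (subject, drug, 3, 3) data")
        caff, plac = drug_axis
        diff = table[:, caff] - table[:, plac]
        return np.tensordot(diff, spec.cells, axes=([1, 2], [0, 1]))
    if table.ndim == 4:
        raise ValueError("topographic contrast expects (subject, 3, 3) data")
    return np.tensordot(table, spec.cells, axes=([1, 2], [0, 1]))


def contrast_test(table: np.ndarray, spec: ContrastSpec,
                  drug_axis: tuple[int, int] | None = None) -> ContrastResult:
    """Single-df repeated-measures contrast: F = squared one-sample t on
    the per-subject contrast scores, df = (1, n - 1), two-sided p (the
    sidedness policy is applied afterwards)."""
    z = contrast_scores(table, spec, drug_axis)
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sd = np.std(z, ddof=1)
    scale = max(1.0, float(np.max(np.abs(table))))
    if sd <= 1e-12 * scale:
        # degenerate: identical scores (e.g. a flat map under a zero-sum
        # contrast, where rounding leaves ~1e-16 constants)
        t = 0.0 if abs(np.mean(z)) <= 1e-10 * scale else np.inf
    else:
        t = float(np.mean(z) / (sd / np.sqrt(n)))
    F = t ** 2
    p = float(2.0 * stats.t.sf(abs(t), n - 1)) if np.isfinite(F) else 0.0
    p = min(p, 1.0) if p > 0 else (1.0 if F == 0 else p)
    eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
    return ContrastResult(spec.name, z, F, (1, n - 1), p, eta, sided=2)


def run_contrast_battery(
    amplitudes: pd.DataFrame, grid: SiteGrid,
    caffeine: str = "caffeine", placebo: str = "placebo",
    alpha: float = ALPHA,
) -> tuple[list[ContrastResult], list[ContrastResult]]:
    """Two-step analysis for one component.

    Step 1: topographic contrasts on the placebo amplitudes.  Step 2: Drug
    main effect and Drug x topography interactions, with the sidedness
    policy applied against the step-1 defining topography.
    """
    table = _amplitude_grid(amplitudes, grid)
    drugs = sorted(amplitudes["drug"].unique().tolist())
    di_caff, di_plac = drugs.index(caffeine), drugs.index(placebo)

    placebo_results = [contrast_test(table[:, di_plac], spec)
                       for spec in build_contrasts(include_drug=False)]
    drug_specs = [s for s in build_contrasts(include_drug=True) if s.drug]
    drug_results = [contrast_test(table, spec, drug_axis=(di_caff, di_plac))
                    for spec in drug_specs]
    drug_results = apply_sidedness(drug_results, placebo_results, table,
                                   (di_caff, di_plac), alpha=alpha)
    return placebo_results, drug_results


def apply_sidedness(
    drug_results: list[ContrastResult],
    placebo_results: list[ContrastResult],
    table: np.ndarray,
    drug_axis: tuple[int, int],
    alpha: float = ALPHA,
) -> list[ContrastResult]:
    """One-sided probability for observed increases of global or defining
    topographic drug terms; two-sided otherwise.

    "Defining topography" = the step-1 placebo contrasts significant at
    ``alpha``.  An interaction Drug x T counts as an observed increase when
    the mean drug-difference score on T has the same sign as the placebo
    mean score on T; the Drug main effect counts as an increase when the
    mean amplitude change has the same sign as the component's grand-mean
    placebo amplitude (its dominant polarity).  Each result carries a rule
    trace.
    """
    di_caff, di_plac = drug_axis
    plac_mean = {r.name: r.mean_score for r in placebo_results}
    defining = {r.name for r in placebo_results if r.p <= alpha}
    polarity = float(np.sign(np.mean(table[:, di_plac])) or 1.0)

    adjusted = []
    for res in drug_results:
        if res.name == "Drug":
            increase = float(np.sign(res.mean_score) or 0.0) == polarity
            eligible = True
            why = f"global term; component polarity {polarity:+.0f}"
        else:
            topo_name = res.name.removeprefix("Drug x ")
            eligible = topo_name in defining
            ref = plac_mean.get(topo_name, 0.0)
            increase = (np.sign(res.mean_score) == np.sign(ref)) and ref != 0.0
            why = (f"topographic term {topo_name!r} "
                   f"{'in' if eligible else 'not in'} defining set")
        if eligible and increase and res.F > 0:
            adjusted.append(replace(
                res, p=res.p / 2.0, sided=1,
                rule=why + "; observed increase -> one-sided"))
        else:
            adjusted.append(replace(
                res, rule=why + "; two-sided retained"))
    return adjusted


def results_table(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "effect": r.name, "F": r.F, "df1": r.df[0], "df2": r.df[1],
        "p": r.p, "sided": r.sided, "partial_eta_sq": r.partial_eta_sq,
        "mean_score": r.mean_score, "rule": r.rule,
    } for r in results])


# ---------------------------------------------------------------------------
# behavioral battery
# ---------------------------------------------------------------------------

BEHAVIORAL_MEASURES = (
    "omission_pct", "fast_rt_pct", "delayed_rt_pct",
    "commission_pct", "rt_mean_ms", "rt_sd_ms",
)


def behavioral_tests(summary: pd.DataFrame,
                     measures: tuple[str, ...] = BEHAVIORAL_MEASURES,
                     caffeine: str = "caffeine",
                     placebo: str = "placebo") -> pd.DataFrame:
    """Paired one-tailed t-tests of the caffeine effect on each behavioral
    measure (prediction: reduction under caffeine; t on placebo - caffeine,
    p = P(T >= t)).  Output mirrors the means/SD/t/p summary layout."""
    wide = summary.pivot(index="subject", columns="drug", values=list(measures))
    n = wide.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for paired tests")
    rows = []
    for meas in measures:
        plac = wide[(meas, placebo)].to_numpy(dtype=float)
        caff = wide[(meas, caffeine)].to_numpy(dtype=float)
        diff = plac - caff
        sd = np.std(diff, ddof=1)
        t = 0.0 if sd == 0.0 else float(np.mean(diff) / (sd / np.sqrt(n)))
        p = float(stats.t.sf(t, n - 1))
        rows.append({
            "measure": meas,
            "placebo_mean": plac.mean(), "placebo_sd": plac.std(ddof=1),
            "caffeine_mean": caff.mean(), "caffeine_sd": caff.std(ddof=1),
            "t": t, "df": n - 1, "p_one_tailed": p,
        })
    return pd.DataFrame(rows)
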