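"""Condition-wise temporal PCA with Varimax rotation.

One PCA is run per drug x condition dataset (Go placebo, Go caffeine,
NoGo placebo, NoGo caffeine), treating time points as variables and
subject x block x channel average waveforms as cases.  Each PCA
eigendecomposes the time x time covariance matrix of the column-centered
case matrix; unrotated loadings are eigenvectors scaled by the square root
of their eigenvalue (so loadings carry microvolt units and factor scores
are standardized), and the full factor set is then Varimax-rotated with
Kaiser (row) normalization.

Rotated factors are ordered by percent variance, sign-flipped so each
peak loading is positive (polarity is carried by the scores), selected by
a variance floor (2% by default, with a 1% fallback for factors matching a
component selected in the reference/placebo decomposition), and labelled
against a component template library by peak latency and topographic
congruence.

Component amplitude at a site is defined as factor score times the loading
value at the factor's peak-loading latency, averaged over blocks — the
"peak component amplitude" entering the topographic statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import AverageSet
from .montage import Montage
from .templates import (
    ComponentTemplate, LABEL_WINDOWS_MS, make_default_templates,
)

logger = logging.getLogger(__name__)

_EPS_EIG = 1e-12


@dataclass
class CaseMatrix:
    """PCA input: rows = subject x block x channel cases, columns = time."""

    data: np.ndarray                 # (n_cases, n_times), uV
    case_meta: pd.DataFrame          # subject, block, channel
    times: np.ndarray                # seconds (decimated axis)
    tag: str                         # e.g. "go-placebo"
    montage: Montage

    @property
    def n_cases(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def case_to_variable_ratio(self) -> float:
        return self.n_cases / self.n_variables


def build_case_matrix(averages: AverageSet, drug: str, condition: str) -> CaseMatrix:
    """Stack one drug x condition dataset into the cases x time matrix.

    Requires a complete cell set: every subject x block must contribute a
    waveform; missing cells are reported by key.
    """
    sub = averages.select(drug, condition)
    subjects = sub.subjects
    blocks = sorted(sub.meta["block"].unique().tolist())
    expected = {(s, b) for s in subjects for b in blocks}
    present = set(map(tuple, sub.meta[["subject", "block"]].to_numpy()))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"missing average cells for {drug}/{condition}: {missing}")

    rows, keys = [], []
    order = sub.meta.sort_values(["subject", "block"]).index
    for i in order:
        wave = sub.data[i]                       # (n_ch, n_times)
        s, b = sub.meta.loc[i, ["subject", "block"]]
        for ci, ch in enumerate(sub.channels):
            rows.append(wave[ci])
            keys.append((s, b, ch))
    case_meta = pd.DataFrame(keys, columns=["subject", "block", "channel"])
    return CaseMatrix(
        data=np.asarray(rows, dtype=np.float64),
        case_meta=case_meta,
        times=sub.times,
        tag=f"{condition}-{drug}",
        montage=sub.montage,
    )


@dataclass
class Decomposition:
    """Rotated temporal factor solution for one drug x condition dataset."""

    tag: str
    times: np.ndarray
    case_meta: pd.DataFrame
    montage: Montage
    column_means: np.ndarray          # (n_times,)
    eigenvalues: np.ndarray           # unrotated, descending
    loadings: np.ndarray              # (n_times, n_factors), uV-scaled, rotated
    scores: np.ndarray                # (n_cases, n_factors), standardized
    pct_variance: np.ndarray          # per rotated factor, of total variance
    total_variance: float             # trace of the covariance matrix
    rotation: np.ndarray | None = None
    converged: bool = True
    criterion_trace: np.ndarray | None = None
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    labels: list[str] = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def peak_latency_ms(self) -> np.ndarray:
        return self.times[np.argmax(np.abs(self.loadings), axis=0)] * 1000.0

    def factor_by_label(self, label: str) -> int:
        hits = [i for i, lab in enumerate(self.labels)
                if lab == label and self.selected[i]]
        if len(hits) != 1:
            raise KeyError(f"{label!r}: {len(hits)} selected factors carry it")
        return hits[0]

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": np.arange(self.n_factors),
            "label": self.labels or ["" for _ in range(self.n_factors)],
            "pct_variance": self.pct_variance,
            "peak_latency_ms": self.peak_latency_ms,
            "selected": self.selected if self.selected.size else False,
        })


@dataclass(frozen=True)
class SelectionRule:
    """Variance floors (percent): primary, plus a fallback used only for
    factors whose label matches a component selected in the reference
    decomposition."""

    primary_floor: float = 2.0
    fallback_floor: float = 1.0

    def __post_init__(self) -> None:
        if not self.fallback_floor < self.primary_floor:
            raise ValueError("fallback floor must be below the primary floor")


# ---------------------------------------------------------------------------
# covariance PCA
# ---------------------------------------------------------------------------

def covariance_pca(cases: CaseMatrix) -> Decomposition:
    """Eigendecomposition of the time x time covariance of the cases.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), so that with
    standardized scores the matrix product ``scores @ loadings.T`` plus the
    column means reproduces the input exactly when all factors are kept.
    Zero-variance directions get zero loadings and scores (epsilon guard).
    """
    X = cases.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cases")
    mu = X.mean(axis=0)
    Xc = X - mu
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    good = eigval > _EPS_EIG * max(eigval.max(), 1.0)
    root = np.sqrt(np.where(good, eigval, 1.0))
    loadings = eigvec * np.where(good, root, 0.0)[None, :]
    scores = (Xc @ eigvec) / root[None, :]
    scores[:, ~good] = 0.0

    total = float(np.trace(cov))
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return Decomposition(
        tag=cases.tag,
        times=cases.times,
        case_meta=cases.case_meta,
        montage=cases.montage,
        column_means=mu,
        eigenvalues=eigval,
        loadings=loadings,
        scores=scores,
        pct_variance=pct,
        total_variance=total,
    )


# ---------------------------------------------------------------------------
# Varimax rotation
# ---------------------------------------------------------------------------

def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw Varimax criterion: sum over factors of the variance of squared
    loadings across variables."""
    L2 = loadings ** 2
    p = loadings.shape[0]
    return float(np.sum(L2 ** 2) / p - np.sum((L2.sum(axis=0) / p) ** 2))


def _varimax(L: np.ndarray, tol: float, max_iter: int
             ) -> tuple[np.ndarray, bool, np.ndarray]:
    """SVD-based Varimax; returns rotation matrix, convergence flag and the
    criterion trace (non-decreasing up to numerical noise)."""
    p, k = L.shape
    R = np.eye(k)
    d = 0.0
    trace = [varimax_criterion(L)]
    converged = False
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p),
            full_matrices=False)
        R = u @ vt
        d_new = float(s.sum())
        trace.append(varimax_criterion(L @ R))
        if d_new <= d * (1.0 + tol):
            converged = True
            break
        d = d_new
    return R, converged, np.array(trace)


def varimax_rotate(dec: Decomposition, kaiser: bool = True,
                   tol: float = 1e-9, max_iter: int = 1000,
                   n_rotate: int | None = None) -> Decomposition:
    """Varimax-rotate the factor solution (all factors by default).

    With ``kaiser=True`` the loading rows are normalized by their
    communalities before rotation and restored afterwards.  Rotated factors
    are re-ordered by descending percent variance and sign-flipped so each
    factor's peak loading is positive.  Non-convergence returns the best
    iterate with ``converged=False``.
    """
    L = dec.loadings
    active = np.flatnonzero((L ** 2).sum(axis=0) > _EPS_EIG)
    if n_rotate is not None:
        active = active[:n_rotate]
    La = L[:, active]

    if kaiser:
        h = np.sqrt((La ** 2).sum(axis=1))
        h_safe = np.where(h > 1e-12, h, 1.0)
        Ln = La / h_safe[:, None]
    else:
        h_safe = None
        Ln = La

    R, converged, trace = _varimax(Ln, tol, max_iter)
    if not converged:
        logger.warning("Varimax did not converge in %d iterations (%s)",
                       max_iter, dec.tag)
    Lr = (Ln @ R) * (h_safe[:, None] if kaiser else 1.0)
    Sr = dec.scores[:, active] @ R

    # order by explained variance, positive-peak sign convention
    var = (Lr ** 2).sum(axis=0)
    order = np.argsort(var)[::-1]
    Lr, Sr, var = Lr[:, order], Sr[:, order], var[order]
    flip = np.sign(Lr[np.argmax(np.abs(Lr), axis=0), np.arange(Lr.shape[1])])
    flip = np.where(flip == 0, 1.0, flip)
    Lr *= flip[None, :]
    Sr *= flip[None, :]

    loadings = np.zeros_like(L)
    scores = np.zeros_like(dec.scores)
    loadings[:, :len(active)] = Lr
    scores[:, :len(active)] = Sr
    pct = np.zeros(L.shape[1])
    pct[:len(active)] = 100.0 * var / dec.total_variance
    return replace(
        dec,
        loadings=loadings,
        scores=scores,
        pct_variance=pct,
        rotation=R,
        converged=converged,
        criterion_trace=trace,
    )


# ---------------------------------------------------------------------------
# selection and labelling
# ---------------------------------------------------------------------------

def select_components(dec: Decomposition, rule: SelectionRule = SelectionRule(),
                      reference_labels: list[str] | None = None) -> np.ndarray:
    """Variance-floor selection with a labelled fallback.

    Factors are selected in decreasing variance order while their percent
    variance stays at or above the primary floor.  For a non-reference
    (caffeine) decomposition, a factor whose label matches a reference-
    selected component is additionally selected if its variance exceeds the
    fallback floor.  Returns (and stores) the boolean selection flags.
    """
    pct = dec.pct_variance
    flags = pct >= rule.primary_floor
    if reference_labels:
        if not dec.labels:
            raise ValueError("labels required for fallback selection")
        for i, lab in enumerate(dec.labels):
            if (not flags[i] and lab in reference_labels and lab != "unknown"
                    and pct[i] > rule.fallback_floor):
                flags[i] = True
    dec.selected = flags
    return flags


def grand_topography(dec: Decomposition, factor: int) -> np.ndarray:
    """Grand-mean peak amplitude of a factor at each of the 19 scalp sites."""
    amap = component_amplitude_map(dec, factor)
    return amap.groupby("channel", sort=False)["amplitude_uv"].mean().reindex(
        list(dec.montage.scalp_channels)).to_numpy()


def label_components(
    dec: Decomposition,
    templates: tuple[ComponentTemplate, ...] | None = None,
    candidate_floor_pct: float = 1.0,
    min_score: float = 0.5,
    windows_ms: dict[str, tuple[float, float]] | None = None,
) -> list[str]:
    """Assign schema labels to factors by latency window + topographic fit.

    Candidate factors (percent variance above ``candidate_floor_pct``) are
    scored against every template whose latency window contains the
    factor's peak-loading latency; the score is the congruence between the
    factor's grand-mean amplitude topography and the template's signed
    topography.  Assignment is greedy by descending score, one factor per
    label; ties break toward the higher-variance factor.  Factors with no
    admissible template (or best score below ``min_score``) are "unknown".
    """
    from .match import tucker_congruence

    templates = templates or make_default_templates(dec.montage)
    windows = windows_ms or LABEL_WINDOWS_MS
    labels = ["unknown"] * dec.n_factors
    candidates = np.flatnonzero(dec.pct_variance >= candidate_floor_pct)
    peaks = dec.peak_latency_ms

    pairs = []  # (score, pct, factor, label)
    for i in candidates:
        topo_i = grand_topography(dec, int(i))
        if not np.any(np.abs(topo_i) > 0):
            continue
        for t in templates:
            lo, hi = windows.get(t.label, (-np.inf, np.inf))
            if not lo <= peaks[i] <= hi:
                continue
            ref = t.topo_vector(dec.montage.scalp_channels) * np.sign(t.amplitude_uv)
            # factor maps live in the column-centered case space, where the
            # channel-mean pattern is absorbed by the column means
            ref = ref - ref.mean()
            score = tucker_congruence(topo_i, ref)
            if score >= min_score:
                pairs.append((score, dec.pct_variance[i], int(i), t.label))

    used_factors: set[int] = set()
    used_labels: set[str] = set()
    for score, _, fac, lab in sorted(pairs, key=lambda p: (-p[0], -p[1])):
        if fac in used_factors or lab in used_labels:
            continue
        labels[fac] = lab
        used_factors.add(fac)
        used_labels.add(lab)
    dec.labels = labels
    return labels


# ---------------------------------------------------------------------------
# amplitudes and reconstitution
# ---------------------------------------------------------------------------

def component_amplitude_map(dec: Decomposition, factor: int,
                            sites: list[str] | None = None) -> pd.DataFrame:
    """Per-subject, per-channel peak component amplitude (uV).

    amplitude(subject, channel) = mean over blocks of
    score(subject, block, channel) x loading at the factor's peak-loading
    latency.
    """
    if sites is not None:
        unknown = [s for s in sites if s not in dec.montage.scalp_channels]
        if unknown:
            raise ValueError(f"channels not in montage: {unknown}")
    peak_idx = int(np.argmax(np.abs(dec.loadings[:, factor])))
    peak_loading = float(dec.loadings[peak_idx, factor])
    df = dec.case_meta.copy()
    df["amplitude_uv"] = dec.scores[:, factor] * peak_loading
    out = (df.groupby(["subject", "channel"], sort=False)["amplitude_uv"]
           .mean().reset_index())
    if sites is not None:
        out = out[out["channel"].isin(sites)].reset_index(drop=True)
    return out


def reconstitute(dec: Decomposition, selected_only: bool = True
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grand-mean waveforms per site from the summed (selected) factors.

    Returns (waveforms, fit) where ``waveforms`` holds, per scalp site, the
    raw grand mean, the reconstituted grand mean and their difference, and
    ``fit`` the per-site Pearson correlation between raw and reconstituted
    waveforms.  Keeping all factors reproduces the raw data exactly.
    """
    from scipy.stats import pearsonr

    keep = (dec.selected if (selected_only and dec.selected.size)
            else np.ones(dec.n_factors, dtype=bool))
    part = dec.scores[:, keep] @ dec.loadings[:, keep].T   # deviations
    raw = dec.scores @ dec.loadings.T

    wave_rows, fit_rows = [], []
    chans = dec.case_meta["channel"].to_numpy()
    for ch in dec.montage.scalp_channels:
        m = chans == ch
        raw_gm = raw[m].mean(axis=0) + dec.column_means
        rec_gm = part[m].mean(axis=0) + dec.column_means
        for t, a, b in zip(dec.times, raw_gm, rec_gm):
            wave_rows.append((ch, t, a, b, a - b))
        if np.std(raw_gm) > 0 and np.std(rec_gm) > 0:
            r, p = pearsonr(raw_gm, rec_gm)
        else:
            r, p = np.nan, np.nan
        fit_rows.append((ch, r, p))
    waves = pd.DataFrame(
        wave_rows, columns=["channel", "time_s", "raw_uv",
                            "reconstituted_uv", "difference_uv"])
    fit = pd.DataFrame(fit_rows, columns=["channel", "r", "p"])
    return waves, fit


def decompose_dataset(
    averages: AverageSet, drug: str, condition: str,
    rule: SelectionRule = SelectionRule(),
    templates: tuple[ComponentTemplate, ...] | None = None,
    reference: Decomposition | None = None,
    kaiser: bool = True, max_iter: int = 1000,
) -> Decomposition:
    """Full chain for one dataset: case matrix -> PCA -> Varimax ->
    label -> select (with reference fallback when given)."""
    cases = build_case_matrix(averages, drug, condition)
    dec = varimax_rotate(covariance_pca(cases), kaiser=kaiser, max_iter=max_iter)
    label_components(dec, templates, candidate_floor_pct=rule.fallback_floor)
    ref_labels = None
    if reference is not None:
        ref_labels = [lab for lab, sel in zip(reference.labels, reference.selected)
                      if sel]
    select_components(dec, rule, reference_labels=ref_labels)
    return dec
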