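"""Cross-condition component matching.

Corresponding components from the placebo and caffeine decompositions of
the same stimulus condition are paired by label and compared with Tucker's
congruence coefficient r_c = sum(a*b) / sqrt(sum(a^2) * sum(b^2)):
r_c >= 0.95 indicates equality, 0.85 <= r_c < 0.95 similarity, anything
lower leaves the pair unmatched (and excluded from drug statistics).
Congruence is computed both on the temporal loadings and on the grand-mean
topographies; classification conservatively uses the smaller of the two,
and both are reported.  Topographic similarity is additionally quantified
by the Pearson correlation over the 19 scalp sites (df = 17), with p from
the exact t transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .decompose import Decomposition, grand_topography

EQUALITY_THRESHOLD = 0.95
SIMILARITY_THRESHOLD = 0.85


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two vectors.

    Scale-invariant under positive rescaling; sign flip of one argument
    negates it.  Undefined (ValueError) for zero vectors.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    na, nb = np.sum(a ** 2), np.sum(b ** 2)
    if na == 0.0 or nb == 0.0:
        raise ValueError("congruence undefined for a zero vector")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def topographic_correlation(a: np.ndarray, b: np.ndarray
                            ) -> tuple[float, int, float]:
    """Pearson correlation between two site maps with df = n_sites - 2 and
    a two-sided p from t = r * sqrt(df / (1 - r^2))."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must cover the same sites")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("correlation undefined for a constant map")
    r, p = pearsonr(a, b)
    return float(r), a.size - 2, float(p)


def classify(r_c: float) -> str:
    if r_c >= EQUALITY_THRESHOLD:
        return "equality"
    if r_c >= SIMILARITY_THRESHOLD:
        return "similarity"
    return "unmatched"


@dataclass(frozen=True)
class ComponentMatch:
    """One placebo/caffeine component pair and its similarity summary."""

    label: str
    placebo_factor: int
    caffeine_factor: int
    temporal_congruence: float
    topographic_congruence: float
    topographic_r: float
    df: int
    p: float
    match_class: str


def match_components(placebo: Decomposition, caffeine: Decomposition
                     ) -> list[ComponentMatch]:
    """Pair same-label selected components across the drug conditions.

    Duplicate labels within one decomposition are rejected; labels present
    in only one decomposition simply yield no pair.
    """
    matches = []
    for dec in (placebo, caffeine):
        sel = [lab for lab, s in zip(dec.labels, dec.selected)
               if s and lab != "unknown"]
        if len(sel) != len(set(sel)):
            raise ValueError(f"duplicate component labels in {dec.tag}")
    plac_sel = {lab: i for i, lab in enumerate(placebo.labels)
                if placebo.selected[i] and lab != "unknown"}
    caff_sel = {lab: i for i, lab in enumerate(caffeine.labels)
                if caffeine.selected[i] and lab != "unknown"}
    for lab in [l for l in plac_sel if l in caff_sel]:
        ip, ic = plac_sel[lab], caff_sel[lab]
        rc_t = tucker_congruence(placebo.loadings[:, ip], caffeine.loadings[:, ic])
        topo_p = grand_topography(placebo, ip)
        topo_c = grand_topography(caffeine, ic)
        rc_s = tucker_congruence(topo_p, topo_c)
        r, df, p = topographic_correlation(topo_p, topo_c)
        matches.append(ComponentMatch(
            label=lab, placebo_factor=ip, caffeine_factor=ic,
            temporal_congruence=rc_t, topographic_congruence=rc_s,
            topographic_r=r, df=df, p=p,
            match_class=classify(min(rc_t, rc_s)),
        ))
    return matches


def match_table(matches: list[ComponentMatch]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in matches])
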