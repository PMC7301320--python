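"""Artifact correction, epoching, trial selection and averaging.

The processing chain mirrors standard ERP practice for this paradigm:

1. ocular correction by least-squares regression of the scalp channels on
   the bipolar vertical/horizontal EOG derivations;
2. zero-phase low-pass filtering (25 Hz, 4th-order Butterworth applied
   forward-backward);
3. epoching from -100 to 750 ms around stimulus onset and baseline
   correction over the prestimulus interval;
4. rejection of epochs exceeding +/-75 uV at any scalp site (EOG channels
   are ignored by this rule);
5. behavioral validation: NoGo trials with a response (commissions), Go
   trials without one (omissions) and Go trials whose RT falls outside the
   individual mean +/- 1.5 SD are excluded;
6. per-cell averaging (subject x drug x block x condition) followed by
   half-sampling of the averages to 256 Hz.

Artifact and behavioral flags are independent boolean columns, so the two
rejection steps commute.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .data import AverageSet, EpochSet

logger = logging.getLogger(__name__)

ARTIFACT_THRESHOLD_UV = 75.0
RT_SD_CRITERION = 1.5


# ---------------------------------------------------------------------------
# EOG regression
# ---------------------------------------------------------------------------

def _eog_regressors(epochs: EpochSet) -> np.ndarray:
    """(n_epochs, n_reg, n_times) regressor stack.

    Uses bipolar derivations when both members of a pair are present
    (VEOG = VEOGU - VEOGL, HEOG = HEOGL - HEOGR), otherwise the raw EOG
    channels.  At least one EOG channel is required.
    """
    names = epochs.channels
    have = {c: names.index(c) for c in epochs.montage.eog_channels if c in names}
    if not have:
        raise ValueError("no EOG channels present")
    regs = []
    if "VEOGU" in have and "VEOGL" in have:
        regs.append(epochs.data[:, have["VEOGU"]] - epochs.data[:, have["VEOGL"]])
        used = {"VEOGU", "VEOGL"}
    else:
        used = set()
    if "HEOGL" in have and "HEOGR" in have:
        regs.append(epochs.data[:, have["HEOGL"]] - epochs.data[:, have["HEOGR"]])
        used |= {"HEOGL", "HEOGR"}
    for c, i in have.items():
        if c not in used:
            regs.append(epochs.data[:, i])
    return np.stack(regs, axis=1)


def regress_eog(epochs: EpochSet) -> tuple[EpochSet, pd.DataFrame]:
    """Remove the least-squares EOG contribution from every scalp channel.

    Regression coefficients are estimated per subject x drug session
    (pooling all of that session's epochs) and returned in a tidy table
    (subject, drug, regressor, channel, coefficient).  A constant EOG
    regressor makes the fit singular and is rejected.
    """
    out = epochs.copy()
    # an EOG electrode stuck at a non-zero constant is broken and would
    # silently cancel in a bipolar derivation; reject it outright
    for i in epochs.eog_picks:
        ch = epochs.data[:, i]
        if np.ptp(ch) == 0.0 and np.any(ch != 0.0):
            raise ValueError(
                f"constant EOG channel {epochs.channels[i]!r}: singular fit")
    regs = _eog_regressors(epochs)
    n_reg = regs.shape[1]
    scalp = epochs.scalp_picks
    coef_rows = []
    reg_names = [f"eog{j}" for j in range(n_reg)]
    if n_reg >= 1 and {"VEOGU", "VEOGL"}.issubset(epochs.channels):
        reg_names[0] = "VEOG"
        if n_reg >= 2 and {"HEOGL", "HEOGR"}.issubset(epochs.channels):
            reg_names[1] = "HEOG"

    for (subj, drug), grp in epochs.meta.groupby(["subject", "drug"], sort=True):
        idx = grp.index.to_numpy()
        X = regs[idx].transpose(1, 0, 2).reshape(n_reg, -1).T          # (n_obs, n_reg)
        Xc = X - X.mean(axis=0)
        # identically zero regressors carry no ocular signal and are
        # dropped; a regressor stuck at a non-zero constant is a broken
        # electrode and makes the fit singular
        silent = np.max(np.abs(X), axis=0) == 0.0
        degenerate = Xc.std(axis=0) < 1e-12
        if np.any(degenerate & ~silent):
            raise ValueError(
                f"constant EOG regressor for subject {subj} ({drug}): singular fit")
        active = ~silent
        beta = np.zeros((n_reg, len(scalp)))
        if active.any():
            Y = epochs.data[idx][:, scalp].transpose(1, 0, 2).reshape(len(scalp), -1).T
            beta[active], *_ = np.linalg.lstsq(
                Xc[:, active], Y - Y.mean(axis=0), rcond=None)
            fitted = (regs[idx].transpose(0, 2, 1) @ beta).transpose(0, 2, 1)
            out.data[idx[:, None], scalp[None, :]] -= fitted.astype(out.data.dtype)
        for j, rname in enumerate(reg_names):
            for k, ch_i in enumerate(scalp):
                coef_rows.append((subj, drug, rname, epochs.channels[ch_i],
                                  float(beta[j, k])))
    coefs = pd.DataFrame(
        coef_rows, columns=["subject", "drug", "regressor", "channel", "coefficient"])
    return out, coefs


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_zero_phase(data: np.ndarray, sfreq: float, cutoff: float = 25.0,
                       order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth low-pass along the last axis.

    A 4th-order Butterworth has a 24 dB/octave asymptotic slope per pass;
    the two passes cancel the phase response exactly.
    """
    if cutoff >= sfreq / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = butter(order, cutoff, btype="low", fs=sfreq, output="sos")
    return sosfiltfilt(sos, np.asarray(data, dtype=np.float64), axis=-1)


def lowpass_epochs(epochs: EpochSet, cutoff: float = 25.0, order: int = 4,
                   chunk: int = 512) -> EpochSet:
    # chunked to keep the float64 filtering workspace small
    out = np.empty_like(epochs.data)
    for i in range(0, epochs.n_epochs, chunk):
        out[i:i + chunk] = lowpass_zero_phase(
            epochs.data[i:i + chunk], epochs.sfreq, cutoff, order
        ).astype(epochs.data.dtype)
    return epochs.copy(data=out)


# ---------------------------------------------------------------------------
# epoching and baseline
# ---------------------------------------------------------------------------

def extract_epochs(
    continuous: np.ndarray,
    event_samples: np.ndarray,
    sfreq: float,
    epochs_like: EpochSet | None = None,
    window_ms: tuple[float, float] = (-100.0, 750.0),
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Cut stimulus-locked epochs from a continuous (n_ch, n_times) record.

    The sample grid is left-closed: t_k = tmin + k/sfreq with t_k < tmax
    (436 samples for -100..750 ms at 512 Hz).  Events too close to either
    recording edge are skipped with a warning and reported.

    Returns (epoch array, epoch time axis, indices of skipped events).
    """
    tmin, tmax = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    n_samples = int(np.floor((tmax - tmin) * sfreq - 1e-9)) + 1
    times = tmin + np.arange(n_samples) / sfreq
    offset = int(round(tmin * sfreq))
    cut, skipped = [], []
    for i, ev in enumerate(np.asarray(event_samples, dtype=int)):
        start = ev + offset
        if start < 0 or start + n_samples > continuous.shape[-1]:
            logger.warning("event %d at sample %d too close to recording edge; skipped",
                           i, ev)
            skipped.append(i)
            continue
        cut.append(continuous[:, start:start + n_samples])
    data = np.stack(cut) if cut else np.empty((0, continuous.shape[0], n_samples))
    return data, times, skipped


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each channel's prestimulus (t < 0) mean from every epoch."""
    pre = epochs.times < 0
    if not np.any(pre):
        raise ValueError("baseline window not inside epoch")
    out = epochs.copy()
    base = out.data[..., pre].mean(axis=-1, keepdims=True)
    out.data = out.data - base
    return out


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

def reject_artifacts(epochs: EpochSet,
                     threshold_uv: float = ARTIFACT_THRESHOLD_UV) -> EpochSet:
    """Flag epochs whose absolute amplitude exceeds the threshold at any
    scalp site; EOG channels are not considered."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    out = epochs.copy()
    peak = np.abs(out.data[:, out.scalp_picks]).max(axis=(1, 2))
    bad = peak > threshold_uv
    out.meta.loc[bad, "reject_artifact"] = True
    out.meta.loc[bad, "reject_reason"] = (
        out.meta.loc[bad, "reject_reason"].astype(str) + "|amplitude")
    return out


def rt_bounds(rts: np.ndarray, criterion: float = RT_SD_CRITERION
              ) -> tuple[float, float, float, float]:
    """Individual RT mean, SD (ddof=1) and the mean +/- criterion*SD bounds.

    With a single RT, or identical RTs, the SD is 0 and the bounds collapse
    to the mean: no RT-based exclusion in that degenerate case.
    """
    rts = np.asarray(rts, dtype=float)
    m = float(np.mean(rts))
    sd = float(np.std(rts, ddof=1)) if rts.size > 1 else 0.0
    return m, sd, m - criterion * sd, m + criterion * sd


def select_valid_trials(epochs: EpochSet,
                        criterion: float = RT_SD_CRITERION) -> EpochSet:
    """Flag behaviorally invalid trials.

    NoGo trials with a response (commission) and Go trials without one
    (omission) are flagged; responded Go trials are flagged when their RT
    falls outside the individual mean +/- 1.5 SD.  RT statistics are
    computed per subject x drug session, pooling both blocks.  A subject
    session with no valid Go RTs cannot be bounded and is rejected.
    """
    out = epochs.copy()
    meta = out.meta
    commission = (meta["condition"] == "nogo") & meta["response"]
    omission = (meta["condition"] == "go") & ~meta["response"]
    meta.loc[commission, "reject_behavior"] = True
    meta.loc[commission, "reject_reason"] = (
        meta.loc[commission, "reject_reason"].astype(str) + "|commission")
    meta.loc[omission, "reject_behavior"] = True
    meta.loc[omission, "reject_reason"] = (
        meta.loc[omission, "reject_reason"].astype(str) + "|omission")

    responded_go = (meta["condition"] == "go") & meta["response"]
    for (subj, drug), grp in meta[responded_go].groupby(["subject", "drug"]):
        rts = grp["rt_ms"].to_numpy(dtype=float)
        if rts.size == 0 or np.any(~np.isfinite(rts)):
            raise ValueError(f"no valid Go RTs for subject {subj} ({drug})")
        _, sd, lo, hi = rt_bounds(rts, criterion)
        if sd == 0.0:
            continue
        bad = grp.index[(rts < lo) | (rts > hi)]
        meta.loc[bad, "reject_behavior"] = True
        meta.loc[bad, "reject_reason"] = (
            meta.loc[bad, "reject_reason"].astype(str) + "|rt_outlier")
    sessions_without_go = (
        meta.groupby(["subject", "drug"])
        .apply(lambda g: int(((g["condition"] == "go") & g["response"]).sum()),
               include_groups=False)
    )
    if (sessions_without_go == 0).any():
        missing = sessions_without_go[sessions_without_go == 0].index.tolist()
        raise ValueError(f"no valid Go RTs for sessions {missing}")
    return out


# ---------------------------------------------------------------------------
# averaging and half-sampling
# ---------------------------------------------------------------------------

def average_and_downsample(epochs: EpochSet, decimate: int = 2) -> AverageSet:
    """Average accepted epochs per subject x drug x block x condition and
    half-sample the averages (every ``decimate``-th point, no refilter:
    the data are already low-passed well below the decimated Nyquist).

    Averages keep scalp channels only.  Cells with no accepted trial are
    excluded with a warning.
    """
    scalp = epochs.scalp_picks
    accepted = epochs.accepted
    cells, rows = [], []
    for key, grp in epochs.meta.groupby(
            ["subject", "drug", "block", "condition"], sort=True):
        idx = grp.index.to_numpy()
        ok = idx[accepted[idx]]
        if ok.size == 0:
            logger.warning("cell %s has no accepted trials; excluded", key)
            continue
        avg = epochs.data[ok][:, scalp].mean(axis=0, dtype=np.float64)
        cells.append(avg[:, ::decimate])
        rows.append(key + (len(ok), len(idx)))
    meta = pd.DataFrame(
        rows, columns=["subject", "drug", "block", "condition",
                       "n_accepted", "n_presented"])
    return AverageSet(
        data=np.stack(cells),
        channels=[epochs.channels[i] for i in scalp],
        times=epochs.times[::decimate],
        sfreq=epochs.sfreq / decimate,
        meta=meta,
        montage=epochs.montage,
        ground_truth=epochs.ground_truth,
    )


# ---------------------------------------------------------------------------
# behavioral summary (per subject x drug)
# ---------------------------------------------------------------------------

def behavior_summary(log: pd.DataFrame, criterion: float = RT_SD_CRITERION
                     ) -> pd.DataFrame:
    """Per subject x drug behavioral measures.

    Go omission %, fast-RT %, delayed-RT % (RTs below/under the individual
    mean -/+ 1.5 SD bounds), NoGo commission %, mean RT and RT variability
    (within-subject SD) over responded Go trials.
    """
    recs = []
    for (subj, drug), g in log.groupby(["subject", "drug"], sort=True):
        go = g[g["condition"] == "go"]
        nogo = g[g["condition"] == "nogo"]
        rts = go.loc[go["response"], "rt_ms"].to_numpy(dtype=float)
        if rts.size == 0:
            raise ValueError(f"no Go responses for subject {subj} ({drug})")
        m, sd, lo, hi = rt_bounds(rts, criterion)
        recs.append({
            "subject": subj, "drug": drug,
            "omission_pct": 100.0 * (~go["response"]).mean(),
            "fast_rt_pct": 100.0 * np.mean(rts < lo) * len(rts) / len(go),
            "delayed_rt_pct": 100.0 * np.mean(rts > hi) * len(rts) / len(go),
            "commission_pct": 100.0 * nogo["response"].mean() if len(nogo) else 0.0,
            "rt_mean_ms": m,
            "rt_sd_ms": sd,
        })
    return pd.DataFrame(recs)


def preprocess_epochs(epochs: EpochSet, cutoff: float = 25.0,
                      threshold_uv: float = ARTIFACT_THRESHOLD_UV) -> EpochSet:
    """EOG regression -> low-pass -> baseline -> artifact and behavioral flags."""
    corrected, _ = regress_eog(epochs)
    filtered = lowpass_epochs(corrected, cutoff=cutoff)
    based = baseline_correct(filtered)
    flagged = reject_artifacts(based, threshold_uv)
    return select_valid_trials(flagged)
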