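"""Synthetic equiprobable Go/NoGo crossover sessions with known ground truth.

The generator emulates the study design the pipeline targets: a two-drug
(placebo / caffeine) x two-block x two-condition (Go / NoGo) within-subject
crossover, 19 scalp channels plus 4 EOG channels sampled at 512 Hz,
150 tones per block (75 Go / 75 NoGo) at a fixed 1100 ms stimulus-onset
asynchrony.  Every trial's clean signal is the sum over component templates
of (temporal shape x topographic weight x condition multiplier x drug
multiplier x subject factor); temporally autocorrelated, spatially
correlated noise, stereotyped eye blinks and ex-Gaussian reaction times are
layered on top.  Ground truth (templates, subject factors, blink
propagation weights) is attached to every generated `EpochSet` so recovery
tests never re-derive it.

All randomness flows from the single `GeneratorConfig.seed`; identical
seeds produce bit-identical sessions.  Subject amplitude factors are drawn
from a seed stream that does not depend on the drug label, so the placebo
and caffeine arms share subjects, as in a crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data import EpochSet, META_COLUMNS
from .montage import Montage, default_montage
from .templates import ComponentTemplate, make_default_templates

_DRUG_CODE = {"placebo": 1, "caffeine": 2}

# seed-stream tags (arbitrary, fixed)
_STREAM_SUBJECTS = 11
_STREAM_SEQUENCE = 17
_STREAM_NOISE = 23
_STREAM_BEHAVIOR = 29
_STREAM_BLINKS = 31
_STREAM_ARTIFACTS = 37
_STREAM_BLOCKS = 41


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator."""

    n_subjects: int = 24
    n_blocks: int = 2
    tones_per_block: int = 150
    go_proportion: float = 0.5
    soa_ms: float = 1100.0
    sfreq: float = 512.0
    epoch_window_ms: tuple[float, float] = (-100.0, 750.0)

    # noise model: AR(1) in time, spatially correlated across channels,
    # plus sparse large artifact transients (muscle/movement analogue)
    ar_coef: float = 0.9
    channel_corr_scale: float = 0.6     # spatial correlation length (head units)
    noise_amplitude_uv: float = 8.0     # stationary single-trial SD per channel
    artifact_rate: float = 0.025        # per-trial probability of a transient
    artifact_amplitude_uv: float = 120.0  # median transient peak
    artifact_duration_ms: float = 250.0

    # blink model
    blink_rate_per_min: float = 12.0
    blink_amplitude_uv: float = 250.0   # bipolar VEOG peak
    blink_duration_ms: float = 300.0
    eog_noise_uv: float = 4.0
    eog_propagation: dict[str, float] | None = None  # scalp weight per channel

    # behavior
    rt_mu_ms: float = 265.0
    rt_sigma_ms: float = 35.0
    rt_tau_ms: float = 50.0
    omission_rate: float = 0.02
    commission_rate: float = 0.015

    subject_sigma: float = 0.3          # log-normal spread of subject factors
    block_sigma: float = 0.25           # log-normal block-to-block drift
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.go_proportion <= 1.0:
            raise ValueError("go_proportion must be in [0, 1]")
        for name in ("omission_rate", "commission_rate", "artifact_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.go_proportion == 0.5 and self.tones_per_block % 2:
            raise ValueError("tones_per_block must be even at go_proportion 0.5")
        if self.tones_per_block < 1 or self.n_subjects < 1 or self.n_blocks < 1:
            raise ValueError("design sizes must be positive")
        span = self.epoch_window_ms[1] - self.epoch_window_ms[0]
        if span <= 0:
            raise ValueError("epoch window must have positive length")
        if span > self.soa_ms:
            raise ValueError("epoch window must not exceed the SOA")

    # -- derived geometry -----------------------------------------------

    @property
    def n_samples(self) -> int:
        """Left-closed sample grid: t_k = tmin + k / sfreq, t_k < tmax."""
        span_s = (self.epoch_window_ms[1] - self.epoch_window_ms[0]) / 1000.0
        return int(np.floor(span_s * self.sfreq - 1e-9)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.epoch_window_ms[0] / 1000.0 + np.arange(self.n_samples) / self.sfreq

    def default_eog_weights(self, montage: Montage) -> np.ndarray:
        """Frontally weighted blink propagation (scalp / bipolar-VEOG gain)."""
        if self.eog_propagation is not None:
            return np.array(
                [self.eog_propagation.get(c, 0.0) for c in montage.scalp_channels])
        y = montage.coords()[:, 1]
        return 0.02 + 0.30 * ((y + 1.0) / 2.0) ** 3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_window_ms"] = list(self.epoch_window_ms)
        return d


def simulate_task_sequence(
    config: GeneratorConfig,
    block: int,
    subject: int = 0,
    drug: str = "placebo",
) -> pd.DataFrame:
    """Randomized tone sequence for one block.

    Exactly ``round(go_proportion * tones_per_block)`` Go (target) trials,
    onsets spaced by the fixed SOA.  The permutation is drawn from a
    generator seeded by (config seed, drug, subject, block), so repeated
    calls with the same arguments are identical.
    """
    n = config.tones_per_block
    n_go = int(round(config.go_proportion * n))
    rng = np.random.default_rng(
        [config.seed, _STREAM_SEQUENCE, _DRUG_CODE[drug], subject, block])
    is_go = np.zeros(n, dtype=bool)
    is_go[rng.permutation(n)[:n_go]] = True
    return pd.DataFrame({
        "trial": np.arange(n),
        "tone_hz": np.where(is_go, 1000, 1500),
        "onset_s": np.arange(n) * config.soa_ms / 1000.0,
        "is_go": is_go,
    })


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               ar: float, burn: int = 64) -> np.ndarray:
    """Unit-variance stationary AR(1) noise along the last axis."""
    n = shape[-1]
    e = rng.standard_normal(shape[:-1] + (n + burn,), dtype=np.float32)
    e *= np.sqrt(1.0 - ar ** 2)
    x = lfilter([1.0], [1.0, -ar], e, axis=-1)
    return np.asarray(x[..., burn:], dtype=np.float32)


def _spatial_mixing(montage: Montage, scale: float) -> np.ndarray:
    """Cholesky factor of an exponential-decay channel correlation matrix."""
    xy = montage.coords()
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    corr = np.exp(-d / scale)
    return np.linalg.cholesky(corr + 1e-9 * np.eye(len(xy)))


def _draw_rts(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    rt = (rng.normal(cfg.rt_mu_ms, cfg.rt_sigma_ms, size=n)
          + rng.exponential(cfg.rt_tau_ms, size=n))
    return np.maximum(rt, 120.0)


def subject_factors(config: GeneratorConfig,
                    templates: tuple[ComponentTemplate, ...]) -> np.ndarray:
    """Log-normal per subject x component amplitude factors (drug-independent)."""
    rng = np.random.default_rng([config.seed, _STREAM_SUBJECTS])
    return np.exp(rng.normal(0.0, config.subject_sigma,
                             size=(config.n_subjects, len(templates))))


def block_factors(config: GeneratorConfig,
                  templates: tuple[ComponentTemplate, ...]) -> np.ndarray:
    """Log-normal per subject x block x component drift (arousal / state
    fluctuations between blocks; drug-independent, like the subject factors)."""
    rng = np.random.default_rng([config.seed, _STREAM_BLOCKS])
    return np.exp(rng.normal(0.0, config.block_sigma,
                             size=(config.n_subjects, config.n_blocks,
                                   len(templates))))


def simulate_session(
    config: GeneratorConfig,
    templates: tuple[ComponentTemplate, ...] | None = None,
    drug: str = "placebo",
    montage: Montage | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """One drug arm of the crossover: all subjects x blocks x trials.

    Returns the stimulus-locked `EpochSet` (scalp + EOG channels, with
    ground truth attached) and the behavioral trial log.
    """
    if drug not in _DRUG_CODE:
        raise ValueError(f"unknown drug label {drug!r}")
    montage = montage or default_montage()
    if templates is None:
        templates = make_default_templates(montage)

    times = config.times
    tmin_ms, tmax_ms = config.epoch_window_ms
    for t in templates:
        if not tmin_ms <= t.peak_ms <= tmax_ms:
            raise ValueError(f"template {t.label}: peak outside epoch window")

    n_subj, n_blocks, n_trials = config.n_subjects, config.n_blocks, config.tones_per_block
    n_epochs = n_subj * n_blocks * n_trials
    n_scalp = len(montage.scalp_channels)
    n_eog = len(montage.eog_channels)
    n_t = config.n_samples

    # --- clean component sum per subject x condition --------------------
    shapes = np.stack([t.temporal_shape(times) for t in templates])      # (k, t)
    topo = np.stack([t.topo_vector(montage.scalp_channels) for t in templates])
    sfac = subject_factors(config, templates)                             # (s, k)
    bfac = block_factors(config, templates)                               # (s, b, k)
    eff = sfac[:, None, :] * bfac                                         # (s, b, k)
    gains = {c: np.array([t.gain(c, drug) for t in templates]) for c in ("go", "nogo")}
    clean = {
        c: np.einsum("sbk,kc,kt->sbct", eff * gains[c][None, None, :], topo, shapes)
        for c in ("go", "nogo")
    }  # (subject, block, channel, time), float64

    # --- noise ----------------------------------------------------------
    rng_noise = np.random.default_rng([config.seed, _STREAM_NOISE, _DRUG_CODE[drug]])
    data = np.zeros((n_epochs, n_scalp + n_eog, n_t), dtype=np.float32)
    if config.noise_amplitude_uv > 0:
        white = _ar1_noise(rng_noise, (n_epochs, n_scalp, n_t), config.ar_coef)
        mix = _spatial_mixing(montage, config.channel_corr_scale).astype(np.float32)
        data[:, :n_scalp] = np.einsum("ij,ejt->eit", mix, white)
        data[:, :n_scalp] *= config.noise_amplitude_uv
        del white
    if config.eog_noise_uv > 0:
        data[:, n_scalp:] = config.eog_noise_uv * _ar1_noise(
            rng_noise, (n_epochs, n_eog, n_t), config.ar_coef)

    # --- trial structure, clean signal, behavior ------------------------
    rng_beh = np.random.default_rng([config.seed, _STREAM_BEHAVIOR, _DRUG_CODE[drug]])
    blocks_meta = []
    for s in range(n_subj):
        for b in range(n_blocks):
            seq = simulate_task_sequence(config, b, subject=s, drug=drug)
            is_go = seq["is_go"].to_numpy()
            u = rng_beh.random(n_trials)
            responded = np.where(is_go, u >= config.omission_rate,
                                 u < config.commission_rate)
            rt = _draw_rts(rng_beh, n_trials, config)
            rt = np.where(responded, rt, np.nan)
            blocks_meta.append(pd.DataFrame({
                "subject": s, "drug": drug, "block": b,
                "condition": np.where(is_go, "go", "nogo"),
                "trial": seq["trial"], "onset_s": seq["onset_s"],
                "tone_hz": seq["tone_hz"], "response": responded, "rt_ms": rt,
            }))
    meta = pd.concat(blocks_meta, ignore_index=True)[list(META_COLUMNS)]
    cond_of_epoch = meta["condition"].to_numpy()
    subj_of_epoch = meta["subject"].to_numpy()

    block_of_epoch = meta["block"].to_numpy()
    for cond in ("go", "nogo"):
        sel = np.flatnonzero(cond_of_epoch == cond)
        data[sel, :n_scalp] += clean[cond][
            subj_of_epoch[sel], block_of_epoch[sel]].astype(np.float32)

    # --- blinks ---------------------------------------------------------
    eog_w = config.default_eog_weights(montage)
    rng_blink = np.random.default_rng([config.seed, _STREAM_BLINKS, _DRUG_CODE[drug]])
    p_blink = config.blink_rate_per_min / 60.0 * config.soa_ms / 1000.0
    if p_blink > 0 and config.blink_amplitude_uv > 0:
        has_blink = rng_blink.random(n_epochs) < p_blink
        blink_idx = np.flatnonzero(has_blink)
        if blink_idx.size:
            dur = config.blink_duration_ms / 1000.0
            t0 = rng_blink.uniform(times[0], times[-1] - dur, size=blink_idx.size)
            phase = (times[None, :] - t0[:, None]) / dur
            pulse = np.where((phase >= 0) & (phase <= 1),
                             np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0)
            pulse = (config.blink_amplitude_uv * pulse).astype(np.float32)
            # scalp contamination, then the EOG electrodes themselves
            data[blink_idx, :n_scalp] += eog_w.astype(np.float32)[None, :, None] * pulse[:, None, :]
            iu = montage.eog_channels.index("VEOGU")
            il = montage.eog_channels.index("VEOGL")
            data[blink_idx, n_scalp + iu] += 0.6 * pulse
            data[blink_idx, n_scalp + il] += -0.4 * pulse

    # --- sparse artifact transients -------------------------------------
    rng_art = np.random.default_rng([config.seed, _STREAM_ARTIFACTS, _DRUG_CODE[drug]])
    if config.artifact_rate > 0 and config.artifact_amplitude_uv > 0:
        hit = np.flatnonzero(rng_art.random(n_epochs) < config.artifact_rate)
        if hit.size:
            dur = config.artifact_duration_ms / 1000.0
            t0 = rng_art.uniform(times[0], max(times[-1] - dur, times[0]),
                                 size=hit.size)
            amp = (config.artifact_amplitude_uv
                   * np.exp(rng_art.normal(0.0, 0.3, size=hit.size))
                   * rng_art.choice([-1.0, 1.0], size=hit.size))
            focus = rng_art.integers(0, n_scalp, size=hit.size)
            xy = montage.coords()
            spread = np.exp(-np.linalg.norm(
                xy[None, :, :] - xy[focus][:, None, :], axis=-1)
                / config.channel_corr_scale)                     # (n_hit, n_scalp)
            phase = (times[None, :] - t0[:, None]) / dur
            burst = np.where((phase >= 0) & (phase <= 1),
                             np.sin(np.pi * np.clip(phase, 0, 1)) ** 2, 0.0)
            data[hit, :n_scalp] += (
                amp[:, None, None] * spread[:, :, None] * burst[:, None, :]
            ).astype(np.float32)

    ground_truth = {
        "drug": drug,
        "templates": templates,
        "template_labels": [t.label for t in templates],
        "temporal_shapes": shapes,
        "topographies": topo,
        "subject_factors": sfac,
        "block_factors": bfac,
        "eog_weights": eog_w,
        "config": config.to_dict(),
    }
    epochs = EpochSet(
        data=data,
        channels=montage.all_channels,
        times=times,
        sfreq=config.sfreq,
        meta=meta,
        montage=montage,
        ground_truth=ground_truth,
    )
    return epochs, epochs.behavioral_log()


def simulate_crossover(
    config: GeneratorConfig,
    templates: tuple[ComponentTemplate, ...] | None = None,
    montage: Montage | None = None,
) -> dict[str, tuple[EpochSet, pd.DataFrame]]:
    """Both drug arms with shared subjects (factors drawn once per seed)."""
    return {drug: simulate_session(config, templates, drug, montage)
            for drug in ("placebo", "caffeine")}
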