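"""Ground-truth ERP component templates for the synthetic generator.

Each template is a separable space-time pattern: a unimodal temporal shape
(Gaussian bump: peak latency, width, signed peak amplitude in microvolts)
times a fixed scalp topography (unitless weights, max |w| = 1), scaled by
condition (Go / NoGo) and drug (placebo / caffeine) multipliers.

The default library follows the adult Go/NoGo processing schema for an
equiprobable auditory task: early sensory/discrimination components (N1-1,
Processing Negativity) are shared between conditions; the Go stream carries
the parietal P3b; the NoGo stream carries a composite P2/N2b, a vertex-
dominant P3a (also present, attenuated, in Go), the central SW1 and the
Late Positivity; the frontal-negative/parietal-positive SW2 appears in both
streams.  Drug multipliers default to 1.0, i.e. no planted caffeine effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, default_montage

CONDITIONS = ("go", "nogo")
DRUGS = ("placebo", "caffeine")

COMPONENT_LABELS = ("N1-1", "PN", "P2/N2b", "P3a", "P3b", "SW1", "SW2", "LP")

#: Peak-latency search windows (ms) used when labelling extracted factors.
LABEL_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "N1-1": (70.0, 130.0),
    "PN": (130.0, 260.0),
    "P2/N2b": (160.0, 280.0),
    "P3a": (250.0, 400.0),
    "P3b": (280.0, 450.0),
    "SW1": (350.0, 600.0),
    "SW2": (450.0, 750.0),
    "LP": (500.0, 750.0),
}


@dataclass(frozen=True)
class ComponentTemplate:
    """One planted ERP component (separable temporal shape x topography)."""

    label: str
    peak_ms: float
    width_ms: float          # Gaussian sigma
    amplitude_uv: float      # signed peak amplitude (negative = negativity)
    topography: dict[str, float] = field(default_factory=dict)
    condition_mult: dict[str, float] = field(
        default_factory=lambda: {"go": 1.0, "nogo": 1.0}
    )
    drug_mult: dict[str, float] = field(
        default_factory=lambda: {"placebo": 1.0, "caffeine": 1.0}
    )

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        w = np.array(list(self.topography.values()), dtype=float)
        if w.size and np.max(np.abs(w)) > 1.0 + 1e-12:
            raise ValueError("topographic weights must be bounded by 1")
        for mults in (self.condition_mult, self.drug_mult):
            if any(v < 0 for v in mults.values()):
                raise ValueError("multipliers must be >= 0")

    # -- evaluation ------------------------------------------------------

    def temporal_shape(self, times_s: np.ndarray) -> np.ndarray:
        """Signed waveform (uV) on a time axis in seconds."""
        t = np.asarray(times_s, dtype=float)
        mu = self.peak_ms / 1000.0
        sig = self.width_ms / 1000.0
        return self.amplitude_uv * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    def topo_vector(self, channels: list[str] | tuple[str, ...]) -> np.ndarray:
        return np.array([self.topography.get(ch, 0.0) for ch in channels])

    def gain(self, condition: str, drug: str) -> float:
        return self.condition_mult[condition] * self.drug_mult[drug]

    def with_drug_mult(self, drug: str, mult: float) -> "ComponentTemplate":
        dm = dict(self.drug_mult)
        dm[drug] = mult
        return ComponentTemplate(
            self.label, self.peak_ms, self.width_ms, self.amplitude_uv,
            dict(self.topography), dict(self.condition_mult), dm,
        )


def _gauss_topo(montage: Montage, lobes: list[tuple[float, float, float, float]]) -> dict[str, float]:
    """Topography as a sum of 2-D Gaussian lobes (gain, x, y, rho), scaled to max |w| = 1."""
    xy = montage.coords()
    w = np.zeros(len(montage.scalp_channels))
    for gain, x0, y0, rho in lobes:
        d2 = (xy[:, 0] - x0) ** 2 + (xy[:, 1] - y0) ** 2
        w += gain * np.exp(-d2 / (2.0 * rho ** 2))
    w /= np.max(np.abs(w))
    return dict(zip(montage.scalp_channels, w.tolist()))


def _decorrelate_topographies(maps: np.ndarray) -> np.ndarray:
    """Loewdin (symmetric) orthogonalization of the channel-mean-centered
    maps, rescaled to max |w| = 1.

    ERP components load the same scalp regions heavily, but their *net*
    spatial patterns across subjects are close to independent; symmetric
    orthogonalization is the minimal deformation of the drawn lobes that
    makes the planted component scores exactly uncorrelated over cases
    (what keeps distinct planted factors identifiable).  The small negative
    flanks it introduces mirror the flanking polarity reversals of real
    component head maps.
    """
    mean = maps.mean(axis=1, keepdims=True)
    dev = maps - mean
    g = dev @ dev.T
    vals, vecs = np.linalg.eigh(g)
    inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.clip(vals, 1e-12, None))) @ vecs.T
    # preserve each map's original deviation norm
    dev_o = inv_sqrt @ dev
    dev_o *= (np.linalg.norm(dev, axis=1) / np.linalg.norm(dev_o, axis=1))[:, None]
    out = mean + dev_o
    return out / np.max(np.abs(out), axis=1, keepdims=True)


def make_default_templates(montage: Montage | None = None) -> tuple[ComponentTemplate, ...]:
    """Schema-faithful default component library (no planted drug effect).

    Shared N1-1 and PN; Go-only P3b; NoGo-dominant P3a; NoGo-only P2/N2b,
    SW1 and LP; SW2 in both streams.  Amplitudes are adult grand-average
    scale values (microvolts at the topographic peak); topographies are
    drawn as Gaussian lobes and then decorrelated (see
    :func:`_decorrelate_topographies`).
    """
    m = montage or default_montage()
    cm = lambda go, nogo: {"go": go, "nogo": nogo}  # noqa: E731
    base = (
        ComponentTemplate(
            "N1-1", 100.0, 30.0, -9.0,
            _gauss_topo(m, [(1.0, 0.0, 0.45, 0.50)]), cm(1.0, 1.0)),
        ComponentTemplate(
            "PN", 170.0, 40.0, -5.5,
            _gauss_topo(m, [(1.0, -0.90, 0.05, 0.40), (1.0, 0.90, 0.05, 0.40),
                            (0.35, 0.0, 0.55, 0.45)]),
            cm(1.0, 1.0)),
        ComponentTemplate(
            "P2/N2b", 230.0, 35.0, 7.5,
            _gauss_topo(m, [(1.0, -0.35, 0.0, 0.42), (-0.90, 0.0, 0.85, 0.40)]),
            cm(0.0, 1.0)),
        ComponentTemplate(
            "P3a", 300.0, 40.0, 9.0,
            _gauss_topo(m, [(1.0, 0.0, 0.0, 0.32)]), cm(0.6, 1.0)),
        ComponentTemplate(
            "P3b", 395.0, 50.0, 13.0,
            _gauss_topo(m, [(1.0, -0.38, -0.55, 0.42)]), cm(1.0, 0.0)),
        ComponentTemplate(
            "SW1", 460.0, 50.0, 7.5,
            _gauss_topo(m, [(1.0, 0.25, -0.25, 0.45)]), cm(0.0, 1.0)),
        ComponentTemplate(
            "SW2", 560.0, 55.0, 6.0,
            _gauss_topo(m, [(1.0, 0.0, -0.85, 0.38), (-1.0, 0.0, 0.70, 0.45)]),
            cm(1.0, 1.0)),
        ComponentTemplate(
            "LP", 690.0, 50.0, 6.0,
            _gauss_topo(m, [(1.0, -0.62, -0.22, 0.36), (1.0, 0.62, -0.22, 0.36)]),
            cm(0.0, 1.0)),
    )
    maps = np.stack([t.topo_vector(m.scalp_channels) for t in base])
    maps = _decorrelate_topographies(maps)
    return tuple(
        ComponentTemplate(
            t.label, t.peak_ms, t.width_ms, t.amplitude_uv,
            dict(zip(m.scalp_channels, maps[i].tolist())),
            dict(t.condition_mult), dict(t.drug_mult))
        for i, t in enumerate(base)
    )


def template_by_label(templates: tuple[ComponentTemplate, ...], label: str) -> ComponentTemplate:
    for t in templates:
        if t.label == label:
            return t
    raise KeyError(label)
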