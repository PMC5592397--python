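"""Synthetic dynamic breast-like phantom with known pharmacokinetic truth.

The phantom emulates a single-slice DCE-MRI acquisition: a static tissue
background (smooth elliptical "breast" on near-zero air), an enhancing
circular tumor whose voxel time courses follow the standard Tofts-Kety model
with heterogeneous (Ktrans, v_e), and fully sampled Cartesian k-space per
dynamic with additive complex white Gaussian noise.

Signals are simulated in enhancement-proportional units,

    S(x, t) = background(x) * (1 + gain * C_T(x, t)),

so the downstream fit can convert back with the same linear scaling; no
SPGRE signal equation or T1 mapping is modeled.

The default tumor means (Ktrans = 0.425 /min, v_e = 0.635) are
representative of an enhancing malignant breast lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import pk
from .operators import fft2c

__all__ = [
    "AIFParams",
    "TumorSpec",
    "GroundTruth",
    "AcquisitionSim",
    "make_ground_truth",
    "aif",
    "synthesize_dynamic_image",
    "simulate_kspace",
]

DEFAULT_GAIN = 0.5  # enhancement units per concentration unit


@dataclass(frozen=True)
class AIFParams:
    """Biexponential plasma input: D * sum_i a_i exp(-m_i (t - t0)) for t >= t0.

    Defaults are the classic population parameters (a in mM, m in 1/min).
    """

    dose: float = 1.0
    amplitudes: tuple[float, float] = (3.99, 4.78)
    rates: tuple[float, float] = (0.144, 0.011)
    t0: float = 0.5

    def __post_init__(self) -> None:
        if self.dose < 0 or any(a < 0 for a in self.amplitudes):
            raise ValueError("dose and amplitudes must be >= 0")
        if any(m < 0 for m in self.rates):
            raise ValueError("negative rate constants are not allowed")


@dataclass(frozen=True)
class TumorSpec:
    """Circular tumor: center (row, col), radius (voxels), mean parameters,
    and log-normal heterogeneity (coefficient of variation) per parameter.

    Malignant breast lesions show strong voxel-to-voxel variation in the
    transfer constant (perfused rim vs. necrotic-leaning core) and milder
    variation in the interstitial volume fraction, hence the asymmetric
    defaults; ``ve_heterogeneity`` is also capped by the requirement that
    v_e stay within (0, 1].
    """

    center: tuple[float, float] | None = None
    radius: float = 6.0
    ktrans_mean: float = 0.425
    ve_mean: float = 0.635
    heterogeneity: float = 0.4
    ve_heterogeneity: float = 0.12


@dataclass
class GroundTruth:
    """Known per-voxel truth of the phantom."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    tumor_mask: np.ndarray
    background: np.ndarray
    time_grid: np.ndarray
    aif_params: AIFParams

    def validate(self) -> None:
        if self.time_grid.size < 6 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing with >= 6 entries")
        if np.any(self.ktrans_map < 0):
            raise ValueError("ktrans_map must be nonnegative")
        if np.any(self.ktrans_map[~self.tumor_mask] != 0):
            raise ValueError("ktrans_map must vanish outside the tumor")
        ve_t = self.ve_map[self.tumor_mask]
        if ve_t.size and (np.any(ve_t <= 0) or np.any(ve_t > 1)):
            raise ValueError("ve_map must lie in (0, 1] on the tumor")


@dataclass(frozen=True)
class AcquisitionSim:
    """k-space simulation settings."""

    noise_sigma: float = 0.01
    seed: int = 0
    injection_index: int = 5

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_ground_truth(shape: tuple[int, int] = (48, 32), d: int = 30,
                      tumor_spec: TumorSpec | None = None, seed: int = 0,
                      dt: float = 0.1, injection_index: int = 5,
                      aif_params: AIFParams | None = None) -> GroundTruth:
    """Generate seeded ground-truth maps and acquisition timing.

    The tumor-voxel means of the generated maps equal the requested means to
    within 2% (exactly, up to the rare clipping of extreme v_e draws).
    """
    m, n = shape
    if m <= 0 or n <= 0 or d < 6:
        raise ValueError("shape must be positive and d >= 6")
    if not 3 <= injection_index <= d - 3:
        raise ValueError("injection_index must lie in [3, d-3]")
    spec = tumor_spec or TumorSpec()
    if spec.radius <= 0:
        raise ValueError("tumor radius must be positive")
    if not 0 < spec.ktrans_mean:
        raise ValueError("ktrans_mean must be positive")
    if not 0 < spec.ve_mean < 1:
        raise ValueError("ve_mean must lie in (0, 1)")
    if spec.heterogeneity < 0 or spec.ve_heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    if spec.ve_mean * np.exp(3.0 * spec.ve_heterogeneity) > 1.0:
        raise ValueError("ve_mean with this heterogeneity can exceed 1")
    center = spec.center if spec.center is not None else (m / 2.0, n / 2.0)
    rows, cols = np.ogrid[:m, :n]
    dist2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    tumor = dist2 <= spec.radius**2
    if not tumor.any():
        raise ValueError("tumor lies fully outside the image")
    if (center[0] - spec.radius < 0 or center[0] + spec.radius > m - 1
            or center[1] - spec.radius < 0 or center[1] + spec.radius > n - 1):
        raise ValueError("tumor must fit inside the field of view")

    rng = np.random.default_rng(seed)
    # smooth elliptical tissue on faint air background
    ell = ((rows - m / 2.0) / (0.45 * m)) ** 2 + ((cols - n / 2.0) / (0.45 * n)) ** 2 <= 1.0
    texture = gaussian_filter(rng.standard_normal((m, n)), sigma=3.0)
    texture = texture / max(np.abs(texture).max(), 1e-12)
    background = np.where(ell, 0.8 * (1.0 + 0.1 * texture), 0.05)

    nvox = int(tumor.sum())

    def lognormal_field(mean: float, h: float) -> np.ndarray:
        if h == 0:
            return np.full(nvox, mean)
        vals = mean * rng.lognormal(mean=-0.5 * h * h, sigma=h, size=nvox)
        return vals * (mean / vals.mean())

    ktrans = np.zeros((m, n))
    ktrans[tumor] = lognormal_field(spec.ktrans_mean, spec.heterogeneity)
    ve_vals = lognormal_field(spec.ve_mean, spec.ve_heterogeneity)
    for _ in range(8):
        ve_vals = np.clip(ve_vals * (spec.ve_mean / ve_vals.mean()), 1e-3, 0.999)
        if abs(ve_vals.mean() - spec.ve_mean) <= 1e-12:
            break
    if abs(ve_vals.mean() - spec.ve_mean) > 0.02 * spec.ve_mean:
        raise ValueError("ve spec cannot be realized within (0, 1]")
    ve = np.zeros((m, n))
    ve[tumor] = ve_vals

    time_grid = dt * np.arange(d)
    params = aif_params or AIFParams(t0=float(time_grid[injection_index]))
    gt = GroundTruth(ktrans, ve, tumor, background, time_grid, params)
    gt.validate()
    return gt


def aif(time_grid: np.ndarray, aif_params: AIFParams) -> np.ndarray:
    """Plasma concentration C_P(t): zero before injection, biexponential after."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time_grid must be strictly increasing")
    tau = t - aif_params.t0
    cp = np.zeros_like(t)
    post = tau >= 0
    for a, mrate in zip(aif_params.amplitudes, aif_params.rates):
        cp[post] += aif_params.dose * a * np.exp(-mrate * tau[post])
    return cp


def synthesize_dynamic_image(gt: GroundTruth, gain: float = DEFAULT_GAIN) -> np.ndarray:
    """Complex dynamic image (rows, cols, dynamics) from the ground truth.

    Non-tumor voxels stay at their background value for all dynamics; tumor
    voxels follow ``background * (1 + gain * C_T)`` with C_T from the
    Tofts-Kety forward model. The imaginary part is zero before noise.
    """
    gt.validate()
    if gain <= 0:
        raise ValueError("gain must be positive")
    d = gt.time_grid.size
    cp = aif(gt.time_grid, gt.aif_params)
    m, n = gt.background.shape
    signal = np.repeat(gt.background[:, :, None], d, axis=2).astype(complex)
    idx = np.argwhere(gt.tumor_mask)
    if idx.size:
        kt = gt.ktrans_map[gt.tumor_mask]
        ve = gt.ve_map[gt.tumor_mask]
        ct = pk.tofts_forward(kt, ve, cp, gt.time_grid)  # (V, d)
        bg = gt.background[gt.tumor_mask][:, None]
        signal[gt.tumor_mask, :] = bg * (1.0 + gain * ct)
    return signal


def simulate_kspace(x: np.ndarray, acq: AcquisitionSim) -> np.ndarray:
    """Fully sampled centered k-space per dynamic plus complex Gaussian noise.

    Noise of standard deviation ``acq.noise_sigma`` is added independently to
    the real and imaginary parts of every k-space sample; the transform is
    orthonormal, so the noiseless round trip is exact to float tolerance.
    """
    x = np.asarray(x, dtype=complex)
    k = fft2c(x)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        noise = acq.noise_sigma * (rng.standard_normal(k.shape)
                                   + 1j * rng.standard_normal(k.shape))
        k = k + noise
    return k
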