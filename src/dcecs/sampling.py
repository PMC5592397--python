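"""Seeded Cartesian variable-density undersampling masks.

Each dynamic samples full k-space lines (phase encodes): a fully sampled
central window of low frequencies plus randomly timed peripheral lines. The
peripheral allocation is balanced by construction — the total peripheral
budget is divided as evenly as possible across peripheral lines, and each
line's quota of appearances is assigned to random dynamics — so every
peripheral phase encode is sampled roughly the same number of times, but at
random time points. Masks are stored (phase_encode, readout, dynamic) with
the DC line at the array center, matching centered k-space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskSet", "make_mask", "acceleration", "render_mask"]


@dataclass
class MaskSet:
    """Binary Cartesian sampling pattern with its generation parameters."""

    mask: np.ndarray           # uint8, (n_pe, n_ro, d)
    center_width: int
    seed: int
    target_R: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def _center_slice(n_pe: int, center_width: int) -> slice:
    start = n_pe // 2 - center_width // 2
    return slice(start, start + center_width)


def make_mask(n_pe: int, n_ro: int, d: int, center_width: int = 20,
              target_R: float = 4.5, seed: int = 0,
              mode: str = "balanced") -> MaskSet:
    """Generate one seeded mask set.

    The number of sampled lines per dynamic implied by ``target_R`` is
    ``round(n_pe / target_R)``; the center window accounts for
    ``center_width`` of them and the remainder ``p`` is drawn from the
    periphery. ``mode="balanced"`` (default) assigns per-line quotas to
    random dynamics, so the per-dynamic count varies slightly around ``p``;
    ``mode="fixed_p"`` samples exactly ``p`` peripheral lines per dynamic
    while keeping per-line totals balanced greedily.
    """
    if n_pe <= 0 or n_ro <= 0 or d <= 0:
        raise ValueError("mask dimensions must be positive")
    if center_width < 0 or center_width >= n_pe:
        raise ValueError("center_width must satisfy 0 <= center_width < n_pe")
    if target_R < 1:
        raise ValueError("target_R must be >= 1")
    lines_per_frame = int(round(n_pe / target_R))
    p = lines_per_frame - center_width
    if p < 0:
        raise ValueError(
            f"target_R={target_R} implies {lines_per_frame} lines/frame, "
            f"fewer than the {center_width} central lines")
    if mode not in ("balanced", "fixed_p"):
        raise ValueError("mode must be 'balanced' or 'fixed_p'")

    rng = np.random.default_rng(seed)
    mask = np.zeros((n_pe, n_ro, d), dtype=np.uint8)
    mask[_center_slice(n_pe, center_width), :, :] = 1

    peripheral = np.array([i for i in range(n_pe)
                           if not (_center_slice(n_pe, center_width).start <= i
                                   < _center_slice(n_pe, center_width).stop)])
    n_per = peripheral.size
    if p > 0 and n_per > 0:
        budget = p * d
        base, rem = divmod(budget, n_per)
        quotas = np.full(n_per, base, dtype=int)
        if rem:
            quotas[rng.choice(n_per, size=rem, replace=False)] += 1
        quotas = np.minimum(quotas, d)
        if mode == "balanced":
            for line, quota in zip(peripheral, quotas):
                if quota:
                    dyn = rng.choice(d, size=quota, replace=False)
                    mask[line, :, dyn] = 1
        else:  # fixed_p
            counts = np.zeros(n_per)
            for j in range(d):
                keys = counts + 0.5 * rng.random(n_per)
                chosen = np.argsort(keys, kind="stable")[:p]
                mask[peripheral[chosen], :, j] = 1
                counts[chosen] += 1
    return MaskSet(mask=mask, center_width=center_width, seed=seed,
                   target_R=float(target_R))


def acceleration(maskset: MaskSet | np.ndarray) -> float:
    """Achieved acceleration: total k-space entries over sampled entries."""
    mask = maskset.mask if isinstance(maskset, MaskSet) else np.asarray(maskset)
    if mask.size == 0:
        raise ValueError("mask is empty")
    sampled = int(mask.sum())
    if sampled == 0:
        raise ValueError("mask samples no entries")
    return mask.size / sampled


def render_mask(maskset: MaskSet, png_path: str | None = None,
                tsv_path: str | None = None) -> np.ndarray:
    """Phase-encode-by-dynamic rendering of the line pattern.

    Returns the (n_pe, d) binary pattern; optionally writes it as a grayscale
    PNG and/or a TSV table for visual inspection.
    """
    pattern = maskset.mask[:, 0, :]
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        plt.imsave(png_path, pattern, cmap="gray")
    if tsv_path is not None:
        np.savetxt(tsv_path, pattern, fmt="%d", delimiter="\t")
    return pattern
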