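"""DNase hypersensitivity meta-profiles and promoter accessibility calls.

An actively transcribed gene has an accessible (DNase-hypersensitive)
promoter.  Multiple DNase signal tracks from the same cell type are
averaged into a meta-profile over a locus; the promoter window is then
called open or closed by comparing its mean signal to a trimmed-mean
background estimated from the rest of the locus.  The fold-over-background
rule replaces a by-eye browser judgement with a reproducible, configurable
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from leakygene.io import SignalTrack

__all__ = ["MetaProfile", "build_meta_profile", "call_promoter_accessibility"]


@dataclass
class MetaProfile:
    """Mean signal per fixed-width bin across tracks over one region."""

    chrom: str
    start: int
    end: int
    step: int
    values: np.ndarray
    n_tracks: int

    def __post_init__(self) -> None:
        expected = math.ceil((self.end - self.start) / self.step)
        if len(self.values) != expected:
            raise ValueError(
                f"{len(self.values)} bins for a region needing {expected}"
            )
        if (np.asarray(self.values) < 0).any():
            raise ValueError("profile values must be non-negative")


def _binned_profile(
    track: SignalTrack, start: int, end: int, step: int
) -> np.ndarray:
    """Coverage-weighted mean signal per bin; uncovered bases contribute 0."""
    n_bins = math.ceil((end - start) / step)
    sums = np.zeros(n_bins)
    for iv_start, iv_end, value in track.intervals:
        lo = max(iv_start, start)
        hi = min(iv_end, end)
        if hi <= lo:
            continue
        first_bin = (lo - start) // step
        last_bin = (hi - 1 - start) // step
        for b in range(first_bin, last_bin + 1):
            bin_lo = start + b * step
            bin_hi = min(bin_lo + step, end)
            overlap = min(hi, bin_hi) - max(lo, bin_lo)
            sums[b] += value * overlap
    widths = np.full(n_bins, step, dtype=float)
    widths[-1] = end - (start + (n_bins - 1) * step)
    return sums / widths


def build_meta_profile(
    tracks: list[SignalTrack],
    region: tuple[str, int, int],
    step: int = 20,
) -> MetaProfile:
    """Average signal tracks into a binned meta-profile over a region.

    Each track is first reduced to a coverage-weighted mean per bin
    (absent coverage counts as 0 signal); the meta-profile is the mean of
    those per-track profiles.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    if not tracks:
        raise ValueError("at least one track is required")
    if step <= 0:
        raise ValueError("step must be positive")
    profiles = np.stack([_binned_profile(t, start, end, step) for t in tracks])
    return MetaProfile(
        chrom=chrom,
        start=start,
        end=end,
        step=step,
        values=profiles.mean(axis=0),
        n_tracks=len(tracks),
    )


def call_promoter_accessibility(
    profile: MetaProfile,
    promoter: tuple[int, int],
    fold_threshold: float = 3.0,
    trim: float = 0.1,
) -> dict:
    """Call a promoter window open or closed against the locus background.

    The promoter's mean signal is compared to the trimmed mean (default
    10% per tail) of the bins outside the promoter; the call is ``open``
    when the fold reaches ``fold_threshold``.  Because the rule is
    fold-based, it is invariant to rescaling every track by a positive
    constant.  Returns the call plus both means and the fold.
    """
    p_start, p_end = promoter
    if p_start < profile.start or p_end > profile.end or p_end <= p_start:
        raise ValueError(
            f"promoter ({p_start}, {p_end}) outside region "
            f"({profile.start}, {profile.end})"
        )
    bin_starts = profile.start + profile.step * np.arange(len(profile.values))
    bin_ends = np.minimum(bin_starts + profile.step, profile.end)
    inside = (bin_starts < p_end) & (bin_ends > p_start)
    if not inside.any():
        raise ValueError("promoter window covers no profile bin")
    promoter_mean = float(profile.values[inside].mean())
    background = float(stats.trim_mean(profile.values[~inside], trim)) if (
        ~inside
    ).any() else 0.0

    if background == 0.0:
        fold = math.inf if promoter_mean > 0 else math.nan
        call = "open" if promoter_mean > 0 else "closed"
    else:
        fold = promoter_mean / background
        call = "open" if fold >= fold_threshold else "closed"
    return {
        "call": call,
        "promoter_mean": promoter_mean,
        "background_mean": background,
        "fold": fold,
        "fold_threshold": fold_threshold,
        "fold_defined": math.isfinite(fold),
    }
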