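"""Between-sample scaling: spike-in-anchored size factors and RPM conversion.

Spike-in (e.g. yeast) counts anchor the factors so that genome-wide shifts
in transcription are not normalised away; datasets without spike-ins fall
back to library-size factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import CoverageTrack


@dataclass
class ScaleFactorSet:
    """Per-sample positive multipliers; dividing counts by the factor puts
    samples on a common scale.  Factors are gauged so their geometric mean
    is 1."""

    factors: dict[str, float]
    method: str
    reference: str = ""

    def __post_init__(self):
        vals = np.array(list(self.factors.values()), float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("scale factors must be positive and finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors)


def median_of_ratios_size_factors(counts: pd.DataFrame, reference: str = "") -> ScaleFactorSet:
    """Median-of-ratios size factors (the DESeq estimator).

    Per-gene reference = geometric mean across samples, over genes with no
    zero count in any sample; factor_s = median over those genes of
    count_{g,s} / reference_g, then gauged to geometric mean 1.
    """
    counts = counts.astype(float)
    if np.any(counts.values < 0):
        raise ValueError("counts must be non-negative")
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "use library_size_factors as a fallback"
        )
    sub = counts.loc[nonzero]
    ref = np.exp(np.log(sub).mean(axis=1))  # per-gene geometric mean
    factors = np.median(sub.div(ref, axis=0), axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return ScaleFactorSet(
        dict(zip(counts.columns, map(float, factors))), "median_of_ratios", reference
    )


def library_size_factors(counts: pd.DataFrame, reference: str = "") -> ScaleFactorSet:
    """Column-sum factors, gauged to geometric mean 1."""
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals.values <= 0):
        raise ValueError("every sample needs positive total counts")
    factors = totals / np.exp(np.mean(np.log(totals)))
    return ScaleFactorSet({k: float(v) for k, v in factors.items()}, "library_size", reference)


def apply_scale(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Divide depths by a per-sample factor (larger library => factor > 1
    => depths shrink).  Refuses to re-scale an already scaled track."""
    if factor <= 0 or not np.isfinite(factor):
        raise ValueError("factor must be positive and finite")
    if track.scale_factor is not None:
        raise ValueError(
            f"track {track.label!r} already scaled by {track.scale_factor}; "
            "re-application refused"
        )
    out = track.copy(scale_factor=float(factor))
    for key in out.data:
        out.data[key] = out.data[key] / factor
    return out


def to_rpm(track: CoverageTrack) -> CoverageTrack:
    """Rescale so the genome-wide sum of depth x bin_size equals 1e6.
    Idempotent, and invariant to any prior global scaling."""
    total = track.total_signal()
    if total <= 0:
        raise ValueError("cannot convert an all-zero track to RPM")
    out = track.copy()
    for key in out.data:
        out.data[key] = out.data[key] * (1e6 / total)
    return out
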