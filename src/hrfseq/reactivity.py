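"""Per-position accessibility from EUC-weighted fragments.

Termination counts, effective coverage, the termination-coverage ratio
(TCR), the treated-minus-control difference (dTCR), a detection-probability
coverage cutoff, and the offset moving average.  Positions are 1-based;
arrays are indexed 0-based with ``array[p - 1]`` holding position ``p``.
Masked (undefined) values are NaN throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def termination_counts(table: pd.DataFrame, length: int) -> np.ndarray:
    """Sum of fragment EUCs terminating at each position.

    Total mass is conserved: ``termination_counts(...).sum() == euc.sum()``.
    """
    out = np.zeros(length, dtype=float)
    if table.empty:
        return out
    pos = table["termination_pos"].to_numpy(dtype=np.int64)
    if pos.min() < 1 or pos.max() > length:
        raise ValueError("termination positions outside [1, reference length]")
    np.add.at(out, pos - 1, table["euc"].to_numpy(dtype=float))
    return out


def effective_coverage(
    table: pd.DataFrame, length: int, min_priming_distance: int = 0
) -> np.ndarray:
    """EUC-weighted coverage of fragments terminating at or spanning a position.

    A fragment contributes to position ``p`` when
    ``termination_pos <= p <= priming_pos`` and, to neutralize size
    selection, ``priming_pos - p >= min_priming_distance``.  With
    ``min_priming_distance = 0`` this is plain span coverage.
    """
    if min_priming_distance < 0:
        raise ValueError("min_priming_distance must be >= 0")
    out = np.zeros(length + 1, dtype=float)
    if table.empty:
        return out[:length]
    term = table["termination_pos"].to_numpy(dtype=np.int64)
    prime = table["priming_pos"].to_numpy(dtype=np.int64)
    euc = table["euc"].to_numpy(dtype=float)
    hi = np.minimum(prime - min_priming_distance, length)  # inclusive upper bound
    keep = hi >= term
    # difference-array interval accumulation over [term, hi]
    np.add.at(out, term[keep] - 1, euc[keep])
    np.add.at(out, hi[keep], -euc[keep])
    return np.cumsum(out)[:length]


def tcr_profile(termination: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Termination-coverage ratio; NaN where coverage is zero."""
    with np.errstate(divide="ignore", invalid="ignore"):
        tcr = np.where(coverage > 0, termination / coverage, np.nan)
    return tcr


def delta_tcr(tcr_treated: np.ndarray, tcr_control: np.ndarray) -> np.ndarray:
    """Treated minus control TCR; negative values are preserved."""
    return tcr_treated - tcr_control


def coverage_cutoff(median_delta_tcr: float, detection_prob: float = 0.9) -> int:
    """Smallest coverage giving ``detection_prob`` chance of >= 1 termination.

    With per-read termination probability ``p`` (the median dTCR), the
    probability of observing at least one termination among ``c`` covering
    molecules is ``1 - (1 - p)**c``; the cutoff is the smallest integer ``c``
    reaching ``detection_prob``.
    """
    p = float(median_delta_tcr)
    if p <= 0:
        raise ValueError("median delta-TCR must be > 0 to define a coverage cutoff")
    if p >= 1:
        return 1
    if detection_prob <= 0:
        return 1
    if detection_prob >= 1:
        raise ValueError("detection probability must be < 1")
    return max(1, math.ceil(math.log(1.0 - detection_prob) / math.log(1.0 - p)))


def smooth_offset(
    values: np.ndarray, window: int = 3, offset_upstream: int = 1
) -> np.ndarray:
    """Moving average with the window shifted downstream of the position.

    ``smoothed[p]`` averages the ``window`` values centered at
    ``p + offset_upstream`` — for the default 3-nt window offset one
    position upstream this is ``mean(values[p .. p+2])``, reflecting that
    reverse transcription stops one nucleotide before the cleaved position.
    Windows touching a NaN or the array boundary are NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    start_shift = offset_upstream - half  # window for p is [p+start_shift, ...+window-1]
    out = np.full(n, np.nan)
    for p in range(n):
        lo = p + start_shift
        hi = lo + window
        if lo < 0 or hi > n:
            continue
        chunk = values[lo:hi]
        if np.any(np.isnan(chunk)):
            continue
        out[p] = chunk.mean()
    return out


def moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Plain centered moving average (NaN at boundaries / masked windows)."""
    return smooth_offset(values, window=window, offset_upstream=0)


def background_fraction(
    tcr_treated: np.ndarray,
    tcr_control: np.ndarray,
    region: tuple[int, int] | None = None,
) -> float:
    """Percentage of the treated TCR signal attributable to background.

    ``100 * sum(control TCR) / sum(treated TCR)`` over the analysis region
    (1-based inclusive bounds), restricted to positions where both profiles
    are defined.  The region should exclude the 5' run-off.
    """
    t = np.asarray(tcr_treated, dtype=float)
    c = np.asarray(tcr_control, dtype=float)
    if region is not None:
        lo, hi = region
        t = t[lo - 1 : hi]
        c = c[lo - 1 : hi]
    both = np.isfinite(t) & np.isfinite(c)
    treated_sum = t[both].sum()
    if treated_sum <= 0:
        raise ValueError("treated TCR sums to zero on the region; background undefined")
    return 100.0 * c[both].sum() / treated_sum


def nucleotides_per_cleavage(median_delta_tcr: float) -> float:
    """Average nucleotides per cleavage implied by the median dTCR."""
    if median_delta_tcr <= 0:
        raise ValueError("median delta-TCR must be > 0")
    return 1.0 / median_delta_tcr


def round_to_sigfigs(value: float, sigfigs: int) -> float:
    """Round to a number of significant figures (e.g. 303.03 -> 300 at 1)."""
    if value == 0:
        return 0.0
    digits = sigfigs - 1 - math.floor(math.log10(abs(value)))
    return round(value, digits)


@dataclass
class PositionSignal:
    """Per-position termination EUC, effective coverage and TCR of one library."""

    termination_euc: np.ndarray
    effective_coverage: np.ndarray
    tcr: np.ndarray

    @classmethod
    def from_fragments(
        cls, table: pd.DataFrame, length: int, min_priming_distance: int = 0
    ) -> "PositionSignal":
        term = termination_counts(table, length)
        cov = effective_coverage(table, length, min_priming_distance)
        bad = term > cov + 1e-9
        if np.any(bad & (cov > 0)):
            logger.warning(
                "termination EUC exceeds effective coverage at %d position(s); "
                "check the priming-distance rule",
                int(bad.sum()),
            )
        return cls(term, cov, tcr_profile(term, cov))


@dataclass
class ReactivityProfile:
    """Full per-position accessibility result for a treated/control pair."""

    treated: PositionSignal
    control: PositionSignal
    delta_tcr: np.ndarray
    smoothed: np.ndarray
    mask: np.ndarray  # True where the position is valid
    median_delta_tcr: float
    cutoff: int
    background_percent: float
    region: tuple[int, int]
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        n = self.delta_tcr.size
        return pd.DataFrame(
            {
                "position": np.arange(1, n + 1),
                "termination_euc_t": self.treated.termination_euc,
                "termination_euc_c": self.control.termination_euc,
                "coverage_t": self.treated.effective_coverage,
                "coverage_c": self.control.effective_coverage,
                "tcr_t": self.treated.tcr,
                "tcr_c": self.control.tcr,
                "delta_tcr": self.delta_tcr,
                "smoothed": self.smoothed,
                "masked": (~self.mask).astype(int),
            }
        )

    def summary(self) -> dict:
        return {
            "median_delta_tcr": self.median_delta_tcr,
            "coverage_cutoff": self.cutoff,
            "background_percent": self.background_percent,
            "region_start": self.region[0],
            "region_end": self.region[1],
            "n_valid_positions": int(self.mask.sum()),
            **self.params,
        }


def compute_profile(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    length: int,
    *,
    min_priming_distance: int = 0,
    region: tuple[int, int] | None = None,
    window: int = 3,
    offset_upstream: int = 1,
    detection_prob: float = 0.9,
    floor_negative: bool = False,
) -> ReactivityProfile:
    """Run the per-position accessibility calculation end to end.

    The coverage cutoff is iterated once: a first-pass median dTCR over all
    covered in-region positions sets the cutoff, which then masks
    low-coverage positions in both libraries before the reported median,
    background fraction and smoothing are computed.
    """
    if region is None:
        region = (1, length)
    lo, hi = region
    if not (1 <= lo <= hi <= length):
        raise ValueError(f"analysis region {region} outside [1, {length}]")

    sig_t = PositionSignal.from_fragments(treated, length, min_priming_distance)
    sig_c = PositionSignal.from_fragments(control, length, min_priming_distance)
    dtcr = delta_tcr(sig_t.tcr, sig_c.tcr)

    in_region = np.zeros(length, dtype=bool)
    in_region[lo - 1 : hi] = True
    covered = np.isfinite(sig_t.tcr) & np.isfinite(sig_c.tcr) & in_region
    if not covered.any():
        raise ValueError("no position in the analysis region is covered in both libraries")

    first_pass_median = float(np.median(dtcr[covered]))
    if first_pass_median > 0:
        cutoff = coverage_cutoff(first_pass_median, detection_prob)
    else:
        cutoff = 1
        logger.warning(
            "first-pass median delta-TCR is %.3g <= 0; coverage cutoff disabled",
            first_pass_median,
        )
    mask = (
        covered
        & (sig_t.effective_coverage >= cutoff)
        & (sig_c.effective_coverage >= cutoff)
    )
    if not mask.any():
        raise ValueError(f"coverage cutoff {cutoff} masks every position")

    median_dtcr = float(np.median(dtcr[mask]))
    bg = background_fraction(
        np.where(mask, sig_t.tcr, np.nan),
        np.where(mask, sig_c.tcr, np.nan),
        region,
    )

    if floor_negative:
        dtcr = np.maximum(dtcr, 0.0)
    masked_dtcr = np.where(mask, dtcr, np.nan)
    smoothed = smooth_offset(masked_dtcr, window=window, offset_upstream=offset_upstream)

    return ReactivityProfile(
        treated=sig_t,
        control=sig_c,
        delta_tcr=masked_dtcr,
        smoothed=smoothed,
        mask=mask,
        median_delta_tcr=median_dtcr,
        cutoff=cutoff,
        background_percent=bg,
        region=region,
        params={
            "min_priming_distance": min_priming_distance,
            "window": window,
            "offset_upstream": offset_upstream,
            "detection_prob": detection_prob,
        },
    )
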