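"""Unequal-frequency barcode model and saturation-corrected unique counting.

A degenerate barcode of length ``L`` is ligated to each cDNA before PCR.
Counting the distinct barcodes ``k`` observed on a fragment estimates the
number of pre-PCR molecules ``n``, but the estimate saturates once ``n``
approaches the barcode pool size.  This module estimates the per-position
nucleotide frequencies of the barcode pool from data, derives the
probability ``P_i`` of each of the ``m = 4**L`` barcodes under positional
independence, and inverts the occupancy expectation

    E[k] = sum_i (1 - (1 - P_i)**n)

to map an observed ``k`` back to an estimated unique count (EUC) ``n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: refuse to enumerate barcode spaces larger than 4**12 (~16.7M probabilities)
MAX_BARCODE_LENGTH = 12

#: hard cap on the tabulated ligation-event count
N_MAX_CAP = 10_000_000


class SaturatedBarcodeError(ValueError):
    """Observed distinct-barcode count lies beyond the invertible range."""

    def __init__(self, k: int, k_max: int):
        self.k = k
        self.k_max = k_max
        super().__init__(
            f"observed unique-barcode count k={k} is saturated beyond the "
            f"lookup table; largest invertible k is {k_max}"
        )


@dataclass(frozen=True)
class BarcodeDistribution:
    """Per-position nucleotide frequencies of a barcode pool.

    Parameters
    ----------
    freq:
        ``(L, 4)`` matrix of nucleotide frequencies, rows indexed by barcode
        position (5' to 3'), columns by base in ``ACGT`` order.  Each row
        must sum to 1.
    """

    freq: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError(f"freq must be (L, 4), got {freq.shape}")
        if freq.shape[0] < 1:
            raise ValueError("barcode length must be >= 1")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        rowsums = freq.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError(f"frequency rows must sum to 1, got {rowsums}")
        object.__setattr__(self, "freq", freq)

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def n_barcodes(self) -> int:
        return 4 ** self.length

    def probabilities(self) -> np.ndarray:
        """Probability of every possible barcode (product over positions).

        Barcodes are indexed as base-4 integers with A=0, C=1, G=2, T=3 and
        position 1 the most significant digit.
        """
        return barcode_probabilities(self.freq)

    @classmethod
    def uniform(cls, length: int) -> "BarcodeDistribution":
        return cls(np.full((length, 4), 0.25))

    def to_frame(self) -> pd.DataFrame:
        """Frequency matrix as a DataFrame (rows = positions, cols = bases)."""
        return pd.DataFrame(
            self.freq,
            index=pd.RangeIndex(1, self.length + 1, name="position"),
            columns=list(BASES),
        )


def _valid_barcode_mask(barcodes: pd.Series, length: int) -> np.ndarray:
    """True for barcodes of the right length over the ACGT alphabet."""
    bc = barcodes.astype(str)
    ok_len = bc.str.len() == length
    ok_alpha = bc.str.fullmatch(f"[ACGT]{{{length}}}").fillna(False)
    return (ok_len & ok_alpha).to_numpy()


def estimate_position_frequencies(
    fragments: pd.DataFrame,
    length: int = 7,
    *,
    quartile: float = 75.0,
) -> BarcodeDistribution:
    """Estimate barcode-pool nucleotide frequencies from observed fragments.

    Fragments whose total read count exceeds the 75th percentile
    (linear-interpolation convention) of per-fragment read counts are
    excluded, so that clonally amplified fragments do not bias the pool
    estimate.  Frequencies are then tallied per barcode position over the
    distinct barcodes of the surviving fragments.

    Parameters
    ----------
    fragments:
        Read-level or aggregated table with columns ``rna_id``,
        ``termination_pos``, ``priming_pos``, ``barcode`` and ``read_count``.
        A fragment is the (rna_id, termination_pos, priming_pos) triple; its
        read count is the sum over its rows.
    length:
        Expected barcode length.

    Raises
    ------
    ValueError
        If no fragment survives the quartile filter or no valid barcode
        remains.
    """
    if fragments.empty:
        raise ValueError("cannot estimate barcode frequencies from an empty table")
    required = {"rna_id", "termination_pos", "priming_pos", "barcode", "read_count"}
    missing = required - set(fragments.columns)
    if missing:
        raise ValueError(f"fragment table lacks columns: {sorted(missing)}")

    key = ["rna_id", "termination_pos", "priming_pos"]
    per_fragment = fragments.groupby(key, sort=False)["read_count"].sum()
    q3 = float(np.percentile(per_fragment.to_numpy(), quartile))
    kept_fragments = per_fragment.index[per_fragment.to_numpy() <= q3]
    if len(kept_fragments) == 0:
        raise ValueError("no fragment survives the read-count quartile filter")

    merged = fragments.set_index(key)
    surviving = merged.loc[merged.index.isin(kept_fragments)].reset_index()
    # the observed *set* of barcodes: one vote per distinct barcode per fragment
    votes = surviving.drop_duplicates(subset=key + ["barcode"])

    valid = _valid_barcode_mask(votes["barcode"], length)
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.info(
            "rejected %d barcode observation(s) with non-ACGT characters "
            "or wrong length during frequency estimation",
            n_rejected,
        )
    barcodes = votes.loc[valid, "barcode"].to_numpy()
    if barcodes.size == 0:
        raise ValueError("no valid ACGT barcode observations after filtering")

    counts = np.zeros((length, 4), dtype=float)
    codes = np.frombuffer("".join(barcodes).encode("ascii"), dtype=np.uint8)
    codes = codes.reshape(len(barcodes), length)
    for i, base in enumerate(BASES):
        counts[:, i] = (codes == ord(base)).sum(axis=0)
    freq = counts / counts.sum(axis=1, keepdims=True)
    return BarcodeDistribution(freq)


def barcode_probabilities(freq: np.ndarray) -> np.ndarray:
    """Probability of each of the ``4**L`` barcodes under independence.

    ``P(b1..bL) = prod_j freq[j, b_j]``; returned vector sums to 1 and is
    indexed by the barcode read as a base-4 number (A=0..T=3, position 1
    most significant).
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 4:
        raise ValueError(f"freq must be (L, 4), got {freq.shape}")
    L = freq.shape[0]
    if L > MAX_BARCODE_LENGTH:
        raise ValueError(
            f"barcode length {L} gives 4**{L} probabilities; refuse above "
            f"L={MAX_BARCODE_LENGTH} — reduce the barcode length"
        )
    probs = freq[0].copy()
    for row in freq[1:]:
        probs = np.outer(probs, row).ravel()
    return probs


def barcode_index(barcode: str) -> int:
    """Index of a barcode in the probability vector (base-4 integer)."""
    idx = 0
    for ch in barcode:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def expected_unique_barcodes(n, probs: np.ndarray):
    """Expected number of distinct barcodes after ``n`` ligation events.

    ``E[k] = sum_i (1 - (1 - P_i)**n)`` with the power evaluated in
    log-space to stay accurate for large ``n``.  ``n`` may be a scalar or an
    array; the result has the same shape.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("ligation-event count n must be >= 0")
    probs = np.asarray(probs, dtype=float)
    # collapse duplicate probabilities: the sum only depends on the multiset
    uniq, counts = np.unique(probs, return_counts=True)
    log1m = np.log1p(-uniq)  # -inf where P_i == 1, handled by exp -> 0
    out = np.empty(n_arr.shape if n_arr.ndim else (1,), dtype=float)
    flat_n = np.atleast_1d(n_arr)
    chunk = max(1, int(4_000_000 // max(1, uniq.size)))
    for start in range(0, flat_n.size, chunk):
        block = flat_n[start : start + chunk]
        with np.errstate(invalid="ignore"):
            surv = np.exp(np.outer(block, log1m))
        surv[block == 0, :] = 1.0  # exp(0 * -inf) is nan; no event, all survive
        out.reshape(-1)[start : start + chunk] = ((1.0 - surv) * counts).sum(axis=1)
    return float(out[0]) if n_arr.ndim == 0 else out.reshape(n_arr.shape)


@dataclass(frozen=True)
class EucTable:
    """Invertible mapping between expected unique barcodes and unique counts.

    ``k_of_n[i]`` is the expected distinct-barcode count after ``i + 1``
    ligation events; ``n_of_k[k]`` is the estimated unique count for an
    observed distinct-barcode count ``k`` (index 0 maps to 0).
    """

    k_of_n: np.ndarray
    n_of_k: np.ndarray = field(repr=False)
    m: int

    @property
    def n_max(self) -> int:
        return len(self.k_of_n)

    @property
    def k_max(self) -> int:
        """Largest observed-barcode count the table can invert."""
        return len(self.n_of_k) - 1

    def lookup(self, k: int) -> int:
        if k < 0:
            raise ValueError("observed unique-barcode count must be >= 0")
        if k > self.k_max:
            raise SaturatedBarcodeError(k, self.k_max)
        return int(self.n_of_k[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(len(self.n_of_k)), "n": self.n_of_k}
        )


def _default_n_max(probs: np.ndarray, k_needed: float | None = None) -> int:
    """Smallest n with E[k] >= target, capped; found by doubling search.

    The target is ``m - 0.5`` (full saturation) or, when ``k_needed`` is
    given, just past the largest k that must be invertible.
    """
    m = probs.size
    target = m - 0.5
    if k_needed is not None:
        target = min(target, float(k_needed) + 0.5)
    n = max(16, m)
    while expected_unique_barcodes(n, probs) < target:
        n *= 2
        if n >= N_MAX_CAP:
            return N_MAX_CAP
    lo, hi = n // 2, n
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if expected_unique_barcodes(mid, probs) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def build_euc_table(
    probs: np.ndarray, n_max: int | None = None, k_needed: int | None = None
) -> EucTable:
    """Tabulate k(n) for n = 1..n_max and invert it to an n(k) lookup.

    For each achievable integer ``k``, ``n_of_k[k]`` is the ``n`` whose
    ``k(n)`` is nearest to ``k`` (ties resolved toward smaller ``n``, the
    conservative choice).  ``k_needed`` bounds the tabulation to the largest
    observed-barcode count that must be invertible, which keeps the table
    small far from saturation; by default the table extends to saturation.
    """
    probs = np.asarray(probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("barcode probabilities must sum to 1")
    if n_max is None:
        n_max = _default_n_max(probs, k_needed)
    n_max = int(n_max)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")

    n_grid = np.arange(1, n_max + 1, dtype=float)
    k_of_n = expected_unique_barcodes(n_grid, probs)

    k_top = int(np.floor(k_of_n[-1]))
    ks = np.arange(0, k_top + 1, dtype=float)
    # index of first n with k(n) >= k; k(n) strictly increasing
    right = np.searchsorted(k_of_n, ks, side="left")
    right = np.clip(right, 0, n_max - 1)
    left = np.clip(right - 1, 0, n_max - 1)
    pick_left = np.abs(k_of_n[left] - ks) <= np.abs(k_of_n[right] - ks)
    idx = np.where(pick_left, left, right)
    n_of_k = idx + 1
    n_of_k[0] = 0
    n_of_k = np.maximum.accumulate(n_of_k)  # guard monotonicity against fp noise
    return EucTable(k_of_n=k_of_n, n_of_k=n_of_k.astype(np.int64), m=probs.size)


def estimate_unique_count(k: int, table: EucTable) -> int:
    """Estimated unique count (EUC) for an observed distinct-barcode count."""
    return table.lookup(int(k))


def attach_euc(aggregated: pd.DataFrame, table: EucTable) -> pd.DataFrame:
    """Add an ``euc`` column to an aggregated fragment table.

    Expects a ``k`` column (distinct valid barcodes per fragment).  Values of
    ``k`` beyond the table's invertible range raise
    :class:`SaturatedBarcodeError`.
    """
    ks = aggregated["k"].to_numpy()
    if ks.size and ks.max() > table.k_max:
        raise SaturatedBarcodeError(int(ks.max()), table.k_max)
    out = aggregated.copy()
    out["euc"] = table.n_of_k[ks]
    return out
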