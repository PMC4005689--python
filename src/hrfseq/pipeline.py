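"""Convenience wiring of the stages: fragments -> EUC -> reactivity."""

from __future__ import annotations

import pandas as pd

from . import barcode_model, fragment_extraction, reactivity


def euc_fragments(
    records: pd.DataFrame,
    barcode_length: int = 7,
    min_span: int = 0,
    n_max: int | None = None,
) -> pd.DataFrame:
    """Read-level fragment records -> aggregated table with EUC attached.

    Estimates the barcode pool from the records themselves (per-library, as
    each ligation reaction has its own pool), builds the saturation table
    just past the largest observed k, and fills the ``euc`` column.
    """
    records = fragment_extraction.span_filter(records, min_span)
    if records.empty:
        raise ValueError("no fragments left after span filtering")
    dist = barcode_model.estimate_position_frequencies(records, barcode_length)
    aggregated = fragment_extraction.aggregate_fragments(records)
    table = barcode_model.build_euc_table(
        dist.probabilities(), n_max=n_max, k_needed=int(aggregated["k"].max())
    )
    return barcode_model.attach_euc(aggregated, table)


def analyze_experiment(
    treated_records: pd.DataFrame,
    control_records: pd.DataFrame,
    length: int,
    *,
    barcode_length: int = 7,
    min_span: int = 0,
    min_priming_distance: int = 0,
    region: tuple[int, int] | None = None,
    window: int = 3,
    offset_upstream: int = 1,
    detection_prob: float = 0.9,
) -> reactivity.ReactivityProfile:
    """Full analysis from read-level records of both libraries."""
    treated = euc_fragments(treated_records, barcode_length, min_span)
    control = euc_fragments(control_records, barcode_length, min_span)
    return reactivity.compute_profile(
        treated,
        control,
        length,
        min_priming_distance=min_priming_distance,
        region=region,
        window=window,
        offset_upstream=offset_upstream,
        detection_prob=detection_prob,
    )
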