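"""Synthetic probing experiments with fully known ground truth.

Simulates the whole wet-lab signal chain the downstream modules must undo:
per-position backbone cleavage, spontaneous reverse-transcription stops,
barcode ligation from an unequal-frequency pool, PCR duplication with
fragment-length bias, and library size selection.  Emits read-level fragment
records, paired SAM alignments and a truth table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_model import BASES, BarcodeDistribution
from .fragment_extraction import BARCODE_TAG, FRAGMENT_COLUMNS

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def random_rna_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@dataclass
class SimulationConfig:
    """Everything needed to generate one treated/control experiment."""

    rna_length: int = 300
    sequence: str | None = None
    cleavage: np.ndarray | None = None  # per-position cleavage probability
    background: float = 0.002  # spontaneous RT stop probability per nt
    priming: str = "threeprime"  # "threeprime" | "random"
    priming_weights: np.ndarray | None = None
    n_events: int = 100_000  # RT events per library
    barcode_length: int = 7
    barcode_freq: np.ndarray | None = None  # (L, 4); uniform when None
    pcr_enabled: bool = True
    pcr_p_short: float = 0.05  # geometric success prob for shortest inserts
    pcr_p_long: float = 0.9  # ... and for the longest
    pcr_max_duplication: int = 50
    size_min: int = 0
    size_max: int | None = None
    rna_id: str = "synthetic_rna"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.rna_length = len(self.sequence)
        if self.cleavage is not None:
            self.cleavage = np.asarray(self.cleavage, dtype=float)
            if self.cleavage.size != self.rna_length:
                raise ValueError("cleavage vector length must match rna_length")
            if np.any((self.cleavage < 0) | (self.cleavage > 1)):
                raise ValueError("cleavage probabilities must lie in [0, 1]")
        if not (0 <= self.background <= 1):
            raise ValueError("background probability must lie in [0, 1]")
        if self.size_min < 0:
            raise ValueError("size window must be positive")

    def resolve(self, rng: np.random.Generator) -> None:
        """Fill in sequence / cleavage / barcode frequencies when unset."""
        if self.sequence is None:
            self.sequence = random_rna_sequence(self.rna_length, rng)
        if self.cleavage is None:
            self.cleavage = default_cleavage_profile(self.rna_length, rng)
        if self.barcode_freq is None:
            self.barcode_freq = BarcodeDistribution.uniform(self.barcode_length).freq

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cleavage"] = None if self.cleavage is None else list(map(float, self.cleavage))
        if self.barcode_freq is not None:
            d["barcode_freq"] = [list(map(float, row)) for row in self.barcode_freq]
        if self.priming_weights is not None:
            d["priming_weights"] = list(map(float, self.priming_weights))
        return d


def default_cleavage_profile(length: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothly varying cleavage probabilities in the single-hit regime.

    Random walk squashed into [0, 0.02] with median near 0.003/nt, mimicking
    the probing intensity of a typical experiment.
    """
    walk = np.cumsum(rng.normal(0, 0.35, size=length))
    walk = (walk - walk.mean()) / (walk.std() + 1e-12)
    profile = 0.02 / (1.0 + np.exp(-(walk - 0.8) * 1.4))
    return np.clip(profile, 0.0, 0.02)


def perturbed_barcode_frequencies(
    length: int, rng: np.random.Generator, concentration: float = 30.0
) -> np.ndarray:
    """Unequal per-position base frequencies (Dirichlet around uniform)."""
    return rng.dirichlet([concentration] * 4, size=length)


def _termination_distribution(
    prime: int, stop_prob: np.ndarray
) -> np.ndarray:
    """P(termination = p) for p = 1..prime given per-position stop probs.

    Reverse transcription starts at the priming site and walks 5'-ward; at
    each position it stops with the local probability, and a polymerase
    reaching position 1 runs off (terminates there regardless).
    """
    q = stop_prob[:prime]  # index p-1 -> position p
    one_minus = 1.0 - q
    # suffix[i] = prod(one_minus[i:]); survival of the walk down to index i
    suffix = np.ones(prime + 1)
    suffix[:prime] = np.cumprod(one_minus[::-1])[::-1]
    # P(term = p) = q[p-1] * prod_{j=p+1..prime} (1 - q[j-1]); telescopes to 1
    pmf = q * suffix[1:]
    pmf[0] = suffix[1]  # run-off mass collects at position 1
    return pmf / pmf.sum()


@dataclass
class SimulationTruth:
    """Realized ground truth: one row per unique pre-PCR molecule."""

    config: SimulationConfig
    molecules: pd.DataFrame  # termination_pos, priming_pos, barcode, duplication
    library: str = "treated"

    def per_fragment_n(self) -> pd.DataFrame:
        """True unique-molecule count per (termination, priming) fragment."""
        return (
            self.molecules.groupby(["termination_pos", "priming_pos"])
            .size()
            .rename("true_n")
            .reset_index()
        )


def simulate_library(
    config: SimulationConfig,
    rng: np.random.Generator,
    treated: bool = True,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate read-level fragment records for one library.

    Returns ``(records, truth)``: records carry one row per sequenced read
    (post-PCR, post size selection) in the standard fragment-table layout;
    truth records every surviving unique molecule with its PCR duplication
    factor.
    """
    config.resolve(rng)
    L = config.rna_length
    stop = np.full(L, config.background, dtype=float)
    if treated:
        stop = 1.0 - (1.0 - stop) * (1.0 - config.cleavage)

    # priming sites
    if config.priming == "threeprime":
        primes = np.full(config.n_events, L, dtype=np.int64)
    elif config.priming == "random":
        w = config.priming_weights
        if w is None:
            w = np.ones(L)
        w = np.asarray(w, dtype=float)
        w = w / w.sum()
        primes = rng.choice(L, size=config.n_events, p=w) + 1
    else:
        raise ValueError(f"unknown priming model {config.priming!r}")

    # termination sites, drawn per unique priming site from the exact pmf
    terms = np.empty(config.n_events, dtype=np.int64)
    for prime in np.unique(primes):
        idx = np.where(primes == prime)[0]
        pmf = _termination_distribution(int(prime), stop)
        terms[idx] = rng.choice(int(prime), size=idx.size, p=pmf) + 1

    # barcodes: one ligation event per RT event
    base_arr = np.array(list(BASES))
    cols = [
        rng.choice(4, size=config.n_events, p=config.barcode_freq[j])
        for j in range(config.barcode_length)
    ]
    codes = np.stack(cols, axis=1)
    barcodes = np.array(["".join(base_arr[row]) for row in codes])

    # library size selection on the insert span
    span = primes - terms + 1
    keep = span >= config.size_min
    if config.size_max is not None:
        keep &= span <= config.size_max
    terms, primes, barcodes, span = terms[keep], primes[keep], barcodes[keep], span[keep]

    # PCR duplication, geometric with length-biased success parameter
    if config.pcr_enabled and terms.size:
        lo, hi = config.size_min, config.size_max or L
        rel = np.clip((span - lo) / max(1, hi - lo), 0.0, 1.0)
        p_geo = config.pcr_p_short + rel * (config.pcr_p_long - config.pcr_p_short)
        dup = np.minimum(rng.geometric(p_geo), config.pcr_max_duplication)
    else:
        dup = np.ones(terms.size, dtype=np.int64)

    molecules = pd.DataFrame(
        {
            "termination_pos": terms,
            "priming_pos": primes,
            "barcode": barcodes,
            "duplication": dup,
        }
    )
    records = pd.DataFrame(
        {
            "rna_id": config.rna_id,
            "termination_pos": np.repeat(terms, dup),
            "priming_pos": np.repeat(primes, dup),
            "barcode": np.repeat(barcodes, dup),
            "read_count": 1,
        }
    )[FRAGMENT_COLUMNS]
    truth = SimulationTruth(
        config=config, molecules=molecules, library="treated" if treated else "control"
    )
    logger.info(
        "%s library: %d RT events -> %d molecules -> %d reads",
        truth.library,
        config.n_events,
        len(molecules),
        len(records),
    )
    return records, truth


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth, SimulationTruth]:
    """Treated and control libraries from one config (control: no cleavage)."""
    rng = np.random.default_rng(config.seed)
    config.resolve(rng)
    treated_records, treated_truth = simulate_library(config, rng, treated=True)
    control_records, control_truth = simulate_library(config, rng, treated=False)
    return treated_records, control_records, treated_truth, control_truth


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def emit_alignments(
    records: pd.DataFrame,
    reference: str,
    rna_id: str,
    read_length: int = 50,
    untemplated_prob: float = 0.0,
    max_untemplated: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Render fragment records as paired sense-strand SAM lines.

    Mate 1 aligns forward starting at the termination site; mate 2 aligns
    reverse ending at the priming site.  The barcode rides along in the
    ``BC`` tag.  With ``untemplated_prob`` > 0, 1..max_untemplated random
    bases are prepended to mate 1 (shifting its alignment start upstream),
    emulating terminal-transferase additions; the injected count is recorded
    in the returned truth frame.

    Returns ``(sam_lines, injection_truth)`` where sam_lines includes the
    header.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = len(reference)
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{rna_id}\tLN:{L}",
        "@PG\tID:hrfseq\tPN:hrfseq",
    ]
    inj_rows = []
    base_arr = np.array(list(BASES))
    for i, row in enumerate(records.itertuples(index=False)):
        term = int(row.termination_pos)
        prime = int(row.priming_pos)
        qname = f"frag{i:07d}"

        n_add = 0
        if untemplated_prob > 0 and rng.random() < untemplated_prob:
            n_add = int(rng.integers(1, max_untemplated + 1))
            n_add = min(n_add, term - 1)
        start1 = term - n_add  # 1-based alignment start of mate 1
        len1 = min(read_length, prime - start1 + 1)
        seq1 = list(reference[start1 - 1 : start1 - 1 + len1])
        for j in range(n_add):
            seq1[j] = str(rng.choice(base_arr))
        seq1 = "".join(seq1)

        len2 = min(read_length, prime)
        start2 = prime - len2 + 1
        seq2_fwd = reference[start2 - 1 : prime]

        tlen = prime - start1 + 1
        flag1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
        flag2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
        bc = str(row.barcode)
        lines.append(
            "\t".join(
                [
                    qname, str(flag1), rna_id, str(start1), "42", f"{len1}M",
                    "=", str(start2), str(tlen), seq1, "*", f"{BARCODE_TAG}:Z:{bc}",
                ]
            )
        )
        lines.append(
            "\t".join(
                [
                    qname, str(flag2), rna_id, str(start2), "42", f"{len2}M",
                    "=", str(start1), str(-tlen), seq2_fwd, "*", f"{BARCODE_TAG}:Z:{bc}",
                ]
            )
        )
        inj_rows.append((qname, term, prime, bc, n_add))
    truth = pd.DataFrame(
        inj_rows,
        columns=["qname", "termination_pos", "priming_pos", "barcode", "untemplated_added"],
    )
    return lines, truth
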