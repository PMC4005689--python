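"""Shared I/O: FASTA / SAM readers, TSV interchange, run configuration.

The interchange dialect is tab-separated text with ``#``-prefixed header
comment lines.  Coordinates are 1-based and inclusive everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from . import __version__

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables, with defaults for a random-primed experiment."""

    barcode_length: int = 7
    min_span: int = 100
    min_priming_distance: int = 100
    max_trim: int = 3
    window: int = 3
    offset_upstream: int = 1
    detection_prob: float = 0.9
    contact_radius: float = 14.0
    probe_radius: float = 1.4
    region_start: int | None = None
    region_end: int | None = None
    seed: int = 0

    @classmethod
    def single_primer(cls, **overrides) -> "RunConfig":
        """Defaults for a single-primer analysis: no span/priming filtering."""
        base = dict(min_span=0, min_priming_distance=0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @property
    def region(self) -> tuple[int, int] | None:
        if self.region_start is None or self.region_end is None:
            return None
        return (self.region_start, self.region_end)


def header_comment(config: RunConfig | None = None, **extra) -> list[str]:
    """Standard ``#`` header lines for every output file."""
    lines = [
        f"# hrfseq v{__version__}",
        "# coordinates: 1-based, inclusive",
    ]
    if config is not None:
        lines.append(f"# config_hash={config.hash()} seed={config.seed}")
    for key, value in extra.items():
        lines.append(f"# {key}={value}")
    return lines


def read_reference(path) -> dict[str, str]:
    """Named sequences from a FASTA file, upper-cased with U -> T."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper().replace("U", "T")
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return sequences


def write_reference(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_alignments(path, rna_id: str | None = None):
    """Open a SAM/BAM file and yield its records (headers validated by pysam)."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=True) as fh:
        if rna_id is not None and rna_id not in fh.references:
            raise ValueError(f"reference {rna_id!r} missing from {path} @SQ headers")
        yield from fh


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None, **extra) -> None:
    """Write a TSV with the standard comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comment(config, **extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_fragments(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    write_table(df, path, config, table="fragments")


def read_fragments(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"rna_id", "termination_pos", "priming_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment table {path} lacks columns {sorted(missing)}")
    if "barcode" in df.columns:
        df["barcode"] = df["barcode"].astype(str)
    return df


def write_summary(summary: dict, path) -> None:
    """Machine-readable run summary sidecar (JSON)."""
    with open(path, "w") as fh:
        json.dump({k: _jsonable(v) for k, v in summary.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(value):
    try:
        json.dumps(value)
        return value
    except TypeError:
        return float(value)


def write_sam(lines: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def sam_from_lines(lines: list[str]):
    """Parse SAM text lines into pysam records (via a scratch file)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write("\n".join(lines) + "\n")
        name = fh.name
    try:
        with pysam.AlignmentFile(name, "r", check_sq=True) as sam:
            yield from sam
    finally:
        Path(name).unlink(missing_ok=True)
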