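"""Core record types shared across the package.

Collections of calls and samples travel as :class:`pandas.DataFrame` objects
with the column contracts documented in :mod:`l1audit.io`; the dataclasses
here describe single records and validated composite objects (coverage
tracks, gold-standard sets, model fits).

Coordinates are 0-based half-open everywhere in memory and on disk
(BED/bedGraph convention); they are rendered 1-based only inside
human-readable report strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MATERIALS = ("single_cell", "bulk")
CELL_TYPES = (
    "hippocampal_neuron",
    "hippocampal_glia",
    "cortical_neuron",
    "AGS_neuron",
    "other",
)
JUNCTIONS = ("five_prime_only", "three_prime_only", "both")
CANDIDATE_CLASSES = ("somatic_candidate", "knr_call")


class ValidationError(ValueError):
    """Raised when an input record or table violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file is structurally malformed (e.g. missing column)."""


@dataclass(frozen=True)
class Locus:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __str__(self) -> str:  # 1-based, human-readable only
        return f"{self.contig}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample (a single cell or a bulk tissue sample)."""

    sample_id: str
    individual_id: str
    material: str
    cell_type: str = "other"
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValidationError(f"unknown material {self.material!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(f"unknown cell_type {self.cell_type!r}")
        if self.material == "bulk" and self.cell_type != "other":
            raise ValidationError("bulk samples must have cell_type='other'")
        if self.total_reads < 0:
            raise ValidationError("total_reads must be >= 0")


@dataclass(frozen=True)
class InsertionCall:
    """One candidate/insertion observation in one sample.

    A call record exists only when the insertion was detected in that sample
    (``read_count >= 1``); allelic dropout is represented by the absence of a
    row, never by a zero count.
    """

    sample_id: str
    locus: Locus
    read_count: int
    junctions: str
    prior_study: bool = False
    prior_rcseq_only: bool = False
    candidate_class: str = "somatic_candidate"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValidationError(
                f"read_count must be >= 1 (got {self.read_count}); dropouts "
                "are represented by absence of a record"
            )
        if self.junctions not in JUNCTIONS:
            raise ValidationError(f"unknown junctions value {self.junctions!r}")
        if self.candidate_class not in CANDIDATE_CLASSES:
            raise ValidationError(
                f"unknown candidate_class {self.candidate_class!r}"
            )


def _validate_bins(bins: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = ["contig", "start", "end", value_col]
    missing = [c for c in required if c not in bins.columns]
    if missing:
        raise FormatError(f"coverage bins missing column(s): {missing}")
    bins = bins.loc[:, required].reset_index(drop=True)
    if len(bins) == 0:
        return bins
    if (bins["start"] >= bins["end"]).any():
        raise ValidationError("bins must satisfy start < end")
    if (bins["start"] < 0).any():
        raise ValidationError("bin coordinates must be non-negative")
    # sort within contig, preserve first-appearance contig order
    order = {c: i for i, c in enumerate(bins["contig"].drop_duplicates())}
    bins = bins.sort_values(
        ["contig", "start"], key=lambda s: s.map(order) if s.name == "contig" else s
    ).reset_index(drop=True)
    same = bins["contig"].shift() == bins["contig"]
    if (bins["start"].shift()[same].index.size and
            (bins.loc[same, "start"] < bins["end"].shift()[same]).any()):
        raise ValidationError("bins overlap within a contig")
    return bins


@dataclass
class CoverageTrack:
    """Binned read-depth track (bedGraph-like).

    ``bins`` columns: contig, start, end, depth (non-negative float).
    """

    bins: pd.DataFrame
    bin_scheme: str = "fixed_width"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.bin_scheme not in ("fixed_width", "equal_read"):
            raise ValidationError(f"unknown bin_scheme {self.bin_scheme!r}")
        self.bins = _validate_bins(self.bins, "depth")
        if len(self.bins) and (self.bins["depth"] < 0).any():
            raise ValidationError("depth must be >= 0")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def depths(self) -> np.ndarray:
        return self.bins["depth"].to_numpy(dtype=float)


@dataclass
class Log2RatioTrack:
    """Per-bin log2 copy-number ratios relative to a reference sample."""

    bins: pd.DataFrame
    reference_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bins = _validate_bins(self.bins, "log2_ratio")
        if len(self.bins) and not np.isfinite(
            self.bins["log2_ratio"].to_numpy(dtype=float)
        ).all():
            raise ValidationError("log2 ratios must be finite after pseudocounts")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def values(self) -> np.ndarray:
        return self.bins["log2_ratio"].to_numpy(dtype=float)


@dataclass
class GoldStandardSet:
    """Per-individual set of trusted germline KNR insertions.

    ``selection_log`` holds one row per evaluated locus with boolean columns
    for each criterion and an ``included`` column, so every exclusion has at
    least one named failed criterion.
    """

    individual_id: str
    method: str  # rcseq | wgs | l1ip
    loci: frozenset  # of Locus
    selection_log: pd.DataFrame

    def __post_init__(self) -> None:
        if self.method not in ("rcseq", "wgs", "l1ip"):
            raise ValidationError(f"unknown gold-standard method {self.method!r}")
        self.loci = frozenset(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus: Locus) -> bool:
        return locus in self.loci
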