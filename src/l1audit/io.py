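"""Readers and writers for call tables, coverage tracks, loci, and config.

Call table TSV column contract (exact names, tab-separated, header row)::

    sample_id  individual_id  material  cell_type  contig  start  end
    read_count  junctions  prior_study  prior_rcseq_only  candidate_class
    score

Unknown extra columns are preserved untouched (opaque annotations).
Coverage tracks are 4-column bedGraph; locus exports are 6-column BED.
Parsers never silently drop rows: malformed rows raise with the offending
row number rather than being skipped.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .records import (
    CANDIDATE_CLASSES,
    JUNCTIONS,
    CoverageTrack,
    FormatError,
    InsertionCall,
    Locus,
    SampleRecord,
    ValidationError,
)

PathLike = Union[str, Path, _stdio.IOBase]

CALL_COLUMNS = [
    "sample_id",
    "individual_id",
    "material",
    "cell_type",
    "contig",
    "start",
    "end",
    "read_count",
    "junctions",
    "prior_study",
    "prior_rcseq_only",
    "candidate_class",
    "score",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, True: True, False: False,
}


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    def one(v):
        key = v.lower() if isinstance(v, str) else v
        if isinstance(key, (bool, np.bool_)):
            return bool(key)
        if key in _BOOL_MAP:
            return _BOOL_MAP[key]
        raise FormatError(f"column {name!r}: cannot interpret {v!r} as boolean")
    return series.map(one)


def read_call_table(path: PathLike) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a call table TSV.

    Returns ``(calls, samples)``: one row per :class:`InsertionCall` and the
    deduplicated sample metadata. Raises :class:`FormatError` for a missing
    mandatory column and :class:`ValidationError` (with the 1-based data row
    number) for an invalid read count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sample_id": str,
                                            "individual_id": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"call table missing mandatory column(s): {missing}")
    for col in ("prior_study", "prior_rcseq_only"):
        df[col] = _coerce_bool(df[col], col)
    bad = df.index[df["read_count"] < 1]
    if len(bad):
        raise ValidationError(
            f"read_count < 1 at data row {int(bad[0]) + 1}: dropouts must be "
            "absent rows, not zero counts"
        )
    if (df["start"] >= df["end"]).any():
        row = int(df.index[df["start"] >= df["end"]][0]) + 1
        raise ValidationError(f"start >= end at data row {row}")
    unknown_j = ~df["junctions"].isin(JUNCTIONS)
    if unknown_j.any():
        raise FormatError(
            f"unknown junctions value {df.loc[unknown_j, 'junctions'].iloc[0]!r}"
        )
    unknown_c = ~df["candidate_class"].isin(CANDIDATE_CLASSES)
    if unknown_c.any():
        raise FormatError(
            "unknown candidate_class "
            f"{df.loc[unknown_c, 'candidate_class'].iloc[0]!r}"
        )
    sample_cols = ["sample_id", "individual_id", "material", "cell_type"]
    if "total_reads" in df.columns:
        sample_cols.append("total_reads")
    samples = df[sample_cols].drop_duplicates("sample_id").reset_index(drop=True)
    if "total_reads" not in samples.columns:
        samples["total_reads"] = 0
    return df, samples


def write_call_table(calls: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in CALL_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    calls.loc[:, cols].to_csv(path, sep="\t", index=False)


def calls_to_records(calls: pd.DataFrame) -> list[InsertionCall]:
    """Materialize call-table rows as typed :class:`InsertionCall` records."""
    out = []
    for row in calls.itertuples(index=False):
        score = getattr(row, "score", None)
        out.append(
            InsertionCall(
                sample_id=row.sample_id,
                locus=Locus(row.contig, int(row.start), int(row.end)),
                read_count=int(row.read_count),
                junctions=row.junctions,
                prior_study=bool(row.prior_study),
                prior_rcseq_only=bool(row.prior_rcseq_only),
                candidate_class=row.candidate_class,
                score=None if score is None or pd.isna(score) else float(score),
            )
        )
    return out


def samples_to_records(samples: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=row.sample_id,
            individual_id=row.individual_id,
            material=row.material,
            cell_type=row.cell_type,
            total_reads=int(getattr(row, "total_reads", 0)),
        )
        for row in samples.itertuples(index=False)
    ]


def read_coverage_track(path: PathLike, bin_scheme: str = "fixed_width",
                        provenance: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph into a validated :class:`CoverageTrack`.

    An empty file yields an empty track. Overlapping bins or negative depths
    raise :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["contig", "start", "end", "depth"],
            dtype={"contig": str}, comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["contig", "start", "end", "depth"])
    if not provenance and isinstance(path, (str, Path)):
        provenance = str(path)
    return CoverageTrack(bins=df, bin_scheme=bin_scheme, provenance=provenance)


def write_coverage_track(track: CoverageTrack, path: PathLike) -> None:
    track.bins.to_csv(path, sep="\t", header=False, index=False)


def write_loci_bed(loci: Iterable[Locus], path: PathLike,
                   name: str = ".", score: int = 0) -> None:
    """Write loci as 6-column BED (sorted by contig then start)."""
    rows = sorted(
        ((l.contig, l.start, l.end, name, score, "+") for l in loci),
        key=lambda r: (r[0], r[1]),
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_loci_bed(path: PathLike) -> list[Locus]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    except pd.errors.EmptyDataError:
        return []
    return [Locus(r[0], int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def load_config(path: PathLike, overrides: dict | None = None) -> dict:
    """Load a declarative YAML config; flat ``overrides`` win over file values.

    Override keys use dotted paths into nested sections
    (e.g. ``{"thresholds.min_reads": 3}``).
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = yaml.safe_load(path) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    for key, value in (overrides or {}).items():
        node = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return cfg
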