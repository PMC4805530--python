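"""Sensitivity-corrected somatic insertion rates and junction statistics.

Allelic dropout during whole-genome amplification means a single cell only
exposes a fraction of the insertions it carries.  Each cell's detection
sensitivity is measured on the gold-standard germline KNR insertions of its
individual (the fraction detected at or above the read-count threshold);
the cell's surviving somatic candidate count — after thresholding and
chimera exclusion — is divided by that sensitivity to yield the corrected
per-cell rate.  Rates are averaged within cell-type groups and compared by
one-way ANOVA.

Junction detection rates summarize how often candidates are supported at
the 5' junction only, the 3' junction only, or both, in three denominators:
per call (each (sample, locus) detection counted separately), per candidate
restricted to candidates seen in exactly one cell, or per candidate with
junction evidence merged across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import GoldStandardSet, ValidationError

JUNCTION_MODES = (
    "per_call", "per_candidate_single_cell_only", "per_candidate_all",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.145 -> 0.15 at 2 dp)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CellRateEstimate:
    sample_id: str
    n_candidates_above_threshold: int
    n_chimeras_excluded: int
    sensitivity: float
    corrected_rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValidationError("sensitivity must be in (0, 1]")
        if self.corrected_rate < 0:
            raise ValidationError("corrected_rate must be >= 0")


@dataclass
class GroupRateSummary:
    group: str
    mean_rate: float
    sd_rate: float
    n_cells: int
    pct_cells_zero: float


@dataclass
class JunctionRateReport:
    mode: str
    fractions: dict  # five_prime_only / three_prime_only / both -> fraction
    denominator: int

    def __post_init__(self) -> None:
        if self.mode not in JUNCTION_MODES:
            raise ValidationError(f"unknown junction mode {self.mode!r}")
        if self.denominator > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError("junction fractions must sum to 1")


def per_cell_sensitivity(
    cell_calls: pd.DataFrame,
    individual_gold: GoldStandardSet,
    min_reads: int,
) -> float:
    """Fraction of the individual's gold KNR loci detected in this cell at
    ``read_count >= min_reads``."""
    if len(individual_gold) == 0:
        raise ValidationError(
            f"empty gold set for individual {individual_gold.individual_id!r}: "
            "cannot correct this cell"
        )
    gold_keys = {(l.contig, l.start, l.end) for l in individual_gold.loci}
    sub = cell_calls[cell_calls["read_count"] >= min_reads]
    detected = {
        k for k in zip(sub["contig"], sub["start"], sub["end"])
        if k in gold_keys
    }
    return len(detected) / len(gold_keys)


def chimera_adjust(pre_rate: float, n_candidates: int, n_chimeras: int) -> float:
    """Scale a pre-validation rate by the observed non-chimera fraction.

    ``pre_rate * (1 - n_chimeras / n_candidates)``; linear in ``pre_rate``
    and monotone decreasing in ``n_chimeras``.  Reported values are rounded
    half-up to two decimals by the summary layer, not here.
    """
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1 (fraction undefined)")
    if not 0 <= n_chimeras <= n_candidates:
        raise ValidationError("need 0 <= n_chimeras <= n_candidates")
    return pre_rate * (1.0 - n_chimeras / n_candidates)


def per_cell_corrected_rate(
    sample_id: str,
    somatic_calls: pd.DataFrame,
    chimera_call_ids: Iterable,
    min_reads: int,
    sensitivity: float,
) -> CellRateEstimate:
    """Corrected somatic insertion rate for one cell.

    ``somatic_calls`` are the cell's somatic candidate rows;
    ``chimera_call_ids`` indexes (into ``somatic_calls``) the candidates a
    chimera review excluded.  Candidates with ``read_count >= min_reads``
    are counted, classified chimeras subtracted, and the remainder divided
    by the cell's sensitivity.  A cell with zero surviving candidates has
    rate 0 regardless of sensitivity.
    """
    if sensitivity == 0:
        raise ValidationError(
            f"cell {sample_id!r} has zero sensitivity and cannot be corrected"
        )
    surviving = somatic_calls[somatic_calls["read_count"] >= min_reads]
    chimera_ids = set(chimera_call_ids)
    n_above = len(surviving)
    n_chim = sum(1 for i in surviving.index if i in chimera_ids)
    remaining = n_above - n_chim
    rate = 0.0 if remaining == 0 else remaining / sensitivity
    return CellRateEstimate(
        sample_id=sample_id,
        n_candidates_above_threshold=n_above,
        n_chimeras_excluded=n_chim,
        sensitivity=sensitivity,
        corrected_rate=rate,
    )


def cohort_rates(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    gold_sets: Mapping[str, GoldStandardSet],
    chimera_call_ids: Iterable,
    min_reads: int,
) -> list[CellRateEstimate]:
    """Corrected rates for every single cell in a cohort.

    Cells whose individual has an empty/missing gold set, or whose measured
    sensitivity is zero, are skipped (they cannot be corrected).
    """
    chimera_ids = set(chimera_call_ids)
    out: list[CellRateEstimate] = []
    cells = samples[samples["material"] == "single_cell"]
    sc = calls[calls["material"] == "single_cell"]
    by_cell = dict(tuple(sc.groupby("sample_id")))
    for row in cells.itertuples(index=False):
        gold = gold_sets.get(row.individual_id)
        if gold is None or len(gold) == 0:
            continue
        cell_calls = by_cell.get(
            row.sample_id,
            sc.iloc[0:0],
        )
        knr = cell_calls[cell_calls["candidate_class"] == "knr_call"]
        sens = per_cell_sensitivity(knr, gold, min_reads)
        if sens == 0:
            continue
        som = cell_calls[cell_calls["candidate_class"] == "somatic_candidate"]
        out.append(
            per_cell_corrected_rate(
                row.sample_id, som, chimera_ids, min_reads, sens
            )
        )
    return out


def aggregate_rates(
    estimates: Sequence[CellRateEstimate],
    groups: Mapping[str, str],
) -> tuple[list[GroupRateSummary], Optional[float]]:
    """Group means +/- SD and a one-way ANOVA p-value across groups.

    ``groups`` maps sample_id -> group label (typically the cell type).
    Every estimated cell stays in its group's denominator, including cells
    with zero surviving candidates.  The p-value is ``None`` with fewer than
    two groups of >= 2 cells.
    """
    rates_by_group: dict[str, list[float]] = {}
    for est in estimates:
        g = groups.get(est.sample_id)
        if g is None:
            raise ValidationError(f"no group for sample {est.sample_id!r}")
        rates_by_group.setdefault(g, []).append(est.corrected_rate)
    summaries = [
        GroupRateSummary(
            group=g,
            mean_rate=float(np.mean(v)),
            sd_rate=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            n_cells=len(v),
            pct_cells_zero=100.0 * sum(1 for r in v if r == 0) / len(v),
        )
        for g, v in sorted(rates_by_group.items())
    ]
    eligible = [v for v in rates_by_group.values() if len(v) >= 2]
    p_value: Optional[float] = None
    if len(eligible) >= 2:
        arrays = [np.asarray(v) for v in eligible]
        if all(np.ptp(a) == 0 for a in arrays) and \
                np.ptp(np.concatenate(arrays)) == 0:
            p_value = 1.0  # identical values in every group: F = 0
        else:
            p_value = float(stats.f_oneway(*arrays).pvalue)
    return summaries, p_value


def aggregate_rates_kruskal(
    estimates: Sequence[CellRateEstimate], groups: Mapping[str, str]
) -> Optional[float]:
    """Nonparametric alternative to the ANOVA comparison (Kruskal-Wallis)."""
    rates_by_group: dict[str, list[float]] = {}
    for est in estimates:
        rates_by_group.setdefault(groups[est.sample_id], []).append(
            est.corrected_rate
        )
    eligible = [v for v in rates_by_group.values() if len(v) >= 2]
    if len(eligible) < 2:
        return None
    return float(stats.kruskal(*eligible).pvalue)


def junction_detection_rates(
    calls: pd.DataFrame, mode: str
) -> JunctionRateReport:
    """Junction detection fractions under the requested denominator.

    ``per_call``: each (sample, locus) call counts separately.
    ``per_candidate_single_cell_only``: candidates (loci) detected in more
    than one cell are excluded entirely.
    ``per_candidate_all``: junction evidence is merged across cells — a
    candidate counts as both-junction even when the 5' and 3' detections
    came from different cells.
    """
    if mode not in JUNCTION_MODES:
        raise ValidationError(f"unknown junction mode {mode!r}")
    if calls["junctions"].isna().any():
        raise ValidationError("junctions field must be populated")

    if mode == "per_call":
        statuses = calls["junctions"]
    else:
        key_cols = ["contig", "start", "end"]
        grouped = calls.groupby(key_cols)["junctions"]
        n_cells = calls.groupby(key_cols)["sample_id"].nunique()
        if mode == "per_candidate_single_cell_only":
            merged = grouped.first()
            statuses = merged[n_cells == 1]
        else:  # per_candidate_all

            def merge(vals) -> str:
                s = set(vals)
                if "both" in s or {"five_prime_only", "three_prime_only"} <= s:
                    return "both"
                return next(iter(s))

            statuses = grouped.agg(merge)

    denom = len(statuses)
    fractions = {
        k: (float((statuses == k).sum()) / denom if denom else 0.0)
        for k in ("five_prime_only", "three_prime_only", "both")
    }
    return JunctionRateReport(mode=mode, fractions=fractions,
                              denominator=denom)
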