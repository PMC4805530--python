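"""Gold-standard germline KNR insertion selection.

Known non-reference (KNR) L1 insertions — population-polymorphic insertions
absent from the reference genome but catalogued by prior, independent L1
profiling studies — serve as the truth set against which single-cell
sensitivity and read-count signal models are calibrated.  Three
method-specific selection rules are implemented; every inequality is
inclusive exactly as written:

rcseq
    locus detected with >= ``min_bulk_reads`` (default 40) reads in *both*
    bulk samples of the individual, and identified in a prior independent
    (non RC-seq) study; calls known only from prior RC-seq work are
    excluded unless ``include_prior_rcseq_only`` is set.
wgs
    in both bulk samples (cortex and heart): >= 2 read-anchored-mate (RAM)
    reads on each side of the breakpoint, >= 4 clipped reads, a TSD or
    target-site deletion <= 50 bp without a poly-A tail (<= 250 bp with
    one), at least half of clipped reads aligned within +/- 2 bp of the
    breakpoint, and a prior-study annotation.
l1ip
    confidence score >= 0.5 in at least half (ceiling for odd counts) of
    the individual's bulk samples, plus a prior-study annotation.

Selection is a pure function of the input tables; the ``selection_log`` of
each returned set records, per evaluated locus, which criteria passed, so
every exclusion names at least one failed criterion.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd

from .records import GoldStandardSet, Locus, ValidationError

WGS_EVIDENCE_COLUMNS = [
    "ram_reads_left", "ram_reads_right", "clipped_reads",
    "clipped_reads_at_breakpoint", "tsd_or_deletion_bp", "polyA_detected",
    "prior_study",
]


def _bulk_calls_by_individual(calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    bulk = calls[calls["material"] == "bulk"]
    return {ind: grp for ind, grp in bulk.groupby("individual_id")}


def select_rcseq_gold(
    calls: pd.DataFrame,
    min_bulk_reads: int = 40,
    include_prior_rcseq_only: bool = False,
) -> dict[str, GoldStandardSet]:
    """Select the RC-seq gold standard, per individual.

    Each individual must have exactly two bulk samples; a locus is included
    iff its read count is >= ``min_bulk_reads`` in *both* bulks and it
    carries a prior-study annotation.
    """
    out: dict[str, GoldStandardSet] = {}
    for ind, bulk in _bulk_calls_by_individual(calls).items():
        bulk_ids = sorted(bulk["sample_id"].unique())
        if len(bulk_ids) != 2:
            raise ValidationError(
                f"individual {ind!r} has {len(bulk_ids)} bulk sample(s); "
                "the RC-seq rule requires exactly two"
            )
        pivot = bulk.pivot_table(
            index=["contig", "start", "end"], columns="sample_id",
            values="read_count", aggfunc="max",
        ).reindex(columns=bulk_ids)
        ann = bulk.groupby(["contig", "start", "end"])[
            ["prior_study", "prior_rcseq_only"]
        ].any()
        log_rows, loci = [], []
        for key, counts in pivot.iterrows():
            both_bulks = bool(
                counts.notna().all() and (counts >= min_bulk_reads).all()
            )
            prior = bool(ann.loc[key, "prior_study"])
            rcseq_only = bool(ann.loc[key, "prior_rcseq_only"])
            prior_ok = prior or (include_prior_rcseq_only and rcseq_only)
            included = both_bulks and prior_ok
            log_rows.append(
                {"contig": key[0], "start": key[1], "end": key[2],
                 "both_bulks_min_reads": both_bulks, "prior_ok": prior_ok,
                 "included": included}
            )
            if included:
                loci.append(Locus(key[0], int(key[1]), int(key[2])))
        out[ind] = GoldStandardSet(
            individual_id=ind, method="rcseq", loci=frozenset(loci),
            selection_log=pd.DataFrame(log_rows),
        )
    return out


def select_wgs_gold(evidence: pd.DataFrame) -> dict[str, GoldStandardSet]:
    """Select the WGS gold standard from per-bulk evidence rows.

    ``evidence`` holds one row per (individual, bulk sample, locus) with the
    columns of :data:`WGS_EVIDENCE_COLUMNS` plus ``individual_id``,
    ``sample_id``, ``contig``, ``start``, ``end``.  A locus is included iff
    all five clauses hold in *every* bulk sample of the individual.
    """
    required = ["individual_id", "sample_id", "contig", "start", "end",
                *WGS_EVIDENCE_COLUMNS]
    missing = [c for c in required if c not in evidence.columns]
    if missing:
        raise ValidationError(f"WGS evidence missing column(s): {missing}")
    if evidence[WGS_EVIDENCE_COLUMNS].isna().any().any():
        raise ValidationError("WGS evidence contains missing values")

    ev = evidence.copy()
    ev["ram_ok"] = (ev["ram_reads_left"] >= 2) & (ev["ram_reads_right"] >= 2)
    ev["clipped_ok"] = ev["clipped_reads"] >= 4
    ev["tsd_ok"] = np.where(
        ev["polyA_detected"].astype(bool),
        ev["tsd_or_deletion_bp"] <= 250,
        ev["tsd_or_deletion_bp"] <= 50,
    )
    ev["breakpoint_ok"] = (
        ev["clipped_reads_at_breakpoint"] >= ev["clipped_reads"] / 2.0
    )
    ev["prior_ok"] = ev["prior_study"].astype(bool)
    clause_cols = ["ram_ok", "clipped_ok", "tsd_ok", "breakpoint_ok",
                   "prior_ok"]

    out: dict[str, GoldStandardSet] = {}
    for ind, grp in ev.groupby("individual_id"):
        n_bulks = grp["sample_id"].nunique()
        per_locus = grp.groupby(["contig", "start", "end"]).agg(
            n_samples=("sample_id", "nunique"),
            **{c: (c, "all") for c in clause_cols},
        )
        per_locus["all_bulks_present"] = per_locus["n_samples"] == n_bulks
        per_locus["included"] = per_locus[
            clause_cols + ["all_bulks_present"]
        ].all(axis=1)
        loci = [
            Locus(c, int(s), int(e))
            for (c, s, e), inc in per_locus["included"].items() if inc
        ]
        out[ind] = GoldStandardSet(
            individual_id=ind, method="wgs", loci=frozenset(loci),
            selection_log=per_locus.reset_index(),
        )
    return out


def select_l1ip_gold(calls: pd.DataFrame) -> dict[str, GoldStandardSet]:
    """Select the L1-IP gold standard from scored bulk calls.

    A locus is included iff it was detected with score >= 0.5 in at least
    half of the individual's bulk samples (ceiling for odd counts) and
    carries a prior-study annotation.
    """
    by_ind = _bulk_calls_by_individual(calls)
    if not by_ind:
        raise ValidationError("no bulk samples in call table")
    out: dict[str, GoldStandardSet] = {}
    for ind, bulk in by_ind.items():
        if bulk["score"].isna().any():
            raise ValidationError(
                f"individual {ind!r}: L1-IP rule requires populated scores"
            )
        n_bulks = bulk["sample_id"].nunique()
        need = math.ceil(n_bulks / 2)
        grp = bulk.groupby(["contig", "start", "end"])
        log = grp.agg(
            n_scored=("score", lambda s: int((s >= 0.5).sum())),
            prior_ok=("prior_study", "any"),
        )
        log["score_ok"] = log["n_scored"] >= need
        log["included"] = log["score_ok"] & log["prior_ok"]
        loci = [
            Locus(c, int(s), int(e))
            for (c, s, e), inc in log["included"].items() if inc
        ]
        out[ind] = GoldStandardSet(
            individual_id=ind, method="l1ip", loci=frozenset(loci),
            selection_log=log.reset_index(),
        )
    return out


def gold_sets_from_truth(
    truth_prior: pd.DataFrame, include_prior_rcseq_only: bool = False
) -> dict[str, GoldStandardSet]:
    """Build gold sets directly from simulator truth (an oracle helper).

    Uses the simulator's per-locus prior-study annotations without any
    read-count evidence; useful for tests that need the idealized reference.
    """
    out = {}
    for ind, grp in truth_prior.groupby("individual_id"):
        keep = grp["prior_study"]
        if include_prior_rcseq_only:
            keep = keep | grp["prior_rcseq_only"]
        loci = [
            Locus(r.contig, int(r.start), int(r.end))
            for r in grp[keep].itertuples(index=False)
        ]
        log = grp.assign(included=keep.to_numpy())
        out[ind] = GoldStandardSet(ind, "rcseq", frozenset(loci), log)
    return out
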