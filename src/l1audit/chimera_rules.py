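"""Rule engine separating chimera artifacts from plausible true L1 insertions.

Whole-genome amplification and library PCR join unrelated DNA fragments into
chimeric molecules whose junctions mimic retrotransposition breakpoints.  A
candidate insertion contig (assembled junction sequence plus its alignment
annotations) can be screened against structural hallmarks of genuine L1
mobilization: an active source subfamily, a poly-A tail at the 3' junction, a
short target-site duplication (TSD), and a single source element explaining
both junctions.  The rules below encode those checks explicitly:

``R1``
    The candidate traces to a source element from an inactive or truncated
    L1 subfamily (e.g. the L1PA primate lineage) that cannot mobilize.
``R2``
    A 3' junction with no poly-A tail.
``R3``
    The 5' and 3' junctions trace to two distinct source elements, i.e. two
    independent chimeric molecules were merged into one "insertion".
``R4``
    The junction arises inside an L1 body or within a poly-A tract; such
    breakpoints cannot be distinguished from real ones by sequence analysis
    alone, so the verdict is *indeterminate*, never *chimera*.
``F1`` (flag)
    TSD larger than ``tsd_max`` (default 50 bp).  Flags annotate the verdict
    but never by themselves produce ``chimera``.

Subfamily activity is an input annotation: a lookup table shipped with the
package lists the human-specific L1Hs subfamily as active and L1PA2-L1PA17
as inactive.  Sequence-level ORF analysis is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import Locus, ValidationError

DEFINITE_RULES = ("R1", "R2", "R3")
TSD_MAX_DEFAULT = 50

_activity_cache: dict[str, bool] | None = None


def subfamily_activity_table() -> dict[str, bool]:
    """Load the packaged L1 subfamily activity lookup (name -> active?)."""
    global _activity_cache
    if _activity_cache is None:
        with resources.files("l1audit.data").joinpath(
            "l1_subfamily_activity.tsv"
        ).open() as fh:
            df = pd.read_csv(fh, sep="\t")
        _activity_cache = {
            str(r.subfamily): bool(r.active) for r in df.itertuples(index=False)
        }
    return _activity_cache


@dataclass(frozen=True)
class Segment:
    """One aligned segment of a candidate contig (coordinates on the contig)."""

    start: int
    end: int
    source: str  # L1_element | genomic | polyA
    subfamily: str = ""
    subfamily_active: Optional[bool] = None
    source_locus: Optional[Locus] = None

    def __post_init__(self) -> None:
        if self.source not in ("L1_element", "genomic", "polyA"):
            raise ValidationError(f"unknown segment source {self.source!r}")
        if self.start < 0 or self.start >= self.end:
            raise ValidationError("segment must satisfy 0 <= start < end")


@dataclass
class AnnotatedContig:
    """A candidate insertion contig with its structural annotations."""

    contig_id: str
    segments: Sequence[Segment]
    junction_side: str  # five_prime | three_prime | both
    tsd_bp: Optional[int] = None
    transduction_source: Optional[Locus] = None
    polyA_length: int = 0
    breakpoint_in_repeat: bool = False

    def __post_init__(self) -> None:
        if self.junction_side not in ("five_prime", "three_prime", "both"):
            raise ValidationError(
                f"unknown junction_side {self.junction_side!r}"
            )
        if self.polyA_length < 0:
            raise ValidationError("polyA_length must be >= 0")
        if self.tsd_bp is not None and self.tsd_bp < 0:
            raise ValidationError("tsd_bp must be >= 0")
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"contig {self.contig_id}: segments overlap"
                )
        self.segments = tuple(segs)

    @property
    def l1_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.source == "L1_element")

    @property
    def source_loci(self) -> tuple[Locus, ...]:
        seen: list[Locus] = []
        for s in self.l1_segments:
            if s.source_locus is not None and s.source_locus not in seen:
                seen.append(s.source_locus)
        return tuple(seen)


@dataclass
class ChimeraVerdict:
    contig_id: str
    verdict: str  # chimera | indeterminate | consistent_with_true_insertion
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict not in (
            "chimera", "indeterminate", "consistent_with_true_insertion"
        ):
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "chimera" and not any(
            r in DEFINITE_RULES for r in self.reasons
        ):
            raise ValidationError("chimera verdict requires a definite rule")
        if self.verdict != "consistent_with_true_insertion" and not self.reasons:
            raise ValidationError("non-consistent verdict requires reasons")


def _segment_active(seg: Segment, activity: dict[str, bool]) -> Optional[bool]:
    if seg.subfamily_active is not None:
        return seg.subfamily_active
    if seg.subfamily and seg.subfamily in activity:
        return activity[seg.subfamily]
    return None


def classify_candidate(
    contig: AnnotatedContig,
    tsd_max: int = TSD_MAX_DEFAULT,
    activity: dict[str, bool] | None = None,
) -> ChimeraVerdict:
    """Classify one candidate contig.

    Definite rules (R1-R3) produce ``chimera``; R4 and missing annotations
    produce ``indeterminate``; a candidate is ``consistent_with_true_insertion``
    only when it carries a poly-A tail, a TSD <= ``tsd_max``, an active
    subfamily source, and a single source element.  Flags (F1) are appended to
    ``reasons`` but never change the verdict on their own.
    """
    if activity is None:
        activity = subfamily_activity_table()

    reasons: list[str] = []
    indeterminate_reasons: list[str] = []

    activities = [_segment_active(s, activity) for s in contig.l1_segments]
    if contig.l1_segments and any(a is None for a in activities):
        indeterminate_reasons.append("unannotated")
    elif any(a is False for a in activities):
        reasons.append("R1")

    has_three_prime = contig.junction_side in ("three_prime", "both")
    if has_three_prime and contig.polyA_length == 0:
        reasons.append("R2")

    if contig.junction_side == "both" and len(contig.source_loci) > 1:
        reasons.append("R3")

    if contig.breakpoint_in_repeat:
        indeterminate_reasons.append("R4")

    flags = []
    if contig.tsd_bp is not None and contig.tsd_bp > tsd_max:
        flags.append("F1")

    if reasons:
        return ChimeraVerdict(contig.contig_id, "chimera", reasons + flags)
    if indeterminate_reasons:
        return ChimeraVerdict(
            contig.contig_id, "indeterminate", indeterminate_reasons + flags
        )

    consistent = (
        contig.polyA_length > 0
        and contig.tsd_bp is not None
        and contig.tsd_bp <= tsd_max
        and contig.l1_segments
        and all(a is True for a in activities)
        and len(contig.source_loci) <= 1
    )
    if consistent and not flags:
        return ChimeraVerdict(
            contig.contig_id, "consistent_with_true_insertion", []
        )
    return ChimeraVerdict(
        contig.contig_id, "indeterminate", flags or ["incomplete_evidence"]
    )


def tsd_size(flank_left: Locus, flank_right: Locus) -> int:
    """Implied TSD size: overlap of the two flank reference intervals.

    Two junction contigs aligning to overlapping reference intervals imply a
    target-site duplication of the overlap length; disjoint flanks imply 0.
    """
    if flank_left.contig != flank_right.contig:
        raise ValidationError(
            "flank alignments on different reference contigs: "
            f"{flank_left.contig!r} vs {flank_right.contig!r}"
        )
    return max(
        0,
        min(flank_left.end, flank_right.end)
        - max(flank_left.start, flank_right.start),
    )


def classify_all(
    contigs: Iterable[AnnotatedContig],
    tsd_max: int = TSD_MAX_DEFAULT,
    activity: dict[str, bool] | None = None,
) -> list[ChimeraVerdict]:
    return [classify_candidate(c, tsd_max, activity) for c in contigs]


def evaluate_classifier(
    contigs: Sequence[AnnotatedContig],
    truth: Sequence[str],
    tsd_max: int = TSD_MAX_DEFAULT,
) -> dict:
    """Score verdicts against ground-truth labels.

    ``truth`` holds one label per contig (``true_insertion`` or a chimera
    class name).  Returns the confusion matrix of verdict vs truth plus the
    precision of each definite rule (fraction of its firings on truly
    chimeric contigs).
    """
    if len(contigs) != len(truth):
        raise ValidationError(
            f"{len(contigs)} contigs but {len(truth)} truth labels"
        )
    verdicts = classify_all(contigs, tsd_max)
    is_chimera_truth = [t != "true_insertion" for t in truth]
    confusion = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
    rule_fired = {r: 0 for r in DEFINITE_RULES}
    rule_correct = {r: 0 for r in DEFINITE_RULES}
    table = []
    for v, t, chim in zip(verdicts, truth, is_chimera_truth):
        called = v.verdict == "chimera"
        key = ("TP" if chim else "FP") if called else ("FN" if chim else "TN")
        confusion[key] += 1
        for r in v.reasons:
            if r in DEFINITE_RULES:
                rule_fired[r] += 1
                rule_correct[r] += int(chim)
        table.append((v.contig_id, t, v.verdict, ",".join(v.reasons)))
    precision = {
        r: (rule_correct[r] / rule_fired[r]) if rule_fired[r] else float("nan")
        for r in DEFINITE_RULES
    }
    return {
        "confusion": confusion,
        "rule_precision": precision,
        "verdicts": verdicts,
        "table": pd.DataFrame(
            table, columns=["contig_id", "truth", "verdict", "reasons"]
        ),
    }
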