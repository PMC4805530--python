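"""Synthetic cohorts, coverage tracks, and candidate contigs with truth labels.

The generator emulates the statistical structure a single-cell L1 call-set
audit relies on, so every downstream stage is testable without any external
download:

* per-cell germline known-non-reference (KNR) insertion calls whose per-sample
  read counts follow a bimodal mixture (a low mode concentrated at 1-2 reads
  from amplification non-uniformity, and an overdispersed high mode) thinned
  by allelic dropout;
* rare true somatic insertions drawn per cell from a Poisson law, detected
  with KNR-like dropout and read counts (a true somatic insertion is
  molecularly indistinguishable from a heterozygous germline one);
* abundant chimeric false positives whose read counts are concentrated at
  1-2 reads;
* MDA-like vs MALBAC-like binned coverage tracks (long-range multiplicative
  waviness vs quasi-periodic ~1 kb amplification peaks and troughs);
* annotated candidate contigs with ground-truth chimera class labels.

All randomness derives from one global seed through named substreams, so
adding a stream never perturbs the draws of another and identical
config+seed yields byte-identical outputs.

Default parameter values are calibrated once to the distribution shape the
audited study type exhibits: mixture weights 2/3 low / 1/3 high, ~32% of KNR
calls at a single read and ~53% at >= 3 reads, per-cell detection
probability 0.45, ~28 chimeric candidates per cell with 97% at a single
read, a true somatic rate of 0.2 insertions per cell, and both-junction
detection rates of 11% (KNR) vs 0.04% (candidates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chimera_rules import AnnotatedContig, Segment
from .records import CoverageTrack, Locus, ValidationError

_STREAMS = {"knr": 0, "somatic": 1, "chimera": 2, "coverage": 3, "contigs": 4}

CONTIG_CLASSES = (
    "true_insertion",
    "inactive_source_chimera",
    "no_polyA_chimera",
    "split_source_chimera",
    "large_TSD_artifact",
)

_INACTIVE_SUBFAMILIES = tuple(f"L1PA{i}" for i in range(2, 18))


def stream_rng(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Derive a named, order-independent substream from the global seed."""
    if name not in _STREAMS:
        raise ValidationError(f"unknown random stream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name], extra))
    )


@dataclass(frozen=True)
class KnrMixture:
    """Two-component per-sample read-count law for detected KNR insertions.

    Low component: zero-truncated geometric with mean ``low_count_mean``
    (mass at 1-2 reads).  High component: zero-truncated negative binomial
    with mean ``high_count_mean`` and shape ``high_count_dispersion``
    (smaller shape = more overdispersed).
    """

    weight_low: float = 2.0 / 3.0
    low_count_mean: float = 1.0 / 0.45
    high_count_mean: float = 55.0
    high_count_dispersion: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_low <= 1.0:
            raise ValidationError("weight_low must be in [0, 1]")
        if self.low_count_mean < 1.0:
            raise ValidationError("low_count_mean must be >= 1 (count support)")
        if self.high_count_mean <= 0 or self.high_count_dispersion <= 0:
            raise ValidationError("high component parameters must be positive")

    @property
    def low_p(self) -> float:
        return 1.0 / self.low_count_mean


@dataclass(frozen=True)
class ChimeraCountModel:
    """Read-count law of chimeric false positives.

    Point masses at 1 and 2 reads with a geometric tail beyond: the mass at
    a single read dominates, ~99.6% of chimeras sit at <= 2 reads, and the
    residual tail decays by ``tail_decay`` per extra read.
    """

    p_one: float = 0.974
    p_two: float = 0.0235
    tail_decay: float = 7.0 / 12.0

    def __post_init__(self) -> None:
        if min(self.p_one, self.p_two) < 0 or self.p_one + self.p_two > 1:
            raise ValidationError("chimera point masses must sum to <= 1")
        if not 0.0 <= self.tail_decay < 1.0:
            raise ValidationError("tail_decay must be in [0, 1)")

    @property
    def p_tail(self) -> float:
        return 1.0 - self.p_one - self.p_two

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.random(size)
        out = np.ones(size, dtype=np.int64)
        out[u >= self.p_one] = 2
        tail = u >= self.p_one + self.p_two
        n_tail = int(tail.sum())
        if n_tail:
            out[tail] = 2 + rng.geometric(1.0 - self.tail_decay, size=n_tail)
        return out


@dataclass
class SimulationConfig:
    n_individuals: int = 3
    cells_per_individual: int = 57  # ~170 single cells cohort-wide
    knr_per_individual: int = 120
    knr_dropout_prob: float = 0.55
    knr_mixture: KnrMixture = field(default_factory=KnrMixture)
    somatic_rate_per_cell: float = 0.2
    chimera_mean_per_cell: float = 28.0
    chimera_counts: ChimeraCountModel = field(
        default_factory=ChimeraCountModel
    )
    both_junction_prob_true: float = 0.11
    both_junction_prob_chimera: float = 0.0004
    five_prime_frac_chimera: float = 0.27  # among all chimeras (5'-only share)
    prior_study_frac: float = 0.85
    prior_rcseq_only_frac: float = 0.10
    bulk_count_mean: float = 300.0
    bulk_count_dispersion: float = 5.0
    bulk_both_junction_prob: float = 0.5
    cell_types: Sequence[str] = (
        "hippocampal_neuron",
        "hippocampal_glia",
        "cortical_neuron",
        "AGS_neuron",
    )
    genome_contigs: Sequence[str] = ("chr1", "chr2", "chr3", "chr4", "chr5")
    contig_length_bp: int = 100_000_000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError(
                "SimulationConfig.seed is required: draws must be reproducible"
            )
        for name in (
            "knr_dropout_prob",
            "both_junction_prob_true", "both_junction_prob_chimera",
            "prior_study_frac", "prior_rcseq_only_frac",
            "bulk_both_junction_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.prior_study_frac + self.prior_rcseq_only_frac > 1.0:
            raise ValidationError("prior-study fractions must sum to <= 1")
        if self.somatic_rate_per_cell < 0 or self.chimera_mean_per_cell < 0:
            raise ValidationError("rates must be non-negative")
        if min(self.n_individuals, self.cells_per_individual,
               self.knr_per_individual) < 1:
            raise ValidationError("cohort dimensions must be >= 1")


@dataclass
class TruthLabels:
    """Ground truth emitted alongside a simulated call table."""

    labels: pd.Series  # aligned to call-table index: knr_true|somatic_true|chimera
    per_cell_true_somatic: pd.Series  # sample_id -> true somatic count
    knr_presence: dict  # sample_id -> frozenset of (contig, start, end)
    knr_prior: pd.DataFrame  # locus table with prior_study / prior_rcseq_only

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels})


def _zt_nbinom(rng: np.random.Generator, mean: float, shape: float,
               size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (mean/shape parameterization)."""
    p = shape / (shape + mean)
    out = rng.negative_binomial(shape, p, size=size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.negative_binomial(shape, p, size=int(zeros.sum()))


def _mixture_counts(rng: np.random.Generator, mix: KnrMixture,
                    size: int) -> np.ndarray:
    low = rng.random(size) < mix.weight_low
    counts = np.empty(size, dtype=np.int64)
    n_low = int(low.sum())
    if n_low:
        counts[low] = rng.geometric(mix.low_p, size=n_low)
    n_high = size - n_low
    if n_high:
        counts[~low] = _zt_nbinom(
            rng, mix.high_count_mean, mix.high_count_dispersion, n_high
        )
    return counts


def _junctions(rng: np.random.Generator, size: int, p_both: float,
               p_five_only: float | None = None) -> np.ndarray:
    """Sample junction status; non-both mass split 5'-only / 3'-only."""
    u = rng.random(size)
    out = np.full(size, "three_prime_only", dtype=object)
    out[u < p_both] = "both"
    if p_five_only is None:
        p_five_only = (1.0 - p_both) / 2.0
    out[(u >= p_both) & (u < p_both + p_five_only)] = "five_prime_only"
    return out


def _random_loci(rng: np.random.Generator, config: SimulationConfig,
                 n: int, width: int = 1) -> list[tuple[str, int, int]]:
    contigs = np.asarray(config.genome_contigs, dtype=object)
    idx = rng.integers(0, len(contigs), size=n)
    starts = rng.integers(0, config.contig_length_bp - width, size=n)
    return [(str(contigs[i]), int(s), int(s) + width)
            for i, s in zip(idx, starts)]


def simulate_call_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate a full cohort call table with per-call truth labels.

    Returns ``(calls, samples, truth)`` where ``calls``/``samples`` follow the
    TSV column contract of :mod:`l1audit.io` and ``truth.labels`` is aligned
    with the index of ``calls``.
    """
    rng_knr = stream_rng(config.seed, "knr")
    rng_som = stream_rng(config.seed, "somatic")
    rng_chi = stream_rng(config.seed, "chimera")
    mix = config.knr_mixture

    call_rows: list[dict] = []
    labels: list[str] = []
    sample_rows: list[dict] = []
    per_cell_somatic: dict[str, int] = {}
    knr_presence: dict[str, frozenset] = {}
    prior_rows: list[dict] = []

    for i in range(config.n_individuals):
        ind = f"ind{i + 1}"
        loci = _random_loci(rng_knr, config, config.knr_per_individual)
        u = rng_knr.random(config.knr_per_individual)
        prior_study = u < config.prior_study_frac
        prior_rcseq = (~prior_study) & (
            u < config.prior_study_frac + config.prior_rcseq_only_frac
        )
        for (c, s, e), ps, pr in zip(loci, prior_study, prior_rcseq):
            prior_rows.append(
                {"individual_id": ind, "contig": c, "start": s, "end": e,
                 "prior_study": bool(ps), "prior_rcseq_only": bool(pr)}
            )

        # two bulk samples carrying every germline KNR insertion at high depth
        for b in (1, 2):
            sid = f"{ind}_bulk{b}"
            sample_rows.append(
                {"sample_id": sid, "individual_id": ind, "material": "bulk",
                 "cell_type": "other", "total_reads": 0}
            )
            counts = _zt_nbinom(
                rng_knr, config.bulk_count_mean,
                config.bulk_count_dispersion, config.knr_per_individual,
            )
            juncs = _junctions(
                rng_knr, config.knr_per_individual,
                config.bulk_both_junction_prob,
            )
            for (c, s, e), ps, pr, rc, j in zip(
                loci, prior_study, prior_rcseq, counts, juncs
            ):
                call_rows.append(
                    {"sample_id": sid, "individual_id": ind,
                     "material": "bulk", "cell_type": "other",
                     "contig": c, "start": s, "end": e, "read_count": int(rc),
                     "junctions": j, "prior_study": bool(ps),
                     "prior_rcseq_only": bool(pr),
                     "candidate_class": "knr_call", "score": np.nan}
                )
                labels.append("knr_true")

        for j in range(config.cells_per_individual):
            sid = f"{ind}_cell{j + 1:03d}"
            ctype = config.cell_types[j % len(config.cell_types)]
            sample_rows.append(
                {"sample_id": sid, "individual_id": ind,
                 "material": "single_cell", "cell_type": ctype,
                 "total_reads": 0}
            )

            # germline KNR calls: dropout thinning then mixture counts
            detected = rng_knr.random(config.knr_per_individual) >= \
                config.knr_dropout_prob
            n_det = int(detected.sum())
            knr_presence[sid] = frozenset(
                loc for loc, d in zip(loci, detected) if d
            )
            if n_det:
                counts = _mixture_counts(rng_knr, mix, n_det)
                juncs = _junctions(
                    rng_knr, n_det, config.both_junction_prob_true
                )
                det_idx = np.flatnonzero(detected)
                for k, rc, jn in zip(det_idx, counts, juncs):
                    c, s, e = loci[k]
                    call_rows.append(
                        {"sample_id": sid, "individual_id": ind,
                         "material": "single_cell", "cell_type": ctype,
                         "contig": c, "start": s, "end": e,
                         "read_count": int(rc), "junctions": jn,
                         "prior_study": bool(prior_study[k]),
                         "prior_rcseq_only": bool(prior_rcseq[k]),
                         "candidate_class": "knr_call", "score": np.nan}
                    )
                    labels.append("knr_true")

            # true somatic insertions: Poisson per cell, KNR-like detection
            n_som = int(rng_som.poisson(config.somatic_rate_per_cell))
            per_cell_somatic[sid] = n_som
            if n_som:
                det = rng_som.random(n_som) >= config.knr_dropout_prob
                n_det = int(det.sum())
                if n_det:
                    som_loci = _random_loci(rng_som, config, n_det)
                    counts = _mixture_counts(rng_som, mix, n_det)
                    juncs = _junctions(
                        rng_som, n_det, config.both_junction_prob_true
                    )
                    for (c, s, e), rc, jn in zip(som_loci, counts, juncs):
                        call_rows.append(
                            {"sample_id": sid, "individual_id": ind,
                             "material": "single_cell", "cell_type": ctype,
                             "contig": c, "start": s, "end": e,
                             "read_count": int(rc), "junctions": jn,
                             "prior_study": False, "prior_rcseq_only": False,
                             "candidate_class": "somatic_candidate",
                             "score": np.nan}
                        )
                        labels.append("somatic_true")

            # chimeric false positives: counts concentrated at 1-2 reads
            n_chi = int(rng_chi.poisson(config.chimera_mean_per_cell))
            if n_chi:
                chi_loci = _random_loci(rng_chi, config, n_chi)
                counts = config.chimera_counts.sample(rng_chi, n_chi)
                juncs = _junctions(
                    rng_chi, n_chi, config.both_junction_prob_chimera,
                    p_five_only=config.five_prime_frac_chimera,
                )
                for (c, s, e), rc, jn in zip(chi_loci, counts, juncs):
                    call_rows.append(
                        {"sample_id": sid, "individual_id": ind,
                         "material": "single_cell", "cell_type": ctype,
                         "contig": c, "start": s, "end": e,
                         "read_count": int(rc), "junctions": jn,
                         "prior_study": False, "prior_rcseq_only": False,
                         "candidate_class": "somatic_candidate",
                         "score": np.nan}
                    )
                    labels.append("chimera")

    calls = pd.DataFrame(call_rows)
    samples = pd.DataFrame(sample_rows)
    truth = TruthLabels(
        labels=pd.Series(labels, index=calls.index, name="label"),
        per_cell_true_somatic=pd.Series(per_cell_somatic,
                                        name="true_somatic_count"),
        knr_presence=knr_presence,
        knr_prior=pd.DataFrame(prior_rows),
    )
    return calls, samples, truth


# ---------------------------------------------------------------------------
# coverage tracks

_COVERAGE_DEFAULTS = {
    "flat": {"depth": 30.0},
    "mda_like": {
        "depth": 30.0, "wave_amp": 0.5, "n_waves": 8,
        "min_period_bp": 50_000, "max_period_bp": 500_000, "white_sd": 0.05,
    },
    "malbac_like": {
        "depth": 30.0, "period_bp": 1_000, "peak_amp": 0.8,
        "phase_jitter": 0.05, "white_sd": 0.3,
    },
}


def simulate_coverage_track(
    kind: str,
    length_bp: int,
    bin_bp: int,
    params: dict | None = None,
    seed: int = 0,
    systematic_seed: int | None = None,
    contig: str = "chr1",
) -> CoverageTrack:
    """Simulate a fixed-width binned coverage track.

    ``flat``
        constant expected depth plus Poisson counting noise;
    ``mda_like``
        smooth multiplicative waviness at long wavelengths (>> 30 kb) from a
        random superposition of low-frequency sinusoids, plus Poisson noise;
    ``malbac_like``
        a quasi-periodic ~1 kb peak/trough amplification pattern (slow phase
        drift) with per-cell multiplicative white noise and Poisson noise.

    The systematic (location-dependent) component is drawn from
    ``systematic_seed`` so that several simulated cells can share the same
    peak/trough positions while their stochastic noise differs; it defaults
    to ``seed``.
    """
    if kind not in _COVERAGE_DEFAULTS:
        raise ValidationError(f"unknown coverage kind {kind!r}")
    if not (0 < bin_bp <= length_bp):
        raise ValidationError("need length_bp >= bin_bp > 0")
    p = dict(_COVERAGE_DEFAULTS[kind])
    p.update(params or {})
    if systematic_seed is None:
        systematic_seed = seed

    n_bins = length_bp // bin_bp
    x = (np.arange(n_bins, dtype=float) + 0.5) * bin_bp
    rng = stream_rng(seed, "coverage")
    rng_sys = stream_rng(systematic_seed, "coverage", extra=1)

    if kind == "flat":
        lam = np.full(n_bins, float(p["depth"]))
    elif kind == "mda_like":
        wave = np.zeros(n_bins)
        periods = rng_sys.uniform(
            p["min_period_bp"], p["max_period_bp"], size=p["n_waves"]
        )
        phases = rng_sys.uniform(0, 2 * math.pi, size=p["n_waves"])
        amps = rng_sys.uniform(0.5, 1.0, size=p["n_waves"])
        for per, ph, a in zip(periods, phases, amps):
            wave += a * np.sin(2 * math.pi * x / per + ph)
        wave *= p["wave_amp"] / math.sqrt(p["n_waves"] / 2.0)
        field = np.exp(wave - wave.var() / 2.0)
        noise = np.exp(rng.normal(0.0, p["white_sd"], n_bins)
                       - p["white_sd"] ** 2 / 2.0)
        lam = p["depth"] * field * noise
    else:  # malbac_like
        drift = np.cumsum(rng_sys.normal(0.0, p["phase_jitter"], n_bins))
        phase0 = rng_sys.uniform(0, 2 * math.pi)
        systematic = 1.0 + p["peak_amp"] * np.sin(
            2 * math.pi * x / p["period_bp"] + phase0 + drift
        )
        systematic = np.clip(systematic, 0.02, None)
        noise = np.exp(rng.normal(0.0, p["white_sd"], n_bins)
                       - p["white_sd"] ** 2 / 2.0)
        lam = p["depth"] * systematic * noise

    depth = rng.poisson(lam).astype(float)
    starts = np.arange(n_bins, dtype=np.int64) * bin_bp
    bins = pd.DataFrame(
        {"contig": contig, "start": starts, "end": starts + bin_bp,
         "depth": depth}
    )
    return CoverageTrack(bins=bins, bin_scheme="fixed_width",
                         provenance=f"simulated:{kind}:seed={seed}")


# ---------------------------------------------------------------------------
# candidate contigs

def _true_insertion_contig(rng, cid) -> AnnotatedContig:
    a = int(rng.integers(0, 10**7))
    src = Locus("chr2", a, a + 6000)
    poly = int(rng.integers(20, 41))
    return AnnotatedContig(
        contig_id=cid,
        segments=[
            Segment(0, 200, "genomic"),
            Segment(200, 1400, "L1_element", subfamily="L1Hs",
                    subfamily_active=True, source_locus=src),
            Segment(1400, 1400 + poly, "polyA"),
        ],
        junction_side="both",
        tsd_bp=int(rng.integers(5, 21)),
        transduction_source=src if rng.random() < 0.5 else None,
        polyA_length=poly,
    )


def _inactive_source_contig(rng, cid) -> AnnotatedContig:
    sub = str(rng.choice(np.asarray(_INACTIVE_SUBFAMILIES, dtype=object)))
    a = int(rng.integers(0, 10**7))
    src = Locus("chr3", a, a + 6000)
    poly = int(rng.integers(0, 30))
    side = "three_prime" if poly > 0 else "five_prime"
    return AnnotatedContig(
        contig_id=cid,
        segments=[
            Segment(0, 300, "genomic"),
            Segment(300, 1200, "L1_element", subfamily=sub,
                    subfamily_active=False, source_locus=src),
        ],
        junction_side=side,
        tsd_bp=int(rng.integers(0, 21)),
        polyA_length=poly,
    )


def _no_polya_contig(rng, cid) -> AnnotatedContig:
    a = int(rng.integers(0, 10**7))
    src = Locus("chr4", a, a + 6000)
    return AnnotatedContig(
        contig_id=cid,
        segments=[
            Segment(0, 250, "genomic"),
            Segment(250, 1100, "L1_element", subfamily="L1Hs",
                    subfamily_active=True, source_locus=src),
        ],
        junction_side="three_prime",
        tsd_bp=int(rng.integers(0, 21)),
        polyA_length=0,
    )


def _split_source_contig(rng, cid) -> AnnotatedContig:
    a = int(rng.integers(0, 10**7))
    b = int(rng.integers(2 * 10**7, 3 * 10**7))
    poly = int(rng.integers(15, 35))
    return AnnotatedContig(
        contig_id=cid,
        segments=[
            Segment(0, 200, "genomic"),
            Segment(200, 800, "L1_element", subfamily="L1Hs",
                    subfamily_active=True, source_locus=Locus("chr5", a, a + 6000)),
            Segment(800, 1500, "L1_element", subfamily="L1Hs",
                    subfamily_active=True, source_locus=Locus("chr5", b, b + 6000)),
            Segment(1500, 1500 + poly, "polyA"),
        ],
        junction_side="both",
        tsd_bp=int(rng.integers(0, 21)),
        polyA_length=poly,
    )


def _large_tsd_contig(rng, cid) -> AnnotatedContig:
    a = int(rng.integers(0, 10**7))
    src = Locus("chr2", a, a + 6000)
    poly = int(rng.integers(15, 35))
    return AnnotatedContig(
        contig_id=cid,
        segments=[
            Segment(0, 200, "genomic"),
            Segment(200, 1300, "L1_element", subfamily="L1Hs",
                    subfamily_active=True, source_locus=src),
            Segment(1300, 1300 + poly, "polyA"),
        ],
        junction_side="both",
        tsd_bp=int(rng.integers(51, 201)),
        polyA_length=poly,
    )


_CONTIG_BUILDERS = {
    "true_insertion": _true_insertion_contig,
    "inactive_source_chimera": _inactive_source_contig,
    "no_polyA_chimera": _no_polya_contig,
    "split_source_chimera": _split_source_contig,
    "large_TSD_artifact": _large_tsd_contig,
}


def simulate_candidate_contigs(
    n: int,
    class_mix: dict[str, float],
    seed: int = 0,
) -> tuple[list[AnnotatedContig], list[str]]:
    """Simulate ``n`` annotated candidate contigs plus their truth labels.

    ``class_mix`` maps class names to probabilities summing to 1.
    """
    unknown = set(class_mix) - set(CONTIG_CLASSES)
    if unknown:
        raise ValidationError(f"unknown contig class(es): {sorted(unknown)}")
    probs = np.array([class_mix.get(c, 0.0) for c in CONTIG_CLASSES])
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("class_mix probabilities must sum to 1")
    rng = stream_rng(seed, "contigs")
    classes = rng.choice(np.asarray(CONTIG_CLASSES, dtype=object), size=n,
                         p=probs)
    contigs, truth = [], []
    for i, cls in enumerate(classes):
        contigs.append(_CONTIG_BUILDERS[str(cls)](rng, f"contig{i + 1:05d}"))
        truth.append(str(cls))
    return contigs, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
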