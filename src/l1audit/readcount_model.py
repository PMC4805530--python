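"""Per-sample read-count histograms, mixture modeling, and threshold choice.

The per-sample read counts of germline KNR insertion calls in single cells
are bimodal: amplification non-uniformity pushes a low mode down to 1-2
reads while the rest of the calls sit in an overdispersed high mode.  A
two-component finite mixture (zero-truncated geometric + zero-truncated
negative binomial) is fit by EM; the high component then serves as the
signal model for true insertions.  Somatic candidate calls are audited by
(a) estimating the fraction of candidates drawn from the true high-signal
component, and (b) tabulating, per read-count threshold, the retained
fraction of gold-standard KNR calls (sensitivity) against the retained
fraction of somatic candidate calls (essentially all false positives), from
which a knee policy chooses the operating threshold.

Counting convention: histograms are per *sample* — a KNR insertion seen in
three cells contributes three calls — and dropouts (gold locus absent from a
cell) contribute nothing, since dropout affects germline and somatic
insertions alike.

A threshold printed as "> 2 reads" is stored as ``min_reads = 3``
(inclusive) throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .records import GoldStandardSet, ValidationError

POPULATIONS = (
    "knr_single_cell", "knr_bulk", "somatic_single_cell", "somatic_bulk",
)


@dataclass
class ReadCountHistogram:
    counts: dict  # read_count -> number of calls
    population: str
    unit: str = "calls"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(f"unknown population {self.population!r}")
        self.counts = {int(k): int(v) for k, v in sorted(self.counts.items())}
        if any(k < 1 or v < 0 for k, v in self.counts.items()):
            raise ValidationError("histogram keys must be >= 1, values >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.array(sorted(self.counts), dtype=np.int64)
        ms = np.array([self.counts[k] for k in ks], dtype=np.int64)
        return ks, ms

    def fraction_at_least(self, min_reads: int) -> float:
        n = self.n_total
        if n == 0:
            return float("nan")
        return sum(v for k, v in self.counts.items() if k >= min_reads) / n


def per_sample_histogram(
    calls: pd.DataFrame,
    reference_set: Optional[Mapping[str, GoldStandardSet]],
    population: str,
) -> ReadCountHistogram:
    """Build a per-sample read-count histogram for one call population.

    For ``knr_*`` populations a gold-standard reference (individual_id ->
    :class:`GoldStandardSet`) is required and only calls at gold loci are
    counted; dropouts are absent rows and thus contribute nothing.
    """
    if population not in POPULATIONS:
        raise ValidationError(f"unknown population {population!r}")
    material = "bulk" if population.endswith("_bulk") else "single_cell"
    sub = calls[calls["material"] == material]
    if population.startswith("knr"):
        if reference_set is None:
            raise ValidationError(
                f"population {population!r} requires a gold-standard reference"
            )
        keep = _calls_at_gold_loci(sub, reference_set)
        sub = sub[keep & (sub["candidate_class"] == "knr_call")]
    else:
        if reference_set is not None:
            raise ValidationError(
                "somatic populations take no gold-standard reference"
            )
        sub = sub[sub["candidate_class"] == "somatic_candidate"]
    return ReadCountHistogram(
        counts=dict(Counter(sub["read_count"].astype(int))),
        population=population,
    )


def _calls_at_gold_loci(
    calls: pd.DataFrame, gold: Mapping[str, GoldStandardSet]
) -> pd.Series:
    if len(calls) == 0:
        return pd.Series(dtype=bool)
    gold_keys = {
        (ind, l.contig, l.start, l.end)
        for ind, gs in gold.items() for l in gs.loci
    }
    keys = list(zip(calls["individual_id"], calls["contig"],
                    calls["start"], calls["end"]))
    return pd.Series([k in gold_keys for k in keys], index=calls.index)


# ---------------------------------------------------------------------------
# zero-truncated component log-pmfs

def _zt_geom_logpmf(k: np.ndarray, p: float) -> np.ndarray:
    # support {1, 2, ...}: already zero-truncated
    return stats.geom.logpmf(k, p)


def _zt_nbinom_logpmf(k: np.ndarray, mean: float, shape: float) -> np.ndarray:
    p = shape / (shape + mean)
    log_norm = np.log1p(-stats.nbinom.pmf(0, shape, p))
    return stats.nbinom.logpmf(k, shape, p) - log_norm


@dataclass
class MixtureFit:
    """Converged EM fit of the two-component read-count mixture."""

    weight_low: float
    weight_high: float
    low_params: dict  # {"p": geometric success prob}
    high_params: dict  # {"mean": ..., "shape": ...}
    loglik: float
    n_iter: int
    converged: bool
    fallback: bool = False  # degenerate data, single-component fit
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.weight_low + self.weight_high - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")

    def component_logpmf(self, k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = _zt_geom_logpmf(k, self.low_params["p"])
        hi = _zt_nbinom_logpmf(
            k, self.high_params["mean"], self.high_params["shape"]
        )
        return lo, hi


def _weighted_loglik(ks, ms, w_low, p_low, mean, shape) -> float:
    lo = np.log(max(w_low, 1e-300)) + _zt_geom_logpmf(ks, p_low)
    hi = np.log(max(1.0 - w_low, 1e-300)) + _zt_nbinom_logpmf(ks, mean, shape)
    return float(np.sum(ms * np.logaddexp(lo, hi)))


def fit_two_component_mixture(
    hist: ReadCountHistogram,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_n: int = 50,
) -> MixtureFit:
    """EM fit of the zero-truncated geometric + negative-binomial mixture.

    Initialization is deterministic: calls are moment-split at a read count
    of 3 (below -> low component, at or above -> high component).
    Convergence when the relative log-likelihood change drops below ``tol``
    or after ``max_iter`` iterations.  Degenerate data (a single distinct
    count) falls back to a flagged single-component fit.
    """
    if hist.n_total < min_n:
        raise ValidationError(
            f"need >= {min_n} calls to fit the mixture, got {hist.n_total}"
        )
    ks, ms = hist.arrays()

    if len(ks) == 1:  # all counts identical: nothing to separate
        w_low = 1.0 if ks[0] < 3 else 0.0
        p_low = 1.0 / ks[0]
        mean, shape = float(max(ks[0], 2)), 1.0
        ll = _weighted_loglik(ks, ms, max(w_low, 1e-12), p_low, mean, shape)
        return MixtureFit(w_low, 1.0 - w_low, {"p": p_low},
                          {"mean": mean, "shape": shape},
                          ll, 0, True, fallback=True)

    # deterministic moment-split init at count 3
    low_mask = ks < 3
    n_low = float(ms[low_mask].sum())
    n_high = float(ms[~low_mask].sum())
    if n_low == 0 or n_high == 0:
        # no split possible; seed a weak opposite component
        n_low = max(n_low, 1.0)
        n_high = max(n_high, 1.0)
    w_low = n_low / (n_low + n_high)
    mean_low = float(np.average(ks[low_mask], weights=ms[low_mask])) \
        if low_mask.any() and ms[low_mask].sum() else 1.2
    p_low = min(1.0, 1.0 / max(mean_low, 1.0))
    if (~low_mask).any() and ms[~low_mask].sum():
        mean_hi = float(np.average(ks[~low_mask], weights=ms[~low_mask]))
        var_hi = float(np.average((ks[~low_mask] - mean_hi) ** 2,
                                  weights=ms[~low_mask]))
    else:
        mean_hi, var_hi = 10.0, 50.0
    shape = mean_hi**2 / max(var_hi - mean_hi, mean_hi * 0.1)
    shape = float(np.clip(shape, 0.05, 100.0))
    mean = max(mean_hi, 1.5)

    trace: list[float] = []
    ll_old = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step
        log_lo = np.log(max(w_low, 1e-300)) + _zt_geom_logpmf(ks, p_low)
        log_hi = np.log(max(1.0 - w_low, 1e-300)) + \
            _zt_nbinom_logpmf(ks, mean, shape)
        denom = np.logaddexp(log_lo, log_hi)
        r_low = np.exp(log_lo - denom)  # responsibility of low component
        ll = float(np.sum(ms * denom))
        trace.append(ll)

        # M-step
        wl = float(np.sum(ms * r_low))
        wh = float(np.sum(ms * (1.0 - r_low)))
        w_low = wl / (wl + wh)
        if wl > 0:
            p_low = min(1.0, wl / float(np.sum(ms * r_low * ks)))
        if wh > 1e-12:
            w = ms * (1.0 - r_low)

            def nll(theta):
                m, s = np.exp(theta)
                return -float(np.sum(w * _zt_nbinom_logpmf(ks, m, s)))

            res = optimize.minimize(
                nll, x0=np.log([mean, shape]), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200},
            )
            cand = np.exp(res.x)
            if nll(res.x) <= nll(np.log([mean, shape])):
                mean, shape = float(cand[0]), float(cand[1])

        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll

    w_low = float(np.clip(w_low, 0.0, 1.0))

    # identifiability guard: when the data carry no second mode, a single
    # component wins by BIC and the fit collapses to the boundary weight
    n = float(ms.sum())
    mean_all = float(np.average(ks, weights=ms))
    p_single = min(1.0, 1.0 / mean_all)
    ll_geom = float(np.sum(ms * _zt_geom_logpmf(ks, p_single)))

    def nll_nb(theta):
        m, s = np.exp(theta)
        return -float(np.sum(ms * _zt_nbinom_logpmf(ks, m, s)))

    res_nb = optimize.minimize(
        nll_nb, x0=np.log([max(mean_all, 1.5), 1.0]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 300},
    )
    ll_nb = -float(res_nb.fun)
    logn = np.log(n)
    bic = {"mixture": 4 * logn - 2 * trace[-1],
           "geom": 1 * logn - 2 * ll_geom,
           "nbinom": 2 * logn - 2 * ll_nb}
    best = min(bic, key=bic.get)
    if best == "geom":
        return MixtureFit(1.0, 0.0, {"p": p_single},
                          {"mean": float(mean), "shape": float(shape)},
                          ll_geom, n_iter, converged, fallback=True,
                          loglik_trace=trace)
    if best == "nbinom":
        m_nb, s_nb = np.exp(res_nb.x)
        return MixtureFit(0.0, 1.0, {"p": float(p_low)},
                          {"mean": float(m_nb), "shape": float(s_nb)},
                          ll_nb, n_iter, converged, fallback=True,
                          loglik_trace=trace)
    return MixtureFit(
        weight_low=w_low, weight_high=1.0 - w_low,
        low_params={"p": float(p_low)},
        high_params={"mean": float(mean), "shape": float(shape)},
        loglik=trace[-1], n_iter=n_iter, converged=converged,
        loglik_trace=trace,
    )


@dataclass
class TrueFractionEstimate:
    fraction: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_calls: int


def _fit_weight_fixed_high(
    ks: np.ndarray, ms: np.ndarray, high_params: dict,
    max_iter: int = 500, tol: float = 1e-10, min_p_low: float = 0.5,
) -> tuple[float, float]:
    """EM over (weight_high, low p) with the high component frozen.

    The free low component models artifact calls and is constrained to the
    1-2-read regime (``p >= min_p_low``) so it cannot absorb the body of the
    frozen signal component.  Returns (weight_high, p_low)."""
    log_hi_pmf = _zt_nbinom_logpmf(ks, high_params["mean"],
                                   high_params["shape"])
    w_high = 0.1
    p_low = max(min_p_low,
                min(1.0, 1.0 / max(float(np.average(ks, weights=ms)), 1.0)))
    ll_old = -np.inf
    for _ in range(max_iter):
        log_lo = np.log(max(1.0 - w_high, 1e-300)) + _zt_geom_logpmf(ks, p_low)
        log_hi = np.log(max(w_high, 1e-300)) + log_hi_pmf
        denom = np.logaddexp(log_lo, log_hi)
        r_hi = np.exp(log_hi - denom)
        ll = float(np.sum(ms * denom))
        wh = float(np.sum(ms * r_hi))
        wl = float(np.sum(ms * (1.0 - r_hi)))
        w_high = wh / (wh + wl)
        if wl > 0:
            p_low = max(
                min_p_low,
                min(1.0, wl / float(np.sum(ms * (1.0 - r_hi) * ks))),
            )
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * max(abs(ll_old), 1.0):
            break
        ll_old = ll
    return float(w_high), float(p_low)


def estimate_true_fraction(
    somatic_hist: ReadCountHistogram,
    gold_fit: MixtureFit,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> TrueFractionEstimate:
    """Estimate the fraction of somatic candidates that are true insertions.

    Fits a two-component mixture to the candidate read counts with the high
    component frozen to the gold-standard KNR fit (the signal model of true
    insertions); the recovered high-component weight is the true fraction.
    A percentile bootstrap over calls gives the confidence interval
    (``n_boot = 0`` skips it).
    """
    if not gold_fit.converged:
        raise ValidationError("gold mixture fit did not converge; refusing")
    ks, ms = somatic_hist.arrays()
    if somatic_hist.n_total == 0:
        raise ValidationError("empty somatic histogram")
    frac, _ = _fit_weight_fixed_high(ks, ms, gold_fit.high_params)

    ci = (None, None)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = somatic_hist.n_total
        probs = ms / n
        boots = np.empty(n_boot)
        for b in range(n_boot):
            m_b = rng.multinomial(n, probs)
            keep = m_b > 0
            boots[b], _ = _fit_weight_fixed_high(
                ks[keep], m_b[keep], gold_fit.high_params
            )
        alpha = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(boots, alpha)),
              float(np.quantile(boots, 1.0 - alpha)))
    return TrueFractionEstimate(float(frac), ci[0], ci[1], somatic_hist.n_total)


# ---------------------------------------------------------------------------
# threshold calibration

def threshold_table(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    gold_sets: Mapping[str, GoldStandardSet],
    max_min_reads: int = 6,
) -> pd.DataFrame:
    """Sensitivity/false-positive retention per read-count threshold.

    For each ``min_reads`` in 1..``max_min_reads``:

    ``call_sensitivity``
        retained single-cell gold KNR calls / all such calls;
    ``mean_per_cell_sensitivity``
        mean over cells of (gold loci of the cell's individual detected with
        ``read_count >= min_reads``) / (gold loci of the individual);
    ``fp_retained``
        retained single-cell somatic candidate calls / all such calls.

    Cells whose individual has an empty (or missing) gold set are skipped.
    """
    sc = calls[calls["material"] == "single_cell"]
    gold_mask = _calls_at_gold_loci(sc, gold_sets)
    gold_calls = sc[gold_mask & (sc["candidate_class"] == "knr_call")]
    som_calls = sc[sc["candidate_class"] == "somatic_candidate"]
    if len(gold_calls) == 0:
        raise ValidationError("no single-cell calls at gold loci")

    cells = samples[samples["material"] == "single_cell"]
    gold_size = {ind: len(gs) for ind, gs in gold_sets.items()}
    counts_by_cell = {
        sid: grp["read_count"].to_numpy()
        for sid, grp in gold_calls.groupby("sample_id")
    }
    per_cell_detected: list[tuple[np.ndarray, int]] = []
    for row in cells.itertuples(index=False):
        size = gold_size.get(row.individual_id, 0)
        if size == 0:
            continue
        per_cell_detected.append(
            (counts_by_cell.get(row.sample_id, np.array([])), size)
        )

    gc = gold_calls["read_count"].to_numpy()
    fc = som_calls["read_count"].to_numpy()
    rows = []
    for t in range(1, max_min_reads + 1):
        call_sens = float((gc >= t).mean())
        fp = float((fc >= t).mean()) if len(fc) else 0.0
        cell_sens = [
            (cnts >= t).sum() / size for cnts, size in per_cell_detected
        ]
        rows.append(
            {"min_reads": t, "call_sensitivity": call_sens,
             "mean_per_cell_sensitivity": float(np.mean(cell_sens))
             if cell_sens else float("nan"),
             "fp_retained": fp}
        )
    return pd.DataFrame(rows)


def choose_threshold(table: pd.DataFrame, knee: float = 0.5) -> int:
    """Pick the read-count threshold by diminishing returns.

    Starting from ``min_reads = 1``, a step to the next threshold is taken
    while it still removes at least a fraction ``knee`` (default 0.5) of the
    remaining false positives *and* removes proportionally more false
    positives than the sensitivity it costs.  Ties break toward smaller
    thresholds; a table with no false positives keeps ``min_reads = 1``.
    """
    if len(table) == 0:
        raise ValidationError("empty threshold table")
    if not 0.0 < knee <= 1.0:
        raise ValidationError("knee must be in (0, 1]")
    tab = table.sort_values("min_reads").reset_index(drop=True)
    fp = tab["fp_retained"].to_numpy(dtype=float)
    sens = tab["call_sensitivity"].to_numpy(dtype=float)
    t = 0
    for i in range(len(tab) - 1):
        if fp[i] <= 0:
            break
        rel_fp = (fp[i] - fp[i + 1]) / fp[i]
        rel_sens = (sens[i] - sens[i + 1]) / sens[i] if sens[i] > 0 else 0.0
        if rel_fp < knee or rel_fp <= rel_sens:
            break
        t = i + 1
    return int(tab.loc[t, "min_reads"])
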