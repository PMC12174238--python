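"""Paired agreement statistics for pre- vs post-treatment dose metrics.

Implements the comparison layer used to judge how well a predictive
(MAA-SPECT-derived) dose metric agrees with its post-treatment
(PET-derived) counterpart across a cohort: Wilcoxon signed-rank tests,
two-way mixed-effects intraclass correlation with the conventional
poor/moderate/good/excellent bands at 0.5/0.75/0.9, Bland-Altman bias and
limits of agreement (parametric and distribution-free), and ordinary
least-squares R-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))

_EXACT_N_MAX = 25
_LOA_Z = 1.96


def icc_band(icc: float) -> str:
    """Classify an ICC estimate: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    for upper, label in ICC_BANDS:
        if icc < upper:
            return label
    return "excellent"


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y


def _signed_rank_exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    # Exact null distribution of 2*W+ by dynamic programming over the
    # (possibly mid-) ranks, doubled to land on an integer lattice.
    max_sum = int(ranks2.sum())
    pmf = np.zeros(max_sum + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: max_sum + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (the classical Wilcoxon convention) and
    tied absolute differences mid-ranked.  The null distribution is exact
    (full enumeration via dynamic programming) for up to 25 non-zero
    pairs, and a normal approximation with tie and continuity corrections
    beyond that.  Returns the smaller signed-rank sum as the statistic.
    """
    x, y = _paired(x, y)
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate pairing: all paired differences are zero")
    if n < 3:
        raise ValueError("need at least 3 non-zero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= _EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        cdf, sf = _signed_rank_exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        diff = w_plus - mean
        # continuity correction toward the mean
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return {
        "statistic": statistic,
        "p_value": p,
        "n_used": n,
        "method": method,
        "w_plus": w_plus,
        "w_minus": w_minus,
    }


def icc_two_way_mixed(x, y, definition: str = "absolute_agreement") -> dict:
    """Single-rater two-way mixed-effects ICC for two fixed raters.

    From the two-way ANOVA mean squares over ``n`` subjects and ``k = 2``
    raters (subjects MS_R, raters MS_C, residual MS_E):

    * consistency:          (MS_R - MS_E) / (MS_R + MS_E)
    * absolute agreement:   (MS_R - MS_E) / (MS_R + MS_E + 2 (MS_C - MS_E) / n)

    The p-value comes from the F test of MS_R / MS_E.  The band label uses
    the 0.5 / 0.75 / 0.9 partition.
    """
    if definition not in ("absolute_agreement", "consistency"):
        raise ValueError("definition must be 'absolute_agreement' or 'consistency'")
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([x, y])  # subjects x raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_rater = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_rater
    ms_r = ss_subj / (n - 1)
    ms_c = ss_rater / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        raise ValueError("zero variance across subjects; ICC undefined")
    if definition == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    icc = (ms_r - ms_e) / denom
    if ms_e > 0:
        f = ms_r / ms_e
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    return {"icc": float(icc), "p_value": p, "band": icc_band(float(icc)),
            "definition": definition, "n": n}


def _order_stat_ci(sorted_d: np.ndarray, q: float, conf: float = 0.95) -> tuple:
    # Distribution-free CI for the q-quantile from binomial order statistics.
    n = sorted_d.size
    alpha = 1.0 - conf
    lo_idx = int(sps.binom.ppf(alpha / 2.0, n, q))
    hi_idx = int(sps.binom.ppf(1.0 - alpha / 2.0, n, q))
    if hi_idx >= n:
        hi_idx = n - 1
    lo_idx = max(0, min(lo_idx, n - 1))
    actual = sps.binom.cdf(hi_idx, n, q) - sps.binom.cdf(lo_idx - 1, n, q)
    if actual < conf - 1e-12 and (lo_idx > 0 or hi_idx < n - 1):
        return float("nan"), float("nan")
    return float(sorted_d[lo_idx]), float(sorted_d[hi_idx])


def bland_altman(x, y, method: str = "nonparametric", conf: float = 0.95) -> dict:
    """Bland-Altman bias and limits of agreement for differences ``y - x``.

    * parametric: bias = mean difference, LoA = bias +/- 1.96 sd, with
      t-based confidence intervals (the classical construction);
    * nonparametric: bias = median difference with a distribution-free
      order-statistic CI, LoA = empirical 2.5th / 97.5th percentiles
      (linear-interpolation quantiles) with order-statistic CIs where the
      sample is large enough (NaN otherwise).
    """
    if method not in ("parametric", "nonparametric"):
        raise ValueError("method must be 'parametric' or 'nonparametric'")
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    d = y - x
    out: dict = {"method": method, "n": n}
    if method == "parametric":
        bias = float(d.mean())
        sd = float(d.std(ddof=1))
        t = float(sps.t.ppf(0.5 + conf / 2.0, n - 1))
        se_bias = sd / math.sqrt(n)
        se_loa = sd * math.sqrt(1.0 / n + _LOA_Z**2 / (2.0 * (n - 1)))
        loa_lower = bias - _LOA_Z * sd
        loa_upper = bias + _LOA_Z * sd
        out.update(
            bias=bias,
            bias_ci=(bias - t * se_bias, bias + t * se_bias),
            loa_lower=loa_lower,
            loa_upper=loa_upper,
            loa_lower_ci=(loa_lower - t * se_loa, loa_lower + t * se_loa),
            loa_upper_ci=(loa_upper - t * se_loa, loa_upper + t * se_loa),
            sd=sd,
        )
    else:
        sorted_d = np.sort(d)
        bias = float(np.median(d))
        out.update(
            bias=bias,
            bias_ci=_order_stat_ci(sorted_d, 0.5, conf),
            loa_lower=float(np.percentile(d, 2.5)),
            loa_upper=float(np.percentile(d, 97.5)),
            loa_lower_ci=_order_stat_ci(sorted_d, 0.025, conf),
            loa_upper_ci=_order_stat_ci(sorted_d, 0.975, conf),
        )
    return out


def ols_r2(x, y) -> dict:
    """Least-squares fit of ``y`` on ``x`` with ``R^2 = 1 - SSE/SST``.

    A constant response is reported as slope 0 with ``R^2 = 0`` (no
    explainable variance); a constant predictor is an error.
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    var_x = float(((x - x.mean()) ** 2).sum())
    if var_x == 0:
        raise ValueError("constant predictor: regression undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).sum()) / var_x
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    return {"slope": slope, "intercept": intercept, "r_squared": r2}


@dataclass(frozen=True)
class PairedMetric:
    """One dose metric measured by two modalities across a cohort stratum."""

    metric: str
    x: tuple  # modality A (e.g. SPECT-derived)
    y: tuple  # modality B (e.g. PET-derived)
    stratum: str = "all"

    def __post_init__(self):
        x, y = _paired(self.x, self.y)
        if x.size < 3:
            raise ValueError("paired metrics need at least 3 cases")
        object.__setattr__(self, "x", tuple(float(v) for v in x))
        object.__setattr__(self, "y", tuple(float(v) for v in y))


def agreement_report(
    pairs,
    icc_definition: str = "absolute_agreement",
    ba_method: str = "nonparametric",
    alpha: float = 0.05,
    holm: bool = False,
) -> dict:
    """Run the full agreement battery over paired metrics.

    One entry per (metric, stratum) with Wilcoxon, ICC (+ band),
    Bland-Altman and regression results.  No multiplicity adjustment is
    applied by default; ``holm=True`` adds Holm-adjusted Wilcoxon
    p-values for reuse beyond the original single-comparison reading.
    """
    entries = {}
    for pm in pairs:
        key = f"{pm.metric}|{pm.stratum}"
        if key in entries:
            raise ValueError(f"duplicate metric/stratum entry {key!r}")
        x, y = np.asarray(pm.x), np.asarray(pm.y)
        try:
            wil = wilcoxon_signed_rank(x, y)
            wil["significant"] = wil["p_value"] < alpha
        except ValueError as exc:
            wil = {"degenerate": True, "detail": str(exc)}
        entries[key] = {
            "metric": pm.metric,
            "stratum": pm.stratum,
            "n": len(pm.x),
            "wilcoxon": wil,
            "icc": icc_two_way_mixed(x, y, icc_definition),
            "bland_altman": bland_altman(x, y, ba_method),
            "regression": ols_r2(x, y),
        }
    if holm:
        keyed = [
            (k, e["wilcoxon"]["p_value"])
            for k, e in entries.items()
            if "p_value" in e["wilcoxon"]
        ]
        m = len(keyed)
        adjusted, running = {}, 0.0
        for rank, (k, p) in enumerate(sorted(keyed, key=lambda kv: kv[1])):
            running = max(running, min(1.0, (m - rank) * p))
            adjusted[k] = running
        for k, p_adj in adjusted.items():
            entries[k]["wilcoxon"]["p_holm"] = p_adj
    return {"alpha": alpha, "icc_definition": icc_definition,
            "ba_method": ba_method, "entries": entries}
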