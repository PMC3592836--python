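"""Differential expression between the hybrid and its parents.

The study design has a single library per genotype (no biological
replicates), so differential transcripts are called with a conditional
binomial test on the two fragment counts, optionally inflated to a
quasi-binomial normal approximation to absorb extra-Poisson noise.
Fold changes are reported as ln(x/H) with x the parent sample (and
ln(P1/P2) for the parental comparison), on pseudocount-adjusted FPKM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ContractViolation
from .quantify import SAMPLES, ExpressionTable

#: the three pairwise comparisons: (name, sample a, sample b)
COMPARISONS = (
    ("H_vs_P1", "H", "P1"),
    ("H_vs_P2", "H", "P2"),
    ("P1_vs_P2", "P1", "P2"),
)


def effective_library_sizes(counts: pd.DataFrame, method: str = "ratio_mode") -> pd.Series:
    """Per-sample library sizes used as totals in the DE test and FPKM.

    Composition matters here: a hybrid library with many strongly
    up-regulated transcripts carries more fragment mass than its parents at
    equal abundance elsewhere, so realized totals misstate relative depth.

    ``ratio_mode`` (default) takes, per sample, the mode (kernel density
    peak) of the log count ratios to the per-transcript geometric mean over
    transcripts expressed in every sample: unchanged transcripts form the
    largest coherent cluster of ratios, so the density peak tracks them
    even when differential expression is heavy and one-sided.
    ``median_ratio`` is the classic median-of-ratios estimator (unbiased
    when well under half the transcripts change). ``total`` uses the
    realized total mapped fragments.

    Size factors are rescaled so their mean matches the mean realized total.
    """
    totals = counts.sum(axis=0).astype(float)
    if method == "total":
        return totals
    if method not in ("median_ratio", "ratio_mode"):
        raise ConfigError(f"normalize: unknown method {method!r}")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        return totals
    logs = np.log(arr[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    if method == "median_ratio" or log_ratios.shape[0] < 50:
        log_size = np.median(log_ratios, axis=0)
    else:
        log_size = np.array([_density_peak(col) for col in log_ratios.T])
    size = np.exp(log_size)
    size = size / size.mean() * totals.mean()
    return pd.Series(size, index=counts.columns)


def _density_peak(x: np.ndarray) -> float:
    """Location of the highest kernel-density peak of a 1-D sample."""
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _quasi_p(count_a, n, p0, phi):
    """Two-sided normal p-value for a binomial proportion with variance
    inflation ``phi`` (quasi-binomial)."""
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.asarray(count_a, dtype=float) - n * p0) / np.sqrt(n * p0 * (1 - p0) * phi)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.where(n > 0, np.minimum(p, 1.0), 1.0)


def test_differential(
    count_a: int,
    total_a: float,
    count_b: int,
    total_b: float,
    overdispersion: float = 1.0,
) -> tuple[float, str]:
    """Two-sided test of equal relative abundance from one count per sample.

    Conditions on n = count_a + count_b: under the null, count_a is
    binomial with success probability total_a/(total_a+total_b). With
    ``overdispersion`` (a variance-inflation factor) above 1, the exact
    binomial is replaced by a quasi-binomial normal approximation with the
    binomial variance multiplied by that factor.

    Returns (p_value, direction) with direction in {"up_in_a", "down_in_a",
    "none"} describing sample a's relative abundance against sample b.
    """
    if total_a <= 0 or total_b <= 0:
        raise ContractViolation("library totals must be > 0")
    if count_a < 0 or count_b < 0:
        raise ContractViolation("counts must be >= 0")
    if overdispersion < 1.0:
        raise ContractViolation("overdispersion (variance inflation) must be >= 1")
    n = count_a + count_b
    p0 = total_a / (total_a + total_b)
    rel_diff = count_a / total_a - count_b / total_b
    direction = "up_in_a" if rel_diff > 0 else ("down_in_a" if rel_diff < 0 else "none")
    if n == 0:
        return 1.0, "none"
    if overdispersion == 1.0:
        p = stats.binomtest(count_a, n, p0).pvalue
    else:
        p = float(_quasi_p(count_a, n, p0, overdispersion))
    return min(float(p), 1.0), direction


def compute_fold_change(fpkm_x: float, fpkm_h: float, pseudo_fpkm: float = 0.1) -> float:
    """ln((fpkm_x + pseudo)/(fpkm_h + pseudo)); pseudo keeps zeros finite."""
    if pseudo_fpkm <= 0:
        raise ContractViolation("pseudo_fpkm must be > 0")
    if fpkm_x < 0 or fpkm_h < 0:
        raise ContractViolation("FPKM values must be >= 0")
    return float(np.log((fpkm_x + pseudo_fpkm) / (fpkm_h + pseudo_fpkm)))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, fdr >= p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractViolation("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _phi_from_dispersion(n: np.ndarray, dispersion: float) -> np.ndarray:
    """Variance-inflation factor of the conditional count split when both
    counts are negative-binomial with dispersion d (var = mu + d*mu^2).

    With gamma-Poisson counts at balanced totals the conditional law is
    beta-binomial with shape k = 1/d, whose variance inflates the binomial
    one by (n + 2k)/(1 + 2k); used as an approximation off balance.
    """
    if dispersion == 0:
        return np.ones_like(n, dtype=float)
    two_k = 2.0 / dispersion
    return np.maximum((n + two_k) / (1.0 + two_k), 1.0)


def call_de(
    expression: ExpressionTable,
    alpha: float = 0.05,
    min_abs_ln_ratio: float = 0.0,
    *,
    pseudo_fpkm: float = 0.1,
    nb_dispersion: float = 0.1,
    normalize: str = "ratio_mode",
) -> pd.DataFrame:
    """Call differential transcripts for the three pairwise comparisons.

    For each transcript and comparison: the quasi-binomial conditional test
    on the two fragment counts (per-transcript inflation derived from
    ``nb_dispersion``; exact binomial when it is 0), the ln(x/H) fold change
    on pseudocount-adjusted FPKM, and a BH FDR computed within each
    comparison separately. A call is significant iff fdr <= alpha and
    |ln_ratio| >= min_abs_ln_ratio.

    Returns a DataFrame with columns transcript_id, comparison, ln_ratio,
    p_value, fdr, significant, direction.
    """
    missing = [s for s in SAMPLES if s not in expression.counts.columns]
    if missing:
        raise ConfigError(f"expression table lacks sample(s) {missing}")
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    counts = expression.counts
    sizes = effective_library_sizes(counts, method=normalize)
    # FPKM on effective library sizes so cross-sample ratios are depth-free
    fpkm = pd.DataFrame(
        {
            s: counts[s].to_numpy()
            / ((expression.lengths.to_numpy() / 1e3) * (sizes[s] / 1e6))
            for s in SAMPLES
        },
        index=counts.index,
    )
    frames = []
    for name, a, b in COMPARISONS:
        ca = counts[a].to_numpy(dtype=float)
        cb = counts[b].to_numpy(dtype=float)
        n = ca + cb
        p0 = sizes[a] / (sizes[a] + sizes[b])
        phi = _phi_from_dispersion(n, nb_dispersion)
        if nb_dispersion == 0:
            pvals = np.array(
                [
                    stats.binomtest(int(x), int(m), p0).pvalue if m > 0 else 1.0
                    for x, m in zip(ca, n)
                ]
            )
        else:
            pvals = _quasi_p(ca, n, p0, phi)
        if name == "P1_vs_P2":
            ln_ratio = np.log((fpkm[a] + pseudo_fpkm) / (fpkm[b] + pseudo_fpkm))
            direction = np.full(len(counts), "n/a", dtype=object)
        else:
            # x = parent, so ln(x/H) with a = H, b = parent
            ln_ratio = np.log((fpkm[b] + pseudo_fpkm) / (fpkm[a] + pseudo_fpkm))
            direction = np.where(
                ln_ratio < 0, "up_in_hybrid", np.where(ln_ratio > 0, "down_in_hybrid", "n/a")
            )
        fdr = adjust_fdr(pvals)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": counts.index,
                    "comparison": name,
                    "ln_ratio": np.asarray(ln_ratio, dtype=float),
                    "p_value": pvals,
                    "fdr": fdr,
                    "significant": (fdr <= alpha) & (np.abs(ln_ratio) >= min_abs_ln_ratio),
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
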