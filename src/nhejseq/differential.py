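"""Two-condition negative-binomial differential joint-frequency testing.

This follows the classic count-based workflow for small replicate numbers:

1. per-sample size factors by the median-of-ratios rule (each sample's counts
   divided by the per-joint geometric mean, take the median over joints);
2. per-joint dispersion by method of moments on size-factor-normalised counts
   pooled within conditions (``alpha = (s^2 - mu) / mu^2``, clamped at zero),
   optionally blended with a fitted mean-dispersion trend by taking the
   maximum of the per-joint and fitted values — conservative when there are
   only two replicates per condition;
3. a conditional exact test per joint: given the total count ``k = kA + kB``,
   the p-value is the summed probability of all splits ``(a, k - a)`` at most
   as likely as the observed one, with each condition's margin negative
   binomial (mean proportional to its summed size factors, variance
   ``mu + alpha * mu^2``).  ``alpha -> 0`` degenerates to the Poisson /
   exact-binomial case;
4. Bonferroni adjustment over the number of joints tested.

Raw counts go in as-is; fractions are for display only.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from .quantify import MAJOR_THRESHOLD, joint_rows

DIRECTION_UP = "increased"
DIRECTION_DOWN = "decreased"
DIRECTION_NS = "ns"

#: numerical floor keeping the NB parameterisation away from the Poisson singularity
DISPERSION_FLOOR = 1e-8

_POISSON_CUTOFF = 1e-10  # below this, use Poisson margins outright


class DifferentialError(ValueError):
    pass


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, one per sample.

    Only joints whose count is positive in every sample (geometric mean > 0)
    contribute to the median.
    """
    counts = joint_rows(table).to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise DifferentialError("size factors require at least two samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise DifferentialError("no joint has positive counts in every sample")
    counts = counts[positive]
    log_geomean = np.log(counts).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(counts) - log_geomean, axis=0))
    return pd.Series(factors, index=joint_rows(table).columns, name="size_factor")


def _split_conditions(
    table: pd.DataFrame, condition_map: Mapping[str, str]
) -> tuple[str, str, list[str], list[str]]:
    conditions = sorted(set(condition_map.values()))
    if len(conditions) != 2:
        raise DifferentialError(f"exactly two conditions required, got {conditions}")
    cond_a, cond_b = conditions
    samples_a = [s for s in table.columns if condition_map.get(s) == cond_a]
    samples_b = [s for s in table.columns if condition_map.get(s) == cond_b]
    if not samples_a or not samples_b:
        raise DifferentialError("each condition needs at least one replicate in the table")
    return cond_a, cond_b, samples_a, samples_b


def _raw_dispersion(
    table: pd.DataFrame,
    factors: pd.Series,
    condition_map: Mapping[str, str],
) -> pd.Series:
    """Unclamped method-of-moments dispersion, ``(s^2 - mu) / mu^2`` averaged
    across conditions.  May be negative; unbiased around the true trend, which
    is what the trend fit needs."""
    _, _, samples_a, samples_b = _split_conditions(table, condition_map)
    joints = joint_rows(table)
    norm = joints / factors
    raw = np.zeros(len(joints))
    for samples in (samples_a, samples_b):
        sub = norm[samples].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        if sub.shape[1] > 1:
            var = sub.var(axis=1, ddof=1)
        else:
            var = mu.copy()  # single replicate: no variance information
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(mu > 0, (var - mu) / np.square(mu), 0.0)
        raw += contrib / 2.0
    return pd.Series(raw, index=joints.index, name="dispersion")


def estimate_dispersion(
    table: pd.DataFrame,
    factors: pd.Series,
    condition_map: Mapping[str, str],
) -> pd.Series:
    """Per-joint method-of-moments dispersion on normalised counts.

    Within each condition the normalised counts give a mean and variance;
    the raw dispersion ``(s^2 - mu) / mu^2`` is averaged across the two
    conditions and clamped at zero (replicates more regular than Poisson
    carry no overdispersion signal).
    """
    return _raw_dispersion(table, factors, condition_map).clip(lower=0.0)


def fit_dispersion_trend(
    base_mean: pd.Series,
    raw_dispersion: pd.Series,
    min_points: int = 10,
    min_mean: float = 5.0,
) -> Callable[[np.ndarray], np.ndarray] | None:
    """Fit the parametric trend ``alpha(mu) = a1 + a0 / mu``.

    Ordinary least squares on the *unclamped* per-joint moment estimates of
    joints with ``base_mean >= min_mean``.  Using unclamped values is
    essential: the moment estimator is unbiased around the true trend, so
    including its negative excursions keeps the fit centred, whereas fitting
    only the positive half (or joints with near-zero counts, whose estimates
    are pure noise) inflates the trend and with it every high-count p-value.
    Returns a vectorised predictor clipped at zero, or None when too few
    joints inform the fit (callers then fall back to per-joint values).
    """
    mask = base_mean.to_numpy() >= min_mean
    if mask.sum() < min_points:
        return None
    mu = base_mean.to_numpy()[mask]
    alpha = raw_dispersion.to_numpy()[mask]
    design = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, *_ = np.linalg.lstsq(design, alpha, rcond=None)
    a1 = max(float(coef[0]), 0.0)
    a0 = max(float(coef[1]), 0.0)

    def predict(m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        out = np.zeros_like(m)
        np.divide(a0, m, out=out, where=m > 0)
        return a1 + out

    return predict


def _margin_logpmf(counts: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    if mu <= 0:
        return np.where(counts == 0, 0.0, -np.inf)
    if alpha < _POISSON_CUTOFF:
        return poisson.logpmf(counts, mu)
    size = 1.0 / alpha
    prob = size / (size + mu)
    return nbinom.logpmf(counts, size, prob)


def nb_exact_test(
    count_a: int,
    count_b: int,
    factors_a: Sequence[float] | float,
    factors_b: Sequence[float] | float,
    dispersion: float,
) -> float:
    """Conditional exact NB test for one joint.

    ``count_a``/``count_b`` are summed counts per condition; ``factors_*`` the
    size factors of the contributing samples.  Given the total ``k``, sums the
    probabilities of every split as or less likely than the observed one,
    normalised over all splits, so p is in (0, 1].
    """
    if count_a < 0 or count_b < 0:
        raise DifferentialError("negative counts")
    s_a = float(np.sum(factors_a))
    s_b = float(np.sum(factors_b))
    k = count_a + count_b
    if k == 0:
        return 1.0
    q = k / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    splits = np.arange(k + 1)
    logp = _margin_logpmf(splits, mu_a, dispersion) + _margin_logpmf(splits[::-1], mu_b, dispersion)
    log_obs = logp[count_a]
    total = logsumexp(logp)
    extreme = logp <= log_obs + 1e-9  # tolerance guards float ties
    return float(min(1.0, np.exp(logsumexp(logp[extreme]) - total)))


def differential_table(
    table: pd.DataFrame,
    condition_map: Mapping[str, str],
    alpha: float = 0.005,
    major_threshold: float = MAJOR_THRESHOLD,
    share_mode: str = "max",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every joint for a frequency difference between two conditions.

    Returns a DataFrame indexed by joint_id with columns ``base_mean``
    (normalised mean count over all samples), ``log2_fold_change`` (second
    condition vs first, conditions ordered alphabetically),
    ``p_value``, ``p_adj`` (Bonferroni over the number of joints tested),
    ``direction`` and ``is_major``.  ``share_mode="max"`` (default) takes the
    maximum of the per-joint dispersion and the fitted mean-dispersion trend;
    ``"per_joint"`` uses the raw per-joint values only.
    """
    if share_mode not in ("max", "per_joint"):
        raise DifferentialError(f"share_mode must be 'max' or 'per_joint', got {share_mode!r}")
    cond_a, cond_b, samples_a, samples_b = _split_conditions(table, condition_map)
    joints = joint_rows(table)[samples_a + samples_b]
    if factors is None:
        factors = size_factors(joints)
    raw_disp = _raw_dispersion(joints, factors, condition_map)
    disp = raw_disp.clip(lower=0.0)

    norm = joints / factors
    base_mean = norm.mean(axis=1)
    if share_mode == "max":
        trend = fit_dispersion_trend(base_mean, raw_disp)
        if trend is not None:
            disp = pd.Series(
                np.maximum(disp.to_numpy(), trend(base_mean.to_numpy())),
                index=disp.index,
            )
    disp = disp.clip(lower=DISPERSION_FLOOR)

    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(mean_b.to_numpy() / mean_a.to_numpy())

    fa = factors[samples_a].to_numpy()
    fb = factors[samples_b].to_numpy()
    ka = joints[samples_a].sum(axis=1).to_numpy()
    kb = joints[samples_b].sum(axis=1).to_numpy()
    pvals = np.array(
        [nb_exact_test(int(a), int(b), fa, fb, float(d)) for a, b, d in zip(ka, kb, disp)]
    )
    m = len(joints)
    padj = np.minimum(1.0, pvals * m)

    frac = joints / joints.sum(axis=0)
    is_major = (frac >= major_threshold).any(axis=1)

    direction = np.where(
        padj < alpha,
        np.where(mean_b.to_numpy() > mean_a.to_numpy(), DIRECTION_UP, DIRECTION_DOWN),
        DIRECTION_NS,
    )
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": l2fc,
            "p_value": pvals,
            "p_adj": padj,
            "direction": direction,
            "is_major": is_major.to_numpy(),
        },
        index=joints.index,
    )
    out.attrs["conditions"] = (cond_a, cond_b)
    return out


def read_condition_map(path) -> dict[str, str]:
    """Read sample-to-condition assignments from a two-column TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, condition = line.split("\t")[:2]
            out[sample] = condition
    return out


def ma_plot(results: pd.DataFrame, path, alpha: float = 0.005) -> None:
    """Write an MA plot (mean vs log2 fold change, significant joints red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = results.replace([np.inf, -np.inf], np.nan).dropna(subset=["log2_fold_change"])
    sig = finite["p_adj"] < alpha
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(finite.loc[~sig, "base_mean"], finite.loc[~sig, "log2_fold_change"], s=8, c="0.5")
    ax.scatter(finite.loc[sig, "base_mean"], finite.loc[sig, "log2_fold_change"], s=10, c="red")
    ax.set_xscale("log")
    ax.set_xlabel("normalised mean count")
    ax.set_ylabel("log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
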