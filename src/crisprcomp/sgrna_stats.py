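"""Per-sgRNA statistics: normalization, fold-changes, and the
non-targeting-calibrated negative-binomial test.

The test asks, for each guide within one screen (one cell line), whether its
final-timepoint abundance is consistent with no fitness effect. The null
expectation is the guide's t0 normalized abundance; the null distribution is
a negative binomial whose quadratic mean-variance trend
``Var = mu + alpha * mu**2`` is fitted on the non-targeting controls, and the
per-screen significance cutoff is chosen so that a target fraction (default
95%) of non-targeting guides is called non-significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger("crisprcomp")

__all__ = [
    "NullModel",
    "median_ratio_normalize",
    "compute_log2fc",
    "fit_nt_null",
    "nb_tail_pvalue",
    "sgrna_pvalues",
    "calibrate_significance",
    "analyze_screens",
]

_POISSON_ALPHA = 1e-10


@dataclass
class NullModel:
    """Fitted null for one screen: dispersion trend and calibrated cutoff.

    The trend is ``Var = scale * mu + alpha * mu**2``. ``scale`` is a
    technical coefficient absorbing the Poisson-level noise of both the
    observation and its t0-derived expectation (it is ~2 for a screen with
    equally many t0 and tfinal replicates); ``alpha`` is the quadratic
    overdispersion.
    """

    alpha: float
    scale: float = 1.0
    cutoff: float | None = None
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.cutoff is not None and not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")


def median_ratio_normalize(counts: pd.DataFrame, pseudocount: float = 0.0,
                           ) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors against a geometric-mean pseudo-sample.

    ``s_j`` is the median over guides (positive in all samples) of
    ``count_ij / geomean_i``; normalized counts are ``count / s_j``. With a
    positive ``pseudocount`` the ratio uses ``count + pseudocount`` so sparse
    matrices with no all-positive guide can still be normalized.
    """
    if counts.shape[1] < 2:
        raise ValueError("median-ratio normalization needs >= 2 samples")
    mat = counts.to_numpy(dtype=float) + pseudocount
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no guide has positive counts in all samples; pass a "
            "pseudocount (e.g. pseudocount=0.5) to normalize anyway")
    sub = mat[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    size_factors = pd.Series(np.exp(np.median(ratios, axis=0)),
                             index=counts.columns, name="size_factor")
    normalized = counts / size_factors
    return size_factors, normalized


def _paired_samples(design: pd.DataFrame) -> pd.DataFrame:
    """One row per (species, individual, replicate) with its t0/tfinal ids."""
    key = ["species", "individual", "replicate"]
    wide = design.pivot_table(index=key, columns="timepoint",
                              values="sample_id", aggfunc="first")
    for tp in ("t0", "tfinal"):
        if tp not in wide.columns or wide[tp].isna().any():
            missing = (wide.index[wide[tp].isna()].tolist()
                       if tp in wide.columns else wide.index.tolist())
            raise ValueError(f"missing {tp} sample for {missing}")
    return wide.reset_index()


def compute_log2fc(normalized: pd.DataFrame, design: pd.DataFrame,
                   pseudocount: float = 0.5,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2((n_final + eps) / (n_0 + eps)) per replicate, and line averages.

    Returns (per-replicate LFC matrix with (species, individual, replicate)
    column MultiIndex, per-line replicate-averaged LFC matrix).
    """
    pairs = _paired_samples(design)
    per_rep = {}
    for _, row in pairs.iterrows():
        lfc = np.log2((normalized[row["tfinal"]] + pseudocount)
                      / (normalized[row["t0"]] + pseudocount))
        per_rep[(row["species"], row["individual"], row["replicate"])] = lfc
    rep_lfc = pd.DataFrame(per_rep)
    rep_lfc.columns.names = ["species", "individual", "replicate"]
    line_lfc = rep_lfc.T.groupby(level=["species", "individual"]).mean().T
    return rep_lfc, line_lfc


def _screen_sums(normalized: pd.DataFrame, design: pd.DataFrame,
                 individual: str) -> tuple[np.ndarray, np.ndarray]:
    """(t0-scaled expectation M, replicate-summed tfinal S) for one screen."""
    sub = design[design["individual"] == individual]
    t0 = sub.loc[sub["timepoint"] == "t0", "sample_id"]
    tf = sub.loc[sub["timepoint"] == "tfinal", "sample_id"]
    if len(tf) < 2:
        raise ValueError(
            f"screen {individual!r} has {len(tf)} tfinal replicates; "
            "at least 2 are required for mean-variance modeling")
    m = normalized[list(t0)].mean(axis=1).to_numpy() * len(tf)
    s = normalized[list(tf)].sum(axis=1).to_numpy()
    return m, s


def fit_nt_null(normalized: pd.DataFrame, design: pd.DataFrame,
                nt_mask: pd.Series, individual: str,
                min_nt: int = 50) -> NullModel:
    """Fit the quadratic dispersion trend on non-targeting guides.

    For one screen, the deviation of the replicate-summed tfinal normalized
    count ``S`` around its t0-derived expectation ``M`` is modeled as
    ``E[(S - M)^2] = M + alpha * M^2``; ``alpha`` is the nonnegative
    least-squares slope of ``(S - M)^2 - M`` on ``M^2`` across NT guides.
    Because the deviations are measured around the same t0-scaled
    expectations the downstream test uses, the fitted trend absorbs t0
    estimation noise and the test is self-calibrating.
    """
    nt = nt_mask.reindex(normalized.index).fillna(False).to_numpy(dtype=bool)
    n_nt = int(nt.sum())
    if n_nt < 2:
        raise ValueError("mean-variance modeling needs >= 2 NT guides")
    if n_nt < min_nt:
        warnings.warn(
            f"only {n_nt} non-targeting guides (< {min_nt}); the dispersion "
            "trend will be unstable", stacklevel=2)
    m, s = _screen_sums(normalized, design, individual)
    sub = design[design["individual"] == individual]
    r_final = int((sub["timepoint"] == "tfinal").sum())
    r_zero = int((sub["timepoint"] == "t0").sum())
    # Poisson-level variance of S around its t0-derived expectation M:
    # Var(S) contributes M, Var(M) contributes (r_final / r_zero) * M
    scale = 1.0 + r_final / r_zero
    m, s = m[nt], s[nt]
    ok = m > 0
    excess = (s[ok] - m[ok]) ** 2 - scale * m[ok]
    m2 = m[ok] ** 2
    alpha = float(max(0.0, (excess * m2).sum() / (m2 ** 2).sum()))
    return NullModel(alpha=alpha, scale=scale)


def nb_tail_pvalue(x, mu, alpha, side: str = "two-sided"):
    """Tail probability of NB(mean=mu, var=mu+alpha*mu^2) at observation x.

    Two-sided p is the doubled smaller tail, ``2*min(P(X<=x), P(X>=x), 0.5)``,
    with the observed point counted once in each tail. Non-integer
    observations (normalized counts) are handled through the continuous
    gamma-Poisson mixture CDF (regularized incomplete beta / gamma
    functions), which coincides with the discrete tails at integers.
    ``mu <= 0`` yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), x.shape).copy()
    scalar = x.ndim == 0
    x, mu = np.atleast_1d(x), np.atleast_1d(mu)
    bad = mu <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} guides with non-positive null mean; "
                      "reporting p = 1", stacklevel=2)
        mu[bad] = 1.0
    if alpha < _POISSON_ALPHA:
        lower = special.gammaincc(x + 1.0, mu)
        upper = np.where(x > 0, special.gammainc(np.maximum(x, 1e-12), mu), 1.0)
    else:
        r = 1.0 / alpha
        p = r / (r + mu)
        lower = special.betainc(r, x + 1.0, p)
        upper = np.where(x > 0, 1.0 - special.betainc(r, np.maximum(x, 1e-12), p),
                         1.0)
    if side == "lower":
        out = lower
    elif side == "upper":
        out = upper
    elif side == "two-sided":
        out = 2.0 * np.minimum(np.minimum(lower, upper), 0.5)
    else:
        raise ValueError(f"unknown side {side!r}")
    out = np.clip(out, np.finfo(float).tiny, 1.0)
    out[bad] = 1.0
    return float(out[0]) if scalar else out


def sgrna_pvalues(model: NullModel, normalized: pd.DataFrame,
                  design: pd.DataFrame, individual: str,
                  side: str = "two-sided") -> pd.Series:
    """Per-guide NB tail p-values for one screen under the no-effect null.

    With the fitted trend ``Var = scale * mu + alpha * mu**2``, the tail is
    evaluated on the rescaled observation ``x / scale`` against mean
    ``mu / scale``: the rescaled variable follows the plain
    ``mu + alpha * mu**2`` gamma-Poisson family with the same ``alpha``.
    """
    m, s = _screen_sums(normalized, design, individual)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = nb_tail_pvalue(s / model.scale, m / model.scale, model.alpha,
                           side=side)
    return pd.Series(p, index=normalized.index, name="p")


def calibrate_significance(pvalues: pd.Series, nt_mask: pd.Series,
                           lfc: pd.Series, target: float = 0.95,
                           ) -> tuple[float, pd.Series]:
    """Choose the largest cutoff leaving >= ``target`` of NT guides ns.

    The cutoff ``c*`` is the largest NT p-value such that the fraction of NT
    guides with ``p <= c*`` stays within ``1 - target``; guides with
    ``p <= c*`` are called 'depleted' or 'enriched' by the sign of their
    log2 fold-change, all others 'ns'.
    """
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    nt = nt_mask.reindex(pvalues.index).fillna(False)
    nt_p = np.sort(pvalues[nt].to_numpy())
    if len(nt_p) == 0:
        raise ValueError("no non-targeting p-values to calibrate on")
    k = int(np.floor(len(nt_p) * (1.0 - target)))
    if k == 0:
        cutoff = float(nt_p[0]) / 2.0
    else:
        candidate = float(nt_p[k - 1])
        # ties at the candidate may push the significant NT count above k
        while k > 0 and np.searchsorted(nt_p, candidate, side="right") > k:
            k -= 1
            candidate = float(nt_p[k - 1]) if k else float(nt_p[0]) / 2.0
        cutoff = candidate
    cutoff = min(max(cutoff, np.finfo(float).tiny), 1.0)
    sig = pvalues <= cutoff
    calls = pd.Series(
        np.where(~sig, "ns", np.where(lfc.reindex(pvalues.index) < 0,
                                      "depleted", "enriched")),
        index=pvalues.index, name="call")
    return cutoff, calls


def analyze_screens(counts: pd.DataFrame, design: pd.DataFrame,
                    library: pd.DataFrame, nt_target: float = 0.95,
                    pseudocount: float = 0.5, side: str = "two-sided",
                    ) -> tuple[pd.DataFrame, dict[str, NullModel]]:
    """Full per-sgRNA analysis of every screen (cell line) in the design.

    Returns a tidy table with one row per guide per screen (columns:
    guide_id, species, individual, lfc, p, p_calibrated, call) and the
    fitted per-screen null models. ``p`` is the raw NB tail probability;
    ``p_calibrated`` maps it through the empirical distribution of the
    non-targeting p-values of the same screen (empirical-null calibration),
    which corrects the mild asymmetric miscalibration the raw tail inherits
    from its noisy t0-derived expectation.
    """
    size_factors, normalized = median_ratio_normalize(counts)
    nt_mask = library.set_index("guide_id")["is_nt"]
    _, line_lfc = compute_log2fc(normalized, design, pseudocount=pseudocount)
    rows = []
    models: dict[str, NullModel] = {}
    for (species, individual) in design[["species", "individual"]
                                        ].drop_duplicates().itertuples(index=False):
        model = fit_nt_null(normalized, design, nt_mask, individual)
        pvals = sgrna_pvalues(model, normalized, design, individual, side=side)
        lfc = line_lfc[(species, individual)]
        cutoff, calls = calibrate_significance(pvals, nt_mask, lfc,
                                               target=nt_target)
        model.cutoff = cutoff
        model.size_factors = size_factors
        models[individual] = model
        nt_sorted = np.sort(
            pvals[nt_mask.reindex(pvals.index).fillna(False)].to_numpy())
        p_cal = (np.searchsorted(nt_sorted, pvals.to_numpy(), side="right")
                 / (len(nt_sorted) + 1.0))
        rows.append(pd.DataFrame({
            "guide_id": pvals.index,
            "species": species,
            "individual": individual,
            "lfc": lfc.to_numpy(),
            "p": pvals.to_numpy(),
            "p_calibrated": p_cal,
            "call": calls.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True), models
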