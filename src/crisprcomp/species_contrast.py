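"""Validation-screen analysis: per-sgRNA species-by-time count models,
alpha-robust rank aggregation, and the species-specific dependency caller.

Each sgRNA's counts are modeled with a log-link negative-binomial GLM whose
linear predictor has per-individual intercepts (fixed effects) and one
time effect per species; the two time effects are contrasted with a Wald
test to find sgRNAs whose fitness effect differs between species. Adjusted
sgRNA p-values are aggregated to gene level with alpha-RRA (Beta
order-statistic rho plus a permutation null), and a gene is called
species-specific when it passes the gene FDR, minimum-guide and
log2-fold-change-difference conditions and is not excluded by the
shared-effect rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .sgrna_stats import median_ratio_normalize

logger = logging.getLogger("crisprcomp")

__all__ = [
    "AlphaRRAConfig",
    "estimate_count_dispersion",
    "fit_sgrna_contrast",
    "adjust_pvalues",
    "alpha_rra",
    "call_species_specific",
    "flag_p53_dependence",
    "variance_partition",
    "run_validation_pipeline",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class AlphaRRAConfig:
    """alpha-RRA settings; ``alpha=None`` derives it from the data as the
    fraction of sgRNAs with adjusted p below ``adj_threshold``."""

    alpha: float | None = None
    adj_threshold: float = 0.01
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def estimate_count_dispersion(counts: pd.DataFrame, design: pd.DataFrame,
                              nt_mask: pd.Series) -> float:
    """Pooled quadratic dispersion of normalized counts across replicates.

    Moment estimator on non-targeting guides: within every
    (individual, timepoint) cell with >= 2 replicates, the sample variance v
    and mean m of the normalized counts satisfy E[v] = m + alpha * m^2; alpha
    is the pooled nonnegative least-squares slope.
    """
    _, norm = median_ratio_normalize(counts)
    nt = nt_mask.reindex(norm.index).fillna(False).to_numpy(dtype=bool)
    num = 0.0
    den = 0.0
    for _, grp in design.groupby(["individual", "timepoint"]):
        cols = grp["sample_id"].tolist()
        if len(cols) < 2:
            continue
        sub = norm.loc[nt, cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += (((v - m) * m**2)[ok]).sum()
        den += ((m**4)[ok]).sum()
    if den == 0:
        raise ValueError("no replicated NT observations to estimate "
                         "dispersion from")
    return float(max(0.0, num / den))


def _contrast_design(design: pd.DataFrame, columns) -> tuple[np.ndarray, int, int, list[str]]:
    """Design matrix: intercept, individual fixed effects (drop-first,
    nested labels), and one tfinal indicator per species."""
    d = design.set_index("sample_id").loc[list(columns)]
    species = sorted(d["species"].unique())
    if len(species) != 2:
        raise ValueError(f"expected 2 species, found {species}")
    for sp in species:
        if d.loc[d["species"] == sp, "individual"].nunique() < 2:
            raise ValueError(f"species {sp} has < 2 individuals")
    indivs = sorted(d["individual"].unique())
    names = ["intercept"] + [f"indiv[{i}]" for i in indivs[1:]]
    cols = [np.ones(len(d))]
    for i in indivs[1:]:
        cols.append((d["individual"] == i).to_numpy(float))
    tf = (d["timepoint"] == "tfinal").to_numpy(float)
    for sp in species:
        cols.append(tf * (d["species"] == sp).to_numpy(float))
        names.append(f"time[{sp}]")
    X = np.column_stack(cols)
    return X, len(names) - 2, len(names) - 1, names


def fit_sgrna_contrast(counts: pd.DataFrame, design: pd.DataFrame,
                       dispersion: float | None = None,
                       nt_mask: pd.Series | None = None,
                       max_iter: int = 50, tol: float = 1e-8) -> pd.DataFrame:
    """Per-sgRNA NB GLM with individual fixed effects and a species x time
    contrast.

    Returns one row per guide: the per-species time effects in log2 units
    (``lfc_time_a``/``lfc_time_b``), their difference ``delta_lfc``
    (species B minus species A), the Wald p-value for the difference, and a
    convergence flag. The NB dispersion is shared across guides: either
    given, or fitted from the non-targeting trend. All-zero guides are
    skipped; non-converged fits are flagged and reported with p = 1.
    """
    if dispersion is None:
        if nt_mask is None:
            raise ValueError("provide either a dispersion or the NT mask "
                             "to estimate it from")
        dispersion = estimate_count_dispersion(counts, design, nt_mask)
    size_factors, _ = median_ratio_normalize(counts)
    X, ia, ib, names = _contrast_design(design, counts.columns)
    offset = np.log(size_factors.to_numpy())

    Y = counts.to_numpy(dtype=float)
    nonzero = Y.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("skipping %d all-zero sgRNAs", int((~nonzero).sum()))
    Yn = Y[nonzero]
    g, n = Yn.shape
    p = X.shape[1]

    mu = Yn + 0.5
    beta = np.zeros((g, p))
    converged = np.zeros(g, dtype=bool)
    XWX = None
    for _ in range(max_iter):
        W = mu / (1.0 + dispersion * mu)
        eta = np.log(mu)
        z = (eta - offset) + (Yn - mu) / mu
        XWX = np.einsum("gn,np,nq->gpq", W, X, X)
        XWz = np.einsum("gn,np->gp", W * z, X)
        try:
            new_beta = np.linalg.solve(XWX, XWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.array([np.linalg.lstsq(a, b, rcond=None)[0]
                                 for a, b in zip(XWX, XWz)])
        step = np.abs(new_beta - beta).max(axis=1)
        converged |= step < tol
        beta = new_beta
        mu = np.exp(np.clip(beta @ X.T + offset, -30.0, 30.0))
        mu = np.maximum(mu, 1e-10)
        if converged.all():
            break

    W = mu / (1.0 + dispersion * mu)
    XWX = np.einsum("gn,np,nq->gpq", W, X, X)
    cov = np.linalg.pinv(XWX)
    c = np.zeros(p)
    c[ib], c[ia] = 1.0, -1.0
    delta = beta @ c
    var = np.einsum("p,gpq,q->g", c, cov, c)
    se = np.sqrt(np.maximum(var, 1e-300))
    se_a = np.sqrt(np.maximum(cov[:, ia, ia], 1e-300))
    se_b = np.sqrt(np.maximum(cov[:, ib, ib], 1e-300))
    pvals = 2.0 * stats.norm.sf(np.abs(delta / se))
    p_a = 2.0 * stats.norm.sf(np.abs(beta[:, ia] / se_a))
    p_b = 2.0 * stats.norm.sf(np.abs(beta[:, ib] / se_b))
    if (~converged).any():
        logger.warning("%d sgRNA fits did not converge; reporting p = 1",
                       int((~converged).sum()))
        pvals[~converged] = 1.0
        p_a[~converged] = 1.0
        p_b[~converged] = 1.0

    out = pd.DataFrame({
        "guide_id": counts.index[nonzero],
        "lfc_time_a": beta[:, ia] / _LN2,
        "lfc_time_b": beta[:, ib] / _LN2,
        "delta_lfc": delta / _LN2,
        "se": se / _LN2,
        "p": pvals,
        "p_a": p_a,
        "p_b": p_b,
        "converged": converged,
    }).set_index("guide_id")
    return out


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rho_min_beta(sorted_pct: np.ndarray, alpha: float) -> np.ndarray:
    """alpha-RRA rho: min over within-alpha order statistics of the Beta CDF.

    ``sorted_pct`` is (n_sets, m) of ascending percentile ranks; the k-th
    smallest (1-based) is scored with BetaCDF(r_(k); k, m - k + 1); ranks
    above alpha are ignored. Rows with no rank below alpha get rho = inf.
    """
    n_sets, m = sorted_pct.shape
    k = np.arange(1, m + 1, dtype=float)
    bc = special.betainc(k, m - k + 1.0, np.clip(sorted_pct, 0.0, 1.0))
    bc = np.where(sorted_pct <= alpha, bc, np.inf)
    return bc.min(axis=1)


def alpha_rra(adj_p: pd.Series, guide_to_gene: pd.Series,
              config: AlphaRRAConfig = AlphaRRAConfig()) -> pd.DataFrame:
    """Gene-level p-values/FDRs from adjusted sgRNA p-values.

    Percentile ranks are computed over *all* sgRNAs in ``adj_p`` (targeting
    and control); genes are the groups of ``guide_to_gene``. The alpha
    threshold removes non-significant sgRNAs from the assessment: guides
    ranked above alpha cannot help a gene. Gene p-values come from a
    permutation null (random guide ranks, ``n_perm`` draws shared within
    each gene-size stratum), FDRs from Benjamini-Hochberg.
    """
    pct = pd.Series(stats.rankdata(adj_p.to_numpy()) / len(adj_p),
                    index=adj_p.index)
    alpha = config.alpha
    if alpha is None:
        alpha = float((adj_p < config.adj_threshold).mean())
    genes = guide_to_gene.reindex(adj_p.index).dropna()
    gene_groups = pct.loc[genes.index].groupby(genes.to_numpy())
    gene_names = list(gene_groups.groups)

    if alpha <= 0:
        warnings.warn("alpha threshold is 0 (no sgRNA below the adjusted-p "
                      "cutoff); all gene p-values are 1", stacklevel=2)
        out = pd.DataFrame({"gene": gene_names})
        out["rho"] = np.inf
        out["n_below_alpha"] = 0
        out["p"] = 1.0
        out["fdr"] = 1.0
        return out.set_index("gene")

    pool = pct.to_numpy()
    n = len(pool)
    rng = np.random.default_rng(config.seed)

    sizes = gene_groups.size()
    rho_obs = {}
    n_below = {}
    for gene, vals in gene_groups:
        arr = np.sort(vals.to_numpy())
        rho_obs[gene] = _rho_min_beta(arr[None, :], alpha)[0]
        n_below[gene] = int((arr <= alpha).sum())

    null_sorted: dict[int, np.ndarray] = {}
    for m in sorted(sizes.unique()):
        idx = rng.integers(0, n, size=(config.n_perm, m))
        if m > 1:  # redraw rows with duplicate guides (sampling w/o replacement)
            for _ in range(20):
                dup = (np.sort(idx, axis=1)[:, 1:]
                       == np.sort(idx, axis=1)[:, :-1]).any(axis=1)
                if not dup.any():
                    break
                idx[dup] = rng.integers(0, n, size=(int(dup.sum()), m))
        draws = np.sort(pool[idx], axis=1)
        null_sorted[m] = np.sort(_rho_min_beta(draws, alpha))

    rows = []
    for gene in gene_names:
        m = int(sizes[gene])
        null = null_sorted[m]
        count = np.searchsorted(null, rho_obs[gene], side="right")
        rows.append((gene, rho_obs[gene], n_below[gene],
                     (1.0 + count) / (config.n_perm + 1.0)))
    out = pd.DataFrame(rows, columns=["gene", "rho", "n_below_alpha", "p"]
                       ).set_index("gene")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def species_different_sgrnas(contrast: pd.DataFrame,
                             max_adj_p: float = 0.01,
                             min_abs_delta: float = 0.5) -> pd.Index:
    """sgRNAs with evidence for a species difference: adjusted p below
    ``max_adj_p`` and |delta log2FC| at least ``min_abs_delta``."""
    if "adj_p" not in contrast.columns:
        contrast = contrast.assign(adj_p=adjust_pvalues(contrast["p"]))
    keep = (contrast["adj_p"] < max_adj_p) \
        & (contrast["delta_lfc"].abs() >= min_abs_delta)
    return contrast.index[keep]


def gene_topk_lfc(lfc: pd.Series, guide_to_gene: pd.Series,
                  k: int = 4) -> pd.Series:
    """Gene log2FC as the mean of the k sgRNAs with largest |LFC|."""
    from .gene_scoring import gene_score
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gene_score(lfc, guide_to_gene, mode="top-k", k=k)


def call_species_specific(rra_contrast: pd.DataFrame, rra_a: pd.DataFrame,
                          rra_b: pd.DataFrame, gene_lfc_a: pd.Series,
                          gene_lfc_b: pd.Series, fdr_threshold: float = 0.01,
                          min_guides_below_alpha: int = 3,
                          min_lfc_diff: float = 0.75) -> pd.DataFrame:
    """Final caller: the three printed conditions plus the shared-effect
    exclusion.

    A gene is called species-specific iff its contrast-term FDR is below
    ``fdr_threshold``, at least ``min_guides_below_alpha`` of its sgRNAs pass
    the alpha threshold, its per-species gene log2FC difference is at least
    ``min_lfc_diff`` in magnitude, and it is not excluded as a shared
    effect. The exclusion threshold is the highest contrast-term FDR among
    genes with at least one sgRNA passing alpha; genes whose FDR in *both*
    species terms falls below that threshold are discarded as shared. The
    direction of a call follows which species shows the stronger depletion
    or enrichment.
    """
    genes = rra_contrast.index
    passing = rra_contrast["n_below_alpha"] >= 1
    exclusion_threshold = (float(rra_contrast.loc[passing, "fdr"].max())
                           if passing.any() else 0.0)
    fdr_a = rra_a["fdr"].reindex(genes).fillna(1.0)
    fdr_b = rra_b["fdr"].reindex(genes).fillna(1.0)
    shared = (fdr_a < exclusion_threshold) & (fdr_b < exclusion_threshold)

    lfc_a = gene_lfc_a.reindex(genes)
    lfc_b = gene_lfc_b.reindex(genes)
    diff = lfc_b - lfc_a
    called = ((rra_contrast["fdr"] < fdr_threshold)
              & (rra_contrast["n_below_alpha"] >= min_guides_below_alpha)
              & (diff.abs() >= min_lfc_diff)
              & ~shared)
    direction = np.where(lfc_a.abs() >= lfc_b.abs(),
                         "speciesA-specific", "speciesB-specific")
    out = pd.DataFrame({
        "fdr_contrast": rra_contrast["fdr"],
        "n_below_alpha": rra_contrast["n_below_alpha"],
        "fdr_a": fdr_a,
        "fdr_b": fdr_b,
        "gene_lfc_a": lfc_a,
        "gene_lfc_b": lfc_b,
        "lfc_diff": diff,
        "excluded_shared": shared,
        "call": np.where(called, direction, "none"),
    }, index=genes)
    out.attrs["exclusion_threshold"] = exclusion_threshold
    return out


def flag_p53_dependence(gene_scores: pd.DataFrame,
                        responsive_lines: list[str],
                        unresponsive_lines: list[str],
                        threshold: float = 0.05) -> pd.DataFrame:
    """Welch two-tailed t-test per gene: unresponsive vs responsive lines.

    ``gene_scores`` is genes x lines. The flag (at the exploratory
    ``threshold``) marks genes whose score differs with p53 responsiveness;
    degenerate (constant) genes are reported with p = 1 and flagged
    ``undefined``.
    """
    for name, group in (("responsive", responsive_lines),
                        ("unresponsive", unresponsive_lines)):
        if len(group) < 2:
            raise ValueError(f"{name} group has {len(group)} lines; "
                             "need >= 2 for a t-test")
    a = gene_scores[unresponsive_lines].to_numpy(dtype=float)
    b = gene_scores[responsive_lines].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    undefined = ~np.isfinite(p)
    p[undefined] = 1.0
    return pd.DataFrame({
        "t": np.where(undefined, np.nan, res.statistic),
        "p": p,
        "undefined": undefined,
        "p53_flagged": (p < threshold) & ~undefined,
    }, index=gene_scores.index)


_VP_COMPONENTS = ["species", "individual", "timepoint", "residual"]


def variance_partition(values: pd.DataFrame, design: pd.DataFrame,
                       guide_to_gene: pd.Series | None = None):
    """Variance fractions per sgRNA for species / individual / timepoint.

    The categorical factors are treated as random intercepts (individual
    nested in species) and their components are estimated per sgRNA with a
    method-of-moments estimator: for every pair of samples,
    ``E[(y_i - y_j)^2] / 2`` equals the residual variance plus the variance
    of each effect the pair does not share; the per-category mean squared
    half-differences are solved for the components by least squares,
    components are truncated at zero and reported as fractions summing to 1.
    Gene-level values are the means over each gene's sgRNAs.
    """
    d = design.set_index("sample_id").loc[list(values.columns)]
    for factor in ("species", "individual", "timepoint"):
        if d[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has < 2 levels")
    sp = d["species"].to_numpy()
    ind = d["individual"].to_numpy()
    tp = d["timepoint"].to_numpy()
    n = len(d)
    ii, jj = np.triu_indices(n, k=1)
    same_s = (sp[ii] == sp[jj])
    same_i = (ind[ii] == ind[jj])
    same_t = (tp[ii] == tp[jj])

    cats = np.stack([~same_s, ~same_i, ~same_t], axis=1).astype(float)
    keys = [tuple(row) for row in cats.astype(int)]
    uniq = sorted(set(keys))
    A = np.array([[*k, 1.0] for k in uniq])
    if np.linalg.matrix_rank(A) < 4:
        aliased = []
        for f1 in range(3):
            for f2 in range(f1 + 1, 3):
                if np.array_equal(cats[:, f1], cats[:, f2]):
                    aliased.append((_VP_COMPONENTS[f1], _VP_COMPONENTS[f2]))
        raise ValueError(f"confounded design; aliased factors: {aliased or A}")

    Y = values.to_numpy(dtype=float)
    half_sq = 0.5 * (Y[:, ii] - Y[:, jj]) ** 2
    key_idx = np.array([uniq.index(k) for k in keys])
    b = np.zeros((len(uniq), Y.shape[0]))
    w = np.zeros(len(uniq))
    for u in range(len(uniq)):
        mask = key_idx == u
        w[u] = mask.sum()
        b[u] = half_sq[:, mask].mean(axis=1)
    sw = np.sqrt(w)[:, None]
    comps, *_ = np.linalg.lstsq(A * sw, b * sw, rcond=None)
    comps = np.maximum(comps, 0.0)  # truncate negative variance components
    total = comps.sum(axis=0)
    total[total == 0] = np.nan
    fracs = pd.DataFrame((comps / total).T, index=values.index,
                         columns=_VP_COMPONENTS)
    if guide_to_gene is None:
        return fracs
    genes = guide_to_gene.reindex(fracs.index)
    gene_means = fracs.groupby(genes.to_numpy()).mean()
    return fracs, gene_means


def run_validation_pipeline(counts: pd.DataFrame, design: pd.DataFrame,
                            library: pd.DataFrame,
                            rra_config: AlphaRRAConfig = AlphaRRAConfig(),
                            fdr_threshold: float = 0.01,
                            min_guides_below_alpha: int = 3,
                            min_lfc_diff: float = 0.75) -> dict:
    """End-to-end validation analysis.

    Fits the per-sgRNA species x time model, BH-adjusts the contrast and
    per-species-term p-values, aggregates each with alpha-RRA, computes
    per-species top-4 gene log2FCs, and applies the final three-condition
    caller with the shared-effect exclusion. Returns a dict with the sgRNA
    table, the three alpha-RRA tables and the gene-level call table.
    """
    nt_mask = library.set_index("guide_id")["is_nt"]
    res = fit_sgrna_contrast(counts, design, nt_mask=nt_mask)
    res["adj_p"] = adjust_pvalues(res["p"].to_numpy())
    for term in ("a", "b"):
        res[f"adj_p_{term}"] = adjust_pvalues(res[f"p_{term}"].to_numpy())

    targeting = library[~library["is_nt"]]
    guide_to_gene = targeting.set_index("guide_id")["gene"]

    rra_contrast = alpha_rra(res["adj_p"], guide_to_gene, rra_config)
    rra_a = alpha_rra(res["adj_p_a"], guide_to_gene, rra_config)
    rra_b = alpha_rra(res["adj_p_b"], guide_to_gene, rra_config)

    lfc_a = gene_topk_lfc(res["lfc_time_a"], guide_to_gene, k=4)
    lfc_b = gene_topk_lfc(res["lfc_time_b"], guide_to_gene, k=4)
    calls = call_species_specific(
        rra_contrast, rra_a, rra_b, lfc_a, lfc_b,
        fdr_threshold=fdr_threshold,
        min_guides_below_alpha=min_guides_below_alpha,
        min_lfc_diff=min_lfc_diff)
    return {"sgrna": res, "rra_contrast": rra_contrast, "rra_a": rra_a,
            "rra_b": rra_b, "calls": calls}
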