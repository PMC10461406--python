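"""Gene-level scores, bootstrap FDRs, direction scores, essentiality classes
and candidate-set selection for the genome-wide screens.

A gene score is the average log2 fold-change of its retained guides (guides
passing the perfect-match and per-guide significance filters), or in top-k
mode the mean of the k guides with the largest |LFC| (k=3 is the genome-wide
convention, k=4 the validation convention). Significance comes from a
bootstrap null built from non-targeting guides: control pseudo-genes are
groups of 1-5 random NT guides, matched by default to the gene's retained
guide count so the variance of the mean is preserved.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crisprcomp")

__all__ = [
    "gene_score",
    "bootstrap_gene_fdr",
    "direction_scores",
    "classify_essentiality",
    "intersection_sets",
    "candidate_selection",
    "CANDIDATE_SET_NAMES",
]


def gene_score(lfc: pd.Series, guide_to_gene: pd.Series,
               mode: str = "retained-mean", retained: pd.Series | None = None,
               k: int = 3) -> pd.Series:
    """Per-gene score from per-guide log2 fold-changes.

    'retained-mean': mean LFC over guides flagged in ``retained`` (genes with
    none retained score NaN). 'top-k': mean of the ``k`` guides with largest
    |LFC| (ties broken by guide id); genes with fewer than ``k`` guides use
    all of them with a warning.
    """
    genes = guide_to_gene.reindex(lfc.index)
    df = pd.DataFrame({"lfc": lfc, "gene": genes}).dropna(subset=["gene"])
    if mode == "retained-mean":
        if retained is None:
            raise ValueError("retained-mean mode requires the retained mask")
        kept = df[retained.reindex(df.index).fillna(False)]
        scores = kept.groupby("gene")["lfc"].mean()
        return scores.reindex(df["gene"].unique()).rename("score")
    if mode == "top-k":
        df = df.assign(abs_lfc=df["lfc"].abs())
        df = df.sort_values(["gene", "abs_lfc"],
                            ascending=[True, False], kind="mergesort")
        short = df.groupby("gene").size()
        if (short < k).any():
            warnings.warn(
                f"{int((short < k).sum())} genes have fewer than k={k} "
                "guides; using all available", stacklevel=2)
        top = df.groupby("gene", group_keys=False).head(k)
        return top.groupby("gene")["lfc"].mean().rename("score")
    raise ValueError(f"unknown mode {mode!r}")


def bootstrap_gene_fdr(lfc: pd.Series, retained: pd.Series,
                       guide_to_gene: pd.Series, nt_lfc: pd.Series,
                       n_boot: int = 10_000, seed: int = 0,
                       match_group_size: bool = True,
                       with_replacement: bool = True) -> pd.DataFrame:
    """Empirical gene p-values against means of random NT guide groups.

    For each gene with ``m`` retained guides, the null score distribution is
    built from ``n_boot`` means of ``m`` NT log2 fold-changes (groups of 1-5
    NT guides standing in for control genes). Two-sided empirical
    ``p = (1 + #{|null| >= |observed|}) / (n_boot + 1)``; FDR is
    Benjamini-Hochberg across genes. Genes with no retained guide are
    excluded. With ``match_group_size=False`` the group size is drawn
    uniformly from 1-5 instead of matched to ``m``.
    """
    pool = nt_lfc.dropna().to_numpy()
    if len(pool) < 50:
        warnings.warn(f"NT pool has only {len(pool)} guides", stacklevel=2)
    genes = guide_to_gene.reindex(lfc.index)
    kept = pd.DataFrame({"lfc": lfc, "gene": genes})[
        retained.reindex(lfc.index).fillna(False).to_numpy(dtype=bool)]
    obs = kept.groupby("gene")["lfc"].agg(["mean", "size"])
    obs.columns = ["score", "m"]
    rng = np.random.default_rng(seed)

    null_by_m: dict[int, np.ndarray] = {}
    sizes = sorted(obs["m"].clip(upper=5).unique())
    for m in sizes:
        group = m if match_group_size else None
        if group is None:
            ms = rng.integers(1, 6, size=n_boot)
            draws = np.array([
                _nt_group_mean(rng, pool, g, with_replacement) for g in ms])
        elif with_replacement:
            draws = rng.choice(pool, size=(n_boot, m), replace=True).mean(axis=1)
        else:
            draws = np.array([
                rng.choice(pool, size=m, replace=False).mean()
                for _ in range(n_boot)])
        null_by_m[m] = np.sort(np.abs(draws))

    pvals = np.empty(len(obs))
    for i, (score, m) in enumerate(zip(obs["score"], obs["m"].clip(upper=5))):
        null = null_by_m[m]
        exceed = len(null) - np.searchsorted(null, abs(score), side="left")
        pvals[i] = (1.0 + exceed) / (n_boot + 1.0)
    out = obs.copy()
    out["p"] = pvals
    out["fdr"] = multipletests(pvals, method="fdr_bh")[1]
    return out.reset_index().rename(columns={"index": "gene"})


def _nt_group_mean(rng, pool, m, with_replacement):
    return rng.choice(pool, size=m, replace=with_replacement).mean()


def direction_scores(stat_table: pd.DataFrame, guide_to_gene: pd.Series,
                     ) -> pd.DataFrame:
    """Per-gene per-screen (# depleted guides) - (# enriched guides).

    ``stat_table`` is the tidy per-sgRNA table from
    :func:`crisprcomp.sgrna_stats.analyze_screens` (columns guide_id,
    species, individual, call). Returns genes x screens; species-level
    scores are the row sums over that species' screens.
    """
    df = stat_table.copy()
    df["gene"] = guide_to_gene.reindex(df["guide_id"]).to_numpy()
    df = df.dropna(subset=["gene"])
    signed = df["call"].map({"depleted": 1, "enriched": -1, "ns": 0})
    df = df.assign(signed=signed)
    table = df.pivot_table(index="gene", columns="individual",
                           values="signed", aggfunc="sum", fill_value=0)
    return table.astype(int)


def classify_essentiality(scores: pd.Series, top_n: int = 3000,
                          essential_max_score: float = -2.0,
                          nonessential_min_score: float = -1.0) -> pd.Series:
    """Essential / nonessential / intermediate classes for one screen.

    Essential: among the ``top_n`` most depleted genes *and* depleted more
    than 4-fold (score <= -2). Nonessential: depleted less than 2-fold
    (score > -1). Everything else is intermediate. Ties at the rank boundary
    are all included.
    """
    s = scores.dropna()
    if top_n > len(s):
        warnings.warn(f"top_n={top_n} exceeds {len(s)} scored genes; "
                      "using all", stacklevel=2)
        top_n = len(s)
    boundary = np.sort(s.to_numpy())[top_n - 1] if top_n else -np.inf
    essential = (s <= boundary) & (s <= essential_max_score)
    nonessential = s > nonessential_min_score
    out = pd.Series("intermediate", index=s.index, name="class")
    out[essential] = "essential"
    out[nonessential & ~essential] = "nonessential"
    return out.reindex(scores.index)


def intersection_sets(classes: pd.DataFrame) -> dict[tuple[str, ...], list[str]]:
    """Dual-inclusion intersection sets across screens.

    ``classes`` is genes x screens with values essential/nonessential/
    intermediate. A gene belongs to the set keyed by a screen subset iff it
    is essential in every member and nonessential in every non-member;
    intermediate genes belong to no set.
    """
    from itertools import combinations

    screens = list(classes.columns)
    out: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(screens) + 1):
        for members in combinations(screens, r):
            non_members = [s for s in screens if s not in members]
            mask = np.ones(len(classes), dtype=bool)
            for s in members:
                mask &= (classes[s] == "essential").to_numpy()
            for s in non_members:
                mask &= (classes[s] == "nonessential").to_numpy()
            out[members] = classes.index[mask].tolist()
    return out


CANDIDATE_SET_NAMES = (
    "human_essential_set1",
    "human_enriched_set1",
    "chimp_essential_set1",
    "chimp_enriched_set1",
    "chimp_essential_human_enriched",
    "human_essential_chimp_enriched",
    "both_essential_human_more",
    "both_essential_chimp_more",
    "human_essential_set2",
    "human_enriched_set2",
    "chimp_essential_set2",
    "chimp_enriched_set2",
    "fdr_candidate_human",
    "fdr_candidate_chimp",
)


def candidate_selection(table: pd.DataFrame,
                        human_lines: tuple[str, str],
                        chimp_lines: tuple[str, str],
                        fdr_within: float = 0.10,
                        fdr_opposite: float = 0.25) -> pd.DataFrame:
    """Evaluate every printed candidate-selection criterion.

    ``table`` is indexed by gene with columns: ``human_avg`` / ``chimp_avg``
    (species means of the gene-averaged LFC), ``fdr_<line>`` (per-line
    bootstrap FDRs) and ``dscore_<line>`` (per-line direction scores) for the
    four line names given. Emits one boolean column per set plus the
    species-level direction-score sums and a ``candidate`` union column; a
    gene may carry multiple labels.
    """
    t = table
    h1, h2 = human_lines
    c1, c2 = chimp_lines
    ha, ca = t["human_avg"], t["chimp_avg"]
    out = pd.DataFrame(index=t.index)

    fdr_cols = {ln: f"fdr_{ln}" for ln in (h1, h2, c1, c2)}
    have_fdrs = all(col in t.columns for col in fdr_cols.values())
    if have_fdrs:
        fdr_h = t[[fdr_cols[h1], fdr_cols[h2]]]
        fdr_c = t[[fdr_cols[c1], fdr_cols[c2]]]
        sig_h = (fdr_h < 0.05).all(axis=1)
        sig_c = (fdr_c < 0.05).all(axis=1)
        sig_all = sig_h & sig_c
    else:
        logger.warning("per-line FDR columns missing; skipping FDR-dependent "
                       "candidate sets")

    if have_fdrs:
        out["human_essential_set1"] = ((ca > -1) & (ca < 1) & (ha < -2)
                                       & (ha - ca < -2) & sig_h)
        out["human_enriched_set1"] = ((ca > -1) & (ca < 1) & (ha > 1)
                                      & (ha - ca > 0.2) & sig_h)
        out["chimp_essential_set1"] = ((ca < -2) & (ha < 1) & (ha > -1)
                                       & (ha - ca > 2) & sig_c)
        out["chimp_enriched_set1"] = ((ca > 2) & (ha < 1) & (ha > -1)
                                      & (ha - ca < -2) & sig_c)
        out["chimp_essential_human_enriched"] = ((ca < -0.8) & (ha > 0.4)
                                                 & (ha - ca > 0.2) & sig_all)
        out["human_essential_chimp_enriched"] = ((ca > 0.8) & (ha < -0.8)
                                                 & (ha - ca < -0.2) & sig_all)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = ha / ca
        out["both_essential_human_more"] = ((ca < -1) & (ha < -2.5)
                                            & (ratio > 2) & sig_all)
        out["both_essential_chimp_more"] = ((ca < -3) & (ha < -1)
                                            & (ratio < 0.3) & sig_all)

    hds = t[f"dscore_{h1}"] + t[f"dscore_{h2}"]
    cds = t[f"dscore_{c1}"] + t[f"dscore_{c2}"]
    out["human_direction_score"] = hds
    out["chimp_direction_score"] = cds
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(np.abs(hds / cds))
    log_ratio = pd.Series(log_ratio, index=t.index)

    out["human_essential_set2"] = ((hds > 4) & (t[f"dscore_{h1}"] >= 2)
                                   & (t[f"dscore_{h2}"] >= 2)
                                   & (hds - cds >= 4))
    out["human_enriched_set2"] = ((hds < -4) & (t[f"dscore_{h1}"] <= -1)
                                  & (t[f"dscore_{h2}"] <= -2)
                                  & (hds - cds <= -3) & (log_ratio >= 1))
    # first clause printed as human_direction_score > 4 in the source
    # criterion; evaluated verbatim
    out["chimp_essential_set2"] = ((hds > 4) & (t[f"dscore_{c1}"] >= -1)
                                   & (t[f"dscore_{c2}"] >= -2)
                                   & (cds - hds >= 4) & (log_ratio >= 1))
    out["chimp_enriched_set2"] = ((cds < -4) & (t[f"dscore_{c1}"] <= -2)
                                  & (t[f"dscore_{c2}"] <= -2)
                                  & (cds - hds <= -4) & (log_ratio >= 1))

    if have_fdrs:
        out["fdr_candidate_human"] = ((fdr_h < fdr_within).all(axis=1)
                                      & (fdr_c > fdr_opposite).all(axis=1))
        out["fdr_candidate_chimp"] = ((fdr_c < fdr_within).all(axis=1)
                                      & (fdr_h > fdr_opposite).all(axis=1))

    set_cols = [c for c in CANDIDATE_SET_NAMES if c in out.columns]
    out[set_cols] = out[set_cols].fillna(False).astype(bool)
    out["candidate"] = out[set_cols].any(axis=1)
    return out
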