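"""Cross-species guide-genome matching and library filtering rules.

Target sites are protospacers immediately followed (3') by an SpCas9 NGG PAM;
the PAM must match exactly while up to ``max_mismatch`` substitutions are
tolerated inside the protospacer. Coordinates are 0-based half-open on the
forward strand of the contig; a '-' strand site at ``start`` means the
reverse complement of ``genome[start:start+20]`` equals the spacer (with its
PAM upstream on the forward strand as CCN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import SPACER_LENGTH, _revcomp

logger = logging.getLogger("crisprcomp")

__all__ = [
    "TargetSite",
    "find_target_sites",
    "cross_species_filter",
    "tss_coverage_filter",
    "select_validation_guides",
]


@dataclass(frozen=True)
class TargetSite:
    contig: str
    start: int  # 0-based start of the protospacer-aligned window
    strand: str  # '+' or '-'
    mismatches: int


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def find_target_sites(spacer: str, genome: dict[str, str],
                      max_mismatch: int = 0) -> list[TargetSite]:
    """All NGG-adjacent sites within Hamming distance ``max_mismatch``.

    Scans both strands of every contig; results are sorted by
    (contig, start, strand).
    """
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise ValueError(f"ambiguous bases in spacer {spacer!r}")
    if len(spacer) != SPACER_LENGTH:
        raise ValueError(f"spacer must be {SPACER_LENGTH} nt, got {len(spacer)}")
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be between 0 and 3")

    fwd = _encode(spacer)
    rev = _encode(_revcomp(spacer))
    L = SPACER_LENGTH
    sites: list[TargetSite] = []
    for contig, seq in genome.items():
        enc = _encode(seq)
        n = len(enc)
        if n < L + 3:
            continue
        g = enc == 2  # G
        c = enc == 1  # C
        # '+' strand: protospacer at [s, s+L), PAM NGG at [s+L, s+L+3)
        plus = np.flatnonzero(g[L + 1:n - 1] & g[L + 2:n])
        # '-' strand: protospacer window [s, s+L), CCN at [s-3, s)
        minus = np.flatnonzero(c[:n - L - 2] & c[1:n - L - 1]) + 3
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        for starts, pattern, strand in ((plus, fwd, "+"), (minus, rev, "-")):
            if len(starts) == 0:
                continue
            mm = (windows[starts] != pattern).sum(axis=1)
            for s, m in zip(starts[mm <= max_mismatch],
                            mm[mm <= max_mismatch]):
                sites.append(TargetSite(contig, int(s), strand, int(m)))
    sites.sort(key=lambda t: (t.contig, t.start, t.strand))
    return sites


def _perfect_site_counts(library: pd.DataFrame,
                         genome: dict[str, str]) -> pd.Series:
    """Number of perfect NGG-adjacent sites per guide, by exact hashing."""
    hits: dict[str, int] = {}
    L = SPACER_LENGTH
    for seq in genome.values():
        seq = seq.upper()
        n = len(seq)
        for s in range(0, n - L - 2):
            if seq[s + L + 1] == "G" and seq[s + L + 2] == "G":
                w = seq[s:s + L]
                hits[w] = hits.get(w, 0) + 1
        for s in range(3, n - L + 1):
            if seq[s - 3] == "C" and seq[s - 2] == "C":
                w = _revcomp(seq[s:s + L])
                hits[w] = hits.get(w, 0) + 1
    return pd.Series([hits.get(sp, 0) for sp in library["spacer"].str.upper()],
                     index=library["guide_id"].to_numpy())


def cross_species_filter(library: pd.DataFrame, genome_a: dict[str, str],
                         genome_b: dict[str, str],
                         ) -> tuple[pd.DataFrame, pd.Index]:
    """Flag each guide's perfect-match status in both genomes.

    The retained set contains the targeting guides with at least one perfect
    NGG-adjacent site in each genome. Non-targeting guides pass vacuously but
    are flagged ``is_nt`` and excluded from the retained targeting set.
    Returns (annotation table, retained targeting guide ids).
    """
    n_a = _perfect_site_counts(library, genome_a)
    n_b = _perfect_site_counts(library, genome_b)
    ann = pd.DataFrame({
        "guide_id": library["guide_id"].to_numpy(),
        "is_nt": library["is_nt"].to_numpy(),
        "n_perfect_a": n_a.to_numpy(),
        "n_perfect_b": n_b.to_numpy(),
    })
    ann["perfect_in_both"] = (ann["n_perfect_a"] >= 1) & (ann["n_perfect_b"] >= 1)
    retained = pd.Index(
        ann.loc[~ann["is_nt"] & ann["perfect_in_both"], "guide_id"])
    return ann, retained


def tss_coverage_filter(library: pd.DataFrame, retained: pd.Index,
                        min_guides: int = 3) -> pd.Index:
    """Genes whose TSS keeps at least ``min_guides`` retained guides."""
    targeting = library[~library["is_nt"]]
    kept = targeting[targeting["guide_id"].isin(retained)]
    per_gene = kept.groupby("gene")["guide_id"].size()
    return pd.Index(per_gene.index[per_gene >= min_guides])


DEFAULT_TSS_BUCKETS: tuple[tuple[float, float], ...] = (
    (0.0, 250.0),        # primary window downstream of the TSS
    (250.0, 500.0),
    (-500.0, 0.0),
    (-np.inf, np.inf),   # fallback round: anything else
)


def select_validation_guides(candidates: pd.DataFrame,
                             n_per_gene: int = 8,
                             min_on_target: float = 0.4378,
                             min_specificity: float = 0.20,
                             max_offtarget_activity: float = 0.80,
                             tss_buckets=DEFAULT_TSS_BUCKETS) -> pd.DataFrame:
    """Pick up to ``n_per_gene`` validation guides per gene.

    Expects annotation columns: guide_id, gene, tss_offset, on_target_score,
    specificity_score, n_perfect_a, n_perfect_b, max_offtarget_activity and an
    optional boolean ``previously_validated``. Scores are inputs, not computed
    here. Filters: exactly one perfect-match site per genome, specificity
    above ``min_specificity``, predicted off-target activity below
    ``max_offtarget_activity``, on-target score at least ``min_on_target``.
    Survivors are bucketed by TSS-position window (in bucket order) and ranked
    within bucket by descending on-target score, ties broken by guide id;
    previously validated guides are retained first regardless of rank.
    """
    df = candidates.copy()
    if "previously_validated" not in df.columns:
        df["previously_validated"] = False
    ok = (
        (df["n_perfect_a"] == 1)
        & (df["n_perfect_b"] == 1)
        & (df["specificity_score"] > min_specificity)
        & (df["max_offtarget_activity"] < max_offtarget_activity)
        & (df["on_target_score"] >= min_on_target)
    )
    surviving = df[ok].copy()

    def bucket_of(offset: float) -> int:
        for i, (lo, hi) in enumerate(tss_buckets):
            if lo <= offset < hi:
                return i
        return len(tss_buckets)

    surviving["bucket"] = surviving["tss_offset"].map(bucket_of)
    surviving = surviving.sort_values(
        by=["gene", "previously_validated", "bucket", "on_target_score",
            "guide_id"],
        ascending=[True, False, True, False, True], kind="mergesort")
    picked = surviving.groupby("gene", group_keys=False).head(n_per_gene)
    short = picked.groupby("gene").size()
    for gene, n in short[short < n_per_gene].items():
        logger.warning("gene %s has only %d surviving guides (< %d)",
                       gene, n, n_per_gene)
    return picked.drop(columns=["bucket"]).reset_index(drop=True)
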