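"""Synthetic two-species pooled CRISPRi screens.

Generates a guide library, toy genomes for both species, and overdispersed
count matrices with known ground truth, so that every downstream stage of the
analysis (normalization, the control-calibrated negative-binomial test, gene
scoring, the species-by-time contrast) can be exercised and validated without
external data.

The generative model is a two-timepoint competitive growth screen: each guide
``i`` starts at a library weight ``w_i`` (lognormal), and its expected relative
abundance at the final timepoint is multiplied by ``2**(gamma[g, s] * a_i)``
where ``gamma[g, s]`` is the total log2 fitness effect of silencing gene ``g``
in species ``s`` over the screen and ``a_i`` in [0, 1] is the guide's activity.
Counts at both timepoints are negative binomial with variance
``mu + alpha * mu**2`` at a constant expected sequencing depth per sample.
Non-targeting guides run through the identical sampling pipeline with
``gamma = 0`` so they are exchangeable with null targeting guides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SPACER_LENGTH",
    "simulate_library",
    "simulate_genomes",
    "simulate_counts",
    "simulate_screen",
]

SPACER_LENGTH = 20
_BASES = np.array(list("ACGT"))

GENE_CLASSES = (
    "neutral",
    "shared-essential",
    "speciesA-specific",
    "speciesB-specific",
    "suppressor",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-species screen.

    Defaults emulate a desk-scale version of a genome-wide CRISPRi fitness
    screen: 5 guides per gene, two cell lines per species with two technical
    replicates each, a two-timepoint (t0 vs tfinal) readout at ~500 expected
    reads per guide, and 22.6% of targeting guides carrying mismatches against
    the species-B genome.
    """

    n_genes: int = 500
    guides_per_gene: int = 5
    n_nt_guides: int = 250
    lines_per_species: int = 2
    reps_per_line: int = 2
    mean_t0_depth: float = 500.0
    dispersion_alpha: float = 0.05
    frac_shared_essential: float = 0.10
    frac_species_specific: float = 0.05
    frac_suppressor: float = 0.02
    effect_lfc_mean: float = -2.0
    effect_lfc_sd: float = 0.5
    min_abs_effect: float = 0.0
    guide_activity_range: tuple[float, float] = (0.5, 1.0)
    frac_mismatch_in_B: float = 0.226
    mismatch_activity_penalty: float = 0.4
    library_weight_sigma: float = 0.5
    line_activity_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "guides_per_gene", "n_nt_guides",
                     "lines_per_species", "reps_per_line"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.mean_t0_depth <= 0:
            raise ValueError("mean_t0_depth must be positive")
        if self.dispersion_alpha < 0:
            raise ValueError("dispersion_alpha must be >= 0")
        for name in ("frac_shared_essential", "frac_species_specific",
                     "frac_suppressor", "frac_mismatch_in_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if (self.frac_shared_essential + self.frac_species_specific
                + self.frac_suppressor) > 1.0:
            raise ValueError("gene-class fractions sum to more than 1")
        lo, hi = self.guide_activity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("guide_activity_range must be a pair in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["guide_activity_range"] = list(self.guide_activity_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "guide_activity_range" in d:
            d["guide_activity_range"] = tuple(d["guide_activity_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True simulation state: per-gene classes/effects and per-guide activity.

    ``genes`` has columns gene, class, gamma_a, gamma_b.
    ``guides`` has columns guide_id, gene, activity, mismatches_b.
    """

    genes: pd.DataFrame
    guides: pd.DataFrame

    def gamma_lookup(self, species: str) -> pd.Series:
        col = "gamma_a" if species == "A" else "gamma_b"
        return self.genes.set_index("gene")[col]


def _streams(config: SimulationConfig):
    """One independent RNG stream per artifact (library / genomes / counts)."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _random_spacers(rng: np.random.Generator, n: int, existing: set[str],
                    max_retries: int = 20) -> list[str]:
    out: list[str] = []
    seen = set(existing)
    for i in range(n):
        for attempt in range(max_retries + 1):
            spacer = "".join(rng.choice(_BASES, size=SPACER_LENGTH))
            if spacer not in seen:
                break
        else:
            raise RuntimeError(
                f"duplicate spacer collision persisted after {max_retries} "
                f"retries (last candidate: {spacer})")
        seen.add(spacer)
        out.append(spacer)
    return out


def simulate_library(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the guide library and its ground truth.

    Returns a library table (guide_id, spacer, gene, tss_offset, is_nt,
    on_target_score, specificity_score) with ``n_genes * guides_per_gene``
    targeting guides plus ``n_nt_guides`` non-targeting controls, and the
    :class:`GroundTruth` describing gene classes, per-species fitness effects
    and guide activities. Deterministic given ``config.seed``.
    """
    rng, _, _ = _streams(config)
    n_genes = config.n_genes
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    n_shared = int(round(config.frac_shared_essential * n_genes))
    n_spec = int(round(config.frac_species_specific * n_genes))
    n_supp = int(round(config.frac_suppressor * n_genes))
    n_spec_a = n_spec // 2
    n_spec_b = n_spec - n_spec_a
    order = rng.permutation(n_genes)
    classes = np.array(["neutral"] * n_genes, dtype=object)
    pos = 0
    for label, count in (("shared-essential", n_shared),
                         ("speciesA-specific", n_spec_a),
                         ("speciesB-specific", n_spec_b),
                         ("suppressor", n_supp)):
        classes[order[pos:pos + count]] = label
        pos += count

    draws = rng.normal(config.effect_lfc_mean, config.effect_lfc_sd, n_genes)
    mag = np.maximum(np.abs(draws), config.min_abs_effect)
    sign = np.where(draws < 0, -1.0, 1.0)
    gamma_a = np.zeros(n_genes)
    gamma_b = np.zeros(n_genes)
    shared = classes == "shared-essential"
    gamma_a[shared] = gamma_b[shared] = -mag[shared]
    supp = classes == "suppressor"
    gamma_a[supp] = gamma_b[supp] = mag[supp]
    only_a = classes == "speciesA-specific"
    gamma_a[only_a] = sign[only_a] * mag[only_a]
    only_b = classes == "speciesB-specific"
    gamma_b[only_b] = sign[only_b] * mag[only_b]

    n_targeting = n_genes * config.guides_per_gene
    spacers = _random_spacers(rng, n_targeting + config.n_nt_guides, set())
    guide_ids = [f"{g}_g{j + 1}" for g in genes
                 for j in range(config.guides_per_gene)]
    nt_ids = [f"NT{i + 1:05d}" for i in range(config.n_nt_guides)]

    lo, hi = config.guide_activity_range
    activity = rng.uniform(lo, hi, n_targeting)

    mismatches = np.zeros(n_targeting, dtype=int)
    n_mm = int(round(config.frac_mismatch_in_B * n_targeting))
    mm_idx = rng.choice(n_targeting, size=n_mm, replace=False)
    mismatches[mm_idx] = rng.integers(1, 4, size=n_mm)

    library = pd.DataFrame({
        "guide_id": guide_ids + nt_ids,
        "spacer": spacers,
        "gene": np.concatenate([np.repeat(genes, config.guides_per_gene),
                                ["NT"] * config.n_nt_guides]),
        "tss_offset": np.concatenate([
            rng.integers(-25, 500, n_targeting),
            np.zeros(config.n_nt_guides, dtype=int)]),
        "is_nt": [False] * n_targeting + [True] * config.n_nt_guides,
        "on_target_score": np.round(rng.uniform(0.2, 0.95,
                                                n_targeting + config.n_nt_guides), 4),
        "specificity_score": np.round(rng.uniform(0.05, 1.0,
                                                  n_targeting + config.n_nt_guides), 4),
    })

    truth = GroundTruth(
        genes=pd.DataFrame({"gene": genes, "class": classes,
                            "gamma_a": gamma_a, "gamma_b": gamma_b}),
        guides=pd.DataFrame({
            "guide_id": library["guide_id"],
            "gene": library["gene"],
            "activity": np.concatenate([activity,
                                        np.zeros(config.n_nt_guides)]),
            "mismatches_b": np.concatenate([mismatches,
                                            np.zeros(config.n_nt_guides,
                                                     dtype=int)]),
        }),
    )
    return library, truth


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _contains_spacer(genome: str, spacer: str) -> bool:
    return spacer in genome or _revcomp(spacer) in genome


def simulate_genomes(library: pd.DataFrame, truth: GroundTruth,
                     config: SimulationConfig,
                     genome_length: int | None = None,
                     ) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Emit one toy contig per species embedding each targeting protospacer.

    Every targeting spacer is embedded exactly once, followed by an AGG PAM.
    In genome B, guides flagged with ``mismatches_b > 0`` have that many
    substitutions introduced inside the embedded protospacer, so they no
    longer align perfectly to species B. Non-targeting spacers are verified
    absent from both genomes and re-drawn if a chance hit occurs; the
    (possibly updated) library is returned alongside the genomes.
    """
    rng = _streams(config)[1]
    targeting = library[~library["is_nt"]].reset_index(drop=True)
    mm = truth.guides.set_index("guide_id")["mismatches_b"]

    gap = 8  # random spacer between embedded sites; >=3 avoids PAM overlap
    unit = SPACER_LENGTH + 3 + gap
    needed = unit * len(targeting) + gap
    if genome_length is None:
        genome_length = needed
    elif genome_length < needed:
        raise ValueError(
            f"genome of length {genome_length} too short to embed "
            f"{len(targeting)} guides without overlap (need >= {needed})")

    def random_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    parts_a: list[str] = []
    parts_b: list[str] = []
    for _, row in targeting.iterrows():
        flank = random_seq(gap)
        spacer = row["spacer"]
        parts_a.append(flank + spacer + "AGG")
        n_mm = int(mm[row["guide_id"]])
        spacer_b = spacer
        if n_mm > 0:
            positions = rng.choice(SPACER_LENGTH, size=n_mm, replace=False)
            chars = list(spacer_b)
            for p in positions:
                alternatives = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alternatives[rng.integers(0, 3)]
            spacer_b = "".join(chars)
        parts_b.append(flank + spacer_b + "AGG")
    tail = random_seq(genome_length - needed + gap)
    seq_a = "".join(parts_a) + tail
    seq_b = "".join(parts_b) + tail

    # re-draw any non-targeting spacer that happens to occur in either genome
    library = library.copy()
    nt_rows = library.index[library["is_nt"]]
    existing = set(library["spacer"])
    for idx in nt_rows:
        spacer = library.at[idx, "spacer"]
        retries = 0
        while _contains_spacer(seq_a, spacer) or _contains_spacer(seq_b, spacer):
            if retries >= 50:
                raise RuntimeError(
                    f"could not draw a genome-absent non-targeting spacer "
                    f"for {library.at[idx, 'guide_id']}")
            spacer = _random_spacers(rng, 1, existing)[0]
            retries += 1
        existing.add(spacer)
        library.at[idx, "spacer"] = spacer

    genomes = {"A": {"chrA": seq_a}, "B": {"chrB": seq_b}}
    return genomes, library


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: species x individual x replicate x {t0, tfinal}."""
    rows = []
    for sp in ("A", "B"):
        for line in range(1, config.lines_per_species + 1):
            indiv = f"{sp}{line}"
            for rep in range(1, config.reps_per_line + 1):
                for tp in ("t0", "tfinal"):
                    rows.append({
                        "sample_id": f"{sp}_L{line}_R{rep}_{tp}",
                        "species": sp,
                        "individual": indiv,
                        "replicate": f"R{rep}",
                        "timepoint": tp,
                    })
    return pd.DataFrame(rows)


def simulate_counts(library: pd.DataFrame, truth: GroundTruth,
                    config: SimulationConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the count matrix (guides x samples) and its sample sheet.

    t0 counts are NB around ``depth * n_guides * p0_i`` where ``p0`` are the
    normalized lognormal library weights; tfinal expected abundances are the
    t0 abundances times ``2**(gamma * activity)`` renormalized to the same
    expected sequencing depth. Per-line multiplicative jitter on gamma
    (``line_activity_sd``) emulates line-to-line variability in knockdown
    strength. Deterministic given ``config.seed``.
    """
    rng = _streams(config)[2]
    design = make_design(config)
    guides = truth.guides
    n = len(guides)
    gamma_by_species = {
        "A": truth.gamma_lookup("A").reindex(guides["gene"]).fillna(0.0).to_numpy(),
        "B": truth.gamma_lookup("B").reindex(guides["gene"]).fillna(0.0).to_numpy(),
    }
    activity = guides["activity"].to_numpy().copy()
    penalty = config.mismatch_activity_penalty ** guides["mismatches_b"].to_numpy()

    w = rng.lognormal(0.0, config.library_weight_sigma, n)
    p0 = w / w.sum()
    depth_total = config.mean_t0_depth * n

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        mean = np.clip(mean, 0.0, None)
        if config.dispersion_alpha == 0:
            return rng.poisson(mean)
        r = 1.0 / config.dispersion_alpha
        return rng.negative_binomial(r, r / (r + mean))

    cols = {}
    for sp in ("A", "B"):
        act = activity * (penalty if sp == "B" else 1.0)
        for line in range(1, config.lines_per_species + 1):
            jitter = 1.0 + rng.normal(0.0, config.line_activity_sd, n)
            gamma_line = gamma_by_species[sp] * act * jitter
            p1 = p0 * np.exp2(gamma_line)
            p1 = p1 / p1.sum()
            for rep in range(1, config.reps_per_line + 1):
                cols[f"{sp}_L{line}_R{rep}_t0"] = nb_draw(depth_total * p0)
                cols[f"{sp}_L{line}_R{rep}_tfinal"] = nb_draw(depth_total * p1)

    counts = pd.DataFrame(cols, index=pd.Index(guides["guide_id"], name="guide_id"))
    counts = counts[design["sample_id"].tolist()]
    return counts, design


def simulate_screen(config: SimulationConfig, with_genomes: bool = False):
    """Convenience wrapper: library + truth + counts (+ genomes)."""
    library, truth = simulate_library(config)
    genomes = None
    if with_genomes:
        genomes, library = simulate_genomes(library, truth, config)
    counts, design = simulate_counts(library, truth, config)
    if with_genomes:
        return library, truth, counts, design, genomes
    return library, truth, counts, design
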