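"""Construction-level benchmark runs used by the acceptance script and the
acceptance test-suite: control calibration on a null screen and realized
false-discovery proportion of the full validation pipeline on screens with
known ground truth."""

from __future__ import annotations

import numpy as np

from .species_contrast import AlphaRRAConfig, run_validation_pipeline
from .sgrna_stats import analyze_screens
from .synthetic_data import SimulationConfig, simulate_screen

SPECIES_SPECIFIC_CLASSES = ("speciesA-specific", "speciesB-specific")


def null_calibration_percent(seed: int, n_nt: int = 5000,
                             nt_target: float = 0.95,
                             individual: str = "A1") -> dict:
    """Percent of non-targeting sgRNAs called non-significant on a null
    screen after per-screen cutoff calibration."""
    cfg = SimulationConfig(n_genes=100, n_nt_guides=n_nt,
                           frac_shared_essential=0.0,
                           frac_species_specific=0.0, frac_suppressor=0.0,
                           frac_mismatch_in_B=0.0, line_activity_sd=0.0,
                           seed=seed)
    library, truth, counts, design = simulate_screen(cfg)
    table, models = analyze_screens(counts, design, library,
                                    nt_target=nt_target)
    nt_ids = set(library.loc[library["is_nt"], "guide_id"])
    sub = table[(table["individual"] == individual)
                & table["guide_id"].isin(nt_ids)]
    percent = 100.0 * float((sub["call"] == "ns").mean())
    return {"value": percent, "n": int(len(sub))}


def validation_screen_config(seed: int) -> SimulationConfig:
    """Study conditions for one simulated validation screen: 1000 genes x 5
    guides + 500 NT guides, 3 individuals per species x 2 replicates at both
    timepoints, 10% of genes species-specific with |delta gamma| >= 2, and a
    perfect-match library (the validation library is designed that way)."""
    return SimulationConfig(
        n_genes=1000, guides_per_gene=5, n_nt_guides=500,
        lines_per_species=3, reps_per_line=2,
        frac_shared_essential=0.10, frac_species_specific=0.10,
        frac_suppressor=0.02, effect_lfc_mean=-2.5, effect_lfc_sd=0.5,
        min_abs_effect=2.0, frac_mismatch_in_B=0.0, seed=seed)


def single_screen_fdp(seed: int, fdr_threshold: float = 0.01,
                      min_guides_below_alpha: int = 3,
                      min_lfc_diff: float = 0.75,
                      n_perm: int = 10_000) -> dict:
    """One simulated validation screen through the full pipeline; returns the
    realized false-discovery proportion and sensitivity of the final caller."""
    cfg = validation_screen_config(seed)
    library, truth, counts, design = simulate_screen(cfg)
    res = run_validation_pipeline(
        counts, design, library,
        rra_config=AlphaRRAConfig(n_perm=n_perm, seed=seed),
        fdr_threshold=fdr_threshold,
        min_guides_below_alpha=min_guides_below_alpha,
        min_lfc_diff=min_lfc_diff)
    calls = res["calls"]
    truth_class = truth.genes.set_index("gene")["class"]
    called = calls.index[calls["call"] != "none"]
    is_true = truth_class.reindex(called).isin(SPECIES_SPECIFIC_CLASSES)
    n_called = int(len(called))
    n_false = int((~is_true).sum())
    n_positive = int(truth_class.isin(SPECIES_SPECIFIC_CLASSES).sum())
    return {
        "n_called": n_called,
        "n_false": n_false,
        "fdp": n_false / max(1, n_called),
        "sensitivity": int(is_true.sum()) / max(1, n_positive),
    }


def mean_fdp_percent(seed: int, n_screens: int = 20) -> dict:
    """Mean realized FDP (in percent) of the species-specific caller over
    ``n_screens`` independently simulated validation screens."""
    fdps = []
    for rep in range(n_screens):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        fdps.append(single_screen_fdp(rep_seed)["fdp"])
    fdps = np.asarray(fdps)
    return {
        "value": 100.0 * float(fdps.mean()),
        "n": int(n_screens),
        "se_percent": 100.0 * float(fdps.std(ddof=1) / np.sqrt(n_screens))
        if n_screens > 1 else 0.0,
    }
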