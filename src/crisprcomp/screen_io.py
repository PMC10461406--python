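"""Readers, writers and validation for screen file formats.

All tables are TSV with a header row, UTF-8, no index column. Counts are
nonnegative integers with no missing values. Coordinates in site reports are
0-based half-open with strand '+'/'-'. FASTA/FASTQ parsing goes through
Biopython; FASTQ input may be gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("crisprcomp")

SPECIES_LEVELS = ("A", "B")
TIMEPOINT_LEVELS = ("t0", "tfinal")

LIBRARY_COLUMNS = ["guide_id", "spacer", "gene", "tss_offset", "is_nt",
                   "on_target_score", "specificity_score"]
DESIGN_COLUMNS = ["sample_id", "species", "individual", "replicate", "timepoint"]


class ValidationError(ValueError):
    """A screen input file violated its schema."""


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_library(library: pd.DataFrame, path) -> None:
    write_table(library[LIBRARY_COLUMNS], path)


def read_library(path) -> pd.DataFrame:
    lib = read_table(path)
    missing = [c for c in LIBRARY_COLUMNS if c not in lib.columns]
    if missing:
        raise ValidationError(f"library file {path} missing columns {missing}")
    if lib["guide_id"].duplicated().any():
        dups = lib.loc[lib["guide_id"].duplicated(), "guide_id"].tolist()
        raise ValidationError(f"duplicate guide ids in library: {dups[:5]}")
    lib["is_nt"] = lib["is_nt"].astype(bool)
    lib["spacer"] = lib["spacer"].str.upper()
    return lib


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("guide_id").to_csv(path, sep="\t")


def read_counts(path, library: pd.DataFrame | None = None,
                design: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "guide_id"
    validate_counts(counts, library=library, design=design, source=str(path))
    return counts


def validate_counts(counts: pd.DataFrame, library: pd.DataFrame | None = None,
                    design: pd.DataFrame | None = None,
                    source: str = "count matrix") -> None:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].tolist()
        raise ValidationError(f"{source}: duplicate guide ids {dups[:5]}")
    if counts.isna().any().any():
        raise ValidationError(f"{source}: missing values are forbidden")
    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError(f"{source}: non-numeric counts in sample {col}")
        bad = vals[(vals % 1 != 0)]
        if len(bad):
            raise ValidationError(
                f"{source}: non-integer count for guide {bad.index[0]!r} "
                f"in sample {col!r}")
        neg = vals[vals < 0]
        if len(neg):
            raise ValidationError(
                f"{source}: negative count for guide {neg.index[0]!r} "
                f"in sample {col!r}")
    if (counts.sum(axis=0) == 0).any():
        empty = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValidationError(f"{source}: all-zero sample columns {empty}")
    if library is not None:
        unknown = counts.index.difference(library["guide_id"])
        if len(unknown):
            raise ValidationError(
                f"{source}: guide ids absent from the library: "
                f"{unknown.tolist()[:5]}")
    if design is not None:
        unknown = [c for c in counts.columns
                   if c not in set(design["sample_id"])]
        if unknown:
            raise ValidationError(
                f"{source}: samples absent from the sample sheet: {unknown}")


def write_design(design: pd.DataFrame, path) -> None:
    write_table(design[DESIGN_COLUMNS], path)


def read_design(path, require_pairing: bool = False) -> pd.DataFrame:
    design = read_table(path)
    validate_design(design, require_pairing=require_pairing)
    return design


def validate_design(design: pd.DataFrame, require_pairing: bool = False) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"]
        raise ValidationError(f"duplicate sample ids: {dups.tolist()}")
    bad_tp = set(design["timepoint"]) - set(TIMEPOINT_LEVELS)
    if bad_tp:
        raise ValidationError(
            f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINT_LEVELS}")
    if require_pairing:
        key = ["species", "individual", "replicate"]
        tp_sets = design.groupby(key)["timepoint"].agg(set)
        unpaired = tp_sets[tp_sets.map(lambda s: s != set(TIMEPOINT_LEVELS))]
        if len(unpaired):
            raise ValidationError(
                "samples lacking a t0/tfinal pair: "
                f"{unpaired.index.tolist()}")


# ---------------------------------------------------------------------------
# sequences

def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Parse FASTA (multi-line sequences), case-folded to uppercase."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_reads(fastq, library: pd.DataFrame,
                spacer_window: tuple[int, int]) -> tuple[pd.Series, int]:
    """Exact-match counting of one FASTQ file against the library.

    ``spacer_window`` is a 0-based half-open slice of each read in which the
    spacer is expected. Matching is exact and forward-orientation only; reads
    whose window does not equal any library spacer are tallied as unmatched.
    Returns (counts indexed like the library, number of unmatched reads).
    """
    start, end = spacer_window
    spacer_len = library["spacer"].str.len().unique()
    if len(spacer_len) != 1:
        raise ValidationError("library spacers must all have the same length")
    if end - start != spacer_len[0]:
        raise ValidationError(
            f"spacer window {spacer_window} has length {end - start}, "
            f"library spacers have length {spacer_len[0]}")
    lookup = {s: i for i, s in enumerate(library["spacer"].str.upper())}
    tallies = np.zeros(len(library), dtype=np.int64)
    unmatched = 0
    total = 0
    handle = _open_text(fastq) if isinstance(fastq, (str, Path)) else fastq
    try:
        for total, rec in enumerate(SeqIO.parse(handle, "fastq"), start=1):
            seq = str(rec.seq).upper()
            if len(seq) < end:
                raise ValidationError(
                    f"read #{total} ({rec.id}) is shorter than the spacer "
                    f"window end {end}")
            idx = lookup.get(seq[start:end])
            if idx is None:
                unmatched += 1
            else:
                tallies[idx] += 1
    finally:
        if isinstance(fastq, (str, Path)):
            handle.close()
    if total == 0:
        logger.warning("empty FASTQ input: returning all-zero counts")
    return pd.Series(tallies, index=pd.Index(library["guide_id"],
                                             name="guide_id")), unmatched
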