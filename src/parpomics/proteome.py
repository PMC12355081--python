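"""Protein-group table cleaning into an analysis-ready log2 matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adpr import filter_min_replicates
from .io_design import SampleDesign

__all__ = ["clean_protein_groups"]


def clean_protein_groups(
    table: pd.DataFrame,
    design: SampleDesign,
    min_reps: int = 3,
) -> pd.DataFrame:
    """Clean a protein-groups table into a protein x sample log2 matrix.

    Steps: drop records flagged reverse, contaminant or only-identified-by-
    site; treat LFQ intensity 0 as not quantified; log2-transform; keep a
    protein iff it is quantified in at least ``min_reps`` replicates of at
    least one cell line (all treatments of a line pooled — proteome samples
    are untreated, so the natural replicate group is the cell line).
    """
    lfq_cols = [c for c in table.columns if c.startswith("lfq_")]
    samples = [c[len("lfq_"):] for c in lfq_cols]
    present = [s for s in samples if s in design.samples]
    if not present:
        raise ValueError("no LFQ columns match samples in the design")

    keep = ~(table["is_reverse"] | table["is_contaminant"] | table["only_identified_by_site"])
    clean = table.loc[keep]
    mat = clean[[f"lfq_{s}" for s in present]].copy()
    mat.columns = present
    mat.index = pd.Index(clean["protein_group"], name="protein")
    mat = mat.where(mat > 0)  # LFQ 0 means not quantified
    mat = np.log2(mat)
    return filter_min_replicates(mat, design, min_reps=min_reps, grouping="line")
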