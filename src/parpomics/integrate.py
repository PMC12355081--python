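"""Cross-layer integration: phospho-vs-protein quadrants, peptide coverage
maps, PCA scores and fold-change summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import VolcanoResult

__all__ = [
    "QUADRANT_CATEGORIES",
    "quadrant_classify",
    "CoverageMap",
    "map_peptides",
    "region_overlap",
    "pca_scores",
    "fold_change_summary",
]

QUADRANT_CATEGORIES = (
    "same_direction",
    "opposite_directions",
    "phospho_only",
    "protein_only",
    "not_significant",
)


def _category(
    phospho_sig: bool, protein_sig: bool, phospho_fc: float, protein_fc: float
) -> str:
    if phospho_sig and protein_sig:
        same = np.sign(phospho_fc) == np.sign(protein_fc)
        return "same_direction" if same else "opposite_directions"
    if phospho_sig:
        return "phospho_only"
    if protein_sig:
        return "protein_only"
    return "not_significant"


def quadrant_classify(
    phospho_results: VolcanoResult | pd.DataFrame,
    protein_results: VolcanoResult | pd.DataFrame,
    site_to_protein: Mapping,
) -> pd.DataFrame:
    """Classify phosphosites by joint phospho/protein significance.

    Categories follow the scatter-plot convention: *same_direction* (both
    layers significant, same fold-change sign), *opposite_directions* (both
    significant, opposite signs), *phospho_only*, *protein_only*,
    *not_significant*. Sites whose protein was not measured at the protein
    level are flagged ``protein_unmeasured`` and can only be classified as
    phospho_only or not_significant.
    """
    ph = phospho_results.table if isinstance(phospho_results, VolcanoResult) else phospho_results
    pr = protein_results.table if isinstance(protein_results, VolcanoResult) else protein_results
    rows = []
    for site in ph.index:
        prot = site_to_protein.get(site)
        p_fc = float(ph.at[site, "log2_fc"])
        p_sig = bool(ph.at[site, "significant"])
        measured = prot is not None and prot in pr.index
        if measured:
            r_fc = float(pr.at[prot, "log2_fc"])
            r_sig = bool(pr.at[prot, "significant"])
        else:
            r_fc, r_sig = np.nan, False
        rows.append(
            {
                "site": site,
                "protein": prot,
                "phospho_log2_fc": p_fc,
                "protein_log2_fc": r_fc,
                "phospho_significant": p_sig,
                "protein_significant": r_sig,
                "protein_unmeasured": not measured,
                "category": _category(p_sig, r_sig, p_fc, r_fc),
            }
        )
    return pd.DataFrame(rows).set_index("site")


@dataclass
class CoverageMap:
    """Peptide intervals on a protein, 1-based inclusive coordinates."""

    length: int
    intervals: list[tuple[int, int]]
    unmatched: list[str] = field(default_factory=list)
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"interval ({s}, {e}) outside sequence of length {self.length}")


def map_peptides(protein_sequence: str, peptides: Sequence[str]) -> CoverageMap:
    """Locate every exact occurrence of each peptide in the sequence.

    Matching is exact substring search (no I/L equivalence); every
    occurrence is reported as a 1-based inclusive interval. Peptides with no
    match are listed in ``unmatched``.
    """
    seq = protein_sequence.upper()
    intervals: list[tuple[int, int]] = []
    unmatched: list[str] = []
    for pep in peptides:
        if not pep:
            raise ValueError("empty peptide")
        pep = pep.upper()
        found = False
        start = seq.find(pep)
        while start != -1:
            intervals.append((start + 1, start + len(pep)))
            found = True
            start = seq.find(pep, start + 1)
        if not found:
            unmatched.append(pep)
    return CoverageMap(length=len(seq), intervals=intervals, unmatched=unmatched)


def region_overlap(coverage: CoverageMap, region: tuple[int, int]) -> int:
    """Count peptide intervals intersecting a closed region.

    Touching endpoints count as overlap (closed-interval intersection).
    """
    rs, re = region
    if not (1 <= rs <= re <= coverage.length):
        raise ValueError(f"region {region} outside sequence of length {coverage.length}")
    return sum(1 for s, e in coverage.intervals if s <= re and e >= rs)


def pca_scores(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    drop_incomplete: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of samples from a feature x sample matrix.

    Features are centered (no scaling); features with any missing value are
    dropped by default (complete-case PCA). The sign of each component is
    fixed so its largest-magnitude loading is positive. Returns
    ``(scores, variance_explained_fraction)`` with one score row per sample.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.dropna(axis=0) if drop_incomplete else matrix
    if x.isna().any().any():
        raise ValueError("matrix contains missing values; impute or drop first")
    data = x.to_numpy(dtype=float)
    centered = data - data.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x features matrix
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    k = n_components or min(len(s), matrix.shape[1] - 1)
    k = min(k, len(s))
    loadings = vt[:k]  # components x features
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    scores = (u[:, :k] * s[:k]) * flip
    var = s**2
    var_frac = (var / var.sum())[:k] if var.sum() > 0 else np.zeros(k)
    out = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return out, var_frac


def fold_change_summary(
    cc50_table: pd.DataFrame, parent_label: str | None = None
) -> pd.DataFrame:
    """Per-line mean CC50 and ratio to the parent line.

    ``cc50_table`` has columns ``line`` and ``cc50`` (one row per
    replicate). The parent line is detected by a label containing "parent"
    (case-insensitive) unless given explicitly. Alongside the mean-based
    ratio, per-replicate extreme ratios (min/max replicate over the parent
    mean) are reported.
    """
    if parent_label is None:
        parents = [l for l in cc50_table["line"].unique() if "parent" in l.lower()]
        if len(parents) != 1:
            raise ValueError(f"could not identify a unique parent line among {parents}")
        parent_label = parents[0]
    if parent_label not in set(cc50_table["line"]):
        raise ValueError(f"parent line {parent_label!r} not in table")
    grouped = cc50_table.groupby("line")["cc50"]
    means = grouped.mean()
    parent_mean = means[parent_label]
    if parent_mean == 0:
        raise ZeroDivisionError("parent mean CC50 is zero")
    out = pd.DataFrame(
        {
            "mean_cc50": means,
            "ratio_to_parent": means / parent_mean,
            "min_ratio": grouped.min() / parent_mean,
            "max_ratio": grouped.max() / parent_mean,
            "n_replicates": grouped.count(),
        }
    )
    return out
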