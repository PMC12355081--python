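"""ADP-ribosylation site-level quantification from PSM evidence.

ADPr site tables from serine-ADPr proteomics need manual curation beyond the
search engine's output: decoy and contaminant PSMs are dropped, PSMs carrying
more than one ADPr modification are excluded (their intensity cannot be
attributed to a single site), and two localization-probability gates are
applied — a stricter one for *identifying* a site and a looser one for
letting a PSM contribute to its *quantification*. Both thresholds are strict
(``>``): a PSM at exactly the threshold does not pass.

The per-sample site quantification is the sum of linear intensities of the
qualifying PSMs (the usual site-intensity convention); ``aggregate="max"``
is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from .io_design import SampleDesign

__all__ = [
    "SiteFilterParams",
    "SiteMatrix",
    "build_site_table",
    "filter_min_replicates",
    "residue_distribution",
    "signal_and_overlap_summary",
]

SITE_KEY = ("protein", "position", "residue")


@dataclass(frozen=True)
class SiteFilterParams:
    """Gates applied when building a PTM site table.

    loc_id:
        localization probability a site must exceed (strictly) somewhere to
        count as identified. Default 0.9.
    loc_quant:
        localization probability a PSM must exceed (strictly) to contribute
        intensity. Default 0.75.
    min_reps:
        minimum quantified replicates in at least one condition for the
        replicate filter. Default 3.
    max_ptm_per_psm:
        PSMs with more target-PTM occurrences than this are excluded.
    """

    loc_id: float = 0.9
    loc_quant: float = 0.75
    min_reps: int = 3
    max_ptm_per_psm: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.loc_quant <= self.loc_id <= 1):
            raise ValueError("need 0 <= loc_quant <= loc_id <= 1")
        if self.min_reps < 1:
            raise ValueError("min_reps must be >= 1")


@dataclass
class SiteMatrix:
    """Feature x sample quantitative matrix for PTM sites.

    ``values`` is indexed by (protein, position, residue) with one column
    per sample; NaN means not quantified. ``best_localization`` holds the
    best localization probability seen for each feature. ``scale`` records
    whether values are linear intensities or log2.
    """

    values: pd.DataFrame
    best_localization: pd.Series
    scale: Literal["linear", "log2"] = "linear"

    @property
    def features(self) -> pd.MultiIndex:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


def _empty_site_matrix(samples: list[str]) -> SiteMatrix:
    idx = pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
    return SiteMatrix(
        values=pd.DataFrame(index=idx, columns=samples, dtype=float),
        best_localization=pd.Series(index=idx, dtype=float),
    )


def build_site_table(
    evidence: pd.DataFrame,
    design: SampleDesign,
    params: SiteFilterParams = SiteFilterParams(),
    aggregate: Literal["sum", "max"] = "sum",
) -> SiteMatrix:
    """Build the site-level quantitative table from PSM evidence.

    The procedure, in order:

    1. drop records flagged reverse or contaminant;
    2. drop records with a PTM count other than exactly
       ``params.max_ptm_per_psm`` occurrences (multi-PTM PSMs) or zero;
    3. key features by (protein, position, residue);
    4. a feature is *identified* iff its best localization probability
       (over all its records) exceeds ``loc_id``;
    5. per-sample quantification is the sum (or max) of intensities of the
       feature's records in that sample whose localization exceeds
       ``loc_quant``; samples with no qualifying record stay missing;
    6. non-identified features are dropped.
    """
    unknown = set(evidence["sample"]) - set(design.samples)
    if unknown:
        raise ValueError(f"evidence references samples not in design: {sorted(unknown)}")
    samples = list(design.samples)
    ev = evidence.loc[~evidence["is_reverse"] & ~evidence["is_contaminant"]]
    ev = ev.loc[(ev["n_ptm"] >= 1) & (ev["n_ptm"] <= params.max_ptm_per_psm)]
    if ev.empty:
        return _empty_site_matrix(samples)

    best_loc = ev.groupby(list(SITE_KEY))["localization_prob"].max()
    identified = best_loc[best_loc > params.loc_id]
    if identified.empty:
        return _empty_site_matrix(samples)

    quant = ev.loc[
        ev["localization_prob"] > params.loc_quant, [*SITE_KEY, "sample", "intensity"]
    ].dropna(subset=["intensity"])
    agg = {"sum": "sum", "max": "max"}[aggregate]
    wide = (
        quant.groupby([*SITE_KEY, "sample"])["intensity"]
        .agg(agg)
        .unstack("sample")
        .reindex(index=identified.index, columns=samples)
    )
    wide.index.names = list(SITE_KEY)
    return SiteMatrix(values=wide, best_localization=identified.sort_index(), scale="linear")


def filter_min_replicates(
    matrix: SiteMatrix | pd.DataFrame,
    design: SampleDesign,
    min_reps: int = 3,
    grouping: Literal["condition", "line"] = "condition",
) -> SiteMatrix | pd.DataFrame:
    """Keep features quantified in >= ``min_reps`` replicates of >= 1 group.

    ``grouping="condition"`` groups samples by cell line x treatment (the
    convention for the PTM layers); ``grouping="line"`` pools all treatments
    of a cell line (the proteome convention).
    """
    df = matrix.values if isinstance(matrix, SiteMatrix) else matrix
    if grouping == "condition":
        groups = design.condition_groups()
    else:
        groups = design.line_groups()
    group_lists = [
        [s for s in members if s in df.columns] for members in groups.values()
    ]
    group_lists = [g for g in group_lists if g]
    largest = max((len(g) for g in group_lists), default=0)
    if min_reps > largest:
        warnings.warn(
            f"min_reps={min_reps} exceeds the largest group size ({largest}); "
            "the filter removes every feature",
            stacklevel=2,
        )
    keep = pd.Series(False, index=df.index)
    for members in group_lists:
        keep |= df[members].notna().sum(axis=1) >= min_reps
    if isinstance(matrix, SiteMatrix):
        return SiteMatrix(
            values=df.loc[keep],
            best_localization=matrix.best_localization.loc[keep[keep].index],
            scale=matrix.scale,
        )
    return df.loc[keep]


def residue_distribution(matrix: SiteMatrix) -> dict[str, float]:
    """Fraction of identified sites per modified residue; sums to 1."""
    if len(matrix) == 0:
        return {}
    counts = matrix.values.index.get_level_values("residue").value_counts()
    total = counts.sum()
    return {res: n / total for res, n in counts.items()}


def signal_and_overlap_summary(
    matrices: Mapping[str, SiteMatrix],
    design: SampleDesign,
) -> dict:
    """Summed ADPr signal per (line, treatment) and site overlap across lines.

    ``matrices`` maps cell-line label to that line's SiteMatrix. Sums are
    over present values only. Overlap is computed on identified-site key
    sets; ``exclusive_regions`` gives UpSet-style counts, i.e. the number of
    sites found in exactly that combination of lines and no other.
    """
    signal: dict[tuple[str, str], float] = {}
    for line, mat in matrices.items():
        for trt in sorted({design.treatment[s] for s in design.samples_of(line)}):
            cols = [s for s in design.samples_of(line, trt) if s in mat.values.columns]
            signal[(line, trt)] = float(mat.values[cols].sum().sum()) if cols else 0.0

    site_sets = {line: set(mat.values.index) for line, mat in matrices.items()}
    lines = list(site_sets)
    all_sites = set().union(*site_sets.values()) if site_sets else set()
    exclusive: dict[tuple[str, ...], int] = {}
    for site in all_sites:
        membership = tuple(line for line in lines if site in site_sets[line])
        exclusive[membership] = exclusive.get(membership, 0) + 1
    return {
        "signal": signal,
        "set_sizes": {line: len(s) for line, s in site_sets.items()},
        "exclusive_regions": exclusive,
    }
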