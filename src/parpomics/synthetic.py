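"""Synthetic multi-omics inputs with known ground truth.

Emulates the structure of the study design every pipeline stage consumes:
two parent breast-cancer cell lines with three resistant derivatives each,
three treatments (untreated, H2O2, Olaparib+H2O2), four biological
replicates per condition. Intensities are simulated on the log2 scale
(log-normal on the linear scale) and exponentiated on output.

What the generator reproduces:

* PSM-level evidence with localization probabilities drawn from a mixture
  (a well-localized Beta concentrated near 1 and an ambiguous Beta near
  0.5, so both the 0.9 identification and 0.75 quantification gates are
  exercised), decoy/contaminant records, and multi-PTM PSMs;
* treatment response of the ADPr layer — H2O2 strongly elevates signal and
  PARP-inhibitor pretreatment suppresses the induction;
* intensity-dependent missingness (missing-not-at-random): detection
  follows a logistic curve in true log2 intensity, so low-abundance
  features drop out first — the situation downshifted imputation targets;
* protein groups with resistance-associated features absent from the
  parent line (the BRCA1-reversion pattern);
* phosphopeptide tables with a small fraction of artifactual sub-unit
  intensities (log2 < 0) to exercise censoring;
* per-replicate variant tables with planted variants that satisfy, narrowly
  fail, or are disqualified from the acquisition rule;
* calibration series with blanks and internal-standard area ratios.

All draws flow from a single seed; per-layer sub-streams are derived
deterministically, so identical parameters give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_design import TREATMENTS, SampleDesign
from .metabolites import CalibrationSeries

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "default_design",
    "simulate_evidence",
    "simulate_protein_groups",
    "simulate_phospho",
    "simulate_variants",
    "simulate_calibration",
    "simulate_differential_matrix",
]

_RESIDUES = np.array(list("SRHYKE"))
_RESIDUE_PROBS = np.array([0.90, 0.04, 0.02, 0.02, 0.01, 0.01])


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults describe a realistic label-free MS experiment: log2 intensities
    around 25 +/- 2, replicate CVs around 20% (log2 sd 0.3), 5% of features
    differential between resistant and parent lines with effects around
    2 log2 units, H2O2 inducing ADPr by 5 log2 units and PARP-inhibitor
    pretreatment limiting the induction to 1.
    """

    n_features: int = 1000
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.3
    fraction_differential: float = 0.05
    effect_size_log2_mean: float = 2.0
    effect_size_log2_sd: float = 0.5
    #: additive log2 effects for (untreated, h2o2, ola_h2o2) on the ADPr layer
    treatment_multipliers: tuple[float, float, float] = (0.0, 5.0, 1.0)
    #: logistic detection curve on true log2 intensity
    missing_midpoint: float = 21.0
    missing_slope: float = 1.0
    decoy_fraction: float = 0.05
    multi_ptm_fraction: float = 0.05
    loc_well_fraction: float = 0.85
    loc_well_beta: tuple[float, float] = (40.0, 1.5)
    loc_ambiguous_beta: tuple[float, float] = (8.0, 8.0)
    #: fraction of phosphopeptide intensities replaced by sub-unit artifacts
    artifact_fraction: float = 0.02
    parent_absent_features: int = 10
    n_background_variants: int = 20
    n_acquired_variants: int = 5
    n_failing_variants: int = 3
    n_parent_carrier_variants: int = 2
    cal_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0)
    cal_noise_cv: float = 0.03
    n_blanks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_differential", "decoy_fraction", "multi_ptm_fraction",
                     "loc_well_fraction", "artifact_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_log2_sd", "replicate_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, recorded before missingness is applied."""

    group_means: pd.DataFrame | None = None  # feature x (line, treatment) true log2
    differential: dict = field(default_factory=dict)  # feature -> signed log2 effect
    well_localized: pd.Series | None = None
    acquired_variants: dict = field(default_factory=dict)  # clone -> set of keys
    calibration: dict = field(default_factory=dict)  # analyte -> (slope, intercept)
    sample_concentrations: pd.DataFrame | None = None
    parent_absent: list = field(default_factory=list)
    n_artifacts: int = 0


def default_design(
    parents: Sequence[str] = ("MDAMB436", "HCC1428"),
    n_resistant: int = 3,
    treatments: Sequence[str] = TREATMENTS,
    n_replicates: int = 4,
) -> SampleDesign:
    """The full study layout: parents + resistant derivatives x treatments x replicates."""
    samples, line, treatment, replicate = [], {}, {}, {}
    for parent in parents:
        lines = [f"{parent}_parent"] + [f"{parent}_OR{chr(65 + i)}" for i in range(n_resistant)]
        for ln in lines:
            for trt in treatments:
                for rep in range(1, n_replicates + 1):
                    s = f"{ln}.{trt}.{rep}"
                    samples.append(s)
                    line[s] = ln
                    treatment[s] = trt
                    replicate[s] = rep
    return SampleDesign(tuple(samples), line, treatment, replicate)


def _rng(params: SimulationParams, layer: int) -> np.random.Generator:
    """Deterministic per-layer sub-stream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(layer,)))


def _feature_keys(rng: np.random.Generator, n: int, prefix: str = "P") -> pd.MultiIndex:
    proteins = [f"{prefix}{i:05d}" for i in range(n)]
    positions = rng.integers(1, 1000, size=n)
    residues = rng.choice(_RESIDUES, size=n, p=_RESIDUE_PROBS)
    return pd.MultiIndex.from_arrays(
        [proteins, positions, residues], names=("protein", "position", "residue")
    )


def _true_group_means(
    rng: np.random.Generator,
    design: SampleDesign,
    params: SimulationParams,
    features: pd.Index,
    treatment_effects: bool,
) -> tuple[pd.DataFrame, dict]:
    """Per-feature true log2 mean per (line, treatment) group + differential set."""
    n = len(features)
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)
    n_diff = int(round(params.fraction_differential * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False) if n_diff else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    magnitudes = rng.normal(params.effect_size_log2_mean, params.effect_size_log2_sd, size=n_diff)
    effects = signs * np.abs(magnitudes)
    differential = {features[i]: float(e) for i, e in zip(diff_idx, effects)}

    trt_effect = dict(zip(TREATMENTS, params.treatment_multipliers))
    groups = sorted(design.condition_groups())
    means = pd.DataFrame(index=features, columns=pd.MultiIndex.from_tuples(groups), dtype=float)
    effect_vec = np.zeros(n)
    effect_vec[diff_idx] = effects
    for ln, trt in groups:
        mu = baseline.copy()
        if treatment_effects:
            mu = mu + trt_effect[trt]
        if "parent" not in ln.lower():
            mu = mu + effect_vec
        means[(ln, trt)] = mu
    return means, differential


def _observe(
    rng: np.random.Generator,
    design: SampleDesign,
    means: pd.DataFrame,
    params: SimulationParams,
    apply_missingness: bool = True,
) -> pd.DataFrame:
    """Noisy per-sample log2 values with logistic MNAR dropout (NaN = missing)."""
    n = len(means)
    out = pd.DataFrame(index=means.index, columns=list(design.samples), dtype=float)
    for s in design.samples:
        mu = means[(design.line[s], design.treatment[s])].to_numpy()
        x = mu + rng.normal(0.0, params.replicate_noise_sd, size=n)
        if apply_missingness:
            p_detect = 1.0 / (1.0 + np.exp(-(x - params.missing_midpoint) / params.missing_slope))
            detected = rng.random(n) < p_detect
            x = np.where(detected, x, np.nan)
        out[s] = x
    return out


def simulate_evidence(
    design: SampleDesign, params: SimulationParams = SimulationParams()
) -> tuple[pd.DataFrame, GroundTruth]:
    """PSM-level ADPr evidence records with planted ground truth.

    One main PSM per detected feature x sample; localization probability is
    a per-feature property (well-localized vs ambiguous mixture). Decoy
    features (reverse/contaminant) and multi-PTM PSMs are added on top.
    """
    if len(design.condition_groups()) < 2:
        raise ValueError("design must define at least 2 groups")
    rng = _rng(params, layer=1)
    features = _feature_keys(rng, params.n_features)
    means, differential = _true_group_means(rng, design, params, features, treatment_effects=True)
    observed = _observe(rng, design, means, params)

    well = pd.Series(rng.random(params.n_features) < params.loc_well_fraction, index=features)
    a_w, b_w = params.loc_well_beta
    a_a, b_a = params.loc_ambiguous_beta

    rows = []
    for fi, key in enumerate(features):
        protein, position, residue = key
        peptide = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
        for s in design.samples:
            x = observed.at[key, s]
            if np.isnan(x):
                continue
            loc = rng.beta(a_w, b_w) if well.iloc[fi] else rng.beta(a_a, b_a)
            rows.append(
                (peptide, protein, int(position), residue, 1, float(loc), s,
                 float(2.0**x), False, False)
            )
            if rng.random() < params.multi_ptm_fraction:
                rows.append(
                    (peptide, protein, int(position), residue, 2,
                     float(rng.beta(a_w, b_w)), s, float(2.0 ** (x - 1)), False, False)
                )
    n_decoys = int(round(params.decoy_fraction * params.n_features))
    for di in range(n_decoys):
        is_rev = di % 2 == 0
        prefix = "REV__Q" if is_rev else "CON__Q"
        s = design.samples[int(rng.integers(len(design.samples)))]
        rows.append(
            (
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10)),
                f"{prefix}{di:05d}", int(rng.integers(1, 500)), "S", 1,
                float(rng.beta(a_w, b_w)), s, float(2.0 ** rng.normal(22, 2)),
                is_rev, not is_rev,
            )
        )
    evidence = pd.DataFrame(
        rows,
        columns=["peptide", "protein", "position", "residue", "n_ptm",
                 "localization_prob", "sample", "intensity",
                 "is_reverse", "is_contaminant"],
    )
    evidence["localization_prob"] = evidence["localization_prob"].clip(0.0, 1.0)
    truth = GroundTruth(group_means=means, differential=differential, well_localized=well)
    return evidence, truth


def simulate_protein_groups(
    design: SampleDesign, params: SimulationParams = SimulationParams()
) -> tuple[pd.DataFrame, GroundTruth]:
    """Protein-groups table with LFQ columns; 0 means not quantified.

    ``params.parent_absent_features`` features mimic the reversion pattern:
    no quantification in any parent-line replicate, quantified in resistant
    lines.
    """
    rng = _rng(params, layer=2)
    n = params.n_features
    features = pd.Index([f"PG{i:05d}" for i in range(n)], name="protein")
    means, differential = _true_group_means(rng, design, params, features, treatment_effects=False)
    observed = _observe(rng, design, means, params)

    parent_samples = [s for s in design.samples if "parent" in design.line[s].lower()]
    other_samples = [s for s in design.samples if s not in parent_samples]
    n_absent = min(params.parent_absent_features, n)
    absent_idx = rng.choice(n, size=n_absent, replace=False) if n_absent else np.array([], int)
    for i in absent_idx:
        observed.loc[observed.index[i], parent_samples] = np.nan
        # guarantee presence in resistant lines so the pattern is detectable
        redraw = means.loc[observed.index[i]].max() + rng.normal(
            0.0, params.replicate_noise_sd, size=len(other_samples)
        )
        observed.loc[observed.index[i], other_samples] = redraw

    table = pd.DataFrame(
        {
            "protein_group": features,
            "gene": [f"GENE{i}" for i in range(n)],
            "is_reverse": False,
            "is_contaminant": False,
            "only_identified_by_site": False,
        }
    )
    n_decoys = int(round(params.decoy_fraction * n))
    decoys = pd.DataFrame(
        {
            "protein_group": [f"DECOY{i:05d}" for i in range(n_decoys)],
            "gene": "",
            "is_reverse": [i % 3 == 0 for i in range(n_decoys)],
            "is_contaminant": [i % 3 == 1 for i in range(n_decoys)],
            "only_identified_by_site": [i % 3 == 2 for i in range(n_decoys)],
        }
    )
    table = pd.concat([table, decoys], ignore_index=True)
    for s in design.samples:
        col = np.zeros(len(table))
        present = observed[s].to_numpy()
        vals = np.where(np.isnan(present), 0.0, 2.0**present)
        col[: len(vals)] = vals
        col[len(vals):] = 2.0 ** rng.normal(22, 2, size=n_decoys)
        table[f"lfq_{s}"] = col
    truth = GroundTruth(
        group_means=means,
        differential=differential,
        parent_absent=[features[i] for i in absent_idx],
    )
    return table, truth


def simulate_phospho(
    design: SampleDesign, params: SimulationParams = SimulationParams()
) -> tuple[pd.DataFrame, GroundTruth]:
    """Phosphopeptide quantification table (one row per peptide x sample).

    A fraction ``artifact_fraction`` of present intensities is replaced by a
    sub-unit linear value (log2 < 0), emulating artifactual quantifications
    that the censoring step removes.
    """
    rng = _rng(params, layer=3)
    # protein ids share the protein-group namespace so phosphosites can be
    # joined to protein-level results downstream
    features = _feature_keys(rng, params.n_features, prefix="PG")
    means, differential = _true_group_means(rng, design, params, features, treatment_effects=False)
    observed = _observe(rng, design, means, params)
    well = pd.Series(rng.random(params.n_features) < params.loc_well_fraction, index=features)
    a_w, b_w = params.loc_well_beta
    a_a, b_a = params.loc_ambiguous_beta

    rows = []
    n_artifacts = 0
    for fi, key in enumerate(features):
        protein, position, residue = key
        for s in design.samples:
            x = observed.at[key, s]
            if np.isnan(x):
                continue
            if rng.random() < params.artifact_fraction:
                intensity = float(rng.uniform(0.01, 0.99))  # log2 < 0
                n_artifacts += 1
            else:
                intensity = float(2.0**x)
            loc = rng.beta(a_w, b_w) if well.iloc[fi] else rng.beta(a_a, b_a)
            rows.append((protein, int(position), residue, float(loc), s, intensity))
    table = pd.DataFrame(
        rows,
        columns=["protein", "position", "residue", "localization_prob", "sample", "intensity"],
    )
    truth = GroundTruth(
        group_means=means, differential=differential,
        well_localized=well, n_artifacts=n_artifacts,
    )
    return table, truth


def _variant_row(chrom: str, pos: int, ref: str, alt: str, alt_depth: int) -> dict:
    total = alt_depth + 20
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "alt_depth": alt_depth, "total_depth": total, "annotation": "synthetic",
    }


def simulate_variants(
    design: SampleDesign, params: SimulationParams = SimulationParams()
) -> tuple[dict[str, dict[str, pd.DataFrame]], GroundTruth]:
    """Per-replicate variant tables for every cell line (untreated samples).

    Planted per clone: variants satisfying the acquisition rule (alt depth
    >= 2 in >= 3 clone replicates, absent from every parent replicate),
    variants narrowly failing it (only 2 supporting replicates), variants
    disqualified by a single parent carrier, and shared background variants
    present everywhere. Returns ``{line: {replicate_sample: table}}``.
    """
    rng = _rng(params, layer=4)
    bases = np.array(list("ACGT"))
    lines = design.lines
    parents = [ln for ln in lines if "parent" in ln.lower()]
    if not parents:
        raise ValueError("design has no parent line")

    def new_key(i: int) -> tuple[str, int, str, str]:
        ref, alt = rng.choice(bases, size=2, replace=False)
        return (f"chr{1 + i % 22}", int(rng.integers(1, 10_000_000)), str(ref), str(alt))

    background = [new_key(i) for i in range(params.n_background_variants)]
    per_line_rows: dict[str, dict[str, list[dict]]] = {
        ln: {s: [] for s in design.samples_of(ln, "untreated")} for ln in lines
    }
    for ln in lines:
        for s, rows in per_line_rows[ln].items():
            for key in background:
                rows.append(_variant_row(*key, alt_depth=int(rng.integers(5, 40))))

    acquired: dict[str, set] = {}
    ki = len(background)
    for parent in parents:
        stem = parent.rsplit("_", 1)[0]
        clones = [ln for ln in lines if ln.startswith(stem) and ln != parent]
        for clone in clones:
            clone_samples = list(per_line_rows[clone])
            acquired[clone] = set()
            for _ in range(params.n_acquired_variants):
                key = new_key(ki); ki += 1
                n_sup = int(rng.integers(3, len(clone_samples) + 1))
                chosen = rng.choice(len(clone_samples), size=n_sup, replace=False)
                for ci in chosen:
                    per_line_rows[clone][clone_samples[ci]].append(
                        _variant_row(*key, alt_depth=int(rng.integers(2, 30)))
                    )
                acquired[clone].add(key)
            for _ in range(params.n_failing_variants):
                key = new_key(ki); ki += 1
                chosen = rng.choice(len(clone_samples), size=2, replace=False)
                for ci in chosen:
                    per_line_rows[clone][clone_samples[ci]].append(
                        _variant_row(*key, alt_depth=int(rng.integers(2, 30)))
                    )
            parent_samples = list(per_line_rows[parent])
            for _ in range(params.n_parent_carrier_variants):
                key = new_key(ki); ki += 1
                chosen = rng.choice(len(clone_samples), size=3, replace=False)
                for ci in chosen:
                    per_line_rows[clone][clone_samples[ci]].append(
                        _variant_row(*key, alt_depth=int(rng.integers(2, 30)))
                    )
                carrier = parent_samples[int(rng.integers(len(parent_samples)))]
                per_line_rows[parent][carrier].append(_variant_row(*key, alt_depth=2))

    tables = {
        ln: {
            s: pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "alt_depth", "total_depth", "annotation"])
            for s, rows in reps.items()
        }
        for ln, reps in per_line_rows.items()
    }
    truth = GroundTruth(acquired_variants=acquired)
    return tables, truth


def simulate_calibration(
    analytes: Sequence[str] = ("NAD", "NADH", "NAM", "NR", "ADPR"),
    params: SimulationParams = SimulationParams(),
    n_samples: int = 8,
) -> tuple[dict[str, CalibrationSeries], pd.DataFrame, GroundTruth]:
    """Calibration series with blanks plus sample area ratios per analyte.

    True response is linear through the origin with a per-analyte slope;
    multiplicative noise at ``cal_noise_cv`` (0 gives exact lines). Returns
    ``(series per analyte, sample ratio table, ground truth)``.
    """
    rng = _rng(params, layer=5)
    levels = np.asarray(params.cal_levels, dtype=float)
    series: dict[str, CalibrationSeries] = {}
    samples = [f"sample{i+1}" for i in range(n_samples)]
    ratio_rows = {}
    true_conc = {}
    truth = GroundTruth()
    for analyte in analytes:
        slope = float(rng.uniform(0.5, 5.0))
        noise = rng.normal(0.0, params.cal_noise_cv, size=len(levels)) if params.cal_noise_cv > 0 else 0.0
        ratios = slope * levels * (1.0 + noise)
        blank_sd = slope * levels[min(2, len(levels) - 1)] / 10.0
        blanks = rng.normal(0.0, blank_sd, size=params.n_blanks)
        series[analyte] = CalibrationSeries(
            analyte=analyte, concentrations=levels, ratios=ratios, blanks=blanks
        )
        conc = np.exp(rng.uniform(np.log(levels[1]), np.log(levels[-2]), size=n_samples))
        ratio_rows[analyte] = slope * conc
        true_conc[analyte] = conc
        truth.calibration[analyte] = (slope, 0.0)
    sample_ratios = pd.DataFrame(ratio_rows, index=samples)
    truth.sample_concentrations = pd.DataFrame(true_conc, index=samples)
    return series, sample_ratios, truth


def simulate_differential_matrix(
    n_features: int = 1000,
    n_per_group: int = 4,
    fraction_differential: float = 0.05,
    effect_log2: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str], set[str]]:
    """Two-group log2 matrix with a known differential subset, no missingness.

    The default conditions match the study layout used to validate the
    differential pipeline: 1000 features, 4 vs 4 replicates, 5% of features
    shifted by 2 log2 units. Returns (matrix, group_a, group_b, truth set).
    """
    rng = np.random.default_rng(seed)
    features = [f"F{i:05d}" for i in range(n_features)]
    group_a = [f"a{i+1}" for i in range(n_per_group)]
    group_b = [f"b{i+1}" for i in range(n_per_group)]
    baseline = rng.normal(25.0, 2.0, size=n_features)
    n_diff = int(round(fraction_differential * n_features))
    diff_idx = rng.choice(n_features, size=n_diff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    shift = np.zeros(n_features)
    shift[diff_idx] = signs * effect_log2
    data = {}
    for s in group_a:
        data[s] = baseline + shift + rng.normal(0.0, noise_sd, size=n_features)
    for s in group_b:
        data[s] = baseline + rng.normal(0.0, noise_sd, size=n_features)
    matrix = pd.DataFrame(data, index=pd.Index(features, name="feature"))
    return matrix, group_a, group_b, {features[i] for i in diff_idx}
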