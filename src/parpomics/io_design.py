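"""Tabular I/O and experimental-design validation.

All tabular input/output is UTF-8 TSV. Default column names follow MaxQuant
conventions but every reader accepts a *dialect* mapping from canonical field
names to file column names, because the upstream search engines (two MaxQuant
versions, Spectronaut, Skyline) name columns differently.

Conventions enforced at this layer:

* protein positions are 1-based inclusive;
* decoy/contaminant flags are ``"+"``/empty in the MaxQuant dialect and are
  parsed to booleans;
* absent intensities stay absent (NaN) — readers never coerce missing to 0
  and never coerce 0 to missing; that semantic decision belongs downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "FormatError",
    "RecordError",
    "SampleDesign",
    "parse_design",
    "EVIDENCE_COLUMNS",
    "MAXQUANT_EVIDENCE_DIALECT",
    "read_evidence",
    "write_evidence",
    "read_protein_groups",
    "read_variant_tables",
    "read_vcf",
    "read_fasta",
]

TREATMENTS = ("untreated", "h2o2", "ola_h2o2")


class DesignError(ValueError):
    """Raised when the sample design is inconsistent."""


class FormatError(ValueError):
    """Raised when a table lacks a mandatory column or cannot be parsed."""


class RecordError(ValueError):
    """Raised when an individual record violates an invariant."""


@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample to a (cell line, treatment, replicate) triple.

    Groups used by downstream filters are derived here:
    ``condition_groups`` pools by cell line x treatment (PTM layers) and
    ``line_groups`` pools by cell line only (proteome layer).
    """

    samples: tuple[str, ...]
    line: Mapping[str, str]
    treatment: Mapping[str, str]
    replicate: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.samples:
            raise DesignError("design contains no samples")
        seen: set[tuple[str, str, int]] = set()
        for s in self.samples:
            trt = self.treatment[s]
            if trt not in TREATMENTS:
                raise DesignError(
                    f"unknown treatment {trt!r} for sample {s!r}; "
                    f"expected one of {TREATMENTS}"
                )
            triple = (self.line[s], trt, int(self.replicate[s]))
            if triple in seen:
                raise DesignError(f"duplicate (line, treatment, replicate) triple {triple}")
            seen.add(triple)

    @property
    def lines(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.samples:
            if self.line[s] not in out:
                out.append(self.line[s])
        return tuple(out)

    def condition_groups(self) -> dict[tuple[str, str], list[str]]:
        """Samples grouped by (cell line, treatment)."""
        groups: dict[tuple[str, str], list[str]] = {}
        for s in self.samples:
            groups.setdefault((self.line[s], self.treatment[s]), []).append(s)
        return groups

    def line_groups(self) -> dict[str, list[str]]:
        """Samples grouped by cell line, all treatments pooled."""
        groups: dict[str, list[str]] = {}
        for s in self.samples:
            groups.setdefault(self.line[s], []).append(s)
        return groups

    def samples_of(self, line: str, treatment: str | None = None) -> list[str]:
        return [
            s
            for s in self.samples
            if self.line[s] == line and (treatment is None or self.treatment[s] == treatment)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.samples),
                "line": [self.line[s] for s in self.samples],
                "treatment": [self.treatment[s] for s in self.samples],
                "replicate": [self.replicate[s] for s in self.samples],
            }
        )


def parse_design(source: str | Path | pd.DataFrame) -> SampleDesign:
    """Read and validate a sample-design table.

    The table needs one row per sample with columns ``sample``, ``line``,
    ``treatment`` and ``replicate``. Duplicate (line, treatment, replicate)
    triples and unknown treatment labels are rejected.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"sample", "line", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    if df.empty:
        raise DesignError("design table has no rows")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise DesignError(f"duplicate sample identifiers: {dups}")
    samples = tuple(df["sample"].astype(str))
    return SampleDesign(
        samples=samples,
        line=dict(zip(samples, df["line"].astype(str))),
        treatment=dict(zip(samples, df["treatment"].astype(str))),
        replicate=dict(zip(samples, df["replicate"].astype(int))),
    )


# ---------------------------------------------------------------------------
# Evidence tables (PSM-level records)
# ---------------------------------------------------------------------------

#: canonical evidence columns, one record per PSM x sample
EVIDENCE_COLUMNS = (
    "peptide",
    "protein",
    "position",
    "residue",
    "n_ptm",
    "localization_prob",
    "sample",
    "intensity",
    "is_reverse",
    "is_contaminant",
)

#: default dialect: canonical name -> MaxQuant-style column header
MAXQUANT_EVIDENCE_DIALECT: dict[str, str] = {
    "peptide": "Sequence",
    "protein": "Proteins",
    "position": "Position",
    "residue": "Amino acid",
    "n_ptm": "Modification count",
    "localization_prob": "Localization prob",
    "sample": "Experiment",
    "intensity": "Intensity",
    "is_reverse": "Reverse",
    "is_contaminant": "Potential contaminant",
}


def _parse_flag(col: pd.Series) -> pd.Series:
    """MaxQuant marks decoy/contaminant rows with '+'; anything else is False."""
    return col.fillna("").astype(str).str.strip().eq("+")


def read_evidence(
    path: str | Path | io.StringIO,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a PSM-level evidence table into canonical form.

    Returns a DataFrame with :data:`EVIDENCE_COLUMNS`; missing intensity
    cells become NaN (absent), never 0.
    """
    dialect = dict(dialect or MAXQUANT_EVIDENCE_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    missing = [dialect[c] for c in EVIDENCE_COLUMNS if dialect[c] not in df.columns]
    if missing:
        raise FormatError(f"evidence table missing mandatory columns: {missing}")
    out = pd.DataFrame(
        {canon: df[dialect[canon]] for canon in EVIDENCE_COLUMNS}
    )
    out["peptide"] = out["peptide"].astype(str).str.upper()
    out["protein"] = out["protein"].astype(str)
    out["position"] = out["position"].astype(int)
    out["residue"] = out["residue"].astype(str)
    out["n_ptm"] = out["n_ptm"].astype(int)
    out["localization_prob"] = out["localization_prob"].astype(float)
    out["sample"] = out["sample"].astype(str)
    # exact float conversion (round-trips to_csv output bit-for-bit)
    out["intensity"] = out["intensity"].map(
        lambda v: np.nan if pd.isna(v) or str(v).strip() == "" else float(v)
    )
    out["is_reverse"] = _parse_flag(out["is_reverse"])
    out["is_contaminant"] = _parse_flag(out["is_contaminant"])
    _validate_evidence(out)
    return out


def _validate_evidence(df: pd.DataFrame) -> None:
    if ((df["localization_prob"] < 0) | (df["localization_prob"] > 1)).any():
        raise RecordError("localization probability outside [0, 1]")
    if (df["intensity"].dropna() < 0).any():
        raise RecordError("negative intensity")
    if (df["position"] < 1).any():
        raise RecordError("site position must be >= 1")


def write_evidence(
    df: pd.DataFrame,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write an evidence table in the canonical (MaxQuant-like) dialect."""
    dialect = dict(dialect or MAXQUANT_EVIDENCE_DIALECT)
    out = pd.DataFrame()
    for canon in EVIDENCE_COLUMNS:
        col = df[canon]
        if canon in ("is_reverse", "is_contaminant"):
            col = col.map(lambda v: "+" if v else "")
        out[dialect[canon]] = col
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein-group tables
# ---------------------------------------------------------------------------

PROTEIN_GROUP_DIALECT: dict[str, str] = {
    "protein_group": "Protein IDs",
    "gene": "Gene names",
    "is_reverse": "Reverse",
    "is_contaminant": "Potential contaminant",
    "only_identified_by_site": "Only identified by site",
}
LFQ_PREFIX = "LFQ intensity "


def read_protein_groups(
    path: str | Path | io.StringIO,
    dialect: Mapping[str, str] | None = None,
    lfq_prefix: str = LFQ_PREFIX,
) -> pd.DataFrame:
    """Read a proteinGroups-style table.

    Output columns: ``protein_group``, ``gene``, the three boolean flags, and
    one ``lfq_<sample>`` column per sample, linear scale, 0 meaning not
    quantified (MaxQuant convention; the 0 -> missing conversion happens in
    the proteome cleaning step, not here).
    """
    dialect = dict(dialect or PROTEIN_GROUP_DIALECT)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in dialect.values() if v not in df.columns]
    if missing:
        raise FormatError(f"protein-groups table missing mandatory columns: {missing}")
    lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise FormatError(f"no per-sample columns with prefix {lfq_prefix!r}")
    out = pd.DataFrame(
        {
            "protein_group": df[dialect["protein_group"]].astype(str),
            "gene": df[dialect["gene"]].fillna("").astype(str),
            "is_reverse": _parse_flag(df[dialect["is_reverse"]]),
            "is_contaminant": _parse_flag(df[dialect["is_contaminant"]]),
            "only_identified_by_site": _parse_flag(df[dialect["only_identified_by_site"]]),
        }
    )
    if out["protein_group"].duplicated().any():
        raise RecordError("protein-group identifiers are not unique")
    for c in lfq_cols:
        sample = c[len(lfq_prefix):]
        vals = pd.to_numeric(df[c], errors="coerce").fillna(0.0)
        if (vals < 0).any():
            raise RecordError(f"negative LFQ intensity in column {c!r}")
        out[f"lfq_{sample}"] = vals
    return out


def write_protein_groups(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame()
    out[PROTEIN_GROUP_DIALECT["protein_group"]] = df["protein_group"]
    out[PROTEIN_GROUP_DIALECT["gene"]] = df["gene"]
    for flag in ("is_reverse", "is_contaminant", "only_identified_by_site"):
        out[PROTEIN_GROUP_DIALECT[flag]] = df[flag].map(lambda v: "+" if v else "")
    for c in df.columns:
        if c.startswith("lfq_"):
            out[LFQ_PREFIX + c[len("lfq_"):]] = df[c]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "alt_depth", "total_depth", "annotation")


def _normalize_variants(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    df["ref"] = df["ref"].astype(str).str.upper()
    df["alt"] = df["alt"].astype(str).str.upper()
    df["alt_depth"] = df["alt_depth"].astype(int)
    df["total_depth"] = df["total_depth"].astype(int)
    df["annotation"] = df.get("annotation", pd.Series([""] * len(df))).fillna("").astype(str)
    bad = df["alt_depth"] > df["total_depth"]
    if bad.any():
        rows = df.index[bad].tolist()
        raise RecordError(f"{origin}: alt_depth exceeds total_depth at rows {rows}")
    if (df["alt_depth"] < 0).any():
        raise RecordError(f"{origin}: negative alt_depth")
    return df[list(VARIANT_COLUMNS)]


def read_variant_tables(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read one TSV variant table per sample, keyed by sample identifier.

    Alleles are normalized to uppercase so the variant key
    (chrom, pos, ref, alt) is consistent across samples.
    """
    tables: dict[str, pd.DataFrame] = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "annotation"]
        if missing:
            raise FormatError(f"variant table {path}: missing columns {missing}")
        tables[sample] = _normalize_variants(df, str(path))
    return tables


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(VARIANT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Thin VCF 4.x reader producing a variant table for one sample.

    Only CHROM/POS/REF/ALT and the per-sample AD (allelic depth) field are
    consumed; multi-allelic records are split into one row per alternate
    allele. Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        if len(vcf.samples) != 1:
            raise FormatError(
                f"{path}: VCF has {len(vcf.samples)} samples; specify which one"
            )
        sample = vcf.samples[0]
    try:
        si = vcf.samples.index(sample)
    except ValueError:
        raise FormatError(f"{path}: sample {sample!r} not in VCF") from None
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        depths = ad[si] if ad is not None else None
        for ai, alt in enumerate(rec.ALT):
            alt_depth = int(depths[ai + 1]) if depths is not None and len(depths) > ai + 1 else 0
            total = int(np.sum(np.clip(depths, 0, None))) if depths is not None else 0
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "alt_depth": max(alt_depth, 0),
                    "total_depth": total,
                    "annotation": "",
                }
            )
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    return _normalize_variants(df, str(path)) if len(df) else df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
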