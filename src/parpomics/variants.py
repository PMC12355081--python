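"""Acquired-variant selection in resistant clones.

A variant is *present* in a replicate when a record with its key
(chromosome, position, ref, alt) exists with alternate-allele depth at or
above ``min_alt_depth`` (default 2). A variant is *acquired* in a clone when
it is present in at least ``min_clone_reps`` clone replicates (default 3)
and present in zero parent replicates. "Absent in parent" is depth-gated by
default — a parent record below the depth threshold still counts as absent;
``parent_absence="strict"`` requires no parent record at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

__all__ = ["VariantFilterParams", "call_acquired"]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantFilterParams:
    min_alt_depth: int = 2
    min_clone_reps: int = 3
    parent_absence: Literal["depth", "strict"] = "depth"

    def __post_init__(self) -> None:
        if self.min_alt_depth < 1 or self.min_clone_reps < 1:
            raise ValueError("min_alt_depth and min_clone_reps must be >= 1")


def _keyed_depths(table: pd.DataFrame) -> dict[VariantKey, int]:
    """Max alt depth per variant key in one replicate table."""
    out: dict[VariantKey, int] = {}
    for row in table.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = max(out.get(key, 0), int(row.alt_depth))
    return out


def call_acquired(
    clone_tables: Mapping[str, pd.DataFrame],
    parent_tables: Mapping[str, pd.DataFrame],
    params: VariantFilterParams = VariantFilterParams(),
) -> pd.DataFrame:
    """Variants acquired in a clone relative to its parent line.

    Returns one row per acquired variant with the supporting clone
    replicates and their depths.
    """
    if not clone_tables:
        raise ValueError("need at least one clone replicate table")
    if not parent_tables:
        raise ValueError("need at least one parent replicate table")
    clone_depths = {rep: _keyed_depths(t) for rep, t in clone_tables.items()}
    parent_depths = {rep: _keyed_depths(t) for rep, t in parent_tables.items()}

    candidates: set[VariantKey] = set()
    for depths in clone_depths.values():
        candidates.update(depths)

    rows = []
    for key in sorted(candidates):
        support = {
            rep: depths[key]
            for rep, depths in clone_depths.items()
            if depths.get(key, 0) >= params.min_alt_depth
        }
        if len(support) < params.min_clone_reps:
            continue
        if params.parent_absence == "depth":
            in_parent = any(
                depths.get(key, 0) >= params.min_alt_depth
                for depths in parent_depths.values()
            )
        else:
            in_parent = any(key in depths for depths in parent_depths.values())
        if in_parent:
            continue
        chrom, pos, ref, alt = key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "n_supporting_reps": len(support),
                "supporting_reps": ",".join(sorted(support)),
                "supporting_depths": ",".join(str(support[r]) for r in sorted(support)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "n_supporting_reps",
            "supporting_reps",
            "supporting_depths",
        ],
    )
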