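"""Site-table construction, replicate filter, residue and overlap summaries."""

import numpy as np
import pandas as pd
import pytest

from parpomics.adpr import (
    SiteFilterParams,
    SiteMatrix,
    build_site_table,
    filter_min_replicates,
    residue_distribution,
    signal_and_overlap_summary,
)
from tests.conftest import random_evidence


def brute_force_site_table(evidence, design, params):
    """Independent re-statement of the six site-table rules with plain loops."""
    records = [
        r
        for r in evidence.to_dict("records")
        if not r["is_reverse"]
        and not r["is_contaminant"]
        and r["n_ptm"] == 1
    ]
    features = {}
    for r in records:
        key = (r["protein"], r["position"], r["residue"])
        features.setdefault(key, []).append(r)
    out = {}
    for key, recs in features.items():
        best = max(r["localization_prob"] for r in recs)
        if not best > params.loc_id:
            continue
        per_sample = {}
        for r in recs:
            if r["localization_prob"] > params.loc_quant and not np.isnan(r["intensity"]):
                per_sample[r["sample"]] = per_sample.get(r["sample"], 0.0) + r["intensity"]
        out[key] = (best, per_sample)
    return out


def make_evidence(rows):
    cols = ["peptide", "protein", "position", "residue", "n_ptm",
            "localization_prob", "sample", "intensity", "is_reverse", "is_contaminant"]
    return pd.DataFrame(rows, columns=cols)


class TestBuildSiteTable:
    def test_worked_five_record_example(self, design_2x2):
        """One site: loc .95/int 100 and loc .80/int 50 pass the quant gate and
        sum to 150; loc .50 fails it; decoy and doubly modified PSMs drop."""
        rows = [
            ("PEP", "P1", 10, "S", 1, 0.95, "parent.r1", 100.0, False, False),
            ("PEP", "P1", 10, "S", 1, 0.80, "parent.r1", 50.0, False, False),
            ("PEP", "P1", 10, "S", 1, 0.50, "parent.r1", 70.0, False, False),
            ("PEP", "P1", 10, "S", 1, 0.99, "parent.r1", 10.0, True, False),
            ("PEP", "P1", 10, "S", 2, 0.99, "parent.r1", 10.0, False, False),
        ]
        mat = build_site_table(make_evidence(rows), design_2x2)
        assert len(mat) == 1
        assert mat.values.loc[("P1", 10, "S"), "parent.r1"] == 150.0

    def test_identification_gate_is_strict(self, design_2x2):
        rows = [("PEP", "P1", 10, "S", 1, 0.9, "parent.r1", 100.0, False, False)]
        assert len(build_site_table(make_evidence(rows), design_2x2)) == 0

    def test_empty_evidence_gives_empty_matrix(self, design_2x2):
        mat = build_site_table(make_evidence([]), design_2x2)
        assert len(mat) == 0
        assert mat.samples == list(design_2x2.samples)

    def test_unknown_sample_rejected(self, design_2x2):
        rows = [("PEP", "P1", 10, "S", 1, 0.95, "nope", 100.0, False, False)]
        with pytest.raises(ValueError, match="nope"):
            build_site_table(make_evidence(rows), design_2x2)

    def test_order_invariance(self, design_2x2):
        rng = np.random.default_rng(11)
        ev = random_evidence(rng, 40)
        a = build_site_table(ev, design_2x2)
        b = build_site_table(ev.sample(frac=1.0, random_state=1), design_2x2)
        pd.testing.assert_frame_equal(a.values, b.values)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, design_2x2, seed):
        rng = np.random.default_rng(seed)
        ev = random_evidence(rng, int(rng.integers(1, 51)))
        params = SiteFilterParams()
        mat = build_site_table(ev, design_2x2, params)
        expected = brute_force_site_table(ev, design_2x2, params)
        assert set(mat.values.index) == set(expected)
        for key, (best, per_sample) in expected.items():
            assert mat.best_localization[key] == pytest.approx(best)
            for s in design_2x2.samples:
                got = mat.values.loc[key, s]
                if s in per_sample:
                    assert got == pytest.approx(per_sample[s])
                else:
                    assert np.isnan(got)

    def test_gate_monotonicity(self, design_2x2):
        rng = np.random.default_rng(5)
        ev = random_evidence(rng, 50)
        lo = build_site_table(ev, design_2x2, SiteFilterParams(loc_id=0.9, loc_quant=0.5))
        hi = build_site_table(ev, design_2x2, SiteFilterParams(loc_id=0.95, loc_quant=0.8))
        assert len(hi) <= len(lo)
        common = hi.values.index.intersection(lo.values.index)
        diff = lo.values.loc[common].fillna(0) - hi.values.loc[common].fillna(0)
        assert (diff >= -1e-9).all().all()


class TestReplicateFilter:
    def _matrix(self, rows, design):
        idx = pd.MultiIndex.from_tuples(
            [(f"P{i}", 1, "S") for i in range(len(rows))],
            names=("protein", "position", "residue"),
        )
        return pd.DataFrame(rows, index=idx, columns=list(design.samples), dtype=float)

    def test_boundary_three_of_four_kept(self, design_2x2):
        row = [1.0, 1.0, 1.0, np.nan, np.nan, np.nan, np.nan, np.nan]
        out = filter_min_replicates(self._matrix([row], design_2x2), design_2x2, 3)
        assert len(out) == 1

    def test_two_everywhere_removed(self, design_2x2):
        row = [1.0, 1.0, np.nan, np.nan, 1.0, 1.0, np.nan, np.nan]
        out = filter_min_replicates(self._matrix([row], design_2x2), design_2x2, 3)
        assert len(out) == 0

    def test_matches_brute_force_rule(self, design_2x2):
        rng = np.random.default_rng(3)
        rows = np.where(rng.random((10, 8)) < 0.5, 1.0, np.nan)
        mat = self._matrix(list(rows), design_2x2)
        out = filter_min_replicates(mat, design_2x2, 3)
        groups = design_2x2.condition_groups()
        expected = [
            any(
                sum(not np.isnan(mat.loc[f, s]) for s in members) >= 3
                for members in groups.values()
            )
            for f in mat.index
        ]
        assert list(mat.index[expected]) == list(out.index)

    def test_min_reps_above_group_size_warns(self, design_2x2):
        mat = self._matrix([[1.0] * 8], design_2x2)
        with pytest.warns(UserWarning, match="largest group"):
            out = filter_min_replicates(mat, design_2x2, 5)
        assert len(out) == 0


class TestSummaries:
    def _site_matrix(self, keys, design, fill=1.0):
        if keys:
            idx = pd.MultiIndex.from_tuples(keys, names=("protein", "position", "residue"))
        else:
            idx = pd.MultiIndex.from_arrays(
                [[], [], []], names=("protein", "position", "residue")
            )
        vals = pd.DataFrame(fill, index=idx, columns=list(design.samples))
        return SiteMatrix(values=vals, best_localization=pd.Series(0.99, index=idx))

    def test_residue_distribution_counts(self, design_2x2):
        keys = [(f"P{i}", 1, "S") for i in range(9)] + [("P9", 1, "R")]
        dist = residue_distribution(self._site_matrix(keys, design_2x2))
        assert dist == {"S": pytest.approx(0.9), "R": pytest.approx(0.1)}

    def test_residue_distribution_sums_to_one(self, design_2x2):
        rng = np.random.default_rng(1)
        keys = [(f"P{i}", 1, str(rng.choice(list("SRYHK")))) for i in range(20)]
        dist = residue_distribution(self._site_matrix(keys, design_2x2))
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_matrix_empty_distribution(self, design_2x2):
        assert residue_distribution(self._site_matrix([], design_2x2)) == {}

    def test_overlap_enumeration(self, design_2x2):
        a = self._site_matrix([("A", 1, "S"), ("B", 1, "S"), ("C", 1, "S")], design_2x2)
        b = self._site_matrix([("B", 1, "S"), ("C", 1, "S"), ("D", 1, "S")], design_2x2)
        summary = signal_and_overlap_summary({"parent": a, "ORA": b}, design_2x2)
        regions = summary["exclusive_regions"]
        assert regions[("parent",)] == 1
        assert regions[("ORA",)] == 1
        assert regions[("parent", "ORA")] == 2

    def test_identical_sets_fully_shared(self, design_2x2):
        keys = [("A", 1, "S"), ("B", 2, "S")]
        summary = signal_and_overlap_summary(
            {"parent": self._site_matrix(keys, design_2x2),
             "ORA": self._site_matrix(keys, design_2x2)},
            design_2x2,
        )
        assert summary["exclusive_regions"] == {("parent", "ORA"): 2}

    def test_sum_over_all_missing_is_zero(self, design_2x2):
        mat = self._site_matrix([("A", 1, "S")], design_2x2, fill=np.nan)
        summary = signal_and_overlap_summary({"parent": mat}, design_2x2)
        assert all(v == 0.0 for v in summary["signal"].values())
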