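import numpy as np
import pandas as pd
import pytest

from posestab.consistency import (
    ConsistencyConfig,
    analyze,
    compound_descriptor_std,
    fit_standardization,
    rotbond_correlation,
    select_top_k,
    summarize_groups,
)
from posestab.model import PoseEnsemble
from posestab.synthetic import SyntheticSpec, make_benchmark_dataset

from .conftest import build_molecule


def toy_ensemble(n_poses, scores=None):
    mol = build_molecule(
        "CCO", [(0, 0, 0), (1.5, 0, 0), (2.1, 1.3, 0)], [(0, 1, 1), (1, 2, 1)], "t"
    )
    poses = [mol.coords + [0, 0, 0.1 * p] for p in range(n_poses)]
    return PoseEnsemble(mol, poses, scores or [float(p) for p in range(n_poses)])


class TestSelectTopK:
    def test_keeps_k_best_by_score(self):
        ens = toy_ensemble(10, scores=[5, 3, 8, 1, 9, 2, 7, 0, 6, 4.0])
        sel = select_top_k(ens, 3)
        assert sorted(sel.docking_scores) == [0.0, 1.0, 2.0]
        assert sel.skip_reason is None

    def test_truncation_when_fewer_available(self):
        sel = select_top_k(toy_ensemble(2), 5)
        assert sel.n_poses == 2 and sel.skip_reason is None

    def test_single_pose_flagged_skip(self):
        sel = select_top_k(toy_ensemble(1), 3)
        assert sel.skip_reason is not None

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(toy_ensemble(5), 1)


class TestStandardization:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        model = fit_standardization(df)
        assert model.dropped == ["a"] and model.retained == ["b"]

    def test_transform_then_inverse_recovers(self):
        df = pd.DataFrame({"b": [0.0, 5.0, 10.0], "c": [-1.0, 0.0, 3.0]})
        model = fit_standardization(df)
        back = model.inverse_transform(model.transform(df))
        assert np.allclose(back, df[model.retained], atol=1e-10)
        scaled = model.transform(df)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(ddof=0), 1.0, atol=1e-12)

    def test_refit_on_standardised_output_is_identity(self):
        df = pd.DataFrame({"b": [0.0, 5.0, 10.0], "c": [-1.0, 0.0, 3.0]})
        model = fit_standardization(df)
        refit = fit_standardization(model.transform(df))
        assert np.allclose(refit.means, 0.0, atol=1e-12)
        assert np.allclose(refit.stds, 1.0, atol=1e-12)

    def test_mostly_undefined_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan, np.nan], "b": [0, 1, 2, 3.0]})
        model = fit_standardization(df)
        assert "a" in model.dropped


class TestCompoundDescriptorStd:
    def test_identical_rows_give_zero(self):
        rows = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert compound_descriptor_std(rows) == 0.0

    def test_single_varying_descriptor_mean_over_d(self):
        """One descriptor swinging (-1, +1) over two poses has population
        std 1; averaged over D retained descriptors the score is 1/D."""
        d = 5
        data = {f"c{i}": [0.0, 0.0] for i in range(d - 1)}
        data["v"] = [-1.0, 1.0]
        assert compound_descriptor_std(pd.DataFrame(data)) == pytest.approx(1.0 / d)

    def test_undefined_entries_excluded_per_descriptor(self):
        rows = pd.DataFrame({"a": [np.nan, 1.0, 2.0], "b": [0.0, 0.0, 0.0]})
        # descriptor a has 2 defined values -> usable; both contribute
        val = compound_descriptor_std(rows)
        assert val == pytest.approx(np.std([1.0, 2.0]) / 2)

    def test_all_undefined_gives_nan(self):
        rows = pd.DataFrame({"a": [np.nan, np.nan]})
        assert np.isnan(compound_descriptor_std(rows))

    def test_scaling_invariance_after_standardisation(self):
        """Multiplying a raw descriptor column by any positive constant
        leaves the standardised consistency score unchanged — the reason
        standardisation is on by default."""
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        scaled_input = raw.copy()
        scaled_input["b"] *= 1e6
        s1 = fit_standardization(raw).transform(raw)
        s2 = fit_standardization(scaled_input).transform(scaled_input)
        for lo in range(0, 12, 3):
            v1 = compound_descriptor_std(s1.iloc[lo : lo + 3])
            v2 = compound_descriptor_std(s2.iloc[lo : lo + 3])
            assert v1 == pytest.approx(v2, rel=1e-10)


class TestGroupsAndCorrelation:
    def _records(self, **cols):
        base = {
            "compound_id": [f"c{i}" for i in range(len(next(iter(cols.values()))))],
            "k": 10,
        }
        base.update(cols)
        return pd.DataFrame(base)

    def test_single_class_reports_missing_not_zero(self):
        recs = self._records(
            descriptor_std=[0.1, 0.2],
            atom_std=[0.5, 0.6],
            n_rot=[1, 2],
            label=["active", "active"],
        )
        out = summarize_groups(recs)
        assert out.loc[0, "n_inactive"] == 0
        assert np.isnan(out.loc[0, "inactive_descriptor_std"])
        assert out.loc[0, "actives_higher_descriptor_std"] is None

    def test_perfect_linear_relation_gives_r_one(self):
        recs = self._records(
            descriptor_std=[0.1 * n for n in range(1, 8)],
            atom_std=[0.0] * 7,
            n_rot=list(range(1, 8)),
            label=["unknown"] * 7,
        )
        assert rotbond_correlation(recs) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        recs = self._records(
            descriptor_std=[0.5, 0.5, 0.5],
            atom_std=[0.0] * 3,
            n_rot=[1, 2, 3],
            label=["unknown"] * 3,
        )
        assert np.isnan(rotbond_correlation(recs))

    def test_permuted_scores_sit_inside_null_band(self):
        """Independence oracle: after permuting descriptor_std against
        n_rot, |r| stays within the 99.9% permutation-null envelope."""
        rng = np.random.default_rng(8)
        n = 60
        n_rot = rng.integers(1, 11, size=n)
        scores = 0.05 * n_rot + rng.normal(scale=0.05, size=n)
        permuted = rng.permutation(scores)
        recs = self._records(
            descriptor_std=permuted, atom_std=np.zeros(n), n_rot=n_rot, label=["unknown"] * n
        )
        r = rotbond_correlation(recs)
        null = []
        for _ in range(500):
            null.append(np.corrcoef(n_rot, rng.permutation(scores))[0, 1])
        assert abs(r) < np.quantile(np.abs(null), 0.999) + 0.05


@pytest.fixture(scope="module")
def results(small_benchmark):
    return analyze(small_benchmark.ensembles, small_benchmark.activities)


class TestAnalyzePipeline:
    def test_every_compound_lands_in_output_or_skip_log(self, small_benchmark, results):
        for k in (3, 5, 10):
            seen = set(results.consistency.query("k == @k")["compound_id"]) | set(
                results.skipped.query("k == @k")["compound_id"]
            )
            assert seen == {e.compound_id for e in small_benchmark.ensembles}

    def test_higher_noise_class_shows_higher_stds(self, results):
        g = results.groups.set_index("k")
        assert g.loc[10, "actives_higher_descriptor_std"]
        assert g.loc[10, "actives_higher_atom_std"]

    def test_descriptor_std_nonnegative_and_finite(self, results):
        assert (results.consistency["descriptor_std"] >= 0).all()
        assert np.isfinite(results.consistency["atom_std"]).all()

    def test_outputs_deterministic(self, small_benchmark, tmp_path):
        cfg = ConsistencyConfig(ks=(3,))
        for sub in ("a", "b"):
            analyze(small_benchmark.ensembles, small_benchmark.activities, cfg).write(tmp_path / sub)
        for name in ("consistency.csv", "groups.csv", "correlations.csv", "per_descriptor.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_morse_s1_ranks_minimum_in_per_descriptor_summary(self, results):
        top = results.per_descriptor.iloc[0]
        assert top["raw_mean_std"] <= 2e-18
        first_names = set(results.per_descriptor.head(6)["descriptor"])
        assert "morse_u_1" in first_names

    def test_geometric_indexes_in_top_variability_tier(self, results):
        """Shape/Petitjean indexes are among the most pose-sensitive
        descriptors on torsion-perturbed ensembles: above the median and
        close to the maximum standardised variability (high-s MoRSE
        descriptors fluctuate comparably, so exact ranks interleave)."""
        summary = results.per_descriptor.set_index("descriptor")["standardized_mean_std"]
        for name in ("petitjean_3d", "shape_index_3d"):
            assert summary[name] > summary.median()
            assert summary[name] >= 0.85 * summary.max()
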