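import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

import tissuedecoder as td


def _nnls_fractions(sig: pd.DataFrame, mix: pd.Series) -> np.ndarray:
    """Independent oracle: non-negative least squares, then normalize."""
    w, _ = nnls(sig.to_numpy(), mix.loc[sig.index].to_numpy())
    return w / w.sum()


class TestDeconvolveSample:
    def test_pure_signature_column_recovered(self, small_signature):
        sig = small_signature
        for j, t in enumerate(sig.cell_types[:3]):
            est = td.deconvolve_sample(sig.values[t], sig)
            assert est.fractions[t] >= 0.99
            assert all(
                v <= 0.01 for k, v in est.fractions.items() if k != t
            )

    def test_symmetric_mixture(self, small_signature):
        sig = small_signature
        a, b = sig.cell_types[0], sig.cell_types[1]
        mix = 0.5 * sig.values[a] + 0.5 * sig.values[b]
        mix.name = "half"
        est = td.deconvolve_sample(mix, sig)
        assert est.fractions[a] == pytest.approx(0.5, abs=0.02)
        assert est.fractions[b] == pytest.approx(0.5, abs=0.02)

    def test_fractions_sum_to_one_and_nonnegative(self, small_signature, rng):
        sig = small_signature
        for _ in range(5):
            mix = pd.Series(
                rng.gamma(2.0, 100.0, size=sig.values.shape[0]),
                index=sig.values.index,
            )
            est = td.deconvolve_sample(mix, sig)
            vals = np.array(list(est.fractions.values()))
            assert (vals >= 0).all()
            assert vals.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, small_signature, rng):
        sig = small_signature
        mix = pd.Series(
            rng.gamma(2.0, 100.0, size=sig.values.shape[0]),
            index=sig.values.index,
        )
        a = td.deconvolve_sample(mix, sig)
        b = td.deconvolve_sample(mix * 1234.5, sig)
        for t in sig.cell_types:
            assert a.fractions[t] == pytest.approx(b.fractions[t], abs=1e-6)

    def test_agrees_with_nnls_oracle(self, small_ref, small_signature, small_cfg):
        sig = small_signature
        mixtures, truth = td.simulate_mixtures(
            td.type_profiles(small_ref[0]), small_cfg
        )
        worst = 0.0
        for s in mixtures.sample_ids:
            est = td.deconvolve_sample(mixtures.data[s], sig)
            oracle = _nnls_fractions(sig.values, mixtures.data[s])
            svr = np.array([est.fractions[t] for t in sig.cell_types])
            worst = max(worst, np.abs(svr - oracle).max())
        assert worst < 0.05

    def test_noise_degrades_recovery_monotonically(self, small_cfg):
        errors = []
        for cv in (0.0, 0.1, 0.5):
            cfg = td.SimulationConfig(
                **{**small_cfg.__dict__, "noise_cv": cv, "n_mixtures": 15}
            )
            ref, _ = td.simulate_reference(cfg)
            sig = td.build_signature(ref, g_min=5, g_max=10)
            mixtures, truth = td.simulate_mixtures(td.type_profiles(ref), cfg)
            ests = td.deconvolve_dataset(mixtures, sig)
            frame = td.fractions_frame(ests)[list(truth.columns)]
            errors.append(
                float(np.abs(frame.to_numpy() - truth.to_numpy()).mean())
            )
        assert errors[0] < 0.01
        assert errors[0] <= errors[1] <= errors[2]

    def test_quantile_map_absorbs_monotone_distortion(self, small_signature):
        # emulate a platform with compressed dynamics: cube root of the
        # true intensities; rank order is intact, values are not
        sig = small_signature
        t = sig.cell_types[0]
        distorted = sig.values[t] ** (1 / 3)
        mapped = td.deconvolve_sample(distorted, sig, quantile_map=True)
        plain = td.deconvolve_sample(distorted, sig, quantile_map=False)
        assert mapped.fractions[t] >= 0.95
        assert mapped.fractions[t] >= plain.fractions[t]

    def test_low_feature_overlap_errors(self, small_signature, rng):
        sig = small_signature
        n = sig.values.shape[0]
        keep = sig.values.index[: int(0.4 * n)]
        mix = pd.Series(rng.gamma(2.0, 100.0, size=len(keep)), index=keep)
        with pytest.raises(ValueError, match="signature features present"):
            td.deconvolve_sample(mix, sig)


class TestDeconvolveDataset:
    def test_pure_type_matrix_gives_one_hot_estimates(self, small_signature):
        sig = small_signature
        two = td.ExpressionMatrix(sig.values.iloc[:, :2].copy())
        ests = td.deconvolve_dataset(two, sig)
        for est, t in zip(ests, sig.cell_types[:2]):
            assert est.fractions[t] >= 0.99

    def test_empty_feature_intersection_errors(self, small_signature, rng):
        sig = small_signature
        mix = td.ExpressionMatrix(
            pd.DataFrame(
                rng.gamma(2.0, 100.0, size=(10, 2)),
                index=[f"other_{i}" for i in range(10)],
                columns=["s1", "s2"],
            )
        )
        with pytest.raises(ValueError, match="no features"):
            td.deconvolve_dataset(mix, sig)

    def test_self_deconvolution_assigns_own_type_top(self, small_ref, small_signature):
        ref, _ = small_ref
        ests = td.deconvolve_dataset(ref.matrix, small_signature)
        hits = sum(
            1
            for e in ests
            if max(e.fractions, key=e.fractions.get) == ref.labels[e.sample_id]
        )
        assert hits / len(ests) >= 0.95


class TestFitPvalue:
    def test_perfect_reconstruction_gives_floor_p(self, small_signature):
        sig = small_signature
        t = sig.cell_types[0]
        est = td.deconvolve_sample(sig.values[t], sig)
        p = td.fit_pvalue(est, sig.values[t], sig, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_noise_mixture_not_significant(self, small_signature, rng):
        sig = small_signature
        mix = pd.Series(
            rng.permutation(sig.values.iloc[:, 0].to_numpy()),
            index=sig.values.index,
        )
        est = td.deconvolve_sample(mix, sig)
        p = td.fit_pvalue(est, mix, sig, n_perm=99, seed=2)
        assert p >= 0.05

    def test_zero_permutations_disable(self, small_signature):
        sig = small_signature
        est = td.deconvolve_sample(sig.values.iloc[:, 0], sig)
        assert td.fit_pvalue(est, sig.values.iloc[:, 0], sig, n_perm=0) is None


class TestAggregateArchetypes:
    MAPPING_21 = {
        **{f"immune_{i}": "immune" for i in range(12)},
        "asc": "stem_stromal",
        "msc": "stem_stromal",
        "sat_adipocyte": "adipocyte",
        "pat_adipocyte": "adipocyte",
        **{f"other_{i}": "other" for i in range(5)},
    }

    def test_one_hot_immune_member(self):
        fractions = {t: 0.0 for t in self.MAPPING_21}
        fractions["immune_0"] = 1.0
        est = td.FractionEstimate("s", fractions, 0.5, 0.0, 1.0)
        agg = td.aggregate_archetypes(est, self.MAPPING_21)
        assert agg.archetype_fractions["immune"] == 1.0

    def test_uniform_fractions_count_members(self):
        k = len(self.MAPPING_21)
        est = td.FractionEstimate(
            "s", {t: 1.0 / k for t in self.MAPPING_21}, 0.5, 0.0, 1.0
        )
        agg = td.aggregate_archetypes(est, self.MAPPING_21)
        assert agg.archetype_fractions["immune"] == pytest.approx(12 / 21)
        assert agg.archetype_fractions["stem_stromal"] == pytest.approx(2 / 21)
        assert agg.archetype_fractions["adipocyte"] == pytest.approx(2 / 21)
        assert agg.archetype_fractions["other"] == pytest.approx(5 / 21)

    def test_random_fractions_match_loop_oracle(self, rng):
        raw = rng.dirichlet(np.ones(len(self.MAPPING_21)))
        fractions = dict(zip(self.MAPPING_21, raw))
        est = td.FractionEstimate("s", fractions, 0.5, 0.0, 1.0)
        agg = td.aggregate_archetypes(est, self.MAPPING_21)
        for arch in set(self.MAPPING_21.values()):
            expected = sum(
                v for t, v in fractions.items() if self.MAPPING_21[t] == arch
            )
            assert agg.archetype_fractions[arch] == pytest.approx(expected)
        assert sum(agg.archetype_fractions.values()) == pytest.approx(1.0)

    def test_unmapped_cell_type_errors(self):
        est = td.FractionEstimate("s", {"a": 0.5, "b": 0.5}, 0.5, 0.0, 1.0)
        with pytest.raises(KeyError, match="'b'"):
            td.aggregate_archetypes(est, {"a": "immune"})
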