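import numpy as np
import pytest
from scipy.stats import norm

from wgdkit import mixtures, synthetic
from wgdkit.synthetic import MixtureSpec


class TestFitGmmLog:
    def test_single_lognormal_recovery(self):
        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.0, components=[(1.0, 0.0, 0.3)]),
                                5000, seed=0)
        (fit,) = mixtures.fit_gmm_log(s.values, k_range=[1], seed=0)
        c = fit.components[0]
        assert c.log_mean == pytest.approx(0.0, abs=0.02)
        assert c.log_sd == pytest.approx(0.3, abs=0.02)

    def test_two_separated_components(self):
        spec = MixtureSpec(exp_rate=1.0,
                           components=[(0.5, -1.2, 0.2), (0.5, 0.3, 0.2)])
        s = synthetic.sample_ks(spec, 6000, seed=1)
        fits = mixtures.fit_gmm_log(s.values, k_range=[1, 2], seed=0)
        by_k = {f.k: f for f in fits}
        assert by_k[2].bic < by_k[1].bic
        mus = sorted(c.log_mean for c in by_k[2].components)
        assert mus[0] == pytest.approx(-1.2, abs=0.05)
        assert mus[1] == pytest.approx(0.3, abs=0.05)

    def test_matches_sklearn_on_unweighted_data(self):
        from sklearn.mixture import GaussianMixture

        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.0,
                                            components=[(0.5, -1.0, 0.2),
                                                        (0.5, 0.5, 0.25)]),
                                4000, seed=2)
        (fit,) = mixtures.fit_gmm_log(s.values, k_range=[2], seed=0)
        gm = GaussianMixture(2, random_state=0, n_init=5).fit(
            np.log(s.values).reshape(-1, 1))
        mine = sorted(c.log_mean for c in fit.components)
        ref = sorted(gm.means_.ravel())
        assert mine == pytest.approx(ref, abs=0.05)

    def test_degenerate_input(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fits = mixtures.fit_gmm_log([1.0] * 50, k_range=[1])
        assert fits[0].components[0].log_sd == pytest.approx(1e-3)

    def test_loglik_monotone(self):
        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.0,
                                            components=[(0.6, 0.0, 0.4)]),
                                2000, seed=3)
        for fit in mixtures.fit_gmm_log(s.values, k_range=[1, 2, 3], seed=0,
                                        n_init=1):
            h = np.array(fit.loglik_history)
            assert np.all(np.diff(h) >= -1e-8)


class TestFitElmm:
    def test_pure_exponential_rate_recovery(self):
        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.5), 5000, seed=4, max_ks=50.0)
        fits = mixtures.fit_elmm(s.values, max_lognormals=0, seed=0)
        assert fits[0].exp_rate == pytest.approx(1.5, abs=0.05)

    def test_exp_plus_lognormal_recovery_and_bic(self):
        spec = MixtureSpec(exp_rate=1.2, components=[(0.3, -0.2, 0.25)])
        s = synthetic.sample_ks(spec, 8000, seed=5)
        fits = mixtures.fit_elmm(s.values, max_lognormals=2, seed=0)
        by_m = {f.k: f for f in fits}
        assert by_m[1].bic < by_m[0].bic
        best = mixtures.select_model(fits)
        assert best.k == 1
        c = best.components[0]
        assert c.weight == pytest.approx(0.3, abs=0.05)
        assert c.log_mean == pytest.approx(-0.2, abs=0.05)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mixtures.fit_elmm([], max_lognormals=1)

    def test_loglik_monotone(self):
        spec = MixtureSpec(exp_rate=1.0, components=[(0.4, 0.0, 0.3)])
        s = synthetic.sample_ks(spec, 3000, seed=6)
        for fit in mixtures.fit_elmm(s.values, max_lognormals=2, seed=0, n_init=1):
            h = np.array(fit.loglik_history)
            assert np.all(np.diff(h) >= -1e-8)

    def test_weighted_fit_respects_weights(self):
        # duplicate every point with weight 0.5 == original sample
        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.0,
                                            components=[(0.4, 0.0, 0.3)]),
                                2000, seed=7)
        f_plain = mixtures.fit_elmm(s.values, max_lognormals=1, seed=0)[1]
        doubled = np.concatenate([s.values, s.values])
        w = np.full(len(doubled), 0.5)
        f_weighted = mixtures.fit_elmm(doubled, weights=w, max_lognormals=1,
                                       seed=0)[1]
        assert f_weighted.components[0].log_mean == pytest.approx(
            f_plain.components[0].log_mean, abs=1e-6)
        assert f_weighted.exp_rate == pytest.approx(f_plain.exp_rate, abs=1e-6)

    def test_zero_values_excluded_and_counted(self):
        s = synthetic.sample_ks(MixtureSpec(exp_rate=1.0), 500, seed=8)
        vals = np.concatenate([s.values, [0.0, 0.0, -1.0]])
        fits = mixtures.fit_elmm(vals, max_lognormals=0, seed=0)
        assert fits[0].n_excluded == 3
        assert fits[0].n_used == 500


class TestSelectModel:
    def _fit(self, k, bic, converged=True):
        return mixtures.MixtureFit("elmm", [mixtures.LognormalComponent(1, 0, 0.3)] * k,
                                   1.0, 0.0, 0.0, bic, 0.0, 100, converged, 10)

    def test_lowest_bic(self):
        assert mixtures.select_model([self._fit(1, 100), self._fit(2, 90)]).bic == 90

    def test_tie_prefers_fewer_components(self):
        assert mixtures.select_model([self._fit(2, 100), self._fit(1, 100)]).k == 1

    def test_none_converged_errors(self):
        with pytest.raises(RuntimeError):
            mixtures.select_model([self._fit(1, 100, converged=False)])


class TestFilterAnchors:
    def _fit_with(self, log_mean, log_sd, weight=1.0):
        comp = mixtures.LognormalComponent(weight, log_mean, log_sd)
        return mixtures.MixtureFit("elmm", [comp], 1.0, 0.0, 0.0, 0.0, 0.0,
                                   100, True, 10)

    def test_closed_form_interval(self):
        fit = self._fit_with(0.0, 0.5)
        pf = mixtures.filter_anchors([], fit, level=0.95, ks_cutoff=10.0)
        z = norm.ppf(0.975)
        assert pf.interval[0] == pytest.approx(np.exp(-z * 0.5), abs=1e-3)
        assert pf.interval[1] == pytest.approx(np.exp(z * 0.5), abs=1e-3)
        assert pf.interval == (pytest.approx(0.3753, abs=1e-3),
                               pytest.approx(2.6645, abs=1e-3))

    def test_coverage(self):
        rng = np.random.default_rng(9)
        draws = np.exp(rng.normal(0.0, 0.5, 10000))
        fit = self._fit_with(0.0, 0.5)
        pf = mixtures.filter_anchors(list(enumerate(draws)), fit, level=0.95,
                                     ks_cutoff=100.0)
        assert pf.retained_fraction == pytest.approx(0.95, abs=0.01)

    def test_cutoff_truncates_upper_bound(self):
        fit = self._fit_with(0.0, 0.5)
        pf = mixtures.filter_anchors([], fit, level=0.95, ks_cutoff=1.0)
        assert pf.interval[1] == 1.0

    def test_interval_above_cutoff_errors(self):
        fit = self._fit_with(3.0, 0.1)
        with pytest.raises(ValueError, match="cutoff"):
            mixtures.filter_anchors([], fit, ks_cutoff=1.0)

    def test_peak_is_density_argmax(self):
        comp = mixtures.LognormalComponent(1.0, 0.2, 0.4)
        grid = np.linspace(1e-4, 5, 200001)
        dens = (1 / (grid * 0.4 * np.sqrt(2 * np.pi)) *
                np.exp(-0.5 * ((np.log(grid) - 0.2) / 0.4) ** 2))
        assert comp.peak == pytest.approx(grid[np.argmax(dens)], abs=1e-3)


class TestExportDatingInputs:
    def _groups(self, n=3):
        class G:
            def __init__(self, gid, members):
                self.group_id = gid
                self.members = members

        rng = np.random.default_rng(10)
        cds = {}
        groups = []
        for i in range(n):
            members = [f"og{i}_g{j}" for j in range(4)]
            for m in members:
                cds[m] = synthetic.SequenceRecord(m, synthetic.random_cds(20, rng))
            groups.append(G(f"og{i:05d}", members))
        return groups, cds

    def test_file_contract(self, tmp_path):
        groups, cds = self._groups(3)
        tree = "((A:1,B:1):1,C:2);"
        written = mixtures.export_dating_inputs(groups, cds, tree, tmp_path)
        fastas = [p for p in written if p.suffix == ".fasta"]
        assert len(fastas) == 3
        assert (tmp_path / "dating_tree.nwk").exists()
        assert (tmp_path / "dating_control.template.ctl").exists()

    def test_empty_errors(self, tmp_path):
        with pytest.raises(ValueError):
            mixtures.export_dating_inputs([], {}, "(A,B);", tmp_path)

    def test_newick_round_trip(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        groups, cds = self._groups(1)
        tree = "((A:1.0,B:1.0):0.5,C:1.5);"
        mixtures.export_dating_inputs(groups, cds, tree, tmp_path)
        parsed = Phylo.read(str(tmp_path / "dating_tree.nwk"), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A", "B", "C"]

    def test_missing_cds_group_skipped(self, tmp_path):
        groups, cds = self._groups(2)
        del cds[groups[0].members[0]]
        with pytest.warns(UserWarning, match="skipped"):
            written = mixtures.export_dating_inputs(groups, cds, "(A,B);", tmp_path)
        assert len([p for p in written if p.suffix == ".fasta"]) == 1
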