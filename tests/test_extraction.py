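import numpy as np
import pytest
from sklearn.base import clone

from clonalsig.extraction import (
    SignatureNMF,
    _match_cosines,
    contributions_to_frame,
    match_to_catalog,
    nmf_extract,
    refit_contributions,
    select_rank,
)
from clonalsig.io import SignatureCatalog
from clonalsig.profiles import Profile96, cosine_similarity


def _disjoint_signatures():
    s1 = np.zeros(96); s1[:10] = 1 / 10
    s2 = np.zeros(96); s2[50:60] = 1 / 10
    return s1, s2


class TestNMFExtract:
    def test_planted_exact_factorization_recovered(self):
        s1, s2 = _disjoint_signatures()
        W0 = np.column_stack([s1, s2])
        rng = np.random.default_rng(0)
        H0 = rng.uniform(100, 2000, size=(2, 12))
        # pure columns make the factorization identifiable (the planted
        # signatures are then the extreme rays of the data cone)
        H0[:, 0] = [1500.0, 0.0]
        H0[:, 1] = [0.0, 1200.0]
        V = W0 @ H0
        res = nmf_extract(V, rank=2, n_runs=10, seed=0)
        cos = _match_cosines(W0, res.signatures)
        assert (cos >= 0.999).all()

    def test_rank_one_recovers_common_direction(self):
        s1, _ = _disjoint_signatures()
        V = np.outer(s1, [200.0, 900.0, 55.0])
        res = nmf_extract(V, rank=1, n_runs=3, seed=1)
        np.testing.assert_allclose(res.signatures[:, 0], s1, atol=1e-6)

    def test_seeded_determinism_bitwise(self):
        rng = np.random.default_rng(2)
        V = rng.poisson(20.0, size=(96, 8)).astype(float)
        a = nmf_extract(V, rank=2, n_runs=4, seed=9)
        b = nmf_extract(V, rank=2, n_runs=4, seed=9)
        assert a.trajectory == b.trajectory
        assert a.objectives == b.objectives
        np.testing.assert_array_equal(a.signatures, b.signatures)

    def test_normalization_duality(self):
        """W columns sum to 1 and the reconstruction W@H is unchanged by the
        rescaling (checked against an unnormalized reference run)."""
        rng = np.random.default_rng(3)
        V = rng.poisson(15.0, size=(96, 6)).astype(float)
        res = nmf_extract(V, rank=2, n_runs=2, seed=4)
        np.testing.assert_allclose(res.signatures.sum(axis=0), 1.0, atol=1e-12)
        # reconstruction close to V in KL sense: at least finite and shaped
        assert (res.signatures @ res.exposures).shape == V.shape

    def test_input_validation(self):
        V = np.ones((96, 5))
        with pytest.raises(ValueError, match="rank"):
            nmf_extract(V, rank=5)
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_extract(-V, rank=2)
        V2 = V.copy(); V2[:, 0] = 0
        with pytest.raises(ValueError, match="all-zero"):
            nmf_extract(V2, rank=2)

    def test_agrees_with_sklearn_mu_kl(self, catalog):
        """Independent cross-check: sklearn's multiplicative-update KL NMF
        finds the same signatures on a well-posed mixture."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        planted = np.column_stack([catalog.column(s) for s in ("SBS1", "SBS2")])
        V = np.column_stack([
            rng.multinomial(3000, planted @ rng.dirichlet([1, 1])) for _ in range(15)
        ]).astype(float)
        ours = nmf_extract(V, rank=2, n_runs=5, seed=5)
        sk = NMF(n_components=2, solver="mu", beta_loss="kullback-leibler",
                 init="random", random_state=0, max_iter=2000, tol=1e-9).fit(V.T)
        Wsk = sk.components_.T
        Wsk = Wsk / Wsk.sum(axis=0)
        assert (_match_cosines(ours.signatures, Wsk) >= 0.99).all()


class TestSelectRank:
    def test_error_non_increasing_and_rank1_reproducible(self):
        rng = np.random.default_rng(6)
        V = rng.poisson(30.0, size=(96, 10)).astype(float)
        diag = select_rank(V, range(1, 5), n_runs=3, seed=6, max_iter=300)
        errs = diag["kl_error"].to_numpy()
        assert (np.diff(errs) <= 1e-6 * np.maximum(1, errs[:-1])).all()
        assert diag.loc[diag["rank"] == 1, "reproducibility"].iloc[0] == pytest.approx(
            1.0, abs=1e-6
        )

    def test_planted_rank_is_stable(self, catalog):
        rng = np.random.default_rng(7)
        planted = np.column_stack(
            [catalog.column(s) for s in ("SBS1", "SBS2", "SBS7a")]
        )
        V = np.column_stack([
            rng.multinomial(int(rng.integers(1000, 5000)),
                            planted @ rng.dirichlet([1.0] * 3))
            for _ in range(20)
        ]).astype(float)
        diag = select_rank(V, range(2, 4), n_runs=4, seed=7, max_iter=500)
        assert (diag["reproducibility"] >= 0.95).all()


class TestMatchToCatalog:
    def test_exact_column_match(self, catalog):
        res = nmf_extract(
            np.outer(catalog.column("SBS1"), [1000.0, 500.0]), rank=1, n_runs=2, seed=0
        )
        matches = match_to_catalog(res, catalog)
        name, (best, cos) = next(iter(matches.items()))
        assert name == "SBSA"
        assert best == "SBS1"
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_merged_group_wins_for_blended_signature(self, catalog):
        from clonalsig.profiles import merged_signature

        blend = merged_signature(catalog, ["SBS2", "SBS13"])
        res = nmf_extract(np.outer(blend, [800.0, 300.0]), rank=1, n_runs=2, seed=0)
        matches = match_to_catalog(res, catalog,
                                   merge_groups={"SBS2/13": ["SBS2", "SBS13"]})
        best, cos = matches["SBSA"]
        assert best == "SBS2/13"
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_noisy_signature_still_matches_origin(self, catalog):
        rng = np.random.default_rng(8)
        noisy = catalog.column("SBS1") + rng.uniform(0, 0.05 / 96, 96)
        noisy /= noisy.sum()
        res = nmf_extract(np.outer(noisy, [1000.0, 400.0]), rank=1, n_runs=2, seed=0)
        best, cos = match_to_catalog(res, catalog)["SBSA"]
        assert best == "SBS1"
        assert cos == pytest.approx(cosine_similarity(noisy, catalog.column("SBS1")),
                                    abs=1e-3)


class TestRefit:
    def test_exact_mixture(self):
        s1, s2 = _disjoint_signatures()
        W = np.column_stack([s1, s2])
        profile = Profile96(counts=600 * s1 + 400 * s2, label="c")
        res = refit_contributions(profile, W, ["A", "B"])
        np.testing.assert_allclose(res.relative, [0.6, 0.4], atol=1e-9)
        np.testing.assert_allclose(res.absolute, [600, 400], atol=1e-6)
        assert res.reconstruction_similarity == pytest.approx(1.0, abs=1e-12)
        assert res.reliable

    def test_single_signature(self):
        s1, s2 = _disjoint_signatures()
        W = np.column_stack([s1, s2])
        res = refit_contributions(Profile96(counts=s1 * 750, label="c"), W)
        np.testing.assert_allclose(res.relative, [1.0, 0.0], atol=1e-9)
        assert res.absolute[0] == pytest.approx(750, abs=1e-6)

    def test_conservation_of_absolute_contributions(self, catalog):
        rng = np.random.default_rng(9)
        W = np.column_stack([catalog.column(s) for s in ("SBS1", "SBS2", "SBS5")])
        counts = rng.poisson(10.0, 96).astype(float)
        res = refit_contributions(Profile96(counts=counts, label="c"), W)
        assert res.absolute.sum() == pytest.approx(counts.sum(), abs=1e-6)
        assert res.relative.sum() == pytest.approx(1.0, abs=1e-9)

    def test_multinomial_mixture_recovered(self):
        s1, s2 = _disjoint_signatures()
        W = np.column_stack([s1, s2])
        rng = np.random.default_rng(5)
        counts = rng.multinomial(2000, 0.7 * s1 + 0.3 * s2)
        res = refit_contributions(Profile96(counts=counts, label="c"), W)
        np.testing.assert_allclose(res.relative, [0.7, 0.3], atol=0.03)
        assert res.reconstruction_similarity >= 0.98

    def test_orthogonal_profile_flagged_unreliable(self):
        s1, s2 = _disjoint_signatures()
        W = np.column_stack([s1, s2])
        counts = np.zeros(96); counts[90:] = 10
        res = refit_contributions(Profile96(counts=counts, label="c"), W)
        assert not res.reliable
        assert res.reconstruction_similarity == 0.0

    def test_contributions_frame(self, catalog):
        W = np.column_stack([catalog.column("SBS1"), catalog.column("SBS2")])
        res = refit_contributions(
            Profile96(counts=catalog.column("SBS1") * 100, label="c0"), W, ["A", "B"]
        )
        df = contributions_to_frame([res])
        assert set(df["signature"]) == {"A", "B"}
        assert df["relative"].sum() == pytest.approx(1.0)


class TestSignatureNMFEstimator:
    def test_fit_transform_shapes_and_clone(self, catalog):
        rng = np.random.default_rng(10)
        planted = np.column_stack([catalog.column(s) for s in ("SBS1", "SBS2")])
        X = np.stack([
            rng.multinomial(2000, planted @ rng.dirichlet([1, 1])) for _ in range(10)
        ]).astype(float)
        est = SignatureNMF(n_components=2, n_runs=4, random_state=0).fit(X)
        assert est.components_.shape == (2, 96)
        rel = est.transform(X)
        assert rel.shape == (10, 2)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)
        sims = est.reconstruction_similarities(X)
        assert (sims >= 0.9).all()
        assert clone(est).get_params() == est.get_params()
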