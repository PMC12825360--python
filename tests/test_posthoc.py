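"""Moderated-t machinery: contrasts, the variance prior, and the markers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idas import (
    ModerationParams,
    cellstate_markers,
    estimate_moderation,
    fit_contrast,
    interaction_markers,
    moderated_t,
    phenotype_signature,
    simulate_two_way,
)
from idas.datatypes import ObservationDesign, PseudobulkMatrix


class TestFitContrast:
    def test_noiseless_two_group(self):
        vals = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        out = fit_contrast(vals, np.array([0, 0, 0, 1, 1, 1], bool),
                           np.array([1, 1, 1, 0, 0, 0], bool), ["g"])
        assert out.loc["g", "log2fc"] == pytest.approx(1.0)
        assert out.loc["g", "s2"] == pytest.approx(0.0, abs=1e-18)

    def test_pooled_two_sample_formulas(self):
        """(1,2,3) vs (4,5,6): beta=3, pooled s2=1 on 4 df, v = 2/3."""
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        g0 = np.array([1, 1, 1, 0, 0, 0], bool)
        out = fit_contrast(vals, ~g0, g0, ["g"])
        assert out.loc["g", "log2fc"] == pytest.approx(3.0)
        assert out.loc["g", "s2"] == pytest.approx(1.0)
        assert out.loc["g", "df"] == 4
        assert out.loc["g", "v"] == pytest.approx(2.0 / 3.0)

    def test_empty_side_rejected(self):
        vals = np.zeros((1, 4))
        with pytest.raises(ValueError, match="at least one"):
            fit_contrast(vals, np.zeros(4, bool), np.ones(4, bool), ["g"])


class TestModeration:
    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(50, 2.5)
        params = estimate_moderation(s2, np.full(50, 6.0))
        assert np.isinf(params.d0)
        assert params.s0_sq == pytest.approx(2.5, rel=1e-6)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="insufficient"):
            estimate_moderation(np.ones(5), np.full(5, 4.0))

    def test_parameter_recovery_scaled_inv_chi2(self):
        """s2 ~ s0^2 * d0 / chi2(d0) scaled by chi2(d)/d sampling noise:
        the moments estimator recovers (d0=4, s0^2=1) over seeds."""
        d0_true, s0_true, d = 4.0, 1.0, 6.0
        for seed in range(10):
            rng = np.random.default_rng(800 + seed)
            n = 5000
            true_var = s0_true * d0_true / rng.chisquare(d0_true, size=n)
            s2 = true_var * rng.chisquare(d, size=n) / d
            params = estimate_moderation(s2, np.full(n, d))
            assert 2.5 <= params.d0 <= 6.5
            assert 0.8 <= params.s0_sq <= 1.25

    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent oracle: limma::squeezeVar on a shared fixture."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        s2 = 1.2 * 4.0 / rng.chisquare(4.0, size=400) * rng.chisquare(6, size=400) / 6
        d = 6.0
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "squeeze.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE)\n'
            f'fit <- limma::fitFDist(s2, df1={d})\n'
            'cat(fit$df2, fit$scale, sep="\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        d0_ref, s0_ref = (float(x) for x in out.stdout.split())
        params = estimate_moderation(s2, np.full(len(s2), d))
        assert params.d0 == pytest.approx(d0_ref, rel=1e-4)
        assert params.s0_sq == pytest.approx(s0_ref, rel=1e-4)


class TestModeratedT:
    @pytest.fixture()
    def contrasts(self):
        rng = np.random.default_rng(5)
        n = 40
        return pd.DataFrame(
            {
                "log2fc": rng.normal(size=n),
                "s2": rng.chisquare(4, size=n) / 4,
                "df": np.full(n, 4.0),
                "v": np.full(n, 0.5),
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_d0_zero_reproduces_ordinary_t(self, contrasts):
        out = moderated_t(contrasts, ModerationParams(d0=0.0, s0_sq=1.0))
        t_ref = contrasts["log2fc"] / np.sqrt(contrasts["s2"] * contrasts["v"])
        p_ref = 2 * stats.t.sf(np.abs(t_ref), contrasts["df"])
        assert out["t"].to_numpy() == pytest.approx(t_ref.to_numpy(), abs=1e-12)
        assert out["p"].to_numpy() == pytest.approx(p_ref, abs=1e-12)

    def test_d0_inf_uses_prior_variance_and_normal(self, contrasts):
        out = moderated_t(contrasts, ModerationParams(d0=np.inf, s0_sq=0.8))
        assert np.allclose(out["s2_post"], 0.8)
        t = out["t"].iloc[0]
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(t)))

    def test_posterior_variance_plug_in(self):
        con = pd.DataFrame({"log2fc": [1.0], "s2": [4.0], "df": [4.0], "v": [1.0]},
                           index=["g"])
        out = moderated_t(con, ModerationParams(d0=4.0, s0_sq=1.0))
        assert out.loc["g", "s2_post"] == pytest.approx(2.5)

    def test_shrinkage_is_contractive(self, contrasts):
        params = ModerationParams(d0=3.0, s0_sq=0.9)
        out = moderated_t(contrasts, params)
        lo = np.minimum(contrasts["s2"], params.s0_sq)
        hi = np.maximum(contrasts["s2"], params.s0_sq)
        assert np.all(out["s2_post"] >= lo - 1e-12)
        assert np.all(out["s2_post"] <= hi + 1e-12)

    def test_invariant_to_constant_shift_and_permutation(self):
        """DE p-values ignore a per-gene constant offset and obs order."""
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(12, 10))
        g1 = np.array([1] * 5 + [0] * 5, bool)
        base = fit_contrast(vals, g1, ~g1, [f"g{i}" for i in range(12)])
        shifted = fit_contrast(vals + 7.5, g1, ~g1, [f"g{i}" for i in range(12)])
        perm = rng.permutation(10)
        permuted = fit_contrast(vals[:, perm], g1[perm], ~g1[perm],
                                [f"g{i}" for i in range(12)])
        for other in (shifted, permuted):
            assert base["log2fc"].to_numpy() == pytest.approx(
                other["log2fc"].to_numpy(), abs=1e-12)
            assert base["s2"].to_numpy() == pytest.approx(
                other["s2"].to_numpy(), abs=1e-12)


def _marker_pb(seed=0, bump_gene="g0", bump_state="s1", bump=2.0, n_genes=15):
    """Balanced 3-state x 2-phenotype pseudobulk with one elevated gene."""
    rng = np.random.default_rng(seed)
    states = np.repeat(["s0", "s1", "s2"], 8)
    pheno = np.tile(np.repeat(["N", "R"], 4), 3)
    design = ObservationDesign(
        obs_ids=[f"o{i}" for i in range(24)], f1=states, f2=pheno)
    vals = rng.normal(5.0, 0.2, size=(n_genes, 24))
    gidx = int(bump_gene[1:])
    vals[gidx, states == bump_state] += bump
    return PseudobulkMatrix(values=vals,
                            gene_ids=[f"g{i}" for i in range(n_genes)],
                            design=design)


class TestMarkers:
    def test_planted_state_marker_found(self):
        pb = _marker_pb(bump=2.0)
        de = cellstate_markers(pb, pb.gene_ids)
        sub = de.table[de.table["contrast"] == "s1_vs_rest"]
        top = sub.sort_values("p").iloc[0]
        assert top["gene_id"] == "g0"
        assert top["log2fc"] == pytest.approx(2.0, abs=0.3)
        assert top["positive_marker"]

    def test_flat_gene_not_significant(self):
        pb = _marker_pb(bump=0.0)
        de = cellstate_markers(pb, pb.gene_ids)
        assert (de.table["padj"] < 0.01).sum() == 0

    def test_phenotype_signature_labels(self):
        rng = np.random.default_rng(3)
        pheno = np.tile(["N", "R"], 18)
        design = ObservationDesign(obs_ids=[f"o{i}" for i in range(36)],
                                   f1=np.repeat(["s0", "s1"], 18), f2=pheno)
        vals = rng.normal(5.0, 0.2, size=(12, 36))
        vals[0, pheno == "R"] += 1.0  # planted up-in-R
        pb = PseudobulkMatrix(values=vals, gene_ids=[f"g{i}" for i in range(12)],
                              design=design)
        de = phenotype_signature(pb, pb.gene_ids)
        tab = de.table.set_index("gene_id")
        assert tab.loc["g0", "label"] == "up-in-R"
        assert tab.loc["g0", "p"] < 0.001
        assert (tab.drop("g0")["label"] == "below-threshold").all()

    def test_threshold_degeneracy_labels_every_gene_by_sign(self):
        pb = _marker_pb(bump=0.0)
        de = phenotype_signature(pb, pb.gene_ids, p_cut=1.1, fc_cut=0.0)
        assert (de.table["label"] != "below-threshold").all()

    def test_interaction_marker_two_step(self):
        """A gene elevated only in (state s1, phenotype R) passes both the
        state ranking and the within-state phenotype contrast."""
        rng = np.random.default_rng(8)
        states = np.repeat(["s0", "s1", "s2"], 8)
        pheno = np.tile(np.repeat(["N", "R"], 4), 3)
        design = ObservationDesign(obs_ids=[f"o{i}" for i in range(24)],
                                   f1=states, f2=pheno)
        vals = rng.normal(5.0, 0.2, size=(15, 24))
        vals[0, (states == "s1") & (pheno == "R")] += 2.5  # state-specific response
        vals[1, states == "s2"] += 2.0  # pure state effect, no phenotype split
        pb = PseudobulkMatrix(values=vals, gene_ids=[f"g{i}" for i in range(15)],
                              design=design)
        de = interaction_markers(pb, pb.gene_ids, top_k=5)
        tab = de.table
        hit = tab[(tab["gene_id"] == "g0") & (tab["state"] == "s1")]
        assert len(hit) == 1 and hit["specific"].iloc[0]
        assert hit["phenotype"].iloc[0] == "R"
        pure = tab[(tab["gene_id"] == "g1") & (tab["state"] == "s2")]
        assert len(pure) == 1 and not pure["specific"].iloc[0]

    def test_top_k_larger_than_gene_count_keeps_all(self):
        pb = _marker_pb(n_genes=4)
        de = interaction_markers(pb, pb.gene_ids, top_k=50)
        per_state = de.table.groupby("state")["gene_id"].nunique()
        assert (per_state == 4).all()

    def test_single_phenotype_state_skipped(self):
        states = np.array(["s0"] * 4 + ["s1"] * 4)
        pheno = np.array(["N", "N", "R", "R", "N", "N", "N", "N"])
        design = ObservationDesign(obs_ids=[f"o{i}" for i in range(8)],
                                   f1=states, f2=pheno)
        rng = np.random.default_rng(2)
        pb = PseudobulkMatrix(values=rng.normal(size=(12, 8)),
                              gene_ids=[f"g{i}" for i in range(12)], design=design)
        de = interaction_markers(pb, pb.gene_ids, top_k=3)
        assert set(de.table["state"]) == {"s0"}
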