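"""Sparse PLS-DA / multiblock model: oracles, invariants, prediction rules."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from netomics.splsda import (
    SplsModel, _BlockFit, diablo_fit, diablo_predict, load_model, save_model,
    select_features, splsda_fit, splsda_predict, uniform_design,
)
from netomics.tuning import ber


def _toy(n=40, p=8, seed=0, delta=1.5, informative=3):
    rng = np.random.default_rng(seed)
    y = np.array(["case"] * (n // 2) + ["control"] * (n - n // 2))
    X = rng.standard_normal((n, p))
    X[:, :informative] += (y == "case")[:, None] * delta
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y


class TestSplsdaFit:
    def test_dense_component_matches_svd_oracle(self):
        X, y = _toy()
        m = splsda_fit(X, y, ncomp=1)
        Xc = X.to_numpy() - X.to_numpy().mean(0)
        Y = np.stack([(y == "case").astype(float), (y == "control").astype(float)], 1)
        Yc = Y - Y.mean(0)
        u_ref = np.linalg.svd(Xc.T @ Yc)[0][:, 0]
        u = m.fit.U[:, 0]
        assert min(np.abs(u - u_ref).max(), np.abs(u + u_ref).max()) < 1e-10

    def test_dominant_covariance_feature_selected(self):
        rng = np.random.default_rng(1)
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = pd.DataFrame({
            "signal": (y == "a") + rng.normal(0, 0.01, 40),
            "noise": rng.normal(0, 1, 40),
        })
        m = splsda_fit(X, y, ncomp=1, keepX=[1])
        assert list(select_features(m).features("block0")) == ["signal"]

    @pytest.mark.parametrize("keepX", [[3, 5], [8, 8], [1, 2]])
    def test_sparsity_exactness_and_unit_norm(self, keepX):
        X, y = _toy()
        m = splsda_fit(X, y, ncomp=2, keepX=keepX)
        nnz = (np.abs(m.fit.U) > 0).sum(axis=0)
        assert list(nnz) == keepX
        np.testing.assert_allclose(np.linalg.norm(m.fit.U, axis=0), 1.0, atol=1e-8)

    def test_score_orthogonality_after_deflation(self):
        X, y = _toy(n=60, p=20, seed=3)
        m = splsda_fit(X, y, ncomp=3, keepX=[10, 10, 10])
        T = m.fit.T
        for h in range(3):
            for l in range(h + 1, 3):
                cos = abs(T[:, h] @ T[:, l]) / (np.linalg.norm(T[:, h]) * np.linalg.norm(T[:, l]))
                assert cos < 1e-6

    def test_objective_nondecreasing_within_tolerance(self):
        X, y = _toy(n=50, p=30, seed=4)
        m = splsda_fit(X, y, ncomp=2, keepX=[10, 10])
        for hist in m.objective_history:
            diffs = np.diff(hist)
            assert (diffs >= -1e-8 * (1 + np.abs(hist[:-1]))).all()

    def test_single_class_rejected(self):
        X, _ = _toy()
        with pytest.raises(ValueError, match="two classes"):
            splsda_fit(X, np.array(["a"] * len(X)), ncomp=1)

    def test_keepx_out_of_range_rejected(self):
        X, y = _toy()
        with pytest.raises(ValueError):
            splsda_fit(X, y, ncomp=1, keepX=[99])

    def test_matches_mixomics_reference(self, tmp_path):
        """Independent oracle: the mixOmics R implementation on a tiny fixture."""
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript unavailable"
        rng = np.random.default_rng(42)
        n, p = 40, 15
        y = np.array(["case"] * 20 + ["control"] * 20)
        X = rng.standard_normal((n, p))
        X[:, :3] += (y == "case")[:, None] * 1.5
        Xdf = pd.DataFrame(X, index=[f"S{i}" for i in range(n)],
                           columns=[f"f{j}" for j in range(p)])
        Xdf.to_csv(tmp_path / "X.tsv", sep="\t")
        (tmp_path / "y.txt").write_text("\n".join(y) + "\n")
        script = tmp_path / "ref.R"
        script.write_text(
            'suppressMessages(library(mixOmics))\n'
            f'X <- as.matrix(read.table("{tmp_path}/X.tsv", header=TRUE, row.names=1, sep="\\t"))\n'
            f'y <- factor(readLines("{tmp_path}/y.txt"))\n'
            'fit <- splsda(X, y, ncomp=2, keepX=c(5,5), scale=FALSE)\n'
            f'write.table(fit$loadings$X, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)\n')
        subprocess.run([rscript, str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0).to_numpy()
        mine = splsda_fit(Xdf, y, ncomp=2, keepX=[5, 5]).fit.U
        for h in range(2):
            d = min(np.abs(mine[:, h] - ref[:, h]).max(),
                    np.abs(mine[:, h] + ref[:, h]).max())
            assert d < 1e-6


class TestSplsdaPredict:
    def test_separable_training_data_zero_errors(self):
        X, y = _toy(delta=6.0)
        m = splsda_fit(X, y, ncomp=1, keepX=[3])
        labels, _ = splsda_predict(m, X)
        assert ber(y, labels) == 0.0

    def test_centroid_rule_recovers_class_centroid(self):
        X, y = _toy(delta=3.0, seed=5)
        m = splsda_fit(X, y, ncomp=2)
        # a sample sitting exactly at the case centroid in feature space
        case_mean = X[y == "case"].mean(axis=0)
        probe = pd.DataFrame([case_mean], columns=X.columns)
        labels, _ = splsda_predict(m, probe, distance="centroid_dist")
        assert labels[0] == "case"

    def test_feature_mismatch_rejected(self):
        X, y = _toy()
        m = splsda_fit(X, y, ncomp=1)
        with pytest.raises(ValueError, match="feature"):
            splsda_predict(m, X[list(X.columns[::-1])])


class TestDiablo:
    def test_single_block_reduces_to_splsda(self):
        X, y = _toy(n=50, p=12, seed=6)
        single = splsda_fit(X, y, ncomp=2, keepX=[4, 6])
        multi = diablo_fit([X], y, ncomp=2, keepX=[[4, 6]],
                           design=uniform_design(1, 0.0))
        np.testing.assert_allclose(multi.blocks["block0"].U, single.fit.U, atol=1e-8)

    def test_zero_coupling_decouples_blocks(self):
        Xa, y = _toy(n=50, p=10, seed=7)
        Xb, _ = _toy(n=50, p=14, seed=8)
        design = uniform_design(2, 0.0)  # no block-block weight
        multi = diablo_fit([Xa, Xb], y, ncomp=1, keepX=[[4], [5]], design=design)
        for X, name, k in ((Xa, "block0", [4]), (Xb, "block1", [5])):
            ref = splsda_fit(X, y, ncomp=1, keepX=k)
            np.testing.assert_allclose(multi.blocks[name].U[:, 0], ref.fit.U[:, 0],
                                       atol=1e-6)

    def test_coupling_strengthens_cross_block_score_correlation(self):
        """Raising the design weight must pull shared-factor block scores together."""
        med = {}
        for c in (0.0, 0.1, 1.0):
            cors = []
            for s in range(20):
                rng = np.random.default_rng(s)
                n = 60
                y = np.array(["a"] * 30 + ["b"] * 30)
                shared = rng.standard_normal(n) + (y == "a") * 1.0
                Xa = pd.DataFrame(rng.standard_normal((n, 15)) * 1.5)
                Xb = pd.DataFrame(rng.standard_normal((n, 15)) * 1.5)
                Xa.iloc[:, :4] += shared[:, None]
                Xb.iloc[:, :4] += shared[:, None]
                Xa.columns = Xa.columns.astype(str)
                Xb.columns = Xb.columns.astype(str)
                d = uniform_design(2, c)
                m = diablo_fit([Xa, Xb], y, ncomp=1, keepX=[[6], [6]], design=d)
                t1, t2 = m.blocks["block0"].T[:, 0], m.blocks["block1"].T[:, 0]
                cors.append(abs(np.corrcoef(t1, t2)[0, 1]))
            med[c] = np.median(cors)
        assert med[0.0] <= med[0.1] + 1e-9 <= med[1.0] + 2e-9

    def test_objective_monotone_per_sweep(self, log_blocks, small_dataset):
        y = small_dataset.labels.to_numpy()
        m = diablo_fit(log_blocks, y, ncomp=2, keepX=[[15, 15]] * 3)
        for hist in m.objective_history:
            diffs = np.diff(hist)
            assert (diffs >= -1e-8 * (1 + np.abs(hist[:-1]))).all()

    def test_asymmetric_design_rejected(self):
        X, y = _toy()
        bad = uniform_design(1)
        bad[0, 1] = 0.7
        with pytest.raises(ValueError, match="symmetric"):
            diablo_fit([X], y, ncomp=1, design=bad)


class TestDiabloPredict:
    def _two_block_model(self, delta_a=4.0, delta_b=4.0, seed=9):
        Xa, y = _toy(n=60, p=10, seed=seed, delta=delta_a)
        Xb, _ = _toy(n=60, p=10, seed=seed + 1, delta=delta_b)
        m = diablo_fit([Xa, Xb], y, ncomp=1, keepX=[[5], [5]])
        return m, [Xa, Xb], y

    def test_unanimous_blocks_agree_with_combined(self):
        m, blocks, y = self._two_block_model()
        labels, per_block = diablo_predict(m, blocks, scheme="average")
        for name, scores in per_block.items():
            block_labels = m.classes[np.argmax(scores, axis=1)]
            agree = block_labels == labels
            assert agree.mean() > 0.9  # strong-signal blocks mostly unanimous
        maj, _ = diablo_predict(m, blocks, scheme="majority_vote")
        assert (maj == labels).mean() > 0.9

    def test_average_follows_larger_margin(self):
        """Two artificial score matrices with opposite calls: the average must
        side with the block whose margin is bigger (checked via the public
        scheme by constructing blocks with very different signal strength)."""
        m, blocks, y = self._two_block_model(delta_a=6.0, delta_b=0.0, seed=11)
        labels, per_block = diablo_predict(m, blocks, scheme="average")
        strong = m.classes[np.argmax(per_block["block0"], axis=1)]
        assert (labels == strong).mean() > 0.9
        assert ber(y, labels) < 0.2

    def test_missing_block_rejected(self):
        m, blocks, _ = self._two_block_model()
        with pytest.raises(ValueError, match="block"):
            diablo_predict(m, {"block0": blocks[0]})


class TestSignature:
    def test_union_bounds(self):
        X, y = _toy(n=60, p=60, seed=12)
        m = splsda_fit(X, y, ncomp=2, keepX=[8, 50])
        sig = select_features(m)
        assert len(sig.features("block0")) <= 58
        assert len(set(sig.features("block0"))) == len(sig.features("block0"))

    def test_empty_model_yields_empty_signature(self):
        fit = _BlockFit(features=pd.Index(["a", "b"]), x_mean=np.zeros(2),
                        x_scale=np.ones(2), U=np.zeros((2, 0)), T=np.zeros((4, 0)),
                        P=np.zeros((2, 0)), C=np.zeros((2, 0)), keepX=[])
        model = SplsModel(classes=np.array(["x", "y"]), fit=fit, ncomp=0,
                          y_mean=np.zeros(2), V=np.zeros((2, 0)))
        assert select_features(model).features("block0") == []

    def test_serialization_round_trip(self, log_blocks, small_dataset):
        y = small_dataset.labels.to_numpy()
        m = diablo_fit(log_blocks, y, ncomp=2, keepX=[[10, 10]] * 3)
        import tempfile
        with tempfile.NamedTemporaryFile(suffix=".json", mode="w", delete=False) as fh:
            path = fh.name
        save_model(m, path)
        m2 = load_model(path)
        blocks_new = list(log_blocks.values())
        l1, _ = diablo_predict(m, dict(zip(m.block_names, blocks_new)))
        l2, _ = diablo_predict(m2, dict(zip(m2.block_names, blocks_new)))
        assert (l1 == l2).all()
        for name in m.block_names:
            np.testing.assert_allclose(m.blocks[name].U, m2.blocks[name].U)
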