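import numpy as np
import pytest

import hashdemux as hd
from hashdemux.classify import DropletAssignment
from hashdemux.simulate import (
    attenuate_signal,
    benchmark_metrics,
    generate_dataset,
    merge_doublets,
    nbreg_params,
)


def fake_assignment(i, c_hat, label, htos=()):
    return DropletAssignment(
        droplet_id=f"d{i}", c_hat=tuple(c_hat), joint_prob=1.0, label=label,
        htos=tuple(htos), p_acpt=0.9,
    )


class TestGenerateDataset:
    def test_determinism(self):
        kwargs = dict(
            m=500, n=2,
            signal_params=nbreg_params(1000, 0.6, 10),
            background_params=nbreg_params(25, 0.0, 5),
            class_probs=[0.45, 0.45], msm_prob=0.05,
        )
        a = generate_dataset(seed=123, **kwargs)
        b = generate_dataset(seed=123, **kwargs)
        assert np.array_equal(a.experiment.counts, b.experiment.counts)
        assert np.array_equal(a.truth, b.truth)
        assert np.array_equal(a.experiment.detected_genes, b.experiment.detected_genes)
        c = generate_dataset(seed=124, **kwargs)
        assert not np.array_equal(a.experiment.counts, c.experiment.counts)

    def test_beta_zero_means_no_correlation(self):
        ds = generate_dataset(
            m=5000, n=1,
            signal_params=nbreg_params(1000, 0.0, 10),
            background_params=nbreg_params(25, 0.0, 5),
            class_probs=[1.0], seed=0,
        )
        tagged = ds.truth[:, 0] == 1
        logx = np.log(ds.experiment.detected_genes[tagged])
        logy = np.log1p(ds.experiment.counts[tagged, 0])
        r = np.corrcoef(logx, logy)[0, 1]
        assert abs(r) < 0.05

    def test_beta_positive_means_positive_correlation(self):
        ds = generate_dataset(
            m=5000, n=1,
            signal_params=nbreg_params(1000, 0.6, 10),
            background_params=nbreg_params(25, 0.0, 5),
            class_probs=[1.0], seed=0,
        )
        tagged = ds.truth[:, 0] == 1
        logx = np.log(ds.experiment.detected_genes[tagged])
        logy = np.log1p(ds.experiment.counts[tagged, 0])
        assert np.corrcoef(logx, logy)[0, 1] > 0.3

    def test_class_proportions(self):
        ds = generate_dataset(
            m=20000, n=2,
            signal_params=nbreg_params(1000, 0.6, 10),
            background_params=nbreg_params(25, 0.0, 5),
            class_probs=[0.4, 0.4], msm_prob=0.1, seed=5,
        )
        k = ds.truth.sum(axis=1)
        assert np.mean(k == 1) == pytest.approx(0.8, abs=0.02)
        assert np.mean(k == 2) == pytest.approx(0.1, abs=0.01)
        assert np.mean(k == 0) == pytest.approx(0.1, abs=0.01)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(
                m=10, n=1,
                signal_params=nbreg_params(100, 0, 5),
                background_params=nbreg_params(10, 0, 5),
                class_probs=[0.9], msm_prob=0.2, seed=0,
            )
        with pytest.raises(ValueError):
            generate_dataset(
                m=10, n=1,
                signal_params=nbreg_params(100, 0, 5),
                background_params=nbreg_params(10, 0, 5),
                class_probs=[0.5], msm_prob=0.1, seed=0,  # n=1 cannot have MSMs
            )

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            nbreg_params(100, 0.0, -1.0)


class TestAttenuateSignal:
    def test_identity_at_s_one(self, small_simulated):
        out = attenuate_signal(small_simulated.experiment, small_simulated.truth, 1.0)
        assert np.array_equal(out.counts, small_simulated.experiment.counts)

    def test_definition_arithmetic(self):
        exp = hd.HashingExperiment(
            counts=np.array([[100, 25], [30, 200]]),
            detected_genes=[1000, 1000],
            droplet_ids=["a", "b"],
            hto_names=["h1", "h2"],
        )
        truth = np.array([[1, 0], [0, 1]])
        out = attenuate_signal(exp, truth, 0.5)
        assert out.counts.tolist() == [[50, 25], [30, 100]]

    def test_rounding_to_nearest(self):
        exp = hd.HashingExperiment(
            counts=np.array([[7], [7]]),
            detected_genes=[1000, 1000],
            droplet_ids=["a", "b"],
            hto_names=["h1"],
        )
        out = attenuate_signal(exp, np.array([[1], [0]]), 0.1)
        assert out.counts[0, 0] == 1  # round(0.7)
        assert out.counts[1, 0] == 7  # background untouched

    def test_invalid_s(self, small_simulated):
        for s in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                attenuate_signal(small_simulated.experiment, small_simulated.truth, s)


class TestMergeDoublets:
    def _tiny(self):
        exp = hd.HashingExperiment(
            counts=np.array([[10, 2], [4, 20], [8, 1], [2, 30]]),
            detected_genes=[100, 200, 100, 300],
            droplet_ids=list("abcd"),
            hto_names=["h1", "h2"],
        )
        truth = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        return exp, truth

    def test_average_counts(self):
        exp, truth = self._tiny()
        ds = merge_doublets(exp, truth, n_doublets=1, seed=0)
        assert ds.experiment.n_droplets == 5
        new = ds.experiment.counts[-1]
        new_truth = ds.truth[-1]
        assert new_truth.tolist() == [1, 1]  # OR of two different samples
        # the new row must be the rounded average of one h1-SSD and one h2-SSD
        candidates = [
            np.rint((exp.counts[i] + exp.counts[j]) / 2).astype(int).tolist()
            for i in (0, 2) for j in (1, 3)
        ]
        assert new.tolist() in candidates

    def test_paper_sized_doublet_injection(self):
        # 2123 SSDs + 200 doublets -> 2323 droplets
        m = 2123
        rng = np.random.default_rng(0)
        sample = rng.integers(0, 8, m)
        truth = np.zeros((m, 8), dtype=int)
        truth[np.arange(m), sample] = 1
        exp = hd.HashingExperiment(
            counts=rng.integers(0, 100, (m, 8)),
            detected_genes=np.full(m, 1500),
            droplet_ids=[f"d{i}" for i in range(m)],
            hto_names=[f"h{j}" for j in range(8)],
        )
        ds = merge_doublets(exp, truth, n_doublets=200, seed=1)
        assert ds.experiment.n_droplets == 2323
        assert ds.experiment.hto_names.tolist() == exp.hto_names.tolist()
        assert np.array_equal(ds.truth[:m], truth)
        assert np.all(ds.truth[m:].sum(axis=1) == 2)

    def test_single_sample_pool_is_error(self):
        exp = hd.HashingExperiment(
            counts=np.array([[10], [12], [9]]),
            detected_genes=[100, 100, 100],
            droplet_ids=list("abc"),
            hto_names=["h1"],
        )
        truth = np.array([[1], [1], [1]])
        with pytest.raises(ValueError, match="different samples"):
            merge_doublets(exp, truth, n_doublets=1, seed=0)

    def test_detected_genes_averaged(self):
        exp, truth = self._tiny()
        ds = merge_doublets(exp, truth, n_doublets=3, seed=2)
        for g in ds.experiment.detected_genes[-3:]:
            assert g in {150, 200, 250}  # averages of {100,200,300} pairs


class TestBenchmarkMetrics:
    def test_perfect_assignment(self, small_simulated):
        truth = small_simulated.truth
        names = small_simulated.experiment.hto_names
        assignments = []
        for i, row in enumerate(truth):
            k = row.sum()
            label = "negative" if k == 0 else ("SSD" if k == 1 else "MSM")
            htos = tuple(names[j] for j in np.flatnonzero(row))
            assignments.append(fake_assignment(i, row, label, htos))
        bm = benchmark_metrics(assignments, truth)
        assert bm.precision_ssd == 1.0
        assert bm.sensitivity_ssd == 1.0
        assert bm.f_ssd == 1.0
        assert bm.precision_msm == 1.0
        assert bm.msm_proportion == pytest.approx(np.mean(truth.sum(axis=1) >= 2))

    def test_definition_arithmetic(self):
        # 8 true SSDs: 6 correct SSD, 1 wrong-sample SSD, 1 uncertain
        truth = np.zeros((8, 2), dtype=int)
        truth[:, 0] = 1
        assignments = [fake_assignment(i, [1, 0], "SSD", ("h1",)) for i in range(6)]
        assignments.append(fake_assignment(6, [0, 1], "SSD", ("h2",)))
        assignments.append(fake_assignment(7, [0, 0], "uncertain"))
        bm = benchmark_metrics(assignments, truth)
        assert bm.precision_ssd == pytest.approx(6 / 7)
        assert bm.sensitivity_ssd == pytest.approx(7 / 8)

    def test_harmonic_mean_formula(self):
        # oracle: direct arithmetic 2PR/(P+R) for the printed-style P and R
        p, r = 0.9974, 0.8500
        expected = 2 * p * r / (p + r)
        truth = np.zeros((10000, 2), dtype=int)
        truth[:, 0] = 1
        n_pred = 8600
        n_correct = round(n_pred * p)  # 8578 correct of 8600 predicted
        assignments = [
            fake_assignment(i, [1, 0], "SSD", ("h1",)) for i in range(n_correct)
        ]
        assignments += [
            fake_assignment(i, [0, 1], "SSD", ("h2",))
            for i in range(n_correct, n_pred)
        ]
        assignments += [
            fake_assignment(i, [0, 0], "uncertain") for i in range(n_pred, 10000)
        ]
        bm = benchmark_metrics(assignments, truth)
        check = 2 * bm.precision_ssd * bm.sensitivity_ssd / (
            bm.precision_ssd + bm.sensitivity_ssd
        )
        assert bm.f_ssd == pytest.approx(check, rel=1e-12)
        assert expected == pytest.approx(0.91778, abs=5e-5)

    def test_no_predicted_ssd_reports_missing(self):
        truth = np.array([[1, 0], [0, 1]])
        assignments = [
            fake_assignment(0, [0, 0], "uncertain"),
            fake_assignment(1, [0, 0], "negative"),
        ]
        bm = benchmark_metrics(assignments, truth)
        assert bm.precision_ssd is None
        assert bm.sensitivity_ssd == 0.0
        assert bm.f_ssd is None

    def test_confusion_counts_sum_to_m(self, small_simulated):
        res = hd.demultiplex(small_simulated.experiment, seed=3)
        bm = benchmark_metrics(res.assignments, small_simulated.truth)
        assert sum(bm.confusion.values()) == small_simulated.experiment.n_droplets
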