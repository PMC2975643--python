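import numpy as np
import pytest

from boolcore import (Kind, TransferFunction, compute_weight, extract_core,
                      infer_edges, read_perturbation_table, generate_truth,
                      regulatory_sign, simulate_perturbation_dataset,
                      write_perturbation_table)
from boolcore.nullmodels import BetaBias, FixedBias, fit_beta


def edge_precision_recall(true_edges, inferred_edges):
    true_edges, inferred_edges = set(true_edges), set(inferred_edges)
    tp = len(true_edges & inferred_edges)
    precision = tp / len(inferred_edges) if inferred_edges else 1.0
    recall = tp / len(true_edges) if true_edges else 1.0
    return precision, recall


class TestGroundTruth:
    def test_edge_count_from_mean_k(self):
        truth = generate_truth(50, 3.0, seed=0)
        assert truth.net.topology().number_of_edges() == 150

    def test_same_seed_identical_truth(self):
        a = generate_truth(20, 2.0, seed=5)
        b = generate_truth(20, 2.0, seed=5)
        assert set(a.net.topology().edges) == set(b.net.topology().edges)
        for g in a.net.nodes:
            assert a.net.functions[g].table.tolist() == \
                b.net.functions[g].table.tolist()

    def test_no_self_loops_planted(self):
        g = generate_truth(30, 4.0, seed=1).net.topology()
        assert all(u != v for u, v in g.edges)

    def test_beta_bias_realized_pbias_distribution(self):
        """Realized p-biases of a large Beta-mode truth refit to shapes
        near the generating Beta.

        The realized p-bias of a finite table is a binomially smoothed
        version of the drawn bias (and exact 0/1 values are clipped at the
        table resolution before fitting), which biases both fitted shapes
        upward; simulation puts that distortion under ~20 percent here, so
        the refit is checked at 25 percent while the strong left-biased
        U shape and the distribution mean are checked tightly.  (Recovery
        of the *drawn* biases at 5 percent is covered with the null-model
        ensembles.)"""
        pbiases = []
        for s in range(2):
            truth = generate_truth(2500, 8.0,
                                   bias_mode=BetaBias(0.3467, 0.4350),
                                   seed=s)
            for g in truth.net.nodes:
                f = truth.net.functions[g]
                if f.n >= 4:
                    eps = 1.0 / (2 * f.table.size)
                    pbiases.append(float(np.clip(f.pbias, eps, 1 - eps)))
        fit = fit_beta(pbiases)
        assert fit.alpha == pytest.approx(0.3467, rel=0.25)
        assert fit.beta == pytest.approx(0.4350, rel=0.25)
        assert fit.alpha < 1 and fit.beta < 1 and fit.alpha < fit.beta
        assert np.mean(pbiases) == pytest.approx(0.3467 / (0.3467 + 0.4350),
                                                 abs=0.03)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_truth(1, 1.0)
        with pytest.raises(ValueError):
            generate_truth(10, 2.0, effect_scale=0.0)


class TestRegulatorySign:
    def test_activator_and_repressor(self):
        f_act = TransferFunction.from_table("g", ("a",), [0, 1])
        f_rep = TransferFunction.from_table("g", ("a",), [1, 0])
        assert regulatory_sign(f_act, 0) == 1
        assert regulatory_sign(f_rep, 0) == -1

    def test_tie_defaults_to_activation(self):
        f_xor = TransferFunction.from_table("g", ("a", "b"), [0, 1, 1, 0])
        assert regulatory_sign(f_xor, 0) == 1


class TestSimulatedDataset:
    def test_activator_deletion_weight_sign(self):
        """Deleting a true activator must yield W = -10^effect_scale."""
        truth = generate_truth(10, 2.0, seed=3, effect_scale=1.0,
                               noise_sd=0.0)
        ds = simulate_perturbation_dataset(truth)
        checked = 0
        for G in truth.net.nodes:
            f = truth.net.functions[G]
            for pos, j in enumerate(f.inputs):
                s = regulatory_sign(f, pos)
                w_del = compute_weight(ds, G, j, 0)
                w_oe = compute_weight(ds, G, j, 1)
                assert w_del == pytest.approx(-s * 10.0)
                assert w_oe == pytest.approx(s * 10.0)
                checked += 1
        assert checked > 0

    def test_noise_free_recovery_is_perfect(self):
        truth = generate_truth(30, 3.0, seed=8, effect_scale=1.0,
                               noise_sd=0.0)
        ds = simulate_perturbation_dataset(truth)
        inferred = infer_edges(ds, 3.32)
        p, r = edge_precision_recall(truth.net.topology().edges,
                                     inferred.edges)
        assert (p, r) == (1.0, 1.0)
        # and the core matches the true core exactly
        assert set(extract_core(inferred).edges) == \
            set(extract_core(truth.net.topology()).edges)

    def test_zero_effect_scale_yields_no_edges(self):
        # smallest positive effect below any threshold > 1 behaves like the
        # degenerate no-effect limit when noise is off
        truth = generate_truth(10, 2.0, seed=2, effect_scale=1e-9,
                               noise_sd=0.0)
        ds = simulate_perturbation_dataset(truth)
        assert infer_edges(ds, 1.001).number_of_edges() == 0

    def test_recovery_degrades_monotonically_with_noise(self):
        """Average F1 of edge recovery is non-increasing in noise SD."""
        sds = [0.0, 0.3, 0.8]
        f1 = []
        for sd in sds:
            scores = []
            for seed in range(5):
                truth = generate_truth(25, 3.0, seed=seed, effect_scale=0.6,
                                       noise_sd=sd)
                ds = simulate_perturbation_dataset(truth)
                p, r = edge_precision_recall(
                    truth.net.topology().edges, infer_edges(ds, 3.32).edges)
                scores.append(2 * p * r / (p + r) if p + r else 0.0)
            f1.append(np.mean(scores))
        assert f1[0] == 1.0
        assert f1[0] >= f1[1] >= f1[2]
        assert f1[2] < f1[0]

    def test_written_dataset_roundtrips(self, tmp_path):
        truth = generate_truth(12, 2.0, seed=6, noise_sd=0.1)
        ds = simulate_perturbation_dataset(truth)
        tsv, meta = tmp_path / "d.tsv", tmp_path / "d.meta.tsv"
        write_perturbation_table(ds, tsv, meta_path=meta)
        back = read_perturbation_table(tsv, meta=meta)
        assert back.genes == ds.genes
        for a, b in zip(ds.experiments, back.experiments):
            assert (a.perturbed_gene, a.kind) == (b.perturbed_gene, b.kind)
            assert a.ratios == b.ratios

    def test_one_experiment_per_gene_and_kind(self):
        truth = generate_truth(7, 2.0, seed=0)
        ds = simulate_perturbation_dataset(truth)
        assert len(ds.experiments) == 14
        assert ds.get("G1", Kind.DELETION) is not None
        assert ds.get("G1", Kind.OVEREXPRESSION) is not None
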