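"""GBM importance, edge signing, regulon assembly, key-activator TFs."""

import numpy as np
import pytest

from conegrn.config import PipelineConfig
from conegrn.errors import PipelineError
from conegrn.genome import GenomicInterval
from conegrn.grn import (
    Edge,
    Regulon,
    assemble_regulons,
    classify_edge,
    cone_specific_genes,
    importance_scores,
    key_activator_tfs,
    tf_target_regulons,
)
from conegrn.matrix import CountMatrix, normalize_counts
from conegrn.motifs import FootprintScore, MotifHit
from conegrn.ptog import CisElementSet


def _rna(counts):
    m = CountMatrix(
        [f"c{i}" for i in range(counts.shape[0])],
        [f"g{j}" for j in range(counts.shape[1])],
        counts,
    )
    return normalize_counts(m)


class TestImportance:
    def test_copied_target_dominates(self):
        rng = np.random.default_rng(0)
        n = 1000
        tf_counts = rng.poisson(5, size=(n, 11))
        target = tf_counts[:, 0] + rng.poisson(1, n)  # copies TF g0
        rna = _rna(np.hstack([tf_counts, target[:, None]]))
        tfs = [f"g{j}" for j in range(11)]
        imps = importance_scores(rna, tfs, "g11", seed=1)
        assert imps["g0"] > 0.5
        assert abs(sum(imps.values()) - 1.0) < 1e-6

    def test_constant_target_all_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(50, 4))
        counts[:, 3] = 7  # constant depth contribution
        rna = _rna(counts)
        # force exactly constant normalized target
        rna.normalized[:, 3] = 1.0
        imps = importance_scores(rna, ["g0", "g1", "g2"], "g3", seed=0)
        assert all(v == 0.0 for v in imps.values())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        rna = _rna(rng.poisson(5, size=(200, 6)))
        a = importance_scores(rna, [f"g{j}" for j in range(5)], "g5", seed=3)
        b = importance_scores(rna, [f"g{j}" for j in range(5)], "g5", seed=3)
        assert a == b


class TestClassifyEdge:
    @pytest.mark.parametrize(
        "imp,r,expected",
        [
            (0.2, 0.10, "positive"),
            (0.2, -0.10, "negative"),
            (0.1, 0.9, "none"),     # importance boundary strict
            (0.2, 0.05, "none"),    # r boundary strict
            (0.2, -0.05, "none"),
            (0.05, 0.9, "none"),
        ],
    )
    def test_sign_rules(self, imp, r, expected):
        assert classify_edge(imp, r, PipelineConfig()) == expected


def _hit(tf_peak, start=0):
    return MotifHit(tf_peak, "M0", GenomicInterval("chr1", start + 1, start + 11), "+", 10.0)


def _fp():
    return FootprintScore(0.5, 0.2, 0.5, True)


class TestAssemble:
    def test_unsigned_edges_produce_nothing(self):
        binding = {"Cone": [("tf1", _hit("pk1"), _fp())]}
        cis = {"t1": CisElementSet("t1", tss_peaks=["pk1"])}
        edges = [Edge("tf1", "t1", 0.5, 0.0, "none")]
        assert assemble_regulons(binding, cis, edges) == []

    def test_duplicate_triples_removed(self):
        binding = {
            "Cone": [("tf1", _hit("pk1", 0), _fp()), ("tf1", _hit("pk1", 50), _fp())]
        }
        cis = {"t1": CisElementSet("t1", tss_peaks=["pk1"])}
        edges = [Edge("tf1", "t1", 0.5, 0.5, "positive")]
        regs = assemble_regulons(binding, cis, edges)
        assert regs == [Regulon("Cone", "tf1", "pk1", "t1", "positive")]

    def test_peak_must_be_cis_element(self):
        binding = {"Cone": [("tf1", _hit("pk2"), _fp())]}
        cis = {"t1": CisElementSet("t1", tss_peaks=["pk1"])}
        edges = [Edge("tf1", "t1", 0.5, 0.5, "positive")]
        assert assemble_regulons(binding, cis, edges) == []

    def test_tf_target_collapse(self):
        regs = [
            Regulon("Cone", "tf1", "pk1", "t1", "positive"),
            Regulon("RPC", "tf1", "pk2", "t1", "positive"),
        ]
        assert tf_target_regulons(regs) == [("tf1", "t1", "positive")]


class TestConeSpecific:
    def test_strong_cone_gene_found_and_flat_excluded(self):
        rng = np.random.default_rng(4)
        n = 400
        labels = {}
        counts = np.ones((n, 3), dtype=int)
        for i in range(n):
            ct = "Cone" if i < 200 else "Rod"
            labels[f"c{i}"] = ct
        counts[:, 0] = rng.poisson(1, n) + 1          # depth anchor
        counts[:200, 1] = rng.poisson(20, 200)        # cone-specific
        counts[200:, 1] = 0
        counts[:, 2] = rng.poisson(5, n)              # flat
        rna = _rna(counts)
        genes = cone_specific_genes(rna, labels, PipelineConfig())
        assert "g1" in genes
        assert "g2" not in genes

    def test_downregulated_excluded(self):
        rng = np.random.default_rng(5)
        n = 200
        labels = {f"c{i}": "Cone" if i < 100 else "Rod" for i in range(n)}
        counts = np.ones((n, 2), dtype=int)
        counts[100:, 1] = rng.poisson(30, 100)  # rod-specific (cone-down)
        rna = _rna(counts)
        genes = cone_specific_genes(rna, labels, PipelineConfig())
        assert "g1" not in genes

    def test_no_cones_rejected(self):
        rna = _rna(np.ones((10, 2), dtype=int))
        labels = {c: "Rod" for c in rna.cell_ids}
        with pytest.raises(PipelineError, match="no-cone-cells"):
            cone_specific_genes(rna, labels, PipelineConfig())


class TestKeyTFs:
    def _regs(self, mapping):
        out = []
        for tf, targets in mapping.items():
            for t in targets:
                out.append(Regulon("Cone", tf, f"pk_{t}", t, "positive"))
        return out

    def test_saturated_population_excluded(self):
        # every target cone-specific: enrichment impossible, p = 1
        regs = self._regs({"tf1": [f"t{i}" for i in range(10)]})
        cone = [f"t{i}" for i in range(10)]
        assert key_activator_tfs(regs, cone, PipelineConfig()) == []

    def test_zero_coverage_excluded(self):
        regs = self._regs(
            {"tf1": [f"t{i}" for i in range(10)], "tf2": [f"u{i}" for i in range(90)]}
        )
        cone = [f"u{i}" for i in range(30)]
        res = key_activator_tfs(regs, cone, PipelineConfig())
        assert all(r.tf != "tf1" for r in res)

    def test_enriched_tf_reported_with_rank(self):
        # tf1 hits all 20 cone genes out of a 200-target population
        regs = self._regs(
            {
                "tf1": [f"t{i}" for i in range(20)],
                "tf2": [f"u{i}" for i in range(180)],
            }
        )
        cone = [f"t{i}" for i in range(20)]
        res = key_activator_tfs(regs, cone, PipelineConfig())
        assert [r.tf for r in res] == ["tf1"]
        assert res[0].rank == 1
        assert res[0].coverage == 1.0
        assert res[0].p_hyper < 1e-6

    def test_empty_positive_grn_rejected(self):
        regs = [Regulon("Cone", "tf1", "pk", "t1", "negative")]
        with pytest.raises(PipelineError, match="empty-grn"):
            key_activator_tfs(regs, [], PipelineConfig())

    def test_output_capped_at_top_n(self):
        cfg = PipelineConfig(key_tf_top_n=2)
        mapping = {f"tf{j}": [f"t{j}_{i}" for i in range(20)] for j in range(5)}
        regs = self._regs(mapping)
        regs += self._regs({"bg": [f"u{i}" for i in range(400)]})
        cone = [t for j in range(5) for t in (f"t{j}_{i}" for i in range(20))]
        res = key_activator_tfs(regs, cone, cfg)
        assert len(res) <= 2


class TestNullCalibration:
    def test_shuffled_labels_pass_rate_low(self):
        rng = np.random.default_rng(6)
        n_cells, n_genes = 600, 1000
        counts = rng.negative_binomial(2, 2 / (2 + 3), size=(n_cells, n_genes))
        counts[:, 0] += 1  # avoid zero-depth cells
        rna = _rna(counts)
        labels = {
            c: rng.choice(["Cone", "Rod", "BC/Pho pre"]) for c in rna.cell_ids
        }
        genes = cone_specific_genes(rna, labels, PipelineConfig())
        assert len(genes) <= 0.01 * n_genes
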