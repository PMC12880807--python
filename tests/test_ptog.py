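"""Pseudo-cell grouping, peak-to-gene links, cis-element categories."""

import numpy as np
import pytest

from conegrn.config import PipelineConfig
from conegrn.errors import PipelineError
from conegrn.genome import GeneModel, GenomicInterval
from conegrn.matrix import CountMatrix, normalize_counts
from conegrn.ptog import (
    PseudoCellGrouping,
    PtoGLink,
    assign_cis_elements,
    make_pseudocells,
    ptog_correlations,
    tss_distance,
)


def _norm_matrix(counts, prefix="c"):
    m = CountMatrix(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"f{j}" for j in range(counts.shape[1])],
        counts,
    )
    return normalize_counts(m)


class TestPseudocells:
    def test_balanced_sizes(self):
        rng = np.random.default_rng(0)
        rna = _norm_matrix(rng.poisson(5, size=(200, 30)) + 1)
        g = make_pseudocells(rna, n_groups=10, seed=0, min_size=20)
        sizes = np.bincount(list(g.assignments.values()))
        assert sizes.min() >= 20 - 1 and sizes.max() <= 20 + 1

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        lo = rng.poisson(2, size=(60, 20))
        hi = rng.poisson(2, size=(60, 20)) + np.array([200] * 10 + [0] * 10)
        rna = _norm_matrix(np.vstack([lo, hi]) + 1)
        g = make_pseudocells(rna, n_groups=2, seed=0, min_size=20)
        labels = np.array([g.assignments[c] for c in rna.cell_ids])
        # each blob lands in one group
        assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
        assert labels[0] != labels[-1]

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        rna = _norm_matrix(rng.poisson(5, size=(120, 25)) + 1)
        g1 = make_pseudocells(rna, 4, seed=7)
        g2 = make_pseudocells(rna, 4, seed=7)
        assert g1.assignments == g2.assignments

    def test_too_few_cells(self):
        rna = _norm_matrix(np.ones((30, 5), dtype=int))
        with pytest.raises(PipelineError, match="too-few-cells"):
            make_pseudocells(rna, n_groups=4, min_size=20)


def _toy_gene(gene_id="g1", chrom="chr1", start=100_000, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, start + 10_000, strand), strand)


class TestDistance:
    def test_zero_when_covering_tss(self):
        gene = _toy_gene()
        assert tss_distance(GenomicInterval("chr1", 99_950, 100_050), gene) == 0

    def test_edge_distance(self):
        gene = _toy_gene()
        assert tss_distance(GenomicInterval("chr1", 100_500, 100_700), gene) == 500
        assert tss_distance(GenomicInterval("chr1", 99_000, 99_500), gene) == 501


class TestPtoGCorrelations:
    def _setup(self, n_groups=25, seed=0):
        rng = np.random.default_rng(seed)
        n_cells = n_groups * 20
        signal = np.repeat(rng.uniform(1, 10, n_groups), 20)
        rna_counts = np.hstack(
            [rng.poisson(signal)[:, None] + 1, rng.poisson(3, (n_cells, 1)) + 1]
        )
        atac_counts = np.hstack(
            [rng.poisson(signal)[:, None] + 1, rng.poisson(3, (n_cells, 1)) + 1]
        )
        rna = _norm_matrix(rna_counts)
        atac = CountMatrix(rna.cell_ids, ["p0", "p1"], atac_counts)
        atac = normalize_counts(atac)
        grouping = PseudoCellGrouping(
            {c: i // 20 for i, c in enumerate(rna.cell_ids)}, n_groups
        )
        genes = [_toy_gene("f0"), _toy_gene("f1", start=200_000)]
        peaks = {
            "p0": GenomicInterval("chr1", 120_000, 120_200),
            "p1": GenomicInterval("chr1", 220_000, 220_200),
        }
        return rna, atac, grouping, genes, peaks

    def test_correlated_pair_found(self):
        rna, atac, grouping, genes, peaks = self._setup()
        links = ptog_correlations(rna, atac, grouping, genes, peaks, PipelineConfig())
        link = {(l.peak_id, l.gene_id): l for l in links}[("p0", "f0")]
        assert link.r > 0.6
        assert link.fdr < 0.05

    def test_distance_window_respected(self):
        rna, atac, grouping, genes, peaks = self._setup()
        peaks["p1"] = GenomicInterval("chr1", 900_000, 900_200)  # > 500 kb from f1
        links = ptog_correlations(rna, atac, grouping, genes, peaks, PipelineConfig())
        assert not any(l.peak_id == "p1" and l.gene_id == "f1" for l in links)

    def test_disjoint_modalities_rejected(self):
        rna, atac, grouping, genes, peaks = self._setup()
        atac2 = CountMatrix(
            [f"x{i}" for i in range(atac.n_cells)], atac.feature_ids, atac.counts
        )
        atac2 = normalize_counts(atac2)
        with pytest.raises(PipelineError, match="modalities-disjoint"):
            ptog_correlations(rna, atac2, grouping, genes, peaks, PipelineConfig())

    def test_null_calibration_under_permutation(self):
        # with group-shuffled signal, few links pass fdr < 0.05
        rng = np.random.default_rng(3)
        n_groups, per = 30, 20
        n_cells = n_groups * per
        rna = _norm_matrix(rng.poisson(5, (n_cells, 40)) + 1)
        atac = normalize_counts(
            CountMatrix(rna.cell_ids, [f"p{j}" for j in range(30)],
                        rng.poisson(5, (n_cells, 30)) + 1)
        )
        grouping = PseudoCellGrouping(
            {c: i // per for i, c in enumerate(rna.cell_ids)}, n_groups
        )
        genes = [_toy_gene(f"f{j}", start=100_000 + 12_000 * j) for j in range(40)]
        peaks = {
            f"p{j}": GenomicInterval("chr1", 100_500 + 12_000 * j, 100_700 + 12_000 * j)
            for j in range(30)
        }
        links = ptog_correlations(rna, atac, grouping, genes, peaks, PipelineConfig())
        assert len(links) >= 1000
        frac = np.mean([l.fdr < 0.05 for l in links])
        assert frac <= 0.06


class TestCisElements:
    def _links(self, gene_id, entries):
        return [
            PtoGLink(pid, gene_id, r, 1e-6, fdr, dist) for pid, r, fdr, dist in entries
        ]

    def test_tss_peak_needs_no_correlation(self):
        gene = _toy_gene()
        peaks = {"pk": GenomicInterval("chr1", 99_950, 100_050)}
        ces = assign_cis_elements(gene, peaks, [], [gene], PipelineConfig())
        assert ces.tss_peaks == ["pk"]

    def test_gene_body_r_boundary_strict(self):
        gene = _toy_gene()
        peaks = {"pk": GenomicInterval("chr1", 105_000, 105_200)}
        links = self._links("g1", [("pk", 0.25, 0.001, 0)])
        ces = assign_cis_elements(gene, peaks, links, [gene], PipelineConfig())
        assert ces.gene_body_peaks == []  # r must be strictly > 0.25
        links = self._links("g1", [("pk", 0.26, 0.001, 0)])
        ces = assign_cis_elements(gene, peaks, links, [gene], PipelineConfig())
        assert ces.gene_body_peaks == ["pk"]

    def test_intergenic_excludes_other_gene_space(self):
        gene = _toy_gene()
        other = _toy_gene("g2", start=150_000)
        inside_other = {"pk": GenomicInterval("chr1", 155_000, 155_200)}
        links = self._links("g1", [("pk", 0.9, 1e-4, 55_000)])
        ces = assign_cis_elements(
            gene, inside_other, links, [gene, other], PipelineConfig()
        )
        assert ces.intergenic_peaks == []
        clear = {"pk": GenomicInterval("chr1", 180_000, 180_200)}
        ces = assign_cis_elements(gene, clear, links, [gene, other], PipelineConfig())
        assert ces.intergenic_peaks == ["pk"]

    def test_categories_disjoint_randomized(self):
        rng = np.random.default_rng(9)
        genes = [_toy_gene(f"g{j}", start=100_000 + 40_000 * j) for j in range(5)]
        starts = rng.integers(50_000, 400_000, size=60)
        peaks = {
            f"pk{i}": GenomicInterval("chr1", int(s), int(s) + 200)
            for i, s in enumerate(starts)
        }
        links = [
            PtoGLink(pid, g.gene_id, float(rng.uniform(-1, 1)), 1e-4,
                     float(rng.uniform(0, 0.2)), 0)
            for pid in peaks for g in genes
        ]
        for g in genes:
            ces = assign_cis_elements(g, peaks, links, genes, PipelineConfig())
            sets = [set(ces.tss_peaks), set(ces.gene_body_peaks), set(ces.intergenic_peaks)]
            assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    def test_planted_links_recovered(self, default_dataset, default_config, pipeline_results):
        res = pipeline_results["species"]["a"]
        truth = default_dataset.truth
        links = {(l.peak_id, l.gene_id): l for l in res.links}
        planted = [
            (pk, t) for tf, pk, t, s in truth.planted_regulons["a"] if s == "positive"
        ]
        recovered = [
            (pk, t) in links
            and links[(pk, t)].r > default_config.ptog_r_min
            and links[(pk, t)].fdr < default_config.ptog_fdr_grn
            for pk, t in planted
        ]
        assert np.mean(recovered) >= 0.8
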