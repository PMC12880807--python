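"""Ortholog collapsing, cross-species DEGs, clustering, element counts,
local alignment and conserved-pair calling."""

import numpy as np
import pytest

from conegrn.config import PipelineConfig
from conegrn.cross_species import (
    cluster_deg_patterns,
    collapse_orthologs,
    conserved_pairs,
    count_elements_per_gene,
    cross_species_degs,
    local_align_best,
)
from conegrn.errors import PipelineError
from conegrn.matrix import CountMatrix, OrthologyMap, normalize_counts
from conegrn.motifs import revcomp
from conegrn.ptog import PtoGLink
from conegrn.synthetic import generate_peak_sequences


def sw_affine_oracle(s1, s2, match=1.0, mismatch=-1.0, open_=-3.0, ext=-1.0):
    """Independent Gotoh local-alignment DP (first gap base open_, then ext)."""
    n, m = len(s1), len(s2)
    NEG = -1e18
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if (s1[i - 1] == s2[j - 1] and s1[i - 1] != "N") else mismatch
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + sub)
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + ext)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + ext)
            best = max(best, M[i, j], Ix[i, j], Iy[i, j])
    return best


class TestCollapse:
    def test_many_to_one_sums(self):
        rna = CountMatrix(["c1"], ["a1", "a2", "a3"], np.array([[3, 4, 7]]))
        omap = OrthologyMap([("a1", "B"), ("a2", "B"), ("a3", "C")])
        out = collapse_orthologs(rna, omap)
        assert out.feature_ids == ["B", "C"]
        assert out.counts.tolist() == [[7, 7]]

    def test_one_to_one_is_renaming(self):
        rna = CountMatrix(["c1", "c2"], ["a1", "a2"], np.array([[1, 2], [3, 4]]))
        omap = OrthologyMap([("a1", "B1"), ("a2", "B2")])
        out = collapse_orthologs(rna, omap)
        assert np.array_equal(out.counts, rna.counts)

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(0)
        rna = CountMatrix(
            [f"c{i}" for i in range(5)],
            [f"a{j}" for j in range(8)],
            rng.poisson(4, (5, 8)),
        )
        omap = OrthologyMap([(f"a{j}", f"B{j % 3}") for j in range(8)])
        out = collapse_orthologs(rna, omap)
        assert out.counts.sum() == rna.counts.sum()


def _merged(seed=0, effect_cells=None):
    # 20 housekeeping genes anchor depth; G0 is low-baseline so a planted
    # fold change survives the log1p compression
    rng = np.random.default_rng(seed)
    cells, species, cts = [], {}, {}
    rows = []
    for sp in ("a", "b"):
        for ct in ("RPC", "N.RPC", "BC/Pho pre", "Cone", "Rod"):
            for i in range(40):
                cid = f"{sp}_{ct}_{i}"
                cells.append(cid)
                species[cid] = sp
                cts[cid] = ct
                mu = np.full(20, 3.0)
                mu[0] = 0.3
                if effect_cells and (sp, ct) in effect_cells:
                    mu[0] *= effect_cells[(sp, ct)]
                rows.append(rng.poisson(mu) + (np.arange(20) > 0).astype(int))
    m = normalize_counts(
        CountMatrix(cells, [f"G{j}" for j in range(20)], np.array(rows))
    )
    return m, species, cts


class TestDEGs:
    def test_planted_up_gene_found_in_cone_contrast(self):
        merged, sp, ct = _merged(effect_cells={("a", "Cone"): 30.0})
        degs = cross_species_degs(merged, sp, ct, PipelineConfig())
        cone = [d for d in degs if d.comparison == "Cone_vs_Cone" and d.gene == "G0"]
        assert cone and cone[0].direction == "species_a_up"

    def test_identical_species_empty(self):
        merged, sp, ct = _merged()
        assert cross_species_degs(merged, sp, ct, PipelineConfig()) == []

    def test_lfc_threshold_strict(self):
        # every retained record satisfies |lfc| > 0.35 and p < 1e-6 strictly
        merged, sp, ct = _merged(effect_cells={("a", "Cone"): 30.0})
        degs = cross_species_degs(merged, sp, ct, PipelineConfig())
        assert all(abs(d.log2fc) > 0.35 and d.p < 1e-6 for d in degs)


class TestClusters:
    def test_archetypes_recovered(self):
        rng = np.random.default_rng(1)
        archetypes = rng.normal(0, 3, size=(8, 10))
        genes, profiles, truth = [], [], []
        for g in range(120):
            k = g % 8
            genes.append(f"G{g}")
            profiles.append(archetypes[k] + rng.normal(0, 0.1, 10))
            truth.append(k)
        ca = cluster_deg_patterns(genes, np.array(profiles), [f"grp{i}" for i in range(10)], k=8, seed=0)
        from sklearn.metrics import adjusted_rand_score

        labels = [ca.clusters[g] for g in genes]
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert len(set(labels)) == 8
        assert set(ca.clusters) == set(genes)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        profiles = rng.normal(size=(40, 10))
        genes = [f"G{g}" for g in range(40)]
        a = cluster_deg_patterns(genes, profiles, list("abcdefghij"), seed=5)
        b = cluster_deg_patterns(genes, profiles, list("abcdefghij"), seed=5)
        assert a.clusters == b.clusters

    def test_too_few_profiles_rejected(self):
        with pytest.raises(PipelineError, match="too-few-profiles"):
            cluster_deg_patterns(
                ["G0", "G1"], np.ones((2, 10)), list("abcdefghij"), k=8
            )


class TestElementCounts:
    def _links(self, gene_counts, species="a"):
        links = []
        for g, n in gene_counts.items():
            for i in range(n):
                links.append(PtoGLink(f"{species}_pk{g}_{i}", g, 0.5, 1e-8, 1e-4, 1000))
        return links

    def test_normalization_arithmetic(self):
        links_a = self._links({"ga1": 2, "ga2": 4})
        links_b = self._links({"gb1": 3, "gb2": 3}, "b")
        clusters = {"gb1": 1, "gb2": 1}
        records, tests = count_elements_per_gene(
            links_a, links_b, [("ga1", "gb1"), ("ga2", "gb2")], clusters,
            PipelineConfig(),
        )
        norms = sorted(r.norm_a for r in records)
        assert norms == pytest.approx([2 / 3, 4 / 3])

    def test_degenerate_cluster_p_sentinel(self):
        links_a = self._links({"ga1": 2, "ga2": 2})
        links_b = self._links({"gb1": 2, "gb2": 2}, "b")
        clusters = {"gb1": 1, "gb2": 1}
        _, tests = count_elements_per_gene(
            links_a, links_b, [("ga1", "gb1"), ("ga2", "gb2")], clusters,
            PipelineConfig(),
        )
        assert tests[1]["p"] == 1.0

    def test_planted_excess_detected(self):
        # cluster-2 genes carry 3x elements in species a RELATIVE to the rest
        # of the genome (the per-species mean normalization removes any
        # uniform species-wide excess by construction)
        rng = np.random.default_rng(3)
        gene_counts_a, gene_counts_b, clusters, pairs = {}, {}, {}, []
        for i in range(40):
            ga, gb = f"ga{i}", f"gb{i}"
            planted = i < 20
            gene_counts_a[ga] = int(rng.poisson(9)) + 3 if planted else int(rng.poisson(3)) + 1
            gene_counts_b[gb] = int(rng.poisson(3)) + 1
            clusters[gb] = 2 if planted else 1
            pairs.append((ga, gb))
        records, tests = count_elements_per_gene(
            self._links(gene_counts_a), self._links(gene_counts_b, "b"),
            pairs, clusters, PipelineConfig(),
        )
        assert tests[2]["p"] < 0.01
        assert tests[2]["median_a"] > tests[2]["median_b"]


class TestLocalAlign:
    def test_perfect_match(self):
        score, orient = local_align_best("ACGTACGT", "ACGTACGT", PipelineConfig())
        assert score == 8.0 and orient == "forward"

    def test_revcomp_orientation(self):
        seq = "ACGTTGCAGGTT"
        score, orient = local_align_best(seq, revcomp(seq), PipelineConfig())
        assert score == float(len(seq)) and orient == "revcomp"

    def test_empty_rejected(self):
        with pytest.raises(PipelineError, match="empty-seq"):
            local_align_best("", "ACGT", PipelineConfig())

    def test_matches_dp_oracle_on_random_pairs(self):
        cfg = PipelineConfig()
        rng = np.random.default_rng(7)
        for _ in range(50):
            l1, l2 = rng.integers(5, 40, 2)
            s1 = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, l1)])
            s2 = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, l2)])
            expected = max(
                sw_affine_oracle(s1, s2), sw_affine_oracle(s1, revcomp(s2))
            )
            assert local_align_best(s1, s2, cfg)[0] == expected

    def test_double_revcomp_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            s1 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30)])
            s2 = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 25)])
            a = local_align_best(s1, s2, PipelineConfig())[0]
            b = local_align_best(revcomp(s1), revcomp(s2), PipelineConfig())[0]
            assert a == b


class TestConservedPairs:
    def test_normal_quantile_threshold(self):
        rng = np.random.default_rng(9)
        # independent random pairs: threshold = mu + 1.6449 sigma of scores
        fa, fb, flags = generate_peak_sequences(200, 0.0, 0.9, 100, seed=1)
        pairs = [
            (a, b, fa[a], fb[b]) for a, b in zip(sorted(fa), sorted(fb))
        ]
        calls = conserved_pairs(pairs, PipelineConfig())
        scores = np.array([c.score for c in calls])
        from scipy.stats import norm

        expected = scores.mean() + norm.ppf(0.95) * scores.std()
        assert calls[0].threshold == pytest.approx(expected)

    def test_all_equal_scores_rejected(self):
        pairs = [(f"a{i}", f"b{i}", "ACGTACGT", "ACGTACGT") for i in range(40)]
        with pytest.raises(PipelineError, match="degenerate-scores"):
            conserved_pairs(pairs, PipelineConfig())

    def test_planted_mixture_separated(self):
        fa, fb, flags = generate_peak_sequences(300, 0.1, 0.9, 200, seed=2)
        names_a, names_b = sorted(fa), sorted(fb)
        pairs = [(a, b, fa[a], fb[b]) for a, b in zip(names_a, names_b)]
        calls = conserved_pairs(pairs, PipelineConfig())
        by_name = {c.peak_a: c.conserved for c in calls}
        planted = [by_name[a] for a, f in zip(names_a, flags) if f]
        random_ = [by_name[a] for a, f in zip(names_a, flags) if not f]
        assert np.mean(planted) >= 0.95
        assert np.mean(random_) <= 0.10
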