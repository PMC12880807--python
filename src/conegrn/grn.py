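"""Signed TF-peak-target regulon inference and key-activator-TF scoring.

TF-target importance comes from a gradient-boosted tree regression of
each target's normalized expression on all TF expressions (100 trees,
depth 3, learning rate 0.1, subsample 0.9, fixed seed); per-target total
split gains are normalized to sum to 1 over TFs so the importance cutoff
(default 0.1) has a defined scale. An edge is positive when importance
> 0.1 and Pearson r > 0.05, negative when importance > 0.1 and
r < -0.05, otherwise unsigned.

A regulon is the triple (cell type, TF, peak, target, sign): the peak must
belong to the target's cis-element set and carry a footprint-passing
binding site for the TF in that cell type, and the TF-target edge must be
signed. Exact duplicate triples are removed.

Key cone-promoting activators are TFs whose positive targets are enriched
for cone-specific genes: upper-tail hypergeometric test over the positive
GRN's distinct targets, filtered at p < 1e-6 and coverage > 0.2, ranked by
the number of positively regulated cone-specific targets (top 30).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import PipelineError
from .matrix import CountMatrix
from .stats import bh_adjust, hypergeom_upper_tail, log2_fold_change, wilcoxon_rank_sum


@dataclass(frozen=True)
class Edge:
    tf: str
    target: str
    importance: float
    r: float
    sign: str  # positive | negative | none


@dataclass(frozen=True)
class Regulon:
    cell_type: str
    tf: str
    peak_id: str
    target: str
    sign: str


@dataclass(frozen=True)
class KeyTFResult:
    tf: str
    p_hyper: float
    coverage: float
    n_positive_cone_targets: int
    n_positive_targets: int
    rank: int


def importance_scores(
    normalized_rna: CountMatrix,
    tf_ids: list[str],
    target_id: str,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Per-TF normalized total-gain importance for one target gene."""
    import xgboost as xgb

    cfg = cfg or PipelineConfig()
    predictors = [t for t in tf_ids if t != target_id]
    if len(predictors) < 2:
        raise PipelineError("too-few-tfs", "need >= 2 TF predictors")
    X = normalized_rna.require_normalized()
    tf_idx = [normalized_rna.feature_idx(t) for t in predictors]
    y = X[:, normalized_rna.feature_idx(target_id)]
    if np.ptp(y) == 0:
        return {t: 0.0 for t in predictors}
    model = xgb.XGBRegressor(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        subsample=0.9,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    model.fit(X[:, tf_idx], y)
    gains = model.get_booster().get_score(importance_type="total_gain")
    raw = np.array([gains.get(f"f{i}", 0.0) for i in range(len(predictors))])
    total = raw.sum()
    if total <= 0:
        return {t: 0.0 for t in predictors}
    raw = raw / total
    return {t: float(v) for t, v in zip(predictors, raw)}


def classify_edge(importance: float, r: float, cfg: PipelineConfig | None = None) -> str:
    cfg = cfg or PipelineConfig()
    if importance < 0:
        raise PipelineError("bad-importance", "importance must be >= 0")
    if importance > cfg.importance_min and r > cfg.edge_r_pos:
        return "positive"
    if importance > cfg.importance_min and r < cfg.edge_r_neg:
        return "negative"
    return "none"


def infer_edges(
    normalized_rna: CountMatrix,
    tf_ids: list[str],
    target_ids: list[str],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> list[Edge]:
    """Importance + correlation + sign for every (TF, target) pair."""
    cfg = cfg or PipelineConfig()
    X = normalized_rna.require_normalized()
    edges: list[Edge] = []
    for j, target in enumerate(target_ids):
        imps = importance_scores(normalized_rna, tf_ids, target, cfg, seed=seed + j)
        y = X[:, normalized_rna.feature_idx(target)]
        for tf, imp in imps.items():
            x = X[:, normalized_rna.feature_idx(tf)]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            edges.append(Edge(tf, target, imp, r, classify_edge(imp, r, cfg)))
    return edges


def assemble_regulons(
    binding_by_celltype: dict[str, list],
    cis_elements: dict[str, "object"],
    edges: list[Edge],
    cfg: PipelineConfig | None = None,
) -> list[Regulon]:
    """Integrate binding sites, cis elements, and signed edges into regulons."""
    bound: dict[str, dict[str, set[str]]] = {}
    for cell_type, entries in binding_by_celltype.items():
        per_tf: dict[str, set[str]] = {}
        for tf, hit, _fp in entries:
            per_tf.setdefault(tf, set()).add(hit.peak_id)
        bound[cell_type] = per_tf
    out: set[Regulon] = set()
    for edge in edges:
        if edge.sign == "none":
            continue
        ces = cis_elements.get(edge.target)
        if ces is None:
            continue
        allowed = ces.all_peaks()
        for cell_type, per_tf in bound.items():
            for pid in per_tf.get(edge.tf, set()) & allowed:
                out.add(Regulon(cell_type, edge.tf, pid, edge.target, edge.sign))
    return sorted(out, key=lambda r: (r.cell_type, r.tf, r.peak_id, r.target))


def tf_target_regulons(regulons: list[Regulon]) -> list[tuple[str, str, str]]:
    """Peak-collapsed, deduplicated (tf, target, sign) regulons."""
    return sorted({(r.tf, r.target, r.sign) for r in regulons})


def cone_specific_genes(
    normalized_rna: CountMatrix,
    cell_labels: dict[str, str],
    cfg: PipelineConfig | None = None,
    cone_label: str = "Cone",
    other_labels: list[str] | None = None,
) -> list[str]:
    """Genes upregulated in cones vs other late-stage neurons.

    Wilcoxon rank-sum per gene, BH adjustment across genes; keep genes with
    log2 fold change > ``cone_de_lfc`` and adjusted p < ``cone_de_padj``,
    cone-upregulated only.
    """
    cfg = cfg or PipelineConfig()
    X = normalized_rna.require_normalized()
    labels = np.array([cell_labels[c] for c in normalized_rna.cell_ids])
    cone_mask = labels == cone_label
    if other_labels is None:
        other_mask = ~cone_mask
    else:
        other_mask = np.isin(labels, other_labels)
    if not cone_mask.any():
        raise PipelineError("no-cone-cells", "no cells labelled as cones")
    if not other_mask.any():
        raise PipelineError("no-comparison-cells", "no late-stage comparison cells")
    ps, lfcs = [], []
    for j in range(X.shape[1]):
        a, b = X[cone_mask, j], X[other_mask, j]
        ps.append(wilcoxon_rank_sum(a, b).p_value)
        lfcs.append(log2_fold_change(a.mean(), b.mean(), cfg.pseudocount).log2fc)
    padj = bh_adjust(ps)
    return [
        normalized_rna.feature_ids[j]
        for j in range(X.shape[1])
        if lfcs[j] > cfg.cone_de_lfc and padj[j] < cfg.cone_de_padj
    ]


def key_activator_tfs(
    regulons: list[Regulon],
    cone_genes: list[str],
    cfg: PipelineConfig | None = None,
) -> list[KeyTFResult]:
    """Key cone-promoting activator TFs from the positive GRN.

    Population = distinct targets across all positive regulons; per TF the
    draws are its distinct positive targets and the successes the
    cone-specific ones. Filter p < ``key_tf_p`` and coverage >
    ``key_tf_coverage``; rank by cone-specific target count (descending),
    ties by p then TF id; truncate to ``key_tf_top_n``.
    """
    cfg = cfg or PipelineConfig()
    positive = [(r.tf, r.target) for r in regulons if r.sign == "positive"]
    if not positive:
        raise PipelineError("empty-grn", "no positive regulons")
    cone_set = set(cone_genes)
    all_targets = {t for _, t in positive}
    N_pop = len(all_targets)
    K_success = len(all_targets & cone_set)
    targets_by_tf: dict[str, set[str]] = {}
    for tf, t in positive:
        targets_by_tf.setdefault(tf, set()).add(t)
    results = []
    for tf, targets in targets_by_tf.items():
        n_draws = len(targets)
        k = len(targets & cone_set)
        p = hypergeom_upper_tail(k, n_draws, K_success, N_pop)
        coverage = k / n_draws
        if p < cfg.key_tf_p and coverage > cfg.key_tf_coverage:
            results.append((tf, p, coverage, k, n_draws))
    results.sort(key=lambda x: (-x[3], x[1], x[0]))
    return [
        KeyTFResult(tf, p, cov, k, n, rank)
        for rank, (tf, p, cov, k, n) in enumerate(results[: cfg.key_tf_top_n], start=1)
    ]
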