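"""Cross-species comparison: ortholog collapsing, differential genes and
their k-means expression patterns, regulatory-element counting per
conserved gene pair, and conserved-enhancer calling by local alignment.

Ortholog collapsing maps species-a gene ids into the species-b gene space,
summing counts when several a-genes share one b-ortholog. Cross-species
DEGs are Wilcoxon tests per gene within each of the five cell-type
contrasts (RPC, N.RPC, BC/Pho precursor, cone vs cone, cone vs rod),
retained at |log2FC| > 0.35 and p < 1e-6. Merged DEG profiles (mean
normalized expression over the 10 species x cell-type groups,
row-standardized) are clustered with k-means, k = 8.

Conserved elements: per candidate peak pair, the Smith-Waterman local
alignment score (match +1, mismatch -1, affine gap open -2 / extend -1,
i.e. a length-L gap costs 2 + L) of the a-peak sequence against the b-peak
sequence in both orientations; a normal distribution is fitted to all
scores and pairs above its upper 5% quantile are called conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import PipelineConfig
from .errors import PipelineError
from .matrix import CountMatrix, OrthologyMap
from .motifs import revcomp
from .stats import log2_fold_change, paired_t, wilcoxon_rank_sum

FIVE_CONTRASTS = [
    ("RPC", "RPC"),
    ("N.RPC", "N.RPC"),
    ("BC/Pho pre", "BC/Pho pre"),
    ("Cone", "Cone"),
    ("Cone", "Rod"),
]


@dataclass(frozen=True)
class DEGRecord:
    gene: str                  # shared (species-b) gene id
    comparison: str            # e.g. "Cone_vs_Rod"
    log2fc: float              # species a over species b
    p: float
    direction: str             # species_a_up | species_b_up


@dataclass
class ClusterAssignment:
    clusters: dict[str, int]        # gene -> cluster id (1..k)
    centroids: np.ndarray           # k x n_groups
    group_names: list[str]


@dataclass(frozen=True)
class ConservationCall:
    peak_a: str
    peak_b: str
    score: float
    orientation: str            # forward | revcomp
    threshold: float
    conserved: bool


@dataclass(frozen=True)
class ElementCountRecord:
    gene_a: str
    gene_b: str
    cluster: int
    count_a: int
    count_b: int
    norm_a: float
    norm_b: float


def collapse_orthologs(rna: CountMatrix, omap: OrthologyMap) -> CountMatrix:
    """Collapse species-a genes into the species-b ortholog space.

    Counts of a-genes sharing one b-ortholog are summed per cell; genes
    without an ortholog are dropped. Total counts over mapped genes are
    conserved exactly.
    """
    if not omap.pairs:
        raise PipelineError("empty-ortholog-map", "no ortholog pairs")
    a2b = omap.a_to_b()
    targets = sorted({b for a, b in omap.pairs if a in set(rna.feature_ids)})
    t_index = {b: i for i, b in enumerate(targets)}
    out = np.zeros((rna.n_cells, len(targets)), dtype=rna.counts.dtype)
    present = set(rna.feature_ids)
    for a, b in omap.pairs:
        if a in present:
            out[:, t_index[b]] += rna.counts[:, rna.feature_idx(a)]
    return CountMatrix(list(rna.cell_ids), targets, out)


def cross_species_degs(
    merged_rna: CountMatrix,
    species: dict[str, str],
    cell_types: dict[str, str],
    cfg: PipelineConfig | None = None,
    species_a: str = "a",
    species_b: str = "b",
    contrasts: list[tuple[str, str]] | None = None,
) -> list[DEGRecord]:
    """Per-gene Wilcoxon DEGs for the five cross-species contrasts."""
    import warnings

    cfg = cfg or PipelineConfig()
    contrasts = contrasts if contrasts is not None else FIVE_CONTRASTS
    X = merged_rna.require_normalized()
    sp = np.array([species[c] for c in merged_rna.cell_ids])
    ct = np.array([cell_types[c] for c in merged_rna.cell_ids])
    records: list[DEGRecord] = []
    for ct_a, ct_b in contrasts:
        mask_a = (sp == species_a) & (ct == ct_a)
        mask_b = (sp == species_b) & (ct == ct_b)
        if not mask_a.any() or not mask_b.any():
            warnings.warn(f"contrast {ct_a} vs {ct_b}: a cell type is missing; skipped")
            continue
        name = f"{ct_a}_vs_{ct_b}".replace(" ", "").replace("/", "-")
        for j, gene in enumerate(merged_rna.feature_ids):
            a, b = X[mask_a, j], X[mask_b, j]
            lfc = log2_fold_change(a.mean(), b.mean(), cfg.pseudocount).log2fc
            if abs(lfc) <= cfg.deg_lfc:
                continue
            p = wilcoxon_rank_sum(a, b).p_value
            if p < cfg.deg_p:
                records.append(
                    DEGRecord(
                        gene,
                        name,
                        lfc,
                        p,
                        "species_a_up" if lfc > 0 else "species_b_up",
                    )
                )
    return records


def deg_mean_profiles(
    merged_rna: CountMatrix,
    species: dict[str, str],
    cell_types: dict[str, str],
    genes: list[str],
    cell_type_order: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-gene mean normalized expression over species x cell-type groups."""
    X = merged_rna.require_normalized()
    sp = np.array([species[c] for c in merged_rna.cell_ids])
    ct = np.array([cell_types[c] for c in merged_rna.cell_ids])
    if cell_type_order is None:
        cell_type_order = sorted(set(ct))
    groups, names = [], []
    for s in sorted(set(sp)):
        for c in cell_type_order:
            mask = (sp == s) & (ct == c)
            if mask.any():
                groups.append(mask)
                names.append(f"{s}:{c}")
    idx = [merged_rna.feature_idx(g) for g in genes]
    profiles = np.stack([X[m][:, idx].mean(axis=0) for m in groups], axis=1)
    return profiles, names


def cluster_deg_patterns(
    genes: list[str],
    profiles: np.ndarray,
    group_names: list[str],
    k: int = 8,
    seed: int = 0,
) -> ClusterAssignment:
    """Row-standardize profiles and k-means them into k clusters (10 runs)."""
    from sklearn.cluster import KMeans

    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] != len(genes):
        raise PipelineError("profile-shape", "one profile row per gene required")
    distinct = np.unique(profiles, axis=0).shape[0]
    if distinct < k:
        raise PipelineError("too-few-profiles", f"{distinct} distinct profiles < k={k}")
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (profiles - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(z)
    return ClusterAssignment(
        {g: int(lbl) + 1 for g, lbl in zip(genes, km.labels_)},
        km.cluster_centers_,
        list(group_names),
    )


def count_elements_per_gene(
    links_a: list,
    links_b: list,
    gene_pairs: list[tuple[str, str]],
    clusters: dict[str, int],
    cfg: PipelineConfig | None = None,
) -> tuple[list[ElementCountRecord], dict[int, dict]]:
    """Regulatory-element counts per conserved gene pair, normalized per
    species by the mean count per gene, with a paired t-test per cluster.

    A gene's regulatory elements are peaks within 500 kb with r > 0.25 and
    FDR < ``ptog_fdr_deg`` (0.01). Degenerate clusters (all differences
    zero) report the p = 1 sentinel; clusters with < 2 pairs skip the test
    but still report medians.
    """
    cfg = cfg or PipelineConfig()

    def _counts(links) -> dict[str, int]:
        out: dict[str, int] = {}
        for lk in links:
            if (
                lk.distance_bp <= cfg.cis_window_bp
                and lk.r > cfg.ptog_r_min
                and lk.fdr < cfg.ptog_fdr_deg
            ):
                out[lk.gene_id] = out.get(lk.gene_id, 0) + 1
        return out

    ca, cb = _counts(links_a), _counts(links_b)
    raw = [
        (ga, gb, ca.get(ga, 0), cb.get(gb, 0))
        for ga, gb in gene_pairs
        if gb in clusters
    ]
    if not raw:
        return [], {}
    mean_a = np.mean([r[2] for r in raw]) or 1.0
    mean_b = np.mean([r[3] for r in raw]) or 1.0
    records = [
        ElementCountRecord(ga, gb, clusters[gb], na, nb, na / mean_a, nb / mean_b)
        for ga, gb, na, nb in raw
    ]
    tests: dict[int, dict] = {}
    for cluster in sorted({r.cluster for r in records}):
        sub = [r for r in records if r.cluster == cluster]
        norm_a = np.array([r.norm_a for r in sub])
        norm_b = np.array([r.norm_b for r in sub])
        entry = {
            "n_pairs": len(sub),
            "median_a": float(np.median(norm_a)),
            "median_b": float(np.median(norm_b)),
            "statistic": float("nan"),
            "p": float("nan"),
        }
        if len(sub) >= 2:
            try:
                res = paired_t(norm_a, norm_b)
                entry["statistic"], entry["p"] = res.statistic, res.p_value
            except PipelineError as exc:
                if exc.code != "degenerate":
                    raise
                entry["statistic"], entry["p"] = 0.0, 1.0
        tests[cluster] = entry
    return records, tests


# --------------------------------------------------------------- conservation

_ALIGNER_CACHE: dict[tuple, object] = {}


def _aligner(cfg: PipelineConfig):
    from Bio import Align
    from Bio.Align import substitution_matrices

    key = (cfg.align_match, cfg.align_mismatch, cfg.gap_open, cfg.gap_extend)
    if key not in _ALIGNER_CACHE:
        a = Align.PairwiseAligner()
        a.mode = "local"
        m = np.full((5, 5), cfg.align_mismatch, dtype=float)
        for i in range(4):
            m[i, i] = cfg.align_match
        # N never matches, not even itself
        a.substitution_matrix = substitution_matrices.Array("ACGTN", dims=2, data=m)
        # Biostrings convention: a length-L gap costs |open| + |extend| * L
        a.open_gap_score = cfg.gap_open + cfg.gap_extend
        a.extend_gap_score = cfg.gap_extend
        _ALIGNER_CACHE[key] = a
    return _ALIGNER_CACHE[key]


def local_align_best(
    seq_a: str, seq_b: str, cfg: PipelineConfig | None = None
) -> tuple[float, str]:
    """Best local alignment score of seq_a vs seq_b over both orientations."""
    cfg = cfg or PipelineConfig()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise PipelineError("empty-seq", "empty sequence")
    bad = (set(seq_a) | set(seq_b)) - set("ACGTN")
    if bad:
        raise PipelineError("fasta-alphabet", f"invalid characters {sorted(bad)}")
    aligner = _aligner(cfg)
    fwd = float(aligner.score(seq_a, seq_b))
    rev = float(aligner.score(seq_a, revcomp(seq_b)))
    return (fwd, "forward") if fwd >= rev else (rev, "revcomp")


def conserved_pairs(
    pairs: list[tuple[str, str, str, str]],
    cfg: PipelineConfig | None = None,
) -> list[ConservationCall]:
    """Call conserved peak pairs against a fitted-normal score threshold.

    ``pairs``: (peak_a_id, peak_b_id, seq_a, seq_b). A normal distribution
    is fitted by maximum likelihood to ALL pairwise best-orientation
    scores; the threshold is its upper ``conserved_p`` (default 0.05)
    quantile and a pair is conserved iff its score strictly exceeds it.
    """
    cfg = cfg or PipelineConfig()
    if len(pairs) < 30:
        raise PipelineError("too-few-pairs", "need >= 30 pairs for a stable fit")
    scored = [
        (pa, pb, *local_align_best(sa, sb, cfg)) for pa, pb, sa, sb in pairs
    ]
    scores = np.array([s for _, _, s, _ in scored], dtype=float)
    mu, sigma = float(scores.mean()), float(scores.std())
    if sigma == 0:
        raise PipelineError("degenerate-scores", "all alignment scores equal")
    threshold = mu + sps.norm.ppf(1 - cfg.conserved_p) * sigma
    return [
        ConservationCall(pa, pb, s, orient, threshold, s > threshold)
        for pa, pb, s, orient in scored
    ]
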