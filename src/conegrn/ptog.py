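"""Peak-to-gene linking and cis-element assignment.

Raw single-cell accessibility is too sparse for per-cell correlations, so
cells are first aggregated into balanced pseudo-cell groups (k-means on
the top principal components of normalized expression, followed by a
balanced nearest-centroid assignment). Peak-to-gene (PtoG) links are then
Pearson correlations between group-mean normalized accessibility and
group-mean normalized expression for every peak within 500 kb of a gene's
TSS, with BH correction over all tested pairs.

Per target gene, three disjoint cis-element categories are assigned with
precedence TSS > gene body > intergenic:

1. TSS peaks — overlap the 1-kb window centred on the TSS (no
   correlation requirement);
2. gene-body peaks — overlap the gene body, with r > 0.25 and
   FDR below the caller's threshold;
3. intergenic peaks — within 500 kb of the TSS, overlapping no target
   gene's TSS window or body, with the same correlation requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .config import PipelineConfig
from .errors import PipelineError
from .genome import GeneModel, GenomicInterval
from .matrix import CountMatrix
from .stats import bh_adjust


@dataclass
class PseudoCellGrouping:
    assignments: dict[str, int]
    n_groups: int

    def group_indices(self, cell_ids: list[str]) -> np.ndarray:
        return np.array([self.assignments[c] for c in cell_ids], dtype=int)


@dataclass(frozen=True)
class PtoGLink:
    peak_id: str
    gene_id: str
    r: float
    p: float
    fdr: float
    distance_bp: int


@dataclass
class CisElementSet:
    gene_id: str
    tss_peaks: list[str] = field(default_factory=list)
    gene_body_peaks: list[str] = field(default_factory=list)
    intergenic_peaks: list[str] = field(default_factory=list)

    def all_peaks(self) -> set[str]:
        return set(self.tss_peaks) | set(self.gene_body_peaks) | set(self.intergenic_peaks)


def make_pseudocells(
    normalized_rna: CountMatrix,
    n_groups: int,
    seed: int = 0,
    min_size: int = 20,
    n_pcs: int = 30,
) -> PseudoCellGrouping:
    """Balanced k-means grouping of cells on top principal components.

    K-means provides centroids; cells are then assigned round-robin, each
    centroid in turn claiming its nearest unassigned cell, so group sizes
    differ by at most one. Deterministic under ``seed``.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = normalized_rna.require_normalized()
    n_cells = X.shape[0]
    if n_cells < n_groups * min_size:
        raise PipelineError(
            "too-few-cells", f"{n_cells} cells < {n_groups} groups x {min_size}"
        )
    k_pcs = min(n_pcs, X.shape[1], n_cells - 1)
    pcs = PCA(n_components=k_pcs, random_state=seed).fit_transform(X - X.mean(axis=0))
    km = KMeans(n_clusters=n_groups, random_state=seed, n_init=10).fit(pcs)
    # balanced assignment: round-robin over centroids by proximity
    d2 = ((pcs[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=0, kind="stable")  # per centroid, cells by distance
    ptr = np.zeros(n_groups, dtype=int)
    assigned = np.full(n_cells, -1, dtype=int)
    remaining = n_cells
    while remaining > 0:
        for g in range(n_groups):
            if remaining == 0:
                break
            while ptr[g] < n_cells and assigned[order[ptr[g], g]] != -1:
                ptr[g] += 1
            if ptr[g] < n_cells:
                assigned[order[ptr[g], g]] = g
                remaining -= 1
    return PseudoCellGrouping(
        {c: int(assigned[i]) for i, c in enumerate(normalized_rna.cell_ids)}, n_groups
    )


def _group_means(matrix: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    sums = np.zeros((n_groups, matrix.shape[1]))
    np.add.at(sums, groups, matrix)
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    return sums / counts[:, None]


def tss_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    """Distance from peak to the gene's TSS; 0 when the peak covers it."""
    tss = gene.tss
    if peak.chrom != tss.chrom:
        raise PipelineError("different-chrom", "peak and gene on different chromosomes")
    if peak.start <= tss.start < peak.end:
        return 0
    return max(peak.start - tss.start, tss.start - (peak.end - 1))


def ptog_correlations(
    rna: CountMatrix,
    atac: CountMatrix,
    grouping: PseudoCellGrouping,
    gene_models: list[GeneModel],
    peaks: dict[str, GenomicInterval],
    cfg: PipelineConfig | None = None,
) -> list[PtoGLink]:
    """Pearson PtoG links for every (peak, gene) within ``cis_window_bp``."""
    cfg = cfg or PipelineConfig()
    shared = [c for c in rna.cell_ids if c in set(atac.cell_ids)]
    if not shared:
        raise PipelineError("modalities-disjoint", "no shared cell ids")
    rna_s = rna.subset_cells(shared)
    atac_s = atac.subset_cells(shared)
    groups = grouping.group_indices(shared)
    ge = _group_means(rna_s.require_normalized(), groups, grouping.n_groups)
    pa = _group_means(atac_s.require_normalized(), groups, grouping.n_groups)
    n = grouping.n_groups

    # standardize columns once; constant columns get r = 0 downstream
    def _zscore(m):
        mu = m.mean(axis=0)
        sd = m.std(axis=0)
        ok = sd > 0
        z = np.zeros_like(m)
        z[:, ok] = (m[:, ok] - mu[ok]) / sd[ok]
        return z, ok

    zg, gene_ok = _zscore(ge)
    zp, peak_ok = _zscore(pa)

    peak_ids = list(peaks)
    peak_pos = {p: i for i, p in enumerate(atac_s.feature_ids)}
    candidates: list[tuple[str, str, int]] = []
    for gene in gene_models:
        for pid in peak_ids:
            pk = peaks[pid]
            if pk.chrom != gene.tss.chrom:
                continue
            d = tss_distance(pk, gene)
            if d <= cfg.cis_window_bp:
                candidates.append((pid, gene.gene_id, d))
    if not candidates:
        return []
    gene_pos = {g: i for i, g in enumerate(rna_s.feature_ids)}
    rs = np.empty(len(candidates))
    for i, (pid, gid, _) in enumerate(candidates):
        gi, pi = gene_pos[gid], peak_pos[pid]
        if gene_ok[gi] and peak_ok[pi]:
            rs[i] = float(zg[:, gi] @ zp[:, pi]) / n
        else:
            rs[i] = 0.0
    rs = np.clip(rs, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rs**2))
    ps = 2 * sps.t.sf(np.abs(t), df=n - 2)
    ps = np.clip(ps, 0.0, 1.0)
    fdrs = bh_adjust(ps)
    return [
        PtoGLink(pid, gid, float(rs[i]), float(ps[i]), float(fdrs[i]), d)
        for i, (pid, gid, d) in enumerate(candidates)
    ]


def _peaks_overlapping_gene_space(
    peaks: dict[str, GenomicInterval], gene_models: list[GeneModel], tss_half: int
) -> set[str]:
    """Peak ids overlapping ANY target gene's TSS window or body."""
    regions = []
    for g in gene_models:
        regions.append(g.body)
        regions.append(g.tss_window(tss_half))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    arrays = {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }
    excluded = set()
    for pid, pk in peaks.items():
        if pk.chrom not in arrays:
            continue
        starts, ends = arrays[pk.chrom]
        if np.any((starts < pk.end) & (pk.start < ends)):
            excluded.add(pid)
    return excluded


def assign_cis_elements(
    gene: GeneModel,
    peaks: dict[str, GenomicInterval],
    links: list[PtoGLink],
    all_gene_models: list[GeneModel],
    cfg: PipelineConfig | None = None,
    fdr_threshold: float | None = None,
    _excluded_peaks: set[str] | None = None,
    _gene_links: dict[str, PtoGLink] | None = None,
) -> CisElementSet:
    """Assign the three disjoint cis-element categories for one gene."""
    cfg = cfg or PipelineConfig()
    fdr_threshold = cfg.ptog_fdr_grn if fdr_threshold is None else fdr_threshold
    by_peak = (
        _gene_links
        if _gene_links is not None
        else {lk.peak_id: lk for lk in links if lk.gene_id == gene.gene_id}
    )
    half = cfg.tss_window_bp // 2
    tss_win = gene.tss_window(half)
    if _excluded_peaks is None:
        _excluded_peaks = _peaks_overlapping_gene_space(peaks, all_gene_models, half)
    out = CisElementSet(gene.gene_id)
    taken: set[str] = set()

    for pid, pk in peaks.items():
        if pk.overlaps(tss_win):
            out.tss_peaks.append(pid)
            taken.add(pid)

    def _passes(pid: str) -> bool:
        lk = by_peak.get(pid)
        return lk is not None and lk.r > cfg.ptog_r_min and lk.fdr < fdr_threshold

    for pid, pk in peaks.items():
        if pid in taken:
            continue
        if pk.overlaps(gene.body) and _passes(pid):
            out.gene_body_peaks.append(pid)
            taken.add(pid)

    for pid, pk in peaks.items():
        if pid in taken or pid in _excluded_peaks:
            continue
        if pk.chrom != gene.tss.chrom or tss_distance(pk, gene) > cfg.cis_window_bp:
            continue
        if _passes(pid):
            out.intergenic_peaks.append(pid)
            taken.add(pid)
    return out


def assign_all_cis_elements(
    gene_models: list[GeneModel],
    peaks: dict[str, GenomicInterval],
    links: list[PtoGLink],
    cfg: PipelineConfig | None = None,
    fdr_threshold: float | None = None,
) -> dict[str, CisElementSet]:
    """Cis-element sets for every target gene, sharing precomputed indexes."""
    cfg = cfg or PipelineConfig()
    half = cfg.tss_window_bp // 2
    excluded = _peaks_overlapping_gene_space(peaks, gene_models, half)
    links_by_gene: dict[str, dict[str, PtoGLink]] = {}
    for lk in links:
        links_by_gene.setdefault(lk.gene_id, {})[lk.peak_id] = lk
    return {
        g.gene_id: assign_cis_elements(
            g,
            peaks,
            links,
            gene_models,
            cfg,
            fdr_threshold,
            _excluded_peaks=excluded,
            _gene_links=links_by_gene.get(g.gene_id, {}),
        )
        for g in gene_models
    }
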