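"""Per-cell motif accessibility deviations (chromVAR-style) and the
cell-type-specific / cross-species differential-motif selections.

For a motif annotating a peak set S, the expected fragment count of a cell
is its depth times the fraction of all fragments falling in S; the raw
deviation is (observed - expected) / expected. Each motif's raw deviation
is standardized against ``n_background`` (default 50) background peak
sets, sampled per peak from a 2-D grid of (GC fraction, mean
accessibility) quantile bins, giving a z-score per cell and motif.

Differential motifs follow the marker conventions used for expression:
Wilcoxon on z-scores, BH adjustment across motifs, avg_diff = difference
of group mean z, retained at adjusted p < 0.01 and avg_diff > 2
(positive only); cross-species calls additionally require the motif's
gene to change expression in the same direction, and the merged set is
ordered by average-linkage hierarchical clustering of group-mean z
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import PipelineError
from .matrix import CountMatrix
from .stats import bh_adjust, wilcoxon_rank_sum


@dataclass
class DeviationMatrix:
    cell_ids: list[str]
    motif_ids: list[str]
    z: np.ndarray  # cells x motifs

    def motif_idx(self, motif_id: str) -> int:
        return self.motif_ids.index(motif_id)


@dataclass(frozen=True)
class DifferentialMotif:
    motif_id: str
    contrast: str
    avg_diff: float
    padj: float
    consistent_with_expression: bool | None = None


def gc_accessibility_bins(
    peak_ids: list[str],
    sequences: dict[str, str],
    atac: CountMatrix,
    n_bins: int = 10,
) -> dict[str, list[str]]:
    """Background candidates per peak from (GC, accessibility) quantile bins.

    Buckets containing a single peak are merged with the nearest bucket
    (Euclidean distance in the binned coordinates) with a warning.
    """
    gc = np.array(
        [
            (sequences[p].count("G") + sequences[p].count("C")) / max(1, len(sequences[p]))
            for p in peak_ids
        ]
    )
    idx = [atac.feature_idx(p) for p in peak_ids]
    access = atac.counts[:, idx].mean(axis=0).astype(float)

    def _qbin(x):
        qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(qs, x, side="right")

    bx, by = _qbin(gc), _qbin(access)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(bx, by)):
        buckets.setdefault(key, []).append(i)
    keys = list(buckets)
    for key in keys:
        if len(buckets.get(key, [])) == 1:
            others = [k for k in buckets if k != key and len(buckets[k]) > 1]
            if not others:
                continue
            nearest = min(others, key=lambda k: (k[0] - key[0]) ** 2 + (k[1] - key[1]) ** 2)
            warnings.warn(f"bucket {key} has one peak; merged into {nearest}")
            buckets[nearest].extend(buckets.pop(key))
    candidates: dict[str, list[str]] = {}
    member_of = {i: key for key, members in buckets.items() for i in members}
    for i, pid in enumerate(peak_ids):
        members = buckets[member_of[i]]
        candidates[pid] = [peak_ids[j] for j in members if j != i] or [pid]
    return candidates


def raw_deviations(atac: CountMatrix, peak_ids: list[str]) -> np.ndarray:
    """Per-cell raw accessibility deviation for one peak set.

    expected = cell depth x (peak set's fraction of all counts);
    raw = (observed - expected) / expected.
    """
    counts = atac.counts.astype(float)
    depths = counts.sum(axis=1)
    peak_idx = np.array([atac.feature_idx(p) for p in peak_ids])
    observed = counts[:, peak_idx].sum(axis=1)
    expected = depths * counts[:, peak_idx].sum() / counts.sum()
    expected = np.maximum(expected, 1e-12)
    return (observed - expected) / expected


def motif_deviations(
    atac: CountMatrix,
    motif_annotation: dict[str, list[str]],
    backgrounds: dict[str, list[str]],
    n_background: int = 50,
    seed: int = 0,
) -> DeviationMatrix:
    """Background-standardized accessibility deviation z-scores.

    Motifs annotating < 5 peaks are dropped with a warning. A motif whose
    background deviations have zero spread in a cell gets z = 0 there.
    """
    rng = np.random.default_rng(seed)
    counts = atac.counts.astype(float)
    depths = counts.sum(axis=1)
    total = counts.sum()
    peak_fraction = counts.sum(axis=0) / total
    pos = {p: i for i, p in enumerate(atac.feature_ids)}

    def _raw_deviation(peak_idx: np.ndarray) -> np.ndarray:
        observed = counts[:, peak_idx].sum(axis=1)
        expected = depths * peak_fraction[peak_idx].sum()
        expected = np.maximum(expected, 1e-12)
        return (observed - expected) / expected

    motif_ids = []
    zs = []
    for motif_id, peak_set in motif_annotation.items():
        if len(peak_set) < 5:
            warnings.warn(f"motif {motif_id} annotates < 5 peaks; dropped")
            continue
        peak_idx = np.array([pos[p] for p in peak_set])
        raw = _raw_deviation(peak_idx)
        bg_devs = np.empty((n_background, atac.n_cells))
        for b in range(n_background):
            bg_idx = np.array(
                [pos[rng.choice(backgrounds[p])] for p in peak_set]
            )
            bg_devs[b] = _raw_deviation(bg_idx)
        mu = bg_devs.mean(axis=0)
        sd = bg_devs.std(axis=0)
        z = np.zeros(atac.n_cells)
        ok = sd > 0
        z[ok] = (raw[ok] - mu[ok]) / sd[ok]
        motif_ids.append(motif_id)
        zs.append(z)
    if not motif_ids:
        raise PipelineError("no-motifs", "no motif annotates >= 5 peaks")
    return DeviationMatrix(list(atac.cell_ids), motif_ids, np.stack(zs, axis=1))


def _differential(
    dev: DeviationMatrix, mask_in: np.ndarray, mask_out: np.ndarray, contrast: str,
    cfg: PipelineConfig,
) -> list[DifferentialMotif]:
    ps, diffs = [], []
    for j in range(len(dev.motif_ids)):
        a, b = dev.z[mask_in, j], dev.z[mask_out, j]
        ps.append(wilcoxon_rank_sum(a, b).p_value)
        diffs.append(float(a.mean() - b.mean()))
    padj = bh_adjust(ps)
    return [
        DifferentialMotif(dev.motif_ids[j], contrast, diffs[j], float(padj[j]))
        for j in range(len(dev.motif_ids))
        if padj[j] < cfg.motif_padj and diffs[j] > cfg.motif_avg_diff
    ]


def celltype_specific_motifs(
    dev: DeviationMatrix,
    labels: dict[str, str],
    cfg: PipelineConfig | None = None,
) -> list[DifferentialMotif]:
    """One-vs-rest positive differential motifs per cell type."""
    cfg = cfg or PipelineConfig()
    lab = np.array([labels[c] for c in dev.cell_ids])
    types = sorted(set(lab))
    if len(types) < 2:
        raise PipelineError("single-group", "need >= 2 cell types")
    out = []
    for t in types:
        mask = lab == t
        out.extend(_differential(dev, mask, ~mask, t, cfg))
    return out


def cross_species_differential_motifs(
    dev: DeviationMatrix,
    species: dict[str, str],
    cell_types: dict[str, str],
    motif_genes: dict[str, str],
    expression_lfc: dict[tuple[str, str], float],
    cfg: PipelineConfig | None = None,
    species_a: str = "a",
    species_b: str = "b",
    contrasts: list[tuple[str, str]] | None = None,
) -> tuple[list[DifferentialMotif], list[str]]:
    """Species-vs-species differential motifs with expression consistency.

    ``expression_lfc`` maps (gene, contrast_name) -> log2 fold change of
    the motif's gene in the same contrast; a motif is retained only when
    the sign of its avg_diff matches the sign of that fold change. Motifs
    without a mapped gene are excluded with a warning. Returns the calls
    plus the merged motif ordering from average-linkage hierarchical
    clustering of group-mean z profiles.
    """
    from .cross_species import FIVE_CONTRASTS

    cfg = cfg or PipelineConfig()
    contrasts = contrasts if contrasts is not None else FIVE_CONTRASTS
    sp = np.array([species[c] for c in dev.cell_ids])
    ct = np.array([cell_types[c] for c in dev.cell_ids])
    calls: list[DifferentialMotif] = []
    for ct_a, ct_b in contrasts:
        mask_a = (sp == species_a) & (ct == ct_a)
        mask_b = (sp == species_b) & (ct == ct_b)
        if not mask_a.any() or not mask_b.any():
            continue
        name = f"{ct_a}_vs_{ct_b}".replace(" ", "").replace("/", "-")
        ps, diffs = [], []
        for j in range(len(dev.motif_ids)):
            a, b = dev.z[mask_a, j], dev.z[mask_b, j]
            ps.append(wilcoxon_rank_sum(a, b).p_value)
            diffs.append(float(a.mean() - b.mean()))
        padj = bh_adjust(ps)
        for j, motif_id in enumerate(dev.motif_ids):
            if padj[j] >= cfg.motif_padj or diffs[j] <= cfg.motif_avg_diff:
                continue
            gene = motif_genes.get(motif_id)
            if gene is None:
                warnings.warn(f"motif {motif_id} has no mapped gene; excluded")
                continue
            lfc = expression_lfc.get((gene, name))
            if lfc is None:
                warnings.warn(f"no expression fold change for {gene} in {name}; excluded")
                continue
            consistent = np.sign(diffs[j]) == np.sign(lfc) and lfc != 0
            if consistent:
                calls.append(
                    DifferentialMotif(motif_id, name, diffs[j], float(padj[j]), True)
                )
    retained = sorted({c.motif_id for c in calls})
    ordering = _hierarchical_order(dev, retained, species, cell_types)
    return calls, ordering


def _hierarchical_order(
    dev: DeviationMatrix, motif_ids: list[str], species: dict, cell_types: dict
) -> list[str]:
    if len(motif_ids) <= 2:
        return list(motif_ids)
    from scipy.cluster.hierarchy import average, leaves_list

    sp = np.array([species[c] for c in dev.cell_ids])
    ct = np.array([cell_types[c] for c in dev.cell_ids])
    groups = []
    for s in sorted(set(sp)):
        for c in sorted(set(ct)):
            mask = (sp == s) & (ct == c)
            if mask.any():
                groups.append(mask)
    idx = [dev.motif_ids.index(m) for m in motif_ids]
    profiles = np.stack([dev.z[m][:, idx].mean(axis=0) for m in groups], axis=1)
    from scipy.spatial.distance import pdist

    link = average(pdist(profiles, metric="euclidean"))
    return [motif_ids[i] for i in leaves_list(link)]
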