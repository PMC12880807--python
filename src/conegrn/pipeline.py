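"""End-to-end orchestration of the cross-species multiome analysis.

``run_all`` executes the eleven stages on a dataset directory and writes
TSV/JSON outputs plus a manifest: element annotation, peak-to-gene
linking, TF-binding-site prediction, GRN assembly and key-TF scoring per
species; then ortholog collapsing, cross-species DEGs and their k-means
patterns, regulatory-element counting, conserved-enhancer calling, motif
deviations and differential motifs across species.

Every stochastic stage consumes an independent substream spawned from the
single config seed, so re-running with the same config reproduces
hash-identical outputs and adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .cross_species import (
    cluster_deg_patterns,
    collapse_orthologs,
    conserved_pairs,
    count_elements_per_gene,
    cross_species_degs,
    deg_mean_profiles,
)
from .elements import annotate_elements
from .errors import PipelineError
from .grn import (
    assemble_regulons,
    cone_specific_genes,
    infer_edges,
    key_activator_tfs,
    tf_target_regulons,
)
from .io import write_tsv
from .matrix import CountMatrix, normalize_counts
from .motif_activity import (
    cross_species_differential_motifs,
    gc_accessibility_bins,
    motif_deviations,
)
from .motifs import predict_binding_sites, scan_peak, score_threshold
from .ptog import assign_all_cis_elements, make_pseudocells, ptog_correlations
from .stats import log2_fold_change
from .synthetic import CELL_TYPES, SpeciesData, SyntheticDataset

LATE_NEURON_TYPES = ["BC/Pho pre", "Rod"]  # cone comparison set


@dataclass
class SpeciesResults:
    annotations: dict
    grouping: object
    links: list
    cis_elements: dict
    binding: dict
    edges: list
    regulons: list
    tf_target: list


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    stages: list[dict]
    seed: int
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def validate_dataset(ds: SyntheticDataset) -> list[str]:
    """Consistency report; empty list means the dataset is valid."""
    failures = []
    for sp, data in ds.species.items():
        if set(data.rna.cell_ids) != set(data.atac.cell_ids):
            failures.append(f"{sp}: modalities-disjoint")
        missing_seq = set(data.peaks) - set(data.sequences)
        if missing_seq:
            failures.append(f"{sp}: missing-sequence ({len(missing_seq)} peaks)")
        if set(data.cell_types) != set(data.rna.cell_ids):
            failures.append(f"{sp}: annotation-cell-mismatch")
        gene_set = set(g.gene_id for g in data.gene_models)
        if gene_set != set(data.rna.feature_ids):
            failures.append(f"{sp}: gene-model-mismatch")
        for tf in data.tf_motifs:
            if tf not in gene_set:
                failures.append(f"{sp}: tf-not-a-gene ({tf})")
        for tf, m in data.tf_motifs.items():
            if m not in ds.pwms:
                failures.append(f"{sp}: missing-pwm ({m})")
    genes_a = {g.gene_id for g in ds.species.get("a").gene_models} if "a" in ds.species else set()
    genes_b = {g.gene_id for g in ds.species.get("b").gene_models} if "b" in ds.species else set()
    for a, b in ds.truth.ortholog_map.pairs:
        if genes_a and a not in genes_a:
            failures.append(f"orthology: unknown gene_a {a}")
        if genes_b and b not in genes_b:
            failures.append(f"orthology: unknown gene_b {b}")
    return failures


def mean_tf_expression_by_celltype(
    rna: CountMatrix, cell_types: dict[str, str], tf_ids: list[str]
) -> dict[str, dict[str, float]]:
    X = rna.require_normalized()
    labels = np.array([cell_types[c] for c in rna.cell_ids])
    out: dict[str, dict[str, float]] = {}
    for ct in sorted(set(labels)):
        mask = labels == ct
        out[ct] = {
            tf: float(X[mask, rna.feature_idx(tf)].mean()) for tf in tf_ids
        }
    return out


class StageLog:
    """Accumulates wall time per named pipeline stage (insertion order)."""

    def __init__(self):
        self.seconds: dict[str, float] = {}

    def record(self, name: str, t0: float) -> float:
        now = time.time()
        self.seconds[name] = self.seconds.get(name, 0.0) + (now - t0)
        return now

    def entries(self) -> list[dict]:
        return [
            {"stage": name, "seconds": round(sec, 3)}
            for name, sec in self.seconds.items()
        ]


def analyze_species(
    data: SpeciesData,
    pwms: dict,
    cfg: PipelineConfig,
    seed: int,
    fdr_threshold: float | None = None,
    stage_log: StageLog | None = None,
) -> SpeciesResults:
    """Per-species stages: elements, PtoG, binding sites, edges, regulons."""
    log = stage_log or StageLog()
    t = time.time()
    annotations = annotate_elements(
        data.peaks, data.histone_peaks, data.histone_tracks, cfg
    )
    t = log.record("annotate-elements", t)
    n_cells = data.rna.n_cells
    n_groups = min(cfg.pseudocell_groups, n_cells // (2 * cfg.pseudocell_min_size))
    grouping = make_pseudocells(
        data.rna, n_groups, seed=seed, min_size=cfg.pseudocell_min_size,
        n_pcs=cfg.n_pcs,
    )
    links = ptog_correlations(
        data.rna, data.atac, grouping, data.gene_models, data.peaks, cfg
    )
    cis = assign_all_cis_elements(
        data.gene_models, data.peaks, links, cfg, fdr_threshold
    )
    t = log.record("ptog", t)
    expr_by_ct = mean_tf_expression_by_celltype(data.rna, data.cell_types, data.tf_ids)
    binding = predict_binding_sites(
        expr_by_ct, pwms, data.tf_motifs, data.peaks, data.sequences,
        data.insertion_by_celltype, cfg,
    )
    t = log.record("tfbs", t)
    targets = [g.gene_id for g in data.gene_models if g.gene_id not in set(data.tf_ids)]
    edges = infer_edges(data.rna, data.tf_ids, targets, cfg, seed=seed)
    regulons = assemble_regulons(binding, cis, edges, cfg)
    log.record("grn", t)
    return SpeciesResults(
        annotations, grouping, links, cis, binding, edges, regulons,
        tf_target_regulons(regulons),
    )


def merge_species_rna(ds: SyntheticDataset, cfg: PipelineConfig) -> tuple[
    CountMatrix, dict[str, str], dict[str, str]
]:
    """Collapse species-a genes onto b orthologs and merge both matrices."""
    a, b = ds.species["a"], ds.species["b"]
    collapsed = collapse_orthologs(a.rna, ds.truth.ortholog_map)
    shared = [g for g in collapsed.feature_ids if g in set(b.rna.feature_ids)]
    idx_a = [collapsed.feature_idx(g) for g in shared]
    idx_b = [b.rna.feature_idx(g) for g in shared]
    counts = np.vstack([collapsed.counts[:, idx_a], b.rna.counts[:, idx_b]])
    merged = normalize_counts(
        CountMatrix(list(collapsed.cell_ids) + list(b.rna.cell_ids), shared, counts),
        cfg.normalize_scale,
    )
    species = {c: "a" for c in a.rna.cell_ids} | {c: "b" for c in b.rna.cell_ids}
    cell_types = dict(a.cell_types) | dict(b.cell_types)
    return merged, species, cell_types


def conservation_candidates(
    ds: SyntheticDataset, results: dict[str, SpeciesResults]
) -> list[tuple[str, str, str, str]]:
    """Candidate peak pairs: TSS-window peaks of each 1-1 ortholog gene pair."""
    a, b = ds.species["a"], ds.species["b"]
    pairs = []
    seen = set()
    for ga, gb in ds.truth.ortholog_map.one_to_one():
        ces_a = results["a"].cis_elements.get(ga)
        ces_b = results["b"].cis_elements.get(gb)
        if ces_a is None or ces_b is None:
            continue
        for pa in ces_a.tss_peaks:
            for pb in ces_b.tss_peaks:
                if (pa, pb) in seen:
                    continue
                seen.add((pa, pb))
                pairs.append((pa, pb, a.sequences[pa], b.sequences[pb]))
    return pairs


def run_analysis(
    ds: SyntheticDataset,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run all stages in memory; returns a dict of stage results."""
    cfg = cfg or ds.config
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]
    failures = validate_dataset(ds)
    if failures:
        raise PipelineError("invalid-dataset", "; ".join(failures))
    log = StageLog()
    results: dict[str, SpeciesResults] = {}
    for i, sp in enumerate(sorted(ds.species)):
        results[sp] = analyze_species(
            ds.species[sp], ds.pwms, cfg, seed=subseeds[i % 2], stage_log=log
        )
    out: dict = {"species": results, "stage_log": log}

    # key cone-promoting TFs (species a)
    t = time.time()
    a = ds.species["a"]
    cone_genes = cone_specific_genes(
        a.rna, a.cell_types, cfg, other_labels=LATE_NEURON_TYPES
    )
    out["cone_genes"] = cone_genes
    try:
        out["key_tfs"] = key_activator_tfs(results["a"].regulons, cone_genes, cfg)
    except PipelineError as exc:
        if exc.code != "empty-grn":
            raise
        import warnings

        warnings.warn("no positive regulons in species a; key-TF list is empty")
        out["key_tfs"] = []
    t = log.record("key-tfs", t)

    # cross-species expression comparison
    merged, species_lbl, ct_lbl = merge_species_rna(ds, cfg)
    t = log.record("orthologs", t)
    out["merged_rna"] = merged
    degs = cross_species_degs(merged, species_lbl, ct_lbl, cfg)
    out["degs"] = degs
    t = log.record("degs", t)
    deg_genes = sorted({d.gene for d in degs})
    if len(deg_genes) >= cfg.kmeans_k:
        profiles, group_names = deg_mean_profiles(
            merged, species_lbl, ct_lbl, deg_genes, cell_type_order=CELL_TYPES
        )
        clusters = cluster_deg_patterns(
            deg_genes, profiles, group_names, k=cfg.kmeans_k, seed=subseeds[2]
        )
        out["deg_clusters"] = clusters
        # element counts per conserved gene pair
        b_of = dict(ds.truth.ortholog_map.one_to_one())
        gene_pairs = [(ga, gb) for ga, gb in b_of.items()]
        records, tests = count_elements_per_gene(
            results["a"].links, results["b"].links, gene_pairs,
            clusters.clusters, cfg,
        )
        out["element_counts"] = (records, tests)
    else:
        out["deg_clusters"] = None
        out["element_counts"] = ([], {})
    t = log.record("element-counts", t)

    # conserved regulatory elements
    candidates = conservation_candidates(ds, results)
    out["conservation"] = (
        conserved_pairs(candidates, cfg) if len(candidates) >= 30 else []
    )
    t = log.record("conservation", t)

    # motif activity
    devs = {}
    for sp in sorted(ds.species):
        data = ds.species[sp]
        thresholds = {m: score_threshold(p, cfg.motif_p) for m, p in ds.pwms.items()}
        annotation: dict[str, list[str]] = {}
        for mid, pwm in ds.pwms.items():
            hit_peaks = [
                pid
                for pid, seq in data.sequences.items()
                if scan_peak(pwm, seq, thresholds[mid], data.peaks[pid], pid)
            ]
            if len(hit_peaks) >= 5:
                annotation[mid] = hit_peaks
        backgrounds = gc_accessibility_bins(
            list(data.peaks), data.sequences, data.atac, cfg.gc_bins
        )
        devs[sp] = motif_deviations(
            data.atac, annotation, backgrounds, cfg.n_background, seed=subseeds[3]
        )
    common_motifs = sorted(set(devs["a"].motif_ids) & set(devs["b"].motif_ids))
    from .motif_activity import DeviationMatrix

    za = devs["a"].z[:, [devs["a"].motif_ids.index(m) for m in common_motifs]]
    zb = devs["b"].z[:, [devs["b"].motif_ids.index(m) for m in common_motifs]]
    combined = DeviationMatrix(
        list(devs["a"].cell_ids) + list(devs["b"].cell_ids),
        common_motifs,
        np.vstack([za, zb]),
    )
    out["deviations"] = combined
    t = log.record("motif-dev", t)

    # motif -> shared gene map and expression fold changes per contrast
    a2b = ds.truth.ortholog_map.a_to_b()
    motif_genes = {}
    for tf, m in ds.species["a"].tf_motifs.items():
        if tf in a2b:
            motif_genes[m] = a2b[tf]
    expression_lfc = _expression_lfc_by_contrast(merged, species_lbl, ct_lbl, cfg)
    calls, ordering = cross_species_differential_motifs(
        combined, species_lbl, ct_lbl, motif_genes, expression_lfc, cfg
    )
    out["diff_motifs"] = (calls, ordering)
    log.record("diff-motifs", t)
    return out


def _expression_lfc_by_contrast(merged, species_lbl, ct_lbl, cfg):
    from .cross_species import FIVE_CONTRASTS

    X = merged.require_normalized()
    sp = np.array([species_lbl[c] for c in merged.cell_ids])
    ct = np.array([ct_lbl[c] for c in merged.cell_ids])
    out: dict[tuple[str, str], float] = {}
    for ct_a, ct_b in FIVE_CONTRASTS:
        mask_a = (sp == "a") & (ct == ct_a)
        mask_b = (sp == "b") & (ct == ct_b)
        if not mask_a.any() or not mask_b.any():
            continue
        name = f"{ct_a}_vs_{ct_b}".replace(" ", "").replace("/", "-")
        for j, gene in enumerate(merged.feature_ids):
            lfc = log2_fold_change(
                X[mask_a, j].mean(), X[mask_b, j].mean(), cfg.pseudocount
            ).log2fc
            out[(gene, name)] = lfc
    return out


# ------------------------------------------------------------------ on disk


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(dataset_dir: str | Path, out_dir: str | Path,
            cfg: PipelineConfig | None = None) -> RunManifest:
    """Load a dataset directory, run all stages, write outputs + manifest."""
    from .dataset import load_dataset

    dataset_dir, out_dir = Path(dataset_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(dataset_dir)
    if cfg is not None:
        ds.config = cfg
    cfg = ds.config
    stages: list[dict] = []

    def _stage(name, fn):
        t0 = time.time()
        res = fn()
        stages.append({"stage": name, "seconds": round(time.time() - t0, 3)})
        return res

    failures = _stage("validate", lambda: validate_dataset(ds))
    if failures:
        raise PipelineError("invalid-dataset", "; ".join(failures))
    res = run_analysis(ds, cfg)
    stages.extend(res["stage_log"].entries())

    outputs: dict[str, str] = {}

    def _write(name, rows, columns):
        path = out_dir / name
        write_tsv(rows, path, columns)
        outputs[name] = _hash_file(path)

    for sp, r in res["species"].items():
        _write(
            f"elements_{sp}.tsv",
            [
                {
                    "peak_id": pid,
                    "cls": ann.cls,
                    **{
                        f"{m}_positive": int(ann.calls[m].positive)
                        for m in ("H3K4me3", "H3K27ac", "H3K4me1")
                    },
                }
                for pid, ann in sorted(r.annotations.items())
            ],
            None,
        )
        _write(
            f"ptog_links_{sp}.tsv",
            [
                {
                    "peak_id": lk.peak_id, "gene_id": lk.gene_id,
                    "r": f"{lk.r:.6g}", "p": f"{lk.p:.6g}",
                    "fdr": f"{lk.fdr:.6g}", "distance_bp": lk.distance_bp,
                }
                for lk in r.links
            ],
            None,
        )
        _write(
            f"regulons_{sp}.tsv",
            [
                {
                    "cell_type": g.cell_type, "tf": g.tf, "peak_id": g.peak_id,
                    "target": g.target, "sign": g.sign,
                }
                for g in r.regulons
            ],
            None,
        )
    _write(
        "key_tfs.tsv",
        [
            {
                "tf": k.tf, "rank": k.rank, "k": k.n_positive_cone_targets,
                "n": k.n_positive_targets, "p": f"{k.p_hyper:.6g}",
                "coverage": f"{k.coverage:.4f}",
            }
            for k in res["key_tfs"]
        ],
        None,
    )
    _write(
        "degs.tsv",
        [
            {
                "gene": d.gene, "comparison": d.comparison,
                "log2fc": f"{d.log2fc:.6g}", "p": f"{d.p:.6g}",
                "direction": d.direction,
            }
            for d in res["degs"]
        ],
        None,
    )
    if res["deg_clusters"] is not None:
        _write(
            "deg_clusters.tsv",
            [
                {"gene": g, "cluster": c}
                for g, c in sorted(res["deg_clusters"].clusters.items())
            ],
            None,
        )
    records, tests = res["element_counts"]
    _write(
        "element_counts.tsv",
        [
            {
                "gene_a": r.gene_a, "gene_b": r.gene_b, "cluster": r.cluster,
                "count_a": r.count_a, "count_b": r.count_b,
                "norm_a": f"{r.norm_a:.4f}", "norm_b": f"{r.norm_b:.4f}",
            }
            for r in records
        ],
        None,
    )
    _write(
        "conservation.tsv",
        [
            {
                "peak_a": c.peak_a, "peak_b": c.peak_b,
                "score": f"{c.score:.4f}", "orientation": c.orientation,
                "threshold": f"{c.threshold:.4f}", "conserved": int(c.conserved),
            }
            for c in res["conservation"]
        ],
        None,
    )
    calls, ordering = res["diff_motifs"]
    _write(
        "diff_motifs.tsv",
        [
            {
                "motif_id": c.motif_id, "contrast": c.contrast,
                "avg_diff": f"{c.avg_diff:.4f}", "padj": f"{c.padj:.6g}",
            }
            for c in calls
        ],
        None,
    )

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        input_checksums={
            str(p.relative_to(dataset_dir)): _hash_file(p)
            for p in sorted(dataset_dir.rglob("*"))
            if p.is_file()
        },
        stages=stages,
        seed=cfg.seed,
        outputs=outputs,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
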