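"""Synthetic two-species multiome generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline can be exercised and scored without any external data:

* five retinal cell types (RPC, N.RPC, BC/Pho pre, Cone, Rod) with
  negative-binomial RNA and ATAC counts;
* TFs with cell-type activity patterns (a primary type at full activity
  plus a distinct secondary type at partial activity, so co-active TFs
  remain statistically distinguishable); five designated cone-promoting
  TFs whose positive targets form the planted cone program;
* planted TF -> peak -> target regulons: positive targets are
  over-expressed by ``effect_size`` per unit TF activity and their
  enhancer peaks gain accessibility in step; negative targets are
  repressed where the TF is active, through a TSS-proximal peak;
* bound motif sites embedded in enhancer sequences, with
  footprint-protected Tn5 insertion profiles (center rate = 0.4 x flank
  rate) in the cell types where the TF is expressed;
* histone-mark peaks and signal consistent with each element's class
  (TSS / aEnhancer / pEnhancer / unclassified);
* a second species derived from the same ancestral layout with two
  species-a-specific cone TFs removed, plus a many-to-one ortholog map
  (10% of a-side genes are duplicates of a b-side gene);
* conserved promoter-sequence pairs sharing a high-identity core, half of
  them reverse-complemented.

Everything is deterministic given the seed; independent substreams are
spawned per stage so adding a stage never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import PipelineError
from .genome import GeneModel, GenomicInterval, SignalTrack
from .matrix import CountMatrix, OrthologyMap, normalize_counts
from .motifs import PWM, build_pwm, revcomp

CELL_TYPES = ["RPC", "N.RPC", "BC/Pho pre", "Cone", "Rod"]
CELL_TYPE_PROPORTIONS = {
    "RPC": 0.25,
    "N.RPC": 0.20,
    "BC/Pho pre": 0.20,
    "Cone": 0.20,
    "Rod": 0.15,
}

# generator defaults (the study conditions; see docs/methods.md)
TF_HIGH_MU = 6.0
TF_LOW_MU = 0.02
SECONDARY_LEVEL = 0.35
BASE_MU_LOG_MEAN = 0.3
BASE_MU_LOG_SD = 0.4
PROMOTER_ATAC_MU = 3.0
ENHANCER_ATAC_MU = 1.0
BACKGROUND_ATAC_MU = 1.0
GENE_SPACING = 40_000
GENE_BODY_LEN = 10_000
PEAK_LEN = 200
MOTIF_LEN = 10
FLANK_RATE = 0.5
PROTECTION_FACTOR = 0.4
INSERTION_DEPTH = 100.0
INSERTION_BIN = 10
HISTONE_ON_MEAN, HISTONE_ON_SD = 5.0, 0.7
HISTONE_OFF_MEAN, HISTONE_OFF_SD = 1.0, 0.5
ACTIVATION_HALF = 3.0
N_CONE_TFS = 5
N_CONE_TARGETS = 18
N_OTHER_POS_TARGETS = 7
N_OTHER_NEG_TARGETS = 2
DUPLICATE_FRAC = 0.1


@dataclass(frozen=True)
class PlantedSite:
    peak_id: str
    motif_id: str
    site: GenomicInterval
    strand: str
    bound_cell_types: tuple


@dataclass
class SyntheticTruth:
    planted_regulons: dict[str, list[tuple[str, str, str, str]]]
    bound_sites: dict[str, list[PlantedSite]]
    conserved_pairs: list[tuple[str, str]]
    cone_tfs: list[str]
    element_classes: dict[str, dict[str, str]]
    ortholog_map: OrthologyMap


@dataclass
class SpeciesData:
    name: str
    rna: CountMatrix
    atac: CountMatrix
    peaks: dict[str, GenomicInterval]
    gene_models: list[GeneModel]
    cell_types: dict[str, str]
    time_points: dict[str, str]
    tf_ids: list[str]
    tf_motifs: dict[str, str]
    sequences: dict[str, str]
    insertion_by_celltype: dict[str, SignalTrack]
    histone_peaks: dict[str, list[GenomicInterval]]
    histone_tracks: dict[str, SignalTrack]
    chrom_lengths: dict[str, int]


@dataclass
class SyntheticDataset:
    species: dict[str, SpeciesData]
    pwms: dict[str, PWM]
    truth: SyntheticTruth
    config: PipelineConfig = field(default_factory=PipelineConfig)


# --------------------------------------------------------------- primitives


def generate_insertion_profile(
    site: GenomicInterval, bound: bool, depth: float, seed: int
) -> SignalTrack:
    """Per-base normalized Tn5 insertion signal over site plus 3x flanks.

    Poisson per-base counts at ``FLANK_RATE * depth``; a bound site's
    center rate is ``PROTECTION_FACTOR`` times the flank rate. Values are
    counts divided by depth, so the expected flank signal is FLANK_RATE.
    """
    if len(site) < 5:
        raise PipelineError("bad-site", "site length must be >= 5")
    rng = np.random.default_rng(seed)
    w = len(site) * 3
    start = max(0, site.start - w)
    end = site.end + w
    intervals, values = [], []
    for pos in range(start, end):
        in_center = site.start <= pos < site.end
        rate = FLANK_RATE * (PROTECTION_FACTOR if (bound and in_center) else 1.0)
        count = rng.poisson(rate * depth)
        intervals.append(GenomicInterval(site.chrom, pos, pos + 1))
        values.append(count / depth)
    return SignalTrack(intervals, values)


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = []
    for b in seq:
        if rng.random() < 1 - identity:
            out.append(bases[(bases.index(b) + rng.integers(1, 4)) % 4])
        else:
            out.append(b)
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def generate_peak_sequences(
    n_pairs: int,
    conserved_frac: float,
    identity: float,
    length: int,
    seed: int,
) -> tuple[dict[str, str], dict[str, str], list[bool]]:
    """Peak-sequence pairs; a ``conserved_frac`` share a high-identity core.

    Conserved partners are the a-side sequence with per-base substitution
    rate ``1 - identity``; every second conserved partner is
    reverse-complemented. Non-conserved pairs are independent uniform
    sequences.
    """
    if not (0.5 < identity <= 1.0):
        raise PipelineError("bad-identity", "identity must be in (0.5, 1]")
    if length < 50:
        raise PipelineError("bad-length", "length must be >= 50")
    rng = np.random.default_rng(seed)
    fasta_a, fasta_b, flags = {}, {}, []
    n_conserved = int(round(n_pairs * conserved_frac))
    conserved_idx = set(rng.choice(n_pairs, size=n_conserved, replace=False).tolist())
    n_rc = 0
    for i in range(n_pairs):
        a = _random_seq(length, rng)
        if i in conserved_idx:
            b = _mutate(a, identity, rng)
            if n_rc % 2 == 1:
                b = revcomp(b)
            n_rc += 1
            flags.append(True)
        else:
            b = _random_seq(length, rng)
            flags.append(False)
        fasta_a[f"pa_{i:05d}"] = a
        fasta_b[f"pb_{i:05d}"] = b
    return fasta_a, fasta_b, flags


def generate_histone_tracks(
    element_classes: dict[str, str],
    peaks: dict[str, GenomicInterval],
    seed: int,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, SignalTrack]]:
    """Histone peak calls + signal tracks consistent with element classes.

    The defining mark of a class (TSS -> H3K4me3, aEnhancer -> H3K27ac,
    pEnhancer -> H3K4me1) gets a peak call over the element and signal
    ~ Normal(5, 0.7); all other marks have no call there and signal
    ~ |Normal(1, 0.5)|.
    """
    rng = np.random.default_rng(seed)
    defining = {"TSS": "H3K4me3", "aEnhancer": "H3K27ac", "pEnhancer": "H3K4me1"}
    marks = ["H3K4me3", "H3K27ac", "H3K4me1"]
    mark_peaks: dict[str, list[GenomicInterval]] = {m: [] for m in marks}
    mark_vals: dict[str, tuple[list, list]] = {m: ([], []) for m in marks}
    for pid in sorted(element_classes):
        cls = element_classes[pid]
        region = peaks[pid]
        on_mark = defining.get(cls)
        for m in marks:
            ivs, vals = mark_vals[m]
            if m == on_mark:
                mark_peaks[m].append(region)
                v = max(0.0, rng.normal(HISTONE_ON_MEAN, HISTONE_ON_SD))
            else:
                v = abs(rng.normal(HISTONE_OFF_MEAN, HISTONE_OFF_SD))
            ivs.append(region)
            vals.append(v)
    tracks = {m: SignalTrack(*mark_vals[m]) for m in marks}
    return mark_peaks, tracks


# ------------------------------------------------------------ full dataset


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu, var mu + mu^2 / dispersion."""
    mu = np.maximum(mu, 1e-9)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _distinct_consensus(rng, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        c = _random_seq(length, rng)
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def generate_dataset(
    cfg: PipelineConfig | None = None,
    n_cells: int = 1500,
    n_genes: int = 300,
    n_tfs: int = 25,
    n_peaks: int = 1200,
    conserved_frac: float = 0.1,
    conserved_identity: float = 0.9,
    effect_size: float = 5.0,
    nb_dispersion: float = 2.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate the full two-species multiome with planted truth.

    ``n_cells`` / ``n_genes`` / ``n_peaks`` are per species; the first
    ``n_tfs`` genes are TFs, the first five of those the planted
    cone-promoting TFs (two of them species-a specific).
    """
    cfg = cfg or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    if effect_size <= 1.0:
        raise PipelineError("unidentifiable-truth", "effect_size must be > 1")
    if n_tfs < N_CONE_TFS + 4 or n_genes < n_tfs + N_CONE_TFS * N_CONE_TARGETS + (
        n_tfs - N_CONE_TFS
    ) * (N_OTHER_POS_TARGETS + N_OTHER_NEG_TARGETS):
        raise PipelineError("bad-sizes", "too few genes/TFs for the planted design")

    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["layout", "pwm", "seq_a", "seq_b", "rna_a", "rna_b", "atac_a",
             "atac_b", "insert_a", "insert_b", "histone_a", "histone_b",
             "conserve"],
            ss.spawn(13),
        )
    }
    rng = streams["layout"]

    # ---- ancestral layout: genes, TF activity patterns, regulons ----------
    gene_idx = list(range(n_genes))
    tf_idx = gene_idx[:n_tfs]
    cone_tf_idx = tf_idx[:N_CONE_TFS]
    a_specific_cone_tfs = cone_tf_idx[:2]
    other_tf_idx = tf_idx[N_CONE_TFS:]

    non_cone_primaries = ["RPC", "N.RPC", "BC/Pho pre", "Rod"]
    activity: dict[int, dict[str, float]] = {}
    # cone TFs: secondary activity only in progenitor types (never in the
    # late-stage comparison neurons), distinct (type, level) per TF
    cone_secondaries = [
        ("RPC", SECONDARY_LEVEL),
        ("N.RPC", SECONDARY_LEVEL),
        ("RPC", 0.18),
        ("N.RPC", 0.18),
        (None, 0.0),
    ]
    for j, t in enumerate(cone_tf_idx):
        sec, lvl = cone_secondaries[j % len(cone_secondaries)]
        levels = {ct: 0.0 for ct in CELL_TYPES}
        levels["Cone"] = 1.0
        if sec is not None:
            levels[sec] = lvl
        activity[t] = levels
    for j, t in enumerate(other_tf_idx):
        primary = non_cone_primaries[j % 4]
        # distinct secondary per TF within a primary group, so no two TFs
        # share an identical activity pattern (keeps them separable)
        others = [ct for ct in CELL_TYPES if ct != primary] + [None]
        sec = others[(j // 4) % len(others)]
        levels = {ct: 0.0 for ct in CELL_TYPES}
        levels[primary] = 1.0
        if sec is not None:
            levels[sec] = SECONDARY_LEVEL
        activity[t] = levels

    pool = list(gene_idx[n_tfs:])
    rng.shuffle(pool)
    regulon_plan: list[tuple[int, int, str]] = []  # (tf, target, sign)
    cursor = 0
    for t in cone_tf_idx:
        for _ in range(N_CONE_TARGETS):
            regulon_plan.append((t, pool[cursor], "positive"))
            cursor += 1
    for t in other_tf_idx:
        for _ in range(N_OTHER_POS_TARGETS):
            regulon_plan.append((t, pool[cursor], "positive"))
            cursor += 1
        for _ in range(N_OTHER_NEG_TARGETS):
            regulon_plan.append((t, pool[cursor], "negative"))
            cursor += 1
    tf_of_target = {target: (tf, sign) for tf, target, sign in regulon_plan}

    base_mu = np.exp(rng.normal(BASE_MU_LOG_MEAN, BASE_MU_LOG_SD, n_genes))

    # ---- genome layout (shared between species) ---------------------------
    genes_per_chrom = (n_genes + 1) // 2
    def _gene_coords(i: int) -> tuple[str, int]:
        chrom = "chr1" if i < genes_per_chrom else "chr2"
        rank = i if i < genes_per_chrom else i - genes_per_chrom
        return chrom, 30_000 + rank * GENE_SPACING

    chrom_lengths = {
        "chr1": 30_000 + genes_per_chrom * GENE_SPACING + 100_000,
        "chr2": 30_000 + (n_genes - genes_per_chrom + max(1, int(n_genes * DUPLICATE_FRAC))) * GENE_SPACING + 100_000,
    }

    strands = ["+" if i % 2 == 0 else "-" for i in gene_idx]
    bodies = {}
    for i in gene_idx:
        chrom, start = _gene_coords(i)
        bodies[i] = GenomicInterval(chrom, start, start + GENE_BODY_LEN, strands[i])

    def _tss_pos(i: int) -> tuple[str, int]:
        b = bodies[i]
        return b.chrom, (b.start if strands[i] == "+" else b.end - 1)

    # peaks: promoter per gene, enhancer per positive regulon, background
    peak_regions: dict[str, GenomicInterval] = {}
    promoter_of: dict[int, str] = {}
    used: list[tuple[str, int, int]] = []

    def _claim(chrom, start, pid):
        iv = GenomicInterval(chrom, start, start + PEAK_LEN)
        peak_regions[pid] = iv
        used.append((chrom, start, start + PEAK_LEN))
        return iv

    for i in gene_idx:
        chrom, tss = _tss_pos(i)
        _claim(chrom, tss - PEAK_LEN // 2, f"prom_{i:04d}")
        promoter_of[i] = f"prom_{i:04d}"

    enhancer_of: dict[int, str] = {}
    n_enh = 0
    element_classes: dict[str, str] = {pid: "TSS" for pid in peak_regions}
    for tf, target, sign in regulon_plan:
        if sign != "positive":
            continue
        b = bodies[target]
        chrom, tss = _tss_pos(target)
        if n_enh % 2 == 0:
            start = b.start + 2_000 + (n_enh % 3) * 400      # gene body
        else:
            start = max(0, b.start - 15_000 - (n_enh % 3) * 400)  # intergenic
        pid = f"enh_{target:04d}"
        _claim(chrom, start, pid)
        enhancer_of[target] = pid
        element_classes[pid] = "aEnhancer" if n_enh % 2 == 0 else "pEnhancer"
        n_enh += 1

    n_background = n_peaks - len(peak_regions)
    if n_background < 0:
        raise PipelineError("bad-sizes", "n_peaks too small for the planted design")
    occupied = sorted(used)
    bg = 0
    attempts = 0
    while bg < n_background:
        attempts += 1
        if attempts > 50 * n_background:
            raise PipelineError("layout-failure", "could not place background peaks")
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(1_000, chrom_lengths[chrom] - PEAK_LEN - 1_000))
        clash = any(
            c == chrom and start < e + 100 and s - 100 < start + PEAK_LEN
            for c, s, e in used
        )
        if clash:
            continue
        pid = f"bg_{bg:04d}"
        _claim(chrom, start, pid)
        element_classes[pid] = "unclassified"
        bg += 1

    # ---- PWMs (shared) ----------------------------------------------------
    prng = streams["pwm"]
    consensi = _distinct_consensus(prng, n_tfs, MOTIF_LEN)
    pwms: dict[str, PWM] = {}
    tf_motifs: dict[int, str] = {}
    for j, t in enumerate(tf_idx):
        motif_id = f"M{j:03d}"
        counts = np.zeros((MOTIF_LEN, 4))
        for pos, b in enumerate(consensi[j]):
            counts[pos, "ACGT".index(b)] = 40
        pwms[motif_id] = build_pwm(counts, pseudocount=0.5, motif_id=motif_id,
                                   tf_name=f"TF{j:03d}")
        tf_motifs[t] = motif_id

    # ---- per-species assembly --------------------------------------------
    cone_tf_ids_a = [f"gA_{t:04d}" for t in cone_tf_idx]
    truth_regulons: dict[str, list] = {"a": [], "b": []}
    truth_sites: dict[str, list] = {"a": [], "b": []}
    truth_classes: dict[str, dict[str, str]] = {}
    species_data: dict[str, SpeciesData] = {}

    n_dup = max(1, int(round(n_genes * DUPLICATE_FRAC)))
    dup_targets = sorted(
        rng.choice([g for g in gene_idx if g not in tf_idx], n_dup, replace=False).tolist()
    )

    conserve_rng = streams["conserve"]
    n_conserved = int(round(n_genes * conserved_frac))
    conserved_genes = sorted(
        conserve_rng.choice(n_genes, n_conserved, replace=False).tolist()
    )

    for sp in ("a", "b"):
        tag = "A" if sp == "a" else "B"
        gid = lambda i: f"g{tag}_{i:04d}"
        pid_sp = lambda p: f"{sp}_{p}"
        inactive_tfs = set() if sp == "a" else set(a_specific_cone_tfs)

        def _level(tf: int, ct: str) -> float:
            return 0.0 if tf in inactive_tfs else activity[tf][ct]

        # cells
        crng = streams[f"rna_{sp}"]
        counts_per_type = {
            ct: int(round(n_cells * frac)) for ct, frac in CELL_TYPE_PROPORTIONS.items()
        }
        # adjust rounding drift
        drift = n_cells - sum(counts_per_type.values())
        counts_per_type["RPC"] += drift
        cell_ids, cell_types, time_points = [], {}, {}
        for ct in CELL_TYPES:
            for j in range(counts_per_type[ct]):
                cid = f"s{tag}_{ct.replace(' ', '').replace('/', '')}_{j:04d}"
                cell_ids.append(cid)
                cell_types[cid] = ct
                time_points[cid] = ["t0", "t1", "t2"][j % 3]

        # RNA counts. TF columns are drawn first from their cell-type means;
        # each planted target's mean is then driven by its own TF's realized
        # expression (saturating activation), so the TF -> target dependence
        # is present at single-cell resolution, as GRN inference assumes.
        ct_index = {ct: i for i, ct in enumerate(CELL_TYPES)}
        cell_ct = np.array([ct_index[cell_types[c]] for c in cell_ids])
        n_cells_sp = len(cell_ids)
        sat = TF_HIGH_MU / (TF_HIGH_MU + ACTIVATION_HALF)
        tf_counts: dict[int, np.ndarray] = {}
        lv_by_tf: dict[int, np.ndarray] = {}
        for t in tf_idx:
            mu_t = np.array(
                [TF_LOW_MU + TF_HIGH_MU * _level(t, ct) for ct in CELL_TYPES]
            )[cell_ct]
            x = _nb_counts(crng, mu_t, nb_dispersion).astype(float)
            tf_counts[t] = x
            lv_by_tf[t] = np.clip((x / (x + ACTIVATION_HALF)) / sat, 0.0, 1.0)
        mu_cells = np.tile(base_mu[None, :], (n_cells_sp, 1))
        for tf, target, sign in regulon_plan:
            lv = lv_by_tf[tf]
            if sign == "positive":
                mu_cells[:, target] = base_mu[target] * effect_size**lv
            else:
                mu_cells[:, target] = base_mu[target] * effect_size ** (1.0 - lv)
        rna_counts = _nb_counts(crng, mu_cells, nb_dispersion)
        for t in tf_idx:
            rna_counts[:, t] = tf_counts[t]

        # duplicate a-side genes (many-to-one orthologs), half expression
        gene_ids = [gid(i) for i in gene_idx]
        gene_models = [GeneModel(gid(i), bodies[i], strands[i]) for i in gene_idx]
        if sp == "a":
            dup_cols = []
            for j, g in enumerate(dup_targets):
                dup_cols.append(_nb_counts(crng, 0.5 * mu_cells[:, g], nb_dispersion))
                gene_ids.append(f"gA_dup{j:03d}")
                rank = n_genes - genes_per_chrom + j
                start = 30_000 + rank * GENE_SPACING
                body = GenomicInterval("chr2", start, start + GENE_BODY_LEN, "+")
                gene_models.append(GeneModel(f"gA_dup{j:03d}", body, "+"))
            rna_counts = np.hstack([rna_counts] + [c[:, None] for c in dup_cols])

        rna = normalize_counts(
            CountMatrix(cell_ids, gene_ids, rna_counts), cfg.normalize_scale
        )

        # ATAC means per peak x cell type
        peak_ids = sorted(peak_regions)
        atac_mu = np.full((len(peak_ids), len(CELL_TYPES)), BACKGROUND_ATAC_MU)
        ppos = {p: i for i, p in enumerate(peak_ids)}
        for i in gene_idx:
            atac_mu[ppos[promoter_of[i]], :] = PROMOTER_ATAC_MU
        for tf, target, sign in regulon_plan:
            if sign != "positive":
                continue
            row = ppos[enhancer_of[target]]
            for ci, ct in enumerate(CELL_TYPES):
                atac_mu[row, ci] = ENHANCER_ATAC_MU * effect_size ** _level(tf, ct)
        arng = streams[f"atac_{sp}"]
        atac_counts = _nb_counts(arng, atac_mu.T[cell_ct, :], nb_dispersion)
        atac = normalize_counts(
            CountMatrix(cell_ids, [pid_sp(p) for p in peak_ids], atac_counts),
            cfg.normalize_scale,
        )

        # sequences + planted motif sites; each species has independent
        # random sequences (conserved cores are copied below for species b)
        seq_rng = streams[f"seq_{sp}"]
        sequences: dict[str, str] = {}
        for p in peak_ids:
            sequences[pid_sp(p)] = _random_seq(PEAK_LEN, seq_rng)
        site_offset = (PEAK_LEN - MOTIF_LEN) // 2
        for tf, target, sign in regulon_plan:
            if sp == "b" and tf in inactive_tfs:
                continue
            peak = enhancer_of[target] if sign == "positive" else promoter_of[target]
            motif_id = tf_motifs[tf]
            consensus = consensi[tf_idx.index(tf)]
            strand = "+" if target % 2 == 0 else "-"
            planted = consensus if strand == "+" else revcomp(consensus)
            seq = sequences[pid_sp(peak)]
            sequences[pid_sp(peak)] = (
                seq[:site_offset] + planted + seq[site_offset + MOTIF_LEN:]
            )
            region = peak_regions[peak]
            site = GenomicInterval(
                region.chrom, region.start + site_offset,
                region.start + site_offset + MOTIF_LEN,
            )
            bound_cts = tuple(ct for ct in CELL_TYPES if _level(tf, ct) > 0)
            truth_sites[sp].append(
                PlantedSite(pid_sp(peak), motif_id, site, strand, bound_cts)
            )
            truth_regulons[sp].append((gid(tf), pid_sp(peak), gid(target), sign))

        # conserved promoter cores for species b
        if sp == "b":
            for j, g in enumerate(conserved_genes):
                core = species_data["a"].sequences[f"a_{promoter_of[g]}"]
                mutated = _mutate(core, conserved_identity, conserve_rng)
                if j % 2 == 1:
                    mutated = revcomp(mutated)
                sequences[pid_sp(promoter_of[g])] = mutated

        # insertion tracks: binned Poisson within peaks, per-base near sites
        irng = streams[f"insert_{sp}"]
        bound_by_ct: dict[str, list[GenomicInterval]] = {ct: [] for ct in CELL_TYPES}
        for ps in truth_sites[sp]:
            for ct in ps.bound_cell_types:
                bound_by_ct[ct].append(ps.site)
        insertion = {}
        for ct in CELL_TYPES:
            ivs, vals = [], []
            for p in peak_ids:
                region = peak_regions[p]
                fine = [
                    s for s in bound_by_ct[ct]
                    if s.chrom == region.chrom
                    and s.start >= region.start and s.end <= region.end
                ]
                fine_ranges = sorted(
                    (max(region.start, s.start - 3 * MOTIF_LEN),
                     min(region.end, s.end + 3 * MOTIF_LEN),
                     s.start, s.end)
                    for s in fine
                )
                cursor_pos = region.start
                def _emit_binned(a, b):
                    nonlocal ivs, vals
                    p0 = a
                    while p0 < b:
                        p1 = min(p0 + INSERTION_BIN, b)
                        width = p1 - p0
                        count = irng.poisson(FLANK_RATE * INSERTION_DEPTH * width)
                        ivs.append(GenomicInterval(region.chrom, p0, p1))
                        vals.append(count / (INSERTION_DEPTH * width))
                        p0 = p1
                for fa, fb, s0, s1 in fine_ranges:
                    if fa > cursor_pos:
                        _emit_binned(cursor_pos, fa)
                    for p0 in range(max(fa, cursor_pos), fb):
                        rate = FLANK_RATE * (
                            PROTECTION_FACTOR if s0 <= p0 < s1 else 1.0
                        )
                        count = irng.poisson(rate * INSERTION_DEPTH)
                        ivs.append(GenomicInterval(region.chrom, p0, p0 + 1))
                        vals.append(count / INSERTION_DEPTH)
                    cursor_pos = max(cursor_pos, fb)
                if cursor_pos < region.end:
                    _emit_binned(cursor_pos, region.end)
            insertion[ct] = SignalTrack(ivs, vals)

        # histone tracks
        classes_sp = {pid_sp(p): element_classes[p] for p in peak_ids}
        hpeaks, htracks = generate_histone_tracks(
            {p: element_classes[p] for p in peak_ids},
            peak_regions,
            int(streams[f"histone_{sp}"].integers(0, 2**31 - 1)),
        )
        truth_classes[sp] = classes_sp

        species_data[sp] = SpeciesData(
            name=sp,
            rna=rna,
            atac=atac,
            peaks={pid_sp(p): peak_regions[p] for p in peak_ids},
            gene_models=gene_models,
            cell_types=cell_types,
            time_points=time_points,
            tf_ids=[gid(t) for t in tf_idx],
            tf_motifs={gid(t): m for t, m in tf_motifs.items()},
            sequences=sequences,
            insertion_by_celltype=insertion,
            histone_peaks=hpeaks,
            histone_tracks=htracks,
            chrom_lengths=dict(chrom_lengths),
        )

    ortho_pairs = [(f"gA_{i:04d}", f"gB_{i:04d}") for i in gene_idx]
    ortho_pairs += [
        (f"gA_dup{j:03d}", f"gB_{g:04d}") for j, g in enumerate(dup_targets)
    ]
    conserved_pairs = [
        (f"a_{promoter_of[g]}", f"b_{promoter_of[g]}") for g in conserved_genes
    ]
    truth = SyntheticTruth(
        planted_regulons=truth_regulons,
        bound_sites=truth_sites,
        conserved_pairs=conserved_pairs,
        cone_tfs=cone_tf_ids_a,
        element_classes=truth_classes,
        ortholog_map=OrthologyMap(ortho_pairs),
    )
    return SyntheticDataset(species=species_data, pwms=pwms, truth=truth, config=cfg)
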