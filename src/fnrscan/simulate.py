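"""Synthetic genomes, annotations, TSS maps, planted boxes and expression tables.

The generator emits the same three artifacts the real analysis consumes —
a per-gene fold-change table for three genotype comparisons, a genome FASTA
with GFF3 annotation, and a TSS table — together with a ground-truth object,
so every pipeline stage is testable without external data.

Default condition sizes mirror the study this pipeline models: 478 genes
differential at least threefold in anaerobiosis, 102 of them moved less
than twofold in both mutants, category sizes 26/107/25/57/36, and twelve
box-bearing operons for the direct-regulon category, with box centers
massed at the class II position -41.5.

Planted motif instances realize the configured per-column base frequencies
as exact (largest-remainder rounded) per-column compositions, with the
rare "mismatch" bases spread across sites so no single planted instance
degenerates; the planted frequency matrix is therefore recovered, not
merely approximated, by downstream discovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import (
    Category,
    ExpressionComparison,
    GeneRecord,
    TSSRecord,
    write_annotation,
    write_expression_table,
    write_tss_table,
)

BASES = "ACGT"

#: planted per-column base frequencies of the dyad box, order A,C,G,T.
#: Conserved flanks at 0.94; the half-conserved inner positions split
#: between two bases; the four-spacer positions are unconstrained.
def default_box_matrix() -> np.ndarray:
    cons = {b: [0.94 if x == b else 0.02 for x in BASES] for b in BASES}
    uniform = [0.25, 0.25, 0.25, 0.25]
    ct = [0.04, 0.50, 0.04, 0.42]  # C over T
    ga = [0.42, 0.04, 0.50, 0.04]  # G over A
    rows = [cons["T"], cons["T"], cons["G"], cons["A"], ct,
            uniform, uniform, uniform, uniform,
            ga, cons["T"], cons["C"], cons["A"], cons["A"]]
    return np.array(rows, float)


#: per-group (A, F, N) samplers, as log2-uniform ranges of linear ratios.
#: "nf" entries sample N as F times a ratio.  Ranges keep every group at
#: least two noise SDs clear of the rule boundaries it must not cross.
DEFAULT_EFFECTS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "CAT1": {"A": (9, 200), "F": (1 / 8, 1 / 2), "nf": (6, 60)},
    "CAT2": {"A": (9, 200), "F": (1 / 60, 1 / 9), "nf": (1 / 1.5, 1.5)},
    "CAT3": {"A": (6, 30), "F": (4, 20), "nf": (1 / 1.5, 1.5)},
    "CAT4": {"A": (1 / 200, 1 / 6), "F": (6, 30), "nf": (1 / 1.5, 1.5)},
    "CAT5": {"A": (1.2, 2.5), "F": (6, 50), "N": (2 ** -0.25, 2 ** 0.25)},
    "UNAFFECTED": {"A": (6, 100), "F": (2 ** -0.25, 2 ** 0.25), "N": (2 ** -0.25, 2 ** 0.25)},
    "OTHER": {"A": (6, 100), "F": (0.8, 1.25), "N": (1 / 8, 1 / 4)},
    "UNREGULATED": {"A": (2 ** -0.25, 2 ** 0.25), "F": (2 ** -0.5, 2 ** 0.5),
                    "N": (2 ** -0.5, 2 ** 0.5)},
}

#: expected classifier label for each planted group
GROUP_LABEL = {
    "CAT1": Category.CAT1,
    "CAT2": Category.CAT2,
    "CAT3": Category.CAT3,
    "CAT4": Category.CAT4,
    "CAT5": Category.CAT5,
    "UNAFFECTED": Category.UNCLASSIFIED,
    "OTHER": Category.UNCLASSIFIED,
    "UNREGULATED": Category.UNREGULATED,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic data generator."""

    seed: int
    n_genes: int = 1000
    category_counts: Mapping[str, int] = field(
        default_factory=lambda: {"CAT1": 26, "CAT2": 107, "CAT3": 25, "CAT4": 57, "CAT5": 36}
    )
    n_unaffected: int = 102
    n_other_regulated: int = 161
    repressed_fraction: float = 0.25  # of UNAFFECTED/OTHER differential genes
    n_cat1_operons: int = 12
    cat2_box_fraction: float = 0.0
    mean_operon_size: float = 1.6
    gene_length: tuple[int, int] = (300, 1500)
    intra_operon_gap: tuple[int, int] = (5, 80)
    inter_operon_gap: tuple[int, int] = (260, 600)
    divergent_box_gap: tuple[int, int] = (800, 1200)
    tss_offset: tuple[int, int] = (25, 120)
    tss_probability: float = 0.9
    box_centers: Mapping[float, float] = field(
        default_factory=lambda: {-41.5: 0.6, -42.5: 0.2, -60.5: 0.1, -93.5: 0.1}
    )
    box_matrix: Optional[np.ndarray] = None
    gc: float = 0.65
    noise_sigma: float = 0.25
    effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    contig: str = "chr"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        n_special = (sum(self.category_counts.values()) + self.n_unaffected
                     + self.n_other_regulated)
        if n_special > self.n_genes:
            raise ValueError(
                f"category/unaffected/other counts ({n_special}) exceed n_genes ({self.n_genes})"
            )

    @property
    def matrix(self) -> np.ndarray:
        return default_box_matrix() if self.box_matrix is None else np.asarray(self.box_matrix)


@dataclass
class PlantedBox:
    operon_id: str
    lead_gene: str
    center: float
    strand: str
    start: int  # genomic, 1-based inclusive
    end: int
    site: str  # 14-mer on the coding strand


@dataclass
class GroundTruth:
    """Everything the generator planted, reconcilable with the emitted files."""

    labels: dict[str, str]  # gene_id -> expected classifier label
    groups: dict[str, str]  # gene_id -> planted group
    operons: list[dict]  # operon_id, gene_ids (transcription order), strand, tss
    boxes: list[PlantedBox]
    expression_true: dict[str, tuple[float, float, float]]  # clean (A, F, N)

    def to_json(self) -> str:
        payload = {
            "labels": self.labels,
            "groups": self.groups,
            "operons": self.operons,
            "boxes": [asdict(b) for b in self.boxes],
            "expression_true": self.expression_true,
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimResult:
    config: SimConfig
    genome: str
    genes: list[GeneRecord]
    tss: list[TSSRecord]
    expression: list[ExpressionComparison]
    truth: GroundTruth
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Site sampling with exact per-column composition
# ---------------------------------------------------------------------------

def _largest_remainder(freqs: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items proportional to freqs (sums to n)."""
    target = freqs * n
    alloc = np.floor(target).astype(int)
    short = n - alloc.sum()
    if short > 0:
        order = np.argsort(-(target - alloc), kind="stable")
        for i in order[:short]:
            alloc[i] += 1
    return alloc


def sample_box_sites(n: int, matrix: np.ndarray, rng: np.random.Generator,
                     rare_cutoff: float = 0.2) -> list[str]:
    """Draw n motif instances realizing the matrix's per-column composition.

    Per column the base counts are the largest-remainder rounding of
    ``n * freq``.  Bases with planted frequency below ``rare_cutoff``
    (the mismatches) are assigned to the instances carrying the fewest
    mismatches so far, so degeneracy is spread rather than piled onto a
    few sites; common bases are shuffled uniformly.
    """
    W = matrix.shape[0]
    sites = np.zeros((n, W), dtype=np.int64)
    load = np.zeros(n, dtype=int)  # mismatches carried per site
    for j in range(W):
        alloc = _largest_remainder(matrix[j], n)
        rare = matrix[j] < rare_cutoff
        assigned = np.full(n, -1, dtype=np.int64)
        # place rare bases on least-loaded sites first
        rare_bases = []
        for b in range(4):
            if rare[b]:
                rare_bases.extend([b] * alloc[b])
        if rare_bases:
            order = np.lexsort((rng.random(n), load))
            for k, b in enumerate(rare_bases):
                assigned[order[k]] = b
                load[order[k]] += 1
        common_bases = []
        for b in range(4):
            if not rare[b]:
                common_bases.extend([b] * alloc[b])
        slots = np.flatnonzero(assigned < 0)
        common = np.array(common_bases, dtype=np.int64)
        rng.shuffle(common)
        assigned[slots] = common
        sites[:, j] = assigned
    return ["".join(BASES[b] for b in row) for row in sites]


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# Expression sampling
# ---------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp2(rng.uniform(np.log2(lo), np.log2(hi), size=n))


def _sample_effects(group: str, n: int, cfg: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    spec = cfg.effects[group]
    A = _log_uniform(rng, *spec["A"], n)
    F = _log_uniform(rng, *spec["F"], n)
    if "nf" in spec:
        N = F * _log_uniform(rng, *spec["nf"], n)
    else:
        N = _log_uniform(rng, *spec["N"], n)
    if group in ("UNAFFECTED", "OTHER") and cfg.repressed_fraction > 0:
        k = int(round(cfg.repressed_fraction * n))
        flip = rng.permutation(n)[:k]
        A[flip] = 1.0 / A[flip]
    return np.column_stack([A, F, N])


def perturb(records: Sequence[ExpressionComparison], sigma: float,
            seed: Optional[int] = 0) -> list[ExpressionComparison]:
    """Apply multiplicative log-normal noise to every present ratio."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        vals = {}
        for k in "AFN":
            v = getattr(r, k)
            if v is None or sigma == 0:
                vals[k] = v
            else:
                vals[k] = float(v * np.exp2(rng.normal(0.0, sigma)))
        out.append(ExpressionComparison(gene_id=r.gene_id, **vals))
    return out


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def _operon_sizes(group: str, count: int, cfg: SimConfig,
                  rng: np.random.Generator) -> list[int]:
    """Partition a group's gene count into operon sizes."""
    if count == 0:
        return []
    if group == "CAT1":
        k = min(cfg.n_cat1_operons, count)
        sizes = np.ones(k, dtype=int)
        extra = count - k
        if extra > 0:
            sizes += rng.multinomial(extra, np.full(k, 1.0 / k))
        return [int(s) for s in sizes]
    sizes = []
    left = count
    p = 1.0 / cfg.mean_operon_size
    while left > 0:
        s = min(int(rng.geometric(p)), 5, left)
        sizes.append(s)
        left -= s
    return sizes


def simulate(cfg: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """Generate genome, annotation, TSS map, expression table and truth.

    Fully reproducible from ``cfg.seed``: identical configs give
    byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)
    matrix = cfg.matrix
    W = matrix.shape[0]

    # ---- plan operons per group ------------------------------------------
    groups_plan: list[tuple[str, int]] = []  # (group, size) per operon
    counts = {c: 0 for c in ("CAT1", "CAT2", "CAT3", "CAT4", "CAT5")}
    counts.update(cfg.category_counts)
    counts["UNAFFECTED"] = cfg.n_unaffected
    counts["OTHER"] = cfg.n_other_regulated
    n_special = sum(counts.values())
    counts["UNREGULATED"] = cfg.n_genes - n_special
    for group in ("CAT1", "CAT2", "CAT3", "CAT4", "CAT5",
                  "UNAFFECTED", "OTHER", "UNREGULATED"):
        for s in _operon_sizes(group, counts[group], cfg, rng):
            groups_plan.append((group, s))
    order = rng.permutation(len(groups_plan))
    groups_plan = [groups_plan[i] for i in order]

    # ---- which operons carry a planted box -------------------------------
    has_box = []
    for group, _ in groups_plan:
        if group == "CAT1":
            has_box.append(True)
        elif group == "CAT2" and cfg.cat2_box_fraction > 0:
            has_box.append(bool(rng.random() < cfg.cat2_box_fraction))
        else:
            has_box.append(False)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in groups_plan]

    centers_vals = np.array(list(cfg.box_centers.keys()), float)
    centers_w = np.array(list(cfg.box_centers.values()), float)
    centers_w = centers_w / centers_w.sum()
    n_boxes = sum(has_box)
    box_centers = centers_vals[rng.choice(len(centers_vals), size=n_boxes, p=centers_w)]
    box_sites = sample_box_sites(n_boxes, matrix, rng)

    # ---- lay out the genome ----------------------------------------------
    genes: list[GeneRecord] = []
    tss_records: list[TSSRecord] = []
    operon_truth: list[dict] = []
    planted: list[PlantedBox] = []
    gene_group: dict[str, str] = {}

    cursor = 600  # room for the first promoter window
    gene_no = 0
    box_no = 0
    prev_strand = None
    prev_box = False
    for op_i, ((group, size), strand, boxed) in enumerate(
            zip(groups_plan, strands, has_box), start=1):
        lo, hi = cfg.inter_operon_gap
        if prev_strand == "-" and strand == "+" and (prev_box or boxed):
            lo, hi = cfg.divergent_box_gap  # keep divergent promoters apart
        cursor += int(rng.integers(lo, hi + 1))

        op_genes: list[GeneRecord] = []
        for k in range(size):
            if k > 0:
                cursor += int(rng.integers(cfg.intra_operon_gap[0],
                                           cfg.intra_operon_gap[1] + 1))
            length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
            gene_no += 1
            gid = f"SYN_{gene_no:04d}"
            op_genes.append(GeneRecord(gene_id=gid, contig=cfg.contig,
                                       start=cursor, end=cursor + length - 1,
                                       strand=strand, product=f"{group} protein"))
            cursor += length
        genes.extend(op_genes)

        ids = [g.gene_id for g in op_genes]
        if strand == "-":
            ids = ids[::-1]  # transcription order
        for gid in ids:
            gene_group[gid] = group

        operon_id = f"OP{op_i:04d}"
        lead = ids[0]
        lead_gene = next(g for g in op_genes if g.gene_id == lead)
        need_tss = boxed or rng.random() < cfg.tss_probability
        tss_pos = None
        if need_tss:
            d = int(rng.integers(cfg.tss_offset[0], cfg.tss_offset[1] + 1))
            tss_pos = lead_gene.start - d if strand == "+" else lead_gene.end + d
            tss_records.append(TSSRecord(tss_id=f"TSS_{operon_id}", position=tss_pos,
                                         strand=strand, assigned_gene=lead))
        if boxed:
            c = float(box_centers[box_no])
            site = box_sites[box_no]
            box_no += 1
            if strand == "+":
                s = int(tss_pos + c - (W / 2 - 0.5))
                e = int(tss_pos + c + (W / 2 - 0.5))
            else:
                s = int(tss_pos - c - (W / 2 - 0.5))
                e = int(tss_pos - c + (W / 2 - 0.5))
            planted.append(PlantedBox(operon_id=operon_id, lead_gene=lead, center=c,
                                      strand=strand, start=s, end=e, site=site))
        operon_truth.append({"operon_id": operon_id, "gene_ids": ids,
                             "strand": strand, "tss": tss_pos})
        prev_strand, prev_box = strand, boxed

    genome_len = cursor + 600
    p_base = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    genome_arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                            size=genome_len, p=p_base)
    for b in planted:
        written = b.site if b.strand == "+" else _revcomp(b.site)
        genome_arr[b.start - 1 : b.end] = np.frombuffer(written.encode(), dtype=np.uint8)
    genome = genome_arr.tobytes().decode("ascii")

    # ---- expression -------------------------------------------------------
    by_group: dict[str, list[str]] = {}
    for gid, group in gene_group.items():
        by_group.setdefault(group, []).append(gid)
    truth_expr: dict[str, tuple[float, float, float]] = {}
    for group, gids in by_group.items():
        eff = _sample_effects(group, len(gids), cfg, rng)
        for gid, (A, F, N) in zip(sorted(gids), eff):
            truth_expr[gid] = (float(A), float(F), float(N))
    clean = [ExpressionComparison(gene_id=g.gene_id, A=truth_expr[g.gene_id][0],
                                  F=truth_expr[g.gene_id][1], N=truth_expr[g.gene_id][2])
             for g in genes]
    noise_seed = int(rng.integers(0, 2 ** 31 - 1))
    noisy = perturb(clean, cfg.noise_sigma, seed=noise_seed)

    labels = {gid: GROUP_LABEL[group].value for gid, group in gene_group.items()}
    truth = GroundTruth(labels=labels, groups=dict(gene_group), operons=operon_truth,
                        boxes=planted, expression_true=truth_expr)
    result = SimResult(config=cfg, genome=genome, genes=genes, tss=tss_records,
                       expression=noisy, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "genome.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{cfg.contig}\n")
            for i in range(0, len(genome), 80):
                fh.write(genome[i : i + 80] + "\n")
        gff = out / "annotation.gff3"
        write_annotation(genes, gff)
        tss_path = out / "tss.tsv"
        write_tss_table(tss_records, tss_path)
        expr = out / "expression.tsv"
        write_expression_table(noisy, expr)
        truth_path = out / "truth.json"
        truth_path.write_text(truth.to_json())
        result.paths = {"genome": str(fasta), "annotation": str(gff),
                        "tss": str(tss_path), "expression": str(expr),
                        "truth": str(truth_path)}
    return result
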