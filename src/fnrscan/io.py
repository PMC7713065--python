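"""Domain types and readers/writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Gene and TSS coordinates are 1-based inclusive (GFF3 / biology convention).
BED output is 0-based half-open.  Fold changes are stored as *linear* ratios
(a threefold repression is the ratio 1/3); log2 is an accessor, never state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fnrscan")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class Category(str, Enum):
    """Regulatory category of a gene inferred from its (A, F, N) fold changes."""

    CAT1 = "CAT1"
    CAT2 = "CAT2"
    CAT3 = "CAT3"
    CAT4 = "CAT4"
    CAT5 = "CAT5"
    UNREGULATED = "UNREGULATED"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PromoterClass(str, Enum):
    """Position class of an activator site relative to the promoter core."""

    CLASS_I = "CLASS_I"
    CLASS_II = "CLASS_II"
    CORE_OVERLAP = "CORE_OVERLAP"
    DISTAL = "DISTAL"
    NO_TSS = "NO_TSS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    """A genomic gene with 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    name: Optional[str] = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TSSRecord:
    """A mapped transcription start site (+1 position of a transcript)."""

    tss_id: str
    position: int
    strand: str
    assigned_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.tss_id}: TSS position must be >= 1, got {self.position}")
        if self.strand not in "+-":
            raise ValueError(f"{self.tss_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ExpressionComparison:
    """Per-gene triple of linear expression ratios across genotype comparisons.

    A : WT anaerobic / WT aerobic
    F : double fnr-mutant anaerobic / WT anaerobic
    N : narG-mutant anaerobic / WT anaerobic

    ``None`` marks a missing/invalid ratio (the gene was barely expressed, or
    the table carried a non-positive value).  Present ratios are strictly > 0.
    """

    gene_id: str
    A: Optional[float]
    F: Optional[float]
    N: Optional[float]

    def __post_init__(self) -> None:
        for label in "AFN":
            v = getattr(self, label)
            if v is not None and not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{self.gene_id}: ratio {label}={v!r} must be finite and > 0")

    @property
    def complete(self) -> bool:
        return self.A is not None and self.F is not None and self.N is not None

    def log2(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        """log2 of the three ratios; accessor only, never stored."""
        return tuple(None if v is None else float(np.log2(v)) for v in (self.A, self.F, self.N))


@dataclass(frozen=True)
class Thresholds:
    """Fold-change cutoffs of the category rules (all linear ratios > 1).

    t_ind   : induction/repression cutoff ("at least threefold")
    t_unaff : unaffected band ("affected less than twofold")
    t_diff  : mutant-vs-mutant ratio cutoff (N/F at least threefold)
    t_up    : "even more induced" cutoff in both mutants
    """

    t_ind: float = 3.0
    t_unaff: float = 2.0
    t_diff: float = 3.0
    t_up: float = 2.0

    def __post_init__(self) -> None:
        for name in ("t_ind", "t_unaff", "t_diff", "t_up"):
            if not getattr(self, name) > 1:
                raise ValueError(f"threshold {name} must be > 1")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

DEFAULT_EXPRESSION_COLUMNS: Mapping[str, str] = {
    "gene_id": "gene_id",
    "A": "fc_anaerobic_vs_aerobic",
    "F": "fc_fnr_vs_wt",
    "N": "fc_narG_vs_wt",
}


def read_expression_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ExpressionComparison]:
    """Read a per-gene fold-change TSV into :class:`ExpressionComparison` records.

    ``column_map`` maps the logical fields gene_id/A/F/N onto the file's
    headers, so a real supplementary-table export and synthetic tables share
    one reader.  Rows with non-positive or unparseable ratios are kept with
    the offending ratio flagged missing (None) and a warning is logged.
    """
    cmap = dict(DEFAULT_EXPRESSION_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["gene_id"]: str})
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"expression table {path} is missing mapped column(s): {missing_cols}")
    ids = df[cmap["gene_id"]].tolist()
    dupes = sorted({g for g in ids if ids.count(g) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise ValueError(f"duplicate gene_id(s) in expression table: {dupes}")

    records: list[ExpressionComparison] = []
    n_flagged = 0
    for _, row in df.iterrows():
        vals: dict[str, Optional[float]] = {}
        for key in "AFN":
            raw = row[cmap[key]]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                v = float("nan")
            if not np.isfinite(v) or v <= 0:
                vals[key] = None
                n_flagged += 1
            else:
                vals[key] = v
        records.append(ExpressionComparison(gene_id=str(row[cmap["gene_id"]]), **vals))
    if n_flagged:
        logger.warning("expression table %s: %d ratio value(s) flagged missing", path, n_flagged)
        warnings.warn(f"{n_flagged} ratio value(s) flagged missing in {path}", stacklevel=2)
    return records


def write_expression_table(
    records: Iterable[ExpressionComparison],
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    cmap = dict(DEFAULT_EXPRESSION_COLUMNS)
    if column_map:
        cmap.update(column_map)
    rows = []
    for r in records:
        rows.append(
            {
                cmap["gene_id"]: r.gene_id,
                cmap["A"]: "NA" if r.A is None else repr(float(r.A)),
                cmap["F"]: "NA" if r.F is None else repr(float(r.F)),
                cmap["N"]: "NA" if r.N is None else repr(float(r.N)),
            }
        )
    pd.DataFrame(rows, columns=list(cmap.values())).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation (GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read gene records from a GFF3 file (gene/CDS features with locus_tag).

    Coordinates stay 1-based inclusive.  Features without a locus_tag are
    skipped with a warning; file order is preserved.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # malformed file
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc

    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.all_features(order_by=None):
        if feat.featuretype not in ("gene", "CDS"):
            continue
        locus = feat.attributes.get("locus_tag", [None])[0]
        if locus is None:
            logger.warning("GFF3 %s: %s feature at %s:%d without locus_tag skipped",
                           path, feat.featuretype, feat.seqid, feat.start)
            continue
        if locus in seen:
            continue  # gene + its CDS carry the same locus_tag
        seen.add(locus)
        name = feat.attributes.get("gene", [None])[0] or feat.attributes.get("Name", [None])[0]
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneRecord(
                gene_id=locus,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                name=name,
                product=product,
            )
        )
    return genes


def write_annotation(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records as a minimal GFF3 file (one gene feature per record)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", f"locus_tag={g.gene_id}"]
            if g.name:
                attrs.append(f"gene={g.name}")
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write(
                f"{g.contig}\tfnrscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS TSV (tss_id, position, strand, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"tss_id": str, "gene_id": str})
    records = []
    for _, row in df.iterrows():
        pos = int(row["position"])
        if pos < 1:
            raise ValueError(f"TSS table {path}: coordinate {pos} < 1 for {row['tss_id']}")
        gene = row.get("gene_id")
        if pd.isna(gene) or gene == "":
            gene = None
        records.append(TSSRecord(tss_id=str(row["tss_id"]), position=pos,
                                 strand=str(row["strand"]), assigned_gene=gene))
    return records


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    rows = [
        {"tss_id": t.tss_id, "position": t.position, "strand": t.strand,
         "gene_id": t.assigned_gene or ""}
        for t in records
    ]
    pd.DataFrame(rows, columns=["tss_id", "position", "strand", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED6 sites
# ---------------------------------------------------------------------------

def write_sites_bed(sites: Iterable, path: str | Path) -> None:
    """Write scored sites as BED6 (0-based half-open).

    Each site needs attributes contig, start, end (1-based inclusive genomic),
    a name, a score and a strand; ScanHit and BoxSite both qualify.
    """
    with open(path, "w") as fh:
        for s in sites:
            name = getattr(s, "name", None) or getattr(s, "site_id", None) or getattr(s, "ref_id", "site")
            score = getattr(s, "score", 0.0)
            fh.write(
                f"{s.contig}\t{s.start - 1}\t{s.end}\t{name}\t{score:.4f}\t{s.strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[dict]:
    """Read a BED6 file back into dicts with 1-based inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            contig, start0, end, name, score, strand = line.split("\t")[:6]
            out.append(
                {"contig": contig, "start": int(start0) + 1, "end": int(end),
                 "name": name, "score": float(score), "strand": strand}
            )
    return out


# ---------------------------------------------------------------------------
# Minimal MEME motif format
# ---------------------------------------------------------------------------

def write_motif(pwm, path: str | Path, name: str = "motif_1", nsites: Optional[int] = None) -> None:
    """Write a PWM in minimal MEME motif text format.

    The probability matrix is emitted at 6 decimals with a large nominal
    nsites so that count-based parsers recover the probabilities to 1e-6.
    """
    nominal = 1_000_000  # re-readable to 1e-6 by count-reconstructing parsers
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pwm.background)) + "\n\n")
        fh.write(f"MOTIF {name}\n\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {nsites or nominal} E= 0\n"
        )
        for row in pwm.matrix:
            fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")


def read_motif(path: str | Path):
    """Read a minimal MEME motif file into a PWM (via Biopython's parser)."""
    import Bio.motifs

    from .motifs import PWM

    with open(path) as fh:
        motifs = Bio.motifs.parse(fh, "minimal")
    if not motifs:
        raise ValueError(f"no motif found in {path}")
    m = motifs[0]
    counts = np.array([[m.counts[b][j] for b in BASES] for j in range(m.length)], float)
    matrix = counts / counts.sum(axis=1, keepdims=True)
    bg = np.array([m.background[b] for b in BASES], float)
    bg = bg / bg.sum()
    return PWM(matrix=matrix, background=bg, name=m.name)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def read_overrides(path: str | Path) -> dict[str, tuple[Category, str]]:
    """Read a per-gene label override TSV (gene_id, label, reason).

    Supports the manual curation calls an analyst may make on top of the
    rule table (e.g. assigning a regulator deleted in the mutant itself).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = (Category(row["label"]), row.get("reason", "") or "")
    return out
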