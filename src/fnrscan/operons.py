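"""Operon construction, upstream promoter extraction and box-center geometry.

Promoter coordinates use the biologist's gapped axis: the TSS is +1, the
base immediately upstream is -1 and there is no position 0.  A 14-bp site
fully upstream of the TSS therefore has a half-integer center, e.g. a site
occupying -48..-35 is centered at -41.5 — the geometry in which class II
activator sites cluster around -41.5 and class I sites around -60/-90.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .io import GeneRecord, PromoterClass, TSSRecord

logger = logging.getLogger("fnrscan")

DEFAULT_MAX_GAP = 100
DEFAULT_UPSTREAM_LENGTH = 450

#: Center windows (inclusive bounds on a no-zero axis) for promoter classes.
DEFAULT_CLASS_WINDOWS: Mapping[str, tuple[float, float]] = {
    "CLASS_II": (-49.5, -35.5),
    "CLASS_I": (-110.5, -50.5),
    "CORE_OVERLAP": (-35.4, -20.5),  # open at -35.5: (-35.5, -20.5]
}


@dataclass
class Operon:
    """An ordered run of co-transcribed same-strand genes."""

    operon_id: str
    gene_ids: list[str]
    strand: str
    contig: str
    tss: Optional[TSSRecord] = None
    internal_tss: list[TSSRecord] = field(default_factory=list)

    @property
    def lead_gene(self) -> str:
        return self.gene_ids[0]

    @property
    def span(self) -> str:
        if len(self.gene_ids) == 1:
            return self.gene_ids[0]
        return f"{self.gene_ids[0]}-{self.gene_ids[-1]}"


@dataclass
class PromoterRegion:
    """Upstream DNA of an operon lead (or single gene), on the coding strand.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the
    region; ``sequence`` reads 5'->3' on the gene's coding strand, so its
    last base abuts the anchor (TSS or start codon) in gene orientation.
    """

    ref_id: str
    sequence: str
    contig: str
    start: int
    end: int
    strand: str
    anchor: str  # "tss" or "start_codon"
    anchor_pos: int
    tss: Optional[TSSRecord] = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"{self.ref_id}: sequence length != interval length")

    def genomic_interval(self, offset: int, width: int) -> tuple[int, int]:
        """Genomic 1-based interval of a window at 0-based promoter offset."""
        if self.strand == "+":
            first = self.start + offset
            return first, first + width - 1
        last = self.end - offset
        return last - width + 1, last


@dataclass
class BoxSite:
    """A scored motif match annotated with TSS-relative geometry."""

    ref_id: str
    contig: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str
    matched: str
    score: float
    p_value: float
    center_offset: Optional[float] = None
    promoter_class: PromoterClass = PromoterClass.NO_TSS
    internal: bool = False

    @property
    def name(self) -> str:
        return f"{self.ref_id}_box"


# ---------------------------------------------------------------------------
# Operon building
# ---------------------------------------------------------------------------

def build_operons(
    genes: Sequence[GeneRecord],
    tss: Sequence[TSSRecord] = (),
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Operon]:
    """Group genes into operons by strand continuity and intergenic distance.

    Consecutive same-strand genes on one contig merge when the intergenic
    gap is at most ``max_gap`` bp AND no mapped TSS assigned to the
    downstream (in transcription order) gene lies in the gap.  Every gene
    belongs to exactly one operon.  A TSS assigned to an operon's lead gene
    becomes the operon's promoter anchor; TSSs assigned to internal genes
    are retained as internal-promoter anchors.
    """
    tss_by_gene: dict[str, TSSRecord] = {}
    for t in tss:
        if t.assigned_gene is not None:
            tss_by_gene.setdefault(t.assigned_gene, t)

    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    operons: list[Operon] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: (g.start, g.end))
        runs: list[list[GeneRecord]] = []
        for g in ordered:
            if runs and _merges(runs[-1][-1], g, max_gap, tss_by_gene):
                runs[-1].append(g)
            else:
                runs.append([g])
        for run in runs:
            strand = run[0].strand
            ids = [g.gene_id for g in run]
            if strand == "-":
                ids = ids[::-1]  # transcription order: descending coordinates
            op = Operon(
                operon_id="",  # assigned below, in genome order
                gene_ids=ids,
                strand=strand,
                contig=contig,
                tss=tss_by_gene.get(ids[0]),
                internal_tss=[tss_by_gene[g] for g in ids[1:] if g in tss_by_gene],
            )
            operons.append(op)
    for i, op in enumerate(operons, start=1):
        op.operon_id = f"OP{i:04d}"
    return operons


def _merges(prev: GeneRecord, nxt: GeneRecord, max_gap: int,
            tss_by_gene: Mapping[str, TSSRecord]) -> bool:
    if nxt.strand != prev.strand:
        return False
    gap = nxt.start - prev.end - 1
    if gap < 0:
        logger.warning("overlapping same-strand genes %s/%s merged", prev.gene_id, nxt.gene_id)
        return True
    if gap > max_gap:
        return False
    # downstream gene in transcription order: nxt on '+', prev on '-'
    downstream = nxt if prev.strand == "+" else prev
    t = tss_by_gene.get(downstream.gene_id)
    if t is not None and prev.end < t.position < nxt.start:
        return False
    return True


# ---------------------------------------------------------------------------
# Upstream extraction
# ---------------------------------------------------------------------------

def extract_upstream(
    operon: Operon,
    genes_by_id: Mapping[str, GeneRecord],
    genome,
    length: int = DEFAULT_UPSTREAM_LENGTH,
    anchor: str = "start_codon",
) -> PromoterRegion:
    """Extract the upstream region of an operon's lead gene.

    ``genome`` is a pyfaidx.Fasta (or any mapping of contig -> indexable
    sequence).  With ``anchor="tss"`` the region ends at the base before
    the operon's TSS; without a mapped TSS it falls back to the start codon
    and the region is tagged anchor="start_codon" (the downstream class
    assignment then reports NO_TSS).  Regions are clipped at contig edges.
    """
    lead = genes_by_id[operon.lead_gene]
    use_anchor = anchor
    tss = operon.tss
    if anchor == "tss" and tss is None:
        logger.warning("%s: no TSS mapped, anchoring at start codon", operon.operon_id)
        use_anchor = "start_codon"
    if use_anchor == "tss":
        anchor_pos = tss.position
    else:
        anchor_pos = lead.start if lead.strand == "+" else lead.end

    contig_seq = genome[lead.contig]
    contig_len = len(contig_seq)
    if lead.strand == "+":
        end = anchor_pos - 1
        start = max(1, end - length + 1)
    else:
        start = anchor_pos + 1
        end = min(contig_len, start + length - 1)
    if end < start:
        raise ValueError(f"{operon.operon_id}: no upstream sequence at contig edge")
    raw = str(contig_seq[start - 1 : end]).upper()
    seq = str(Seq(raw).reverse_complement()) if lead.strand == "-" else raw
    clipped = len(seq) < length
    if clipped:
        logger.warning("%s: upstream region clipped to %d bp at contig edge",
                       operon.operon_id, len(seq))
    return PromoterRegion(
        ref_id=operon.operon_id,
        sequence=seq,
        contig=lead.contig,
        start=start,
        end=end,
        strand=lead.strand,
        anchor=use_anchor,
        anchor_pos=anchor_pos,
        tss=tss,
        clipped=clipped,
    )


def extract_gene_upstream(
    gene: GeneRecord,
    genome,
    length: int = DEFAULT_UPSTREAM_LENGTH,
    tss: Optional[TSSRecord] = None,
) -> PromoterRegion:
    """Upstream region of a single gene (5' region scan); start-codon anchored."""
    op = Operon(operon_id=gene.gene_id, gene_ids=[gene.gene_id],
                strand=gene.strand, contig=gene.contig, tss=tss)
    return extract_upstream(op, {gene.gene_id: gene}, genome, length=length,
                            anchor="start_codon")


# ---------------------------------------------------------------------------
# Center geometry and promoter classes
# ---------------------------------------------------------------------------

def _tss_relative(pos: int, tss_position: int, strand: str) -> int:
    """Map a genomic coordinate onto the no-zero TSS axis (+1 at the TSS)."""
    delta = pos - tss_position if strand == "+" else tss_position - pos
    return delta + 1 if delta >= 0 else delta


def center_offset(start: int, end: int, tss_position: int, strand: str) -> float:
    """Center of a genomic site on the no-zero axis relative to a TSS.

    ``start``/``end`` are genomic 1-based inclusive bounds.  For a site fully
    upstream of the TSS this is the half-integer mean of the first and last
    occupied positions; sites spanning the TSS use the same gapped-axis
    mapping of both bounds.
    """
    if strand == "+":
        first, last = start, end
    else:
        first, last = end, start
    return (_tss_relative(first, tss_position, strand)
            + _tss_relative(last, tss_position, strand)) / 2.0


def assign_promoter_class(
    center: Optional[float],
    windows: Mapping[str, tuple[float, float]] = DEFAULT_CLASS_WINDOWS,
) -> PromoterClass:
    """Classify an activator-site center into promoter classes.

    Class II sites overlap the -35 element region (default center window
    [-49.5, -35.5]); class I sites sit one or more helical turns further
    upstream ([-110.5, -50.5]); centers inside the core promoter
    ((-35.5, -20.5]) overlap the -35 hexamer itself; anything else is
    distal and an unlikely direct activator site.
    """
    if center is None:
        return PromoterClass.NO_TSS
    lo, hi = windows["CLASS_II"]
    if lo <= center <= hi:
        return PromoterClass.CLASS_II
    lo, hi = windows["CLASS_I"]
    if lo <= center <= hi:
        return PromoterClass.CLASS_I
    lo, hi = windows["CORE_OVERLAP"]
    if lo <= center <= hi:
        return PromoterClass.CORE_OVERLAP
    return PromoterClass.DISTAL


def annotate_site(
    region: PromoterRegion,
    offset: int,
    width: int,
    matched: str,
    score: float,
    p_value: float,
    windows: Mapping[str, tuple[float, float]] = DEFAULT_CLASS_WINDOWS,
) -> BoxSite:
    """Turn a promoter-relative scan hit into a genomically annotated BoxSite."""
    start, end = region.genomic_interval(offset, width)
    if region.tss is not None:
        center = center_offset(start, end, region.tss.position, region.strand)
        pclass = assign_promoter_class(center, windows)
    else:
        center = None
        pclass = PromoterClass.NO_TSS
    return BoxSite(
        ref_id=region.ref_id,
        contig=region.contig,
        start=start,
        end=end,
        strand=region.strand,
        matched=matched,
        score=score,
        p_value=p_value,
        center_offset=center,
        promoter_class=pclass,
    )
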