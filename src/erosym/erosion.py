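"""Pseudogene calling, putative-HGT classification, and erosion metrics.

Host-restricted bacterial symbionts erode: relaxed selection and deletion
bias first pseudogenize genes, then delete them. The caller here is
length-based — a gene substantially shorter than its closest protein
database match is called a pseudogene — mirroring annotation pipelines that
compare each ORF to its best BLASTP hit. Genes with no hit are *unclassified*
(tri-state), never silently counted as intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io_model import GeneRecord, Genome, HitRecord

PSEUDOGENE = "pseudogene"
INTACT = "intact"
UNCLASSIFIED = "unclassified"

NATIVE = "native"
PUTATIVE_HGT = "putative_hgt"


def call_pseudogene(hit: Optional[HitRecord], length_fraction_threshold: float = 0.8) -> str:
    """Length-based pseudogene call against the gene's best protein hit.

    Returns ``"pseudogene"`` iff qlen/slen is strictly below the threshold
    (boundary kept intact), ``"intact"`` otherwise, and ``"unclassified"``
    when there is no hit at all.
    """
    if not (0.0 < length_fraction_threshold <= 1.0):
        raise ValueError("length_fraction_threshold must be in (0, 1]")
    if hit is None:
        return UNCLASSIFIED
    if hit.query_len_aa <= 0 or hit.subject_len_aa <= 0:
        raise ValueError("nonpositive hit lengths")
    ratio = hit.query_len_aa / hit.subject_len_aa
    return PSEUDOGENE if ratio < length_fraction_threshold else INTACT


def classify_hgt(hit: HitRecord, native_taxon_label: str, pident_floor: float = 50.0) -> str:
    """Putative horizontal transfer: low identity OR a foreign subject taxon.

    The taxon test is a case-sensitive substring match on the subject title,
    e.g. the literal token "Burkholderia".
    """
    if not native_taxon_label:
        raise ValueError("native_taxon_label must be nonempty")
    if hit.percent_identity < pident_floor or native_taxon_label not in hit.subject_title:
        return PUTATIVE_HGT
    return NATIVE


def apply_pseudogene_calls(
    genome: Genome,
    hits: list[HitRecord],
    length_fraction_threshold: float = 0.8,
) -> dict[str, str]:
    """Overwrite the genome's pseudogene flags from hit-table calls.

    Annotation flags are priors; a hit-based call overrides them. Returns
    the per-gene tri-state call map (genes without hits keep their prior
    flag and are mapped to ``"unclassified"``).
    """
    by_gene = {h.gene_id: h for h in hits}
    calls: dict[str, str] = {}
    for g in genome.genes:
        call = call_pseudogene(by_gene.get(g.gene_id), length_fraction_threshold)
        calls[g.gene_id] = call
        if call != UNCLASSIFIED:
            g.is_pseudogene = call == PSEUDOGENE
    return calls


# ---------------------------------------------------------------------------
# Erosion report


@dataclass
class ErosionReport:
    genome_id: str
    n_orfs: int
    n_pseudogenes: int
    pseudogene_fraction: float  # percent
    coding_density_with_pseudo: float  # percent of genome bp
    coding_density_without_pseudo: float
    per_replicon_pseudogene_capacity: dict[str, float] = field(default_factory=dict)
    cog_counts_with: dict[str, int] = field(default_factory=dict)
    cog_counts_without: dict[str, int] = field(default_factory=dict)
    cog_percent_change: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": self.genome_id,
                    "n_orfs": self.n_orfs,
                    "n_pseudogenes": self.n_pseudogenes,
                    "pseudogene_fraction": self.pseudogene_fraction,
                    "coding_density_with_pseudo": self.coding_density_with_pseudo,
                    "coding_density_without_pseudo": self.coding_density_without_pseudo,
                }
            ]
        )


def pseudogene_fraction(n_pseudogenes: int, n_orfs: int) -> float:
    """Percent of ORFs flagged as pseudogenes (e.g. 1613/3676 → 43.87)."""
    if n_orfs <= 0:
        raise ValueError("n_orfs must be positive")
    if n_pseudogenes > n_orfs:
        raise ValueError("more pseudogenes than ORFs")
    return 100.0 * n_pseudogenes / n_orfs


def _covered_bp(genes: list[GeneRecord], rep_len: dict[str, int]) -> int:
    """Union length of gene intervals (overlapping genes counted once)."""
    total = 0
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_rep.setdefault(g.replicon_id, []).append((g.start, g.end))
    for rep_id, ivals in by_rep.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total


def erosion_report(genome: Genome) -> ErosionReport:
    """Genome-erosion metrics from resolved pseudogene flags.

    Coding densities are union-covered gene bp over genome bp, with and
    without pseudogenes. Per-replicon pseudogene coding capacity is
    pseudogene bp over total gene bp on that replicon. COG percent change is
    100·(with − without)/with per category.
    """
    rep_len = {r.id: len(r) for r in genome.replicons}
    size = genome.size
    genes = genome.genes
    n_orfs = len(genes)
    pseudo = [g for g in genes if g.is_pseudogene]
    intact = [g for g in genes if not g.is_pseudogene]
    if n_orfs == 0:
        import warnings

        warnings.warn(f"genome {genome.genome_id}: no genes; densities set to 0")
        return ErosionReport(genome.genome_id, 0, 0, 0.0, 0.0, 0.0)

    cd_with = 100.0 * _covered_bp(genes, rep_len) / size
    cd_without = (100.0 * _covered_bp(intact, rep_len) / size) if intact else 0.0

    per_rep: dict[str, float] = {}
    for rep in genome.replicons:
        total_gene_bp = sum(len(g) for g in genes if g.replicon_id == rep.id)
        pseudo_bp = sum(len(g) for g in pseudo if g.replicon_id == rep.id)
        per_rep[rep.id] = 100.0 * pseudo_bp / total_gene_bp if total_gene_bp else 0.0

    cog_with: dict[str, int] = {}
    cog_without: dict[str, int] = {}
    for g in genes:
        if g.cog_category:
            cog_with[g.cog_category] = cog_with.get(g.cog_category, 0) + 1
            if not g.is_pseudogene:
                cog_without[g.cog_category] = cog_without.get(g.cog_category, 0) + 1
    cog_change = {
        cat: 100.0 * (cog_with[cat] - cog_without.get(cat, 0)) / cog_with[cat]
        for cat in cog_with
    }

    return ErosionReport(
        genome_id=genome.genome_id,
        n_orfs=n_orfs,
        n_pseudogenes=len(pseudo),
        pseudogene_fraction=pseudogene_fraction(len(pseudo), n_orfs),
        coding_density_with_pseudo=cd_with,
        coding_density_without_pseudo=cd_without,
        per_replicon_pseudogene_capacity=per_rep,
        cog_counts_with=cog_with,
        cog_counts_without=cog_without,
        cog_percent_change=cog_change,
    )


def gene_integrity(genomes: list[Genome], gene_label: str) -> pd.DataFrame:
    """Per-genome integrity of one labeled gene (e.g. "polA").

    Length ratio is against the longest copy observed in any genome; genomes
    without the gene report status "absent". Useful to spot lineage-specific
    truncation/pseudogenization of DNA-repair genes.
    """
    rows = []
    longest = 0
    found = False
    for genome in genomes:
        for g in genome.genes:
            if g.product_label == gene_label:
                found = True
                longest = max(longest, len(g))
    if not found:
        raise ValueError(f"gene label {gene_label!r} found in no genome")
    for genome in genomes:
        copies = [g for g in genome.genes if g.product_label == gene_label]
        if not copies:
            rows.append(
                {"genome_id": genome.genome_id, "length_ratio": float("nan"),
                 "is_pseudogene": False, "status": "absent"}
            )
        else:
            g = max(copies, key=len)
            rows.append(
                {"genome_id": genome.genome_id, "length_ratio": len(g) / longest,
                 "is_pseudogene": g.is_pseudogene, "status": "present"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frameshift detection


@dataclass
class FrameshiftReport:
    pair: tuple[str, str]
    indels: list[tuple[int, int, str]]  # (position in cds_a, length, "ins"/"del")
    net_frame_shift: int  # (insertions − deletions) mod 3
    premature_stop: bool
    stop_position: Optional[int] = None  # codon index in cds_a's frame
    alignment_text: str = ""


_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def detect_frameshift(cds_a: str, cds_b: str, ids: tuple[str, str] = ("a", "b")) -> FrameshiftReport:
    """Align two CDS globally and extract indel events and frame consequences.

    Affine gap scoring (match +1, mismatch −1, open −5, extend −1) so a
    contiguous 37 bp deletion is one event. ``net_frame_shift`` is the total
    inserted minus deleted length mod 3. ``premature_stop`` is true iff
    translating cds_b in cds_a's frame (bacterial code) hits a stop before
    90% of cds_a's length.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(cds_a.upper(), cds_b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    indels: list[tuple[int, int, str]] = []
    # gaps between consecutive aligned blocks
    prev_a_end, prev_b_end = 0, 0
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        if a_s > prev_a_end:  # cds_a has extra sequence → deletion in cds_b
            indels.append((prev_a_end + 1, a_s - prev_a_end, "del"))
        if b_s > prev_b_end:  # cds_b has extra sequence → insertion
            indels.append((prev_a_end + 1, b_s - prev_b_end, "ins"))
        prev_a_end, prev_b_end = a_e, b_e
    if len(cds_a) > prev_a_end:
        indels.append((prev_a_end + 1, len(cds_a) - prev_a_end, "del"))
    if len(cds_b) > prev_b_end:
        indels.append((prev_a_end + 1, len(cds_b) - prev_b_end, "ins"))

    ins = sum(l for _, l, t in indels if t == "ins")
    dels = sum(l for _, l, t in indels if t == "del")
    net = (ins - dels) % 3

    stop_pos = None
    prot = str(Seq(cds_b[: len(cds_b) - len(cds_b) % 3]).translate(table=11))
    star = prot.find("*")
    # ignore the natural terminal stop
    if star != -1 and star < len(prot) - 1 and (star + 1) * 3 < 0.9 * len(cds_a):
        stop_pos = star
    return FrameshiftReport(
        pair=ids,
        indels=indels,
        net_frame_shift=net,
        premature_stop=stop_pos is not None,
        stop_position=stop_pos,
        alignment_text=str(aln),
    )


def erosion_table(reports: list[ErosionReport]) -> pd.DataFrame:
    """One row per genome; per-replicon capacities flattened as extra rows."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
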