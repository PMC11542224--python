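"""End-to-end orchestration: simulate or load genomes, run every analysis
stage, and classify the evolutionary scenario.

Stage order mirrors the inference chain: pseudogene calling and erosion
metrics → orthology with a pseudogene/putative-HGT-excluded single-copy core
→ p-distances and neighbor-joining trees (genome-wide core and BGC gene set)
→ k-mer composition anomaly of the BGC → ANI/AF species clustering →
host–symbiont congruence and minimum lifestyle transitions → scenario call.

The scenario decision rule:

* no eroded BGC-carrying symbionts detected → ``ambiguous``;
* symbionts monophyletic AND host–symbiont congruence ≥ floor →
  ``single_acquisition_codiversification``;
* symbionts non-monophyletic OR ≥ 2 minimum transitions →
  ``multiple_independent_acquisitions``;
* anything else → ``ambiguous``.

All artifacts are written as TSV/Newick/JSON with a sha256 manifest; reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import erosion as ero
from . import orthology, phylo, relatedness
from .composition import bgc_anomaly_score
from .io_model import (
    Genome,
    IntervalSet,
    read_genome,
    read_hit_table,
    read_intervals_bed,
)
from .synthetic_data import SimConfig, SimResult, simulate_dataset

SINGLE = "single_acquisition_codiversification"
MULTIPLE = "multiple_independent_acquisitions"
AMBIGUOUS = "ambiguous"


@dataclass
class PipelineConfig:
    """Thresholds and inputs for one pipeline run.

    Either ``sim`` (a :class:`SimConfig`) or ``input_dir`` (a directory laid
    out like :func:`erosym.synthetic_data.write_dataset` output) must be set.
    """

    sim: Optional[SimConfig] = None
    input_dir: Optional[str] = None
    length_fraction_threshold: float = 0.8
    pident_floor: float = 50.0
    native_taxon: str = "Burkholderia"
    prevalence_threshold: float = 0.90
    exclude_hgt_from_core: bool = True
    ani_cutoff: float = 95.0
    af_cutoff: float = 60.0
    congruence_floor: float = 0.9
    eroded_fraction_threshold: float = 5.0  # % pseudogenes marking an eroded genome
    anomaly_window: int = 4000  # sized to simulator-scale genomes; use 20000 for MAGs
    anomaly_step: int = 2000
    kmer_k: int = 5
    n_bootstrap: int = 0
    jc_correction: bool = True
    min_core_loci: int = 3  # walk the prevalence ladder until this many loci


@dataclass
class ScenarioCall:
    call: str
    monophyly_of_bgc_symbionts: Optional[bool]
    fitch_transitions: Optional[int]
    host_symbiont_congruence: Optional[float]
    erosion_dispersion: Optional[float]
    bgc_anomaly_percentiles: dict[str, float] = field(default_factory=dict)
    rationale: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def classify_scenario(
    monophyly: Optional[bool],
    fitch_transitions: Optional[int],
    congruence: Optional[float],
    n_eroded_symbionts: int,
    congruence_floor: float = 0.9,
) -> tuple[str, list[str]]:
    """Apply the decision rule; returns (call, rationale strings)."""
    rationale: list[str] = []
    if n_eroded_symbionts == 0:
        return AMBIGUOUS, ["no eroded symbionts detected"]
    if monophyly and congruence is not None and congruence >= congruence_floor:
        rationale.append(
            f"eroded symbionts monophyletic and host congruence "
            f"{congruence:.3f} >= {congruence_floor}"
        )
        return SINGLE, rationale
    if (monophyly is not None and not monophyly) or (
        fitch_transitions is not None and fitch_transitions >= 2
    ):
        if monophyly is not None and not monophyly:
            rationale.append("eroded symbionts do not form a monophyletic clade")
        if fitch_transitions is not None and fitch_transitions >= 2:
            rationale.append(
                f"minimum of {fitch_transitions} independent transitions to the "
                "symbiotic lifestyle"
            )
        return MULTIPLE, rationale
    rationale.append("evidence does not separate the scenarios")
    return AMBIGUOUS, rationale


# ---------------------------------------------------------------------------
# Input loading


@dataclass
class DatasetInputs:
    genomes: list[Genome]
    hit_tables: dict[str, list]
    host_tree_newick: Optional[str]
    bgc_intervals: dict[str, IntervalSet]
    symbiont_to_host: dict[str, str]


def load_dataset(indir) -> DatasetInputs:
    """Load a dataset directory (FASTA/GFF3/hit tables/trees/BED intervals).

    Symbiont→host tip mapping is read from ``mapping.tsv`` (symbiont_id,
    host_id) when present, else inferred from ``sym_<host>`` genome ids.
    """
    indir = Path(indir)
    genomes = []
    hit_tables = {}
    bgc = {}
    for fa in sorted(indir.glob("*.fasta")):
        gid = fa.stem
        gff = indir / f"{gid}.gff3"
        if not gff.exists():
            raise FileNotFoundError(f"stage input missing: no GFF3 for {gid}")
        genomes.append(read_genome(fa, gff, genome_id=gid))
        hits = indir / f"{gid}.hits.tsv"
        hit_tables[gid] = read_hit_table(hits) if hits.exists() else []
        bed = indir / f"{gid}.bgc.bed"
        if bed.exists():
            bgc[gid] = read_intervals_bed(bed)
    if not genomes:
        raise FileNotFoundError(f"stage input missing: no genomes in {indir}")
    host_nwk = None
    ht = indir / "host_tree.nwk"
    if ht.exists():
        host_nwk = ht.read_text().strip()
    mapping = {}
    mp = indir / "mapping.tsv"
    if mp.exists():
        df = pd.read_csv(mp, sep="\t")
        mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    else:
        for g in genomes:
            if g.genome_id.startswith("sym_"):
                mapping[g.genome_id] = g.genome_id[4:]
    return DatasetInputs(genomes, hit_tables, host_nwk, bgc, mapping)


def _inputs_from_sim(result: SimResult) -> DatasetInputs:
    return DatasetInputs(
        genomes=result.genomes,
        hit_tables=result.hit_tables,
        host_tree_newick=result.truth.true_host_tree,
        bgc_intervals=result.truth.bgc_intervals,
        symbiont_to_host=result.truth.symbiont_to_host,
    )


def _translate(dna: str) -> str:
    """Bacterial-code translation of the annotated CDS; stops become X."""
    trimmed = dna[: len(dna) - len(dna) % 3]
    prot = str(Seq(trimmed).translate(table=11)).rstrip("*").replace("*", "X")
    return prot if prot else "X"


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: PipelineConfig, outdir=None) -> ScenarioCall:
    """Execute every stage and classify the scenario.

    When ``outdir`` is given, all stage artifacts plus a sha256 manifest are
    written there; the run is fully deterministic for a fixed config.
    """
    if (config.sim is None) == (config.input_dir is None):
        raise ValueError("exactly one of sim / input_dir must be set")
    if config.sim is not None:
        data = _inputs_from_sim(simulate_dataset(config.sim))
        native_taxon = config.sim.native_taxon
    else:
        data = load_dataset(config.input_dir)
        native_taxon = config.native_taxon

    artifacts: dict[str, str] = {}

    # --- stage: erosion ----------------------------------------------------
    reports = []
    pseudo_ids: set[str] = set()
    hgt_rows = []
    hgt_ids: set[str] = set()
    for genome in data.genomes:
        hits = data.hit_tables.get(genome.genome_id, [])
        ero.apply_pseudogene_calls(genome, hits, config.length_fraction_threshold)
        pseudo_ids |= {g.gene_id for g in genome.genes if g.is_pseudogene}
        for h in hits:
            cls = ero.classify_hgt(h, native_taxon, config.pident_floor)
            hgt_rows.append(
                {"genome_id": genome.genome_id, "gene_id": h.gene_id, "class": cls}
            )
            if cls == ero.PUTATIVE_HGT:
                hgt_ids.add(h.gene_id)
        reports.append(ero.erosion_report(genome))
    erosion_df = ero.erosion_table(reports)
    hgt_df = pd.DataFrame(hgt_rows, columns=["genome_id", "gene_id", "class"])

    # focal set: eroded genomes that carry the BGC
    frac = {r.genome_id: r.pseudogene_fraction for r in reports}
    focal = sorted(
        gid
        for gid in frac
        if frac[gid] >= config.eroded_fraction_threshold and gid in data.bgc_intervals
    )

    # --- stage: orthology --------------------------------------------------
    # pseudogenes are removed from each genome before orthology inference;
    # putative-HGT genes are excluded at core selection
    proteomes = {
        g.genome_id: {
            gene.gene_id: _translate(g.gene_sequence(gene))
            for gene in g.genes
            if not gene.is_pseudogene
        }
        for g in data.genomes
    }
    table = orthology.cluster_orthogroups(proteomes)
    exclude = hgt_ids if config.exclude_hgt_from_core else set()

    seq_of = {
        (g.genome_id, gene.gene_id): g.gene_sequence(gene)
        for g in data.genomes
        for gene in g.genes
    }

    def usable_loci(core_set: set[str]) -> dict[str, dict[str, str]]:
        out = {}
        for og in sorted(core_set):
            seqs = {
                gid: seq_of[(gid, genes[0])] for gid, genes in table.members[og].items()
            }
            if len({len(s) for s in seqs.values()}) == 1 and len(seqs) >= 4:
                out[og] = seqs
        return out

    # prevalence ladder: start at the configured threshold and relax until
    # enough single-copy core loci support a tree
    ladder = [config.prevalence_threshold] + [
        t for t in (0.8, 0.7, 0.6, 0.5, 0.4, 0.3) if t < config.prevalence_threshold
    ]
    core: set[str] = set()
    loci: dict[str, dict[str, str]] = {}
    prevalence_used = ladder[0]
    for thr in ladder:
        cand = orthology.select_core(
            table, thr, single_copy_only=True, exclude_gene_ids=exclude
        )
        cand_loci = usable_loci(cand)
        if len(cand_loci) >= len(loci):
            core, loci, prevalence_used = cand, cand_loci, thr
        if len(cand_loci) >= config.min_core_loci:
            break
    shared_df, _ = orthology.shared_matrix(table)

    # --- stage: core trees --------------------------------------------------
    if len(loci) < 1:
        raise RuntimeError("stage 'phylogeny' has no usable core loci")
    if config.n_bootstrap > 0:
        symbiont_tree = phylo.bootstrap_support(
            loci, n_replicates=config.n_bootstrap, seed=0,
            jc_correction=config.jc_correction,
        )
    else:
        symbiont_tree = phylo.nj_from_pdistance(loci, jc_correction=config.jc_correction)

    # BGC gene tree over carriers (orthogroups overlapping a BGC interval)
    bgc_tree = None
    carrier_ids = sorted(data.bgc_intervals)
    if len(carrier_ids) >= 3:
        gene_lookup = {
            (g.genome_id, gene.gene_id): gene for g in data.genomes for gene in g.genes
        }
        bgc_loci = {}
        for og, by_genome in sorted(table.members.items()):
            in_bgc = False
            for gid, genes in by_genome.items():
                ival = data.bgc_intervals.get(gid)
                if ival is None:
                    continue
                gene = gene_lookup[(gid, genes[0])]
                if ival.covers(gene.replicon_id, gene.start):
                    in_bgc = True
                    break
            if not in_bgc:
                continue
            seqs = {
                gid: seq_of[(gid, genes[0])]
                for gid, genes in by_genome.items()
                if gid in data.bgc_intervals and len(genes) == 1
            }
            if len(seqs) >= 3 and len({len(s) for s in seqs.values()}) == 1:
                bgc_loci[og] = seqs
        if bgc_loci:
            try:
                bgc_tree = phylo.nj_from_pdistance(bgc_loci)
            except ValueError:
                bgc_tree = None

    # --- stage: composition anomaly ----------------------------------------
    anomalies: dict[str, float] = {}
    for g in data.genomes:
        ival = data.bgc_intervals.get(g.genome_id)
        if ival is None:
            continue
        try:
            anomalies[g.genome_id] = bgc_anomaly_score(
                g, ival, k=config.kmer_k,
                window=config.anomaly_window, step=config.anomaly_step,
            )
        except ValueError:
            anomalies[g.genome_id] = float("nan")

    # --- stage: ANI / species ----------------------------------------------
    ani_results = relatedness.all_pairs_ani(data.genomes)
    species = relatedness.species_clusters(
        ani_results,
        genome_ids=sorted(g.genome_id for g in data.genomes),
        ani_cutoff=config.ani_cutoff,
        af_cutoff=config.af_cutoff,
    )

    # --- stage: congruence, monophyly, transitions --------------------------
    monophyly = fitch = congruence = None
    tree_tips = set(phylo.tip_labels(symbiont_tree))
    focal_in_tree = [g for g in focal if g in tree_tips]
    if focal_in_tree and 2 <= len(focal_in_tree) <= len(tree_tips) - 1:
        monophyly = phylo.is_monophyletic(symbiont_tree, set(focal_in_tree))
        states = {
            lbl: ("symbiotic" if lbl in focal_in_tree else "free") for lbl in tree_tips
        }
        fitch = phylo.fitch_min_transitions(symbiont_tree, states)
    elif len(focal_in_tree) == 1:
        monophyly, fitch = True, 1
    if data.host_tree_newick and focal_in_tree:
        mapping = {s: h for s, h in data.symbiont_to_host.items() if s in focal_in_tree}
        if len(mapping) >= 4:
            host_tree = phylo.tree_from_newick(data.host_tree_newick)
            rep = phylo.tanglegram_congruence(
                symbiont_tree, host_tree, mapping, "symbionts", "hosts"
            )
            congruence = rep.shared_bipartition_fraction

    disp = None
    if focal:
        vals = np.array([frac[g] for g in focal])
        disp = float(vals.std() / vals.mean()) if vals.mean() > 0 else 0.0

    call_name, rationale = classify_scenario(
        monophyly, fitch, congruence, len(focal), config.congruence_floor
    )
    call = ScenarioCall(
        call=call_name,
        monophyly_of_bgc_symbionts=monophyly,
        fitch_transitions=fitch,
        host_symbiont_congruence=congruence,
        erosion_dispersion=disp,
        bgc_anomaly_percentiles=anomalies,
        rationale=rationale,
    )

    # --- artifacts ----------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def emit(name: str, text: str) -> None:
            (outdir / name).write_text(text)
            artifacts[name] = hashlib.sha256(text.encode()).hexdigest()

        emit("erosion.tsv", erosion_df.to_csv(sep="\t", index=False))
        emit("hgt_calls.tsv", hgt_df.to_csv(sep="\t", index=False))
        emit("orthogroups.tsv", table.to_frame().to_csv(sep="\t", index=False))
        emit(
            "core_orthogroups.txt",
            f"# prevalence_threshold_used={prevalence_used}\n" + "\n".join(sorted(core)) + "\n",
        )
        emit("shared_matrix.tsv", shared_df.to_csv(sep="\t"))
        emit(
            "symbiont_tree.nwk",
            symbiont_tree.as_string(schema="newick", unquoted_underscores=True,
                                    suppress_rooting=True),
        )
        if bgc_tree is not None:
            emit(
                "bgc_tree.nwk",
                bgc_tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True),
            )
        emit(
            "composition_anomaly.tsv",
            "genome_id\tbgc_anomaly_percentile\n"
            + "".join(f"{k}\t{v:.4f}\n" for k, v in sorted(anomalies.items())),
        )
        emit(
            "ani.tsv",
            "genome_a\tgenome_b\tani\taf\tani_ab\tani_ba\taf_ab\taf_ba\n"
            + "".join(
                f"{r.genome_a}\t{r.genome_b}\t{r.ani:.4f}\t{r.af:.4f}\t"
                f"{r.ani_ab:.4f}\t{r.ani_ba:.4f}\t{r.af_ab:.4f}\t{r.af_ba:.4f}\n"
                for r in ani_results
            ),
        )
        emit(
            "species.tsv",
            "genome_id\tspecies_id\n"
            + "".join(f"{k}\t{v}\n" for k, v in sorted(species.items())),
        )
        emit("scenario_call.json", call.to_json() + "\n")
        manifest = json.dumps(artifacts, indent=2, sort_keys=True) + "\n"
        (outdir / "manifest.json").write_text(manifest)

    return call
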