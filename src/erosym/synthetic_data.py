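"""Genome-evolution simulator for symbiont acquisition and erosion.

The generative model mirrors the inference problem: an ancestral full-sized
bacterial genome carries a horizontally acquired biosynthetic gene cluster
(BGC) whose nucleotide composition differs from the chromosomal background.
Free-living descendants diverge neutrally (Jukes–Cantor) and usually lose
the BGC; host-restricted (symbiotic) lineages evolve faster (an erosion rate
multiplier, further amplified once the DNA-repair gene labeled "polA" is
pseudogenized), accumulate pseudogenes as a per-gene Poisson process
(pseudogenization truncates the annotated gene to a uniform fraction of its
length), and delete existing pseudogenes with a per-unit-time probability —
the canonical pseudogenize-then-delete trajectory of genome erosion.

Two acquisition scenarios are supported:

* ``codiversification`` — one ancestral acquisition; the symbiont is
  transmitted down the host tree, so the true symbiont tree restricted to
  symbiotic tips equals the host tree.
* ``independent_acquisitions`` — ``n_acquisitions`` separate host-restricted
  lineages start from phylogenetically independent donors in the free-living
  pool (donor sets are rejection-sampled so the minimum number of
  lifestyle transitions on the true tree equals ``n_acquisitions``).

Everything is driven by a single numpy Generator, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    GeneRecord,
    Genome,
    HitRecord,
    IntervalSet,
    Replicon,
    write_genome,
    write_hit_table,
    write_intervals_bed,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CODIVERSIFICATION = "codiversification"
INDEPENDENT = "independent_acquisitions"

_COG_POOL = list("JKLMNEFGHICPTOUVQRS")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset. Rates are per unit tree height."""

    seed: int = 0
    n_hosts: int = 8
    n_free_living: int = 6
    n_ancestral_genes: int = 120
    mean_gene_len: int = 300  # bp, codon-rounded
    genome_gc: float = 0.59  # chromosomal background GC fraction
    bgc_gc: float = 0.49  # donor signature of the acquired cluster
    bgc_n_genes: int = 9  # lgaA..lgaI-sized cluster
    bgc_mean_gene_len: int = 600
    scenario: str = INDEPENDENT
    n_acquisitions: int = 4
    sub_rate_free: float = 0.02  # substitutions/site/unit height
    erosion_rate_multiplier: float = 3.0
    pseudogenization_rate: float = 1.5  # events/gene/unit height (symbiotic)
    deletion_prob: float = 0.15  # per pseudogene per unit height
    repair_loss_multiplier: float = 2.0  # applied after polA pseudogenization
    host_tree_height: float = 1.0
    bgc_loss_prob_free: float = 1.0  # free-living tips secondarily lose the BGC
    hgt_title_fraction: float = 0.05  # genes given a foreign-taxon hit title
    native_taxon: str = "Burkholderia"
    foreign_taxon: str = "Pseudomonas sp."
    mean_spacer_len: int = 120
    min_donor_branch: float = 0.25  # established associations: donors sit on long tip branches
    donor_min_edge_sep: float = 0.05  # diverse pool: donor-donor paths cross only resolvable edges
    force_polA_pseudogenization: bool = False

    def validate(self) -> None:
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be >= 2")
        if not (0.0 < self.genome_gc < 1.0 and 0.0 < self.bgc_gc < 1.0):
            raise ValueError("GC fractions must be in (0, 1)")
        for name in (
            "sub_rate_free",
            "pseudogenization_rate",
            "deletion_prob",
            "host_tree_height",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.erosion_rate_multiplier < 1 or self.repair_loss_multiplier < 1:
            raise ValueError("rate multipliers must be >= 1")
        if self.scenario not in (CODIVERSIFICATION, INDEPENDENT):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == INDEPENDENT:
            if not (1 <= self.n_acquisitions <= self.n_hosts):
                raise ValueError("need 1 <= n_acquisitions <= n_hosts")
        elif self.n_acquisitions != 1:
            raise ValueError("codiversification implies n_acquisitions == 1")


# ---------------------------------------------------------------------------
# Lightweight tree used during simulation


class _Node:
    __slots__ = ("label", "children", "length", "symbiotic", "host")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.children: list[_Node] = []
        self.length = float(length)
        self.symbiotic = False
        self.host: str | None = None

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.length:.10g}"


def _yule(n_tips: int, height: float, rng: np.random.Generator, prefix: str) -> _Node:
    """Ultrametric pure-birth tree with ``n_tips`` tips scaled to ``height``."""
    root = _Node(length=0.0)
    a, b = _Node(), _Node()
    root.children = [a, b]
    births = {id(root): 0.0}
    active = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(0, k))
        node, _birth = active.pop(i)
        node.length = t - _birth
        c1, c2 = _Node(), _Node()
        node.children = [c1, c2]
        active.extend([(c1, t), (c2, t)])
    t_end = t + rng.exponential(1.0 / n_tips)
    for j, (node, birth) in enumerate(active):
        node.length = t_end - birth
        node.label = f"{prefix}{j + 1:02d}"
    # scale to requested height
    scale = height / t_end if t_end > 0 else 1.0
    stack = [root]
    while stack:
        nd = stack.pop()
        nd.length *= scale
        stack.extend(nd.children)
    return root


def high_signal_codiversification_config(seed: int = 0) -> SimConfig:
    """Codiversification conditions with enough phylogenetic signal that the
    host topology is recoverable from the symbiont core: a larger gene set,
    a higher base substitution rate, and milder pseudogenization so more
    single-copy core loci survive erosion."""
    return SimConfig(
        seed=seed,
        scenario=CODIVERSIFICATION,
        n_acquisitions=1,
        n_ancestral_genes=300,
        sub_rate_free=0.05,
        pseudogenization_rate=0.5,
    )


def simulate_host_tree(n_hosts: int, seed: int, height: float = 1.0) -> str:
    """Yule pure-birth host phylogeny as a Newick string (deterministic)."""
    if n_hosts < 2:
        raise ValueError("n_hosts must be >= 2")
    rng = np.random.default_rng(seed)
    return _yule(n_hosts, height, rng, prefix="host").newick()


def _donors_well_separated(root: _Node, hot: set[str], floor: float) -> bool:
    """True iff every internal edge on every donor–donor path is >= floor.

    Encodes "acquisitions from a diverse pool": each pair of donor lineages
    is separated by divergence deep enough to be phylogenetically resolvable.
    """
    parent: dict[int, _Node] = {}
    nodes = {}
    stack = [root]
    while stack:
        nd = stack.pop()
        nodes[id(nd)] = nd
        for c in nd.children:
            parent[id(c)] = nd
            stack.append(c)
    tips = {lf.label: lf for lf in root.leaves() if lf.label in hot}

    def ancestors(nd):
        out = [nd]
        while id(nd) in parent:
            nd = parent[id(nd)]
            out.append(nd)
        return out

    labels = sorted(tips)
    for i, a in enumerate(labels):
        anc_a = ancestors(tips[a])
        set_a = {id(x) for x in anc_a}
        for b in labels[i + 1 :]:
            anc_b = ancestors(tips[b])
            mrca = next(x for x in anc_b if id(x) in set_a)
            path = []
            for nd in anc_a:
                if nd is mrca:
                    break
                path.append(nd)
            for nd in anc_b:
                if nd is mrca:
                    break
                path.append(nd)
            for nd in path:
                if nd.children and nd.length < floor:  # internal edge too short
                    return False
    return True


def _min_transitions(root: _Node, hot: set[str]) -> int:
    """Tiny Hartigan parsimony count for a binary labeling (truth machinery)."""
    changes = 0

    def rec(node: _Node) -> frozenset:
        nonlocal changes
        if not node.children:
            return frozenset([node.label in hot])
        votes: dict[bool, int] = {}
        for c in node.children:
            for s in rec(c):
                votes[s] = votes.get(s, 0) + 1
        k = max(votes.values())
        changes += len(node.children) - k
        return frozenset(s for s, v in votes.items() if v == k)

    rec(root)
    return changes


# ---------------------------------------------------------------------------
# Ancestral genome


@dataclass
class _AncGene:
    gene_id: str
    product: str
    cog: str
    seq: np.ndarray  # base codes 0..3
    is_bgc: bool
    foreign_title: bool


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _make_ancestor(cfg: SimConfig, rng: np.random.Generator):
    genes: list[_AncGene] = []
    pola_idx = cfg.n_ancestral_genes // 2
    for i in range(cfg.n_ancestral_genes):
        L = 3 * max(20, int(round(rng.uniform(0.5, 1.5) * cfg.mean_gene_len / 3)))
        product = "polA" if i == pola_idx else f"protein_{i:04d}"
        cog = "L" if i == pola_idx else _COG_POOL[int(rng.integers(0, len(_COG_POOL)))]
        genes.append(
            _AncGene(
                gene_id=f"g{i:04d}",
                product=product,
                cog=cog,
                seq=_random_seq(rng, L, cfg.genome_gc),
                is_bgc=False,
                foreign_title=bool(rng.random() < cfg.hgt_title_fraction),
            )
        )
    insert_at = cfg.n_ancestral_genes // 3
    bgc = []
    for j in range(cfg.bgc_n_genes):
        L = 3 * max(40, int(round(rng.uniform(0.6, 1.4) * cfg.bgc_mean_gene_len / 3)))
        bgc.append(
            _AncGene(
                gene_id=f"lga{j:02d}",
                product=f"lga{chr(ord('A') + j) if j < 26 else j}",
                cog="Q",
                seq=_random_seq(rng, L, cfg.bgc_gc),
                is_bgc=True,
                foreign_title=False,
            )
        )
    genes = genes[:insert_at] + bgc + genes[insert_at:]
    spacers = []
    for i in range(len(genes) + 1):
        # intergenic DNA inside the acquired cluster carries the donor signature
        within_bgc = insert_at + 1 <= i <= insert_at + cfg.bgc_n_genes - 1
        gc = cfg.bgc_gc if within_bgc else cfg.genome_gc
        length = int(rng.integers(cfg.mean_spacer_len // 2, cfg.mean_spacer_len * 3 // 2 + 1))
        spacers.append(_random_seq(rng, length, gc))
    return genes, spacers


# ---------------------------------------------------------------------------
# Lineage state and branch evolution

INTACT, PSEUDO, DELETED = 0, 1, 2


@dataclass
class _Lineage:
    seqs: list[np.ndarray]
    spacers: list[np.ndarray]
    ann_len: np.ndarray  # annotated length per gene (bp)
    status: np.ndarray  # 0 intact / 1 pseudogene / 2 deleted
    pola_lost: bool = False

    def copy(self) -> "_Lineage":
        return _Lineage(
            [s.copy() for s in self.seqs],
            [s.copy() for s in self.spacers],
            self.ann_len.copy(),
            self.status.copy(),
            self.pola_lost,
        )


def _jc_p(expected_subs: float) -> float:
    """Probability a site differs after d expected substitutions (JC69)."""
    return 0.75 * (1.0 - np.exp(-4.0 * expected_subs / 3.0))


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> None:
    if p <= 0 or seq.size == 0:
        return
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n:
        seq[mask] = (seq[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4


def apply_erosion(
    status: np.ndarray,
    ann_len: np.ndarray,
    full_len: np.ndarray,
    lam: float,
    deletion_prob: float,
    duration: float,
    rng: np.random.Generator,
) -> None:
    """One erosion step over ``duration`` time units, in place.

    Intact genes are pseudogenized with probability 1 − exp(−λ·t) (Poisson
    waiting time), truncating the annotation to a U[0.1, 0.7] fraction.
    Pseudogenes existing at the start of the interval are deleted with
    probability 1 − exp(−deletion_prob·t); genes pseudogenized *within* the
    interval at time τ (truncated-exponential given the event) can also be
    deleted over the remaining t − τ — without this, terminal-branch
    pseudogenes could never be lost. All random draws happen
    unconditionally, so runs differing only in rates stay coupled: a higher
    deletion_prob deletes a superset of genes for the same seed.
    """
    n = status.size
    u_del = rng.random(n)
    u_ps = rng.random(n)
    fracs = rng.uniform(0.1, 0.7, size=n)
    u_tau = rng.random(n)
    u_del2 = rng.random(n)
    if duration <= 0:
        return
    was_pseudo = status == PSEUDO
    p_del = 1.0 - np.exp(-deletion_prob * duration)
    del_existing = was_pseudo & (u_del < p_del)

    intact = status == INTACT
    p_pseudo = 1.0 - np.exp(-lam * duration)
    new_pseudo = intact & (u_ps < p_pseudo)

    status[del_existing] = DELETED
    status[new_pseudo] = PSEUDO
    idx = np.where(new_pseudo)[0]
    ann_len[idx] = np.maximum(3, (np.floor(fracs[idx] * full_len[idx] / 3) * 3)).astype(int)
    if lam > 0 and idx.size:
        # event time within the interval, given that the event happened
        tau = -np.log1p(-u_tau[idx] * p_pseudo) / lam
        p_del2 = 1.0 - np.exp(-deletion_prob * (duration - tau))
        status[idx[u_del2[idx] < p_del2]] = DELETED


def _evolve_branch(
    lin: _Lineage,
    duration: float,
    symbiotic: bool,
    cfg: SimConfig,
    rng: np.random.Generator,
    pola_index: int,
) -> None:
    rate = cfg.sub_rate_free
    if symbiotic:
        rate *= cfg.erosion_rate_multiplier
        if lin.pola_lost:
            rate *= cfg.repair_loss_multiplier
    p = _jc_p(rate * duration)
    for i, s in enumerate(lin.seqs):
        if lin.status[i] != DELETED:
            _mutate(s, p, rng)
    for sp in lin.spacers:
        _mutate(sp, p, rng)
    if symbiotic:
        full_len = np.array([s.size for s in lin.seqs])
        apply_erosion(
            lin.status,
            lin.ann_len,
            full_len,
            cfg.pseudogenization_rate,
            cfg.deletion_prob,
            duration,
            rng,
        )
        if lin.status[pola_index] != INTACT:
            lin.pola_lost = True


# ---------------------------------------------------------------------------
# Scenario truth and results


@dataclass
class ScenarioTruth:
    scenario: str
    true_host_tree: str  # newick
    true_symbiont_tree: str  # newick over free-living + symbiotic tips
    acquisition_events: list[tuple[str, float]]
    gene_status: dict[str, dict[str, str]]  # genome -> gene -> intact/pseudogene/deleted
    bgc_intervals: dict[str, IntervalSet]
    lifestyles: dict[str, str]
    symbiont_to_host: dict[str, str]


@dataclass
class SimResult:
    config: SimConfig
    genomes: list[Genome]
    hit_tables: dict[str, list[HitRecord]]
    truth: ScenarioTruth
    ancestor_genes: dict[str, int]  # gene_id -> ancestral length (bp)


# ---------------------------------------------------------------------------
# Main simulation


def simulate_dataset(config: SimConfig) -> SimResult:
    """Simulate genomes, best-hit tables and ground truth for one scenario."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H = cfg.host_tree_height

    host_root = _yule(cfg.n_hosts, H, rng, prefix="host")
    host_newick = host_root.newick()
    host_labels = sorted(lf.label for lf in host_root.leaves())

    anc_genes, anc_spacers = _make_ancestor(cfg, rng)
    pola_index = next(i for i, g in enumerate(anc_genes) if g.product == "polA")
    root_lineage = _Lineage(
        seqs=[g.seq.copy() for g in anc_genes],
        spacers=[s.copy() for s in anc_spacers],
        ann_len=np.array([g.seq.size for g in anc_genes]),
        status=np.zeros(len(anc_genes), dtype=int),
    )

    acquisition_events: list[tuple[str, float]] = []
    symbiont_to_host: dict[str, str] = {}

    if cfg.scenario == INDEPENDENT:
        # phylogenetically independent, established acquisitions: donors on
        # sufficiently long terminal branches, minimum transition count equal
        # to n_acquisitions; resample the pool tree if a draw is infeasible
        pool = tips = hot = None
        for _ in range(200):
            pool = _yule(cfg.n_free_living + cfg.n_acquisitions, H, rng, prefix="lin")
            tips = sorted(pool.leaves(), key=lambda n: n.label)
            eligible = [i for i, t in enumerate(tips) if t.length >= cfg.min_donor_branch]
            if len(eligible) < cfg.n_acquisitions:
                continue
            for _ in range(200):
                donors = rng.choice(len(eligible), size=cfg.n_acquisitions, replace=False)
                cand = {tips[eligible[i]].label for i in donors}
                if _min_transitions(pool, cand) == cfg.n_acquisitions and _donors_well_separated(
                    pool, cand, cfg.donor_min_edge_sep
                ):
                    hot = cand
                    break
            if hot is not None:
                break
        if hot is None:
            raise RuntimeError("could not place phylogenetically independent acquisitions")
        hosts_for = rng.choice(cfg.n_hosts, size=cfg.n_acquisitions, replace=False)
        donor_tips = sorted(hot)
        for donor_label, hidx in zip(donor_tips, sorted(hosts_for)):
            host = host_labels[hidx]
            tip = next(t for t in tips if t.label == donor_label)
            tip.symbiotic = True
            tip.host = host
            tip.label = f"sym_{host}"
            symbiont_to_host[tip.label] = host
        free_idx = 1
        for t in tips:
            if not t.symbiotic:
                t.label = f"free{free_idx:02d}"
                free_idx += 1
        system_root = pool
    else:  # codiversification
        carrier = None
        for _ in range(200):
            pool = _yule(cfg.n_free_living + 1, H, rng, prefix="lin")
            tips = sorted(pool.leaves(), key=lambda n: n.label)
            eligible = [t for t in tips if t.length >= cfg.min_donor_branch]
            if eligible:
                carrier = eligible[int(rng.integers(0, len(eligible)))]
                break
        if carrier is None:
            raise RuntimeError("no terminal branch long enough for the ancestral acquisition")
        free_idx = 1
        for t in tips:
            if t is not carrier:
                t.label = f"free{free_idx:02d}"
                free_idx += 1
        # graft the host tree onto the carrier's terminal branch
        u = rng.uniform(0.15, 0.45)
        t_keep = carrier.length * u
        remainder = carrier.length - t_keep
        carrier.length = t_keep
        graft = _scaled_copy(host_root, remainder)
        for lf in graft.leaves():
            host = lf.label
            lf.label = f"sym_{host}"
            symbiont_to_host[lf.label] = host
        for nd in _iter_nodes(graft):
            nd.symbiotic = True
        carrier.children = graft.children
        carrier.label = None
        acquisition_events.append(("ancestral", float(H - remainder)))
        system_root = pool

    # --- evolve sequences down the system tree -----------------------------
    genome_states: dict[str, _Lineage] = {}
    tip_symbiotic: dict[str, bool] = {}

    def descend(node: _Node, lin: _Lineage, depth: float) -> None:
        if node.children:
            _evolve_branch(lin, node.length, node.symbiotic, cfg, rng, pola_index)
            for c in sorted(node.children, key=_sort_key):
                descend(c, lin.copy(), depth + node.length)
        else:
            if node.symbiotic and cfg.scenario == INDEPENDENT:
                # split the terminal branch at the acquisition time
                u = rng.uniform(0.1, 0.5)
                free_part = node.length * u
                sym_part = node.length - free_part
                _evolve_branch(lin, free_part, False, cfg, rng, pola_index)
                if cfg.force_polA_pseudogenization and lin.status[pola_index] == INTACT:
                    lin.status[pola_index] = PSEUDO
                    lin.ann_len[pola_index] = max(
                        3, int(0.3 * lin.seqs[pola_index].size // 3) * 3
                    )
                    lin.pola_lost = True
                acquisition_events.append((node.host, float(depth + free_part)))
                _evolve_branch(lin, sym_part, True, cfg, rng, pola_index)
            else:
                if (
                    node.symbiotic
                    and cfg.force_polA_pseudogenization
                    and lin.status[pola_index] == INTACT
                ):
                    lin.status[pola_index] = PSEUDO
                    lin.ann_len[pola_index] = max(
                        3, int(0.3 * lin.seqs[pola_index].size // 3) * 3
                    )
                    lin.pola_lost = True
                _evolve_branch(lin, node.length, node.symbiotic, cfg, rng, pola_index)
            genome_states[node.label] = lin
            tip_symbiotic[node.label] = node.symbiotic

    # root branch: evolve nothing above the root
    for child in sorted(system_root.children, key=_sort_key):
        descend(child, root_lineage.copy(), 0.0)

    # free-living BGC loss (secondary loss in the non-symbiotic clade)
    bgc_idx = np.array([i for i, g in enumerate(anc_genes) if g.is_bgc], dtype=int)
    for label in sorted(genome_states):
        if not tip_symbiotic[label] and rng.random() < cfg.bgc_loss_prob_free:
            genome_states[label].status[bgc_idx] = DELETED

    # --- emit genomes, hit tables, truth -----------------------------------
    genomes: list[Genome] = []
    hit_tables: dict[str, list[HitRecord]] = {}
    gene_status: dict[str, dict[str, str]] = {}
    bgc_intervals: dict[str, IntervalSet] = {}
    lifestyles: dict[str, str] = {}
    status_names = {INTACT: "intact", PSEUDO: "pseudogene", DELETED: "deleted"}

    for label in sorted(genome_states):
        lin = genome_states[label]
        parts: list[np.ndarray] = []
        genes: list[GeneRecord] = []
        hits: list[HitRecord] = []
        pos = 1
        bgc_lo, bgc_hi = None, None
        rep_id = f"{label}_chr"
        for i, anc in enumerate(anc_genes):
            sp = lin.spacers[i]
            parts.append(sp)
            pos += sp.size
            if lin.status[i] == DELETED:
                continue
            seq = lin.seqs[i]
            ann = int(lin.ann_len[i])
            start, end = pos, pos + ann - 1
            parts.append(seq)
            pos += seq.size
            is_pseudo = lin.status[i] == PSEUDO
            genes.append(
                GeneRecord(
                    gene_id=f"{label}_{anc.gene_id}",
                    replicon_id=rep_id,
                    start=start,
                    end=end,
                    strand="+",
                    is_pseudogene=is_pseudo,
                    cog_category=anc.cog,
                    product_label=anc.product,
                )
            )
            if anc.is_bgc:
                bgc_lo = start if bgc_lo is None else min(bgc_lo, start)
                bgc_hi = end if bgc_hi is None else max(bgc_hi, end)
            # best hit vs the unmutated ancestral copy
            diff = int((seq[:ann] != anc.seq[:ann]).sum())
            pident = 100.0 * (ann - diff) / ann
            taxon = cfg.foreign_taxon if anc.foreign_title else cfg.native_taxon
            hits.append(
                HitRecord(
                    gene_id=f"{label}_{anc.gene_id}",
                    subject_title=f"{taxon} {anc.product}",
                    percent_identity=round(pident, 2),
                    query_len_aa=max(1, ann // 3),
                    subject_len_aa=max(1, anc.seq.size // 3),
                )
            )
        parts.append(lin.spacers[-1])
        seq_str = _BASES[np.concatenate(parts)].tobytes().decode()
        genome = Genome(
            genome_id=label,
            replicons=[Replicon(rep_id, seq_str, topology="circular")],
            genes=genes,
            lifestyle_label="symbiotic" if tip_symbiotic[label] else "free_living",
        )
        genomes.append(genome)
        hit_tables[label] = hits
        gene_status[label] = {
            anc.gene_id: status_names[int(lin.status[i])]
            for i, anc in enumerate(anc_genes)
        }
        if bgc_lo is not None:
            bgc_intervals[label] = IntervalSet([(rep_id, bgc_lo, bgc_hi)])
        lifestyles[label] = genome.lifestyle_label

    truth = ScenarioTruth(
        scenario=cfg.scenario,
        true_host_tree=host_newick,
        true_symbiont_tree=system_root.newick(),
        acquisition_events=sorted(acquisition_events),
        gene_status=gene_status,
        bgc_intervals=bgc_intervals,
        lifestyles=lifestyles,
        symbiont_to_host=symbiont_to_host,
    )
    return SimResult(
        config=cfg,
        genomes=genomes,
        hit_tables=hit_tables,
        truth=truth,
        ancestor_genes={g.gene_id: int(g.seq.size) for g in anc_genes},
    )


def _sort_key(node: _Node):
    return min(lf.label for lf in node.leaves())


def _iter_nodes(root: _Node):
    stack = [root]
    while stack:
        nd = stack.pop()
        yield nd
        stack.extend(nd.children)


def _depth_of(root: _Node, target: _Node, acc: float = 0.0):
    if root is target:
        return acc + root.length
    for c in root.children:
        d = _depth_of(c, target, acc + root.length)
        if d is not None:
            return d
    return None


def _scaled_copy(root: _Node, new_height: float) -> _Node:
    """Deep copy of a tree rescaled to a new total height."""
    height = 0.0
    node, acc = root, 0.0
    # height of an ultrametric tree: follow any path to a leaf
    nd = root
    while nd.children:
        nd = nd.children[0]
        height += nd.length
    scale = new_height / height if height > 0 else 1.0

    def rec(nd: _Node) -> _Node:
        out = _Node(label=nd.label, length=nd.length * scale)
        out.children = [rec(c) for c in nd.children]
        return out

    out = rec(root)
    out.length = 0.0
    return out


# ---------------------------------------------------------------------------
# Emission to disk


def write_dataset(result: SimResult, outdir) -> dict[str, str]:
    """Write genomes (FASTA+GFF3), hit tables, truth tables, trees and the
    echoed config; returns a name → path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for genome in result.genomes:
        fa = outdir / f"{genome.genome_id}.fasta"
        gff = outdir / f"{genome.genome_id}.gff3"
        write_genome(genome, fa, gff)
        paths[f"fasta:{genome.genome_id}"] = str(fa)
        paths[f"gff3:{genome.genome_id}"] = str(gff)
        hits = result.hit_tables[genome.genome_id]
        ht = outdir / f"{genome.genome_id}.hits.tsv"
        write_hit_table(hits, ht)
        paths[f"hits:{genome.genome_id}"] = str(ht)
        ival = result.truth.bgc_intervals.get(genome.genome_id)
        if ival:
            bed = outdir / f"{genome.genome_id}.bgc.bed"
            write_intervals_bed(ival, bed)
            paths[f"bgc:{genome.genome_id}"] = str(bed)
    (outdir / "host_tree.nwk").write_text(result.truth.true_host_tree + "\n")
    (outdir / "symbiont_tree.nwk").write_text(result.truth.true_symbiont_tree + "\n")
    paths["host_tree"] = str(outdir / "host_tree.nwk")
    paths["symbiont_tree"] = str(outdir / "symbiont_tree.nwk")
    with open(outdir / "truth_gene_status.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tstatus\n")
        for gid in sorted(result.truth.gene_status):
            for gene, st in sorted(result.truth.gene_status[gid].items()):
                fh.write(f"{gid}\t{gene}\t{st}\n")
    paths["truth_gene_status"] = str(outdir / "truth_gene_status.tsv")
    cfg = dataclasses.asdict(result.config)
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    paths["config"] = str(outdir / "sim_config.json")
    return paths
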